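"""VariantSite table schema and VCF round-trip.

A call set is a pandas DataFrame with one row per (trio, site).  Per-member
evidence uses column prefixes ``fa_``/``mo_``/``ch_`` (father, mother,
child/proband).  On disk this is a VCFv4.2 file whose three sample columns
are FATHER, MOTHER and PROBAND, with the owning trio and cohort-level
annotations (transmission probability, cohort call rate, carrier count) in
INFO.  Positions are 1-based in memory and on disk; conversion to the
0-based half-open convention of the interval module happens at lookup.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

MEMBERS = ("fa", "mo", "ch")
MEMBER_FIELDS = [
    "gt", "qual", "refscore", "dp1", "dp2", "ref1", "alt1", "ref2", "alt2",
    "third", "fbc", "sdl", "pl0", "pl1", "pl2",
]
SITE_COLUMNS = (
    ["trio_id", "chrom", "pos", "ref", "alt", "call_rate", "carrier_count", "tp"]
    + [f"{m}_{f}" for m in MEMBERS for f in MEMBER_FIELDS]
)

_SAMPLE_NAMES = {"fa": "FATHER", "mo": "MOTHER", "ch": "PROBAND"}

_HEADER_LINES = [
    '##INFO=<ID=TRIO,Number=1,Type=String,Description="Owning trio id">',
    '##INFO=<ID=TP,Number=1,Type=Integer,Description="Phred-scaled transmission probability">',
    '##INFO=<ID=CR,Number=1,Type=Float,Description="Cohort call rate at this site">',
    '##INFO=<ID=CC,Number=1,Type=Integer,Description="Cohort carrier count at this site">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=QC,Number=1,Type=String,Description="Genotype quality class (HIGH or other)">',
    '##FORMAT=<ID=RS,Number=1,Type=Integer,Description="Reference score">',
    '##FORMAT=<ID=DP1,Number=1,Type=Integer,Description="Tier-1 read depth">',
    '##FORMAT=<ID=DP2,Number=1,Type=Integer,Description="Tier-2 read depth">',
    '##FORMAT=<ID=AD1,Number=2,Type=Integer,Description="Tier-1 ref,alt read counts">',
    '##FORMAT=<ID=AD2,Number=2,Type=Integer,Description="Tier-2 ref,alt read counts">',
    '##FORMAT=<ID=TAC,Number=1,Type=Integer,Description="Third-allele read count">',
    '##FORMAT=<ID=FBC,Number=1,Type=Integer,Description="Filtered basecalls">',
    '##FORMAT=<ID=SDL,Number=1,Type=Integer,Description="Reads with spanning deletions">',
    '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
]


def empty_sites() -> pd.DataFrame:
    return pd.DataFrame(columns=SITE_COLUMNS)


def write_vcf(sites: pd.DataFrame, path) -> None:
    """Write a call set as VCFv4.2 text (sorted by chrom, pos, trio)."""
    if len(sites):
        sites = sites.sort_values(["chrom", "pos", "trio_id"], kind="stable")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=denovotrio\n")
        chroms = sorted(sites["chrom"].unique()) if len(sites) else []
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        for line in _HEADER_LINES:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tFATHER\tMOTHER\tPROBAND\n"
        )
        fmt = "GT:QC:RS:DP1:DP2:AD1:AD2:TAC:FBC:SDL:PL"
        for row in sites.itertuples(index=False):
            d = row._asdict()
            info = (
                f"TRIO={d['trio_id']};TP={int(d['tp'])};"
                f"CR={d['call_rate']:.6g};CC={int(d['carrier_count'])}"
            )
            samples = []
            for m in MEMBERS:
                samples.append(
                    "{gt}:{qual}:{rs}:{dp1}:{dp2}:{r1},{a1}:{r2},{a2}:{tac}:{fbc}:{sdl}:{p0},{p1},{p2}".format(
                        gt=d[f"{m}_gt"], qual=d[f"{m}_qual"], rs=int(d[f"{m}_refscore"]),
                        dp1=int(d[f"{m}_dp1"]), dp2=int(d[f"{m}_dp2"]),
                        r1=int(d[f"{m}_ref1"]), a1=int(d[f"{m}_alt1"]),
                        r2=int(d[f"{m}_ref2"]), a2=int(d[f"{m}_alt2"]),
                        tac=int(d[f"{m}_third"]), fbc=int(d[f"{m}_fbc"]),
                        sdl=int(d[f"{m}_sdl"]), p0=int(d[f"{m}_pl0"]),
                        p1=int(d[f"{m}_pl1"]), p2=int(d[f"{m}_pl2"]),
                    )
                )
            fh.write(
                f"{d['chrom']}\t{int(d['pos'])}\t.\t{d['ref']}\t{d['alt']}\t.\tPASS\t"
                f"{info}\t{fmt}\t" + "\t".join(samples) + "\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read a call set written by :func:`write_vcf` back into a DataFrame."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            row = {
                "trio_id": rec.info["TRIO"],
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "call_rate": float(rec.info["CR"]),
                "carrier_count": int(rec.info["CC"]),
                "tp": int(rec.info["TP"]),
            }
            for m in MEMBERS:
                s = rec.samples[_SAMPLE_NAMES[m]]
                gt = s["GT"]
                row[f"{m}_gt"] = "./." if gt is None or gt[0] is None else f"{gt[0]}/{gt[1]}"
                row[f"{m}_qual"] = s["QC"]
                row[f"{m}_refscore"] = int(s["RS"])
                row[f"{m}_dp1"] = int(s["DP1"])
                row[f"{m}_dp2"] = int(s["DP2"])
                row[f"{m}_ref1"], row[f"{m}_alt1"] = (int(x) for x in s["AD1"])
                row[f"{m}_ref2"], row[f"{m}_alt2"] = (int(x) for x in s["AD2"])
                row[f"{m}_third"] = int(s["TAC"])
                row[f"{m}_fbc"] = int(s["FBC"])
                row[f"{m}_sdl"] = int(s["SDL"])
                pl = s["PL"]
                row[f"{m}_pl0"], row[f"{m}_pl1"], row[f"{m}_pl2"] = (int(x) for x in pl)
            rows.append(row)
    if not rows:
        return empty_sites()
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def site_keys(sites: pd.DataFrame) -> pd.Index:
    """(trio, chrom, pos, ref, alt) identity keys for set comparisons."""
    return pd.MultiIndex.from_frame(sites[["trio_id", "chrom", "pos", "ref", "alt"]])
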