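"""Parent-of-origin assignment for de novo mutations.

A DNM's origin is determined by combining two phase sources:

1. *Transmission phasing* — at a nearby heterozygous child site, Mendelian
   logic on the trio genotypes may determine uniquely which child allele
   came from which parent (a phase-informative site).
2. *Read-backed phasing* — proband fragments (read pairs / molecules)
   co-observing the DNM allele and informative-site alleles tie them to the
   same physical haplotype.

If the DNM allele sits on the haplotype carrying a paternally transmitted
allele (and no maternally transmitted allele in the same block), the DNM is
paternal, and vice versa; conflicts or the absence of an informative site
leave it undetermined.  Informative sites are only eligible within +/-20 kb
of the DNM.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 20_000


@dataclass(frozen=True)
class TransmissionResult:
    """Which child allele came from which parent at one biallelic site."""

    paternal_allele: str | None
    maternal_allele: str | None
    status: str  # "phased" | "ambiguous" | "mendelian_violation"


def transmission_phase(
    father_gt: tuple[str, str] | None,
    mother_gt: tuple[str, str] | None,
    child_gt: tuple[str, str] | None,
) -> TransmissionResult:
    """Assign the child's two alleles to parents by Mendelian logic.

    Returns ``ambiguous`` when the assignment is not unique (e.g. all three
    members heterozygous for the same alleles) or any genotype is missing;
    ``mendelian_violation`` when no consistent assignment exists.
    """
    if father_gt is None or mother_gt is None or child_gt is None:
        return TransmissionResult(None, None, "ambiguous")
    a, b = child_gt
    assignments = set()
    for pat, mat in ((a, b), (b, a)):
        if pat in father_gt and mat in mother_gt:
            assignments.add((pat, mat))
    if not assignments:
        return TransmissionResult(None, None, "mendelian_violation")
    if len(assignments) > 1:
        return TransmissionResult(None, None, "ambiguous")
    pat, mat = assignments.pop()
    return TransmissionResult(pat, mat, "phased")


@dataclass
class HaplotypeBlock:
    """Connected set of sites with a relative phase between their alleles.

    ``phase`` maps position -> {allele: haplotype index 0/1}.  Haplotype 0
    is the haplotype carrying the first-seen allele of the anchor site.
    """

    positions: list[int]
    phase: dict[int, dict[str, int]]


def build_blocks(fragments: list[list[tuple[int, str]]]) -> list[HaplotypeBlock]:
    """Assemble haplotype blocks from proband fragments by majority vote.

    Two sites land in the same block when some fragment covers both; the
    relative phase between adjacent sites is the majority orientation over
    the fragments covering the pair, and a tied vote splits the block at
    that junction.
    """
    # collect per-site observed alleles and pairwise co-occurrence votes
    alleles: dict[int, list[str]] = defaultdict(list)
    votes: dict[tuple[int, int], dict[tuple[str, str], int]] = defaultdict(lambda: defaultdict(int))
    for frag in fragments:
        seen = sorted(frag)
        for pos, al in seen:
            if al not in alleles[pos]:
                alleles[pos].append(al)
        for (p1, a1), (p2, a2) in zip(seen, seen[1:]):
            if p1 != p2:
                votes[(p1, p2)][(a1, a2)] += 1

    # resolve each adjacent pair: cis (first alleles together) vs trans
    edges: dict[tuple[int, int], bool] = {}  # True => first-seen alleles are in cis
    for (p1, p2), tally in votes.items():
        a1 = alleles[p1][0]
        a2 = alleles[p2][0]
        cis = sum(n for (x, y), n in tally.items() if (x == a1) == (y == a2))
        trans = sum(n for (x, y), n in tally.items() if (x == a1) != (y == a2))
        if cis == trans:
            continue  # tie: block splits at this junction
        edges[(p1, p2)] = cis > trans

    # union-find over sites connected by decided edges
    parent: dict[int, int] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # orientation relative to component root: 0 if first allele on hap0
    orient: dict[int, int] = {}
    for pos in alleles:
        find(pos)
        orient[pos] = 0
    for (p1, p2), cis in edges.items():
        r1, r2 = find(p1), find(p2)
        rel = (orient[p1] + orient[p2] + (0 if cis else 1)) % 2
        if r1 != r2:
            parent[r2] = r1
            # re-orient everything in r2's tree lazily: recompute below
    # simple fixpoint re-orientation (small graphs)
    changed = True
    orient = {pos: 0 for pos in alleles}
    roots = {pos: find(pos) for pos in alleles}
    # parity-inconsistent cycles cannot converge; cap the propagation
    for _ in range(len(edges) + len(alleles) + 1):
        if not changed:
            break
        changed = False
        for (p1, p2), cis in edges.items():
            want = (orient[p1] + (0 if cis else 1)) % 2
            if orient[p2] != want:
                orient[p2] = want
                changed = True

    comps: dict[int, list[int]] = defaultdict(list)
    for pos in alleles:
        comps[roots[pos]].append(pos)
    blocks = []
    for members in comps.values():
        phase = {}
        for pos in sorted(members):
            als = alleles[pos]
            ph = {als[0]: orient[pos]}
            if len(als) > 1:
                ph[als[1]] = 1 - orient[pos]
            phase[pos] = ph
        blocks.append(HaplotypeBlock(sorted(members), phase))
    return blocks


@dataclass(frozen=True)
class OriginCall:
    trio_id: str
    chrom: str
    pos: int
    origin: str  # "paternal" | "maternal" | "undetermined"
    reason: str  # "phased" | "no_informative_site" | "conflict"


def assign_origin(
    dnm_pos: int,
    dnm_alt: str,
    blocks: list[HaplotypeBlock],
    transmissions: dict[int, TransmissionResult],
    trio_id: str = "",
    chrom: str = "",
    window: int = DEFAULT_WINDOW,
) -> OriginCall:
    """Combine haplotype blocks with transmission assignments for one DNM.

    The DNM is paternal iff its allele shares a haplotype with at least one
    paternally transmitted allele at an informative site within ``window``
    bp, and with no maternally transmitted allele in the same block
    (symmetric for maternal); any opposition is a conflict.
    """
    block = next(
        (b for b in blocks if dnm_pos in b.phase and dnm_alt in b.phase[dnm_pos]), None
    )
    if block is None:
        return OriginCall(trio_id, chrom, dnm_pos, "undetermined", "no_informative_site")
    hap = block.phase[dnm_pos][dnm_alt]
    support = set()
    for pos in block.positions:
        if pos == dnm_pos or abs(pos - dnm_pos) > window:
            continue
        tr = transmissions.get(pos)
        if tr is None or tr.status != "phased":
            continue
        for allele, allele_hap in block.phase[pos].items():
            if allele_hap != hap:
                continue
            if allele == tr.paternal_allele:
                support.add("paternal")
            if allele == tr.maternal_allele:
                support.add("maternal")
    if support == {"paternal"}:
        return OriginCall(trio_id, chrom, dnm_pos, "paternal", "phased")
    if support == {"maternal"}:
        return OriginCall(trio_id, chrom, dnm_pos, "maternal", "phased")
    if len(support) == 2:
        return OriginCall(trio_id, chrom, dnm_pos, "undetermined", "conflict")
    return OriginCall(trio_id, chrom, dnm_pos, "undetermined", "no_informative_site")


def phase_instances(instances: list[dict], window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Run the full origin pipeline over simulated phasing instances.

    Each instance (see :func:`denovotrio.simulate.simulate_phasing`) carries
    one DNM, its nearby het sites with trio genotypes, and proband
    fragments.  Returns one OriginCall row per DNM.
    """
    rows = []
    for inst in instances:
        transmissions = {
            h["pos"]: transmission_phase(h["father_gt"], h["mother_gt"], h["child_gt"])
            for h in inst["het_sites"]
        }
        blocks = build_blocks(inst["fragments"])
        call = assign_origin(
            inst["dnm_pos"], inst["dnm_alt"], blocks, transmissions,
            trio_id=inst["trio_id"], chrom=inst["chrom"], window=window,
        )
        rows.append(
            {
                "trio_id": call.trio_id,
                "chrom": call.chrom,
                "pos": call.pos,
                "origin": call.origin,
                "reason": call.reason,
            }
        )
    return pd.DataFrame(rows, columns=["trio_id", "chrom", "pos", "origin", "reason"])


def normalize_origin_counts(origin_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-trio origin counts scaled by the proportion of DNMs phased.

    normalized = observed / phased_fraction, per parent per trio, where
    phased_fraction = (paternal + maternal) / total DNMs for that trio.
    Trios with zero phased DNMs are excluded (with a warning) and flagged.
    """
    rows = []
    excluded = []
    for tid, sub in origin_calls.groupby("trio_id"):
        total = len(sub)
        pat = int((sub["origin"] == "paternal").sum())
        mat = int((sub["origin"] == "maternal").sum())
        phased = pat + mat
        if phased == 0:
            excluded.append(tid)
            continue
        frac = phased / total
        rows.append(
            {
                "trio_id": tid,
                "n_dnm": total,
                "n_paternal": pat,
                "n_maternal": mat,
                "phased_fraction": frac,
                "normalized_paternal": pat / frac,
                "normalized_maternal": mat / frac,
            }
        )
    if excluded:
        logger.warning("%d trio(s) had no phased DNMs and were excluded", len(excluded))
    out = pd.DataFrame(
        rows,
        columns=["trio_id", "n_dnm", "n_paternal", "n_maternal",
                 "phased_fraction", "normalized_paternal", "normalized_maternal"],
    )
    out.attrs["excluded_trios"] = excluded
    return out
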