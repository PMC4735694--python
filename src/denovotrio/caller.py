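"""De novo SNV candidate filtering: three explicit rule cascades.

Each cascade is an ordered list of named predicates over a VariantSite table
(see :mod:`denovotrio.variants`).  Sites are evaluated against every rule;
the verdict and the first failed rule are recorded in a FilterTrace so a
reviewer can see exactly why any candidate was removed.

Cascades
--------
``cgi``      cohort-privacy/quality/refScore rules with a tier-1 allele-depth
             final step (autosomes).
``cgi_x``    same cascade for chromosome X in male probands, with the final
             step replaced by a hemizygous depth / reference-fraction rule.
``strelka``  tier1/tier2 consistency rules in the somatic-caller style.
``gatk``     transmission-probability and genotype-likelihood rules.

Positional filters (cluster removal, mask subtraction, known-variant
removal) are shared across cascades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet


@dataclass
class CascadeResult:
    """Passing sites plus a per-input-site trace."""

    passed: pd.DataFrame
    trace: pd.DataFrame  # columns: trio_id, chrom, pos, ref, alt, verdict, first_failed_rule
    cascade: str = ""


def _require(sites: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in sites.columns]
    if missing:
        raise KeyError(f"sites table is missing required column(s): {missing}")


def _apply_rules(sites: pd.DataFrame, rules: list[tuple[str, np.ndarray]], name: str) -> CascadeResult:
    ok = np.ones(len(sites), dtype=bool)
    first_fail = np.full(len(sites), "", dtype=object)
    for rule_name, mask in rules:
        newly = ok & ~mask
        first_fail[newly] = rule_name
        ok &= mask
    trace = sites[["trio_id", "chrom", "pos", "ref", "alt"]].copy()
    trace["verdict"] = np.where(ok, "pass", "fail")
    trace["first_failed_rule"] = first_fail
    return CascadeResult(sites.loc[ok].reset_index(drop=True), trace, name)


# ---------------------------------------------------------------------------
# shared positional filters
# ---------------------------------------------------------------------------

def region_filters(
    sites: pd.DataFrame,
    alignability: IntervalSet | None = None,
    segdup: IntervalSet | None = None,
    tandem_repeat: IntervalSet | None = None,
) -> pd.DataFrame:
    """Remove sites whose position falls inside any mask.

    Masks are 0-based half-open; VCF positions are 1-based, so position
    ``pos`` is tested as base ``pos - 1``.
    """
    if len(sites) == 0:
        return sites.copy()
    drop = np.zeros(len(sites), dtype=bool)
    for mask in (alignability, segdup, tandem_repeat):
        if mask is None:
            continue
        for chrom, sub in sites.groupby("chrom", sort=False):
            hit = mask.contains(chrom, sub["pos"].to_numpy() - 1)
            drop[sub.index[hit]] = True
    return sites.loc[~drop].reset_index(drop=True)


def population_filter(sites: pd.DataFrame, known_sites) -> pd.DataFrame:
    """Remove exact-allele matches against a known-variant catalogue.

    ``known_sites`` is an iterable of (chrom, pos, ref, alt) tuples (or a
    DataFrame with those columns).  A different alt at the same position is
    kept.
    """
    if len(sites) == 0:
        return sites.copy()
    if isinstance(known_sites, pd.DataFrame):
        known = set(map(tuple, known_sites[["chrom", "pos", "ref", "alt"]].itertuples(index=False)))
    else:
        known = set(map(tuple, known_sites))
    keys = list(map(tuple, sites[["chrom", "pos", "ref", "alt"]].itertuples(index=False)))
    keep = np.array([k not in known for k in keys], dtype=bool)
    return sites.loc[keep].reset_index(drop=True)


def remove_clusters(sites: pd.DataFrame, window: int = 1000) -> pd.DataFrame:
    """Remove every site with another same-proband site within ``window`` bp.

    Both members of a close pair are removed (the conservative reading of a
    symmetric proximity rule); the operation is idempotent.  ``window`` 0 is
    the identity for distinct positions.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if len(sites) == 0 or window == 0:
        return sites.copy().reset_index(drop=True)
    drop = np.zeros(len(sites), dtype=bool)
    for (_, _), sub in sites.groupby(["trio_id", "chrom"], sort=False):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        p = pos[order]
        close = np.diff(p) <= window
        bad = np.zeros(len(p), dtype=bool)
        bad[:-1] |= close
        bad[1:] |= close
        drop[sub.index[order[bad]]] = True
    return sites.loc[~drop].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cascades
# ---------------------------------------------------------------------------

def cgi_candidate_filter(sites: pd.DataFrame) -> CascadeResult:
    """Cohort-level candidate rules of the CGI-style cascade (step 1)."""
    _require(sites, ["call_rate", "carrier_count", "ch_qual", "fa_refscore",
                     "mo_refscore", "ch_alt1", "ch_dp1"])
    dp = sites["ch_dp1"].to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(dp > 0, sites["ch_alt1"].to_numpy() / dp, 0.0)
    rules = [
        ("autosomal", ~sites["chrom"].astype(str).str.contains("X|Y", regex=True).to_numpy()),
        ("call_rate", sites["call_rate"].to_numpy() >= 0.99),
        ("not_private", sites["carrier_count"].to_numpy() == 1),
        ("proband_quality", (sites["ch_qual"] == "HIGH").to_numpy()),
        ("parent_refscore", (sites["fa_refscore"].to_numpy() > 0) & (sites["mo_refscore"].to_numpy() > 0)),
        ("alt_fraction", alt_frac >= 0.3),
    ]
    return _apply_rules(sites, rules, "cgi_candidate")


def depth_filter_cgi(sites: pd.DataFrame) -> CascadeResult:
    """Final CGI step: >=5 reads on each allele, <=5% third-allele reads."""
    _require(sites, ["ch_ref1", "ch_alt1", "ch_third", "ch_dp1"])
    dp = sites["ch_dp1"].to_numpy().astype(float)
    rules = [
        ("ref_reads", sites["ch_ref1"].to_numpy() >= 5),
        ("alt_reads", sites["ch_alt1"].to_numpy() >= 5),
        ("third_allele", sites["ch_third"].to_numpy() <= 0.05 * dp),
    ]
    return _apply_rules(sites, rules, "cgi_depth")


def chrx_male_filter(sites: pd.DataFrame, proband_sex: str = "M") -> CascadeResult:
    """Hemizygous chromosome-X rule for male probands.

    Replaces the autosomal allele-depth step: total depth >= 5 and reference
    allele fraction < 5%.
    """
    if proband_sex != "M":
        raise ValueError("chrX hemizygous filter applies to male probands only")
    _require(sites, ["ch_ref1", "ch_dp1"])
    dp = sites["ch_dp1"].to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_frac = np.where(dp > 0, sites["ch_ref1"].to_numpy() / dp, 1.0)
    rules = [
        ("depth", dp >= 5),
        ("ref_fraction", ref_frac < 0.05),
    ]
    return _apply_rules(sites, rules, "cgi_chrx")


def strelka_style_filter(sites: pd.DataFrame) -> CascadeResult:
    """Tier1/tier2 consistency cascade in the somatic-caller style."""
    needed = [f"{m}_{f}" for m in ("fa", "mo", "ch")
              for f in ("dp1", "dp2", "ref1", "alt1", "ref2", "alt2", "fbc", "sdl")]
    _require(sites, needed)
    g = {c: sites[c].to_numpy().astype(float) for c in needed}
    rules = [("depth_all_members",
              (g["fa_dp1"] >= 10) & (g["mo_dp1"] >= 10) & (g["ch_dp1"] >= 10))]
    rules.append(("filtered_basecalls",
                  (g["fa_fbc"] < 0.20 * g["fa_dp1"]) & (g["mo_fbc"] < 0.20 * g["mo_dp1"])
                  & (g["ch_fbc"] < 0.20 * g["ch_dp1"])))
    rules.append(("spanning_deletions",
                  (g["fa_sdl"] <= 1) & (g["mo_sdl"] <= 1) & (g["ch_sdl"] <= 1)))
    for m, label in (("fa", "father"), ("mo", "mother")):
        rules.append((f"{label}_ref_fraction", g[f"{m}_ref1"] >= 0.9 * g[f"{m}_dp1"]))
        rules.append((f"{label}_alt_reads", (g[f"{m}_alt1"] == 0) & (g[f"{m}_alt2"] == 0)))
        rules.append((f"{label}_tier_ratio", g[f"{m}_ref1"] >= 0.8 * g[f"{m}_ref2"]))
    rules.append(("proband_genotype_reads",
                  g["ch_ref1"] + g["ch_alt1"] >= 0.9 * g["ch_dp1"]))
    rules.append(("proband_tier_ratio",
                  (g["ch_ref1"] >= 0.8 * g["ch_ref2"]) & (g["ch_alt1"] >= 0.8 * g["ch_alt2"])))
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.minimum(g["ch_ref1"], g["ch_alt1"]) / np.where(g["ch_dp1"] > 0, g["ch_dp1"], 1)
    rules.append(("minor_allele_fraction", minor >= 0.30))
    return _apply_rules(sites, rules, "strelka")


def gatk_style_filter(sites: pd.DataFrame) -> CascadeResult:
    """Transmission-probability / genotype-likelihood cascade."""
    needed = (["tp"] + [f"{m}_pl{i}" for m in ("fa", "mo", "ch") for i in range(3)]
              + [f"{m}_dp1" for m in ("fa", "mo", "ch")]
              + [f"{m}_alt1" for m in ("fa", "mo")] + ["ch_ref1", "ch_alt1"])
    _require(sites, needed)
    g = {c: sites[c].to_numpy().astype(float) for c in needed}
    rules = [
        ("transmission_probability", g["tp"] >= 30),
        ("depth_all_members",
         (g["fa_dp1"] >= 10) & (g["fa_dp1"] <= 100)
         & (g["mo_dp1"] >= 10) & (g["mo_dp1"] <= 100)
         & (g["ch_dp1"] >= 10) & (g["ch_dp1"] <= 100)),
        ("parent_homref_pl", (g["fa_pl0"] == 0) & (g["mo_pl0"] == 0)),
        ("proband_het_pl", g["ch_pl1"] == 0),
        ("parent_alt_reads", (g["fa_alt1"] == 0) & (g["mo_alt1"] == 0)),
        ("proband_allele_depth", (g["ch_ref1"] >= 5) & (g["ch_alt1"] >= 5)),
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.minimum(g["ch_ref1"], g["ch_alt1"]) / np.where(g["ch_dp1"] > 0, g["ch_dp1"], 1)
    rules.append(("minor_allele_fraction", minor >= 0.30))
    return _apply_rules(sites, rules, "gatk")


@dataclass
class Masks:
    alignability: IntervalSet | None = None
    segdup: IntervalSet | None = None
    tandem_repeat: IntervalSet | None = None
    known_sites: list = field(default_factory=list)


def run_cascade(
    sites: pd.DataFrame,
    cascade: str,
    masks: Masks | None = None,
    window: int = 1000,
) -> pd.DataFrame:
    """Apply one full cascade in its published order; returns passing sites."""
    masks = masks or Masks()
    if cascade == "cgi":
        out = cgi_candidate_filter(sites).passed
        out = region_filters(out, alignability=masks.alignability)
        out = remove_clusters(out, window)
        out = population_filter(out, masks.known_sites)
        out = region_filters(out, segdup=masks.segdup)
        out = region_filters(out, tandem_repeat=masks.tandem_repeat)
        out = depth_filter_cgi(out).passed
    elif cascade == "cgi_x":
        # chrX cascade: same cohort rules minus the autosomal restriction
        res = _apply_rules(
            sites,
            [
                ("call_rate", sites["call_rate"].to_numpy() >= 0.99),
                ("not_private", sites["carrier_count"].to_numpy() == 1),
                ("proband_quality", (sites["ch_qual"] == "HIGH").to_numpy()),
                ("parent_refscore", (sites["fa_refscore"].to_numpy() > 0)
                 & (sites["mo_refscore"].to_numpy() > 0)),
            ],
            "cgi_x_candidate",
        )
        out = region_filters(res.passed, alignability=masks.alignability)
        out = remove_clusters(out, window)
        out = population_filter(out, masks.known_sites)
        out = region_filters(out, segdup=masks.segdup, tandem_repeat=masks.tandem_repeat)
        out = chrx_male_filter(out).passed
    elif cascade == "strelka":
        out = strelka_style_filter(sites).passed
        out = remove_clusters(out, window)
        out = region_filters(out, alignability=masks.alignability,
                             tandem_repeat=masks.tandem_repeat)
        out = population_filter(out, masks.known_sites)
    elif cascade == "gatk":
        out = gatk_style_filter(sites).passed
        out = remove_clusters(out, window)
        out = region_filters(out, alignability=masks.alignability,
                             tandem_repeat=masks.tandem_repeat)
        out = population_filter(out, masks.known_sites)
    else:
        raise ValueError(f"unknown cascade {cascade!r}")
    return out.reset_index(drop=True)


def count_dnms(
    calls: pd.DataFrame,
    cohort: pd.DataFrame,
    by_chromosome: bool = False,
    by_context: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-trio DNM count table, zero-filled for trios with no calls.

    ``by_context`` optionally supplies a truth table keyed by
    (trio, chrom, pos, ref, alt) with a ``context`` column to partition
    counts into CpG / non-CpG.
    """
    trios = cohort["trio_id"]
    unknown = set(calls["trio_id"]) - set(trios)
    if unknown:
        raise ValueError(f"calls reference unknown trio id(s): {sorted(unknown)[:5]}")
    if by_chromosome:
        tab = (
            calls.groupby(["trio_id", "chrom"]).size().unstack(fill_value=0)
            .reindex(trios, fill_value=0)
        )
        tab.index.name = "trio_id"
        return tab.reset_index()
    if by_context is not None:
        key = ["trio_id", "chrom", "pos", "ref", "alt"]
        merged = calls.merge(by_context[key + ["context"]], on=key, how="left")
        merged["context"] = merged["context"].fillna("non-CpG")
        tab = (
            merged.groupby(["trio_id", "context"]).size().unstack(fill_value=0)
            .reindex(trios, fill_value=0)
        )
        for col in ("CpG", "non-CpG"):
            if col not in tab.columns:
                tab[col] = 0
        tab.index.name = "trio_id"
        return tab.reset_index()
    counts = calls.groupby("trio_id").size().reindex(trios, fill_value=0)
    return pd.DataFrame({"trio_id": trios.to_numpy(), "n_dnm": counts.to_numpy()})
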