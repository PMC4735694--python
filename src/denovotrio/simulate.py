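"""Site-level simulation: DNM placement, read evidence, detection channel.

`place_dnms` materializes per-trio true DNM counts as genomic sites with a
mutation context (CpG / non-CpG), class (transition / transversion),
strength class and a true parent-of-origin.  `synthesize_evidence` pushes
the truth through a detection channel -- binomial thinning at the configured
sensitivity, false-positive injection at the configured precision, clustered
artifact injection -- and emits a trio-aware variant table carrying three
consistent read-evidence channels (CGI-style quality/refScore/allele counts,
Strelka-style tier1/tier2 tallies, GATK-style genotype likelihoods and
transmission probability) so that every downstream filter cascade sees the
data it expects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig
from .intervals import IntervalSet
from . import variants

# hg19 autosome lengths (bp), used only as relative proportions when carving
# the configured effective genome into 22 pseudo-chromosomes.
_HG19_AUTOSOME_BP = np.array(
    [249250621, 243199373, 198022430, 191154276, 180915260, 171115067,
     159138663, 146364022, 141213431, 135534747, 135006516, 133851895,
     115169878, 107349540, 102531392, 90354753, 81195210, 78077248,
     59128983, 63025520, 48129895, 51304566], dtype=float,
)

TRUTH_COLUMNS = [
    "trio_id", "chrom", "pos", "ref", "alt", "context", "mut_class",
    "strength_class", "true_origin", "is_artifact", "is_detected",
]


def genome_layout(config: CohortConfig) -> pd.DataFrame:
    """Pseudo-chromosome names and lengths summing to L_effective."""
    gm = config.genome_model
    props = _HG19_AUTOSOME_BP[: gm.n_chromosomes]
    props = props / props.sum()
    lengths = np.floor(props * gm.L_effective).astype(np.int64)
    lengths[0] += gm.L_effective - lengths.sum()
    return pd.DataFrame(
        {"chrom": [f"chr{i+1}" for i in range(gm.n_chromosomes)], "length": lengths}
    )


def _strength_probs(config: CohortConfig) -> dict:
    """Direction probabilities making the overall strong->weak : weak->strong
    intensity ratio equal the configured value.

    At CpG context the reference base is always strong (C or G), so CpG
    transitions are all strong->weak and CpG transversions are strong->weak
    or neutral.  The non-CpG strong->weak share p1 is solved so the
    cohort-level ratio matches ``strong_to_weak_ratio``.
    """
    sp = config.spectrum
    gm = config.genome_model
    f_n = sp.transversion_neutral_fraction
    w_cpg_ts = gm.cpg_bases * sp.cpg_transition_multiplier * sp.ts_tv_intensity_ratio
    w_cpg_tv = gm.cpg_bases * sp.cpg_transversion_multiplier
    w_non_ts = gm.noncpg_bases * sp.ts_tv_intensity_ratio
    w_non_tv = gm.noncpg_bases
    A = w_cpg_ts + w_cpg_tv * (1 - f_n)
    B = w_non_ts + w_non_tv * (1 - f_n)
    R = sp.strong_to_weak_ratio
    p1 = (R * B - A) / (B * (1 + R))
    p1 = float(np.clip(p1, 0.0, 1.0))
    total = w_cpg_ts + w_cpg_tv + w_non_ts + w_non_tv
    cell_probs = np.array([w_cpg_ts, w_cpg_tv, w_non_ts, w_non_tv]) / total
    return {"p1_noncpg_sw": p1, "cell_probs": cell_probs, "neutral_tv": f_n}


_BASES = {
    # (context, class, strength) -> list of (ref, alt) choices
    ("CpG", "transition", "strong_to_weak"): [("C", "T"), ("G", "A")],
    ("CpG", "transversion", "strong_to_weak"): [("C", "A"), ("G", "T")],
    ("CpG", "transversion", "neutral"): [("C", "G"), ("G", "C")],
    ("non-CpG", "transition", "strong_to_weak"): [("C", "T"), ("G", "A")],
    ("non-CpG", "transition", "weak_to_strong"): [("T", "C"), ("A", "G")],
    ("non-CpG", "transversion", "strong_to_weak"): [("C", "A"), ("G", "T")],
    ("non-CpG", "transversion", "weak_to_strong"): [("A", "C"), ("T", "G")],
    ("non-CpG", "transversion", "neutral"): [("C", "G"), ("G", "C"), ("A", "T"), ("T", "A")],
}


def place_dnms(
    counts: pd.Series, config: CohortConfig, seed: int | None = None
) -> pd.DataFrame:
    """Materialize per-trio true DNM counts as a truth table of sites.

    Positions are uniform over the effective genome; context, mutation class
    and strength class follow the configured spectrum; origin is paternal
    with the configured probability.  Clustered artifact pairs are appended
    with ``is_artifact=True``.
    """
    if config.genome_model.L_effective <= 0:
        raise ValueError("zero-length genome")
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    layout = genome_layout(config)
    total = int(counts.sum())
    trio_ids = np.repeat(counts.index.to_numpy(), counts.to_numpy().astype(int))

    probs = _strength_probs(config)
    cells = rng.choice(4, size=total, p=probs["cell_probs"])
    context = np.where(cells < 2, "CpG", "non-CpG")
    mut_class = np.where(cells % 2 == 0, "transition", "transversion")

    strength = np.empty(total, dtype=object)
    u = rng.random(total)
    p1 = probs["p1_noncpg_sw"]
    f_n = probs["neutral_tv"]
    for i in range(total):
        c, cls = context[i], mut_class[i]
        if c == "CpG":
            if cls == "transition":
                strength[i] = "strong_to_weak"
            else:
                strength[i] = "neutral" if u[i] < f_n else "strong_to_weak"
        else:
            if cls == "transition":
                strength[i] = "strong_to_weak" if u[i] < p1 else "weak_to_strong"
            else:
                if u[i] < f_n:
                    strength[i] = "neutral"
                elif u[i] < f_n + (1 - f_n) * p1:
                    strength[i] = "strong_to_weak"
                else:
                    strength[i] = "weak_to_strong"

    refs = np.empty(total, dtype=object)
    alts = np.empty(total, dtype=object)
    pick = rng.random(total)
    for i in range(total):
        choices = _BASES[(context[i], mut_class[i], strength[i])]
        ref, alt = choices[int(pick[i] * len(choices))]
        refs[i], alts[i] = ref, alt

    chrom_idx = rng.choice(
        len(layout), size=total, p=layout["length"].to_numpy() / layout["length"].sum()
    )
    pos = (rng.random(total) * layout["length"].to_numpy()[chrom_idx]).astype(np.int64) + 1
    origin = np.where(
        rng.random(total) < config.origin_model.paternal_fraction, "paternal", "maternal"
    )

    truth = pd.DataFrame(
        {
            "trio_id": trio_ids,
            "chrom": layout["chrom"].to_numpy()[chrom_idx],
            "pos": pos,
            "ref": refs,
            "alt": alts,
            "context": context,
            "mut_class": mut_class,
            "strength_class": strength,
            "true_origin": origin,
            "is_artifact": False,
            "is_detected": True,
        }
    )

    art_rate = config.genome_model.cluster_artifact_rate
    if art_rate > 0:
        art = _artifact_pairs(counts.index.to_numpy(), config, layout, rng)
        truth = pd.concat([truth, art], ignore_index=True)
    return truth


def _artifact_pairs(trio_ids, config, layout, rng) -> pd.DataFrame:
    gm = config.genome_model
    rows = []
    for tid in trio_ids:
        for _ in range(rng.poisson(gm.cluster_artifact_rate)):
            ci = rng.integers(len(layout))
            length = layout["length"].iloc[ci]
            p = int(rng.integers(1, max(2, length - gm.cluster_window)))
            delta = int(rng.integers(1, gm.cluster_window + 1))
            for pos in (p, p + delta):
                ref, alt = [("C", "A"), ("G", "T"), ("A", "G"), ("T", "C")][rng.integers(4)]
                rows.append((tid, layout["chrom"].iloc[ci], pos, ref, alt))
    art = pd.DataFrame(rows, columns=["trio_id", "chrom", "pos", "ref", "alt"])
    art["context"] = "non-CpG"
    art["mut_class"] = "transversion"
    art["strength_class"] = "neutral"
    art["true_origin"] = "paternal"
    art["is_artifact"] = True
    art["is_detected"] = True
    return art


def thin_and_inject(
    true_counts: np.ndarray,
    sensitivity: float,
    precision: float,
    rng: np.random.Generator,
    genome_proportion: float = 1.0,
    fp_offsets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Detection channel on per-trio counts.

    Returns ``(observed, detected_true, false_positives)`` where each true
    DNM falls in the effective genome with probability ``genome_proportion``,
    is detected with probability ``sensitivity``, and false positives are
    Poisson with per-trio intensity ``detected_i * (1-q)/q`` (plus optional
    additive batch offsets) so the expected precision of the observed call
    set equals ``precision``.
    """
    if precision <= 0:
        raise ValueError("precision must be > 0 (false-positive intensity undefined)")
    true_counts = np.asarray(true_counts)
    detected = rng.binomial(true_counts, genome_proportion * sensitivity)
    lam = detected * (1 - precision) / precision
    if fp_offsets is not None:
        lam = np.clip(lam + fp_offsets, 0.0, None)
    fps = rng.poisson(lam)
    return detected + fps, detected, fps


def synthesize_evidence(
    truth: pd.DataFrame,
    cohort: pd.DataFrame,
    config: CohortConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, IntervalSet]]:
    """Emit a VariantSite table (plus no-call masks) from a truth table.

    Returns ``(sites, truth, masks)`` where ``truth`` carries an updated
    ``is_detected`` column, ``sites`` holds every emitted call (detected true
    DNMs, clustered artifacts, injected false positives) with all three
    evidence channels populated so a clean true DNM passes every cascade,
    and ``masks`` maps individual ids (``<trio>_fa`` etc.) to no-call
    interval sets.
    """
    config.detection.validate()
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    det = config.detection
    layout = genome_layout(config)

    truth = truth.copy()
    real = ~truth["is_artifact"].to_numpy()
    is_det = np.ones(len(truth), dtype=bool)
    is_det[real] = rng.random(int(real.sum())) < det.sensitivity
    truth["is_detected"] = is_det

    emitted = truth.loc[truth["is_detected"], ["trio_id", "chrom", "pos", "ref", "alt"]]

    # false positives: per-trio Poisson intensity proportional to the trio's
    # detected-true load, plus any batch offset keyed by software version
    det_counts = (
        truth.loc[truth["is_detected"] & real, "trio_id"].value_counts()
        .reindex(cohort["trio_id"], fill_value=0)
        .to_numpy()
    )
    offsets = np.array(
        [config.batch.fp_offsets.get(lbl, 0.0) for lbl in cohort["batch_label"]]
    )
    lam = np.clip(det_counts * (1 - det.precision) / det.precision + offsets, 0.0, None)
    n_fp = rng.poisson(lam)
    fp_rows = []
    for tid, k in zip(cohort["trio_id"], n_fp):
        for _ in range(int(k)):
            ci = rng.integers(len(layout))
            pos = int(rng.integers(1, layout["length"].iloc[ci] + 1))
            ref, alt = [("A", "C"), ("C", "T"), ("G", "A"), ("T", "G")][rng.integers(4)]
            fp_rows.append((tid, layout["chrom"].iloc[ci], pos, ref, alt))
    if fp_rows:
        emitted = pd.concat(
            [emitted, pd.DataFrame(fp_rows, columns=emitted.columns)], ignore_index=True
        )
    emitted = emitted.reset_index(drop=True)

    sites = _clean_evidence(emitted, det.mean_depth, rng)
    masks = _nocall_masks(cohort, config, layout, rng)
    return sites, truth, masks


def _clean_evidence(emitted: pd.DataFrame, mean_depth: float, rng) -> pd.DataFrame:
    """Populate all three evidence channels for emitted sites.

    One latent depth draw per site per member keeps the channels consistent:
    tier1 == tier2 tallies, genotype likelihoods matching the genotypes, no
    third-allele or filtered-base noise.
    """
    n = len(emitted)
    sites = emitted.copy()
    sites["call_rate"] = 1.0
    sites["carrier_count"] = 1
    sites["tp"] = 60
    for member in ("fa", "mo", "ch"):
        dp = np.clip(rng.poisson(mean_depth, size=n), 10, 100).astype(np.int64)
        if member == "ch":
            alt = rng.binomial(dp, 0.5)
            lo = np.maximum(5, np.ceil(0.3 * dp).astype(np.int64))
            hi = np.minimum(dp - 5, np.floor(0.7 * dp).astype(np.int64))
            alt = np.clip(alt, lo, hi)
            ref = dp - alt
            gt, qual = "0/1", "HIGH"
            pl = (60, 0, 600)
            refscore = 0
        else:
            ref, alt = dp, np.zeros(n, dtype=np.int64)
            gt, qual = "0/0", "HIGH"
            pl = (0, 60, 600)
            refscore = 40
        sites[f"{member}_gt"] = gt
        sites[f"{member}_qual"] = qual
        sites[f"{member}_refscore"] = refscore
        sites[f"{member}_dp1"] = dp
        sites[f"{member}_dp2"] = dp
        sites[f"{member}_ref1"] = ref
        sites[f"{member}_alt1"] = alt
        sites[f"{member}_ref2"] = ref
        sites[f"{member}_alt2"] = alt
        sites[f"{member}_third"] = 0
        sites[f"{member}_fbc"] = 0
        sites[f"{member}_sdl"] = 0
        sites[f"{member}_pl0"] = pl[0]
        sites[f"{member}_pl1"] = pl[1]
        sites[f"{member}_pl2"] = pl[2]
    return sites[variants.SITE_COLUMNS]


def _nocall_masks(cohort, config, layout, rng) -> dict[str, IntervalSet]:
    rate = config.genome_model.nocall_rate
    masks: dict[str, IntervalSet] = {}
    chunk = 1000  # bp per no-call interval
    for tid in cohort["trio_id"]:
        for member in ("fa", "mo", "ch"):
            recs = []
            if rate > 0:
                for ci in range(len(layout)):
                    length = int(layout["length"].iloc[ci])
                    k = rng.poisson(rate * length / chunk)
                    if k:
                        starts = rng.integers(0, max(1, length - chunk), size=k)
                        recs += [
                            (layout["chrom"].iloc[ci], int(s), int(s) + chunk)
                            for s in starts
                        ]
            masks[f"{tid}_{member}"] = IntervalSet(recs)
    return masks


def simulate_phasing(
    truth: pd.DataFrame,
    config: CohortConfig,
    seed: int | None = None,
    window: int = 20_000,
) -> list[dict]:
    """Build per-DNM phasing instances (informative sites + fragments).

    For each detected non-artifact DNM, with probability ``phased_fraction``
    an unambiguous phase-informative het site is placed within ``window`` bp
    and two concordant proband fragments link the DNM allele to the allele
    transmitted by the true parent of origin.  Otherwise the DNM's fragments
    cover no informative site, so its origin is undeterminable.
    """
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    keep = truth["is_detected"].to_numpy() & ~truth["is_artifact"].to_numpy()
    rows = truth.loc[keep]
    instances = []
    phased = rng.random(len(rows)) < config.origin_model.phased_fraction
    offs = rng.integers(1, window, size=len(rows))
    signs = rng.choice([-1, 1], size=len(rows))
    for i, (_, row) in enumerate(rows.iterrows()):
        dnm_pos, alt = int(row["pos"]), row["alt"]
        inst = {
            "trio_id": row["trio_id"],
            "chrom": row["chrom"],
            "dnm_pos": dnm_pos,
            "dnm_ref": row["ref"],
            "dnm_alt": alt,
            "true_origin": row["true_origin"],
        }
        if phased[i]:
            info_pos = max(1, dnm_pos + int(signs[i]) * int(offs[i]))
            # father T/T, mother C/C, child C/T: T is paternal, C maternal
            linked = "T" if row["true_origin"] == "paternal" else "C"
            inst["het_sites"] = [
                {"pos": info_pos, "father_gt": ("T", "T"), "mother_gt": ("C", "C"),
                 "child_gt": ("C", "T")}
            ]
            frag = sorted([(dnm_pos, alt), (info_pos, linked)])
            inst["fragments"] = [frag, list(frag)]
        else:
            inst["het_sites"] = []
            inst["fragments"] = [[(dnm_pos, alt)]]
        instances.append(inst)
    return instances


def write_cohort(
    cohort: pd.DataFrame,
    sites: pd.DataFrame,
    masks: dict[str, IntervalSet],
    truth: pd.DataFrame | None,
    out_dir,
) -> dict[str, str]:
    """Write covariates CSV, sites VCF, truth CSV and per-individual BED masks."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "cohort": os.path.join(out_dir, "cohort.csv"),
        "sites": os.path.join(out_dir, "sites.vcf"),
    }
    cohort.to_csv(paths["cohort"], index=False)
    variants.write_vcf(sites, paths["sites"])
    if truth is not None:
        paths["truth"] = os.path.join(out_dir, "truth.csv")
        truth.to_csv(paths["truth"], index=False)
    mask_dir = os.path.join(out_dir, "masks")
    os.makedirs(mask_dir, exist_ok=True)
    for name, iset in masks.items():
        iset.write_bed(os.path.join(mask_dir, f"{name}.bed"))
    paths["masks"] = mask_dir
    return paths


def simulate_cohort(config: CohortConfig, seed: int | None = None):
    """End-to-end convenience: ages, counts, truth, evidence, masks.

    Returns ``(cohort, truth, sites, masks)``.  Seeds for the stages are
    spawned from ``seed`` (default: the config seed).
    """
    from .cohort import sample_ages, sample_counts

    root = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    cohort = sample_ages(config, seed=sub[0])
    counts = sample_counts(cohort, config, seed=sub[1])
    truth = place_dnms(counts, config, seed=sub[2])
    sites, truth, masks = synthesize_evidence(truth, cohort, config, seed=sub[3])
    return cohort, truth, sites, masks
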