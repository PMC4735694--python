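"""Mutation-rate estimation adjusted for pipeline accuracy.

The observed DNM count overstates the truth by the false-positive load and
understates it by missed detections; with call-set precision q and
sensitivity s the true count is approximately observed * q / s.  The
per-base per-generation rate divides by twice the effective diploid base
count per trio.  Regression slopes on observed counts are corrected the
same way and additionally rescaled by the fraction of the (non-gap) genome
that is effectively callable, and — for parent-of-origin slopes — by the
mean fraction of DNMs that could be phased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PipelineAccuracy:
    sensitivity: float
    precision: float

    def __post_init__(self):
        if not 0 < self.sensitivity <= 1:
            raise ValueError("sensitivity must be in (0, 1]")
        if not 0 < self.precision <= 1:
            raise ValueError("precision must be in (0, 1]")


@dataclass(frozen=True)
class EffectiveGenome:
    effective_autosomal_bases: int
    commonly_callable_bases: int
    genome_nogap_bases: int
    cpg_bases: int = 0
    noncpg_bases: int = 0

    def __post_init__(self):
        if not (
            self.effective_autosomal_bases
            <= self.commonly_callable_bases
            <= self.genome_nogap_bases
        ):
            raise ValueError("expected effective <= commonly callable <= non-gap genome")
        if self.cpg_bases and self.noncpg_bases:
            if self.cpg_bases + self.noncpg_bases != self.effective_autosomal_bases:
                raise ValueError("cpg + noncpg bases must equal effective bases")

    @property
    def genome_proportion(self) -> float:
        return self.effective_autosomal_bases / self.genome_nogap_bases


def estimate_rate(
    n_dnm: float, n_trios: int, accuracy: PipelineAccuracy, effective_bases: float
) -> float:
    """Per-base per-generation mutation rate from a cohort DNM total.

    rate = (n_dnm * precision / sensitivity) / (2 * effective_bases * n_trios)
    """
    if n_dnm < 0 or n_trios <= 0 or effective_bases <= 0:
        raise ValueError("n_dnm must be >= 0 and n_trios, effective_bases positive")
    true_count = n_dnm * accuracy.precision / accuracy.sensitivity
    return true_count / (2.0 * effective_bases * n_trios)


def adjust_slope(
    observed_slope: float, accuracy: PipelineAccuracy, genome_proportion: float
) -> float:
    """Correct an observed per-year slope for accuracy and callable fraction."""
    if not 0 < genome_proportion <= 1:
        raise ValueError("genome_proportion must be in (0, 1]")
    return observed_slope * accuracy.precision / accuracy.sensitivity / genome_proportion


def adjust_phased_slope(
    observed_slope: float,
    accuracy: PipelineAccuracy,
    genome_proportion: float,
    mean_phased_fraction: float,
) -> float:
    """As :func:`adjust_slope`, further divided by the mean phased fraction."""
    if not 0 < mean_phased_fraction <= 1:
        raise ValueError("mean_phased_fraction must be in (0, 1]")
    return adjust_slope(observed_slope, accuracy, genome_proportion) / mean_phased_fraction


def context_rates(
    dnms: pd.DataFrame,
    genome: EffectiveGenome,
    n_trios: int,
    accuracy: PipelineAccuracy,
) -> dict:
    """Context-specific mutation rates and their ratios.

    ``dnms`` must carry ``context`` (CpG / non-CpG), ``mut_class``
    (transition / transversion) and ``strength_class`` columns.  Rates use
    the context's own base count as denominator; the CpG:non-CpG ratio per
    class and the strong->weak : weak->strong ratio (over all contexts,
    common denominator) are reported.  Accuracy and trio count cancel in
    every ratio.
    """
    bases = {"CpG": genome.cpg_bases, "non-CpG": genome.noncpg_bases}
    table = []
    rates = {}
    for context, n_bases in bases.items():
        for klass in ("transition", "transversion"):
            n = int(((dnms["context"] == context) & (dnms["mut_class"] == klass)).sum())
            if n_bases <= 0:
                rate = np.nan
            else:
                rate = estimate_rate(n, n_trios, accuracy, n_bases)
            rates[(context, klass)] = rate
            table.append({"context": context, "mut_class": klass, "n": n, "rate": rate})
    ratios = {}
    for klass in ("transition", "transversion"):
        num, den = rates[("CpG", klass)], rates[("non-CpG", klass)]
        ratios[f"cpg_{klass}_ratio"] = num / den if den and np.isfinite(den) else np.nan
    n_sw = int((dnms["strength_class"] == "strong_to_weak").sum())
    n_ws = int((dnms["strength_class"] == "weak_to_strong").sum())
    ratios["strong_to_weak_ratio"] = n_sw / n_ws if n_ws else np.nan
    return {"rates": pd.DataFrame(table), "ratios": ratios}
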