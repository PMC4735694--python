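"""Cross-pipeline call-set comparison.

Call sets are compared on exact (trio, chrom, pos, ref, alt) identity:
Venn partitions over three pipelines, a >=2-pipeline truth set,
sensitivity/precision of one pipeline against that truth restricted to
commonly callable bases, and monozygotic-twin concordance (twins share all
germline DNMs, so discordance measures pipeline error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .intervals import IntervalSet

Key = tuple  # (trio_id, chrom, pos, ref, alt)


@dataclass
class CallSet:
    name: str
    calls: set = field(default_factory=set)

    @classmethod
    def from_frame(cls, name: str, sites: pd.DataFrame) -> "CallSet":
        keys = set(
            map(tuple, sites[["trio_id", "chrom", "pos", "ref", "alt"]].itertuples(index=False))
        )
        return cls(name, keys)

    def restrict(self, regions: IntervalSet) -> "CallSet":
        """Keep only calls whose (1-based) position falls in the regions."""
        kept = {
            k for k in self.calls if regions.contains(k[1], [k[2] - 1])[0]
        }
        return CallSet(self.name, kept)


def venn_counts(a: CallSet, b: CallSet, c: CallSet) -> dict:
    """Counts for the seven intersection regions of three call sets."""
    A, B, C = a.calls, b.calls, c.calls
    return {
        f"{a.name}_only": len(A - B - C),
        f"{b.name}_only": len(B - A - C),
        f"{c.name}_only": len(C - A - B),
        f"{a.name}_{b.name}_only": len((A & B) - C),
        f"{a.name}_{c.name}_only": len((A & C) - B),
        f"{b.name}_{c.name}_only": len((B & C) - A),
        "all_three": len(A & B & C),
        "union": len(A | B | C),
        "at_least_two": len((A & B) | (A & C) | (B & C)),
    }


def truth_set(a: CallSet, b: CallSet, c: CallSet) -> CallSet:
    """DNMs called by at least two of the three pipelines."""
    A, B, C = a.calls, b.calls, c.calls
    return CallSet("truth", (A & B) | (A & C) | (B & C))


def sensitivity_precision(
    calls: CallSet, truth: CallSet, common_callable: IntervalSet | None = None
) -> dict:
    """Sensitivity and precision of a call set against a truth set.

    When ``common_callable`` is given, both sets are restricted to it
    (symmetrically) before comparison.
    """
    if common_callable is not None:
        calls = calls.restrict(common_callable)
        truth = truth.restrict(common_callable)
    tp = len(calls.calls & truth.calls)
    sens = tp / len(truth.calls) if truth.calls else float("nan")
    prec = tp / len(calls.calls) if calls.calls else float("nan")
    return {
        "sensitivity": sens,
        "precision": prec,
        "n_true_positive": tp,
        "n_calls": len(calls.calls),
        "n_truth": len(truth.calls),
        "truth_empty": not truth.calls,
    }


def twin_concordance(calls_a: CallSet, calls_b: CallSet) -> dict:
    """Shared / exclusive counts between monozygotic twins' call sets.

    Site identity ignores the trio (twin) id; shared fraction is shared
    over the union.
    """
    A = {k[1:] for k in calls_a.calls}
    B = {k[1:] for k in calls_b.calls}
    shared = len(A & B)
    union = len(A | B)
    return {
        "shared": shared,
        "a_only": len(A - B),
        "b_only": len(B - A),
        "shared_fraction": shared / union if union else float("nan"),
    }
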