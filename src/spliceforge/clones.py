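"""Clone-count quantification of splice-variant proportions.

Randomly picked plasmid clones are classified by insert size against
per-variant reference lengths (the gel size-marker logic), tallied per
condition, turned into proportions with Wilson confidence intervals, and
compared across conditions with a homogeneity test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass
class CloneCounts:
    """Variant tallies per condition, with the unassignable remainder."""

    counts: pd.DataFrame      # index condition, columns variant names
    ambiguous: pd.Series      # per condition

    @property
    def n_total(self) -> pd.Series:
        return self.counts.sum(axis=1) + self.ambiguous

    @property
    def assigned(self) -> pd.Series:
        return self.counts.sum(axis=1)


def size_classify(
    inserts: pd.DataFrame,
    reference_lengths: dict[str, float],
    tolerance: float = 0.008,
) -> CloneCounts:
    """Assign each clone to the nearest reference length within tolerance.

    ``inserts`` needs columns ``condition`` and ``insert_length``.
    ``tolerance`` is a fraction of the reference length when < 1, otherwise
    an absolute tolerance in nt.  Clones matching no reference (or, with
    equal distances, more than one) are counted as ambiguous.  Reference
    pairs closer than the sum of their tolerances are a configuration error:
    such variants are indistinguishable by size and must be merged
    explicitly upstream.
    """
    names = sorted(reference_lengths)
    refs = np.array([reference_lengths[n] for n in names], dtype=float)
    tol = refs * tolerance if tolerance < 1 else np.full_like(refs, tolerance)
    for i in range(len(refs)):
        for j in range(i + 1, len(refs)):
            if abs(refs[i] - refs[j]) < tol[i] + tol[j]:
                raise ValueError(
                    f"reference lengths for {names[i]} ({refs[i]:g}) and "
                    f"{names[j]} ({refs[j]:g}) are closer than their size "
                    f"tolerance; merge them into one declared class"
                )
    conditions = sorted(inserts["condition"].unique())
    counts = pd.DataFrame(0, index=conditions, columns=names, dtype=int)
    ambiguous = pd.Series(0, index=conditions, dtype=int)
    for cond, sub in inserts.groupby("condition"):
        for length in sub["insert_length"].to_numpy(dtype=float):
            d = np.abs(refs - length)
            within = d <= tol
            if within.sum() == 0:
                ambiguous[cond] += 1
                continue
            best = np.flatnonzero(within & (d == d[within].min()))
            if len(best) > 1:
                ambiguous[cond] += 1
            else:
                counts.loc[cond, names[best[0]]] += 1
    return CloneCounts(counts=counts, ambiguous=ambiguous)


def clone_counts_from_tallies(tallies: pd.DataFrame) -> CloneCounts:
    """Pool truth tallies (condition, variant, count rows) into CloneCounts."""
    piv = tallies.pivot_table(
        index="condition", columns="variant", values="count", aggfunc="sum"
    ).fillna(0).astype(int)
    piv.columns.name = None
    return CloneCounts(counts=piv, ambiguous=pd.Series(0, index=piv.index))


def proportions_ci(counts: CloneCounts, level: float = 0.95) -> pd.DataFrame:
    """Per-variant proportion of assigned clones with Wilson score intervals.

    Ambiguous clones are excluded from the denominator.
    """
    rows = []
    for cond in counts.counts.index:
        n = int(counts.assigned[cond])
        if n == 0:
            raise ValueError(f"no assigned clones in condition {cond!r}")
        for variant in counts.counts.columns:
            k = int(counts.counts.loc[cond, variant])
            lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
            rows.append(
                {
                    "condition": cond,
                    "variant": variant,
                    "count": k,
                    "n_assigned": n,
                    "p_hat": k / n,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(rows)


def proportion_shift_test(counts: CloneCounts, min_expected: float = 1.0) -> float:
    """Homogeneity test of the condition x variant table.

    Variants whose expected count falls below ``min_expected`` in any cell
    are pooled into an "other" class; 2x2 tables use Fisher's exact test,
    larger tables the chi-square test of homogeneity.
    """
    tab = counts.counts.copy()
    if len(tab) < 2:
        raise ValueError("need at least two conditions")
    n = tab.to_numpy(dtype=float)
    expected = np.outer(n.sum(axis=1), n.sum(axis=0)) / n.sum()
    keep = (expected >= min_expected).all(axis=0)
    if not keep.all():
        pooled = tab.loc[:, ~keep].sum(axis=1)
        tab = tab.loc[:, keep]
        if (pooled > 0).any() or not keep.any():
            tab = tab.assign(other=pooled)
    tab = tab.loc[:, tab.sum(axis=0) > 0]
    arr = tab.to_numpy(dtype=int)
    if arr.shape[1] < 2:
        return 1.0
    if arr.shape == (2, 2):
        return float(stats.fisher_exact(arr)[1])
    if (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.chi2_contingency(arr, correction=False)[1])
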