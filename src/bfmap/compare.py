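"""Correlation-coefficient comparison of input/output distributions.

Whether transcriptomically defined cell types receive and send distinct
whole-brain connections is tested here with Pearson correlation coefficients
(CCs) between per-region distribution vectors, computed by default at the
spatial scale of the 12 major brain subdivisions:

* ``celltype_cc_matrix`` — CCs between cell-type *mean* distributions, for
  input/input, output/output, or input/output modality pairs (the last is
  generally asymmetric: rows are the input types, columns the output types).
* ``within_across_cc`` — CCs between *individual brain samples*, pooled into
  same-type and different-type groups (self-pairs excluded, each unordered
  pair counted once) and compared with a Welch two-sample t-test.  A higher
  within-type mean demonstrates type differences beyond experimental
  variability.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import DistributionVector

__all__ = [
    "CCMatrix",
    "WithinAcrossResult",
    "mean_distribution",
    "cc",
    "celltype_cc_matrix",
    "within_across_cc",
    "anova_by_region",
]


@dataclass
class CCMatrix:
    """Labeled matrix of Pearson correlation coefficients."""

    values: pd.DataFrame  # rows/cols labeled by cell type or sample id
    level: int
    modality_pair: tuple[str, str]

    @property
    def is_symmetric(self) -> bool:
        v = self.values.to_numpy()
        return v.shape[0] == v.shape[1] and np.allclose(v, v.T)


@dataclass
class WithinAcrossResult:
    within: np.ndarray
    across: np.ndarray
    within_mean: float
    within_sem: float
    across_mean: float
    across_sem: float
    t: float | None
    p: float | None
    n_within: int
    n_across: int


def mean_distribution(samples: list[DistributionVector]) -> pd.Series:
    """Element-wise mean of per-sample distributions (region order preserved)."""
    if not samples:
        raise ValueError("need at least one sample")
    index = samples[0].fractions.index
    for s in samples[1:]:
        if not s.fractions.index.equals(index):
            raise ValueError("samples have mismatched region supports")
    return pd.concat([s.fractions for s in samples], axis=1).mean(axis=1)


def cc(x, y) -> float:
    """Pearson product-moment correlation between two region vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("vectors must be 1D, equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


def celltype_cc_matrix(
    means_a: dict[str, pd.Series],
    means_b: dict[str, pd.Series] | None = None,
    modality_pair: tuple[str, str] = ("input", "input"),
    level: int = 1,
) -> CCMatrix:
    """Matrix of CCs between cell-type mean distributions.

    With one dict the matrix is symmetric with unit diagonal (e.g.
    input/input).  With two dicts (e.g. input means vs output means) rows
    come from ``means_a`` and columns from ``means_b``; the matrix is
    generally asymmetric and callers wanting both orientations can
    transpose.
    """
    if means_b is None:
        means_b = means_a
    rows, cols = list(means_a), list(means_b)
    vals = pd.DataFrame(
        [[cc(means_a[r].to_numpy(), means_b[c].to_numpy()) for c in cols] for r in rows],
        index=rows,
        columns=cols,
    )
    return CCMatrix(values=vals, level=level, modality_pair=modality_pair)


def within_across_cc(
    samples: list[DistributionVector],
    modality: str = "input",
) -> WithinAcrossResult:
    """Sample-pair CCs pooled by same/different cell type, plus Welch t-test.

    All pairwise CCs between individual samples of the given modality are
    computed; the diagonal (each sample with itself, CC = 1) is excluded and
    each unordered pair enters once.  Pairs are split into within-type and
    across-type groups; group means, standard errors, and the Welch
    (unequal-variance) two-sample t-test p-value are returned.  When either
    group has fewer than 2 pairs the test is skipped with a warning.
    """
    subset = [s for s in samples if s.modality == modality]
    if len(subset) < 2:
        raise ValueError("need at least 2 samples")
    within, across = [], []
    for a, b in itertools.combinations(subset, 2):
        value = cc(a.values, b.values)
        (within if a.cell_type == b.cell_type else across).append(value)
    within_a, across_a = np.asarray(within), np.asarray(across)

    def _mean_sem(v: np.ndarray) -> tuple[float, float]:
        if v.size == 0:
            return np.nan, np.nan
        return float(v.mean()), float(stats.sem(v)) if v.size > 1 else np.nan

    wm, ws = _mean_sem(within_a)
    am, asem = _mean_sem(across_a)
    t = p = None
    if within_a.size >= 2 and across_a.size >= 2 and (
        np.std(within_a) > 0 or np.std(across_a) > 0
    ):
        res = stats.ttest_ind(within_a, across_a, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
    else:
        warnings.warn(
            "within/across t-test skipped: a group has <2 pairs or zero variance",
            stacklevel=2,
        )
    return WithinAcrossResult(
        within=within_a,
        across=across_a,
        within_mean=wm,
        within_sem=ws,
        across_mean=am,
        across_sem=asem,
        t=t,
        p=p,
        n_within=within_a.size,
        n_across=across_a.size,
    )


def anova_by_region(samples: list[DistributionVector]) -> pd.DataFrame:
    """Descriptive one-way ANOVA of per-region fractions across cell types.

    Convenience wrapper only: for each region, tests whether the mean
    fraction differs across cell types.  Returns a table with F and p per
    region; no multiple-testing correction is applied and no inference
    machinery is built on top.
    """
    by_type: dict[str, list[DistributionVector]] = {}
    for s in samples:
        by_type.setdefault(s.cell_type, []).append(s)
    if len(by_type) < 2:
        raise ValueError("need samples from at least 2 cell types")
    index = samples[0].fractions.index
    rows = []
    for region in index:
        groups = [[s.fractions[region] for s in group] for group in by_type.values()]
        if all(len(g) >= 2 for g in groups) and any(np.std(g) > 0 for g in groups):
            f, p = stats.f_oneway(*groups)
        else:
            f, p = np.nan, np.nan
        rows.append({"region": region, "F": float(f), "p": float(p)})
    return pd.DataFrame(rows)
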