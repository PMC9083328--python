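"""Per-metabolite concentration comparison across extraction protocols.

For every metabolite that is detectable under at least one protocol in a
sample matrix, the analysis asks which protocols recover it best:

1. missing and zero concentrations are imputed with 20% of the metabolite's
   minimal positive value (taken across all samples of the matrix),
2. concentrations are log2-transformed,
3. a one-way fixed-effects ANOVA with protocol as the categorical factor is
   fit, followed by an all-pairs Tukey HSD post-hoc test (Tukey-Kramer for
   unequal group sizes) on the studentized-range distribution,
4. the *optimal set* is the protocol with the highest median log2
   concentration together with every protocol whose concentration is not
   significantly lower than it (adjusted p > alpha); when exactly one
   protocol remains the metabolite has a *unique best* protocol.

Median ties for the top are broken symmetrically: all tied protocols are
treated as top and the union of their optimal sets is used.  The ANOVA
p-value is reported but does not gate the post-hoc test, since the
selection rule depends only on adjusted pairwise p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from ._tukey import studentized_range_sf
from .detectability import DetectabilityMatrix, DetectionRule, compute_detectability
from .model import (
    ConfigError,
    ExtractBenchError,
    MatrixKey,
    MeasurementTable,
    MetabolitePanel,
    QuantStatus,
)

__all__ = [
    "ComparisonConfig",
    "ProtocolComparison",
    "ImputationError",
    "impute",
    "log2_transform",
    "anova_tukey",
    "optimal_protocols",
    "compare_protocols",
    "OptimalCounts",
    "count_optimal_by_class",
]


class ImputationError(ExtractBenchError):
    """A vector with no strictly positive entry cannot be imputed."""


@dataclass(frozen=True)
class ComparisonConfig:
    """Tunables of the protocol comparison.

    ``alpha`` is the Tukey significance level, ``impute_fraction`` the
    multiple of the minimal positive value used for missing/zero cells.
    The transform base is fixed at 2 (fold changes in doublings).
    """

    alpha: float = 0.05
    impute_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 < self.impute_fraction):
            raise ConfigError(
                f"impute_fraction must be positive, got {self.impute_fraction}"
            )


def impute(values, fraction: float = 0.2) -> np.ndarray:
    """Replace missing (NaN) and zero entries by ``fraction`` × min positive.

    Positive entries pass through unchanged.  Raises
    :class:`ImputationError` when no strictly positive entry exists — such a
    metabolite should have been excluded as nowhere-detectable upstream.
    """
    arr = np.asarray(values, dtype=float).copy()
    pos = arr[np.isfinite(arr) & (arr > 0)]
    if pos.size == 0:
        raise ImputationError("no strictly positive value to impute from")
    floor = fraction * pos.min()
    mask = ~np.isfinite(arr) | (arr == 0)
    arr[mask] = floor
    return arr


def log2_transform(values) -> np.ndarray:
    """Elementwise log base 2; the input must be strictly positive."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr) & (arr > 0)):
        raise ValueError("log2_transform requires strictly positive finite values")
    return np.log2(arr)


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
    config: ComparisonConfig = ComparisonConfig(),
) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA p-value and Tukey HSD adjusted p-value matrix.

    ``groups`` maps protocol name → replicate values (log2 scale).  Needs at
    least two groups with at least two values each.  The adjusted p-value
    matrix is symmetric with unit diagonal; Tukey-Kramer standard errors
    handle unequal group sizes.

    Degenerate inputs (zero pooled within-group variance) use the
    conventions: all values equal → every p-value 1; unequal means with zero
    variance → ANOVA p 0 and pairwise p 0 for unequal / 1 for equal means.
    Both are reported with a warning since they usually arise from
    constant imputation floors.
    """
    names = list(groups)
    if len(names) < 2:
        raise ConfigError("anova_tukey needs at least two protocol groups")
    data = [np.asarray(groups[g], dtype=float) for g in names]
    sizes = np.array([d.size for d in data])
    if (sizes < 2).any():
        small = names[int(np.argmin(sizes))]
        raise ConfigError(
            f"group {small!r} has fewer than 2 values ({sizes.min()})"
        )
    k = len(names)
    means = np.array([d.mean() for d in data])
    n_total = int(sizes.sum())
    df_err = n_total - k
    ss_within = float(sum(((d - m) ** 2).sum() for d, m in zip(data, means)))
    grand = float(np.concatenate(data).mean())
    ss_between = float((sizes * (means - grand) ** 2).sum())

    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    if ss_within == 0.0:
        if np.allclose(means, means[0], rtol=0.0, atol=0.0):
            warnings.warn("all values identical: ANOVA/Tukey p set to 1")
            return 1.0, pmat
        warnings.warn(
            "zero within-group variance with unequal means: p set to 0 "
            "for unequal pairs"
        )
        for i in range(k):
            for j in range(i + 1, k):
                p = 1.0 if means[i] == means[j] else 0.0
                pmat.iloc[i, j] = pmat.iloc[j, i] = p
        return 0.0, pmat

    ms_within = ss_within / df_err
    f_stat = (ss_between / (k - 1)) / ms_within
    anova_p = float(f_dist.sf(f_stat, k - 1, df_err))

    iu, ju = np.triu_indices(k, 1)
    se = np.sqrt(ms_within / 2.0 * (1.0 / sizes[iu] + 1.0 / sizes[ju]))
    q = np.abs(means[iu] - means[ju]) / se
    p_adj = studentized_range_sf(q, k, df_err)
    arr = pmat.to_numpy()
    arr[iu, ju] = p_adj
    arr[ju, iu] = p_adj
    return anova_p, pd.DataFrame(arr, index=names, columns=names)


def optimal_protocols(
    medians: pd.Series, tukey_adj_p: pd.DataFrame, alpha: float = 0.05
) -> frozenset[str]:
    """Protocols with the top median or not significantly below it.

    ``medians`` holds per-protocol median log2 concentrations; the top
    protocol(s) (exact median ties unioned) anchor the comparison and every
    protocol with adjusted p > alpha against an anchor joins the set.
    """
    top_value = medians.max()
    tops = [p for p in medians.index if medians[p] == top_value]
    optimal = set(tops)
    for p in medians.index:
        if any(tukey_adj_p.loc[p, t] > alpha for t in tops):
            optimal.add(p)
    return frozenset(optimal)


@dataclass
class ProtocolComparison:
    """Comparison result for one metabolite within one sample matrix."""

    matrix_key: MatrixKey
    metabolite: str
    protocol_medians: pd.Series        # median log2 imputed concentration
    anova_p: float
    tukey_adj_p: pd.DataFrame
    optimal_set: frozenset[str]
    unique_best: str | None = field(init=False)

    def __post_init__(self) -> None:
        self.unique_best = (
            next(iter(self.optimal_set)) if len(self.optimal_set) == 1 else None
        )


def compare_protocols(
    table: MeasurementTable,
    config: ComparisonConfig = ComparisonConfig(),
    detectability: Mapping[MatrixKey, DetectabilityMatrix] | None = None,
    rule: DetectionRule = DetectionRule(),
) -> dict[MatrixKey, dict[str, ProtocolComparison]]:
    """Run the imputation → log2 → ANOVA/Tukey → optimal-set chain.

    Every metabolite detectable under at least one protocol in a matrix is
    compared across *all* of the matrix's protocols; groups in which the
    metabolite is undetectable contribute their exported numbers or imputed
    floor values, so that a protocol that fails to recover a metabolite is
    penalized rather than dropped.
    """
    if detectability is None:
        detectability = compute_detectability(table, rule)
    results: dict[MatrixKey, dict[str, ProtocolComparison]] = {}
    conc_all = table.concentrations.to_numpy()
    stat_all = table.statuses.to_numpy()
    names = table.panel.names

    for matrix in table.matrices():
        det = detectability[matrix]
        protocols = table.protocols(matrix)
        rows_by_prot = {p: table.group_rows(matrix, p) for p in protocols}
        matrix_rows = np.concatenate([rows_by_prot[p] for p in protocols])
        compare = det.detectable.any(axis=1)
        per_matrix: dict[str, ProtocolComparison] = {}
        for j, met in enumerate(names):
            if not compare[met]:
                continue
            vec = conc_all[matrix_rows, j].copy()
            missing = stat_all[matrix_rows, j] == QuantStatus.MISSING.value
            vec[missing] = np.nan
            try:
                imputed = impute(vec, config.impute_fraction)
            except ImputationError:
                warnings.warn(
                    f"metabolite {met!r} in {matrix}: detectable but no "
                    "positive concentration; skipped"
                )
                continue
            logged = log2_transform(imputed)
            offsets = np.cumsum([0] + [rows_by_prot[p].size for p in protocols])
            groups = {
                p: logged[offsets[i]:offsets[i + 1]]
                for i, p in enumerate(protocols)
            }
            medians = pd.Series({p: float(np.median(v)) for p, v in groups.items()})
            anova_p, padj = anova_tukey(groups, config)
            opt = optimal_protocols(medians, padj, config.alpha)
            per_matrix[met] = ProtocolComparison(
                matrix, met, medians, anova_p, padj, opt
            )
        results[matrix] = per_matrix
    return results


@dataclass
class OptimalCounts:
    """Per-class winner counts for one sample matrix.

    ``optimal`` counts metabolites whose optimal set contains the protocol
    (the stacked-bar heights of the winners figure); ``unique_best`` counts
    metabolites for which that protocol is the single significantly best
    one; ``detectable_total`` is the matrix's number of compared metabolites
    (the dotted line in the winners figure).
    """

    matrix_key: MatrixKey
    optimal: pd.DataFrame
    unique_best: pd.DataFrame
    detectable_total: int


def count_optimal_by_class(
    comparisons: Mapping[str, ProtocolComparison],
    panel: MetabolitePanel,
    det: DetectabilityMatrix,
) -> OptimalCounts:
    """Aggregate optimal-set membership into per (protocol, class) counts."""
    classes = panel.classes
    protocols = list(det.detectable.columns)
    cls = panel.class_of()
    optimal = pd.DataFrame(0, index=protocols, columns=classes, dtype=int)
    unique = pd.DataFrame(0, index=protocols, columns=classes, dtype=int)
    for met, comp in comparisons.items():
        c = cls[met]
        for p in comp.optimal_set:
            optimal.loc[p, c] += 1
        if comp.unique_best is not None:
            unique.loc[comp.unique_best, c] += 1
    optimal["total"] = optimal[classes].sum(axis=1)
    unique["total"] = unique[classes].sum(axis=1)
    detectable_total = int(det.detectable.any(axis=1).sum())
    return OptimalCounts(det.matrix_key, optimal, unique, detectable_total)
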