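"""Differential expression statistics and p-filtered PCA.

Two-group comparisons use the classical pooled-variance (equal-variance)
Student's t-test per antibody, with Benjamini-Hochberg q-values and log10
fold changes (group1 mean minus group2 mean, so positive = upregulated in
group1).  Multi-group comparisons use one-way fixed-effects ANOVA.  For
visualization, antibodies are filtered on a p-value threshold, z-scored,
and projected onto the leading principal components.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = [
    "ttest_table",
    "welch_ttest_table",
    "bh_adjust",
    "anova_pvalues",
    "anova_table",
    "significance_fraction",
    "top_table",
    "PcaResult",
    "pca_projection",
]

_P_FLOOR = 5e-324  # smallest subnormal double; stands in for p -> 0 degeneracies


def _group_arrays(
    m: ExpressionMatrix | pd.DataFrame, labels: dict[str, str] | pd.Series
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    values = m.values if isinstance(m, ExpressionMatrix) else m
    labels = pd.Series(labels)
    labels = labels[labels.index.isin(values.index)]
    values = values.loc[labels.index]
    groups = sorted(labels.unique(), key=str)
    return values, labels.to_numpy(), groups


def ttest_table(
    m: ExpressionMatrix | pd.DataFrame,
    labels: dict[str, str] | pd.Series,
    group_order: tuple[str, str] | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-antibody two-sided Student's t-test between two groups.

    ``log10_fc`` is ``mean(group1) - mean(group2)`` with group1 the first
    of ``group_order`` (default: lexicographic).  Degenerate antibodies
    with zero pooled variance get t=0, p=1 when the means agree, and are
    flagged ``degenerate`` with p at the floating-point floor when they do
    not.  Returns a DataFrame indexed by antibody with columns
    ``t_stat, p_value, q_value, log10_fc, fold_change, direction,
    degenerate``.
    """
    values, y, groups = _group_arrays(m, labels)
    if group_order is not None:
        g1, g2 = group_order
    else:
        g1, g2 = groups
    X1 = values.to_numpy()[y == g1]
    X2 = values.to_numpy()[y == g2]
    n1, n2 = len(X1), len(X2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group, got {n1} ({g1}) and {n2} ({g2})")
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    if equal_var:
        v1 = X1.var(axis=0, ddof=1)
        v2 = X2.var(axis=0, ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full(values.shape[1], n1 + n2 - 2, dtype=float)
    else:
        v1 = X1.var(axis=0, ddof=1) / n1
        v2 = X2.var(axis=0, ddof=1) / n2
        se = np.sqrt(v1 + v2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, n1 + n2 - 2)

    diff = m1 - m2
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.where(se == 0, 1.0, se))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    # zero variance: equal means -> no evidence (p=1); unequal -> maximal evidence
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), _P_FLOOR, p)
    table = pd.DataFrame(
        {
            "t_stat": t,
            "p_value": p,
            "q_value": bh_adjust(p),
            "log10_fc": diff,
            "fold_change": 10.0**diff,
            "direction": np.where(diff > 0, "up", "down"),
            "degenerate": degenerate & (diff != 0),
        },
        index=values.columns,
    )
    table.index.name = "antibody_id"
    table.attrs["groups"] = (g1, g2)
    return table


def welch_ttest_table(m, labels, group_order=None) -> pd.DataFrame:
    """Welch (unequal-variance) variant of :func:`ttest_table`."""
    return ttest_table(m, labels, group_order=group_order, equal_var=False)


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def anova_pvalues(X: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Vectorized one-way fixed-effects ANOVA p-values, one per column.

    ``codes`` are integer group labels per row.  Columns with zero
    between- and within-group variance return p=1 (no evidence); zero
    within- with nonzero between-group variance returns the smallest
    representable p.
    """
    X = np.asarray(X, dtype=float)
    codes = np.asarray(codes)
    groups = np.unique(codes)
    k, n = len(groups), X.shape[0]
    if k < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if n <= k:
        raise ValueError("ANOVA requires more samples than groups")
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for g in groups:
        Xi = X[codes == g]
        mu = Xi.mean(axis=0)
        ssb += len(Xi) * (mu - grand) ** 2
        ssw += ((Xi - mu) ** 2).sum(axis=0)
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = sps.f.sf(F, dfb, dfw)
    both_zero = (ssb <= 1e-300) & (ssw <= 1e-300)
    p = np.where(both_zero, 1.0, p)
    p = np.where((ssw <= 1e-300) & ~both_zero, _P_FLOOR, p)
    return p


def anova_table(
    m: ExpressionMatrix | pd.DataFrame, labels: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-antibody one-way ANOVA over k>=2 groups: columns ``F, p_value,
    q_value``."""
    values, y, groups = _group_arrays(m, labels)
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs >=2 samples")
    codes = pd.Categorical(y).codes
    X = values.to_numpy()
    p = anova_pvalues(X, codes)
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for g in np.unique(codes):
        Xi = X[codes == g]
        mu = Xi.mean(axis=0)
        ssb += len(Xi) * (mu - grand) ** 2
        ssw += ((Xi - mu) ** 2).sum(axis=0)
    dfb, dfw = len(np.unique(codes)) - 1, len(y) - len(np.unique(codes))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ssw > 0, (ssb / dfb) / (ssw / dfw), np.where(ssb > 0, np.inf, 0.0))
    table = pd.DataFrame(
        {"F": F, "p_value": p, "q_value": bh_adjust(p)}, index=values.columns
    )
    table.index.name = "antibody_id"
    return table


def significance_fraction(p: np.ndarray | list[float], threshold: float) -> float:
    """Percentage of p-values strictly below a threshold."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    return 100.0 * float(np.mean(p < threshold))


def top_table(d: pd.DataFrame, k: int = 25, by: str = "q_value") -> pd.DataFrame:
    """The k most discriminating antibodies, ranked ascending by q-value.

    Ties broken by p-value then antibody id (lexicographic) for
    reproducibility.  The result keeps a ``direction`` column so callers
    can partition into up-/downregulated blocks.
    """
    if k > len(d):
        raise ValueError(f"k={k} exceeds the {len(d)} available antibodies")
    ranked = d.copy()
    ranked["_ab"] = ranked.index.astype(str)
    sort_cols = [by] + (["p_value"] if "p_value" in d.columns and by != "p_value" else [])
    ranked = ranked.sort_values(sort_cols + ["_ab"], kind="mergesort").drop(columns="_ab")
    return ranked.head(k)


class PcaResult:
    """Filtered PCA projection: kept antibodies, sample coordinates, and the
    variance fraction per component."""

    def __init__(self, antibodies_kept: list[str], coordinates: pd.DataFrame,
                 variance_explained: np.ndarray):
        self.antibodies_kept = antibodies_kept
        self.coordinates = coordinates
        self.variance_explained = variance_explained


def pca_projection(
    m: ExpressionMatrix | pd.DataFrame,
    p: pd.Series | np.ndarray,
    threshold: float = 1e-10,
    n_components: int = 3,
) -> PcaResult:
    """PCA on p-filtered, per-antibody z-scored data.

    Antibodies with ``p < threshold`` are kept, z-scored (mean 0, sd 1;
    variance normalization as array-PCA tools default to), and the samples
    projected onto the leading components.  The component sign is fixed so
    the largest-magnitude loading is positive, making coordinates
    reproducible across runs.
    """
    values = m.values if isinstance(m, ExpressionMatrix) else m
    p = pd.Series(np.asarray(p, dtype=float), index=values.columns) \
        if not isinstance(p, pd.Series) else p
    keep = [a for a in values.columns if p[a] < threshold]
    if len(keep) < n_components:
        raise ValueError(
            f"only {len(keep)} antibodies pass p < {threshold}; "
            f"need at least n_components={n_components}"
        )
    X = values[keep].to_numpy()
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(Z)
    # fix sign: largest-|loading| of each component made positive
    for c in range(n_components):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1.0
    coordinates = pd.DataFrame(
        coords, index=values.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return PcaResult(keep, coordinates, pca.explained_variance_ratio_.copy())
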