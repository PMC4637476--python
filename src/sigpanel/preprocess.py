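"""Spot-level preprocessing: from raw replicate spots to a normalized matrix.

Pipeline order (each step an explicit, testable operation):

1. local background subtraction per spot, floored at 1.0 linear unit;
2. replicate aggregation under the 15% CV rule — the mean of the 3
   replicate spots is used unless their CV exceeds the cutoff, in which
   case the replicate farthest from the mean is dismissed and the mean of
   the remaining 2 is used;
3. exclusion of near-signal-free samples (robust z-score of the per-sample
   median log10 intensity);
4. log10 transform;
5. round (analysis-day) normalization by the subtract-group-mean strategy:
   per antibody, the within-round mean is subtracted and the global
   antibody mean added back;
6. array-to-array scaling using the 20% of antibodies with the lowest
   cross-sample CV as a reference set, applied as a per-sample offset in
   log10 space (equivalent to a multiplicative factor on the linear
   scale);
7. preanalytical-factor screening: per-antibody one-way ANOVA on hospital,
   gender, age quartile, subarray position and round.

The two normalization steps are exposed both as functions and as
scikit-learn compatible transformers (:class:`RoundMeanNormalizer`,
:class:`ArrayScaleNormalizer`) so they compose with sklearn pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix
from .diffexp import anova_pvalues

__all__ = [
    "ReplicateStats",
    "PreanalyticalReport",
    "PreprocessConfig",
    "RoundMeanNormalizer",
    "ArrayScaleNormalizer",
    "subtract_background",
    "aggregate_replicates",
    "flag_failed_samples",
    "log_transform",
    "normalize_round_means",
    "normalize_array_scale",
    "check_preanalytical_factors",
    "run_preprocessing",
]

_FLOOR = 1.0  # linear-intensity floor after background subtraction


@dataclass
class ReplicateStats:
    """Per-(sample, antibody) replicate quality: CV (%), replicates used,
    and which replicate (1-based index) was dismissed, if any."""

    cv: pd.DataFrame
    n_used: pd.DataFrame
    dismissed: pd.DataFrame  # 0 = none dismissed

    def fraction_from_three(self) -> float:
        """Fraction of values aggregated from all 3 replicates."""
        n = self.n_used.to_numpy()
        valid = n >= 2
        return float((n[valid] == 3).mean()) if valid.any() else float("nan")


@dataclass
class PreanalyticalReport:
    """Per-factor fraction of antibodies with ANOVA p below alpha."""

    fractions: dict[str, float] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.01


@dataclass
class PreprocessConfig:
    cv_cutoff: float = 15.0
    lowcv_fraction: float = 0.20
    z_cutoff: float = -4.0
    median_log_floor: float = 1.0
    alpha: float = 0.01


def subtract_background(spots: pd.DataFrame, floor: float = _FLOOR) -> pd.Series:
    """Net spot signal: intensity minus local background, floored.

    Flooring at 1.0 keeps the subsequent log10 defined (log10(1) = 0) when
    a spot is at or below its local background.
    """
    return (spots["intensity"] - spots["background"]).clip(lower=floor)


def aggregate_replicates(
    spots: pd.DataFrame, cv_cutoff: float = 15.0
) -> tuple[ExpressionMatrix, ReplicateStats]:
    """Aggregate replicate spots into one linear value per (sample, antibody).

    The replicate CV is ``100 * sd / mean`` (sample sd, linear scale) over
    the background-subtracted replicates.  With 3 replicates and CV above
    the cutoff, the replicate farthest from the 3-replicate mean is
    dismissed and the remaining 2 averaged; with fewer than 2 usable
    replicates the value is flagged missing (NaN).
    """
    net = subtract_background(spots)
    wide = spots[["sample_id", "antibody_id", "replicate_index"]].copy()
    wide["net"] = net.to_numpy()
    cube = wide.pivot_table(
        index="sample_id", columns=["antibody_id", "replicate_index"],
        values="net", sort=True,
    )
    samples = list(cube.index)
    antibodies = sorted(wide["antibody_id"].unique())
    max_rep = int(wide["replicate_index"].max())
    arr = np.full((len(samples), len(antibodies), max_rep), np.nan)
    col_ab = cube.columns.get_level_values(0)
    col_rep = cube.columns.get_level_values(1).astype(int)
    ab_pos = {a: i for i, a in enumerate(antibodies)}
    for j, (ab, rep) in enumerate(zip(col_ab, col_rep)):
        arr[:, ab_pos[ab], rep - 1] = cube.iloc[:, j].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        count = np.sum(~np.isnan(arr), axis=2)
        mean = np.nanmean(arr, axis=2)
        sd = np.nanstd(arr, axis=2, ddof=1)
    cv = np.where(mean > 0, 100.0 * sd / mean, 0.0)
    cv = np.where(count >= 2, cv, np.nan)

    value = mean.copy()
    n_used = count.copy()
    dismissed = np.zeros_like(count)

    over = (count == 3) & (cv > cv_cutoff)
    if over.any():
        dev = np.abs(arr - mean[:, :, None])
        far = np.nanargmax(np.where(np.isnan(arr), -np.inf, dev), axis=2)
        si, ai = np.nonzero(over)
        for s, a in zip(si, ai):
            f = far[s, a]
            keep = [r for r in range(3) if r != f and not np.isnan(arr[s, a, r])]
            value[s, a] = arr[s, a, keep].mean()
            n_used[s, a] = len(keep)
            dismissed[s, a] = f + 1

    value[count < 2] = np.nan
    n_used[count < 2] = count[count < 2]

    values = pd.DataFrame(value, index=samples, columns=antibodies)
    if values.isna().any().any():
        n_missing = int(values.isna().sum().sum())
        warnings.warn(f"{n_missing} (sample, antibody) values flagged missing "
                      "(<2 usable replicates)")
    matrix = ExpressionMatrix(
        values=values.fillna(_FLOOR),
        stage="raw_aggregated",
        replicates_used=pd.DataFrame(n_used, index=samples, columns=antibodies),
    )
    stats = ReplicateStats(
        cv=pd.DataFrame(cv, index=samples, columns=antibodies),
        n_used=matrix.replicates_used,
        dismissed=pd.DataFrame(dismissed, index=samples, columns=antibodies),
    )
    return matrix, stats


def flag_failed_samples(
    m: ExpressionMatrix,
    z_cutoff: float = -4.0,
    median_log_floor: float = 1.0,
) -> list[str]:
    """Flag near-signal-free samples.

    A sample is flagged when the robust z-score of its median log10
    intensity — (median_i - cohort median) / (1.4826 * MAD) — falls below
    ``z_cutoff``.  When the cohort MAD is zero the rule degrades to an
    absolute floor on the median log10 intensity.
    """
    if m.stage != "raw_aggregated":
        raise ValueError("flag_failed_samples expects the raw_aggregated stage")
    med = np.log10(np.clip(m.values.to_numpy(), _FLOOR, None))
    sample_median = np.median(med, axis=1)
    center = np.median(sample_median)
    mad = np.median(np.abs(sample_median - center))
    if mad > 0:
        z = (sample_median - center) / (1.4826 * mad)
        flagged = z < z_cutoff
    else:
        flagged = sample_median < median_log_floor
    return [s for s, f in zip(m.samples, flagged) if f]


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log10 of the floored linear values."""
    if m.stage != "raw_aggregated":
        raise ValueError("log_transform expects the raw_aggregated stage")
    logged = np.log10(m.values.clip(lower=_FLOOR))
    return m.with_values(logged, stage="logged")


class RoundMeanNormalizer(TransformerMixin, BaseEstimator):
    """Remove analysis-day (round) batch shifts per antibody.

    Subtract-group-mean strategy: within each round the per-antibody mean
    is subtracted (zero-centering the round) and the global antibody mean
    is added back so intensities stay on their original log10 scale.
    After ``transform`` every (antibody, round) mean equals the global
    antibody mean.

    Parameters
    ----------
    rounds : mapping sample_id -> round, or None to read a ``round``
        column from a sample sheet passed to :meth:`fit`.
    """

    def __init__(self, rounds: dict[str, int] | pd.Series | None = None):
        self.rounds = rounds

    def fit(self, X: pd.DataFrame, y=None):
        if self.rounds is None:
            raise ValueError("RoundMeanNormalizer requires a sample->round mapping")
        rounds = pd.Series(self.rounds)
        missing = [s for s in X.index if s not in rounds.index]
        if missing:
            raise ValueError(f"samples without a round assignment: {missing[:5]}")
        r = rounds.loc[X.index]
        singletons = r.value_counts()
        if (singletons == 1).any():
            warnings.warn(
                "round(s) with a single sample map exactly onto the global mean: "
                f"{sorted(singletons.index[singletons == 1].tolist())}"
            )
        self.global_mean_ = X.mean(axis=0)
        self.round_means_ = X.groupby(r.to_numpy()).mean()
        self.rounds_ = r
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        r = pd.Series(self.rounds).loc[X.index]
        offsets = self.round_means_.loc[r.to_numpy()].to_numpy() - self.global_mean_.to_numpy()
        return X - offsets


class ArrayScaleNormalizer(TransformerMixin, BaseEstimator):
    """Equalize array-to-array intensity scale via low-CV reference antibodies.

    The reference set is the ``lowcv_fraction`` of antibodies with the
    lowest cross-sample CV, computed on the linear scale (CV ties broken
    lexicographically by antibody id).  Each sample's offset is its mean
    log10 level over the reference set minus the grand mean of that
    quantity; the offset is subtracted from all of the sample's values, so
    per-sample reference-set means are equal afterwards.  In linear units
    this is a per-array multiplicative scaling factor.
    """

    def __init__(self, lowcv_fraction: float = 0.20):
        self.lowcv_fraction = lowcv_fraction

    def fit(self, X: pd.DataFrame, y=None):
        n_ref = int(np.floor(self.lowcv_fraction * X.shape[1]))
        if n_ref < 1:
            raise ValueError(
                f"lowcv_fraction={self.lowcv_fraction} selects an empty reference set "
                f"for {X.shape[1]} antibodies"
            )
        linear = 10.0 ** X.to_numpy()
        mu = linear.mean(axis=0)
        sd = linear.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros_like(mu)
        cv = np.where(mu > 0, sd / mu, np.inf)
        order = sorted(range(X.shape[1]), key=lambda j: (cv[j], X.columns[j]))
        self.reference_antibodies_ = [X.columns[j] for j in order[:n_ref]]
        self.grand_mean_ = float(X[self.reference_antibodies_].mean(axis=1).mean())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        offsets = X[self.reference_antibodies_].mean(axis=1) - self.grand_mean_
        return X.sub(offsets, axis=0)

    def sample_offsets(self, X: pd.DataFrame) -> pd.Series:
        return X[self.reference_antibodies_].mean(axis=1) - self.grand_mean_


def normalize_round_means(
    m: ExpressionMatrix, rounds: dict[str, int] | pd.Series
) -> ExpressionMatrix:
    """Functional wrapper over :class:`RoundMeanNormalizer`."""
    if m.stage != "logged":
        raise ValueError("normalize_round_means expects the logged stage")
    norm = RoundMeanNormalizer(rounds=rounds).fit(m.values)
    return m.with_values(norm.transform(m.values), stage="round_normalized")


def normalize_array_scale(
    m: ExpressionMatrix, lowcv_fraction: float = 0.20
) -> ExpressionMatrix:
    """Functional wrapper over :class:`ArrayScaleNormalizer`."""
    if m.stage != "round_normalized":
        raise ValueError("normalize_array_scale expects the round_normalized stage")
    norm = ArrayScaleNormalizer(lowcv_fraction=lowcv_fraction).fit(m.values)
    out = m.with_values(norm.transform(m.values), stage="fully_normalized")
    return out


_PREANALYTICAL_FACTORS = ("center", "gender", "age_bin", "subarray", "round")


def check_preanalytical_factors(
    m: ExpressionMatrix, sheet: pd.DataFrame, alpha: float = 0.01
) -> PreanalyticalReport:
    """Screen technical/demographic factors for systematic effects.

    Per factor, a one-way ANOVA is run for every antibody and the fraction
    of antibodies with p below ``alpha`` reported — a screening use, so no
    multiplicity correction.  Age enters binned into quartiles.  Factors
    with fewer than 2 levels are skipped with a note.
    """
    if m.stage not in ("logged", "fully_normalized", "round_normalized"):
        raise ValueError("preanalytical checks expect log10-scale data")
    meta = sheet.set_index("sample_id").loc[m.samples]
    factor_values = {
        "center": meta["hospital"],
        "gender": meta["gender"],
        "age_bin": pd.qcut(meta["age"], q=4, duplicates="drop").astype(str),
        "subarray": meta["subarray"].astype(str),
        "round": meta["round"].astype(str),
    }
    report = PreanalyticalReport(alpha=alpha)
    X = m.values.to_numpy()
    for factor, levels in factor_values.items():
        codes = pd.Categorical(levels).codes
        if len(np.unique(codes)) < 2:
            report.skipped[factor] = "fewer than 2 levels"
            continue
        p = anova_pvalues(X, codes)
        report.fractions[factor] = float(np.mean(p < alpha))
    return report


def run_preprocessing(
    spots: pd.DataFrame,
    sheet: pd.DataFrame,
    config: PreprocessConfig | None = None,
) -> tuple[ExpressionMatrix, ReplicateStats, PreanalyticalReport]:
    """Full preprocessing pipeline, spot table in, normalized matrix out.

    Order: background subtraction -> replicate aggregation (CV rule) ->
    failed-sample exclusion -> log10 -> round normalization -> array
    scaling -> preanalytical report.  The returned matrix carries the
    excluded samples with reasons; per-stage counts are stored in
    ``matrix.values.attrs['preprocess_log']``.
    """
    config = config or PreprocessConfig()
    matrix, stats = aggregate_replicates(spots, cv_cutoff=config.cv_cutoff)
    failed = flag_failed_samples(
        matrix, z_cutoff=config.z_cutoff, median_log_floor=config.median_log_floor
    )
    if failed:
        matrix = ExpressionMatrix(
            values=matrix.values.drop(index=failed),
            stage=matrix.stage,
            replicates_used=matrix.replicates_used.drop(index=failed),
            excluded_samples=matrix.excluded_samples
            + [(s, "near-signal-free (robust z below cutoff)") for s in failed],
        )
    logged = log_transform(matrix)
    rounds = sheet.set_index("sample_id")["round"]
    round_norm = normalize_round_means(logged, rounds)
    full = normalize_array_scale(round_norm, lowcv_fraction=config.lowcv_fraction)
    report = check_preanalytical_factors(full, sheet, alpha=config.alpha)
    full.values.attrs["preprocess_log"] = {
        "n_samples_in": int(spots["sample_id"].nunique()),
        "n_samples_out": len(full.samples),
        "n_excluded": len(full.excluded_samples),
        "fraction_from_three_replicates": stats.fraction_from_three(),
        "mean_replicate_cv_pct": float(np.nanmean(stats.cv.to_numpy())),
    }
    return full, stats, report
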