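"""Canned validation experiments on the synthetic cohort generator.

These are the package's standard self-checks, runnable from tests or
scripts: a parameter-recovery experiment (can the discovery engine find
planted markers and separate the groups on held-out samples?), a null
calibration (does performance collapse to chance and the t-test hold its
type-I rate when nothing is planted?), and batch-effect / failed-sample
checks on the preprocessing chain.  Problem sizes are chosen so each
experiment completes in minutes on one core while leaving the planted
signal recoverable but not trivial.
"""

from __future__ import annotations

import numpy as np

from .diffexp import ttest_table
from .preprocess import PreprocessConfig, run_preprocessing
from .signature import DiscoveryConfig, run_signature_discovery
from .simulate import (
    CohortConfig,
    EffectProfile,
    NoiseModel,
    antibody_ids,
    build_design,
    plant_effect_profile,
    simulate_spot_table,
)

__all__ = [
    "recovery_cohort",
    "planted_recovery_experiment",
    "null_calibration_experiment",
    "batch_effect_experiment",
    "failed_sample_experiment",
]

#: canonical recovery-experiment design: 60 cases vs 20 controls,
#: 100 antibodies of which 10 carry a 0.8 log10 case-vs-control shift
_RECOVERY = dict(n_cases=60, n_controls=20, n_antibodies=100, k_informative=10,
                 delta=0.8)


def recovery_cohort(seed: int, k_informative: int | None = None,
                    delta: float | None = None):
    """Simulate the two-group recovery cohort (cases=PDAC, controls=NPC).

    Returns ``(spots, sheet, informative_ids)``.  ``k_informative=0``
    gives the matched null cohort with no planted markers.
    """
    k = _RECOVERY["k_informative"] if k_informative is None else k_informative
    delta = _RECOVERY["delta"] if delta is None else delta
    cfg = CohortConfig(
        n_pdac=_RECOVERY["n_cases"],
        n_opd=0,
        n_npc=_RECOVERY["n_controls"],
        subsite_counts={"head": _RECOVERY["n_cases"]},
        n_antibodies=_RECOVERY["n_antibodies"],
        seed=seed,
    )
    ids = antibody_ids(cfg.n_antibodies)
    if k > 0:
        effects = plant_effect_profile(ids, k_npc=k, k_opd=0, k_site=0,
                                       delta=delta, seed=seed)
    else:
        effects = EffectProfile.null(ids)
    sheet = build_design(cfg)
    spots = simulate_spot_table(sheet, effects, NoiseModel(), seed=seed)
    return spots, sheet, effects.informative_sets["delta_pdac_vs_npc"]


def planted_recovery_experiment(seed: int = 7, n_repeats: int = 10,
                                panel_size: int = 25) -> dict:
    """Recover planted markers with the full discovery procedure.

    Runs preprocessing plus 10-repeat backward-elimination discovery on the
    canonical recovery cohort and reports the mean held-out AUC and how
    many of the planted markers made the consensus panel.
    """
    spots, sheet, informative = recovery_cohort(seed)
    matrix, _, _ = run_preprocessing(spots, sheet, PreprocessConfig())
    labels = sheet.set_index("sample_id").loc[matrix.samples, "group"]
    result = run_signature_discovery(
        matrix, labels, ("PDAC", "NPC"),
        DiscoveryConfig(n_repeats=n_repeats, panel_size=panel_size, seed=seed),
    )
    recovered = sorted(set(informative) & set(result["consensus"]["panel"]))
    return {
        "mean_auc": result["summary"]["mean_auc"],
        "mean_sensitivity": result["summary"]["mean_sensitivity"],
        "mean_specificity": result["summary"]["mean_specificity"],
        "n_planted": len(informative),
        "n_recovered": len(recovered),
        "recovered": recovered,
        "summary": result["summary"],
        "result": result,
    }


def null_calibration_experiment(seed: int = 7, n_repeats: int = 10,
                                alpha: float = 0.05) -> dict:
    """Null cohort: chance-level held-out AUC and calibrated type-I rate.

    With no planted effects the discovery engine should not beat chance on
    held-out samples, and the per-antibody t-test should reject at
    approximately ``alpha``.
    """
    spots, sheet, _ = recovery_cohort(seed, k_informative=0)
    matrix, _, _ = run_preprocessing(spots, sheet, PreprocessConfig())
    labels = sheet.set_index("sample_id").loc[matrix.samples, "group"]
    result = run_signature_discovery(
        matrix, labels, ("PDAC", "NPC"),
        DiscoveryConfig(n_repeats=n_repeats, seed=seed),
    )
    de = ttest_table(matrix, labels, group_order=("PDAC", "NPC"))
    return {
        "mean_auc": result["summary"]["mean_auc"],
        "type1_rate": float((de["p_value"] < alpha).mean()),
        "alpha": alpha,
        "n_antibodies": len(de),
    }


def batch_effect_experiment(seed: int = 7) -> dict:
    """Planted round offsets: significant before normalization, chance after.

    Uses a null cohort with strong per-round (analysis-day) log10 offsets
    and reports the fraction of antibodies with round-ANOVA p < 0.01 on
    logged data before and after round normalization.
    """
    from .preprocess import (
        aggregate_replicates,
        check_preanalytical_factors,
        log_transform,
        normalize_round_means,
    )

    cfg = CohortConfig(
        n_pdac=40, n_opd=40, n_npc=20,
        subsite_counts={"head": 40},
        n_antibodies=60,
        seed=seed,
    )
    noise = NoiseModel(round_offsets=[0.30, -0.10, 0.05, -0.20, 0.12],
                       n_failed_opd=0)
    sheet = build_design(cfg)
    spots = simulate_spot_table(
        sheet, EffectProfile.null(antibody_ids(cfg.n_antibodies)), noise,
        seed=seed,
    )
    matrix, _ = aggregate_replicates(spots)
    logged = log_transform(matrix)
    before = check_preanalytical_factors(logged, sheet).fractions["round"]
    rounds = sheet.set_index("sample_id")["round"]
    normalized = normalize_round_means(logged, rounds)
    after = check_preanalytical_factors(normalized, sheet).fractions["round"]
    return {"fraction_significant_before": before,
            "fraction_significant_after": after}


def failed_sample_experiment(seed: int = 7) -> dict:
    """Two near-signal-free samples planted; preprocessing must exclude
    exactly those and nothing else."""
    cfg = CohortConfig(
        n_pdac=30, n_opd=30, n_npc=15,
        subsite_counts={"head": 30},
        n_antibodies=60,
        seed=seed,
    )
    sheet = build_design(cfg)
    spots = simulate_spot_table(
        sheet, EffectProfile.null(antibody_ids(cfg.n_antibodies)),
        NoiseModel(), seed=seed,
    )
    matrix, _, _ = run_preprocessing(spots, sheet, PreprocessConfig())
    excluded = sorted(s for s, _ in matrix.excluded_samples)
    planted = sorted(spots.attrs.get("failed_sample_ids", []))
    return {"excluded": excluded, "planted": planted,
            "exact_match": excluded == planted,
            "n_samples_out": len(matrix.samples)}
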