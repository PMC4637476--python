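"""Full-study orchestration: preprocess, differential expression, PCA and
signature discovery for every configured contrast, with a reproducible
file-tree export.

The standard analysis runs three contrasts — disease vs nonpancreatic
controls (PDAC:NPC), disease vs other pancreatic diseases (PDAC:OPD) and
pancreatic head vs body/tail tumors — and writes, per contrast, the
differential-expression table, the endurance-score (consensus) table, the
K-L elimination curves per repeat, the filtered PCA coordinates, and a
metrics summary.  A manifest with per-file SHA-256 checksums plus a
provenance block (seed, config, package version) closes the export; the
whole tree is byte-identical under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexp import anova_table, pca_projection, top_table, ttest_table
from .io import ExpressionMatrix, write_expression_matrix
from .preprocess import PreprocessConfig, run_preprocessing
from .signature import DiscoveryConfig, run_signature_discovery

__all__ = ["StudyConfig", "StudyReport", "run_full_analysis", "export_report_tables"]

#: the three study contrasts; head:bodytail pools body+tail tumor subsites
DEFAULT_CONTRASTS = ("PDAC:NPC", "PDAC:OPD", "head:bodytail")


@dataclass
class StudyConfig:
    """Flat configuration for the end-to-end analysis (defaults follow the
    published parameters: CV cutoff 15%, low-CV fraction 20%, 2/3 split,
    10 repeats, 25-antibody panels, SVM cost 1, PCA filter p < 1e-10)."""

    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    cv_cutoff: float = 15.0
    lowcv_fraction: float = 0.20
    train_fraction: float = 2.0 / 3.0
    n_repeats: int = 10
    panel_size: int = 25
    cost: float = 1.0
    k_folds: int = 5
    pca_threshold: float = 1e-10
    top_k: int = 25
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contrasts" in data:
            data = {**data, "contrasts": tuple(data["contrasts"])}
        return cls(**data)


@dataclass
class StudyReport:
    matrix: ExpressionMatrix
    diffexp: dict[str, pd.DataFrame] = field(default_factory=dict)
    top_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scores: dict[str, pd.DataFrame] = field(default_factory=dict)
    kl_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    pca: dict[str, pd.DataFrame] = field(default_factory=dict)
    metrics: dict[str, dict] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    preanalytical: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _contrast_labels(
    contrast: str, sheet: pd.DataFrame, samples: list[str]
) -> tuple[pd.Series, tuple[str, str]] | None:
    """Labels for a named contrast; None when a side has <3 samples.

    ``head:bodytail`` compares PDAC head tumors against pooled body+tail
    tumors; subsite ``other``/``unspecified`` samples are excluded from it.
    """
    g1, g2 = contrast.split(":")
    meta = sheet.set_index("sample_id").loc[[s for s in samples]]
    if contrast == "head:bodytail":
        site = meta.loc[meta["group"] == "PDAC", "subsite"]
        lab = site.map({"head": "head", "body": "bodytail", "tail": "bodytail"}).dropna()
    else:
        lab = meta["group"][meta["group"].isin([g1, g2])]
    counts = lab.value_counts()
    if counts.get(g1, 0) < 3 or counts.get(g2, 0) < 3:
        return None
    return lab, (g1, g2)


def run_full_analysis(
    spots: pd.DataFrame,
    sheet: pd.DataFrame,
    config: StudyConfig | None = None,
    annotation: pd.DataFrame | None = None,
) -> StudyReport:
    """Preprocess the cohort and run every configured contrast end to end."""
    config = config or StudyConfig()
    matrix, stats, prereport = run_preprocessing(
        spots,
        sheet,
        PreprocessConfig(cv_cutoff=config.cv_cutoff,
                         lowcv_fraction=config.lowcv_fraction),
    )
    report = StudyReport(matrix=matrix, preanalytical=dict(prereport.fractions))
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.contrasts))
    for contrast, seed in zip(config.contrasts, seeds):
        resolved = _contrast_labels(contrast, sheet, matrix.samples)
        if resolved is None:
            report.skipped[contrast] = "insufficient samples on one side"
            continue
        labels, (g1, g2) = resolved
        sub = matrix.values.loc[labels.index]

        de = ttest_table(sub, labels, group_order=(g1, g2))
        report.diffexp[contrast] = de
        report.top_tables[contrast] = top_table(de, k=min(config.top_k, len(de)))
        try:
            report.pca[contrast] = pca_projection(
                sub, de["p_value"], threshold=config.pca_threshold
            ).coordinates
        except ValueError:
            report.skipped[f"{contrast}/pca"] = "too few antibodies pass the p filter"

        disc = run_signature_discovery(
            sub,
            labels,
            (g1, g2),
            DiscoveryConfig(
                train_fraction=config.train_fraction,
                n_repeats=config.n_repeats,
                panel_size=config.panel_size,
                cost=config.cost,
                k_folds=config.k_folds,
                seed=int(seed.generate_state(1)[0] % (2**31)),
            ),
            annotation=annotation,
        )
        scores = disc["scores"].copy()
        scores["endurances"] = scores["endurances"].map(
            lambda e: ",".join(str(x) for x in e)
        )
        report.scores[contrast] = scores
        report.kl_curves[contrast] = pd.DataFrame(
            {f"repeat_{t.repeat_index}": t.kl_curve for t in disc["traces"]}
        )
        report.metrics[contrast] = {
            **disc["summary"],
            "consensus_panel": disc["consensus"]["panel"],
            "n_nonredundant": disc["consensus"]["n_nonredundant"],
            "per_repeat_auc": [e.auc for e in disc["evaluations"]],
        }
    three_group = sheet.set_index("sample_id").loc[matrix.samples, "group"]
    if three_group.nunique() >= 2 and all(
        c >= 2 for c in three_group.value_counts()
    ):
        report.metrics["multigroup_anova"] = {
            "fraction_p_lt_0.001": float(
                (anova_table(matrix.values, three_group)["p_value"] < 1e-3).mean()
            )
        }
    report.provenance = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()},
        "sigpanel_version": __version__,
        "n_samples": len(matrix.samples),
        "n_antibodies": len(matrix.antibodies),
        "excluded_samples": [list(p) for p in matrix.excluded_samples],
        "preanalytical_fractions": dict(report.preanalytical),
    }
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_report_tables(report: StudyReport, outdir: str | Path) -> list[Path]:
    """Write every report table as TSV/JSON plus a checksummed manifest.

    Re-exporting the same report yields byte-identical files, which the
    manifest makes checkable at a glance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", float_format="%.12g")
        written.append(path)

    write_expression_matrix(report.matrix, outdir / "expression_matrix.tsv")
    written += [outdir / "expression_matrix.tsv",
                outdir / "expression_matrix.tsv.meta.json"]
    for contrast, de in report.diffexp.items():
        tag = contrast.replace(":", "_vs_")
        save_tsv(de, f"diffexp_{tag}.tsv")
        save_tsv(report.top_tables[contrast], f"top{len(report.top_tables[contrast])}_{tag}.tsv")
        if contrast in report.scores:
            save_tsv(report.scores[contrast], f"scores_{tag}.tsv")
        if contrast in report.kl_curves:
            save_tsv(report.kl_curves[contrast], f"kl_curves_{tag}.tsv")
        if contrast in report.pca:
            save_tsv(report.pca[contrast], f"pca_{tag}.tsv")
    metrics_path = outdir / "metrics.json"
    metrics_path.write_text(json.dumps(report.metrics, indent=1, sort_keys=True))
    written.append(metrics_path)
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(report.provenance, indent=1, sort_keys=True))
    written.append(prov_path)
    if report.skipped:
        skip_path = outdir / "skipped.json"
        skip_path.write_text(json.dumps(report.skipped, indent=1, sort_keys=True))
        written.append(skip_path)

    manifest = {p.name: _sha256(p) for p in sorted(written)}
    manifest_path = outdir / "MANIFEST.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written.append(manifest_path)
    return written
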