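"""Data model and TSV interchange for spot-level antibody-microarray data.

Three flat, tab-delimited formats move data between pipeline stages:

* **spot table** — one row per (sample, antibody, replicate spot), carrying
  raw foreground intensity and local background so that background
  subtraction is an explicit, testable step;
* **sample sheet** — per-sample clinical and technical metadata (diagnosis
  group, tumor subsite, hospital, analysis round/slide/subarray, gender,
  age);
* **expression matrix** — samples x antibodies numeric matrix with a JSON
  sidecar recording the processing stage and any excluded samples.

All files are UTF-8, tab-delimited, ``.`` decimal, with a header row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SPOT_COLUMNS",
    "SHEET_COLUMNS",
    "GROUPS",
    "SUBSITES",
    "GENDERS",
    "STAGES",
    "ExpressionMatrix",
    "ValidationReport",
    "SpotTableError",
    "SampleSheetError",
    "read_spot_table",
    "write_spot_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_antibody_annotation",
    "write_antibody_annotation",
    "validate_dataset",
]

SPOT_COLUMNS = [
    "sample_id",
    "round",
    "slide",
    "subarray",
    "antibody_id",
    "replicate_index",
    "segment",
    "intensity",
    "background",
]

SHEET_COLUMNS = [
    "sample_id",
    "group",
    "subsite",
    "diagnosis_detail",
    "hospital",
    "round",
    "slide",
    "subarray",
    "gender",
    "age",
]

ANNOTATION_COLUMNS = ["antibody_id", "antigen", "clone_suffix"]

GROUPS = ("PDAC", "OPD", "NPC")
SUBSITES = ("head", "body", "tail", "other", "unspecified", "NA")
GENDERS = ("M", "F")
STAGES = ("raw_aggregated", "logged", "round_normalized", "fully_normalized")


class SpotTableError(ValueError):
    """Raised when a spot table file violates the format contract."""


class SampleSheetError(ValueError):
    """Raised when a sample sheet file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Samples x antibodies intensity matrix with processing provenance.

    Parameters
    ----------
    values
        DataFrame indexed by ``sample_id`` with one column per
        ``antibody_id``.  Linear fluorescence units at stage
        ``raw_aggregated``, log10 units at every later stage.
    stage
        One of :data:`STAGES`, recording how far preprocessing has run.
    replicates_used
        Optional int DataFrame (same shape) with the number of replicate
        spots (2 or 3) behind each value.
    excluded_samples
        ``(sample_id, reason)`` pairs for samples dropped from ``values``.
    """

    values: pd.DataFrame
    stage: str = "raw_aggregated"
    replicates_used: pd.DataFrame | None = None
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        vals = self.values.to_numpy(dtype=float, copy=False)
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")
        excluded = {s for s, _ in self.excluded_samples}
        overlap = excluded & set(self.values.index)
        if overlap:
            raise ValueError(f"excluded samples still present in matrix: {sorted(overlap)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def antibodies(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        """Return a copy carrying new values/stage but the same provenance."""
        return ExpressionMatrix(
            values=values,
            stage=stage,
            replicates_used=self.replicates_used,
            excluded_samples=list(self.excluded_samples),
        )


@dataclass
class ValidationReport:
    """Cross-check result for a (spot table, sample sheet) pair.

    Violations are data, not exceptions: an empty list means the pair is
    consistent.
    """

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy == valid, mirroring `if report:`
        return self.ok


def _require_columns(df: pd.DataFrame, columns: list[str], what: str, exc: type) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise exc(f"{what}: missing required column(s) {missing}")


def read_spot_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a spot-level intensity table.

    Returns a DataFrame with :data:`SPOT_COLUMNS` in canonical order and
    original row order preserved.  Raises :class:`SpotTableError` naming the
    offending line (1-based, counting the header as line 1) on duplicate
    (sample, antibody, replicate) keys, non-numeric intensities, or negative
    values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "antibody_id": str})
    _require_columns(df, SPOT_COLUMNS, str(path), SpotTableError)
    df = df[SPOT_COLUMNS]
    for col in ("round", "slide", "subarray", "replicate_index", "segment"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise SpotTableError(f"{path}: column {col!r} must be integer")
    for col in ("intensity", "background"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise SpotTableError(f"{path}: non-numeric or non-finite {col} at line {line}")
        if (vals < 0).any():
            line = int((vals < 0).idxmax()) + 2
            raise SpotTableError(f"{path}: negative {col} at line {line}")
        df[col] = vals.astype(float)
    dup = df.duplicated(subset=["sample_id", "antibody_id", "replicate_index"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise SpotTableError(
            f"{path}: duplicate (sample_id, antibody_id, replicate_index) at line {line}"
        )
    # replicate indices per (sample, antibody) must form a prefix of {1,2,3}
    grp = df.groupby(["sample_id", "antibody_id"], sort=False)["replicate_index"]
    bad_prefix = grp.agg(lambda s: sorted(s) != list(range(1, len(s) + 1)))
    if bad_prefix.any():
        key = bad_prefix.idxmax()
        raise SpotTableError(
            f"{path}: replicate_index values for {key} are not 1..n"
        )
    return df.reset_index(drop=True)


def write_spot_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[SPOT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-sample metadata sheet.

    Enforces the enum domains for ``group``, ``subsite`` and ``gender``,
    uniqueness of ``sample_id`` and of the (round, slide, subarray) array
    position, and that only PDAC samples carry a pancreatic subsite.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "diagnosis_detail": str, "hospital": str},
        keep_default_na=False,
    )
    _require_columns(df, SHEET_COLUMNS, str(path), SampleSheetError)
    df = df[SHEET_COLUMNS]
    for col, allowed in (("group", GROUPS), ("subsite", SUBSITES), ("gender", GENDERS)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            value = df.loc[bad.idxmax(), col]
            raise SampleSheetError(
                f"{path}: invalid {col} {value!r}; allowed values are {list(allowed)}"
            )
    if df["sample_id"].duplicated().any():
        dup_id = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SampleSheetError(f"{path}: duplicate sample_id {dup_id!r}")
    non_pdac_site = (df["group"] != "PDAC") & (df["subsite"] != "NA")
    if non_pdac_site.any():
        row = df.loc[non_pdac_site.idxmax()]
        raise SampleSheetError(
            f"{path}: sample {row.sample_id!r} in group {row.group} has subsite "
            f"{row.subsite!r}; only PDAC samples may carry a subsite"
        )
    pos_dup = df.duplicated(subset=["round", "slide", "subarray"])
    if pos_dup.any():
        row = df.loc[pos_dup.idxmax()]
        raise SampleSheetError(
            f"{path}: array position (round={row['round']}, slide={row.slide}, "
            f"subarray={row.subarray}) assigned to more than one sample"
        )
    for col in ("round", "slide", "subarray", "age"):
        df[col] = df[col].astype(int)
    return df.reset_index(drop=True)


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> Path:
    """Write a matrix TSV plus a JSON sidecar with stage and exclusions.

    The TSV keeps the matrix a plain numeric table (first column
    ``sample_id``, one column per antibody); provenance lives in
    ``<path>.meta.json`` so generic tools can read the numbers directly.
    Values roundtrip within 1e-12 (written with 17 significant digits).
    """
    path = Path(path)
    out = m.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")
    meta = {
        "stage": m.stage,
        "excluded_samples": [list(pair) for pair in m.excluded_samples],
    }
    if m.replicates_used is not None:
        meta["replicates_used"] = {
            "samples": list(m.replicates_used.index),
            "antibodies": list(m.replicates_used.columns),
            "values": m.replicates_used.to_numpy(dtype=int).tolist(),
        }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="sample_id")
    values.index = values.index.astype(str)
    sidecar = _sidecar_path(path)
    stage, excluded, reps = "raw_aggregated", [], None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        stage = meta.get("stage", stage)
        excluded = [tuple(pair) for pair in meta.get("excluded_samples", [])]
        if "replicates_used" in meta:
            ru = meta["replicates_used"]
            reps = pd.DataFrame(ru["values"], index=ru["samples"], columns=ru["antibodies"])
    return ExpressionMatrix(
        values=values, stage=stage, replicates_used=reps, excluded_samples=excluded
    )


def read_antibody_annotation(path: str | Path) -> pd.DataFrame:
    """Read an antibody -> antigen annotation table (clone-level ids)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ANNOTATION_COLUMNS, str(path), SpotTableError)
    if df["antibody_id"].duplicated().any():
        raise SpotTableError(f"{path}: duplicate antibody_id in annotation")
    if (df["antigen"] == "").any():
        raise SpotTableError(f"{path}: empty antigen name in annotation")
    return df[ANNOTATION_COLUMNS].reset_index(drop=True)


def write_antibody_annotation(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def validate_dataset(spots: pd.DataFrame, sheet: pd.DataFrame) -> ValidationReport:
    """Cross-check a spot table against its sample sheet.

    Never raises on structurally parseable input; every inconsistency is a
    line in the returned report.  Checks sample-id set equality, layout
    agreement (round/slide/subarray per sample) and antibody completeness.
    """
    violations: list[str] = []
    spot_samples = set(spots["sample_id"])
    sheet_samples = set(sheet["sample_id"])
    for s in sorted(spot_samples - sheet_samples):
        violations.append(f"sample {s!r} present in spot table but missing from sample sheet")
    for s in sorted(sheet_samples - spot_samples):
        violations.append(f"sample {s!r} present in sample sheet but missing from spot table")

    common = spot_samples & sheet_samples
    if common:
        layout_cols = ["round", "slide", "subarray"]
        sheet_pos = sheet.set_index("sample_id")[layout_cols]
        spot_pos = spots.groupby("sample_id")[layout_cols].agg(["min", "max"])
        for s in sorted(common):
            lo = spot_pos.loc[s, [(c, "min") for c in layout_cols]].to_numpy()
            hi = spot_pos.loc[s, [(c, "max") for c in layout_cols]].to_numpy()
            expect = sheet_pos.loc[s].to_numpy()
            if not (np.array_equal(lo, hi) and np.array_equal(lo, expect)):
                violations.append(
                    f"sample {s!r}: spot table layout disagrees with sample sheet "
                    f"(sheet {tuple(expect)}, spots min {tuple(lo)} max {tuple(hi)})"
                )
        n_ab = spots.groupby("sample_id")["antibody_id"].nunique()
        full = spots["antibody_id"].nunique()
        for s in sorted(common):
            if n_ab.get(s, 0) != full:
                violations.append(
                    f"sample {s!r}: only {n_ab.get(s, 0)} of {full} antibodies present"
                )
    dup_pos = sheet.duplicated(subset=["round", "slide", "subarray"], keep=False)
    if dup_pos.any():
        for _, grp in sheet[dup_pos].groupby(["round", "slide", "subarray"]):
            ids = sorted(grp["sample_id"])
            if len(ids) > 1:
                violations.append(
                    f"samples {ids} share array position "
                    f"(round={grp['round'].iloc[0]}, slide={grp['slide'].iloc[0]}, "
                    f"subarray={grp['subarray'].iloc[0]})"
                )
    return ValidationReport(violations=violations)
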