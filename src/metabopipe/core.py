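"""Central dataset container with validation, provenance log and checkpoints.

The :class:`MetaboDataset` plays the role that an annotated expression
container plays in omics pipelines: a features x samples intensity matrix,
per-sample metadata (class, group, batch, injection order), per-feature
metadata (m/z, RT, polarity), attached MS2 spectra, and an append-only log
of every operation that touched the object.  Missing intensities are a
distinct marker (NaN) and are never encoded as zero; by default zeros in
input peak tables are read as missing, because a zero peak area means "not
detected", and the missing-rate filters downstream depend on that
distinction.

Checkpoints are versioned JSON containers; restoring an unknown schema or a
truncated file raises :class:`~metabopipe.errors.CheckpointError` instead of
guessing.  All retention times are stored in seconds.
"""

from __future__ import annotations

import copy as _copy
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CheckpointError
from .spectrum import Spectrum

SAMPLE_CLASSES = ("Subject", "QC", "Blank")

_CHECKPOINT_SCHEMA = "metabopipe-checkpoint/1"


@dataclass
class LogEntry:
    """One provenance record: stage name, parameters, and before/after sizes."""

    stage: str
    params: dict
    n_features_in: int
    n_features_out: int
    n_samples_in: int
    n_samples_out: int
    timestamp: float = field(default_factory=time.time)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "params": self.params,
            "n_features_in": self.n_features_in,
            "n_features_out": self.n_features_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogEntry":
        return cls(**d)


@dataclass
class ValidationReport:
    ok: bool
    issues: list[str]
    warnings: list[str]

    def __str__(self):
        lines = ["OK" if self.ok else "INVALID"]
        lines += [f"issue: {s}" for s in self.issues]
        lines += [f"warning: {s}" for s in self.warnings]
        return "\n".join(lines)


class MetaboDataset:
    """Peak-table dataset: intensities, sample/feature metadata, MS2, log.

    Parameters
    ----------
    expression
        DataFrame of shape (n_features, n_samples); index are feature ids,
        columns are sample ids.  NaN marks a missing (undetected) value.
    samples
        DataFrame indexed by sample id with columns
        ``class`` (Subject/QC/Blank), ``group``, ``batch``,
        ``injection_order`` (positive int, unique within batch).
    features
        DataFrame indexed by feature id with columns ``mz`` (Da),
        ``rt`` (seconds), ``polarity`` ('pos'/'neg'), optional ``adduct``.
    ms2
        Mapping feature id -> list of :class:`Spectrum`.
    log
        Prior provenance entries (the log is append-only).
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        samples: pd.DataFrame,
        features: pd.DataFrame,
        ms2: dict[str, list[Spectrum]] | None = None,
        log: list[LogEntry] | None = None,
    ):
        self.expression = expression.astype(float)
        self.samples = samples
        self.features = features
        self.ms2 = ms2 if ms2 is not None else {}
        self.log = list(log) if log is not None else []

    # ------------------------------------------------------------------ basic

    @property
    def n_features(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    def sample_ids_of_class(self, cls: str) -> list[str]:
        return list(self.samples.index[self.samples["class"] == cls])

    @property
    def qc_sample_ids(self) -> list[str]:
        return self.sample_ids_of_class("QC")

    @property
    def subject_sample_ids(self) -> list[str]:
        return self.sample_ids_of_class("Subject")

    @property
    def groups(self) -> list[str]:
        subj = self.samples[self.samples["class"] == "Subject"]
        return sorted(subj["group"].dropna().unique().tolist())

    @property
    def batches(self) -> list[str]:
        return sorted(self.samples["batch"].dropna().astype(str).unique().tolist())

    def copy(self) -> "MetaboDataset":
        return MetaboDataset(
            self.expression.copy(),
            self.samples.copy(),
            self.features.copy(),
            {k: list(v) for k, v in self.ms2.items()},
            [_copy.deepcopy(e) for e in self.log],
        )

    def log_operation(
        self,
        stage: str,
        params: dict,
        n_features_in: int | None = None,
        n_samples_in: int | None = None,
    ) -> None:
        """Append one provenance entry (never mutates earlier entries)."""
        self.log.append(
            LogEntry(
                stage=stage,
                params=params,
                n_features_in=self.n_features if n_features_in is None else n_features_in,
                n_features_out=self.n_features,
                n_samples_in=self.n_samples if n_samples_in is None else n_samples_in,
                n_samples_out=self.n_samples,
            )
        )

    def subset_features(self, feature_ids) -> "MetaboDataset":
        """New dataset keeping only the given features (log is carried over)."""
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return MetaboDataset(
            self.expression.loc[keep],
            self.samples.copy(),
            self.features.loc[keep],
            {k: v for k, v in self.ms2.items() if k in set(keep)},
            [_copy.deepcopy(e) for e in self.log],
        )

    def subset_samples(self, sample_ids) -> "MetaboDataset":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return MetaboDataset(
            self.expression[keep],
            self.samples.loc[keep],
            self.features.copy(),
            {k: list(v) for k, v in self.ms2.items()},
            [_copy.deepcopy(e) for e in self.log],
        )

    def __eq__(self, other):
        if not isinstance(other, MetaboDataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.expression, other.expression)
            pd.testing.assert_frame_equal(self.samples, other.samples)
            pd.testing.assert_frame_equal(self.features, other.features)
        except AssertionError:
            return False
        if self.ms2 != other.ms2:
            return False
        return [e.to_dict() for e in self.log] == [e.to_dict() for e in other.log]

    def __repr__(self):
        return (
            f"<MetaboDataset {self.n_features} features x {self.n_samples} samples, "
            f"{len(self.qc_sample_ids)} QC, {len(self.batches)} batch(es), "
            f"{len(self.log)} logged operation(s)>"
        )

    def summary(self) -> str:
        """Human-readable status block: dimensions, classes, logged stages."""
        cls_counts = self.samples["class"].value_counts().to_dict()
        miss = float(self.expression.isna().to_numpy().mean()) if self.expression.size else 0.0
        lines = [
            repr(self),
            f"sample classes: {cls_counts}",
            f"overall missing rate: {miss:.3f}",
            "stages: " + " -> ".join(e.stage for e in self.log),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# validation


def validate(dataset: MetaboDataset) -> ValidationReport:
    """Check structural invariants; report-only (the dataset is not modified).

    Issues make the report not-ok; conditions that only disable some stages
    (no QC samples) are warnings.
    """
    issues: list[str] = []
    warnings: list[str] = []

    expr = dataset.expression
    if expr.shape[0] != len(dataset.features):
        issues.append(
            f"dimension mismatch: {expr.shape[0]} expression rows vs "
            f"{len(dataset.features)} feature records"
        )
    if expr.shape[1] != len(dataset.samples):
        issues.append(
            f"dimension mismatch: {expr.shape[1]} expression columns vs "
            f"{len(dataset.samples)} sample records"
        )
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        issues.append(f"duplicate feature id: {dups}")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        issues.append(f"duplicate sample id: {dups}")
    if not expr.index.equals(dataset.features.index):
        if not expr.index.duplicated().any() and set(expr.index) == set(dataset.features.index):
            issues.append("feature metadata ordered differently from expression rows")
        elif expr.shape[0] == len(dataset.features):
            issues.append("feature ids of expression and feature table differ")
    if not expr.columns.equals(dataset.samples.index) and expr.shape[1] == len(dataset.samples):
        issues.append("sample ids of expression and sample table differ")

    vals = expr.to_numpy(dtype=float)
    if vals.size and np.any(vals < 0):
        n = int((vals < 0).sum())
        issues.append(f"negative intensities: {n} entr{'y' if n == 1 else 'ies'}")

    bad_cls = set(dataset.samples.get("class", pd.Series(dtype=object)).dropna()) - set(
        SAMPLE_CLASSES
    )
    if bad_cls:
        issues.append(f"unknown sample class values: {sorted(bad_cls)}")

    if "injection_order" in dataset.samples.columns:
        for batch, sub in dataset.samples.groupby("batch"):
            order = sub["injection_order"]
            if order.duplicated().any():
                issues.append(f"injection_order not unique within batch {batch!r}")
            if (order <= 0).any():
                issues.append(f"non-positive injection_order in batch {batch!r}")

    if "mz" in dataset.features.columns and (dataset.features["mz"] <= 0).any():
        issues.append("non-positive m/z in feature table")
    if "rt" in dataset.features.columns and (dataset.features["rt"] < 0).any():
        issues.append("negative RT in feature table")

    if len(dataset.qc_sample_ids) == 0:
        warnings.append("no QC samples: QC-dependent stages unavailable")

    orphan_ms2 = set(dataset.ms2) - set(dataset.feature_ids)
    if orphan_ms2:
        warnings.append(f"MS2 spectra for unknown features: {sorted(orphan_ms2)[:5]}")

    return ValidationReport(ok=not issues, issues=issues, warnings=warnings)


# ---------------------------------------------------------------------------
# checkpoint / restore


def _spectrum_to_dict(s: Spectrum) -> dict:
    return {
        "precursor_mz": s.precursor_mz,
        "polarity": s.polarity,
        "rt": s.rt,
        "peaks": [[m, i] for m, i in s.peaks],
    }


def _spectrum_from_dict(d: dict) -> Spectrum:
    return Spectrum(
        precursor_mz=d["precursor_mz"],
        polarity=d["polarity"],
        rt=d["rt"],
        peaks=[(m, i) for m, i in d["peaks"]],
    )


def _frame_to_payload(df: pd.DataFrame) -> dict:
    def enc(v):
        if isinstance(v, float) and math.isnan(v):
            return None
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            f = float(v)
            return None if math.isnan(f) else f
        return v

    return {
        "index": [str(i) for i in df.index],
        "columns": list(df.columns),
        # float hex round-trips bitwise; other dtypes pass through
        "data": [
            [v.hex() if isinstance(v, float) and not math.isnan(v) else enc(v) for v in row]
            for row in df.itertuples(index=False, name=None)
        ],
        "float_columns": [c for c in df.columns if pd.api.types.is_float_dtype(df[c])],
    }


def _frame_from_payload(p: dict) -> pd.DataFrame:
    float_cols = set(p.get("float_columns", []))
    cols = p["columns"]
    rows = []
    for row in p["data"]:
        out = []
        for c, v in zip(cols, row):
            if v is None:
                out.append(np.nan)
            elif c in float_cols and isinstance(v, str):
                out.append(float.fromhex(v))
            else:
                out.append(v)
        rows.append(out)
    df = pd.DataFrame(rows, columns=cols, index=pd.Index(p["index"]))
    for c in float_cols:
        df[c] = df[c].astype(float)
    return df


def checkpoint(dataset: MetaboDataset, stage: str, dir: str | Path) -> Path:
    """Serialize the dataset under ``<dir>/Result/<stage>.json``.

    The container is versioned; :func:`restore` rejects unknown schemas.
    Matrix values survive the round trip bitwise (floats stored as hex).
    """
    result_dir = Path(dir) / "Result"
    result_dir.mkdir(parents=True, exist_ok=True)
    path = result_dir / f"{stage}.json"
    payload = {
        "schema": _CHECKPOINT_SCHEMA,
        "stage": stage,
        "expression": _frame_to_payload(dataset.expression),
        "samples": _frame_to_payload(dataset.samples),
        "features": _frame_to_payload(dataset.features),
        "ms2": {
            fid: [_spectrum_to_dict(s) for s in specs] for fid, specs in dataset.ms2.items()
        },
        "log": [e.to_dict() for e in dataset.log],
    }
    path.write_text(json.dumps(payload))
    return path


def restore(path: str | Path) -> MetaboDataset:
    """Load a checkpoint written by :func:`checkpoint`.

    Raises
    ------
    CheckpointError
        If the file is truncated/corrupt or carries an unknown schema id.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, OSError) as e:
        raise CheckpointError(f"corrupt or unreadable checkpoint {path}: {e}") from e
    if not isinstance(payload, dict) or payload.get("schema") != _CHECKPOINT_SCHEMA:
        raise CheckpointError(
            f"unknown checkpoint schema {payload.get('schema') if isinstance(payload, dict) else None!r} "
            f"in {path}; expected {_CHECKPOINT_SCHEMA}"
        )
    try:
        expr = _frame_from_payload(payload["expression"])
        samples = _frame_from_payload(payload["samples"])
        features = _frame_from_payload(payload["features"])
        ms2 = {
            fid: [_spectrum_from_dict(d) for d in specs]
            for fid, specs in payload["ms2"].items()
        }
        log = [LogEntry.from_dict(d) for d in payload["log"]]
    except (KeyError, TypeError, ValueError) as e:
        raise CheckpointError(f"corrupt checkpoint payload in {path}: {e}") from e
    expr.index.name = "feature_id"
    samples.index.name = "sample_id"
    features.index.name = "feature_id"
    return MetaboDataset(expr, samples, features, ms2, log)
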