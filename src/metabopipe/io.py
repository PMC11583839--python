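"""Readers/writers: peak tables, sample sheets, MGF spectra, spectral libraries.

Dialects handled:

* peak table — delimited text (delimiter sniffed among comma/tab/semicolon)
  with columns ``feature_id, mz, rt`` followed by one column per sample;
* sample sheet — delimited text with header
  ``sample_id, class, group, batch, injection_order``;
* MGF (Mascot generic) via :mod:`pyteomics.mgf`; block key precedence
  ``FEATURE_ID`` > ``TITLE``, duplicate keys keep all spectra;
* MSP (NIST text) via :mod:`matchms`, keyed by ``COMPOUND_ID``.

All readers are total on these dialects: a malformed input raises a typed
error with a location, never a silent truncation.  Retention times are
normalised to seconds at read time; a column whose maximum is <= 120 is
assumed to be minutes unless the caller overrides (the decision is logged).
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _pyteomics_mgf

from .core import MetaboDataset
from .errors import ParseError, ReconciliationError, ReferentialError, SchemaError
from .spectrum import Spectrum

_RT_MINUTES_MAX = 120.0  # runs longer than 2 h in minutes are unheard of


def _sniff_delimiter(path: Path) -> str:
    sample = Path(path).read_text().splitlines()
    head = "\n".join(sample[:5])
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    delim = _sniff_delimiter(path)
    return pd.read_csv(path, sep=delim, dtype={0: str})


def _rt_to_seconds(rt: pd.Series, rt_unit: str) -> tuple[pd.Series, str]:
    """Normalise an RT column to seconds; returns (series, detected unit)."""
    if rt_unit not in ("auto", "seconds", "minutes"):
        raise SchemaError(f"rt_unit must be auto/seconds/minutes, got {rt_unit!r}")
    unit = rt_unit
    if unit == "auto":
        unit = "seconds" if float(rt.max()) > _RT_MINUTES_MAX else "minutes"
    if unit == "minutes":
        return rt * 60.0, unit
    return rt.astype(float), unit


# ---------------------------------------------------------------------------
# peak table + sample sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    required = ["sample_id", "class", "group", "batch", "injection_order"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"sample sheet {path} lacks mandatory column(s): {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["batch"] = df["batch"].astype(str)
    df["injection_order"] = df["injection_order"].astype(int)
    df = df.set_index("sample_id")
    df.index.name = "sample_id"
    return df


def read_peak_table(
    table: str | Path,
    sample_sheet: str | Path,
    zero_as_missing: bool = True,
    rt_unit: str = "auto",
    polarity_default: str = "pos",
    column_map: dict[str, str] | None = None,
) -> MetaboDataset:
    """Load a delimited peak table plus its sample sheet into a dataset.

    Parameters
    ----------
    zero_as_missing
        Treat 0 intensities as missing (not detected).  Default True.
    rt_unit
        ``auto`` (detect minutes vs seconds by the maximum value),
        ``seconds`` or ``minutes``.
    column_map
        Optional renaming applied before schema checks, e.g.
        ``{"Compound ID": "feature_id"}`` for vendor exports.
    """
    df = _read_delimited(table)
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("feature_id", "mz", "rt"):
        if col not in df.columns:
            raise SchemaError(f"peak table {table} lacks mandatory column {col!r}")
    df["feature_id"] = df["feature_id"].astype(str)

    meta_cols = ["feature_id", "mz", "rt"] + (
        ["polarity"] if "polarity" in df.columns else []
    ) + (["adduct"] if "adduct" in df.columns else [])
    sample_cols = [c for c in df.columns if c not in meta_cols]

    sheet = read_sample_sheet(sample_sheet)
    absent = [s for s in sheet.index if s not in sample_cols]
    if absent:
        raise ReconciliationError(
            f"sample(s) in sheet absent from peak table: {absent}"
        )
    orphans = [c for c in sample_cols if c not in set(sheet.index)]
    if orphans:
        warnings.warn(f"peak-table column(s) not in sample sheet, ignored: {orphans}")
    used = [s for s in sheet.index]  # sheet order defines column order

    expr = df.set_index("feature_id")[used].astype(float)
    if zero_as_missing:
        expr = expr.mask(expr == 0.0)

    rt_s, unit = _rt_to_seconds(df.set_index("feature_id")["rt"].astype(float), rt_unit)
    features = pd.DataFrame(
        {
            "mz": df.set_index("feature_id")["mz"].astype(float),
            "rt": rt_s,
            "polarity": (
                df.set_index("feature_id")["polarity"]
                if "polarity" in df.columns
                else polarity_default
            ),
        }
    )
    if "adduct" in df.columns:
        features["adduct"] = df.set_index("feature_id")["adduct"]
    features.index.name = "feature_id"
    expr.index.name = "feature_id"
    expr.columns.name = None

    ds = MetaboDataset(expr, sheet, features)
    ds.log_operation(
        "import",
        {
            "table": str(table),
            "sample_sheet": str(sample_sheet),
            "zero_as_missing": zero_as_missing,
            "rt_unit_detected": unit,
            "ignored_columns": orphans,
        },
    )
    return ds


def write_peak_table(dataset: MetaboDataset, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    out = dataset.features[["mz", "rt"]].copy()
    if "polarity" in dataset.features.columns:
        out["polarity"] = dataset.features["polarity"]
    out = pd.concat([out, dataset.expression], axis=1)
    out.insert(0, "feature_id", out.index)
    out.to_csv(path, sep=sep, index=False, float_format="%.12g")
    return path


def write_sample_sheet(dataset: MetaboDataset, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    out = dataset.samples.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# MGF


def _check_mgf_blocks(path: Path) -> None:
    """Pre-scan for unbalanced BEGIN IONS/END IONS; reports the line number."""
    open_line = None
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        token = line.strip().upper()
        if token == "BEGIN IONS":
            if open_line is not None:
                raise ParseError("nested BEGIN IONS", line=i)
            open_line = i
        elif token == "END IONS":
            if open_line is None:
                raise ParseError("END IONS without BEGIN IONS", line=i)
            open_line = None
    if open_line is not None:
        raise ParseError("unterminated BEGIN IONS block", line=open_line)


def read_mgf(file: str | Path, polarity_default: str = "pos") -> dict[str, list[Spectrum]]:
    """Parse an MGF file into feature_id -> spectra.

    Key precedence: ``FEATURE_ID`` > ``TITLE``.  A feature with several MS2
    scans keeps them all.  Malformed peak lines inside a block are skipped
    and counted (reported via a warning); unbalanced blocks are an error.
    """
    path = Path(file)
    _check_mgf_blocks(path)
    out: dict[str, list[Spectrum]] = {}
    skipped = 0
    with _pyteomics_mgf.MGF(str(path), convert_arrays=1) as reader:
        for block in reader:
            params = block.get("params", {})
            key = params.get("feature_id") or params.get("title")
            if key is None:
                skipped += 1
                continue
            key = str(key).strip()
            mz_arr = np.asarray(block.get("m/z array", []), dtype=float)
            int_arr = np.asarray(block.get("intensity array", []), dtype=float)
            if mz_arr.size == 0:
                skipped += 1
                continue
            pepmass = params.get("pepmass", (np.nan,))
            precursor = float(pepmass[0]) if isinstance(pepmass, (tuple, list)) else float(pepmass)
            charge = params.get("charge")
            polarity = polarity_default
            if charge:
                try:
                    polarity = "neg" if int(charge[0]) < 0 else "pos"
                except (TypeError, ValueError, IndexError):
                    pass
            rt = params.get("rtinseconds")
            spec = Spectrum(
                precursor_mz=precursor,
                polarity=polarity,
                rt=float(rt) if rt is not None else None,
                peaks=list(zip(mz_arr.tolist(), int_arr.tolist())),
            )
            out.setdefault(key, []).append(spec)
    if skipped:
        warnings.warn(f"{file}: skipped {skipped} malformed/keyless MGF block(s)")
    return out


def write_mgf(spectra: dict[str, list[Spectrum]], path: str | Path) -> Path:
    """Write spectra as MGF with FEATURE_ID keys (inverse of :func:`read_mgf`)."""
    path = Path(path)
    with path.open("w") as fh:
        for fid in spectra:
            for s in spectra[fid]:
                fh.write("BEGIN IONS\n")
                fh.write(f"FEATURE_ID={fid}\n")
                fh.write(f"TITLE={fid}\n")
                fh.write(f"PEPMASS={s.precursor_mz!r}\n")
                fh.write(f"CHARGE=1{'-' if s.polarity == 'neg' else '+'}\n")
                if s.rt is not None:
                    fh.write(f"RTINSECONDS={s.rt!r}\n")
                for m, i in s.peaks:
                    fh.write(f"{m!r} {i!r}\n")
                fh.write("END IONS\n")
    return path


# ---------------------------------------------------------------------------
# spectral library


@dataclass
class LibraryRecord:
    """One reference metabolite: MS1 mass, optional RT/MS2, taxonomy labels."""

    compound_id: str
    name: str
    formula: str | None = None
    monoisotopic_mass: float = 0.0
    rt: float | None = None
    superclass: str | None = None
    chem_class: str | None = None
    subclass: str | None = None
    pathways: list[str] = field(default_factory=list)
    spectra: list[Spectrum] = field(default_factory=list)


@dataclass
class SpectralLibrary:
    records: dict[str, LibraryRecord]
    orphan_spectra: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)
    source: str = "custom"

    @property
    def n_ms1(self) -> int:
        return len(self.records)

    @property
    def n_with_ms2(self) -> int:
        return sum(1 for r in self.records.values() if r.spectra)

    def __iter__(self):
        return iter(self.records.values())


def _read_msp_spectra(path: Path) -> dict[str, list[Spectrum]]:
    from matchms.importing import load_from_msp

    out: dict[str, list[Spectrum]] = {}
    for s in load_from_msp(str(path), metadata_harmonization=False):
        if s is None:
            continue
        meta = {k.lower(): v for k, v in s.metadata.items()}
        cid = meta.get("compound_id") or meta.get("compoundid") or meta.get("compound_name")
        if cid is None:
            continue
        prec = meta.get("precursor_mz") or meta.get("precursormz") or 0.0
        mode = str(meta.get("ion_mode", meta.get("ionmode", "pos"))).lower()
        polarity = "neg" if mode.startswith("n") else "pos"
        out.setdefault(str(cid), []).append(
            Spectrum(
                precursor_mz=float(prec),
                polarity=polarity,
                peaks=list(zip(s.peaks.mz.tolist(), s.peaks.intensities.tolist())),
            )
        )
    return out


def read_library(ms1_table: str | Path, ms2_file: str | Path | None = None,
                 source: str = "custom") -> SpectralLibrary:
    """Load an MS1 compound table and optionally attach MS2 spectra.

    The MS1 table needs ``compound_id, name, formula, monoisotopic_mass``
    (plus optional ``rt``, ``superclass/class/subclass``, ``pathways``
    semicolon-separated).  ``ms2_file`` may be MSP (NIST) or MGF; spectra
    are keyed by compound_id and orphans are reported, not dropped silently.
    """
    df = _read_delimited(ms1_table)
    for col in ("compound_id", "name", "monoisotopic_mass"):
        if col not in df.columns:
            raise SchemaError(f"library table {ms1_table} lacks column {col!r}")
    if df["compound_id"].astype(str).duplicated().any():
        dups = df["compound_id"][df["compound_id"].astype(str).duplicated()].tolist()
        raise SchemaError(f"compound_id collision in {ms1_table}: {dups}")

    records: dict[str, LibraryRecord] = {}
    rejected: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        cid = str(row["compound_id"])
        mass = float(row["monoisotopic_mass"])
        if not mass > 0:
            rejected.append((cid, f"non-positive monoisotopic mass {mass}"))
            continue
        rt = row.get("rt", np.nan)
        rt = None if pd.isna(rt) else float(rt)
        pathways = row.get("pathways", "")
        pathways = (
            [p for p in str(pathways).split(";") if p and p != "nan"]
            if not pd.isna(pathways)
            else []
        )
        records[cid] = LibraryRecord(
            compound_id=cid,
            name=str(row["name"]),
            formula=str(row["formula"]) if "formula" in row and not pd.isna(row["formula"]) else None,
            monoisotopic_mass=mass,
            rt=rt,
            superclass=None if pd.isna(row.get("superclass", np.nan)) else str(row["superclass"]),
            chem_class=None if pd.isna(row.get("class", np.nan)) else str(row["class"]),
            subclass=None if pd.isna(row.get("subclass", np.nan)) else str(row["subclass"]),
            pathways=pathways,
        )

    orphans: list[str] = []
    if ms2_file is not None:
        ms2_path = Path(ms2_file)
        if ms2_path.suffix.lower() == ".mgf":
            spectra = read_mgf(ms2_path)
        else:
            spectra = _read_msp_spectra(ms2_path)
        for cid, specs in spectra.items():
            if cid in records:
                records[cid].spectra.extend(specs)
            else:
                orphans.append(cid)
        if orphans:
            warnings.warn(f"{ms2_file}: MS2 spectra for unknown compound(s): {sorted(orphans)}")

    return SpectralLibrary(records=records, orphan_spectra=sorted(orphans),
                           rejected=rejected, source=source)


# ---------------------------------------------------------------------------
# integrated export


def export_integrated(dataset: MetaboDataset, annotations, dir: str | Path) -> dict:
    """Write the annotated clean data bundle.

    Produces four files under ``dir`` — annotation table, peak-area table,
    sample sheet, and an MGF of the attached MS2 spectra — and returns a
    manifest mapping file role to (path, row count).  Annotation records
    must reference existing features.
    """
    from .annotation import annotation_table  # local import avoids a cycle

    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    known = set(dataset.feature_ids)
    bad = [a.feature_id for a in annotations if a.feature_id not in known]
    if bad:
        raise ReferentialError(f"annotation(s) reference unknown feature(s): {sorted(set(bad))}")

    ann_df = annotation_table(annotations, dataset)
    ann_path = dir / "annotation.tsv"
    ann_df.to_csv(ann_path, sep="\t", index=False, float_format="%.12g")

    peak_path = write_peak_table(dataset, dir / "peak_area.tsv")
    sheet_path = write_sample_sheet(dataset, dir / "sample_sheet.tsv")
    mgf_path = write_mgf(dataset.ms2, dir / "spectra.mgf")

    return {
        "annotation": (str(ann_path), len(ann_df)),
        "peak_area": (str(peak_path), dataset.n_features),
        "sample_sheet": (str(sheet_path), dataset.n_samples),
        "mgf": (str(mgf_path), sum(len(v) for v in dataset.ms2.values())),
    }
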