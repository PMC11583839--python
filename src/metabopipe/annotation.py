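"""Feature annotation against a spectral library with MSI confidence levels.

A feature is cross-referenced against library records by three evidences:

* **m/z** — theoretical adduct m/z within a ppm tolerance (always required);
* **RT** — library retention time present and within ``rt_tol_s``;
* **MS2** — square-root-intensity cosine between the feature's MS2 scan and
  a library spectrum, with greedy one-to-one fragment pairing, at or above
  ``ms2_score_min``.

Confidence follows the Metabolomics Standards Initiative: level 1 needs all
three evidences, level 2 needs m/z + MS2, level 3 is m/z only.  The
composite ``total_score`` is a weighted mean of the evidences actually
present (default weights m/z 0.25, RT 0.25, MS2 0.5, renormalized).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MetaboDataset
from .errors import ParameterError
from .io import SpectralLibrary
from .spectrum import Spectrum

PROTON = 1.007276466  # Da

#: adduct -> (mass shift in Da, charge sign)
ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON, +1),
    "[M+Na]+": (22.989218, +1),
    "[M+NH4]+": (18.033823, +1),
    "[M-H2O+H]+": (PROTON - 18.010565, +1),
    "[M-H]-": (-PROTON, -1),
    "[M+HCOO]-": (44.998201, -1),
}

DEFAULT_WEIGHTS = {"mz": 0.25, "rt": 0.25, "ms2": 0.5}


@dataclass
class AnnotationRecord:
    """One feature <-> library compound hit with its evidences and MSI level."""

    feature_id: str
    compound_id: str
    name: str
    adduct: str
    mz_error_ppm: float
    rt_error_s: float | None
    ms2_score: float | None
    total_score: float
    level: int
    library_source: str = "custom"


def adduct_mz(monoisotopic_mass: float, adduct: str) -> float:
    """Theoretical m/z of ``adduct`` for a neutral monoisotopic mass (singly charged)."""
    if adduct not in ADDUCTS:
        raise ParameterError(
            f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        )
    shift, _ = ADDUCTS[adduct]
    return monoisotopic_mass + shift


def ppm_error(observed: float, theoretical: float) -> float:
    return 1e6 * (observed - theoretical) / theoretical


def match_ms1(
    feature,
    library: SpectralLibrary,
    ppm_tol: float = 25.0,
    polarity_filter: bool = True,
) -> list[tuple[str, str, float]]:
    """All (compound_id, adduct, signed ppm error) within tolerance, by |error|.

    ``feature`` needs attributes/keys ``mz`` and ``polarity``.  When
    ``polarity_filter`` is set, only adducts of the feature's charge sign
    are considered (the record itself carries no polarity).
    """
    mz = float(feature["mz"] if isinstance(feature, (dict, pd.Series)) else feature.mz)
    pol = feature["polarity"] if isinstance(feature, (dict, pd.Series)) else feature.polarity
    sign = -1 if str(pol) == "neg" else +1

    hits = []
    for rec in library:
        for adduct, (shift, charge) in ADDUCTS.items():
            if polarity_filter and charge != sign:
                continue
            theo = rec.monoisotopic_mass + shift
            err = ppm_error(mz, theo)
            if abs(err) <= ppm_tol:
                hits.append((rec.compound_id, adduct, err))
    hits.sort(key=lambda h: (abs(h[2]), h[0], h[1]))
    return hits


def _greedy_pairs(
    mz_a: np.ndarray, mz_b: np.ndarray, tol: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest fragment pairing within an absolute tolerance."""
    cand = [
        (abs(ma - mb), i, j)
        for i, ma in enumerate(mz_a)
        for j, mb in enumerate(mz_b)
        if abs(ma - mb) <= tol
    ]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return pairs


def score_ms2(query: Spectrum, reference: Spectrum, frag_tol_da: float = 0.02) -> float:
    """Square-root-intensity cosine over the union of fragments, in [0, 1].

    Fragments are paired greedily (nearest first, each used once) within
    ``frag_tol_da``; unpaired fragments contribute zero to the other side.
    Symmetric in its arguments and invariant to uniform intensity scaling.
    """
    qa, qb = np.sqrt(query.intensity), np.sqrt(reference.intensity)
    pairs = _greedy_pairs(query.mz, reference.mz, frag_tol_da)
    dot = sum(qa[i] * qb[j] for i, j in pairs)
    norm = float(np.linalg.norm(qa) * np.linalg.norm(qb))
    if norm == 0:
        return 0.0
    return float(min(1.0, dot / norm))


def _best_ms2(
    query_spectra: list[Spectrum], ref_spectra: list[Spectrum], frag_tol_da: float
) -> float | None:
    """Best same-polarity pairwise MS2 score, or None if no comparable pair."""
    best = None
    for q in query_spectra:
        for r in ref_spectra:
            if q.polarity != r.polarity:
                continue
            s = score_ms2(q, r, frag_tol_da)
            best = s if best is None else max(best, s)
    return best


def annotate(
    dataset: MetaboDataset,
    library: SpectralLibrary,
    ppm_tol: float = 25.0,
    rt_tol_s: float = 30.0,
    ms2_score_min: float = 0.5,
    frag_tol_da: float = 0.02,
    levels_allowed: set[int] = frozenset({1, 2, 3}),
    weights: dict[str, float] = None,
) -> list[AnnotationRecord]:
    """Annotate every feature; one record per passing (feature, compound, adduct).

    Level logic: MS1 match within ``ppm_tol`` is the entry ticket; MS2
    evidence additionally requires a score >= ``ms2_score_min``; RT evidence
    requires a library RT within ``rt_tol_s``.  Level 1 = all three,
    level 2 = m/z + MS2, level 3 = m/z only (m/z + RT without MS2 also
    stays level 3).  ``total_score`` averages the present evidences with
    weights renormalized over what is available.
    """
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    records: list[AnnotationRecord] = []
    for fid, feat in dataset.features.iterrows():
        hits = match_ms1(feat, library, ppm_tol=ppm_tol)
        if not hits:
            continue
        query_spectra = dataset.ms2.get(fid, [])
        for compound_id, adduct, ppm in hits:
            rec = library.records[compound_id]
            mz_score = 1.0 - abs(ppm) / ppm_tol if ppm_tol > 0 else 1.0

            rt_err = None
            rt_score = None
            if rec.rt is not None and not np.isnan(feat["rt"]):
                delta = float(feat["rt"]) - rec.rt
                if abs(delta) <= rt_tol_s:
                    rt_err = delta
                    rt_score = 1.0 - abs(delta) / rt_tol_s if rt_tol_s > 0 else 1.0

            ms2 = None
            if query_spectra and rec.spectra:
                ms2 = _best_ms2(query_spectra, rec.spectra, frag_tol_da)
            ms2_pass = ms2 is not None and ms2 >= ms2_score_min

            if ms2_pass and rt_score is not None:
                level = 1
            elif ms2_pass:
                level = 2
            else:
                level = 3
            if level not in levels_allowed:
                continue

            parts = {"mz": mz_score}
            if rt_score is not None:
                parts["rt"] = rt_score
            if ms2_pass:
                parts["ms2"] = ms2
            wsum = sum(weights[k] for k in parts)
            total = sum(weights[k] * v for k, v in parts.items()) / wsum

            records.append(
                AnnotationRecord(
                    feature_id=fid,
                    compound_id=compound_id,
                    name=rec.name,
                    adduct=adduct,
                    mz_error_ppm=ppm,
                    rt_error_s=rt_err,
                    ms2_score=ms2 if ms2_pass else None,
                    total_score=total,
                    level=level,
                    library_source=library.source,
                )
            )
    return records


def deduplicate(
    annotations: list[AnnotationRecord],
    feature_strategy: str = "best_total_score",
    compound_strategy: str = "keep_all",
) -> list[AnnotationRecord]:
    """Resolve redundant annotations.

    ``feature_strategy='best_total_score'`` keeps one record per feature
    (ties: higher level first, then smaller |ppm|, then compound_id);
    ``compound_strategy='best_feature'`` additionally keeps, per compound,
    only its best-scoring feature; ``'first'`` keeps the first feature
    encountered in input order.  Both default to the permissive choice of
    keeping every distinct metabolite that shares an annotation.
    """
    if feature_strategy not in ("best_total_score", "keep_all"):
        raise ParameterError(f"unknown feature_strategy {feature_strategy!r}")
    if compound_strategy not in ("keep_all", "best_feature", "first"):
        raise ParameterError(f"unknown compound_strategy {compound_strategy!r}")

    def rank(a: AnnotationRecord):
        # sort key: best first (MSI level 1 is the most confident)
        return (-a.total_score, a.level, abs(a.mz_error_ppm), a.compound_id)

    out = list(annotations)
    if feature_strategy == "best_total_score":
        best: dict[str, AnnotationRecord] = {}
        for a in out:
            cur = best.get(a.feature_id)
            if cur is None or rank(a) < rank(cur):
                best[a.feature_id] = a
        out = [best[f] for f in sorted(best)]

    if compound_strategy == "best_feature":
        per: dict[str, AnnotationRecord] = {}
        for a in out:
            cur = per.get(a.compound_id)
            if cur is None or rank(a) < rank(cur):
                per[a.compound_id] = a
        out = [per[c] for c in sorted(per)]
    elif compound_strategy == "first":
        seen: set[str] = set()
        kept = []
        for a in out:
            if a.compound_id in seen:
                continue
            seen.add(a.compound_id)
            kept.append(a)
        out = kept

    return out


ANNOTATION_COLUMNS = [
    "feature_id", "mz", "rt", "compound_id", "name", "adduct",
    "mz_error_ppm", "rt_error_s", "ms2_score", "total_score", "level",
    "library_source",
]


def annotation_table(
    annotations: list[AnnotationRecord], dataset: MetaboDataset | None = None
) -> pd.DataFrame:
    """Flat table of annotation records in the stable column order."""
    rows = []
    for a in annotations:
        mz = rt = np.nan
        if dataset is not None and a.feature_id in dataset.features.index:
            mz = dataset.features.loc[a.feature_id, "mz"]
            rt = dataset.features.loc[a.feature_id, "rt"]
        rows.append(
            {
                "feature_id": a.feature_id, "mz": mz, "rt": rt,
                "compound_id": a.compound_id, "name": a.name, "adduct": a.adduct,
                "mz_error_ppm": a.mz_error_ppm, "rt_error_s": a.rt_error_s,
                "ms2_score": a.ms2_score, "total_score": a.total_score,
                "level": a.level, "library_source": a.library_source,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
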