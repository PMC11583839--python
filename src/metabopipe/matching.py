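"""Pseudotargeted MRM ion-pair selection and cross-run feature matching.

MRM selection turns each feature's MS2 scan into a precursor -> product
transition: the precursor is the feature m/z and the product is the most
intense fragment at least 3 Da below the precursor (excluding the
unfragmented precursor itself; ties go to the larger m/z).

Cross-run matching classifies feature pairs into *precise*
(precursor < 100 ppm, product < 20 ppm, RT < 30 s), *rough*
(precursor 100-1,000 ppm, same product/RT gates) or unmatched; an A-feature
counts as matched if it has one or more qualifying B partners.  ppm is
computed against the reference (A) m/z.  Cross-platform consensus uses
greedy mutual-nearest pairing under a combined normalized m/z + RT
distance, each feature used at most once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MetaboDataset

PRECURSOR_EXCLUSION_DA = 3.0  # a "product" this close to the precursor is unfragmented


@dataclass
class IonPair:
    feature_id: str
    precursor_mz: float
    product_mz: float
    rt: float
    polarity: str
    product_rank: int = 1  # intensity rank of the chosen fragment


@dataclass
class MatchClass:
    feature_a: str
    feature_b: str | None
    match: str                      # precise | rough | unmatched
    precursor_ppm: float | None = None
    product_ppm: float | None = None
    rt_delta_s: float | None = None


@dataclass
class MatchSummary:
    pairs: list[MatchClass]
    n_precise: int
    n_rough: int
    n_unmatched: int


def select_mrm(dataset: MetaboDataset,
               exclusion_da: float = PRECURSOR_EXCLUSION_DA) -> tuple[list[IonPair], list[str]]:
    """One MRM transition per feature with MS2; returns (pairs, unpairable ids).

    Product = most intense fragment with mz < precursor - ``exclusion_da``;
    intensity ties resolved toward the larger m/z.  Features whose spectra
    contain no qualifying fragment are reported, not silently dropped.
    """
    pairs: list[IonPair] = []
    unpairable: list[str] = []
    for fid in dataset.feature_ids:
        spectra = dataset.ms2.get(fid, [])
        if not spectra:
            continue
        precursor = float(dataset.features.loc[fid, "mz"])
        rt = float(dataset.features.loc[fid, "rt"])
        polarity = str(dataset.features.loc[fid, "polarity"])
        frags = [(m, i) for s in spectra for m, i in s.peaks
                 if m < precursor - exclusion_da]
        if not frags:
            unpairable.append(fid)
            continue
        # max intensity, ties -> larger m/z; rank among all qualifying frags
        best = max(frags, key=lambda t: (t[1], t[0]))
        rank = 1 + sum(1 for m, i in frags if i > best[1])
        pairs.append(IonPair(fid, precursor, best[0], rt, polarity, product_rank=rank))
    return pairs, unpairable


def mrm_table(pairs: list[IonPair]) -> pd.DataFrame:
    """Vendor-importable transition list."""
    return pd.DataFrame(
        [
            {
                "feature_id": p.feature_id,
                "precursor_mz": p.precursor_mz,
                "product_mz": p.product_mz,
                "rt": p.rt,
                "polarity": p.polarity,
            }
            for p in pairs
        ],
        columns=["feature_id", "precursor_mz", "product_mz", "rt", "polarity"],
    )


def _attrs(x) -> tuple[float, float | None, float]:
    """(precursor_mz, product_mz or None, rt) from an IonPair or feature-like row."""
    if isinstance(x, IonPair):
        return x.precursor_mz, x.product_mz, x.rt
    if isinstance(x, (dict, pd.Series)):
        return float(x["mz"]), x.get("product_mz"), float(x["rt"])
    return float(x.mz), getattr(x, "product_mz", None), float(x.rt)


def _ids(x, i: int) -> str:
    if isinstance(x, IonPair):
        return x.feature_id
    if isinstance(x, (dict, pd.Series)) and "feature_id" in x:
        return str(x["feature_id"])
    return getattr(x, "feature_id", f"f{i}")


def match_feature_sets(
    set_a,
    set_b,
    precursor_ppm_precise: float = 100.0,
    precursor_ppm_rough: float = 1000.0,
    product_ppm: float = 20.0,
    rt_tol_s: float = 30.0,
) -> MatchSummary:
    """Classify every qualifying A x B pair and summarise per A-feature.

    An A-feature is *precise* if at least one B partner passes the precise
    gates, *rough* if its best partner only passes the rough precursor
    window, else unmatched.  Product-ion gates apply only when both sides
    carry a product m/z.  ppm uses the A (reference) m/z as denominator.
    """
    pairs: list[MatchClass] = []
    status: dict[str, str] = {}
    for i, a in enumerate(set_a):
        a_id = _ids(a, i)
        a_pre, a_prod, a_rt = _attrs(a)
        best = "unmatched"
        for j, b in enumerate(set_b):
            b_pre, b_prod, b_rt = _attrs(b)
            pre_ppm = abs(1e6 * (b_pre - a_pre) / a_pre)
            rt_d = abs(b_rt - a_rt)
            if pre_ppm >= precursor_ppm_rough or rt_d >= rt_tol_s:
                continue
            prod_ppm = None
            if a_prod is not None and b_prod is not None:
                prod_ppm = abs(1e6 * (b_prod - a_prod) / a_prod)
                if prod_ppm >= product_ppm:
                    continue
            cls = "precise" if pre_ppm < precursor_ppm_precise else "rough"
            pairs.append(
                MatchClass(a_id, _ids(b, j), cls, pre_ppm, prod_ppm, rt_d)
            )
            if cls == "precise" or best == "unmatched":
                best = cls
        status[a_id] = best
    n_precise = sum(1 for v in status.values() if v == "precise")
    n_rough = sum(1 for v in status.values() if v == "rough")
    n_un = sum(1 for v in status.values() if v == "unmatched")
    for a_id, v in status.items():
        if v == "unmatched":
            pairs.append(MatchClass(a_id, None, "unmatched"))
    return MatchSummary(pairs=pairs, n_precise=n_precise, n_rough=n_rough,
                        n_unmatched=n_un)


def cross_platform_consensus(
    set_a,
    set_b,
    ppm: float = 30.0,
    rt_tol_s: float = 30.0,
) -> pd.DataFrame:
    """Greedy mutual-nearest 1:1 pairing of features across two platforms.

    Candidate pairs must sit within ``ppm`` m/z and ``rt_tol_s`` RT of each
    other; the combined distance is the mean of the two normalized gaps.
    Pairs are consumed nearest-first, each feature used at most once.
    Returns a consensus table keeping A's ids with the B cross-reference.
    """
    cands = []
    a_list = [( _ids(a, i), *_attrs(a)) for i, a in enumerate(set_a)]
    b_list = [( _ids(b, j), *_attrs(b)) for j, b in enumerate(set_b)]
    for ia, (a_id, a_mz, _, a_rt) in enumerate(a_list):
        for ib, (b_id, b_mz, _, b_rt) in enumerate(b_list):
            d_ppm = abs(1e6 * (b_mz - a_mz) / a_mz)
            d_rt = abs(b_rt - a_rt)
            if d_ppm <= ppm and d_rt <= rt_tol_s:
                dist = 0.5 * (d_ppm / ppm + d_rt / rt_tol_s) if (ppm and rt_tol_s) else 0.0
                cands.append((dist, ia, ib, d_ppm, d_rt))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for dist, ia, ib, d_ppm, d_rt in cands:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        rows.append(
            {
                "feature_id": a_list[ia][0],
                "mz": a_list[ia][1],
                "rt": a_list[ia][3],
                "xref_feature_id": b_list[ib][0],
                "xref_mz": b_list[ib][1],
                "xref_rt": b_list[ib][3],
                "ppm": d_ppm,
                "rt_delta_s": d_rt,
            }
        )
    cols = ["feature_id", "mz", "rt", "xref_feature_id", "xref_mz", "xref_rt",
            "ppm", "rt_delta_s"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("feature_id").reset_index(drop=True)
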