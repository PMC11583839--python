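"""Synthetic LC-MS peak-table generator with known ground truth.

Emulates the statistical structure every pipeline stage assumes:

* log-normal baseline intensities, with planted co-accumulation modules
  driven by shared latent factors (hub structure via per-member loadings);
* pooled-QC samples injected every ``qc_every`` runs, equal to the mean
  profile plus small technical noise;
* per-batch multiplicative drift in injection order, visible in QC samples;
* missingness that is part missing-completely-at-random and part
  missing-not-at-random (dropout probability logistic in -log intensity,
  the dominant mechanism in LC-MS);
* optional group effects on chosen features;
* a toy spectral library whose records plant MSI level 1/2/3 evidence for a
  subset of features, plus decoys at least 50 ppm off every feature.

Everything derives from one seed (substreams are spawned deterministically)
so a fixture is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ADDUCTS, PROTON, AnnotationRecord
from .core import MetaboDataset
from .errors import ParameterError
from .io import LibraryRecord, SpectralLibrary
from .spectrum import Spectrum


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset (fully determined by the seed)."""

    module_labels: dict[str, str]                 # feature -> "module_k" or "noise"
    drift_params: dict[str, float]                # batch -> slope
    mcar_rate: float
    mnar_coef: float
    effect_table: dict[tuple[str, str], float] = field(default_factory=dict)
    library_links: dict[str, tuple[str, int]] = field(default_factory=dict)


CHEM_CLASSES = [
    "Prenol lipids", "Fatty acyls", "Flavonoids",
    "Carboxylic acids and derivatives", "Organooxygen compounds",
    "Glucosinolates", "Cinnamic acids and derivatives", "Indoles",
]


def simulate_dataset(
    n_features: int = 300,
    n_samples: int = 100,
    n_groups: int = 2,
    n_batches: int = 1,
    n_modules: int = 5,
    module_size: int = 40,
    within_cor: float = 0.9,
    qc_every: int = 10,
    drift_slope: float = 0.0,
    mcar_rate: float = 0.0,
    mnar_coef: float = 0.0,
    effect_features: int = 0,
    effect_log2: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[MetaboDataset, SimTruth]:
    """Simulate a features x samples peak table with planted structure.

    ``n_samples`` counts Subject samples; QC samples are added on top,
    one per ``qc_every`` injections per batch.  ``within_cor`` is the
    expected pairwise Pearson correlation between members of a module
    (loadings are chosen as sd * sqrt(w / (1 - w)) around the shared
    latent factor).  Drift multiplies intensities by
    ``1 + drift_slope * injection_order`` within each batch.
    """
    if n_modules * module_size > n_features:
        raise ParameterError(
            f"{n_modules} modules x {module_size} features exceed n_features={n_features}"
        )
    if min(n_features, n_samples, n_groups, n_batches, qc_every) < 1:
        raise ParameterError("all size parameters must be positive")
    if not 0.0 <= within_cor < 1.0:
        raise ParameterError("within_cor must be in [0, 1)")

    ss = np.random.SeedSequence(seed)
    rng_base, rng_mod, rng_qc, rng_miss, rng_fx = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    feature_ids = [f"F{i + 1:04d}" for i in range(n_features)]
    module_labels = {}
    for i, fid in enumerate(feature_ids):
        m = i // module_size
        module_labels[fid] = f"module_{m + 1}" if m < n_modules else "noise"

    # subject design: groups round-robin, batches in contiguous blocks
    subj_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    groups = [f"group_{(i % n_groups) + 1}" for i in range(n_samples)]
    batch_of = {}
    per_batch = int(np.ceil(n_samples / n_batches))
    for i, s in enumerate(subj_ids):
        batch_of[s] = f"B{i // per_batch + 1}"

    # log2-scale signal
    base = rng_base.uniform(12.0, 20.0, size=n_features)          # feature means
    lam = noise_sd * np.sqrt(within_cor / (1.0 - within_cor))     # factor loading
    latent = rng_mod.standard_normal((n_modules, n_samples))
    log2x = np.empty((n_features, n_samples))
    for i, fid in enumerate(feature_ids):
        eps = rng_base.standard_normal(n_samples) * noise_sd
        m = i // module_size
        if m < n_modules:
            log2x[i] = base[i] + lam * latent[m] + eps
        else:
            log2x[i] = base[i] + eps

    # planted group effects on the first `effect_features` noise-free features
    effect_table: dict[tuple[str, str], float] = {}
    if effect_features:
        grp_arr = np.array(groups)
        chosen = rng_fx.choice(n_features, size=min(effect_features, n_features),
                               replace=False)
        for i in chosen:
            g = f"group_{int(rng_fx.integers(1, n_groups + 1))}"
            log2x[i, grp_arr == g] += effect_log2
            effect_table[(feature_ids[i], g)] = effect_log2

    # assemble per-batch injection sequences with interleaved QC
    mean_profile = log2x.mean(axis=1)
    columns: list[str] = []
    rows_meta: list[dict] = []
    data_cols: list[np.ndarray] = []
    qc_counter = 0
    for b in sorted(set(batch_of.values())):
        in_batch = [s for s in subj_ids if batch_of[s] == b]
        order = 0
        slot = 0
        for s in in_batch:
            if slot % qc_every == 0:
                qc_counter += 1
                order += 1
                qc_id = f"QC{qc_counter:03d}"
                prof = mean_profile + rng_qc.standard_normal(n_features) * 0.1
                columns.append(qc_id)
                rows_meta.append({"sample_id": qc_id, "class": "QC", "group": "QC",
                                  "batch": b, "injection_order": order})
                data_cols.append(prof)
            order += 1
            slot += 1
            columns.append(s)
            rows_meta.append({"sample_id": s, "class": "Subject",
                              "group": groups[subj_ids.index(s)],
                              "batch": b, "injection_order": order})
            data_cols.append(log2x[:, subj_ids.index(s)])
        # trailing QC closes each batch
        qc_counter += 1
        order += 1
        qc_id = f"QC{qc_counter:03d}"
        columns.append(qc_id)
        rows_meta.append({"sample_id": qc_id, "class": "QC", "group": "QC",
                          "batch": b, "injection_order": order})
        data_cols.append(mean_profile + rng_qc.standard_normal(n_features) * 0.1)

    raw = 2.0 ** np.column_stack(data_cols)
    samples = pd.DataFrame(rows_meta).set_index("sample_id")

    # multiplicative drift per batch
    drift_params = {}
    for b in sorted(set(batch_of.values())):
        drift_params[b] = drift_slope
        if drift_slope:
            ids = samples.index[samples["batch"] == b]
            for s in ids:
                o = samples.loc[s, "injection_order"]
                raw[:, columns.index(s)] *= 1.0 + drift_slope * o

    # missingness: MCAR + MNAR (logistic in -log2 intensity around the 10th pct)
    if mcar_rate or mnar_coef:
        lg = np.log2(raw)
        tau = np.quantile(lg, 0.10)
        p_mnar = 1.0 / (1.0 + np.exp(-mnar_coef * (tau - lg))) if mnar_coef else 0.0
        p = np.clip(mcar_rate + p_mnar, 0.0, 0.95)
        mask = rng_miss.uniform(size=raw.shape) < p
        raw = np.where(mask, np.nan, raw)

    # feature metadata: m/z drawn once, RT in seconds
    rng_feat = np.random.default_rng(ss.spawn(1)[0])
    mz = np.sort(rng_feat.uniform(100.0, 1000.0, size=n_features))
    rt = rng_feat.uniform(30.0, 1200.0, size=n_features)
    polarity = np.where(rng_feat.uniform(size=n_features) < 0.5, "pos", "neg")
    features = pd.DataFrame(
        {"mz": mz, "rt": rt, "polarity": polarity}, index=pd.Index(feature_ids, name="feature_id")
    )

    expr = pd.DataFrame(raw, index=features.index, columns=columns)
    ds = MetaboDataset(expr, samples, features)
    ds.log_operation(
        "simulate",
        {"n_features": n_features, "n_samples": n_samples, "n_modules": n_modules,
         "module_size": module_size, "within_cor": within_cor,
         "n_batches": n_batches, "drift_slope": drift_slope,
         "mcar_rate": mcar_rate, "mnar_coef": mnar_coef, "seed": seed},
    )
    truth = SimTruth(
        module_labels=module_labels,
        drift_params=drift_params,
        mcar_rate=mcar_rate,
        mnar_coef=mnar_coef,
        effect_table=effect_table,
    )
    return ds, truth


def _toy_spectrum(rng: np.random.Generator, precursor: float, polarity: str,
                  n_frag: int = 6, jitter: float = 0.0) -> Spectrum:
    frags = np.sort(rng.uniform(50.0, max(60.0, precursor - 5.0), size=n_frag))
    if jitter:
        frags = frags + rng.normal(0.0, jitter, size=n_frag)
    inten = rng.uniform(0.05, 1.0, size=n_frag)
    return Spectrum(precursor_mz=precursor, polarity=polarity,
                    peaks=list(zip(frags.tolist(), inten.tolist())))


def simulate_library(
    dataset: MetaboDataset,
    n_annotatable: int,
    levels: dict[int, float] | None = None,
    n_decoys: int = 50,
    decoy_min_ppm: float = 50.0,
    seed: int = 0,
) -> tuple[SpectralLibrary, dict[str, int]]:
    """Toy spectral library planting MSI evidence tiers for chosen features.

    For each chosen feature a library record is created whose monoisotopic
    mass back-calculates from the feature m/z under [M+H]+/[M-H]- (so the
    MS1 match is exact), with evidence per planted level:

    * level 1 — library RT equals the feature RT and an MS2 spectrum is
      shared between feature and record;
    * level 2 — shared MS2 but no library RT;
    * level 3 — mass only (no RT, no spectra; any feature MS2 goes unmatched).

    Decoy records sit at least ``decoy_min_ppm`` away from every feature
    m/z.  Returns the library and feature -> planted level.
    """
    if n_annotatable > dataset.n_features:
        raise ParameterError("n_annotatable exceeds the number of features")
    levels = levels or {1: 0.25, 2: 0.5, 3: 0.25}
    probs = np.array([levels.get(1, 0.0), levels.get(2, 0.0), levels.get(3, 0.0)], float)
    if probs.sum() <= 0:
        raise ParameterError("level distribution must have positive mass")
    probs = probs / probs.sum()

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    chosen = list(
        rng.choice(dataset.feature_ids, size=n_annotatable, replace=False)
    )
    records: dict[str, LibraryRecord] = {}
    planted: dict[str, int] = {}
    for idx, fid in enumerate(chosen):
        mz = float(dataset.features.loc[fid, "mz"])
        rt = float(dataset.features.loc[fid, "rt"])
        pol = str(dataset.features.loc[fid, "polarity"])
        mass = mz - PROTON if pol == "pos" else mz + PROTON
        level = int(rng.choice([1, 2, 3], p=probs))
        planted[fid] = level
        cid = f"CMP{idx + 1:04d}"
        rec = LibraryRecord(
            compound_id=cid,
            name=f"compound-{idx + 1}",
            formula=None,
            monoisotopic_mass=mass,
            rt=rt if level == 1 else None,
            chem_class=str(rng.choice(CHEM_CLASSES)),
        )
        if level in (1, 2):
            spec = _toy_spectrum(rng, mz, pol)
            rec.spectra.append(spec)
            dataset.ms2.setdefault(fid, []).append(
                Spectrum(precursor_mz=mz, polarity=pol, peaks=list(spec.peaks))
            )
        records[cid] = rec

    # decoys: keep shifting until far from every feature m/z
    all_mz = dataset.features["mz"].to_numpy(float)
    n_made = 0
    while n_made < n_decoys:
        mass = float(rng.uniform(120.0, 980.0))
        theo = np.array([mass + shift for shift, _ in ADDUCTS.values()])
        ppm_gap = np.min(
            [np.min(np.abs(1e6 * (all_mz - t) / t)) for t in theo]
        )
        if ppm_gap < decoy_min_ppm:
            continue
        n_made += 1
        records[f"DEC{n_made:04d}"] = LibraryRecord(
            compound_id=f"DEC{n_made:04d}",
            name=f"decoy-{n_made}",
            monoisotopic_mass=mass,
            chem_class=str(rng.choice(CHEM_CLASSES)),
        )

    lib = SpectralLibrary(records=records, source="synthetic-toy")
    return lib, planted


def truth_annotation_records(planted: dict[str, int]) -> list[AnnotationRecord]:
    """Planted feature -> level truth as minimal annotation records."""
    return [
        AnnotationRecord(
            feature_id=fid, compound_id="", name="", adduct="",
            mz_error_ppm=0.0, rt_error_s=None, ms2_score=None,
            total_score=1.0, level=level,
        )
        for fid, level in planted.items()
    ]
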