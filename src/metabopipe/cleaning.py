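"""Data cleaning: noise removal, outlier triage, imputation, QC normalization.

The stage order in the default pipeline is

1. :func:`filter_noise` — drop features badly detected in QC *and* in every
   study group ("more than 20%" is strict: a rate of exactly 0.20 is kept);
2. :func:`triage_outliers` — partition Subject samples by missing rate into
   keep (<50%), review (50-80%, a user decision), remove (>80%);
3. :func:`impute_knn` — feature-space k-nearest-neighbour imputation;
4. :func:`normalize_svr_qc` — per-feature, per-batch support-vector
   regression of QC intensity on injection order, dividing out the fitted
   drift curve;
5. :func:`integrate_batches` — per-feature rescaling so every batch's QC
   median equals the global QC median.

Missing-rate arithmetic is always done on the un-imputed matrix; imputation
never alters observed values; normalization preserves the missingness
pattern.  Distances and RSDs use log2(x+1); the stored matrix stays on the
raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .core import MetaboDataset
from .errors import ParameterError

LOG_OFFSET = 1.0


def _log2p(x):
    return np.log2(np.asarray(x, dtype=float) + LOG_OFFSET)


@dataclass
class MissingProfile:
    """Missing-value rates per feature (QC and per group) and per sample."""

    per_feature_qc_rate: pd.Series
    per_feature_group_rates: pd.DataFrame  # features x groups
    per_sample_rate: pd.Series
    warnings: list[str] = field(default_factory=list)


@dataclass
class OutlierTriage:
    keep: list[str]
    review: list[str]
    remove: list[str]


def missing_profile(dataset: MetaboDataset) -> MissingProfile:
    """Exact missing fractions; denominators count only the relevant class.

    QC rates use QC samples only; group rates use Subject samples of that
    group; sample rates use all features.  Empty groups are excluded with a
    warning rather than producing 0/0.
    """
    expr = dataset.expression
    na = expr.isna()
    warns: list[str] = []

    qc = dataset.qc_sample_ids
    qc_rate = (
        na[qc].mean(axis=1) if qc else pd.Series(np.nan, index=expr.index)
    )
    if not qc:
        warns.append("no QC samples: QC rates undefined")

    subj = dataset.samples[dataset.samples["class"] == "Subject"]
    group_cols = {}
    for g, sub in subj.groupby("group"):
        ids = [s for s in sub.index if s in expr.columns]
        if not ids:
            warns.append(f"group {g!r} has no samples in the matrix; excluded")
            continue
        group_cols[g] = na[ids].mean(axis=1)
    group_rates = pd.DataFrame(group_cols, index=expr.index)

    return MissingProfile(
        per_feature_qc_rate=qc_rate,
        per_feature_group_rates=group_rates,
        per_sample_rate=na.mean(axis=0),
        warnings=warns,
    )


def filter_noise(
    dataset: MetaboDataset, qc_thresh: float = 0.2, group_thresh: float = 0.2
) -> MetaboDataset:
    """Remove noise features.

    A feature is removed iff its QC missing rate exceeds ``qc_thresh`` OR
    its missing rate exceeds ``group_thresh`` in *every* study group (a
    feature cleanly detected in one tissue/genotype is biology, not noise).
    Thresholds are strict inequalities.
    """
    for name, v in (("qc_thresh", qc_thresh), ("group_thresh", group_thresh)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {v}")
    if not dataset.qc_sample_ids:
        raise ParameterError("filter_noise needs at least one QC sample")
    prof = missing_profile(dataset)
    if prof.per_feature_group_rates.shape[1] == 0:
        raise ParameterError("filter_noise needs at least one study group")

    bad_qc = prof.per_feature_qc_rate > qc_thresh
    bad_groups = (prof.per_feature_group_rates > group_thresh).all(axis=1)
    keep = dataset.expression.index[~(bad_qc | bad_groups)]

    n_in = dataset.n_features
    out = dataset.subset_features(keep)
    out.log_operation(
        "filter_noise",
        {"qc_thresh": qc_thresh, "group_thresh": group_thresh,
         "removed": n_in - out.n_features},
        n_features_in=n_in,
    )
    return out


def triage_outliers(
    dataset: MetaboDataset, keep_below: float = 0.5, remove_above: float = 0.8
) -> OutlierTriage:
    """Partition Subject samples by missing rate: keep / review / remove.

    ``rate < keep_below`` -> keep; ``keep_below <= rate <= remove_above`` ->
    review (heterogeneous designs make this a judgement call, so removal is
    a separate explicit step); ``rate > remove_above`` -> remove.
    """
    if keep_below > remove_above:
        raise ParameterError(
            f"keep_below ({keep_below}) must not exceed remove_above ({remove_above})"
        )
    prof = missing_profile(dataset)
    keep, review, remove = [], [], []
    for s in dataset.subject_sample_ids:
        rate = float(prof.per_sample_rate[s])
        if rate < keep_below:
            keep.append(s)
        elif rate > remove_above:
            remove.append(s)
        else:
            review.append(s)
    return OutlierTriage(keep=keep, review=review, remove=remove)


def drop_samples(dataset: MetaboDataset, sample_ids: list[str]) -> MetaboDataset:
    """Explicitly remove samples (the action half of :func:`triage_outliers`)."""
    n_in = dataset.n_samples
    out = dataset.subset_samples([s for s in dataset.sample_ids if s not in set(sample_ids)])
    out.log_operation("drop_samples", {"removed": sorted(sample_ids)}, n_samples_in=n_in)
    return out


def impute_knn(dataset: MetaboDataset, k: int = 10) -> MetaboDataset:
    """Feature-space KNN imputation.

    For a missing entry (feature f, sample s), the imputed value is the mean
    of the observed values *in sample s* of the k features nearest to f.
    Nearness is Euclidean distance between log2(x+1) profiles over the
    samples where both features are observed, scaled to a per-sample average
    so short overlaps are comparable to long ones.  Observed entries are
    never altered.
    """
    expr = dataset.expression
    n_feat = expr.shape[0]
    if k >= n_feat:
        raise ParameterError(f"k={k} must be smaller than the number of features ({n_feat})")
    fully_missing = expr.isna().all(axis=1)
    if fully_missing.any():
        raise ParameterError(
            f"feature(s) 100% missing must be filtered before imputation: "
            f"{expr.index[fully_missing].tolist()[:5]}"
        )
    if not expr.isna().to_numpy().any():
        out = dataset.copy()
        out.log_operation("impute_knn", {"k": k, "imputed": 0})
        return out

    X = _log2p(expr.to_numpy())  # features x samples, NaN preserved
    obs = ~np.isnan(X)
    Xz = np.where(obs, X, 0.0)

    # pairwise mean squared difference over shared observed samples
    # sum((xi-xj)^2 over shared) = sum xi^2 + sum xj^2 - 2 xi.xj, masked
    sq = Xz**2
    shared = obs.astype(float) @ obs.T.astype(float)            # counts
    cross = Xz @ Xz.T
    si = sq @ obs.T.astype(float)                                # sum xi^2 over shared
    sj = obs.astype(float) @ sq.T
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = (si + sj - 2 * cross) / shared
    msd[shared == 0] = np.inf
    np.fill_diagonal(msd, np.inf)

    raw = expr.to_numpy().copy()
    order = np.argsort(msd, axis=1)
    n_imputed = 0
    miss_f, miss_s = np.where(np.isnan(raw))
    for f, s in zip(miss_f, miss_s):
        vals = []
        for g in order[f]:
            if not np.isfinite(msd[f, g]):
                break
            v = raw[g, s]
            if not np.isnan(v):
                vals.append(v)
                if len(vals) == k:
                    break
        if vals:
            raw[f, s] = float(np.mean(vals))
        else:  # no observed neighbour in this sample; feature-mean fallback
            raw[f, s] = float(np.nanmean(raw[f]))
        n_imputed += 1

    out = dataset.copy()
    out.expression = pd.DataFrame(raw, index=expr.index, columns=expr.columns)
    out.log_operation("impute_knn", {"k": k, "imputed": n_imputed})
    return out


def qc_rsd(dataset: MetaboDataset) -> pd.Series:
    """Per-feature relative standard deviation (%) across QC samples (raw scale)."""
    qc = dataset.expression[dataset.qc_sample_ids]
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * sd / mean


def median_qc_rsd(dataset: MetaboDataset) -> float:
    return float(qc_rsd(dataset).median())


def normalize_svr_qc(
    dataset: MetaboDataset,
    min_qc_per_batch: int = 5,
    C: float = 1.0,
    epsilon: float = 0.1,
    rel_floor: float = 1e-6,
) -> MetaboDataset:
    """QC-anchored SVR drift correction, per feature and per batch.

    For each feature within each batch, a radial-kernel support-vector
    regression of log2 QC intensity against injection order models the
    instrument drift curve; every sample in the batch is corrected by

        corrected(s) = raw(s) * median(QC raw) / predicted(order(s)),

    with predictions below ``rel_floor * median(QC raw)`` falling back to
    the median (guards against wild extrapolation).  The median QC RSD never
    increases: if the correction would raise it for a feature/batch, the
    feature is left untouched there.
    """
    if "injection_order" not in dataset.samples.columns:
        raise ParameterError("normalize_svr_qc requires injection_order in the sample sheet")
    for batch in dataset.batches:
        ids = dataset.samples.index[
            (dataset.samples["batch"].astype(str) == batch)
            & (dataset.samples["class"] == "QC")
        ]
        if len(ids) < min_qc_per_batch:
            raise ParameterError(
                f"batch {batch!r} has {len(ids)} QC samples (< {min_qc_per_batch}); "
                "use the median-fold fallback flag (normalize_median_fold) instead"
            )

    expr = dataset.expression.copy()
    samples = dataset.samples
    for batch in dataset.batches:
        in_batch = samples.index[samples["batch"].astype(str) == batch]
        in_batch = [s for s in in_batch if s in expr.columns]
        qc_ids = [s for s in in_batch if samples.loc[s, "class"] == "QC"]
        order = samples.loc[in_batch, "injection_order"].to_numpy(float)
        qc_order = samples.loc[qc_ids, "injection_order"].to_numpy(float)

        for fid in expr.index:
            y_qc = expr.loc[fid, qc_ids].to_numpy(float)
            ok = ~np.isnan(y_qc)
            if ok.sum() < min_qc_per_batch:
                continue  # feature too sparse in QC here; leave as-is
            med = float(np.median(y_qc[ok]))
            if med <= 0:
                continue
            svr = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma="scale")
            svr.fit(qc_order[ok].reshape(-1, 1), _log2p(y_qc[ok]))
            pred = 2.0 ** svr.predict(order.reshape(-1, 1)) - LOG_OFFSET
            pred = np.where(pred < rel_floor * med, med, pred)
            row = expr.loc[fid, in_batch].to_numpy(float)
            corrected = row * med / pred
            # guard: never worsen this feature's QC RSD within the batch
            qc_mask = np.array([s in set(qc_ids) for s in in_batch])
            before = _rsd(row[qc_mask])
            after = _rsd(corrected[qc_mask])
            if np.isfinite(after) and (not np.isfinite(before) or after <= before):
                expr.loc[fid, in_batch] = corrected

    out = dataset.copy()
    out.expression = expr
    out.log_operation(
        "normalize_svr_qc",
        {"min_qc_per_batch": min_qc_per_batch, "C": C, "epsilon": epsilon,
         "kernel": "rbf", "gamma": "scale"},
    )
    return out


def _rsd(v: np.ndarray) -> float:
    v = v[~np.isnan(v)]
    if v.size < 2 or np.mean(v) == 0:
        return np.nan
    return float(np.std(v, ddof=1) / np.mean(v))


def normalize_median_fold(dataset: MetaboDataset) -> MetaboDataset:
    """Median fold-change normalization (fallback when QC are too few).

    Each sample is scaled so the median ratio of its features to the
    feature-wise median profile is 1.
    """
    expr = dataset.expression
    ref = expr.median(axis=1)
    ratios = expr.div(ref, axis=0)
    factors = ratios.median(axis=0)
    out = dataset.copy()
    out.expression = expr.div(factors, axis=1)
    out.log_operation("normalize_median_fold", {})
    return out


def integrate_batches(dataset: MetaboDataset) -> MetaboDataset:
    """Scale each batch so its per-feature QC median matches the global one.

    Single-batch data pass through unchanged (logged no-op).  Every batch
    must contain QC samples.
    """
    batches = dataset.batches
    out = dataset.copy()
    if len(batches) < 2:
        out.log_operation("integrate_batches", {"batches": batches, "noop": True})
        return out
    samples = dataset.samples
    qc_all = dataset.qc_sample_ids
    if not qc_all:
        raise ParameterError("integrate_batches requires QC samples")
    expr = dataset.expression.copy()
    global_med = expr[qc_all].median(axis=1)
    for batch in batches:
        in_batch = [s for s in samples.index[samples["batch"].astype(str) == batch]
                    if s in expr.columns]
        qc_ids = [s for s in in_batch if samples.loc[s, "class"] == "QC"]
        if not qc_ids:
            raise ParameterError(f"batch {batch!r} has no QC samples")
        batch_med = expr[qc_ids].median(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = (global_med / batch_med).replace([np.inf, -np.inf], np.nan).fillna(1.0)
        expr[in_batch] = expr[in_batch].mul(factor, axis=0)
    out.expression = expr
    out.log_operation("integrate_batches", {"batches": batches})
    return out
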