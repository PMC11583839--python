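"""Differential accumulation statistics and chemical-taxonomy enrichment.

Per-feature univariate tests (Welch t or Wilcoxon rank-sum) on log2(x+1)
intensities with Benjamini-Hochberg FDR across the feature family, raw-scale
fold changes, and a PLS-DA variable-influence-on-projection (VIP) score from
a two-group discriminant fit on unit-variance-scaled log2 data.  Enrichment
over chemical-class or pathway terms uses the upper-tail hypergeometric
test with BH correction across terms; the reported ``ratio`` is k/n
(overlap over term size).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from .core import MetaboDataset
from .errors import ParameterError

_FDR_METHODS = {"BH": "fdr_bh", "bonferroni": "bonferroni", "BY": "fdr_by"}


@dataclass
class DamRow:
    feature_id: str
    log2_fc: float
    p_value: float
    fdr: float
    vip: float
    mean_a: float
    mean_b: float
    zero_variance: bool = False


def vip_scores(X: np.ndarray, y: np.ndarray, n_components: int = 2) -> np.ndarray:
    """VIP from a PLS regression of a group indicator on X.

    VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a ),
    where SSY_a is the variance of y explained by component a.  The mean of
    squared VIPs over features equals 1 by construction.
    """
    n, p = X.shape
    n_components = max(1, min(n_components, n - 1, p))
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y.astype(float))
    t = pls.x_scores_          # n x a
    w = pls.x_weights_         # p x a
    q = pls.y_loadings_        # 1 x a
    ssy = np.array([
        (t[:, a] ** 2).sum() * (q[0, a] ** 2) for a in range(t.shape[1])
    ])
    if ssy.sum() == 0:
        return np.zeros(p)
    wnorm = w / np.linalg.norm(w, axis=0, keepdims=True)
    vip = np.sqrt(p * (wnorm**2 @ ssy) / ssy.sum())
    return vip


def dam_analysis(
    dataset: MetaboDataset,
    group_a: str,
    group_b: str,
    test: str = "t",
    fdr_method: str = "BH",
    pls_components: int = 2,
) -> list[DamRow]:
    """Per-feature differential accumulation between two Subject groups.

    Tests run on log2(x+1); ``log2_fc = log2(mean_a / mean_b)`` on the raw
    scale; VIP comes from a PLS-DA fit restricted to the two compared
    groups.  Zero-variance features get p = 1 and a warning flag.
    """
    if test not in ("t", "wilcoxon"):
        raise ParameterError(f"test must be 't' or 'wilcoxon', got {test!r}")
    if fdr_method not in _FDR_METHODS:
        raise ParameterError(f"fdr_method must be one of {sorted(_FDR_METHODS)}")

    subj = dataset.samples[dataset.samples["class"] == "Subject"]
    ids_a = [s for s in subj.index[subj["group"] == group_a] if s in dataset.expression.columns]
    ids_b = [s for s in subj.index[subj["group"] == group_b] if s in dataset.expression.columns]
    for name, ids in ((group_a, ids_a), (group_b, ids_b)):
        if len(ids) < 3:
            raise ParameterError(f"group {name!r} has {len(ids)} Subject samples (< 3)")
    if dataset.expression[ids_a + ids_b].isna().to_numpy().any():
        raise ParameterError("dam_analysis requires an imputed (complete) matrix")

    A = dataset.expression[ids_a].to_numpy(float)
    B = dataset.expression[ids_b].to_numpy(float)
    la, lb = np.log2(A + 1.0), np.log2(B + 1.0)

    n_feat = A.shape[0]
    pvals = np.ones(n_feat)
    zero_var = np.zeros(n_feat, dtype=bool)
    if test == "t":
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue)
    else:
        for i in range(n_feat):
            if np.ptp(la[i]) == 0 and np.ptp(lb[i]) == 0:
                continue
            pvals[i] = stats.mannwhitneyu(la[i], lb[i], alternative="two-sided").pvalue
    for i in range(n_feat):
        if np.var(la[i]) == 0 and np.var(lb[i]) == 0:
            zero_var[i] = True
            pvals[i] = 1.0
    pvals = np.nan_to_num(pvals, nan=1.0)

    _, fdr, _, _ = multipletests(pvals, method=_FDR_METHODS[fdr_method])

    X = np.vstack([la.T, lb.T])  # samples x features
    sd = X.std(axis=0, ddof=1)
    informative = sd > 0
    y = np.array([1.0] * len(ids_a) + [0.0] * len(ids_b))
    vip = np.zeros(n_feat)
    if informative.any():
        Xs = (X[:, informative] - X[:, informative].mean(axis=0)) / sd[informative]
        vip[informative] = vip_scores(Xs, y, n_components=pls_components)

    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2_fc = np.log2(mean_a / mean_b)

    return [
        DamRow(
            feature_id=fid,
            log2_fc=float(log2_fc[i]),
            p_value=float(pvals[i]),
            fdr=float(fdr[i]),
            vip=float(vip[i]),
            mean_a=float(mean_a[i]),
            mean_b=float(mean_b[i]),
            zero_variance=bool(zero_var[i]),
        )
        for i, fid in enumerate(dataset.feature_ids)
    ]


def dam_table(rows: list[DamRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id, "log2_fc": r.log2_fc,
                "p_value": r.p_value, "fdr": r.fdr, "vip": r.vip,
                "mean_a": r.mean_a, "mean_b": r.mean_b,
            }
            for r in rows
        ],
        columns=["feature_id", "log2_fc", "p_value", "fdr", "vip", "mean_a", "mean_b"],
    )


@dataclass
class DamSelection:
    """Per-criterion membership plus all intersections (UpSet-ready)."""

    by_criterion: dict[str, set[str]]
    intersections: dict[tuple[str, ...], set[str]]

    @property
    def selected(self) -> set[str]:
        """Features passing every criterion simultaneously."""
        sets = list(self.by_criterion.values())
        if not sets:
            return set()
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return out


def select_dam(
    rows: list[DamRow],
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    vip_min: float = 1.0,
) -> DamSelection:
    """Membership per criterion (|FC| >= fc_min, FDR <= fdr_max, VIP >= vip_min)
    and every criterion intersection."""
    crit = {
        "fc": {r.feature_id for r in rows if abs(r.log2_fc) >= np.log2(fc_min)},
        "fdr": {r.feature_id for r in rows if r.fdr <= fdr_max},
        "vip": {r.feature_id for r in rows if r.vip >= vip_min},
    }
    inter: dict[tuple[str, ...], set[str]] = {}
    names = sorted(crit)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            s = set(crit[combo[0]])
            for c in combo[1:]:
                s &= crit[c]
            inter[combo] = s
    return DamSelection(by_criterion=crit, intersections=inter)


@dataclass
class EnrichmentRow:
    term_id: str
    term_label: str
    k: int
    n: int
    m: int
    N: int
    ratio: float
    p_value: float
    fdr: float


def enrich(
    selected: set[str],
    term_map: dict[str, set[str]],
    universe: set[str],
    term_labels: dict[str, str] | None = None,
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment of ``selected`` over each term.

    Population N = |universe|, successes n = |term ∩ universe|, draws
    m = |selected|, overlap k; p = P(X >= k).  Terms are intersected with
    the universe; ``selected`` must be a subset of it.  BH across terms.
    """
    if not universe:
        raise ParameterError("enrichment universe is empty")
    if not set(selected) <= set(universe):
        raise ParameterError("selected set must be a subset of the universe")

    N, m = len(universe), len(selected)
    rows = []
    for term_id in sorted(term_map):
        members = set(term_map[term_id]) & set(universe)
        n = len(members)
        if n == 0:
            continue
        k = len(members & set(selected))
        # P(X >= k) for X ~ Hypergeom(N, n, m)
        p = float(stats.hypergeom.sf(k - 1, N, n, m))
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                term_label=(term_labels or {}).get(term_id, term_id),
                k=k, n=n, m=m, N=N,
                ratio=k / n,
                p_value=min(1.0, p),
                fdr=np.nan,
            )
        )
    if rows:
        _, fdr, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        for r, f in zip(rows, fdr):
            r.fdr = float(f)
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_label": r.term_label,
                "k": r.k, "n": r.n, "m": r.m, "N": r.N,
                "ratio": r.ratio, "p_value": r.p_value, "fdr": r.fdr,
            }
            for r in rows
        ],
        columns=["term_id", "term_label", "k", "n", "m", "N", "ratio", "p_value", "fdr"],
    )
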