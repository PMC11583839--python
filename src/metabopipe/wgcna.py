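"""Iterative weighted correlation network analysis for metabolite modules.

The classic pipeline — soft-thresholded correlation adjacency, topological
overlap matrix (TOM), average-linkage clustering on 1−TOM, module
eigenmetabolite by SVD, module membership (kME) — run iteratively: after
each round, features that stayed unassigned (grey) or whose own-module kME
falls below the cutoff are dropped and the remaining features are
re-clustered, until no feature is dropped.  Hub metabolites are the members
with kME strictly above the hub threshold (default 0.8).

Module labels follow the conventional color sequence ordered by module
size; ``"grey"`` marks unassigned features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .errors import ParameterError

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
]

GREY = "grey"


@dataclass
class NetworkParams:
    """Tunables of the network construction and the iterative loop."""

    power: int | None = None          # None = pick by scale-free fit
    network_type: str = "unsigned"
    min_module_size: int = 10
    merge_cut: float = 0.25
    kme_cutoff: float = 0.5
    max_rounds: int = 10
    hub_kme: float = 0.8
    cut_height_frac: float = 0.995
    rsq_cut: float = 0.8

    def __post_init__(self):
        if self.power is not None and not 1 <= self.power <= 30:
            raise ParameterError("power must be in 1..30")
        if self.network_type not in ("unsigned", "signed"):
            raise ParameterError("network_type must be 'unsigned' or 'signed'")
        for name in ("merge_cut", "kme_cutoff", "hub_kme"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.min_module_size < 1 or self.max_rounds < 1:
            raise ParameterError("min_module_size and max_rounds must be >= 1")


@dataclass
class RoundSummary:
    round: int
    n_input: int
    n_assigned: int
    n_dropped: int
    n_modules: int


@dataclass
class ModuleResult:
    """Final module structure: labels, kME, eigenmetabolites, TOM, rounds."""

    assignments: dict[str, str]
    kme: pd.DataFrame                  # features x modules
    eigenmetabolites: pd.DataFrame     # samples x modules
    rounds: list[RoundSummary]
    tom: pd.DataFrame                  # final-round features x features
    power: int
    converged: bool = True

    @property
    def modules(self) -> list[str]:
        return list(self.eigenmetabolites.columns)

    def members(self, module: str) -> list[str]:
        return [f for f, m in self.assignments.items() if m == module]


# ---------------------------------------------------------------------------
# network primitives


def _cor(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns (features) of a samples x features matrix."""
    return np.corrcoef(X, rowvar=False)


def adjacency(X: np.ndarray, power: int, network_type: str = "unsigned") -> np.ndarray:
    c = _cor(X)
    c = np.clip(np.nan_to_num(c, nan=0.0), -1.0, 1.0)
    if network_type == "signed":
        a = ((1.0 + c) / 2.0) ** power
    else:
        a = np.abs(c) ** power
    np.fill_diagonal(a, 1.0)
    return a


def pick_soft_threshold(
    X: np.ndarray,
    powers: range | list[int] = range(1, 21),
    rsq_cut: float = 0.8,
    network_type: str = "unsigned",
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate power, connectivity k_i = sum_{u != i} a_iu; the fit
    is the signed R^2 of log10(frequency) against log10(binned k).  Returns
    the smallest power whose signed R^2 >= ``rsq_cut``, else the argmax.
    Constant features are removed (with a warning in the fit table note).
    """
    X = np.asarray(X, dtype=float)
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    if X.shape[1] < 3:
        raise ParameterError("need at least 3 non-constant features")

    rows = []
    for beta in powers:
        a = adjacency(X, beta, network_type)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=0)
        rows.append({"power": beta, "signed_rsq": _scale_free_rsq(k, n_bins),
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    fit = pd.DataFrame(rows)
    ok = fit[fit["signed_rsq"] >= rsq_cut]
    beta = int(ok["power"].iloc[0]) if len(ok) else int(fit.loc[fit["signed_rsq"].idxmax(), "power"])
    return beta, fit


def _scale_free_rsq(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit (WGCNA convention)."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    centers = np.array([k[idx == b].mean() if (idx == b).any() else np.nan
                        for b in range(n_bins)])
    good = (freq > 0) & np.isfinite(centers) & (centers > 0)
    if good.sum() < 3:
        return 0.0
    res = linregress(np.log10(centers[good]), np.log10(freq[good]))
    return float(-np.sign(res.slope) * res.rvalue**2)


def tom_matrix(X: np.ndarray, power: int, network_type: str = "unsigned") -> np.ndarray:
    """Topological overlap matrix of the soft-thresholded network.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    TOM_ii = 1.  Symmetric with entries in [0, 1].
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 3:
        raise ParameterError("TOM needs at least 3 features")
    if np.isnan(X).any():
        raise ParameterError("TOM input must have no missing values")
    a = adjacency(X, power, network_type)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a                      # diag(a)=0 removes the u=i, u=j terms
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return tom


# ---------------------------------------------------------------------------
# modules, eigenmetabolites, kME


def eigenmetabolite(X_module: np.ndarray) -> np.ndarray:
    """First left singular vector of the z-scored module submatrix.

    ``X_module`` is samples x member features.  The sign is flipped so the
    mean correlation with member profiles is positive; the result is the
    module's summary accumulation profile over samples (unit norm).
    """
    Z = _zscore(X_module)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    e = u[:, 0]
    cors = np.array([_pearson(e, Z[:, j]) for j in range(Z.shape[1])])
    if np.nanmean(cors) < 0:
        e = -e
    return e


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    return (X - mu) / np.where(sd == 0, 1.0, sd)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def detect_modules(
    tom: np.ndarray,
    X: np.ndarray,
    min_module_size: int = 10,
    merge_cut: float = 0.25,
    cut_height_frac: float = 0.995,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Cluster 1−TOM by average linkage; static cut; merge similar modules.

    Returns integer labels per feature (0 = grey/unassigned) and a map
    module label -> eigenmetabolite.  Clusters smaller than
    ``min_module_size`` become grey; modules whose eigenmetabolites
    correlate above ``1 - merge_cut`` are merged and recomputed.
    """
    n = tom.shape[0]
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    link = average(squareform(dissim, checks=False))
    max_h = link[:, 2].max() if len(link) else 0.0
    labels = fcluster(link, t=cut_height_frac * max_h, criterion="distance")

    labels = _drop_small(labels, min_module_size)
    if labels.max() == 0:
        return labels, {}

    # iterative merge of near-identical eigenmetabolites
    while True:
        eig = {m: eigenmetabolite(X[:, labels == m]) for m in np.unique(labels) if m != 0}
        mods = sorted(eig)
        merged = False
        for i, mi in enumerate(mods):
            for mj in mods[i + 1:]:
                if _pearson(eig[mi], eig[mj]) > 1.0 - merge_cut:
                    labels[labels == mj] = mi
                    merged = True
                    break
            if merged:
                break
        if not merged:
            break
    labels = _relabel_by_size(labels)
    eig = {m: eigenmetabolite(X[:, labels == m]) for m in np.unique(labels) if m != 0}
    return labels, eig


def _drop_small(labels: np.ndarray, min_size: int) -> np.ndarray:
    out = labels.copy()
    for m in np.unique(labels):
        if (labels == m).sum() < min_size:
            out[labels == m] = 0
    return out


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber modules 1..M in decreasing size (0 stays grey)."""
    sizes = {m: int((labels == m).sum()) for m in np.unique(labels) if m != 0}
    order = sorted(sizes, key=lambda m: (-sizes[m], m))
    mapping = {m: i + 1 for i, m in enumerate(order)}
    out = np.zeros_like(labels)
    for m, new in mapping.items():
        out[labels == m] = new
    return out


def compute_kme(X: np.ndarray, eigenmetabolites: dict[int, np.ndarray]) -> np.ndarray:
    """kME[f, m] = Pearson correlation of feature f with eigenmetabolite m."""
    mods = sorted(eigenmetabolites)
    out = np.zeros((X.shape[1], len(mods)))
    for j, m in enumerate(mods):
        e = eigenmetabolites[m]
        for f in range(X.shape[1]):
            out[f, j] = _pearson(X[:, f], e)
    return out


# ---------------------------------------------------------------------------
# the iterative loop


def iterative_wgcna(
    X: pd.DataFrame,
    params: NetworkParams | None = None,
) -> ModuleResult:
    """Iterate network construction until every remaining feature is assigned.

    ``X`` is samples x features (cleaned, imputed).  The soft threshold is
    selected in round 1 and then held fixed so rounds stay comparable.
    Each round drops grey features and features whose own-module kME is
    below ``params.kme_cutoff``; iteration stops when nothing is dropped or
    ``max_rounds`` is hit (then ``converged=False``).
    """
    params = params or NetworkParams()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    feats = [f for f in X.columns if X[f].std() > 0]
    X = X[feats]

    power = params.power
    rounds: list[RoundSummary] = []
    converged = False
    labels = np.array([], dtype=int)
    eig: dict[int, np.ndarray] = {}
    kme = np.zeros((0, 0))
    tom = np.zeros((0, 0))

    for r in range(1, params.max_rounds + 1):
        if len(feats) < max(3, params.min_module_size):
            rounds.append(RoundSummary(r, len(feats), 0, len(feats), 0))
            feats = []
            labels = np.array([], dtype=int)
            eig, kme = {}, np.zeros((0, 0))
            tom = np.zeros((0, 0))
            converged = True
            break
        Xr = X[feats].to_numpy(float)
        if power is None:
            power, _ = pick_soft_threshold(Xr, rsq_cut=params.rsq_cut,
                                           network_type=params.network_type)
        tom = tom_matrix(Xr, power, params.network_type)
        labels, eig = detect_modules(
            tom, Xr,
            min_module_size=params.min_module_size,
            merge_cut=params.merge_cut,
            cut_height_frac=params.cut_height_frac,
        )
        kme = compute_kme(Xr, eig)
        mods = sorted(eig)
        own = np.full(len(feats), -np.inf)
        for i, lab in enumerate(labels):
            if lab != 0:
                own[i] = kme[i, mods.index(lab)]
        keep_mask = (labels != 0) & (own >= params.kme_cutoff)
        n_drop = int((~keep_mask).sum())
        rounds.append(
            RoundSummary(r, len(feats), int(keep_mask.sum()), n_drop, len(mods))
        )
        if n_drop == 0:
            converged = True
            break
        feats = [f for f, k in zip(feats, keep_mask) if k]

    # package the final round
    mods = sorted(eig)
    names = {m: MODULE_COLORS[i % len(MODULE_COLORS)] for i, m in enumerate(mods)}
    final_feats = list(feats) if feats else []
    assignments = {f: GREY for f in X.columns}
    for f, lab in zip(final_feats, labels):
        assignments[f] = names[lab] if lab != 0 else GREY

    kme_df = pd.DataFrame(
        kme, index=final_feats, columns=[names[m] for m in mods]
    )
    eig_df = pd.DataFrame(
        {names[m]: eig[m] for m in mods}, index=X.index
    )
    tom_df = pd.DataFrame(tom, index=final_feats, columns=final_feats)
    return ModuleResult(
        assignments=assignments,
        kme=kme_df,
        eigenmetabolites=eig_df,
        rounds=rounds,
        tom=tom_df,
        power=int(power) if power is not None else 0,
        converged=converged,
    )


def hubs(result: ModuleResult, hub_kme: float = 0.8) -> dict[str, list[tuple[str, float]]]:
    """Per-module hub metabolites: own-module kME strictly above ``hub_kme``.

    Sorted by descending kME, ties broken by feature_id; modules without
    hubs map to an empty list.
    """
    out: dict[str, list[tuple[str, float]]] = {m: [] for m in result.modules}
    for f, m in result.assignments.items():
        if m == GREY or f not in result.kme.index:
            continue
        k = float(result.kme.loc[f, m])
        if k > hub_kme:
            out[m].append((f, k))
    for m in out:
        out[m].sort(key=lambda t: (-t[1], t[0]))
    return out


def export_network(
    result: ModuleResult, module: str, weight_min: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge and node tables of one module for Cytoscape/Gephi.

    Edges: undirected (source, target, weight=TOM) with weight >=
    ``weight_min``, source < target, sorted.  Nodes: every member with its
    kME and hub flag.
    """
    if module not in result.modules:
        raise ParameterError(f"unknown module {module!r}; have {result.modules}")
    members = sorted(result.members(module))
    members = [m for m in members if m in result.tom.index]
    edges = []
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            w = float(result.tom.loc[a, b])
            if w >= weight_min:
                edges.append({"source": a, "target": b, "weight": w})
    edge_df = pd.DataFrame(edges, columns=["source", "target", "weight"])
    hub_map = {f for f, _ in hubs(result).get(module, [])}
    node_df = pd.DataFrame(
        [
            {
                "feature_id": f,
                "module": module,
                "kme": float(result.kme.loc[f, module]),
                "is_hub": f in hub_map,
            }
            for f in members
        ],
        columns=["feature_id", "module", "kme", "is_hub"],
    )
    return edge_df, node_df
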