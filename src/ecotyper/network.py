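"""Signed weighted co-abundance network with topological overlap.

ASVs that rise and fall together across the time series form modules.
The network is built from Pearson correlations of ASV profiles via the
signed similarity a_ij = ((1 + cor_ij) / 2)^beta, where the soft-
thresholding power beta is chosen as the smallest candidate whose
scale-free topology fit index reaches a target R^2 (mean connectivity
reported alongside).  The adjacency is converted to a topological
overlap matrix (TOM), which credits two ASVs for shared neighbors as
well as direct association; module detection is "hybrid": k-means on
the rows of the TOM dissimilarity (1 - TOM) instead of hierarchical
tree cutting.  Each module is summarized by its eigengene (first
principal component of the standardized member profiles), modules with
eigengene correlation above a merge threshold are iteratively merged,
and per-ASV module membership (kME) is the correlation between the ASV
profile and the module eigengene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CommunityTable
from .cluster_select import kmeans_fit


@dataclass
class NetworkConfig:
    beta: float = 8.0
    r2_target: float = 0.8
    merge_threshold: float = 0.7
    n_bins: int = 10
    candidate_powers: tuple = tuple(range(1, 21))

    def validate(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not (0 < self.r2_target < 1):
            raise ValueError("r2_target must lie in (0, 1)")
        if not (0 < self.merge_threshold < 1):
            raise ValueError("merge_threshold must lie in (0, 1)")


@dataclass
class NetworkModel:
    asv_ids: list[str]
    correlation: np.ndarray
    adjacency: np.ndarray
    beta: float
    tom: np.ndarray | None = None
    diss_tom: np.ndarray | None = None
    module_labels: pd.Series | None = None
    eigengenes: pd.DataFrame | None = None
    kme: pd.DataFrame | None = None
    trait_correlations: pd.DataFrame | None = None
    trait_pvalues: pd.DataFrame | None = None

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum_{j != i} a_ij."""
        return self.adjacency.sum(axis=0) - np.diag(self.adjacency)


def signed_adjacency(table: CommunityTable, beta: float = 8.0) -> NetworkModel:
    """Signed network: a_ij = ((1 + cor_ij) / 2)^beta, unit diagonal."""
    x = table.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = x.std(axis=0)
    # rounding in the mean makes a constant column's sd ~1e-16, not 0
    tol = 1e-10 * (1.0 + np.abs(x).max())
    zero_var = [a for a, s in zip(table.asv_ids, sd) if s <= tol]
    if zero_var:
        raise ValueError(f"zero-variance ASVs (run network_qc first): {zero_var[:10]}")
    cor = np.corrcoef(x, rowvar=False)
    cor = np.clip(cor, -1.0, 1.0)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return NetworkModel(asv_ids=table.asv_ids, correlation=cor, adjacency=adj, beta=beta)


def scale_free_fit(model: NetworkModel, n_bins: int = 10) -> tuple[float, float, float]:
    """Scale-free topology fit: regress log10 freq on log10 mean connectivity.

    Returns ``(fit_index, slope, mean_connectivity)`` where
    ``fit_index = -sign(slope) * R^2``; values near +1 indicate a
    scale-free (decreasing power-law) degree distribution.  Degenerate
    inputs (all connectivities equal) return ``nan`` fit and slope.
    """
    k = model.connectivity
    if len(k) < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} ASVs for {n_bins} bins")
    mean_k = float(k.mean())
    if np.ptp(k) == 0:
        warnings.warn("all connectivities equal; scale-free fit undefined", stacklevel=2)
        return float("nan"), float("nan"), mean_k
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        log_k.append(np.log10(mk))
        log_f.append(np.log10(mask.sum() / len(k)))
    if len(log_k) < 3:
        warnings.warn("too few non-empty bins; scale-free fit undefined", stacklevel=2)
        return float("nan"), float("nan"), mean_k
    slope, _, r, _, _ = sps.linregress(log_k, log_f)
    fit = float(-np.sign(slope) * r**2)
    return fit, float(slope), mean_k


def pick_soft_power(
    table: CommunityTable, config: NetworkConfig | None = None
) -> tuple[float, pd.DataFrame]:
    """Smallest candidate power whose fit index reaches the R^2 target.

    If no candidate reaches the target, the power with the maximum fit
    index is returned with a warning.  The full per-power diagnostic
    table (fit index, slope, mean connectivity) is returned alongside.
    """
    config = config or NetworkConfig()
    config.validate()
    if not config.candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    rows = []
    for power in config.candidate_powers:
        model = signed_adjacency(table, beta=power)
        fit, slope, mean_k = scale_free_fit(model, n_bins=config.n_bins)
        rows.append({"power": power, "fit_index": fit, "slope": slope,
                     "mean_connectivity": mean_k})
    diag = pd.DataFrame(rows).set_index("power")
    ok = diag[diag["fit_index"] >= config.r2_target]
    if len(ok):
        return float(ok.index[0]), diag
    best = float(diag["fit_index"].idxmax())
    warnings.warn(
        f"no candidate power reached fit index {config.r2_target}; "
        f"using argmax power {best}", stacklevel=2,
    )
    return best, diag


def tom(model: NetworkModel) -> NetworkModel:
    """Topological overlap: tom_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij = sum_{u != i,j} a_iu a_uj and k_i excludes the diagonal;
    the diagonal of the TOM is 1 and diss_tom = 1 - tom.
    """
    a = model.adjacency
    k = model.connectivity
    # (A @ A)_ij includes u = i and u = j terms a_ii*a_ij + a_ij*a_jj = 2 a_ij
    l = a @ a - 2.0 * a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    model.tom = t
    model.diss_tom = 1.0 - t
    return model


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by descending size (ties by first label)."""
    values, counts = np.unique(labels, return_counts=True)
    order = values[np.argsort(-counts, kind="stable")]
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.array([mapping[v] for v in labels])


def detect_modules(model: NetworkModel, k: int, seed: int = 0, n_restarts: int = 25) -> pd.Series:
    """Hybrid module detection: k-means on rows of the TOM dissimilarity.

    Each ASV is represented by its vector of TOM dissimilarities to all
    ASVs; modules are k-means clusters of these vectors, relabeled by
    descending module size (label 0 is reserved for "no module" and is
    not produced here).
    """
    if model.diss_tom is None:
        raise ValueError("run tom() before detect_modules()")
    n = len(model.asv_ids)
    if not (2 <= k < n):
        raise ValueError(f"k must satisfy 2 <= k < {n}")
    sol = kmeans_fit(model.diss_tom, k, n_restarts=n_restarts, seed=seed)
    labels = _relabel_by_size(sol.labels)
    series = pd.Series(labels, index=model.asv_ids, name="module")
    model.module_labels = series
    return series


def module_eigengenes(table: CommunityTable, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized profiles.

    Eigengene scores are scaled to unit variance and sign-oriented so
    the mean correlation with member profiles is positive.  A singleton
    module's eigengene is its standardized profile (flagged by a
    warning).
    """
    x = table.data
    cols = {}
    for m in sorted(set(labels) - {0}):
        members = labels.index[labels == m]
        sub = x[members].to_numpy(dtype=float)
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"constant ASV profile in module {m}")
        z = (sub - mu) / sd
        if len(members) == 1:
            warnings.warn(f"module {m} is a singleton; eigengene = profile", stacklevel=2)
            e = z[:, 0]
        else:
            u, s, _ = np.linalg.svd(z, full_matrices=False)
            e = u[:, 0]
        e = e / e.std(ddof=1)
        cors = np.array([np.corrcoef(e, z[:, j])[0, 1] for j in range(z.shape[1])])
        if cors.mean() < 0:
            e = -e
        cols[f"ME{m}"] = e
    return pd.DataFrame(cols, index=x.index)


def merge_modules(
    table: CommunityTable,
    labels: pd.Series,
    merge_threshold: float = 0.7,
) -> tuple[pd.Series, pd.DataFrame]:
    """Iteratively merge the most correlated module pair above threshold.

    After each merge the eigengenes are recomputed, so the procedure is
    deterministic: highest correlation first, ties broken toward the
    smaller label pair.  Returns the merged labels (relabeled 1..m by
    descending size) and their eigengenes.
    """
    labels = labels.copy()
    while True:
        ids = sorted(set(labels) - {0})
        if len(ids) < 2:
            break
        eig = module_eigengenes(table, labels)
        cor = np.corrcoef(eig.to_numpy(), rowvar=False)
        np.fill_diagonal(cor, -np.inf)
        best, pair = -np.inf, None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if cor[i, j] > best + 1e-15:
                    best, pair = cor[i, j], (ids[i], ids[j])
        if best <= merge_threshold:
            break
        keep, drop = pair
        labels[labels == drop] = keep
    out = labels.to_numpy().copy()
    nonzero = out != 0
    out[nonzero] = _relabel_by_size(out[nonzero])
    merged = pd.Series(out, index=labels.index, name="module")
    return merged, module_eigengenes(table, merged)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the t distribution (n - 2 df)."""
    n = len(x)
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return r, float(p)


def kme_and_trait_stats(
    table: CommunityTable,
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Module membership (kME), module-trait and ASV-trait correlations.

    Returns ``(kme, module_trait_r, module_trait_p, trait_significance)``.
    kme[a, m] is the Pearson correlation between ASV a's profile and
    eigengene m; module_trait correlates eigengenes with trait columns
    (two-sided t-test p-values, no multiple-testing correction, matching
    common reporting practice for module-trait heatmaps — flagged in the
    docs); trait_significance correlates each ASV profile with each
    trait (the kME-vs-GS scatter ingredient).
    """
    x = table.data.loc[eigengenes.index]
    tr = traits.loc[eigengenes.index]
    xv = x.to_numpy(dtype=float)
    ev = eigengenes.to_numpy(dtype=float)

    def _corr_block(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        az = (a - a.mean(axis=0)) / np.where(a.std(axis=0) == 0, np.nan, a.std(axis=0))
        bz = (b - b.mean(axis=0)) / np.where(b.std(axis=0) == 0, np.nan, b.std(axis=0))
        return az.T @ bz / a.shape[0]

    kme = pd.DataFrame(np.clip(_corr_block(xv, ev), -1, 1),
                       index=x.columns, columns=eigengenes.columns)
    mt_r = np.empty((ev.shape[1], tr.shape[1]))
    mt_p = np.empty_like(mt_r)
    for i in range(ev.shape[1]):
        for j, col in enumerate(tr.columns):
            mt_r[i, j], mt_p[i, j] = _pearson_with_p(ev[:, i], tr[col].to_numpy(dtype=float))
    module_trait_r = pd.DataFrame(mt_r, index=eigengenes.columns, columns=tr.columns)
    module_trait_p = pd.DataFrame(mt_p, index=eigengenes.columns, columns=tr.columns)
    gs = pd.DataFrame(np.clip(_corr_block(xv, tr.to_numpy(dtype=float)), -1, 1),
                      index=x.columns, columns=tr.columns)
    return kme, module_trait_r, module_trait_p, gs
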