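"""Distances, classical PCoA, non-metric MDS and environmental fitting.

PCoA is classical metric scaling: Gower double-centering of the squared
distance matrix, B = -1/2 * J D^2 J with J = I - 11'/n, followed by an
eigendecomposition.  On Euclidean distances of a Hellinger-transformed
table this is exactly a PCA of the centered data, which the test suite
uses as its primary correctness anchor.  Negative eigenvalues are
dropped without correction, since the intended input (Euclidean on
Hellinger) yields a positive semi-definite Gower matrix.

NMDS minimizes Kruskal stress-1 by alternating monotone (isotonic)
regression of configuration distances on the input dissimilarities with
Guttman-transform configuration updates, best-of-``n_starts`` random
initializations plus one PCoA initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .containers import CommunityTable, DistanceMatrix

METRICS = ("euclidean", "bray_curtis")


def pairwise_distance(table: CommunityTable, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise sample distances: Euclidean or Bray-Curtis.

    Bray-Curtis d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), requiring
    non-negative input and at least one non-zero row per pair.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    x = table.values
    if metric == "bray_curtis":
        if (x < 0).any():
            raise ValueError("bray_curtis requires non-negative input")
        if (x.sum(axis=1) == 0).sum() >= 2:
            raise ValueError("bray_curtis undefined for two all-zero samples")
        condensed = pdist(x, metric="braycurtis")
    else:
        condensed = pdist(x, metric="euclidean")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids, metric=metric)


@dataclass
class Ordination:
    """Low-dimensional sample projection from PCoA or NMDS."""

    coordinates: pd.DataFrame
    method: str
    eigenvalues: np.ndarray | None = None
    variance_explained: np.ndarray | None = None
    stress: float | None = None
    converged: bool = True
    stress_trace: list[float] = field(default_factory=list)


def _orient_axes(coords: np.ndarray) -> np.ndarray:
    """Flip each axis so its largest-|coordinate| entry is positive."""
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical (metric) multidimensional scaling.

    Eigenvalues below ``1e-8 * max`` (including all negative ones) are
    dropped; per-axis variance explained is lambda_i over the sum of
    the retained positive eigenvalues.  If fewer positive axes exist
    than requested, the available ones are returned with a warning.
    """
    dm = d.matrix
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-8 * max(eigvals.max(), 0.0)
    eigvals_pos, eigvecs_pos = eigvals[pos], eigvecs[:, pos]
    if n_axes > len(eigvals_pos):
        warnings.warn(
            f"requested {n_axes} axes but only {len(eigvals_pos)} positive "
            "eigenvalues; returning fewer axes",
            stacklevel=2,
        )
        n_axes = len(eigvals_pos)
    coords = eigvecs_pos[:, :n_axes] * np.sqrt(eigvals_pos[:n_axes])
    coords = _orient_axes(coords)
    frame = pd.DataFrame(
        coords, index=list(d.ids), columns=[f"axis{i + 1}" for i in range(n_axes)]
    )
    return Ordination(
        coordinates=frame,
        method="pcoa",
        eigenvalues=eigvals_pos,
        variance_explained=eigvals_pos / eigvals_pos.sum(),
    )


def _stress1(dhat: np.ndarray, dist: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - dist) ** 2).sum() / denom))


def _nmds_single(
    delta: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float], bool]:
    """One NMDS start: isotonic regression + Guttman updates.

    The candidate update is accepted only while stress-1 decreases, so
    the recorded stress trace is non-increasing by construction.
    """
    n = x0.shape[0]
    iu = np.triu_indices(n, k=1)
    order = np.argsort(delta[iu], kind="stable")
    iso = IsotonicRegression()
    x = x0.copy()
    trace: list[float] = []
    converged = False
    dist = pdist(x)
    for _ in range(max_iter):
        dhat_sorted = iso.fit_transform(np.arange(len(order)), dist[order])
        dhat = np.empty_like(dist)
        dhat[order] = dhat_sorted
        stress = _stress1(dhat, dist)
        if trace and trace[-1] - stress < tol:
            trace.append(min(stress, trace[-1]))
            converged = True
            break
        if trace and stress > trace[-1]:
            break
        trace.append(stress)
        # Guttman transform with unit weights
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        bmat = -squareform(ratio)
        np.fill_diagonal(bmat, ratio_sums := squareform(ratio).sum(axis=1))
        x = bmat @ x / n
        dist = pdist(x)
    return x, trace[-1], trace, converged


def nmds(
    d: DistanceMatrix,
    d_target: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
    tol: float = 1e-6,
) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs ``n_starts`` seeded random initializations plus one PCoA
    initialization and keeps the configuration with the lowest final
    stress.
    """
    if d.n < 4:
        raise ValueError("nmds requires at least 4 samples")
    rng = np.random.default_rng(seed)
    delta = d.matrix
    inits = [pcoa(d, n_axes=d_target).coordinates.to_numpy()]
    if inits[0].shape[1] < d_target:  # degenerate PCoA: pad with zeros
        pad = np.zeros((d.n, d_target - inits[0].shape[1]))
        inits[0] = np.hstack([inits[0], pad])
    for _ in range(n_starts):
        inits.append(rng.standard_normal((d.n, d_target)))
    best = None
    for x0 in inits:
        x, stress, trace, converged = _nmds_single(delta, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, trace, converged)
    x, stress, trace, converged = best
    x = _orient_axes(x - x.mean(axis=0))
    frame = pd.DataFrame(
        x, index=list(d.ids), columns=[f"axis{i + 1}" for i in range(d_target)]
    )
    return Ordination(
        coordinates=frame,
        method="nmds",
        stress=stress,
        converged=converged,
        stress_trace=trace,
    )


@dataclass
class EnvFitResult:
    """Per-variable fit of environmental covariates onto ordination axes."""

    table: pd.DataFrame  # columns: r_squared, p_value, flagged + direction components
    n_permutations: int


def envfit(
    ordination: Ordination,
    covariates: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> EnvFitResult:
    """Least-squares vector fitting of covariates onto ordination axes.

    r^2 = 1 - SS_resid / SS_total from regressing the covariate on the
    axis coordinates; the p-value is permutational with the add-one
    estimator, permuting covariate values across samples.  Constant
    covariates are flagged with r^2 = 0 and p = 1.
    """
    coords = ordination.coordinates.loc[list(covariates.index)].to_numpy()
    centered = coords - coords.mean(axis=0)
    q, _ = np.linalg.qr(centered)
    rng = np.random.default_rng(seed)
    d = coords.shape[1]
    rows = []
    for name in covariates.columns:
        y = covariates[name].to_numpy(dtype=float)
        yc = y - y.mean()
        ss_total = (yc**2).sum()
        if ss_total <= 0:
            rows.append({"variable": name, "r_squared": 0.0, "p_value": 1.0,
                         "flagged": True, **{f"axis{i+1}": 0.0 for i in range(d)}})
            continue
        proj = q.T @ yc
        r2 = float((proj**2).sum() / ss_total)
        perm = np.array([yc[rng.permutation(len(yc))] for _ in range(n_permutations)]).T
        r2_perm = (q.T @ perm) ** 2
        r2_perm = r2_perm.sum(axis=0) / ss_total
        p = (1 + int((r2_perm >= r2).sum())) / (1 + n_permutations)
        beta, *_ = np.linalg.lstsq(centered, yc, rcond=None)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        rows.append({"variable": name, "r_squared": r2, "p_value": p, "flagged": False,
                     **{f"axis{i+1}": direction[i] for i in range(d)}})
    table = pd.DataFrame(rows).set_index("variable")
    return EnvFitResult(table=table, n_permutations=n_permutations)
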