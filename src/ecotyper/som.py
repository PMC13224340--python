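"""Self-organizing map on a hexagonal, optionally toroidal grid.

A SOM is a grid of units, each holding a prototype ("codebook") vector
in data space.  Training is online competitive learning: samples are
presented in seeded random order; the best-matching unit (BMU, nearest
prototype by Euclidean distance) and all units within the current
neighborhood radius move toward the sample by a learning rate alpha
that decays linearly over the run (default 0.05 -> 0.01, matching
common practice for community time series).  The neighborhood is a hard
"bubble" by default; a Gaussian kernel is available behind a flag.

Grid geometry uses hexagonal offset coordinates (odd rows shifted by
+0.5, row spacing sqrt(3)/2).  On a toroidal grid the distance between
units is the minimum planar distance over the nine shifted copies of
the map, which makes every unit's neighborhood structure identical
(torus homogeneity) provided the number of rows is even.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

ROW_SPACING = np.sqrt(3.0) / 2.0


@dataclass
class SOMGrid:
    rows: int
    cols: int
    toroidal: bool
    unit_coords: np.ndarray  # units x 2 planar positions
    unit_distance: np.ndarray  # units x units grid distances

    @property
    def n_units(self) -> int:
        return self.rows * self.cols


def build_grid(rows: int, cols: int, toroidal: bool = True) -> SOMGrid:
    """Hexagonal offset grid; toroidal wraparound via nine shifted copies.

    Adjacent units in the same row are at distance exactly 1.  With
    ``toroidal=True`` and an odd number of rows the vertical wrap breaks
    the hexagonal packing; a warning is emitted in that case.
    """
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must both be >= 2")
    if toroidal and rows % 2 == 1:
        warnings.warn("toroidal hex grids need an even row count for exact "
                      "wraparound geometry", stacklevel=2)
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = c + 0.5 * (r % 2)
    y = r * ROW_SPACING
    coords = np.column_stack([x.ravel(), y.ravel()])
    if toroidal:
        shifts = [
            (dx * cols, dy * rows * ROW_SPACING)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
        ]
        stacks = [
            cdist(coords, coords + np.array(s)[None, :]) for s in shifts
        ]
        dist = np.minimum.reduce(stacks)
    else:
        dist = cdist(coords, coords)
    return SOMGrid(rows=rows, cols=cols, toroidal=toroidal,
                   unit_coords=coords, unit_distance=dist)


@dataclass
class SOMModel:
    grid: SOMGrid
    codebook: np.ndarray  # units x features
    alpha_start: float
    alpha_end: float
    rlen: int
    seed: int
    training_loss: list[float] = field(default_factory=list)


@dataclass
class SOMMapping:
    bmu: np.ndarray  # per-sample best-matching unit index
    quantization_error: np.ndarray  # per-sample distance to BMU
    occupancy: np.ndarray  # samples per unit


def _mean_qe(x: np.ndarray, codebook: np.ndarray) -> float:
    return float(cdist(x, codebook).min(axis=1).mean())


def _maxmin_init(x: np.ndarray, n_units: int, rng: np.random.Generator) -> np.ndarray:
    """Farthest-point ("maxmin") codebook init from data rows.

    The first prototype is a seeded random row; each further prototype
    is the row farthest from the already-chosen set.  This covers the
    extremes of the data cloud (rare but distinct samples seed their
    own unit) while remaining deterministic under the seed.  Rows are
    reused with a small jitter when there are fewer rows than units.
    """
    n = x.shape[0]
    chosen = [int(rng.integers(n))]
    min_d = cdist(x, x[chosen[-1]][None, :]).ravel()
    while len(chosen) < min(n_units, n):
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        min_d = np.minimum(min_d, cdist(x, x[nxt][None, :]).ravel())
    codebook = x[chosen].copy()
    if n_units > n:
        extra = rng.choice(n, size=n_units - n, replace=True)
        codebook = np.vstack([codebook, x[extra] + 1e-6 * rng.standard_normal((len(extra), x.shape[1]))])
    return codebook


def train_som(
    x: np.ndarray,
    grid: SOMGrid,
    alpha: tuple[float, float] = (0.05, 0.01),
    rlen: int = 100,
    seed: int = 0,
    neighborhood: str = "bubble",
) -> SOMModel:
    """Train a SOM by online competitive learning.

    The codebook is initialized from data rows sampled without
    replacement (seeded).  Over ``rlen * n`` presentations, alpha decays
    linearly from ``alpha[0]`` to ``alpha[1]`` and the neighborhood
    radius decays linearly from the 2/3 quantile of the grid distances
    to just below the minimum positive grid distance (so only the BMU
    is updated at the end).  The mean quantization error is recorded
    after every pass.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("training data must be a non-empty 2-D array")
    if neighborhood not in ("bubble", "gaussian"):
        raise ValueError("neighborhood must be 'bubble' or 'gaussian'")
    n, n_units = x.shape[0], grid.n_units
    if n < n_units:
        warnings.warn(f"{n} samples for {n_units} units; codebook init will "
                      "reuse data rows", stacklevel=2)
    rng = np.random.default_rng(seed)
    codebook = _maxmin_init(x, n_units, rng)

    positive = grid.unit_distance[grid.unit_distance > 0]
    r_start = float(np.quantile(positive, 2.0 / 3.0))
    r_end = float(positive.min()) * 0.999
    total = rlen * n
    a0, a1 = alpha
    loss: list[float] = []
    step = 0
    for _ in range(rlen):
        for i in rng.permutation(n):
            frac = step / max(total - 1, 1)
            a = a0 + (a1 - a0) * frac
            # radius hits its floor a third of the way through training;
            # the rest fine-tunes individual units (BMU-only updates)
            radius = r_start + (r_end - r_start) * min(3.0 * frac, 1.0)
            diff = codebook - x[i]
            bmu = int(np.argmin((diff**2).sum(axis=1)))
            if neighborhood == "bubble":
                mask = grid.unit_distance[bmu] <= radius
                codebook[mask] += a * (x[i] - codebook[mask])
            else:
                h = np.exp(-0.5 * (grid.unit_distance[bmu] / radius) ** 2)
                codebook += (a * h)[:, None] * (x[i] - codebook)
            step += 1
        loss.append(_mean_qe(x, codebook))
    return SOMModel(grid=grid, codebook=codebook, alpha_start=a0, alpha_end=a1,
                    rlen=rlen, seed=seed, training_loss=loss)


def map_samples(model: SOMModel, x: np.ndarray) -> SOMMapping:
    """Assign each sample to its best-matching unit.

    Ties are broken toward the lowest unit index (argmin semantics).
    The per-unit occupancy histogram supports the grid-size diagnostic.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1] != model.codebook.shape[1]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match codebook "
            f"dimension {model.codebook.shape[1]}"
        )
    d = cdist(x, model.codebook)
    bmu = d.argmin(axis=1)
    qe = d[np.arange(len(x)), bmu]
    occupancy = np.bincount(bmu, minlength=model.grid.n_units)
    return SOMMapping(bmu=bmu, quantization_error=qe, occupancy=occupancy)
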