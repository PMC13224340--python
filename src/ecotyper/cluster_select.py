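"""k-means with restarts and the dual k-selection rule (elbow + silhouette).

All three segmentation routes (PCoA coordinates, SOM codebook vectors,
network TOM dissimilarity rows) share this module.  Fitting is Lloyd's
algorithm from k-means++ seeding, best of ``n_restarts`` by within-
cluster sum of squares (WSS), delegated to scikit-learn.  The number of
clusters is chosen by combining the elbow of the WSS curve
(operationalized as the maximum perpendicular distance to the chord
between the first and last k, on axes rescaled to [0, 1]) with the
mean-silhouette maximum; on disagreement the silhouette wins because it
also accounts for between-cluster separation, and the conflict is
recorded in the selection report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass
class ClusterSolution:
    labels: np.ndarray  # 1-based cluster labels
    k: int
    wss: float
    seed: int
    n_restarts: int
    mean_silhouette: float | None = None

    def __post_init__(self) -> None:
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.k:
            raise ValueError("labels must lie in [1, k]")


@dataclass
class KSelectionReport:
    k_values: list[int]
    wss: list[float]
    mean_silhouette: list[float]
    chosen_k: int | None = None
    rule_trace: dict = field(default_factory=dict)


def kmeans_fit(x: np.ndarray, k: int, n_restarts: int = 25, seed: int = 0) -> ClusterSolution:
    """Best-of-restarts k-means; deterministic under ``seed``.

    Labels are 1-based.  scikit-learn's Lloyd implementation repairs
    empty clusters internally by reassigning the farthest points, so
    every returned cluster is non-empty.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("features must be finite")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds {x.shape[0]} items")
    km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++",
                algorithm="lloyd", random_state=seed)
    labels = km.fit_predict(x) + 1
    return ClusterSolution(labels=labels, k=k, wss=float(km.inertia_),
                           seed=seed, n_restarts=n_restarts)


def mean_silhouette(x: np.ndarray, labels: np.ndarray) -> tuple[float, bool]:
    """Mean silhouette s(i) = (b - a) / max(a, b) with Euclidean distances.

    Returns ``(value, flagged)``; the degenerate all-singleton case is
    defined as 0 per convention and flagged.
    """
    x = np.asarray(x, dtype=float)
    n_clusters = len(np.unique(labels))
    if n_clusters < 2 or n_clusters >= len(labels):
        return 0.0, True
    return float(silhouette_score(x, labels, metric="euclidean")), False


def k_diagnostics(
    x: np.ndarray,
    k_range: range | list[int],
    seed: int = 0,
    n_restarts: int = 25,
) -> KSelectionReport:
    """Per-k WSS (best of restarts) and mean silhouette."""
    x = np.asarray(x, dtype=float)
    ks = sorted(k_range)
    if not ks or ks[0] < 2 or ks[-1] > x.shape[0] - 1:
        raise ValueError("k_range must lie within [2, n_items - 1]")
    wss, sil = [], []
    for k in ks:
        sol = kmeans_fit(x, k, n_restarts=n_restarts, seed=seed)
        wss.append(sol.wss)
        s, _ = mean_silhouette(x, sol.labels)
        sil.append(s)
    return KSelectionReport(k_values=ks, wss=wss, mean_silhouette=sil)


def choose_k(report: KSelectionReport) -> int:
    """Combine elbow and silhouette; silhouette wins conflicts.

    The elbow k maximizes the perpendicular distance between the WSS
    curve and the chord from the first to the last k, after rescaling
    both axes to [0, 1] so the rule is invariant to units.
    """
    ks = np.asarray(report.k_values, dtype=float)
    if len(ks) < 3:
        raise ValueError("choose_k needs diagnostics for at least 3 k values")
    wss = np.asarray(report.wss, dtype=float)
    kn = (ks - ks[0]) / (ks[-1] - ks[0])
    wn = (wss - wss.min()) / max(wss.max() - wss.min(), np.finfo(float).tiny)
    # distance from (kn, wn) to chord between first and last points
    p0 = np.array([kn[0], wn[0]])
    p1 = np.array([kn[-1], wn[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([kn, wn]) - p0
    perp = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    elbow_k = int(ks[int(np.argmax(perp))])
    sil_k = int(ks[int(np.argmax(report.mean_silhouette))])
    chosen = sil_k
    report.rule_trace = {
        "elbow_k": elbow_k,
        "silhouette_k": sil_k,
        "conflict": elbow_k != sil_k,
        "decision": "agreement" if elbow_k == sil_k else "silhouette",
    }
    report.chosen_k = chosen
    return chosen
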