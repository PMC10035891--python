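"""Leading-eigenvector dynamics of instantaneous phase-locking.

Implements the timepoint-wise phase-locking matrix ``cos(theta_n - theta_p)``,
its leading eigenvector under a fixed sign convention, the in-/antiphase
magnetization ratio, spherical (cosine-distance) k-means mode extraction with
silhouette-based model selection, mode outer-product connectivity, antiphase
connectogram edge lists and per-region mode contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_score

__all__ = [
    "ipl_at_time",
    "ipl_tensor",
    "leading_eigenvector",
    "apply_sign_convention",
    "magnetization",
    "compute_eigenseries",
    "EigenSeries",
    "ModeSet",
    "extract_modes",
    "select_k_silhouette",
    "assign_modes",
    "half_switch_smooth",
    "mode_fc",
    "connectogram_edges",
    "regional_contribution",
]


def ipl_at_time(phase_column: np.ndarray) -> np.ndarray:
    """Instantaneous phase-locking matrix at one timepoint.

    Entry ``(n, p)`` is ``cos(theta_n - theta_p)``: +1 for in-phase pairs,
    -1 for antiphase pairs. Symmetric with unit diagonal.
    """
    theta = np.asarray(phase_column, dtype=float).ravel()
    if not np.all(np.isfinite(theta)):
        raise ValueError("phases must be finite")
    return np.cos(theta[:, None] - theta[None, :])


def ipl_tensor(phases: np.ndarray) -> np.ndarray:
    """Stack of phase-locking matrices, shape ``(T, N, N)``.

    Uses ``cos(a-b) = cos a cos b + sin a sin b`` to avoid the T-fold
    pairwise subtraction.
    """
    phases = np.asarray(phases, dtype=float)
    c, s = np.cos(phases.T), np.sin(phases.T)  # (T, N)
    return c[:, :, None] * c[:, None, :] + s[:, :, None] * s[:, None, :]


def apply_sign_convention(v: np.ndarray) -> np.ndarray:
    """Flip ``v`` so a strict majority of entries is non-negative.

    Ties (equally many negative as non-negative entries) are broken by
    making the first entry non-negative. Idempotent.
    """
    v = np.asarray(v, dtype=float)
    n_neg = int(np.sum(v < 0))
    n_nonneg = v.size - n_neg
    if n_neg > n_nonneg:
        return -v
    if n_neg == n_nonneg and v[0] < 0:
        return -v
    return v


def leading_eigenvector(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit-norm eigenvector of the largest-magnitude eigenvalue.

    The matrix must be symmetric. The returned vector satisfies the
    majority-non-negative sign convention.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    evals, evecs = np.linalg.eigh(matrix)
    idx = int(np.argmax(np.abs(evals)))
    v = apply_sign_convention(evecs[:, idx])
    return v, float(evals[idx])


def magnetization(v: np.ndarray) -> float:
    """Ratio of antiphase to in-phase regions in a sign-conventioned vector.

    ``M = N_anti / N_in`` where ``N_in`` counts entries carrying the
    majority (non-negative) sign. ``M`` lies in [0, 1]; 0 for a global
    (single-pole) vector.
    """
    v = apply_sign_convention(np.asarray(v, dtype=float))
    n_anti = int(np.sum(v < 0))
    n_in = v.size - n_anti
    return n_anti / n_in


@dataclass
class EigenSeries:
    """Per-timepoint leading eigenvectors of the phase-locking matrices."""

    vectors: np.ndarray  # (N, T), unit-norm sign-conventioned columns
    eigenvalues: np.ndarray  # (T,)
    magnetization: np.ndarray  # (T,)
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.region_labels:
            self.region_labels = [
                f"R{i + 1:03d}" for i in range(self.vectors.shape[0])
            ]

    @property
    def n_regions(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[1]


def compute_eigenseries(
    phases: np.ndarray, region_labels: list[str] | None = None
) -> EigenSeries:
    """Leading eigenvector, eigenvalue and magnetization per timepoint."""
    tensor = ipl_tensor(phases)
    n, t = phases.shape
    vectors = np.empty((n, t))
    eigenvalues = np.empty(t)
    mags = np.empty(t)
    for k in range(t):
        v, lam = leading_eigenvector(tensor[k])
        vectors[:, k] = v
        eigenvalues[k] = lam
        mags[k] = magnetization(v)
    return EigenSeries(vectors, eigenvalues, mags, region_labels or [])


@dataclass
class ModeSet:
    """Result of clustering leading eigenvectors into k recurrent modes.

    Modes are ordered with the global (all non-negative) mode first when
    present, then by descending occupancy; ``labels`` are 1-based.
    """

    k: int
    centroids: np.ndarray  # (N, k), unit-norm, sign-conventioned columns
    labels: np.ndarray  # (T,), values in 1..k
    inertia: float  # summed cosine distance to own centroid
    silhouette: float | None = None

    @property
    def occupancy(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def community(self, mode: int) -> np.ndarray:
        """Region indices of mode ``mode`` (1-based).

        The minority-sign (antiphase) pole; all regions for the global
        mode, which has no negative centroid entries.
        """
        v = self.centroids[:, mode - 1]
        neg = np.flatnonzero(v < 0)
        if neg.size == 0:
            return np.arange(v.size)
        return neg

    @property
    def communities(self) -> list[np.ndarray]:
        return [self.community(m) for m in range(1, self.k + 1)]


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


def _spherical_kmeans_once(
    x: np.ndarray, k: int, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """One k-means replicate under cosine distance on unit-norm rows.

    Empty clusters are re-seeded from a random data point.
    """
    t = x.shape[0]
    centroids = x[rng.choice(t, size=k, replace=False)].copy()
    labels = np.full(t, -1)
    for _ in range(max_iter):
        sim = x @ centroids.T
        new_labels = np.argmax(sim, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = x[labels == c]
            if members.shape[0] == 0:
                centroids[c] = x[rng.integers(t)]
                continue
            mean = members.mean(axis=0)
            norm = np.linalg.norm(mean)
            if norm == 0:  # pathological antipodal cluster; re-seed
                centroids[c] = x[rng.integers(t)]
            else:
                centroids[c] = mean / norm
    sim = x @ centroids.T
    labels = np.argmax(sim, axis=1)
    inertia = float(np.sum(1.0 - sim[np.arange(t), labels]))
    return centroids, labels, inertia


def _order_modes(
    centroids: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Global mode first (if any), then descending occupancy."""
    k = centroids.shape[1]
    occ = np.bincount(labels, minlength=k)
    is_global = np.array([not np.any(centroids[:, c] < 0) for c in range(k)])
    # sort key: global flag desc, occupancy desc, index asc (stable)
    order = sorted(range(k), key=lambda c: (-int(is_global[c]), -occ[c], c))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return centroids[:, order], remap[labels]


def extract_modes(
    vectors: np.ndarray,
    k: int,
    reps: int = 300,
    max_iter: int = 400,
    seed: int | np.random.Generator | None = 0,
) -> ModeSet:
    """Cluster leading eigenvectors of ONE dataset into ``k`` modes.

    k-means under cosine distance (1 - cosine similarity) on unit-normalized
    eigenvectors; best of ``reps`` replicates by within-cluster
    dissimilarity. Centroids are unit-norm and sign-conventioned.

    ``vectors`` is ``(N, T)`` — concatenate subjects of a single dataset
    along time before calling; never concatenate across datasets/groups.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    vectors = np.asarray(vectors, dtype=float)
    x = _unit_rows(vectors.T.copy())  # (T, N)
    t = x.shape[0]
    if t < k:
        raise ValueError(f"need at least k={k} timepoints, got {t}")
    rng = np.random.default_rng(seed)

    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(reps):
        cents, labels, inertia = _spherical_kmeans_once(x, k, max_iter, rng)
        if best is None or inertia < best[2]:
            best = (cents, labels, inertia)
    assert best is not None
    centroids, labels, inertia = best
    if len(np.unique(labels)) < k:
        raise RuntimeError(
            f"degenerate clustering: only {len(np.unique(labels))} of {k} "
            "clusters populated in the best replicate"
        )
    centroids = np.stack(
        [apply_sign_convention(c) for c in centroids], axis=1
    )  # (N, k)
    centroids, labels = _order_modes(centroids, labels)

    sil = None
    if k >= 2 and len(np.unique(labels)) >= 2:
        sil = float(silhouette_score(x, labels, metric="cosine"))
    return ModeSet(
        k=k,
        centroids=centroids,
        labels=labels + 1,
        inertia=inertia,
        silhouette=sil,
    )


def extract_modes_range(
    vectors: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    reps: int = 300,
    max_iter: int = 400,
    seed: int | None = 0,
) -> dict[int, ModeSet]:
    """``extract_modes`` for every k in the closed range ``k_range``."""
    lo, hi = k_range
    rng = np.random.default_rng(seed)
    return {
        k: extract_modes(vectors, k, reps=reps, max_iter=max_iter, seed=rng)
        for k in range(lo, hi + 1)
    }


def select_k_silhouette(
    mode_sets: dict[int, ModeSet], override: int | None = None
) -> tuple[int, dict[int, float]]:
    """Pick k by highest mean silhouette (cosine); ``override`` wins if set."""
    if len(mode_sets) < 2 and override is None:
        raise ValueError("need at least 2 candidate k values")
    table = {
        k: (ms.silhouette if ms.silhouette is not None else float("-inf"))
        for k, ms in sorted(mode_sets.items())
    }
    if override is not None:
        if override not in mode_sets:
            raise ValueError(f"override k={override} not among candidates")
        return override, table
    chosen = max(table, key=lambda k: table[k])
    return chosen, table


def _cosine_distances_to_centroids(
    vectors: np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    x = _unit_rows(np.asarray(vectors, dtype=float).T.copy())
    c = _unit_rows(np.asarray(centroids, dtype=float).T.copy())
    return 1.0 - x @ c.T  # (T, k)


def assign_modes(vectors: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Assign each eigenvector to its nearest centroid by cosine distance.

    Ties go to the lowest mode index. Returns 1-based labels.
    """
    dist = _cosine_distances_to_centroids(vectors, centroids)
    return np.argmin(dist, axis=1) + 1


def half_switch_smooth(
    vectors: np.ndarray,
    centroids: np.ndarray,
    enabled: bool = False,
    delta: float = 0.05,
) -> np.ndarray:
    """Hysteresis label smoothing ('half-switching' stand-in).

    A timepoint keeps the previous timepoint's label when its two smallest
    centroid cosine distances differ by less than ``delta`` and the
    previous label is one of the two. Disabled (raw labels) by default;
    never increases the number of label switches.
    """
    labels = assign_modes(vectors, centroids)
    if not enabled or delta <= 0 or centroids.shape[1] < 2:
        return labels
    dist = _cosine_distances_to_centroids(vectors, centroids)
    smoothed = labels.copy()
    for t in range(1, labels.size):
        order = np.argsort(dist[t], kind="stable")
        gap = dist[t, order[1]] - dist[t, order[0]]
        prev = smoothed[t - 1]
        if gap < delta and prev - 1 in (order[0], order[1]):
            smoothed[t] = prev
    return smoothed


def mode_fc(centroid: np.ndarray) -> np.ndarray:
    """Rank-1 connectivity matrix of a mode: outer product of its centroid."""
    v = np.asarray(centroid, dtype=float).ravel()
    return np.outer(v, v)


def connectogram_edges(
    centroid: np.ndarray, region_labels: list[str] | None = None
) -> list[tuple[int | str, int | str, float]]:
    """Edges among the antiphase (minority-sign) regions of a mode.

    Nodes are the regions with negative centroid entries (in antiphase with
    the global pole); edges are pairs among them whose outer-product
    connectivity is positive, weighted by that value. Empty for a global
    mode.
    """
    v = apply_sign_convention(np.asarray(centroid, dtype=float).ravel())
    fc = np.outer(v, v)
    nodes = np.flatnonzero(v < 0)
    edges: list[tuple[int | str, int | str, float]] = []
    for a_i, a in enumerate(nodes):
        for b in nodes[a_i + 1 :]:
            if fc[a, b] > 0:
                if region_labels is not None:
                    edges.append((region_labels[a], region_labels[b], float(fc[a, b])))
                else:
                    edges.append((int(a), int(b), float(fc[a, b])))
    return edges


def regional_contribution(
    eigs: EigenSeries | np.ndarray,
    labels: np.ndarray,
    region: int,
    mode: int,
) -> tuple[float, int]:
    """Mean leading-eigenvector value of one region over a mode's frames.

    Returns ``(mean, n_frames)``; raises if the mode has zero occupancy.
    """
    vectors = eigs.vectors if isinstance(eigs, EigenSeries) else np.asarray(eigs)
    mask = np.asarray(labels) == mode
    count = int(mask.sum())
    if count == 0:
        raise ValueError(f"mode {mode} has zero occupancy")
    return float(vectors[region, mask].mean()), count


def regional_contribution_ipl(
    phases: np.ndarray,
    labels: np.ndarray,
    region: int,
    mode: int,
) -> tuple[float, int]:
    """Alternative contribution: mean phase-locking row of the region.

    Mean over the mode's frames of the region's average instantaneous
    phase-locking with all other regions.
    """
    mask = np.asarray(labels) == mode
    count = int(mask.sum())
    if count == 0:
        raise ValueError(f"mode {mode} has zero occupancy")
    tensor = ipl_tensor(phases[:, mask])  # (t, N, N)
    n = phases.shape[0]
    others = np.arange(n) != region
    return float(tensor[:, region, others].mean()), count
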