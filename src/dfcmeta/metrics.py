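"""Dynamical summary metrics per subject.

Community Kuramoto order and its temporal variability (META), chimerality
(CHI), the phase-locking variance proxy (VAR), and static graph metrics on
the time-averaged phase-locking matrix: global integration (GINT, integral
of the largest-connected-component fraction over binarization thresholds),
functional segregation (FSEG, Louvain/Newman modularity) and the
metastability index K = FSEG / GINT.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
import networkx as nx

from .leida import ipl_tensor

__all__ = [
    "kuramoto_order",
    "meta",
    "global_meta",
    "chimerality",
    "var_metric",
    "global_var",
    "mean_ipl",
    "integration",
    "segregation",
    "metastability_index",
    "subject_metrics",
]


def kuramoto_order(phases: np.ndarray, community: np.ndarray | None = None) -> np.ndarray:
    """Kuramoto order parameter time series of a community.

    ``R(t) = |mean_m exp(i theta_m(t))|`` over the community members
    (all regions when ``community`` is None). Values lie in [0, 1].
    """
    phases = np.asarray(phases, dtype=float)
    if community is not None:
        community = np.asarray(community, dtype=int)
        if community.size == 0:
            raise ValueError("community must be non-empty")
        if community.min() < 0 or community.max() >= phases.shape[0]:
            raise ValueError("community indices out of range")
        phases = phases[community]
    return np.abs(np.exp(1j * phases).mean(axis=0))


def meta(r_series: np.ndarray, ddof: int = 1) -> float:
    """Metastability of one community: temporal std of its Kuramoto order.

    Sample standard deviation (denominator T-1) by default.
    """
    r_series = np.asarray(r_series, dtype=float)
    if r_series.size < 2:
        raise ValueError("need at least 2 timepoints")
    return float(np.std(r_series, ddof=ddof))


def global_meta(community_metas: np.ndarray | list[float]) -> float:
    """Unweighted mean of per-community META values."""
    return float(np.mean(np.asarray(community_metas, dtype=float)))


def chimerality(r_matrix: np.ndarray, ddof: int = 0) -> np.ndarray:
    """CHI(t): variance of the community Kuramoto orders at each timepoint.

    ``r_matrix`` has one row per community. Population variance by default.
    """
    r_matrix = np.asarray(r_matrix, dtype=float)
    if r_matrix.ndim != 2 or r_matrix.shape[0] < 2:
        raise ValueError("need a (k, T) matrix with k >= 2 communities")
    return np.var(r_matrix, axis=0, ddof=ddof)


def var_metric(
    phases: np.ndarray,
    community: np.ndarray,
    ddof: int = 1,
    per_region: bool = False,
) -> float:
    """Phase-locking metastability VAR of a community.

    The temporal variance of instantaneous phase-locking
    ``cos(theta_n - theta_p)`` is computed for every unordered pair of
    distinct community members and averaged. Unlike the Kuramoto-order
    route this is sensitive to antiphase as well as in-phase variability.

    With ``per_region=True`` the pair variances are first averaged within
    each member's row (every pair then counts towards both of its
    endpoints); for this symmetric scheme the result equals the pairwise
    mean, so the option only matters for downstream per-region reporting.
    """
    community = np.asarray(community, dtype=int)
    if community.size < 2:
        raise ValueError("community must have at least 2 regions")
    phases = np.asarray(phases, dtype=float)[community]
    if phases.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    tensor = ipl_tensor(phases)  # (T, m, m)
    pair_var = np.var(tensor, axis=0, ddof=ddof)  # (m, m)
    m = community.size
    iu = np.triu_indices(m, k=1)
    if per_region:
        mask = ~np.eye(m, dtype=bool)
        row_means = np.array([pair_var[i, mask[i]].mean() for i in range(m)])
        return float(row_means.mean())
    return float(pair_var[iu].mean())


def global_var(community_vars: np.ndarray | list[float]) -> float:
    """Unweighted mean of per-community VAR values."""
    return float(np.mean(np.asarray(community_vars, dtype=float)))


def mean_ipl(phases: np.ndarray) -> np.ndarray:
    """Time-averaged instantaneous phase-locking matrix."""
    return ipl_tensor(np.asarray(phases, dtype=float)).mean(axis=0)


def _lcc_fraction(adj: np.ndarray) -> float:
    """Largest-connected-component size as a fraction of N.

    Components are induced by edges; an edgeless graph has no connected
    structure and scores 0 (so fully antiphase matrices integrate to ~0).
    """
    n = adj.shape[0]
    if not adj.any():
        return 0.0
    _, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels)
    return float(sizes.max()) / n


def integration(
    mean_ipl_matrix: np.ndarray, threshold_step: float = 0.01
) -> float:
    """Global integration GINT of the time-averaged phase-locking matrix.

    The matrix is scanned through thresholds 0, step, ..., 1; at each
    threshold the off-diagonal entries >= threshold define an undirected
    graph, and the largest-connected-component fraction is recorded. GINT
    is the trapezoidal integral of that curve over [0, 1], so GINT lies in
    [0, 1].
    """
    m = np.asarray(mean_ipl_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    off = m.copy()
    np.fill_diagonal(off, -np.inf)
    taus = np.arange(0.0, 1.0 + threshold_step / 2, threshold_step)
    fractions = np.array([_lcc_fraction(off >= tau) for tau in taus])
    return float(np.trapezoid(fractions, taus))


def segregation(
    mean_ipl_matrix: np.ndarray,
    restarts: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> tuple[float, list[set[int]]]:
    """Functional segregation: Newman modularity Q under Louvain.

    Negative entries are excluded from the weighted graph (no edge).
    The Louvain algorithm is stochastic; the best of ``restarts`` seeded
    restarts by Q is returned along with its partition.
    """
    m = np.asarray(mean_ipl_matrix, dtype=float).copy()
    np.fill_diagonal(m, 0.0)
    m[m < 0] = 0.0
    g = nx.from_numpy_array(m)
    if g.number_of_edges() == 0:
        raise ValueError("graph has no positive-weight edges")
    best_q = -np.inf
    best_part: list[set[int]] = []
    for r in range(restarts):
        part = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=seed + r
        )
        q = nx.community.modularity(g, part, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best_part = q, [set(c) for c in part]
    return float(best_q), best_part


def metastability_index(fseg: float, gint: float) -> float:
    """Metastability index K = segregation / integration."""
    if gint <= 0:
        raise ValueError(f"integration must be positive, got {gint}")
    return fseg / gint


def subject_metrics(
    phases: np.ndarray,
    communities: list[np.ndarray],
    ddof_time: int = 1,
    ddof_chi: int = 0,
    threshold_step: float = 0.01,
    louvain_restarts: int = 20,
    louvain_seed: int = 0,
) -> dict[str, float]:
    """All scalar metrics for one subject's phase matrix.

    ``communities`` come from a ModeSet fitted on the subject's dataset.
    META/VAR are computed over all timepoints for every community; CHI is
    summarized by its temporal mean and max.
    """
    metas, vars_ = [], []
    r_rows = []
    for comm in communities:
        r = kuramoto_order(phases, comm)
        r_rows.append(r)
        metas.append(meta(r, ddof=ddof_time))
        if np.asarray(comm).size >= 2:
            vars_.append(var_metric(phases, comm, ddof=ddof_time))
        else:
            vars_.append(0.0)
    out: dict[str, float] = {}
    for i, (m_val, v_val) in enumerate(zip(metas, vars_), start=1):
        out[f"meta_psi{i}"] = m_val
        out[f"var_psi{i}"] = v_val
    out["global_meta"] = global_meta(metas)
    out["global_var"] = global_var(vars_)
    if len(communities) >= 2:
        chi = chimerality(np.vstack(r_rows), ddof=ddof_chi)
        out["chi_mean"] = float(chi.mean())
        out["chi_max"] = float(chi.max())
    mip = mean_ipl(phases)
    gint = integration(mip, threshold_step=threshold_step)
    fseg, _ = segregation(mip, restarts=louvain_restarts, seed=louvain_seed)
    out["gint"] = gint
    out["fseg"] = fseg
    out["k_index"] = metastability_index(fseg, gint)
    return out


def metrics_table(
    records: list[tuple[str, str, int, dict[str, float]]]
) -> pd.DataFrame:
    """Assemble per-subject metric dicts into a tidy table.

    ``records`` are ``(subject_id, group, run, metrics)`` tuples.
    """
    rows = []
    for subject_id, group, run, vals in records:
        row = {"subject": subject_id, "group": group, "run": run}
        row.update(vals)
        rows.append(row)
    return pd.DataFrame(rows)
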