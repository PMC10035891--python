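"""Two-cohort coupled-oscillator simulator.

Generates region x time datasets with the statistical structure the
downstream analysis assumes: band-limited oscillations, community-structured
phase coupling with first- and second-order (antiphase-stabilizing) terms,
recurrent switching between coupling templates, and a case cohort whose
coupling within a designated region block is scaled down.

The phase dynamics follow a multi-oscillator coordination model with drift

    dtheta_i = [2 pi f_i - sum_j (A_ij sin(theta_i - theta_j)
                                  + 2 B_ij sin(2 (theta_i - theta_j)))] dt
               + sigma dW,

with ``B = b * A``. With ``b = 0`` this reduces exactly to the standard
Kuramoto model; with ``b > 0`` the pairwise potential
``-A cos(phi) - B cos(2 phi)`` gains a stable antiphase minimum.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import RegionTimeSeries

__all__ = [
    "SimulationConfig",
    "SubjectRecord",
    "CohortDataset",
    "make_block_templates",
    "simulate_oscillator_network",
    "simulate_phases_with_schedule",
    "apply_observation_model",
    "generate_cohorts",
    "write_fixture",
]

GROUPS = ("control", "case")


class IntegrationError(RuntimeError):
    """Raised when the stochastic integrator produces non-finite state."""


def make_block_templates(
    n_regions: int,
    blocks: list[np.ndarray | list[int]],
    within: float = 1.0,
    between: float = 0.0,
    baseline: float = 0.0,
) -> list[np.ndarray]:
    """One coupling template per block: strong within-block coupling.

    Template ``k`` couples the regions of ``blocks[k]`` at strength
    ``within`` and couples block members to outsiders at ``between``;
    all other pairs get ``baseline``. Symmetric, zero diagonal.
    """
    templates = []
    for block in blocks:
        block = np.asarray(block, dtype=int)
        a = np.full((n_regions, n_regions), baseline, dtype=float)
        in_block = np.zeros(n_regions, dtype=bool)
        in_block[block] = True
        a[np.ix_(in_block, ~in_block)] = between
        a[np.ix_(~in_block, in_block)] = between
        a[np.ix_(in_block, in_block)] = within
        np.fill_diagonal(a, 0.0)
        templates.append(a)
    return templates


@dataclass
class SimulationConfig:
    """Parameters of the two-cohort oscillator simulation."""

    n_regions: int = 116
    n_subjects_per_group: int = 10
    n_frames: int = 150
    tr: float = 2.0
    n_runs: int = 1
    freq_band: tuple[float, float] = (0.01, 0.08)
    natural_freqs: np.ndarray | None = None  # per-region Hz; drawn if None
    coupling_templates: list[np.ndarray] = field(default_factory=list)
    second_order_ratio: float = 0.5  # b such that B = b * A
    dwell_mean: float = 60.0  # seconds
    phase_noise_sd: float = 0.1  # rad * s^-1/2
    obs_noise_sd: float = 0.0
    case_coupling_scale: float = 1.0
    case_block_start: int = 0
    case_block_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 <= self.case_coupling_scale <= 1:
            raise ValueError("case_coupling_scale must lie in [0, 1]")
        f_lo, f_hi = self.freq_band
        if not 0 <= f_lo < f_hi:
            raise ValueError("freq_band must satisfy 0 <= f_lo < f_hi")
        if not self.coupling_templates:
            # default: one weak uniform template
            a = np.full((self.n_regions, self.n_regions), 0.05)
            np.fill_diagonal(a, 0.0)
            self.coupling_templates = [a]
        for a in self.coupling_templates:
            a = np.asarray(a, dtype=float)
            if a.shape != (self.n_regions, self.n_regions):
                raise ValueError(
                    f"coupling template shape {a.shape} != "
                    f"({self.n_regions}, {self.n_regions})"
                )
            if np.any(a < 0):
                raise ValueError("coupling entries must be non-negative")
            if np.any(np.diag(a) != 0):
                raise ValueError("coupling diagonal must be zero")
            if not np.allclose(a, a.T):
                raise ValueError("coupling templates must be symmetric")
        if self.natural_freqs is not None:
            f = np.asarray(self.natural_freqs, dtype=float)
            if f.shape != (self.n_regions,):
                raise ValueError("natural_freqs must have one entry per region")
            if np.any(f < f_lo) or np.any(f > f_hi):
                raise ValueError("natural_freqs must lie within freq_band")

    @property
    def case_block(self) -> np.ndarray:
        # clipped to the region range so small test networks stay valid
        stop = min(self.case_block_start + self.case_block_size, self.n_regions)
        return np.arange(self.case_block_start, stop)


def _case_templates(config: SimulationConfig) -> list[np.ndarray]:
    """Scale rows/columns of the designated block for the case cohort."""
    scale = config.case_coupling_scale
    block = config.case_block
    out = []
    for a in config.coupling_templates:
        a = np.asarray(a, dtype=float).copy()
        a[block, :] *= scale
        a[:, block] *= scale
        # block-internal pairs were scaled twice; keep a single factor
        if scale > 0:
            a[np.ix_(block, block)] /= scale
        out.append(a)
    return out


def _dwell_schedule(
    n_templates: int,
    total_time: float,
    dwell_mean: float,
    rng: np.random.Generator,
) -> list[tuple[int, float]]:
    """Cycle templates in order with exponential dwell times."""
    if n_templates == 1:
        return [(0, total_time)]
    schedule = []
    t, idx = 0.0, 0
    while t < total_time:
        dwell = rng.exponential(dwell_mean)
        schedule.append((idx, dwell))
        t += dwell
        idx = (idx + 1) % n_templates
    return schedule


def simulate_phases_with_schedule(
    config: SimulationConfig,
    group: str = "control",
    seed: int | np.random.SeedSequence | None = None,
    natural_freqs: np.ndarray | None = None,
    initial_phases: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the oscillator network; return phases and template index.

    Returns ``(phases, schedule)`` where ``phases`` is ``(N, T)`` sampled
    every TR (unwrapped radians) and ``schedule[t]`` is the index of the
    coupling template active at frame ``t``.

    Euler-Maruyama with sub-stepping such that the step is at most
    ``tr / 10``. Identical ``(config, seed)`` give identical output.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, t_frames = config.n_regions, config.n_frames

    if natural_freqs is None:
        natural_freqs = config.natural_freqs
    if natural_freqs is None:
        f_lo, f_hi = config.freq_band
        natural_freqs = rng.uniform(f_lo, f_hi, size=n)
    omega = 2.0 * np.pi * np.asarray(natural_freqs, dtype=float)

    templates = (
        _case_templates(config) if group == "case" else config.coupling_templates
    )
    templates = [np.asarray(a, dtype=float) for a in templates]
    b = config.second_order_ratio

    n_sub = 10  # sub-steps per TR -> dt <= tr/10
    dt = config.tr / n_sub
    sqrt_dt = np.sqrt(dt)
    total_time = (t_frames - 1) * config.tr

    raw_schedule = _dwell_schedule(
        len(templates), total_time + config.tr, config.dwell_mean, rng
    )
    # expand to per-substep template index
    n_steps = (t_frames - 1) * n_sub
    step_template = np.zeros(n_steps, dtype=int)
    pos = 0
    for idx, dwell in raw_schedule:
        span = int(np.ceil(dwell / dt))
        step_template[pos : pos + span] = idx
        pos += span
        if pos >= n_steps:
            break
    if pos < n_steps:
        step_template[pos:] = raw_schedule[-1][0] if raw_schedule else 0

    if initial_phases is not None:
        theta = np.asarray(initial_phases, dtype=float).copy()
        if theta.shape != (n,):
            raise ValueError("initial_phases must have one entry per region")
    else:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    phases = np.empty((n, t_frames))
    phases[:, 0] = theta
    frame_template = np.zeros(t_frames, dtype=int)
    frame_template[0] = step_template[0] if n_steps else 0

    noise_sd = config.phase_noise_sd
    for step in range(n_steps):
        a = templates[step_template[step]]
        diff = theta[:, None] - theta[None, :]
        with np.errstate(over="ignore", invalid="ignore"):
            coupling = (a * np.sin(diff)).sum(axis=1)
            if b != 0.0:
                coupling = coupling + (2.0 * b * a * np.sin(2.0 * diff)).sum(axis=1)
            drift = omega - coupling
            theta = theta + drift * dt
        if noise_sd > 0:
            theta = theta + noise_sd * sqrt_dt * rng.standard_normal(n)
        if not np.all(np.isfinite(theta)):
            raise IntegrationError(
                f"non-finite phase state at sub-step {step} (dt={dt} s); "
                "reduce coupling strength or step size"
            )
        if (step + 1) % n_sub == 0:
            frame = (step + 1) // n_sub
            phases[:, frame] = theta
            frame_template[frame] = step_template[step]
    return phases, frame_template


def simulate_oscillator_network(
    config: SimulationConfig,
    group: str = "control",
    seed: int | np.random.SeedSequence | None = None,
    natural_freqs: np.ndarray | None = None,
    initial_phases: np.ndarray | None = None,
) -> np.ndarray:
    """Phase matrix ``(N, T)`` for one subject (see module docstring)."""
    phases, _ = simulate_phases_with_schedule(
        config,
        group=group,
        seed=seed,
        natural_freqs=natural_freqs,
        initial_phases=initial_phases,
    )
    return phases


def apply_observation_model(
    phases: np.ndarray,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> RegionTimeSeries:
    """BOLD-like observation: ``x_i(t) = cos(theta_i(t)) + noise``.

    With zero observation noise the Hilbert phase of the (band-passed)
    output recovers the simulated phase up to edge effects.
    """
    phases = np.asarray(phases, dtype=float)
    if not np.all(np.isfinite(phases)):
        raise ValueError("phases must be finite")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    values = np.cos(phases)
    if config.obs_noise_sd > 0:
        values = values + config.obs_noise_sd * rng.standard_normal(phases.shape)
    labels = [f"R{i + 1:03d}" for i in range(phases.shape[0])]
    return RegionTimeSeries(values, tr=config.tr, region_labels=labels)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    run: int
    series: RegionTimeSeries


@dataclass
class CohortDataset:
    """Labelled collection of subjects with shared region structure."""

    subjects: list[SubjectRecord]
    region_labels: list[str]
    provenance: SimulationConfig | str | None = None

    def __post_init__(self) -> None:
        n = len(self.region_labels)
        for rec in self.subjects:
            if rec.group not in GROUPS:
                raise ValueError(
                    f"subject {rec.subject_id}: unknown group {rec.group!r}"
                )
            if rec.series.n_regions != n:
                raise ValueError(
                    f"subject {rec.subject_id}: {rec.series.n_regions} regions, "
                    f"expected {n}"
                )
            if rec.series.region_labels != self.region_labels:
                raise ValueError(
                    f"subject {rec.subject_id}: region labels differ from dataset"
                )

    def group_subjects(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    @property
    def runs(self) -> list[int]:
        return sorted({s.run for s in self.subjects})


def generate_cohorts(config: SimulationConfig) -> CohortDataset:
    """Simulate control and case cohorts.

    Per-subject/run seeds are spawned deterministically from the master
    seed. A subject's natural frequencies are shared across its runs so
    that between-subject variance persists across runs (test-retest
    structure); phase and observation noise are redrawn per run.
    """
    master = np.random.SeedSequence(config.seed)
    n_children = 2 * config.n_subjects_per_group * (config.n_runs + 1)
    children = iter(master.spawn(n_children))
    labels = [f"R{i + 1:03d}" for i in range(config.n_regions)]
    subjects: list[SubjectRecord] = []
    f_lo, f_hi = config.freq_band
    for group in GROUPS:
        for s in range(config.n_subjects_per_group):
            subject_id = f"{group[:3]}{s + 1:03d}"
            freq_rng = np.random.default_rng(next(children))
            if config.natural_freqs is not None:
                freqs = np.asarray(config.natural_freqs, dtype=float)
            else:
                freqs = freq_rng.uniform(f_lo, f_hi, size=config.n_regions)
            for run in range(1, config.n_runs + 1):
                run_seed = next(children)
                phase_seed, obs_seed = run_seed.spawn(2)
                phases = simulate_oscillator_network(
                    config, group=group, seed=phase_seed, natural_freqs=freqs
                )
                series = apply_observation_model(phases, config, seed=obs_seed)
                subjects.append(SubjectRecord(subject_id, group, run, series))
    return CohortDataset(subjects, labels, provenance=replace(config))


def write_fixture(dataset: CohortDataset, directory: str | os.PathLike) -> str:
    """Write one TSV matrix per subject plus a manifest CSV and run log.

    Returns the manifest path. The matrix format is tab-separated with a
    header row of frame indices and the region label as first column; it
    round-trips through :func:`dfcmeta.io.read_matrix` at full float
    precision.
    """
    directory = os.fspath(directory)
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"output directory does not exist: {directory}")
    from . import io as dio  # local import to avoid a cycle

    rows = []
    for rec in dataset.subjects:
        fname = f"{rec.subject_id}_run{rec.run}.tsv"
        path = os.path.join(directory, fname)
        dio.write_matrix(rec.series, path)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "run": rec.run,
                "tr_seconds": rec.series.tr,
                "path": fname,
            }
        )
    import pandas as pd

    manifest_path = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    seed = (
        dataset.provenance.seed
        if isinstance(dataset.provenance, SimulationConfig)
        else "unknown"
    )
    with open(os.path.join(directory, "run_log.txt"), "w") as fh:
        fh.write(f"master_seed: {seed}\n")
        fh.write(f"n_subjects: {len(dataset.subjects)}\n")
        fh.write(f"n_regions: {len(dataset.region_labels)}\n")
    return manifest_path
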