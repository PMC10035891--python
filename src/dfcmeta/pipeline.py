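"""End-to-end orchestration: signals -> phases -> modes -> metrics -> stats.

Mode extraction is performed per dataset (one group x run combination at a
time); centroids are never fitted across groups or datasets, which avoids
leaking group structure into the dimensionality reduction.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as clf
from . import leida, metrics, signal_prep, stats
from .synthetic import GROUPS, CohortDataset

__all__ = ["PipelineConfig", "run_pipeline", "dataset_phases"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, serialized with every run."""

    band: tuple[float, float] = (0.01, 0.08)
    k_range: tuple[int, int] = (2, 10)
    fixed_k: int | None = None  # override silhouette selection
    kmeans_reps: int = 300
    kmeans_iters: int = 400
    half_switch: bool = False
    half_switch_delta: float = 0.05
    ddof_time: int = 1  # temporal variance/std denominator T-1
    ddof_chi: int = 0  # population variance across communities
    threshold_step: float = 0.01
    louvain_restarts: int = 20
    n_perm: int = 9999
    cv_folds: int = 10
    cv_reps: int = 20
    balance_mode: str = "down"
    classifier_feature: str = "global_var"
    edge_trim: int = 0  # frames dropped at each end after Hilbert
    seed: int = 0

    def validate(self) -> None:
        f_lo, f_hi = self.band
        if not 0 <= f_lo < f_hi:
            raise ValueError("band must satisfy 0 <= f_lo < f_hi")
        lo, hi = self.k_range
        if not 2 <= lo <= hi:
            raise ValueError("k_range must satisfy 2 <= lo <= hi")
        if self.fixed_k is not None and not lo <= self.fixed_k <= hi:
            raise ValueError("fixed_k must lie within k_range")
        if self.balance_mode not in ("down", "up"):
            raise ValueError("balance_mode must be 'down' or 'up'")
        for name in ("kmeans_reps", "kmeans_iters", "n_perm", "cv_folds",
                     "cv_reps", "louvain_restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.edge_trim < 0:
            raise ValueError("edge_trim must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def subject_phases(series, config: PipelineConfig) -> np.ndarray:
    """Band-pass and Hilbert-transform one subject's series into phases."""
    f_lo, f_hi = config.band
    filtered = signal_prep.bandpass_fft(series, f_lo, f_hi)
    analytic = signal_prep.analytic_signal(filtered, band=config.band)
    phase = analytic.phase
    if config.edge_trim > 0:
        phase = phase[:, config.edge_trim : phase.shape[1] - config.edge_trim]
    return phase


def dataset_phases(
    dataset: CohortDataset, config: PipelineConfig
) -> dict[tuple[str, int], dict[str, np.ndarray]]:
    """Phases per (group, run) dataset, keyed by subject id."""
    for rec in dataset.subjects:
        if config.band[1] >= rec.series.nyquist:
            raise ValueError(
                f"subject {rec.subject_id}: band upper edge {config.band[1]} Hz "
                f">= Nyquist {rec.series.nyquist} Hz"
            )
    out: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for rec in dataset.subjects:
        key = (rec.group, rec.run)
        out.setdefault(key, {})[rec.subject_id] = subject_phases(
            rec.series, config
        )
    return out


def run_pipeline(
    dataset: CohortDataset,
    config: PipelineConfig,
    out_dir: str | os.PathLike,
) -> dict:
    """Execute the full analysis and write per-stage artifacts.

    Returns a summary dict; all numeric outputs are reproducible for a
    fixed ``(dataset, config)``.
    """
    config.validate()
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        fh.write(config.to_json())

    phases_by_dataset = dataset_phases(dataset, config)
    rng = np.random.default_rng(config.seed)

    # per-dataset mode extraction
    modesets: dict[tuple[str, int], leida.ModeSet] = {}
    silhouettes: dict[str, dict[int, float]] = {}
    for key in sorted(phases_by_dataset):
        eig_blocks = []
        for sid in sorted(phases_by_dataset[key]):
            eig_blocks.append(
                leida.compute_eigenseries(phases_by_dataset[key][sid]).vectors
            )
        vectors = np.concatenate(eig_blocks, axis=1)
        mode_sets = leida.extract_modes_range(
            vectors,
            k_range=config.k_range,
            reps=config.kmeans_reps,
            max_iter=config.kmeans_iters,
            seed=int(rng.integers(2**31 - 1)),
        )
        chosen_k, sil_table = leida.select_k_silhouette(
            mode_sets, override=config.fixed_k
        )
        modesets[key] = mode_sets[chosen_k]
        silhouettes[f"{key[0]}_run{key[1]}"] = sil_table
        np.savetxt(
            os.path.join(out_dir, f"centroids_{key[0]}_run{key[1]}.tsv"),
            mode_sets[chosen_k].centroids,
            delimiter="\t",
        )
    with open(os.path.join(out_dir, "silhouettes.json"), "w") as fh:
        json.dump(silhouettes, fh, indent=2)

    # per-subject metrics using the subject's dataset communities
    records = []
    for rec in dataset.subjects:
        key = (rec.group, rec.run)
        ms = modesets[key]
        vals = metrics.subject_metrics(
            phases_by_dataset[key][rec.subject_id],
            ms.communities,
            ddof_time=config.ddof_time,
            ddof_chi=config.ddof_chi,
            threshold_step=config.threshold_step,
            louvain_restarts=config.louvain_restarts,
            louvain_seed=config.seed,
        )
        records.append((rec.subject_id, rec.group, rec.run, vals))
    table = metrics.metrics_table(records)
    table = table.sort_values(["group", "subject", "run"]).reset_index(drop=True)
    table.to_csv(os.path.join(out_dir, "metrics.csv"), index=False)

    # group statistics on the classifier feature
    feature = config.classifier_feature
    summary: dict = {"n_subjects": len(dataset.subjects)}
    if feature in table.columns and table["run"].nunique() >= 1:
        long = table[["subject", "group", "run", feature]].rename(
            columns={feature: "value"}
        )
        complete = (
            long.groupby("subject")["run"].nunique() == long["run"].nunique()
        )
        if bool(complete.all()):
            report = stats.flowchart(long)
            with open(os.path.join(out_dir, "stats.json"), "w") as fh:
                fh.write(report.to_json())
            summary["stats_effects"] = {
                e: report.effects[e].get("p_corrected")
                for e in report.effects
            }

    # single-feature classification on the first run
    first_run = table["run"].min()
    sub = table[table["run"] == first_run]
    if feature in sub.columns and all(
        (sub["group"] == g).sum() >= config.cv_folds for g in GROUPS
    ):
        fset = clf.FeatureSet(
            sub[feature].to_numpy(), sub["group"].to_numpy(), "run1"
        )
        perf = clf.repeated_kfold(
            fset,
            k=config.cv_folds,
            reps=config.cv_reps,
            sampling=config.balance_mode,
            seed=config.seed,
        )
        with open(os.path.join(out_dir, "classification.json"), "w") as fh:
            fh.write(perf.to_json())
        summary["classification"] = perf.to_dict()

    with open(os.path.join(out_dir, "run_log.txt"), "w") as fh:
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"datasets: {sorted(map(str, phases_by_dataset))}\n")
        fh.write(f"chosen_k: { {str(k): ms.k for k, ms in modesets.items()} }\n")
    summary["out_dir"] = out_dir
    summary["chosen_k"] = {f"{k[0]}_run{k[1]}": ms.k for k, ms in modesets.items()}
    return summary
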