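"""Readers and writers for the delimited-text interchange formats.

Matrices are tab-separated with regions as rows: a header row of frame
indices and the region label in the first column. Manifests are CSV with
columns ``subject_id, group, run, tr_seconds, path`` (paths relative to the
manifest's directory).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import RegionTimeSeries
from .synthetic import GROUPS, CohortDataset, SubjectRecord

__all__ = ["write_matrix", "read_matrix", "read_manifest", "MANIFEST_COLUMNS"]

MANIFEST_COLUMNS = ["subject_id", "group", "run", "tr_seconds", "path"]


def write_matrix(series: RegionTimeSeries, path: str | os.PathLike) -> None:
    """Write a region x time matrix as TSV (full float precision)."""
    df = pd.DataFrame(
        series.values,
        index=pd.Index(series.region_labels, name="region"),
        columns=np.arange(series.n_frames),
    )
    try:
        df.to_csv(path, sep="\t", float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write matrix to {os.fspath(path)}: {exc}") from exc


def read_matrix(path: str | os.PathLike, tr: float) -> RegionTimeSeries:
    """Read a TSV region x time matrix written by :func:`write_matrix`."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except OSError as exc:
        raise OSError(f"cannot read matrix from {os.fspath(path)}: {exc}") from exc
    return RegionTimeSeries(
        df.to_numpy(dtype=float), tr=tr, region_labels=[str(r) for r in df.index]
    )


def read_manifest(path: str | os.PathLike) -> CohortDataset:
    """Load a cohort from a manifest CSV.

    Validates the column set, group labels, and that all subjects share
    the same regions.
    """
    path = os.fspath(path)
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest.empty:
        raise ValueError(f"manifest is empty: {path}")
    base = os.path.dirname(os.path.abspath(path))

    subjects: list[SubjectRecord] = []
    ref_labels: list[str] | None = None
    ref_subject = ""
    for row in manifest.itertuples(index=False):
        if row.group not in GROUPS:
            raise ValueError(
                f"subject {row.subject_id}: unknown group {row.group!r} "
                f"(expected one of {GROUPS})"
            )
        mpath = row.path
        if not os.path.isabs(mpath):
            mpath = os.path.join(base, mpath)
        series = read_matrix(mpath, tr=float(row.tr_seconds))
        if ref_labels is None:
            ref_labels = series.region_labels
            ref_subject = str(row.subject_id)
        elif series.region_labels != ref_labels:
            raise ValueError(
                f"region mismatch between subjects {ref_subject} "
                f"({len(ref_labels)} regions) and {row.subject_id} "
                f"({series.n_regions} regions)"
            )
        subjects.append(
            SubjectRecord(str(row.subject_id), str(row.group), int(row.run), series)
        )
    assert ref_labels is not None
    return CohortDataset(subjects, ref_labels, provenance=path)
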