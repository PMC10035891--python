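"""Signal preparation: parcellation, FFT band-pass, analytic phase.

Turns raw region x time signals into band-limited analytic phases and
reports whether the amplitude envelope respects the narrowband (Bedrosian)
assumption via a Carson-style envelope-spectrum check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .datatypes import AnalyticSeries, RegionTimeSeries

__all__ = [
    "parcellate",
    "bandpass_fft",
    "analytic_signal",
    "bedrosian_report",
]

DEFAULT_BAND = (0.01, 0.08)


def parcellate(
    voxel_matrix: np.ndarray,
    region_of_voxel: list[str],
    tr: float,
    region_order: list[str] | None = None,
) -> RegionTimeSeries:
    """Average voxel time-courses into one series per region.

    Region order follows first appearance in ``region_of_voxel`` unless an
    explicit ``region_order`` is given.
    """
    voxel_matrix = np.asarray(voxel_matrix, dtype=float)
    if voxel_matrix.ndim != 2:
        raise ValueError("voxel_matrix must be 2-D (voxels x time)")
    if len(region_of_voxel) != voxel_matrix.shape[0]:
        raise ValueError("one region label required per voxel row")

    if region_order is None:
        region_order = list(dict.fromkeys(region_of_voxel))
    labels = np.asarray(region_of_voxel)
    rows = []
    for region in region_order:
        mask = labels == region
        if not mask.any():
            raise ValueError(f"region {region!r} has no voxels")
        rows.append(voxel_matrix[mask].mean(axis=0))
    return RegionTimeSeries(np.vstack(rows), tr=tr, region_labels=list(region_order))


def _band_bins(n_frames: int, tr: float, f_lo: float, f_hi: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_frames, d=tr)
    return (freqs >= f_lo) & (freqs <= f_hi)


def bandpass_fft(
    series: RegionTimeSeries,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
) -> RegionTimeSeries:
    """Ideal (brick-wall) DFT band-pass filter, closed band ``[f_lo, f_hi]``.

    Each row is demeaned, transformed, bins with ``|f|`` outside the band
    zeroed, and inverse-transformed. The output rows have (numerically)
    zero mean.
    """
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"need 0 <= f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi >= series.nyquist:
        raise ValueError(
            f"f_hi={f_hi} Hz must be below the Nyquist frequency "
            f"{series.nyquist} Hz (tr={series.tr} s)"
        )
    keep = _band_bins(series.n_frames, series.tr, f_lo, f_hi)
    if not keep.any():
        raise ValueError(
            f"no FFT bin falls inside [{f_lo}, {f_hi}] Hz for "
            f"T={series.n_frames}, tr={series.tr}; series too short"
        )
    x = series.values - series.values.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(x, axis=1)
    spec[:, ~keep] = 0.0
    filtered = np.fft.irfft(spec, n=series.n_frames, axis=1)
    return RegionTimeSeries(
        filtered, tr=series.tr, region_labels=list(series.region_labels)
    )


def analytic_signal(
    series: RegionTimeSeries,
    band: tuple[float, float] = DEFAULT_BAND,
) -> AnalyticSeries:
    """Hilbert analytic signal: amplitude envelope and wrapped phase.

    All-zero rows get amplitude 0 and phase 0 by convention. The input is
    expected (but not required) to be band-passed already.
    """
    analytic = hilbert(series.values, axis=1)
    amplitude = np.abs(analytic)
    phase = np.angle(analytic)
    zero_rows = ~series.values.any(axis=1)
    if zero_rows.any():
        amplitude[zero_rows] = 0.0
        phase[zero_rows] = 0.0
    # np.angle returns [-pi, pi]; map -pi to +pi for the (-pi, pi] contract
    phase[phase == -np.pi] = np.pi
    return AnalyticSeries(
        amplitude=amplitude,
        phase=phase,
        tr=series.tr,
        band=band,
        region_labels=list(series.region_labels),
    )


def bedrosian_report(
    analytic: AnalyticSeries,
    tolerance: float = 0.05,
    edge_frac: float = 0.1,
) -> pd.DataFrame:
    """Per-region narrowband-validity check on the amplitude envelope.

    For each region the amplitude-envelope power spectrum is computed; a
    region passes when the fraction of (non-DC) envelope power at or above
    the lower band edge ``f_lo`` is at most ``tolerance`` — i.e. the
    envelope varies slowly relative to the carrier, so the Hilbert phase is
    meaningful. Also reports the envelope's dominant modulation frequency
    ``f_mod``, the peak instantaneous-frequency deviation ``delta_f_peak``
    and the Carson bandwidth ``2 * (delta_f_peak + f_mod)``.

    The numeric tolerance is a pipeline decision, not a published
    criterion; it is recorded in the returned table's ``tolerance`` column.
    ``edge_frac`` of the samples at each end are discarded first (Hilbert
    edge transients would otherwise dominate the envelope spectrum).
    """
    f_lo, _ = analytic.band
    tr = analytic.tr
    trim = int(edge_frac * analytic.n_frames)
    sl = slice(trim, analytic.n_frames - trim if trim else None)
    n = analytic.amplitude[:, sl].shape[1]
    freqs = np.fft.rfftfreq(n, d=tr)

    records = []
    for i, label in enumerate(analytic.region_labels):
        env = analytic.amplitude[i, sl]
        env_c = env - env.mean()
        spec_power = np.abs(np.fft.rfft(env_c)) ** 2
        spec_power[0] = 0.0
        total = spec_power.sum()
        # an (almost) constant envelope has only numerical-noise power
        floor = 1e-20 * n * max(env.mean() ** 2, 1e-300)
        if total <= floor:
            total = 0.0
        if total > 0:
            overlap = spec_power[freqs >= f_lo].sum() / total
            f_mod = float(freqs[int(np.argmax(spec_power))])
        else:
            overlap = 0.0
            f_mod = 0.0

        # instantaneous frequency from unwrapped phase, trimmed samples only
        inst_f = np.diff(np.unwrap(analytic.phase[i, sl])) / (2.0 * np.pi * tr)
        interior = inst_f
        if interior.size:
            carrier = float(np.median(interior))
            delta_f_peak = float(np.max(np.abs(interior - carrier)))
        else:
            delta_f_peak = 0.0

        records.append(
            {
                "region": label,
                "overlap_fraction": float(overlap),
                "f_mod": f_mod,
                "delta_f_peak": delta_f_peak,
                "carson_bandwidth": 2.0 * (delta_f_peak + f_mod),
                "tolerance": tolerance,
                "passed": bool(overlap <= tolerance),
            }
        )
    return pd.DataFrame.from_records(records)
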