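"""Temporal preprocessing of ROI BOLD time series.

Spatial preprocessing (slice timing, motion correction, normalisation,
smoothing) is assumed done upstream; this module starts from an aligned 4D
volume or a ready-made T x N ROI table and applies the temporal chain

    trim initial volumes -> linear detrend -> nuisance regression -> band-pass

in that order.  Each step returns a new :class:`SubjectTimeSeries`; the stage
history is recorded and out-of-order or repeated application is refused.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SubjectTimeSeries", "ConfoundSet", "PreprocessError",
    "extract_roi_timeseries", "drop_initial_volumes", "detrend_linear",
    "regress_confounds", "bandpass_filter", "load_roi_table",
    "save_roi_table",
]

# canonical order of the temporal chain; indices enforce the order contract
_STEP_ORDER = ("trim", "detrend", "confounds", "bandpass")


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's T x N ROI BOLD matrix.

    ``stage`` is ``raw`` after extraction, ``trimmed`` after dropping initial
    volumes and ``cleaned`` after band-pass filtering.  ``steps`` records the
    applied operations; ``bad_rois`` flags zero-variance columns (0-based
    indices) so downstream features can be marked missing instead of silently
    producing undefined correlations.
    """

    subject_id: str
    data: np.ndarray          # T x N, float64
    tr: float                 # seconds
    stage: str = "raw"
    steps: tuple[str, ...] = ()
    bad_rois: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] < 2:
            raise PreprocessError(
                f"time series must be T x N with T >= 2, got shape {d.shape}")
        if not np.isfinite(d).all():
            raise PreprocessError("time series contains non-finite values")
        if self.tr <= 0:
            raise PreprocessError("tr must be positive")
        object.__setattr__(self, "data", d)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ConfoundSet:
    """T x C nuisance regressors (motion parameters, CSF, WM, optional GSR)."""

    data: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[1] != len(self.names):
            raise PreprocessError("confound matrix/name mismatch")
        object.__setattr__(self, "data", d)


def _check_step(ts: SubjectTimeSeries, step: str) -> None:
    if step in ts.steps:
        raise PreprocessError(f"step '{step}' already applied (steps={ts.steps})")
    pos = _STEP_ORDER.index(step)
    later = [s for s in ts.steps if _STEP_ORDER.index(s) > pos]
    if later:
        raise PreprocessError(
            f"step '{step}' must precede {later}; applied order is "
            f"{' -> '.join(_STEP_ORDER)}")


def _flag_bad_rois(data: np.ndarray) -> tuple[int, ...]:
    return tuple(int(i) for i in np.flatnonzero(np.ptp(data, axis=0) == 0))


def extract_roi_timeseries(volume4d, labels, parc,
                           subject_id: str = "subject") -> SubjectTimeSeries:
    """Average voxel time series within each parcellation region.

    Parameters
    ----------
    volume4d
        4D array or nibabel image (x, y, z, t).
    labels
        3D integer array or nibabel image on the same grid; 0 = background,
        other values must be parcellation node ids.
    parc
        :class:`~rsfcnet.atlas.AtlasParcellation` giving the node order.
    """
    vol = np.asanyarray(volume4d.dataobj if hasattr(volume4d, "dataobj")
                        else volume4d, dtype=float)
    lab = np.asanyarray(labels.dataobj if hasattr(labels, "dataobj")
                        else labels)
    lab = np.rint(lab).astype(int)
    if vol.ndim != 4:
        raise PreprocessError(f"expected 4D volume, got shape {vol.shape}")
    if lab.shape != vol.shape[:3]:
        raise PreprocessError(
            f"label grid {lab.shape} does not match volume grid {vol.shape[:3]}")
    tr = float(volume4d.header.get_zooms()[3]) if hasattr(volume4d, "header") else 1.0

    T = vol.shape[3]
    out = np.empty((T, parc.n_nodes))
    flat = vol.reshape(-1, T)
    lab_flat = lab.ravel()
    for j, node_id in enumerate(parc.node_ids):
        mask = lab_flat == node_id
        if not mask.any():
            raise PreprocessError(
                f"node {node_id} ({parc.table['node_name'].iloc[j]}) "
                "absent from label volume")
        out[:, j] = flat[mask].mean(axis=0)
    return SubjectTimeSeries(subject_id=subject_id, data=out, tr=tr,
                             stage="raw", bad_rois=_flag_bad_rois(out))


def drop_initial_volumes(ts: SubjectTimeSeries, k: int = 10) -> SubjectTimeSeries:
    """Remove the first ``k`` frames (signal equilibration / adaptation)."""
    if k < 0:
        raise PreprocessError("k must be >= 0")
    if ts.n_timepoints <= k:
        raise PreprocessError(
            f"cannot drop {k} volumes from a series of {ts.n_timepoints}")
    _check_step(ts, "trim")
    return replace(ts, data=ts.data[k:], stage="trimmed",
                   steps=ts.steps + ("trim",),
                   bad_rois=_flag_bad_rois(ts.data[k:]))


def detrend_linear(ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Remove each column's ordinary least-squares line in time."""
    if ts.n_timepoints < 3:
        raise PreprocessError("detrending needs T >= 3")
    _check_step(ts, "detrend")
    out = signal.detrend(ts.data, axis=0, type="linear")
    return replace(ts, data=out, steps=ts.steps + ("detrend",),
                   bad_rois=_flag_bad_rois(out))


def regress_confounds(ts: SubjectTimeSeries,
                      confounds: ConfoundSet) -> SubjectTimeSeries:
    """Replace each column by its OLS residual against intercept + confounds.

    Raises on a rank-deficient design instead of silently falling back to a
    pseudo-inverse, so collinear confounds are surfaced to the caller.
    """
    _check_step(ts, "confounds")
    C = confounds.data
    if C.shape[0] != ts.n_timepoints:
        raise PreprocessError(
            f"confounds have {C.shape[0]} rows, time series has "
            f"{ts.n_timepoints}")
    X = np.column_stack([np.ones(ts.n_timepoints), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise PreprocessError(
            "confound design is rank deficient; remove collinear confound "
            f"columns (rank {rank} < {X.shape[1]} columns)")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    out = ts.data - X @ beta
    return replace(ts, data=out, steps=ts.steps + ("confounds",),
                   bad_rois=_flag_bad_rois(out))


def bandpass_filter(ts: SubjectTimeSeries, low_hz: float = 0.01,
                    high_hz: float = 0.08, order: int = 2) -> SubjectTimeSeries:
    """Zero-phase Butterworth band-pass retaining ``low_hz``–``high_hz``.

    Applied forward-backward (``filtfilt``), so the effective magnitude
    response is the square of a single Butterworth pass and the phase is
    zero.  Marks the series ``cleaned``.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0 < low_hz < high_hz < nyquist):
        raise PreprocessError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist "
            f"{nyquist:.4g} Hz")
    _check_step(ts, "bandpass")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / ts.tr, output="sos")
    out = signal.sosfiltfilt(sos, ts.data, axis=0)
    return replace(ts, data=out, stage="cleaned",
                   steps=ts.steps + ("bandpass",),
                   bad_rois=_flag_bad_rois(out))


def load_roi_table(path: str | Path, tr: float, subject_id: str | None = None,
                   stage: str = "raw") -> SubjectTimeSeries:
    """Read a T x N ROI table (TSV, node ids as column names)."""
    df = pd.read_csv(path, sep="\t")
    sid = subject_id if subject_id is not None else Path(path).stem
    ts = SubjectTimeSeries(subject_id=sid, data=df.to_numpy(dtype=float),
                           tr=tr, stage=stage)
    return replace(ts, bad_rois=_flag_bad_rois(ts.data))


def save_roi_table(ts: SubjectTimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.data,
                      columns=[str(i + 1) for i in range(ts.n_rois)])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
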