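"""Temporal denoising: confound regression, bandpass filtering, scrubbing.

The pipeline order is fixed — nuisance regression first, then bandpass
filtering, then motion scrubbing — and each step is a pure function of a
:class:`~hemilat.core_io.BoldSeries`, so reruns are bit-reproducible.

Confounds follow the common resting-state recipe: the 24-parameter Friston
expansion of the six rigid-body motion traces, white-matter and CSF mean
signals, an intercept and a linear trend.  Framewise displacement uses the
Power convention (sum of absolute backward differences, rotations converted
to arc length on a 50 mm sphere); frames above threshold are deleted.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import signal

from .core_io import BoldSeries, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfoundSet",
    "friston24_expand",
    "regress_confounds",
    "bandpass_filter",
    "framewise_displacement",
    "scrub_high_motion",
    "load_motion_table",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]

#: rotation-to-translation conversion radius for FD, in mm
FD_SPHERE_RADIUS_MM = 50.0


@dataclasses.dataclass
class ConfoundSet:
    """Nuisance regressors aligned with a BOLD series (after volume drop)."""

    motion6: np.ndarray
    wm_signal: np.ndarray | None = None
    csf_signal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.motion6 = np.asarray(self.motion6, dtype=float)
        if self.motion6.ndim != 2 or self.motion6.shape[1] != 6:
            raise ValueError(f"motion6 must be T x 6, got {self.motion6.shape}")
        for name in ("wm_signal", "csf_signal"):
            sig = getattr(self, name)
            if sig is not None:
                sig = np.asarray(sig, dtype=float).ravel()
                if sig.shape[0] != self.motion6.shape[0]:
                    raise ValueError(f"{name} length must match motion rows")
                setattr(self, name, sig)

    @property
    def n_frames(self) -> int:
        return self.motion6.shape[0]


def load_motion_table(path) -> ConfoundSet:
    """Read a motion/confound TSV (trans_*, rot_*, optional wm/csf)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"motion table missing columns: {missing}")
    return ConfoundSet(
        motion6=table[MOTION_COLUMNS].to_numpy(),
        wm_signal=table["wm"].to_numpy() if "wm" in table else None,
        csf_signal=table["csf"].to_numpy() if "csf" in table else None,
    )


def friston24_expand(motion6: np.ndarray) -> np.ndarray:
    """Friston 24-parameter autoregressive expansion of 6 motion traces.

    Columns are ``[m, m^2, m_{t-1}, m_{t-1}^2]`` (6 each); the lagged
    series are padded with 0 at the first frame.
    """
    m = np.asarray(motion6, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"expected T x 6 motion, got {m.shape}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    lag = np.vstack([np.zeros((1, 6)), m[:-1]])
    return np.hstack([m, m**2, lag, lag**2])


def _design_matrix(confounds: ConfoundSet) -> np.ndarray:
    t = confounds.n_frames
    cols = [np.ones(t), np.linspace(-1.0, 1.0, t)]
    cols.append(friston24_expand(confounds.motion6).T)
    if confounds.wm_signal is not None:
        cols.append(confounds.wm_signal)
    if confounds.csf_signal is not None:
        cols.append(confounds.csf_signal)
    return np.column_stack([np.atleast_2d(c).reshape(t, -1) for c in cols])


def regress_confounds(series: BoldSeries, confounds: ConfoundSet) -> BoldSeries:
    """Per-voxel least-squares residuals after removing the nuisance design.

    The design holds an intercept, a linear trend, the Friston-24 motion
    expansion and (when present) WM and CSF signals.  A rank-deficient
    design falls back to the pseudoinverse with a logged warning; residuals
    are orthogonal to the design either way.
    """
    x = _design_matrix(confounds)
    if x.shape[0] != series.n_frames:
        raise ValueError(
            f"confounds have {x.shape[0]} rows, series has {series.n_frames}"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        logger.warning(
            "confound design is rank deficient (rank %d < %d columns); "
            "using pseudoinverse",
            rank,
            x.shape[1],
        )
    beta = np.linalg.pinv(x) @ series.data
    residuals = series.data - x @ beta
    return series.with_data(residuals)


def bandpass_filter(series: BoldSeries, low_hz: float, high_hz: float) -> BoldSeries:
    """Zero-phase temporal bandpass (order-4 Butterworth, forward-backward).

    The contract is spectral: passband amplitude preserved within 5%,
    stopband attenuated by at least 90% at twice the band edges (measured on
    probe sinusoids).  ``low_hz`` may be 0, giving a pure lowpass.
    """
    nyquist = 0.5 / series.tr_s
    if not 0 <= low_hz < high_hz < nyquist:
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist} Hz"
        )
    fs = 1.0 / series.tr_s
    if low_hz > 0:
        sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    else:
        sos = signal.butter(4, high_hz, btype="lowpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, series.data, axis=0)
    return series.with_data(np.ascontiguousarray(filtered))


def framewise_displacement(motion6: np.ndarray) -> np.ndarray:
    """Power-style FD: sum of |backward differences| with rotations in mm.

    Rotations (radians) are converted to displacement on a 50 mm sphere.
    The first frame has FD 0.
    """
    m = np.asarray(motion6, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"expected T x 6 motion, got {m.shape}")
    diff = np.abs(np.diff(m, axis=0))
    diff[:, 3:] *= FD_SPHERE_RADIUS_MM
    fd = np.concatenate([[0.0], diff.sum(axis=1)])
    return fd


def scrub_high_motion(
    series: BoldSeries, motion6: np.ndarray, fd_threshold_mm: float = 0.5
) -> BoldSeries:
    """Delete frames whose framewise displacement exceeds the threshold.

    ``kept_frames`` is updated so retained rows stay traceable to original
    scan volumes.  Fewer than 10 surviving frames is an error.
    """
    fd = framewise_displacement(motion6)
    if fd.shape[0] != series.n_frames:
        raise ValueError("motion rows must match series frames")
    keep = fd <= fd_threshold_mm
    n_keep = int(keep.sum())
    if n_keep < 10:
        raise InsufficientDataError(
            f"scrubbing at FD>{fd_threshold_mm} mm leaves {n_keep} frames (<10)"
        )
    if n_keep == series.n_frames:
        return series
    return series.with_data(series.data[keep], kept_frames=series.kept_frames[keep])
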