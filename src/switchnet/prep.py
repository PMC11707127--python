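"""Condition node time courses before network construction.

Three operations, applied in the fixed order detrend -> despike ->
band-pass, all shape- and node-order-preserving:

* linear detrending per node (least squares);
* robust-z despiking: samples whose median/MAD z-score exceeds a
  threshold are shrunk to the threshold boundary, sign preserved;
* zero-phase band-pass filtering (order-2 Butterworth, forward-backward
  via ``filtfilt``), default 0.01-0.08 Hz, the conventional band for
  resting-state fluctuations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import NodeTimeSeries

__all__ = ["PrepConfig", "detrend", "despike", "bandpass", "preprocess"]

logger = logging.getLogger(__name__)

# scale factor making MAD a consistent estimator of the Gaussian SD
_MAD_TO_SD = 0.6744897501960817


@dataclass
class PrepConfig:
    """Switches and parameters for the conditioning stage; ``enabled``
    bypasses the whole stage (synthetic data may need no conditioning)."""

    enabled: bool = True
    do_detrend: bool = True
    despike_z: float | None = 4.0      # None disables despiking
    band_low_hz: float | None = 0.01   # None disables filtering
    band_high_hz: float | None = 0.08


def detrend(ts: NodeTimeSeries) -> NodeTimeSeries:
    """Remove each node's least-squares linear trend (mean included)."""
    values = ts.values
    flat = values.std(axis=1) == 0
    out = sps.detrend(values, axis=1, type="linear")
    if flat.any():
        # a constant node detrends to exact zeros; keep it, but say so
        logger.warning("detrend: %d zero-variance node(s) left as zeros",
                       int(flat.sum()))
        out[flat] = 0.0
    return ts.copy_with(out)


def despike(ts: NodeTimeSeries, z_threshold: float = 4.0) -> NodeTimeSeries:
    """Clip samples beyond ``z_threshold`` robust (median/MAD) z-scores
    to the threshold boundary, preserving sign; other samples untouched."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    out = ts.values.copy()
    for i in range(out.shape[0]):
        row = out[i]
        med = np.median(row)
        mad = np.median(np.abs(row - med))
        if mad == 0:
            logger.warning("despike: node %s has zero MAD, skipped",
                           ts.node_ids[i])
            continue
        sd = mad / _MAD_TO_SD
        z = (row - med) / sd
        hot = np.abs(z) > z_threshold
        if hot.any():
            out[i, hot] = med + np.sign(z[hot]) * z_threshold * sd
    return ts.copy_with(out)


def bandpass(ts: NodeTimeSeries, low_hz: float = 0.01,
             high_hz: float = 0.08) -> NodeTimeSeries:
    """Zero-phase band-pass: order-2 Butterworth applied forward and
    backward.  ``low_hz = 0`` degenerates to a low-pass."""
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low_hz < high_hz, got [{low_hz}, {high_hz}]")
    if high_hz >= nyquist:
        raise ValueError(
            f"high edge {high_hz} Hz is at or above Nyquist {nyquist} Hz "
            f"for TR {ts.tr_seconds} s")
    fs = 1.0 / ts.tr_seconds
    if low_hz > 0:
        sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs,
                         output="sos")
    else:
        sos = sps.butter(2, high_hz, btype="lowpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, ts.values, axis=1)
    return ts.copy_with(out)


def preprocess(ts: NodeTimeSeries, cfg: PrepConfig | None = None) -> NodeTimeSeries:
    """Apply the conditioning stage in its fixed order."""
    cfg = cfg or PrepConfig()
    if not cfg.enabled:
        return ts
    if cfg.do_detrend:
        ts = detrend(ts)
    if cfg.despike_z is not None:
        ts = despike(ts, cfg.despike_z)
    if cfg.band_low_hz is not None and cfg.band_high_hz is not None:
        ts = bandpass(ts, cfg.band_low_hz, cfg.band_high_hz)
    return ts
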