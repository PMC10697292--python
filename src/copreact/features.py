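"""Reactive-balance features of a perturbation epoch.

Four statistics per axis, computed over the compensatory response
window 0-0.4 s after perturbation contact on the baseline-corrected,
sign-oriented signal:

* D-COP  - peak displacement: maximum excursion in the positive
  direction (perturbation direction for ML, anterior for AP), mm.
* T-COP  - time of that peak, s (earliest sample on ties).
* V-COP  - peak velocity in the positive direction, mm/s.
* RMS    - root mean square of the signal over the window, mm.

Velocity is obtained by central differences on the filtered signal over
the analysis window, with second-order one-sided stencils at the window
edges (``np.gradient`` with ``edge_order=2``).  Differencing is confined
to the window so the estimate at t = 0 is not contaminated by the flat
pre-perturbation segment across the onset corner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .epochs import PerturbationEpoch
from .errors import (
    EpochStateError,
    ParticipantExcludedError,
    SeriesLengthError,
    WindowError,
)

log = logging.getLogger(__name__)

#: Compensatory response window (s after contact).
DEFAULT_WINDOW = (0.0, 0.4)


@dataclass(frozen=True)
class CopFeatures:
    """The eight per-epoch statistics (see module docstring for units)."""

    d_ml: float
    t_ml: float
    v_ml: float
    rms_ml: float
    d_ap: float
    t_ap: float
    v_ap: float
    rms_ap: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _windowed(epoch: PerturbationEpoch, axis: str, window: tuple[float, float]):
    if not epoch.baseline_corrected:
        raise EpochStateError("features require a baseline-corrected epoch")
    sl = epoch.window_slice(*window)
    if sl.stop <= sl.start:
        raise WindowError(f"window {window} contains no samples")
    return epoch.axis(axis)[sl], epoch.rel_time[sl]


def peak_displacement(
    epoch: PerturbationEpoch,
    axis: str,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[float, float]:
    """Peak positive-direction displacement and its time.

    Returns (D, T): the maximum of the signed signal over the closed
    window and the time it is attained, ties broken by the earliest
    sample.  An epoch that only moves against the perturbation still has
    a well-defined maximum (near zero, at the window start).
    """
    x, t = _windowed(epoch, axis, window)
    i = int(np.argmax(x))  # argmax returns the first maximizer
    return float(x[i]), float(t[i])


def peak_velocity(
    epoch: PerturbationEpoch,
    axis: str,
    window: tuple[float, float] = DEFAULT_WINDOW,
    mode: str = "directional",
) -> float:
    """Peak COP velocity over the window, mm/s.

    ``directional`` (default) mirrors the displacement rule: the maximum
    signed velocity toward the positive direction.  ``absolute`` returns
    the largest speed regardless of sign.
    """
    x, _ = _windowed(epoch, axis, window)
    if x.size < 3:
        raise SeriesLengthError("peak_velocity needs >= 3 samples in the window")
    v = np.gradient(x, 1.0 / epoch.fs, edge_order=2)
    if mode == "directional":
        return float(v.max())
    if mode == "absolute":
        return float(np.abs(v).max())
    raise ValueError(f"mode must be 'directional' or 'absolute', got {mode!r}")


def rms(
    epoch: PerturbationEpoch,
    axis: str,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> float:
    """Root mean square of the baseline-corrected signal over the window.

    Computed as the square root of the time-average of x(t)^2 over the
    closed window, evaluated by trapezoidal rule on the sample grid.
    The trapezoidal weighting (half weight on the two window endpoints)
    makes the discrete value a second-order accurate estimate of the
    continuous RMS; a plain sample mean over the closed window would
    double-count one endpoint and bias the value low by ~1/(2n).
    """
    x, t = _windowed(epoch, axis, window)
    if x.size < 2:
        raise WindowError("rms needs >= 2 samples in the window")
    return float(np.sqrt(np.trapezoid(x**2, t) / (t[-1] - t[0])))


def compute_features(
    epoch: PerturbationEpoch,
    window: tuple[float, float] = DEFAULT_WINDOW,
    velocity_mode: str = "directional",
) -> CopFeatures:
    """All eight statistics of one epoch."""
    d_ml, t_ml = peak_displacement(epoch, "ml", window)
    d_ap, t_ap = peak_displacement(epoch, "ap", window)
    return CopFeatures(
        d_ml=d_ml,
        t_ml=t_ml,
        v_ml=peak_velocity(epoch, "ml", window, velocity_mode),
        rms_ml=rms(epoch, "ml", window),
        d_ap=d_ap,
        t_ap=t_ap,
        v_ap=peak_velocity(epoch, "ap", window, velocity_mode),
        rms_ap=rms(epoch, "ap", window),
    )


def aggregate_trials(features_list: list[CopFeatures]) -> CopFeatures:
    """Field-wise mean across the valid epochs of one participant/session.

    Each test trial delivers several perturbations; the participant-level
    value entering the group analysis is the arithmetic mean over the
    epochs that survived QC.  An empty list means the participant/session
    has no usable data and is excluded (mirroring exclusion rather than
    imputation).
    """
    if not features_list:
        raise ParticipantExcludedError("no valid epochs to aggregate")
    log.info("aggregating %d epochs", len(features_list))
    means = {
        name: float(np.mean([getattr(f, name) for f in features_list]))
        for name in (f.name for f in dc_fields(CopFeatures))
    }
    return CopFeatures(**means)
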