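"""Perturbation onset detection and epoch extraction.

The perturbation device is driven by an electrical trigger; the air
cylinder contacts the pelvis a short mechanical delay later.  Onsets
(t = 0, contact) are located as rising threshold crossings of the
trigger channel shifted by that delay.  Epochs are windows around each
onset (default -0.4 to 2.0 s), with the ML channel re-signed so the
perturbation-force direction is positive and the AP channel oriented
anterior-positive, then baseline-corrected by the pre-perturbation mean
over -0.35 to -0.2 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, EpochBoundsError, EpochStateError, WindowError
from .io import CopRecording

log = logging.getLogger(__name__)

#: Default epoch window (s relative to perturbation contact).
DEFAULT_T_PRE = -0.4
DEFAULT_T_POST = 2.0
#: Default baseline window (s); closed interval on the sample grid.
DEFAULT_BASELINE = (-0.35, -0.2)


@dataclass(frozen=True)
class OnsetEvent:
    """One perturbation contact: sample index, time, ML force sign."""

    sample_index: int
    time_s: float
    direction: int = 1

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise DomainError(f"direction must be +1 or -1, got {self.direction}")
        if self.sample_index < 0:
            raise DomainError(f"sample_index must be >= 0, got {self.sample_index}")


@dataclass
class PerturbationEpoch:
    """A perturbation-aligned COP window.

    ``rel_time`` contains 0.0 exactly at the onset sample; ``cop_ml`` is
    signed so the perturbation direction is positive, ``cop_ap`` so
    anterior is positive.
    """

    rel_time: np.ndarray
    cop_ml: np.ndarray
    cop_ap: np.ndarray
    fs: float
    onset: OnsetEvent
    baseline_corrected: bool = False
    baseline_window: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def t_pre(self) -> float:
        return float(self.rel_time[0])

    @property
    def t_post(self) -> float:
        return float(self.rel_time[-1])

    def axis(self, name: str) -> np.ndarray:
        if name.lower() == "ml":
            return self.cop_ml
        if name.lower() == "ap":
            return self.cop_ap
        raise DomainError(f"axis must be 'ml' or 'ap', got {name!r}")

    def window_slice(self, t_lo: float, t_hi: float) -> slice:
        """Index slice of the closed time window [t_lo, t_hi] on the grid."""
        if t_lo < self.t_pre - 1e-9 or t_hi > self.t_post + 1e-9:
            raise WindowError(
                f"window [{t_lo}, {t_hi}] s outside epoch "
                f"[{self.t_pre}, {self.t_post}] s"
            )
        i0 = int(np.ceil(round(t_lo * self.fs, 6)))
        i1 = int(np.floor(round(t_hi * self.fs, 6)))
        onset_pos = int(round(-self.t_pre * self.fs))
        return slice(onset_pos + i0, onset_pos + i1 + 1)


def locate_onsets(
    trigger: np.ndarray,
    fs: float,
    threshold: float,
    mechanical_delay_s: float,
    refractory_s: float = 0.5,
) -> list[OnsetEvent]:
    """Find perturbation onsets as rising trigger crossings plus delay.

    A crossing is a sample where the trigger moves from below threshold
    to at-or-above it.  Crossings closer together than ``refractory_s``
    are treated as contact bounce and merged into the first (a warning
    is logged).  Each event time is the crossing time plus the
    mechanical delay of the actuator, rounded to the nearest sample.
    Directions default to +1 here; the caller attaches per-event
    directions from recording metadata.
    """
    trigger = np.asarray(trigger, dtype=float)
    if mechanical_delay_s < 0:
        raise DomainError("mechanical_delay_s must be >= 0")
    if trigger.size and not (trigger.min() <= threshold <= trigger.max()):
        # threshold outside the observed range can never cross: not an
        # error (all-zero triggers are legal) but worth a log line
        log.debug("trigger threshold %s outside data range", threshold)
    above = trigger >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1

    kept: list[int] = []
    gap = int(round(refractory_s * fs))
    for c in crossings:
        if kept and c - kept[-1] < gap:
            log.warning(
                "trigger re-crossing at sample %d within refractory gap of "
                "sample %d; merged",
                c,
                kept[-1],
            )
            continue
        kept.append(int(c))

    delay = int(round(mechanical_delay_s * fs))
    events = []
    for c in kept:
        idx = c + delay
        if idx >= trigger.size:
            log.warning("onset at sample %d falls past recording end; dropped", idx)
            continue
        events.append(OnsetEvent(sample_index=idx, time_s=idx / fs))
    return events


def attach_directions(events: list[OnsetEvent], rec: CopRecording, default: int = 1):
    """Assign per-event ML directions from recording metadata.

    The recording may carry one direction per event or a single constant;
    if absent, ``default`` applies to every event.
    """
    d = rec.perturbation_direction
    if d is None:
        dirs = [default] * len(events)
    elif np.isscalar(d):
        dirs = [int(d)] * len(events)
    else:
        if len(d) != len(events):
            raise DomainError(
                f"{len(d)} directions for {len(events)} events in recording "
                f"{rec.participant_id!r}"
            )
        dirs = [int(x) for x in d]
    return [replace(ev, direction=di) for ev, di in zip(events, dirs)]


def extract_epoch(
    rec: CopRecording,
    onset: OnsetEvent,
    t_pre: float = DEFAULT_T_PRE,
    t_post: float = DEFAULT_T_POST,
) -> PerturbationEpoch:
    """Cut a window around one onset, applying the sign conventions.

    The epoch has ``round((t_post - t_pre) * fs) + 1`` samples with
    t = 0 exactly at the onset sample.  The ML channel is multiplied by
    the onset direction so the perturbation-force direction reads
    positive; the AP channel is anterior-positive as recorded.  Windows
    that overrun the recording raise (such epochs are dropped, not
    truncated: the features need the full response window).
    """
    fs = rec.fs
    i_lo = onset.sample_index + int(round(t_pre * fs))
    i_hi = onset.sample_index + int(round(t_post * fs))
    if i_lo < 0 or i_hi >= rec.n_samples:
        raise EpochBoundsError(
            f"epoch [{t_pre}, {t_post}] s around sample {onset.sample_index} "
            f"exceeds recording of {rec.n_samples} samples"
        )
    sl = slice(i_lo, i_hi + 1)
    rel_time = (np.arange(i_lo, i_hi + 1) - onset.sample_index) / fs
    return PerturbationEpoch(
        rel_time=rel_time,
        cop_ml=onset.direction * rec.cop_ml[sl].copy(),
        cop_ap=rec.cop_ap[sl].copy(),
        fs=fs,
        onset=onset,
        meta={"participant_id": rec.participant_id, "session": rec.session},
    )


def subtract_baseline(
    epoch: PerturbationEpoch,
    window: tuple[float, float] = DEFAULT_BASELINE,
    force: bool = False,
) -> PerturbationEpoch:
    """Subtract the pre-perturbation mean from each axis.

    The baseline is the per-axis mean over the closed window (default
    -0.35 to -0.2 s, 16 samples at 100 Hz).  Correcting an already
    corrected epoch raises unless ``force`` is set (in which case the
    operation is a no-op up to rounding, since the window mean is
    already zero).
    """
    if epoch.baseline_corrected and not force:
        raise EpochStateError("epoch is already baseline-corrected")
    lo, hi = window
    if not (epoch.t_pre - 1e-9 <= lo < hi <= 0):
        raise WindowError(
            f"baseline window [{lo}, {hi}] must lie within [{epoch.t_pre}, 0) s"
        )
    sl = epoch.window_slice(lo, hi)
    if sl.stop <= sl.start:
        raise WindowError(f"baseline window [{lo}, {hi}] contains no samples")
    return replace(
        epoch,
        cop_ml=epoch.cop_ml - epoch.cop_ml[sl].mean(),
        cop_ap=epoch.cop_ap - epoch.cop_ap[sl].mean(),
        baseline_corrected=True,
        baseline_window=(lo, hi),
    )
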