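"""Synthetic perturbation-trial generator with known ground truth.

Real perturbation-evoked COP data for this protocol are not publicly
deposited, so every pipeline stage is exercised against simulated
recordings whose true onset times, directions and response parameters
are known exactly.

The perturbation response is a smooth single-peaked surrogate

    x(t) = d_true * (t / tau) * exp(1 - t / tau)   for t >= 0, else 0,

whose analytic features are closed-form: peak displacement ``d_true``
attained exactly at ``t = tau``, and peak velocity ``d_true * e / tau``
at t -> 0+.  Baseline sway is Gaussian noise shaped by the same 10 Hz
low-pass family the pipeline uses, rescaled to a target standard
deviation.  A lateral (ML) perturbation also evokes a coupled AP
excursion, scaled by ``kappa_ap``.

Default magnitudes (peak 12 mm at 0.15 s, sway noise 1 mm RMS) are
order-of-magnitude choices for tandem-stance balance in healthy young
adults; see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, SpacingError
from .io import CopRecording
from .preprocess import FilterSpec, lowpass_zero_phase

#: Default actuator travel time between electrical trigger and contact (s).
DEFAULT_MECHANICAL_DELAY_S = 0.03
#: Trigger pulse amplitude (arbitrary TTL-like units) and width (s).
TRIGGER_HIGH = 5.0
TRIGGER_WIDTH_S = 0.1


@dataclass(frozen=True)
class EpochSpec:
    """Ground-truth parameters of one simulated perturbation response."""

    d_true: float = 12.0  # mm, peak displacement
    tau: float = 0.15  # s, time of peak
    kappa_ap: float = 0.5  # AP coupling fraction
    noise_sd: float = 1.0  # mm, sway noise SD
    fs: float = 100.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_true < 0:
            raise DomainError("d_true must be >= 0")
        if not 0 < self.tau < 0.4:
            raise DomainError("tau must lie in (0, 0.4) s")
        if not 0 <= self.kappa_ap <= 1:
            raise DomainError("kappa_ap must lie in [0, 1]")
        if self.fs <= 0:
            raise DomainError("fs must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TableSpec:
    """Ground truth for a balanced 2x2 participant table.

    Effects use +/-1/2 coding, so each ``effect_*`` equals the
    corresponding marginal mean difference (post minus pre, device
    group minus sham, difference of the two pre-post differences).
    """

    n_per_group: int = 9
    grand_mean: float = 10.0
    effect_group: float = 0.0
    effect_time: float = 0.0
    effect_interaction: float = 0.0
    sd_between: float = 1.0  # participant random intercept
    sd_within: float = 1.0  # residual
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise DomainError("n_per_group must be >= 2")
        if self.sd_between < 0 or self.sd_within < 0:
            raise DomainError("standard deviations must be >= 0")


@dataclass(frozen=True)
class StudySpec:
    """A full two-group pre/post perturbation study at recording level.

    Each participant contributes one 60-s recording per session with
    three perturbations.  Participant-level peak displacement varies by
    a random intercept (``sd_between``) plus session-to-session jitter
    (``sd_session``); ``wbed_post_delta`` is added to the device group's
    post-test peak only (the training-effect condition).
    """

    n_per_group: int = 9
    d_true: float = 12.0
    tau: float = 0.15
    kappa_ap: float = 0.5
    noise_sd: float = 1.0
    sd_between: float = 2.0
    sd_session: float = 1.0
    wbed_post_delta: float = 0.0
    fs: float = 100.0
    duration_s: float = 60.0
    n_events: int = 3
    seed: int = 0


def response_curve(t: np.ndarray, d_true: float, tau: float) -> np.ndarray:
    """Closed-form perturbation-response surrogate (zero for t < 0)."""
    if tau <= 0:
        raise DomainError(f"tau must be positive, got {tau}")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = d_true * (t[pos] / tau) * np.exp(1.0 - t[pos] / tau)
    return out


def response_rms(d_true: float, tau: float, window=(0.0, 0.4), n_quad: int = 20001):
    """Fine-grid quadrature RMS of the noiseless response over the window."""
    t = np.linspace(window[0], window[1], n_quad)
    x = response_curve(t, d_true, tau)
    return float(np.sqrt(np.trapezoid(x**2, t) / (window[1] - window[0])))


def _shaped_noise(n: int, sd: float, fs: float, rng: np.random.Generator):
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    shaped = lowpass_zero_phase(white, FilterSpec(fs=fs, cutoff_hz=10.0, order=4))
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


def _draw_event_times(
    rng: np.random.Generator,
    duration_s: float,
    n_events: int,
    min_gap_s: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Uniform event times in [lo, hi] with pairwise gaps >= min_gap_s."""
    span = hi - lo - (n_events - 1) * min_gap_s
    if span <= 0:
        raise SpacingError(
            f"cannot place {n_events} events with {min_gap_s}s gaps in "
            f"[{lo}, {hi}] of a {duration_s}s recording"
        )
    u = np.sort(rng.uniform(0.0, span, size=n_events))
    return lo + u + min_gap_s * np.arange(n_events)


def simulate_recording(
    spec: EpochSpec,
    duration_s: float = 60.0,
    n_events: int = 3,
    min_gap_s: float = 5.0,
    mechanical_delay_s: float = DEFAULT_MECHANICAL_DELAY_S,
    rng: np.random.Generator | None = None,
    **meta,
) -> tuple[CopRecording, dict]:
    """One tandem-stance trial: sway noise + perturbation responses + trigger.

    Returns the recording and a truth record listing each event's onset
    sample/time, ML direction, and analytic feature values.  The trigger
    channel carries a rising edge one mechanical delay *before* each
    contact, emulating the electrical valve command.  Deterministic
    given ``spec.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(duration_s * fs))
    t_pre_margin = 0.5 + mechanical_delay_s  # room for baseline + trigger lead
    t_post_margin = 2.5  # room for the full epoch window
    times = _draw_event_times(
        rng, duration_s, n_events, min_gap_s, t_pre_margin, duration_s - t_post_margin
    )
    onset_samples = np.round(times * fs).astype(int)
    directions = rng.choice([-1, 1], size=n_events)

    cop_ml = _shaped_noise(n, spec.noise_sd, fs, rng)
    cop_ap = _shaped_noise(n, spec.noise_sd, fs, rng)
    trigger = np.zeros(n)

    t_rel_full = np.arange(n, dtype=float)
    delay_smp = int(round(mechanical_delay_s * fs))
    width_smp = max(1, int(round(TRIGGER_WIDTH_S * fs)))
    events = []
    for k, (smp, d) in enumerate(zip(onset_samples, directions)):
        rel = (t_rel_full - smp) / fs
        resp = response_curve(rel, spec.d_true, spec.tau)
        cop_ml += d * resp  # plate frame: response along the force direction
        cop_ap += spec.kappa_ap * resp
        trig_smp = smp - delay_smp
        trigger[trig_smp : trig_smp + width_smp] = TRIGGER_HIGH
        events.append(
            {
                "event": k,
                "onset_sample": int(smp),
                "onset_time_s": smp / fs,
                "direction": int(d),
                "d_true": spec.d_true,
                "tau": spec.tau,
                "v_true": spec.d_true * math.e / spec.tau,
                "rms_true": response_rms(spec.d_true, spec.tau),
                "kappa_ap": spec.kappa_ap,
            }
        )

    rec = CopRecording(
        fs=fs,
        cop_ml=cop_ml,
        cop_ap=cop_ap,
        trigger=trigger,
        perturbation_direction=[int(d) for d in directions],
        **meta,
    )
    truth = {
        "mechanical_delay_s": mechanical_delay_s,
        "noise_sd": spec.noise_sd,
        "events": events,
    }
    return rec, truth


def simulate_trial_table(spec: TableSpec) -> tuple[pd.DataFrame, dict]:
    """Balanced 2x2 participant table from the additive mixed model.

    value = grand + eg*cg + et*ct + egt*cg*ct + b_i + eps, with
    cg, ct in {-1/2, +1/2} (device group / post-test positive),
    b_i ~ N(0, sd_between), eps ~ N(0, sd_within).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth_cells = {}
    for g, cg in (("WBED", +0.5), ("Sham", -0.5)):
        for i in range(spec.n_per_group):
            pid = f"{g}{i + 1:02d}"
            b = rng.normal(0.0, spec.sd_between)
            for tlab, ct in (("pre", -0.5), ("post", +0.5)):
                mu = (
                    spec.grand_mean
                    + spec.effect_group * cg
                    + spec.effect_time * ct
                    + spec.effect_interaction * cg * ct
                )
                truth_cells[(g, tlab)] = mu
                rows.append(
                    {
                        "participant": pid,
                        "group": g,
                        "time": tlab,
                        "value": mu + b + rng.normal(0.0, spec.sd_within),
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "cell_means": {f"{g}/{t}": v for (g, t), v in truth_cells.items()},
        "effect_group": spec.effect_group,
        "effect_time": spec.effect_time,
        "effect_interaction": spec.effect_interaction,
        "sd_between": spec.sd_between,
        "sd_within": spec.sd_within,
    }
    return table, truth


def simulate_study(spec: StudySpec) -> tuple[list[CopRecording], dict]:
    """Participant-level recordings for a full pre/post two-group study.

    Returns one recording per (participant, session) plus a truth record
    with each participant's session-specific d_true.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    recordings = []
    truth: dict = {"participants": [], "wbed_post_delta": spec.wbed_post_delta}
    for g in ("WBED", "Sham"):
        for i in range(spec.n_per_group):
            pid = f"{g}{i + 1:02d}"
            base = spec.d_true + rng.normal(0.0, spec.sd_between)
            per_session = {}
            for session in ("pre", "post"):
                d = base + rng.normal(0.0, spec.sd_session)
                if g == "WBED" and session == "post":
                    d += spec.wbed_post_delta
                d = max(d, 0.0)  # peak displacement cannot be negative
                per_session[session] = d
                rec, rec_truth = simulate_recording(
                    EpochSpec(
                        d_true=d,
                        tau=spec.tau,
                        kappa_ap=spec.kappa_ap,
                        noise_sd=spec.noise_sd,
                        fs=spec.fs,
                    ),
                    duration_s=spec.duration_s,
                    n_events=spec.n_events,
                    rng=rng,
                    participant_id=pid,
                    group=g,
                    session=session,
                )
                rec.meta["truth"] = rec_truth
                recordings.append(rec)
            truth["participants"].append(
                {"participant": pid, "group": g, "d_true": per_session}
            )
    return recordings, truth
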