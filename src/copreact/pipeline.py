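"""End-to-end orchestration: recordings -> features -> statistics.

``run_extract`` chains the processing stages in acquisition order -
low-pass filter, onset location, epoch extraction, baseline correction,
feature computation, per-participant aggregation - and applies the QC
policy: a recording with missing samples or an unexpected perturbation
count is excluded (never imputed), an epoch that overruns the recording
is dropped, and a participant/session with no surviving epochs is
excluded from the feature table.

``run_analyze`` runs, per feature, the split-plot ANOVA with partial
eta-squared, the four simple-effect contrasts under Shaffer's
correction, and the post-hoc power report.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import pandas as pd

from . import epochs as ep
from . import features as ft
from . import stats as st
from .config import PipelineConfig
from .errors import CopReactError, EpochBoundsError, QCError
from .io import FEATURE_VALUE_COLUMNS, CopRecording, validate_features_table
from .preprocess import FilterSpec, filter_recording

log = logging.getLogger(__name__)


def extract_recording_features(
    rec: CopRecording, config: PipelineConfig
) -> list[ft.CopFeatures]:
    """Per-epoch features of one recording, after filtering and QC."""
    rec.qc_check()
    spec = FilterSpec(
        fs=rec.fs, cutoff_hz=config.filter_cutoff_hz, order=config.filter_order
    )
    filtered = filter_recording(rec, spec)

    events = ep.locate_onsets(
        filtered.trigger,
        filtered.fs,
        threshold=config.trigger_threshold,
        mechanical_delay_s=config.require_delay(),
        refractory_s=config.trigger_refractory_s,
    )
    expected = config.expected_events_per_recording
    if expected and len(events) != expected:
        raise QCError(
            f"recording {rec.participant_id!r}/{rec.session!r}: found "
            f"{len(events)} perturbation events, expected {expected}; excluded"
        )
    events = ep.attach_directions(events, rec, default=config.default_direction)

    out = []
    for event in events:
        try:
            epoch = ep.extract_epoch(
                filtered, event, t_pre=config.epoch_t_pre, t_post=config.epoch_t_post
            )
        except EpochBoundsError as exc:
            log.warning("dropping epoch at %.2f s: %s", event.time_s, exc)
            continue
        epoch = ep.subtract_baseline(epoch, window=config.baseline_window)
        out.append(
            ft.compute_features(
                epoch,
                window=config.features_window,
                velocity_mode=config.features_velocity_mode,
            )
        )
    return out


def run_extract(
    recordings: list[CopRecording], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Feature table (one row per participant/session) from recordings.

    Per-recording failures are logged and skip that recording; the run
    fails only if nothing survives.
    """
    if config is None:
        config = PipelineConfig()
    config.echo()
    config.require_delay()  # config problems abort; they are not per-recording QC
    if not recordings:
        raise QCError("no input recordings")

    per_key: dict[tuple, list[ft.CopFeatures]] = defaultdict(list)
    groups: dict[tuple, str] = {}
    n_failed = 0
    for rec in recordings:
        key = (rec.participant_id, rec.session)
        try:
            per_key[key].extend(extract_recording_features(rec, config))
            groups[key] = rec.group
        except CopReactError as exc:
            n_failed += 1
            log.warning("recording %s excluded: %s", key, exc)
    if n_failed == len(recordings):
        raise QCError("all recordings failed extraction")

    rows = []
    for key, feats in per_key.items():
        if not feats:
            log.warning("participant/session %s: no valid epochs; excluded", key)
            continue
        agg = ft.aggregate_trials(feats)
        rows.append(
            {
                "participant": key[0],
                "group": groups[key],
                "session": key[1],
                **agg.as_dict(),
            }
        )
    table = pd.DataFrame(rows).sort_values(["group", "participant", "session"])
    return validate_features_table(table.reset_index(drop=True))


def feature_trial_table(features: pd.DataFrame, feature: str) -> pd.DataFrame:
    """Long (participant, group, time, value) table for one feature column."""
    if feature not in features.columns:
        raise QCError(f"feature column {feature!r} not in table")
    out = features[["participant", "group", "session", feature]].rename(
        columns={"session": "time", feature: "value"}
    )
    return out


def run_analyze(
    features: pd.DataFrame,
    alpha: float = 0.05,
    rho: float = 0.5,
    feature_columns: list[str] | None = None,
) -> dict:
    """ANOVA + Shaffer post-hoc + power report for every feature column."""
    features = validate_features_table(features)
    cols = feature_columns or FEATURE_VALUE_COLUMNS
    results: dict = {"alpha": alpha, "features": {}}
    for col in cols:
        table = feature_trial_table(features, col)
        anova = st.splitplot_anova(table)
        simple = st.simple_effects(table)
        posthoc = st.shaffer_adjust(
            [s.p for s in simple],
            labels=[s.label for s in simple],
            alpha=alpha,
            constraint="two_by_two",
        )
        results["features"][col] = {
            "anova": anova.to_dict(),
            "simple_effects": [
                {"label": s.label, "t": s.statistic, "df": s.df, "p": s.p}
                for s in simple
            ],
            "posthoc": posthoc.to_dict(),
            "achieved_power": st.achieved_power(anova, alpha=alpha, rho=rho),
        }
    return results
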