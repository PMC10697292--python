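"""Reading and writing force-plate recordings and feature tables.

A recording is a delimited text file (CSV/TSV) holding either pre-computed
center-of-pressure channels (``cop_ml``, ``cop_ap``, in mm or m) or raw
force/moment channels (``Fz`` [N], ``Mx``, ``My`` [N m]) plus a TTL-like
trigger channel.  A :class:`RecordingSchema` maps file columns onto these
roles; the internal unit for COP is always mm.

Feature tables are wide CSVs with one row per (participant, session) and
the eight reactive-balance statistics as columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import QCError, SamplingError, SchemaError, UnreliableCopError

GROUPS = ("WBED", "Sham")
SESSIONS = ("pre", "post")

#: Canonical column order of the features CSV.
FEATURE_COLUMNS = [
    "participant",
    "group",
    "session",
    "d_ml",
    "t_ml",
    "v_ml",
    "rms_ml",
    "d_ap",
    "t_ap",
    "v_ap",
    "rms_ap",
]

FEATURE_VALUE_COLUMNS = FEATURE_COLUMNS[3:]


@dataclass
class RecordingSchema:
    """Column mapping and unit declaration for a recording file.

    Either (``cop_ml``, ``cop_ap``) or (``fz``, ``mx``, ``my``) must be
    named.  ``fs`` may be given directly or inferred from a ``time``
    column (which must be uniform to 1e-6 relative).
    """

    trigger: str = "trigger"
    cop_ml: Optional[str] = None
    cop_ap: Optional[str] = None
    fz: Optional[str] = None
    mx: Optional[str] = None
    my: Optional[str] = None
    fx: Optional[str] = None  # shear channels, only needed for z_offset
    fy: Optional[str] = None
    z_offset_m: float = 0.0  # sensor origin depth below plate surface
    time: Optional[str] = None
    fs: Optional[float] = None
    cop_unit: str = "mm"  # "mm" or "m"
    # plate axes -> body axes; the plate's x/y convention is instrument
    # specific, so the mapping is configuration, defaulting x->ML, y->AP
    x_axis: str = "ml"
    y_axis: str = "ap"
    fz_floor: float = 20.0  # N; below this COP is unreliable
    delimiter: str = ","

    def __post_init__(self) -> None:
        has_cop = self.cop_ml is not None and self.cop_ap is not None
        has_force = all(c is not None for c in (self.fz, self.mx, self.my))
        if not (has_cop or has_force):
            raise SchemaError(
                "schema must name either (cop_ml, cop_ap) or (fz, mx, my) columns"
            )
        if self.cop_unit not in ("mm", "m"):
            raise SchemaError(f"cop_unit must be 'mm' or 'm', got {self.cop_unit!r}")
        if {self.x_axis, self.y_axis} != {"ml", "ap"}:
            raise SchemaError("x_axis/y_axis must map onto {'ml', 'ap'}")
        if self.fs is None and self.time is None:
            raise SchemaError("schema must give fs or name a time column")

    @property
    def uses_forces(self) -> bool:
        return self.cop_ml is None


@dataclass
class CopRecording:
    """One stance trial: COP time series plus the perturbation trigger.

    ``perturbation_direction`` is the sign (+1/-1) of the perturbation
    force along the ML axis, either one value per event or a single
    constant; ``None`` means unknown (a configured default applies).
    """

    fs: float
    cop_ml: np.ndarray
    cop_ap: np.ndarray
    trigger: np.ndarray
    participant_id: str = ""
    group: Optional[str] = None
    session: Optional[str] = None
    perturbation_direction: Optional[Sequence[int]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cop_ml = np.asarray(self.cop_ml, dtype=float)
        self.cop_ap = np.asarray(self.cop_ap, dtype=float)
        self.trigger = np.asarray(self.trigger, dtype=float)
        if self.fs <= 0:
            raise SamplingError(f"fs must be positive, got {self.fs}")
        n = len(self.cop_ml)
        if len(self.cop_ap) != n or len(self.trigger) != n:
            raise SchemaError(
                "channel lengths differ: "
                f"ml={len(self.cop_ml)} ap={len(self.cop_ap)} trig={len(self.trigger)}"
            )
        if self.group is not None and self.group not in GROUPS:
            raise SchemaError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.session is not None and self.session not in SESSIONS:
            raise SchemaError(f"session must be one of {SESSIONS}, got {self.session!r}")

    @property
    def n_samples(self) -> int:
        return len(self.cop_ml)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def qc_check(self) -> None:
        """Reject recordings with missing COP samples (exclusion, not imputation)."""
        for name, ch in (("cop_ml", self.cop_ml), ("cop_ap", self.cop_ap)):
            bad = np.flatnonzero(~np.isfinite(ch))
            if bad.size:
                raise QCError(
                    f"{name} contains {bad.size} non-finite samples "
                    f"(first at index {bad[0]}); recording excluded"
                )


def compute_cop_from_forces(
    fz: np.ndarray,
    mx: np.ndarray,
    my: np.ndarray,
    fz_floor: float = 20.0,
    fx: Optional[np.ndarray] = None,
    fy: Optional[np.ndarray] = None,
    z_offset_m: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert plate force/moment channels to COP coordinates in mm.

    Standard moment-over-vertical-force relation for a plate with origin
    at the surface center: ``cop_x = -My / Fz``, ``cop_y = Mx / Fz``
    (inputs N and N m, output mm).  When the sensor origin lies
    ``z_offset_m`` below the plate surface and shear channels are
    available, the thickness correction ``-Fx*dz`` / ``-Fy*dz`` is added
    to the respective moment.  Samples where ``|Fz|`` drops below
    ``fz_floor`` make the quotient unreliable and raise instead.
    """
    fz = np.asarray(fz, dtype=float)
    mx = np.asarray(mx, dtype=float)
    my = np.asarray(my, dtype=float)
    low = np.flatnonzero(np.abs(fz) < fz_floor)
    if low.size:
        raise UnreliableCopError(
            f"|Fz| < {fz_floor} N at {low.size} samples (first at index {low[0]})",
            sample_index=int(low[0]),
        )
    if z_offset_m != 0.0:
        if fx is None or fy is None:
            raise SchemaError("z_offset correction needs Fx and Fy channels")
        mx = mx - np.asarray(fy, float) * z_offset_m
        my = my + np.asarray(fx, float) * z_offset_m
    cop_x = -my / fz * 1000.0
    cop_y = mx / fz * 1000.0
    return cop_x, cop_y


def _infer_fs(time: np.ndarray, rtol: float = 1e-6) -> float:
    dt = np.diff(time)
    if dt.size == 0:
        raise SamplingError("cannot infer fs from a single-sample time column")
    dt0 = float(np.median(dt))
    if dt0 <= 0:
        raise SamplingError("time column is not strictly increasing")
    if np.any(np.abs(dt - dt0) > rtol * dt0):
        raise SamplingError(
            "non-uniform time steps beyond 1e-6 relative tolerance"
        )
    return 1.0 / dt0


def read_recording(path, schema: RecordingSchema, **meta) -> CopRecording:
    """Read a delimited recording file into a :class:`CopRecording`.

    Row order is preserved; units are normalized to mm.  NaNs in the COP
    channels raise :class:`~copreact.errors.QCError` (the recording is
    excluded rather than imputed).  Extra keyword arguments become
    recording metadata (participant_id, group, session, ...).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=schema.delimiter)

    def col(name: str) -> np.ndarray:
        if name not in df.columns:
            raise SchemaError(f"required column {name!r} missing from {path.name}")
        return df[name].to_numpy(dtype=float)

    trigger = col(schema.trigger)
    if schema.fs is not None:
        fs = float(schema.fs)
    else:
        fs = _infer_fs(col(schema.time))

    if schema.uses_forces:
        cop_x, cop_y = compute_cop_from_forces(
            col(schema.fz),
            col(schema.mx),
            col(schema.my),
            schema.fz_floor,
            fx=col(schema.fx) if schema.fx else None,
            fy=col(schema.fy) if schema.fy else None,
            z_offset_m=schema.z_offset_m,
        )
        cop_ml, cop_ap = (cop_x, cop_y) if schema.x_axis == "ml" else (cop_y, cop_x)
    else:
        cop_ml = col(schema.cop_ml)
        cop_ap = col(schema.cop_ap)
        if schema.cop_unit == "m":
            cop_ml = cop_ml * 1000.0
            cop_ap = cop_ap * 1000.0

    rec = CopRecording(fs=fs, cop_ml=cop_ml, cop_ap=cop_ap, trigger=trigger, **meta)
    rec.qc_check()
    return rec


def write_recording(rec: CopRecording, path) -> None:
    """Write a recording as CSV (time, cop_ml, cop_ap, trigger), readable back."""
    t = np.arange(rec.n_samples) / rec.fs
    pd.DataFrame(
        {"time": t, "cop_ml": rec.cop_ml, "cop_ap": rec.cop_ap, "trigger": rec.trigger}
    ).to_csv(path, index=False, float_format="%.12g")


def validate_features_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the wide features table schema and key uniqueness."""
    if table.empty:
        raise SchemaError("features table is empty")
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"features table missing columns: {missing}")
    dup = table.duplicated(subset=["participant", "session"])
    if dup.any():
        keys = table.loc[dup, ["participant", "session"]].to_records(index=False)
        raise SchemaError(f"duplicated (participant, session) keys: {list(keys)}")
    bad_group = set(table["group"]) - set(GROUPS)
    if bad_group:
        raise SchemaError(f"unknown group labels: {sorted(bad_group)}")
    bad_sess = set(table["session"]) - set(SESSIONS)
    if bad_sess:
        raise SchemaError(f"unknown session labels: {sorted(bad_sess)}")
    return table[FEATURE_COLUMNS]


def write_features(table: pd.DataFrame, path) -> None:
    """Write a validated features table with deterministic column order."""
    validate_features_table(table).to_csv(path, index=False, float_format="%.12g")


def read_features(path) -> pd.DataFrame:
    """Read a features CSV written by :func:`write_features`."""
    df = pd.read_csv(path, dtype={"participant": str})
    df = validate_features_table(df)
    return df.astype({c: float for c in FEATURE_VALUE_COLUMNS})
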