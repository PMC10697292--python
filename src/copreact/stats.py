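"""Split-plot factorial ANOVA, Shaffer post-hoc tests, and F-test power.

The study design is a split-plot (mixed) factorial: one between-subject
factor (group: device vs sham) crossed with one within-subject factor
(time: pre vs post), subjects nested in groups.  For a balanced table
the sums of squares decompose exactly as

    SS_total = SS_group + SS_subj(group) + SS_time + SS_gxt + SS_residual

with the group effect tested against the subject-within-group stratum
and the within-subject effects (time, group x time) against the
residual stratum.  Effect size is partial eta-squared,
``SS_effect / (SS_effect + SS_error_term)``, classified with the
conventional cutoffs 0.01 / 0.06 / 0.14.

Post-hoc simple effects (time within each group, group at each time)
are corrected with Shaffer's modified sequentially rejective Bonferroni
procedure: at step ``i`` the divisor is the largest number of null
hypotheses that can simultaneously be true once ``i - 1`` have been
rejected, which the logical structure of the four cell-mean equalities
caps at (4, 2, 2, 1) - strictly more powerful than Holm's
(4, 3, 2, 1) from the second step on.

Power utilities use the noncentral F distribution with the conventional
repeated-measures noncentrality mapping (see :func:`design_ncp`); for a
two-level within factor and the additive random-intercept model this
mapping is exact, not an approximation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    BalanceError,
    ConstraintError,
    DegenerateDataError,
    DomainError,
)

EFFECTS = ("group", "time", "group:time")

#: partial eta-squared class boundaries (exclusive lower bounds)
EFFECT_SIZE_CUTOFFS = (("large", 0.14), ("moderate", 0.06), ("small", 0.01))


def classify_effect_size(partial_eta_sq: float) -> str:
    """Classify partial eta-squared: >0.14 large, >0.06 moderate, >0.01 small."""
    if not 0.0 <= partial_eta_sq <= 1.0:
        raise DomainError(f"partial eta-squared must be in [0, 1], got {partial_eta_sq}")
    for label, cut in EFFECT_SIZE_CUTOFFS:
        if partial_eta_sq > cut:
            return label
    return "negligible"


# --------------------------------------------------------------------------
# trial table validation
# --------------------------------------------------------------------------

def validate_trial_table(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Check a long (participant, group, time, value) table is a balanced 2x2.

    Every participant must appear in exactly one group with exactly one
    row per time level, groups must be equally sized, and the value
    column must be finite.
    """
    required = {"participant", "group", "time", value}
    missing = required - set(table.columns)
    if missing:
        raise BalanceError(f"trial table missing columns: {sorted(missing)}")
    if table[value].isna().any() or not np.isfinite(table[value]).all():
        raise BalanceError("trial table contains missing/non-finite values")

    groups = sorted(table["group"].unique())
    times = sorted(table["time"].unique())
    if len(groups) != 2 or len(times) != 2:
        raise BalanceError(
            f"expected 2 groups x 2 times, got groups={groups} times={times}"
        )
    per_subject = table.groupby("participant")
    bad = [p for p, sub in per_subject if sub["group"].nunique() != 1]
    if bad:
        raise BalanceError(f"participants in more than one group: {bad}")
    bad = [
        p
        for p, sub in per_subject
        if sorted(sub["time"]) != times or len(sub) != len(times)
    ]
    if bad:
        raise BalanceError(f"participants without exactly one row per time: {bad}")
    sizes = table.drop_duplicates("participant").groupby("group").size()
    if sizes.nunique() != 1:
        raise BalanceError(f"unequal group sizes: {sizes.to_dict()}")
    if sizes.iloc[0] < 2:
        raise BalanceError("need at least 2 participants per group")
    return table


def _table_to_array(table: pd.DataFrame, value: str = "value"):
    """Balanced long table -> (a, n, m) array plus level labels.

    Time levels are ordered chronologically when they are the standard
    pre/post labels (alphabetical order would reverse them).
    """
    groups = sorted(table["group"].unique())
    times = sorted(table["time"].unique())
    if set(times) == {"pre", "post"}:
        times = ["pre", "post"]
    wide = table.pivot_table(
        index=["group", "participant"], columns="time", values=value, sort=True
    )
    a, m = len(groups), len(times)
    n = wide.groupby(level="group").size().iloc[0]
    y = np.empty((a, n, m))
    for gi, g in enumerate(groups):
        y[gi] = wide.loc[g][times].to_numpy()
    return y, groups, times


# --------------------------------------------------------------------------
# split-plot ANOVA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectResult:
    """One tested effect: SS, df, MS, F, p, partial eta-squared, class."""

    ss: float
    df: int
    ms: float
    F: float
    p: float
    partial_eta_sq: float
    size_class: str


@dataclass
class AnovaResult:
    """Split-plot ANOVA table: tested effects plus the two error strata."""

    effects: dict[str, EffectResult]
    ss_subjects_within_group: float
    df_subjects_within_group: int
    ss_residual: float
    df_residual: int
    ss_total: float
    n_per_group: int
    groups: list[str] = field(default_factory=list)
    times: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            name: {
                "SS": e.ss,
                "df": e.df,
                "MS": e.ms,
                "F": e.F,
                "p": e.p,
                "partial_eta_sq": e.partial_eta_sq,
                "size_class": e.size_class,
            }
            for name, e in self.effects.items()
        }
        out["error_between"] = {
            "SS": self.ss_subjects_within_group,
            "df": self.df_subjects_within_group,
        }
        out["error_within"] = {"SS": self.ss_residual, "df": self.df_residual}
        return out


def splitplot_anova(table: pd.DataFrame, value: str = "value") -> AnovaResult:
    """Balanced split-plot (between x within) ANOVA with partial eta-squared.

    The group effect is tested against subjects-within-groups; time and
    the interaction against the within-subject residual.  All-constant
    data (both error strata zero) is degenerate and raises.
    """
    validate_trial_table(table, value)
    y, groups, times = _table_to_array(table, value)
    a, n, m = y.shape
    N = a * n

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = y.mean(axis=2)  # (a, n)
    group_means = y.mean(axis=(1, 2))  # (a,)
    time_means = y.mean(axis=(0, 1))  # (m,)
    cell_means = y.mean(axis=1)  # (a, m)

    ss_between = float(m * ((subj_means - grand) ** 2).sum())
    ss_group = float(n * m * ((group_means - grand) ** 2).sum())
    ss_subj = ss_between - ss_group
    ss_time = float(N * ((time_means - grand) ** 2).sum())
    ss_cells = float(n * ((cell_means - grand) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_time
    ss_resid = ss_total - ss_between - ss_time - ss_inter

    df_group, df_subj = a - 1, N - a
    df_time, df_inter = m - 1, (a - 1) * (m - 1)
    df_resid = (N - a) * (m - 1)

    ms_subj = ss_subj / df_subj
    ms_resid = ss_resid / df_resid
    if ms_subj <= 0 and ms_resid <= 0:
        raise DegenerateDataError("all values identical: zero error variance")

    def effect(ss: float, df: int, ms_err: float, df_err: int) -> EffectResult:
        ss = max(ss, 0.0)  # guard tiny negative rounding
        ms = ss / df
        if ms_err <= 0:
            raise DegenerateDataError("zero error variance for an effect test")
        F = ms / ms_err
        p = float(sps.f.sf(F, df, df_err))
        pes = ss / (ss + ms_err * df_err) if (ss + ms_err * df_err) > 0 else 0.0
        return EffectResult(ss, df, ms, F, p, pes, classify_effect_size(pes))

    return AnovaResult(
        effects={
            "group": effect(ss_group, df_group, ms_subj, df_subj),
            "time": effect(ss_time, df_time, ms_resid, df_resid),
            "group:time": effect(ss_inter, df_inter, ms_resid, df_resid),
        },
        ss_subjects_within_group=ss_subj,
        df_subjects_within_group=df_subj,
        ss_residual=ss_resid,
        df_residual=df_resid,
        ss_total=ss_total,
        n_per_group=n,
        groups=list(groups),
        times=list(times),
    )


# --------------------------------------------------------------------------
# simple effects
# --------------------------------------------------------------------------

def _paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, int, float]:
    d = np.asarray(post, float) - np.asarray(pre, float)
    n = d.size
    if n < 2:
        raise DegenerateDataError("paired contrast needs >= 2 participants")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        raise DegenerateDataError("zero variance with nonzero mean difference")
    t = d.mean() / (sd / np.sqrt(n))
    return float(t), n - 1, float(2 * sps.t.sf(abs(t), n - 1))


def _two_sample_t(
    x: np.ndarray, y: np.ndarray, welch: bool = False
) -> tuple[float, float, float]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError("two-sample contrast needs >= 2 per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, x.size + y.size - 2, 1.0
        raise DegenerateDataError("zero variance with unequal means")
    if welch:
        se2x, se2y = vx / x.size, vy / y.size
        t = (x.mean() - y.mean()) / np.sqrt(se2x + se2y)
        df = (se2x + se2y) ** 2 / (
            se2x**2 / (x.size - 1) + se2y**2 / (y.size - 1)
        )
    else:
        df = x.size + y.size - 2
        sp2 = ((x.size - 1) * vx + (y.size - 1) * vy) / df
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / x.size + 1 / y.size))
    return float(t), float(df), float(2 * sps.t.sf(abs(t), df))


@dataclass(frozen=True)
class SimpleEffect:
    label: str
    statistic: float
    df: float
    p: float


def simple_effects(
    table: pd.DataFrame, value: str = "value", welch: bool = False
) -> list[SimpleEffect]:
    """The four 2x2 simple-effect contrasts with two-sided p-values.

    Time within each group is a paired t-test; group at each time is a
    two-sample t-test (pooled variance by default, the design being
    balanced; Welch optional).
    """
    validate_trial_table(table, value)
    y, groups, times = _table_to_array(table, value)
    out = []
    for gi, g in enumerate(groups):
        # statistic is (second time level) minus (first), i.e. post - pre
        t, df, p = _paired_t(y[gi, :, 0], y[gi, :, 1])
        out.append(SimpleEffect(f"{times[1]} vs {times[0]} within {g}", t, df, p))
    for ti, tlab in enumerate(times):
        t, df, p = _two_sample_t(y[0, :, ti], y[1, :, ti], welch=welch)
        out.append(SimpleEffect(f"{groups[0]} vs {groups[1]} at {tlab}", t, df, p))
    return out


# --------------------------------------------------------------------------
# Shaffer's sequentially rejective procedure
# --------------------------------------------------------------------------

def two_by_two_cell_constraint(subset: frozenset) -> bool:
    """Which of the four cell-mean equalities can hold simultaneously.

    Hypotheses 0..3 are equalities among four cell means arranged as
    (group1-pre, group1-post, group2-pre, group2-post):
    0: g1 pre = g1 post, 1: g2 pre = g2 post,
    2: g1 pre = g2 pre,  3: g1 post = g2 post.
    Any three of them imply the fourth, so exactly-three is impossible;
    the attainable numbers of simultaneously true nulls are {0, 1, 2, 4}.
    """
    edges = {0: (0, 1), 1: (2, 3), 2: (0, 2), 3: (1, 3)}
    # a subset is consistent iff some assignment of 4 cell means makes
    # exactly these equalities hold: check via union-find closure that no
    # excluded equality is implied
    parent = list(range(4))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for h in subset:
        a, b = edges[h]
        parent[find(a)] = find(b)
    for h in set(edges) - set(subset):
        a, b = edges[h]
        if find(a) == find(b):
            return False
    return True


def _true_set_cardinalities(
    m: int, constraint: Optional[Callable[[frozenset], bool]]
) -> set[int]:
    if constraint is None:
        return set(range(m + 1))
    if m > 20:
        raise ConstraintError(f"cannot enumerate constraint over {m} hypotheses")
    cards = set()
    for r in range(m + 1):
        for s in itertools.combinations(range(m), r):
            if constraint(frozenset(s)):
                cards.add(r)
                break
    if not cards:
        raise ConstraintError("constraint admits no truth assignment at all")
    return cards


@dataclass(frozen=True)
class PosthocHypothesis:
    label: str
    raw_p: float
    shaffer_t: int
    shaffer_threshold: float
    rejected: bool
    adjusted_p: float


@dataclass
class PosthocResult:
    hypotheses: list[PosthocHypothesis]  # sorted by raw p ascending
    alpha: float
    t_sequence: list[int]

    @property
    def rejected_labels(self) -> list[str]:
        return [h.label for h in self.hypotheses if h.rejected]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "t_sequence": self.t_sequence,
            "hypotheses": [
                {
                    "label": h.label,
                    "p": h.raw_p,
                    "threshold": h.shaffer_threshold,
                    "rejected": h.rejected,
                    "adjusted_p": h.adjusted_p,
                }
                for h in self.hypotheses
            ],
        }


def shaffer_adjust(
    p_values: Sequence[float],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    constraint: Optional[Callable[[frozenset], bool] | str] = "two_by_two",
) -> PosthocResult:
    """Shaffer's modified sequentially rejective Bonferroni procedure.

    P-values are sorted ascending; the i-th is compared with
    ``alpha / t_i`` where ``t_i`` is the maximum number of hypotheses
    that can be simultaneously true given that i-1 have already been
    rejected.  With no logical constraints (``constraint=None``) the
    divisors are (m, m-1, ..., 1) and the procedure is exactly Holm's;
    the 2x2 simple-effect family yields (4, 2, 2, 1).  Rejection stops
    at the first failure.  Adjusted p-values follow the running-max
    convention, ``max_j<=i (t_j * p_(j))`` capped at 1, so that
    "adjusted p < alpha" reproduces the sequential decisions.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    if labels is None:
        labels = [f"H{i + 1}" for i in range(m)]
    if len(labels) != m:
        raise DomainError("labels and p_values lengths differ")
    if isinstance(constraint, str):
        if constraint == "two_by_two":
            if m != 4:
                raise ConstraintError("two_by_two constraint needs 4 hypotheses")
            constraint_fn = two_by_two_cell_constraint
        elif constraint == "none":
            constraint_fn = None
        else:
            raise ConstraintError(f"unknown constraint preset {constraint!r}")
    else:
        constraint_fn = constraint

    cards = _true_set_cardinalities(m, constraint_fn)
    order = np.argsort(p, kind="stable")
    t_seq = []
    for i in range(1, m + 1):
        feasible = [c for c in cards if c <= m - i + 1]
        t_seq.append(max(feasible) if feasible and max(feasible) >= 1 else 1)

    hyps: list[PosthocHypothesis] = []
    still_rejecting = True
    running_adj = 0.0
    for i, idx in enumerate(order):
        t_i = t_seq[i]
        thr = alpha / t_i
        running_adj = max(running_adj, min(1.0, t_i * p[idx]))
        rejected = bool(still_rejecting and p[idx] <= thr)
        if not rejected:
            still_rejecting = False
        hyps.append(
            PosthocHypothesis(
                label=str(labels[idx]),
                raw_p=float(p[idx]),
                shaffer_t=t_i,
                shaffer_threshold=thr,
                rejected=rejected,
                adjusted_p=running_adj,
            )
        )
    return PosthocResult(hypotheses=hyps, alpha=alpha, t_sequence=t_seq)


# --------------------------------------------------------------------------
# power
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Design and targets for an a-priori sample-size computation.

    ``effect_size_f`` is Cohen's f (sigma_effect / sigma_total);
    ``rho`` is the correlation between the repeated measures.
    """

    alpha: float = 0.05
    effect_size_f: float = 0.40
    target_power: float = 0.80
    design: str = "within"  # between | within | interaction
    n_groups: int = 2
    n_measures: int = 2
    rho: float = 0.5
    n_cap: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DomainError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.effect_size_f < 0:
            raise DomainError("effect size f must be >= 0")
        if not 0 < self.target_power < 1:
            raise DomainError("target power must be in (0, 1)")
        if not -1 < self.rho < 1:
            raise DomainError("rho must be in (-1, 1)")
        if self.design not in ("between", "within", "interaction"):
            raise DomainError(f"unknown design {self.design!r}")


def f_test_power(df1: int, df2: int, ncp: float, alpha: float = 0.05) -> float:
    """Power of an F test: P(noncentral F > central critical value)."""
    if df1 < 1 or df2 < 1:
        raise DomainError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if ncp < 0:
        raise DomainError("noncentrality must be >= 0")
    crit = sps.f.isf(alpha, df1, df2)
    if ncp == 0:
        return float(alpha)
    return float(sps.ncf.sf(crit, df1, df2, ncp))


def design_ncp(N: int, spec: PowerSpec) -> tuple[int, int, float]:
    """(df1, df2, ncp) for one effect of the balanced split-plot design.

    Conventional repeated-measures mapping with m measures and
    correlation rho:

        between:              ncp = N * m * f^2 / (1 + (m - 1) * rho)
        within / interaction: ncp = N * m * f^2 / (1 - rho)

    For m = 2 under the additive random-intercept model these are the
    exact noncentralities of the split-plot F statistics.
    """
    a, m, f2 = spec.n_groups, spec.n_measures, spec.effect_size_f**2
    if spec.design == "between":
        return a - 1, N - a, N * m * f2 / (1 + (m - 1) * spec.rho)
    df2 = (N - a) * (m - 1)
    ncp = N * m * f2 / (1 - spec.rho)
    df1 = m - 1 if spec.design == "within" else (a - 1) * (m - 1)
    return df1, df2, ncp


def required_sample_size(spec: PowerSpec) -> dict:
    """Smallest balanced total N reaching the target power.

    Scans N in steps of the group count (balanced groups) from the
    minimal admissible design upward; returns the N, the achieved power
    there, and the (df1, df2, ncp) mapping used.
    """
    a = spec.n_groups
    N = max(2 * a, a + 2)  # >= 2 per group and df2 >= 1
    N += (-N) % a  # balanced
    while N <= spec.n_cap:
        df1, df2, ncp = design_ncp(N, spec)
        power = f_test_power(df1, df2, ncp, spec.alpha)
        if power >= spec.target_power:
            return {
                "N": N,
                "power": power,
                "df1": df1,
                "df2": df2,
                "ncp": ncp,
                "design": spec.design,
                "rho": spec.rho,
            }
        N += a
    raise DomainError(f"target power not reachable below N cap {spec.n_cap}")


def achieved_power(
    anova: AnovaResult,
    n_per_group: Optional[int] = None,
    alpha: float = 0.05,
    rho: float = 0.5,
) -> dict[str, float]:
    """Post-hoc power of each ANOVA effect from its partial eta-squared.

    Converts eta_p^2 to f^2 = eta_p^2 / (1 - eta_p^2) and applies the
    design noncentrality mapping at the realized sample size.
    """
    n = n_per_group if n_per_group is not None else anova.n_per_group
    out = {}
    for name, eff in anova.effects.items():
        if eff.partial_eta_sq >= 1.0:
            raise DegenerateDataError(f"partial eta-squared = 1 for {name}")
        f = np.sqrt(eff.partial_eta_sq / (1.0 - eff.partial_eta_sq))
        design = {"group": "between", "time": "within", "group:time": "interaction"}[
            name
        ]
        pspec = PowerSpec(
            alpha=alpha,
            effect_size_f=float(f),
            target_power=0.8,  # unused by design_ncp
            design=design,
            rho=rho,
        )
        df1, df2, ncp = design_ncp(2 * n, pspec)
        out[name] = f_test_power(df1, df2, ncp, alpha)
    return out
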