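import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from copreact.errors import BalanceError, DegenerateDataError, DomainError
from copreact.stats import (
    classify_effect_size,
    simple_effects,
    splitplot_anova,
)
from copreact.synthetic import TableSpec, simulate_trial_table


def glm_oracle(table: pd.DataFrame) -> dict:
    """Independent split-plot ANOVA via explicit design-matrix projections.

    Sums of squares are residual-sum differences of nested least-squares
    fits (intercept -> +group -> +subject dummies -> +time -> +group:time);
    F ratios use the split-plot error strata.
    """
    df = table.sort_values(["participant", "time"]).reset_index(drop=True)
    y = df["value"].to_numpy()
    n = len(y)
    subjects = pd.get_dummies(df["participant"]).to_numpy(float)
    group = (df["group"] == sorted(df["group"].unique())[0]).to_numpy(float)
    time = (df["time"] == sorted(df["time"].unique())[0]).to_numpy(float)
    inter = group * time

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    one = np.ones((n, 1))
    rss0 = rss(one)
    rss_g = rss(np.column_stack([one, group]))
    rss_s = rss(subjects)
    rss_t = rss(np.column_stack([subjects, time]))
    rss_i = rss(np.column_stack([subjects, time, inter]))

    n_subj = subjects.shape[1]
    a, m = 2, 2
    df_subj, df_res = n_subj - a, (n_subj - a) * (m - 1)
    ss = {
        "group": rss0 - rss_g,
        "subj": rss_g - rss_s,
        "time": rss_s - rss_t,
        "group:time": rss_t - rss_i,
        "resid": rss_i,
    }
    out = {}
    for eff, (df1, ss_err, df_err) in {
        "group": (1, ss["subj"], df_subj),
        "time": (1, ss["resid"], df_res),
        "group:time": (1, ss["resid"], df_res),
    }.items():
        F = (ss[eff] / df1) / (ss_err / df_err)
        out[eff] = {
            "SS": ss[eff],
            "F": F,
            "p": float(sps.f.sf(F, df1, df_err)),
            "np2": ss[eff] / (ss[eff] + ss_err),
        }
    out["ss_subj"], out["ss_resid"] = ss["subj"], ss["resid"]
    return out


def random_table(rng, n_per_group=6):
    spec = TableSpec(
        n_per_group=n_per_group,
        grand_mean=rng.normal(0, 5),
        effect_group=rng.normal(0, 2),
        effect_time=rng.normal(0, 2),
        effect_interaction=rng.normal(0, 2),
        sd_between=rng.uniform(0.2, 3),
        sd_within=rng.uniform(0.2, 3),
        seed=int(rng.integers(2**31)),
    )
    return simulate_trial_table(spec)[0]


class TestSplitplotAnova:
    def test_agrees_with_glm_oracle_on_random_tables(self, rng):
        for _ in range(25):
            table = random_table(rng)
            res = splitplot_anova(table)
            oracle = glm_oracle(table)
            for eff in ("group", "time", "group:time"):
                e = res.effects[eff]
                assert e.ss == pytest.approx(oracle[eff]["SS"], rel=1e-8, abs=1e-10)
                assert e.F == pytest.approx(oracle[eff]["F"], rel=1e-8)
                assert e.p == pytest.approx(oracle[eff]["p"], rel=1e-8, abs=1e-12)
                assert e.partial_eta_sq == pytest.approx(oracle[eff]["np2"], rel=1e-8)

    def test_ss_additivity(self, rng):
        for _ in range(20):
            table = random_table(rng)
            r = splitplot_anova(table)
            parts = (
                r.effects["group"].ss
                + r.ss_subjects_within_group
                + r.effects["time"].ss
                + r.effects["group:time"].ss
                + r.ss_residual
            )
            assert parts == pytest.approx(r.ss_total, rel=1e-8)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        table = random_table(rng)
        res = splitplot_anova(table)
        aov = pg.mixed_anova(
            data=table, dv="value", within="time", between="group",
            subject="participant",
        ).set_index("Source")
        for src, eff in (("group", "group"), ("time", "time"),
                         ("Interaction", "group:time")):
            assert res.effects[eff].F == pytest.approx(aov.loc[src, "F"], rel=1e-9)
            assert res.effects[eff].p == pytest.approx(aov.loc[src, "p_unc"], rel=1e-9)
            assert res.effects[eff].partial_eta_sq == pytest.approx(
                aov.loc[src, "np2"], rel=1e-9
            )

    def test_mirror_groups_give_zero_group_effect(self):
        rows = []
        vals = [1.0, 4.0, 2.5, 0.5]
        for g in ("WBED", "Sham"):  # identical per-subject values in both groups
            for i, v in enumerate(vals[:2]):
                for t, dv in (("pre", 0.0), ("post", vals[2 + i])):
                    rows.append({"participant": f"{g}{i}", "group": g, "time": t,
                                 "value": v + dv})
        table = pd.DataFrame(rows)
        res = splitplot_anova(table)
        assert res.effects["group"].F == pytest.approx(0.0, abs=1e-12)
        assert res.effects["group"].partial_eta_sq == pytest.approx(0.0, abs=1e-12)

    def test_constant_data_is_degenerate(self):
        rows = [
            {"participant": f"P{i}", "group": g, "time": t, "value": 3.0}
            for i, g in enumerate(["WBED", "WBED", "Sham", "Sham"])
            for t in ("pre", "post")
        ]
        with pytest.raises(DegenerateDataError):
            splitplot_anova(pd.DataFrame(rows))

    def test_unbalanced_table_rejected(self, rng):
        table = random_table(rng).iloc[:-1]
        with pytest.raises(BalanceError):
            splitplot_anova(table)

    def test_within_f_equals_pooled_paired_t_squared(self, rng):
        for _ in range(10):
            table = random_table(rng)
            res = splitplot_anova(table)
            wide = table.pivot_table(index=["group", "participant"],
                                     columns="time", values="value")
            d = (wide["post"] - wide["pre"])
            dc = d - d.groupby(level="group").transform("mean")
            n = len(d)
            s2 = float((dc**2).sum()) / (n - 2)
            t2 = n * float(d.mean()) ** 2 / s2
            assert res.effects["time"].F == pytest.approx(t2, rel=1e-9)


class TestEffectSizeClass:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, "negligible"), (0.01, "negligible"), (0.05, "small"),
         (0.06, "small"), (0.1, "moderate"), (0.14, "moderate"), (0.20, "large")],
    )
    def test_cutoffs(self, value, expected):
        assert classify_effect_size(value) == expected

    def test_domain(self):
        with pytest.raises(DomainError):
            classify_effect_size(1.2)


class TestSimpleEffects:
    def test_labels_and_count(self, rng):
        effects = simple_effects(random_table(rng))
        assert len(effects) == 4
        labels = [e.label for e in effects]
        assert sum("within" in l for l in labels) == 2
        assert sum(" at " in l for l in labels) == 2

    def test_matches_scipy_t_tests(self, rng):
        table = random_table(rng, n_per_group=4)
        effects = {e.label: e for e in simple_effects(table)}
        wide = table.pivot_table(index=["group", "participant"], columns="time",
                                 values="value")
        for g in ("Sham", "WBED"):
            ref = sps.ttest_rel(wide.loc[g, "post"], wide.loc[g, "pre"])
            e = effects[f"post vs pre within {g}"]
            assert e.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert e.statistic == pytest.approx(ref.statistic, abs=1e-10)
        for t in ("pre", "post"):
            ref = sps.ttest_ind(wide.loc["Sham", t], wide.loc["WBED", t])
            e = effects[f"Sham vs WBED at {t}"]
            assert e.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_pre_post_gives_p_one(self):
        rows = []
        for g in ("WBED", "Sham"):
            for i in range(3):
                v = float(i) + (10.0 if g == "WBED" else 0.0)
                for t in ("pre", "post"):
                    rows.append({"participant": f"{g}{i}", "group": g,
                                 "time": t, "value": v})
        effects = {e.label: e for e in simple_effects(pd.DataFrame(rows))}
        assert effects["post vs pre within WBED"].statistic == 0.0
        assert effects["post vs pre within WBED"].p == 1.0

    def test_single_participant_per_group_rejected(self):
        rows = [{"participant": g, "group": g, "time": t, "value": float(i)}
                for i, (g, t) in enumerate(
                    [("WBED", "pre"), ("WBED", "post"),
                     ("Sham", "pre"), ("Sham", "post")])]
        with pytest.raises(BalanceError):
            simple_effects(pd.DataFrame(rows))
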