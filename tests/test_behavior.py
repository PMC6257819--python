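"""Behavioral exclusions, contrasts, residualization, brain-behavior models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqdecode.behavior import (
    apply_exclusions,
    evidence_rt_model,
    residualize_rt,
    structure_contrasts,
    wm_decoding_comparison,
    within_subject_ci,
)
from seqdecode.synth_eeg import BehaviorParams, simulate_behavior
from seqdecode.task_model import ExperimentDesign, assign_probes, build_schedule


def _toy_table(**cols):
    n = len(next(iter(cols.values())))
    base = {
        "subject": np.zeros(n, int),
        "block": np.zeros(n, int),
        "within_chunk_position": np.tile([1, 2, 3], n)[:n],
        "rt": np.full(n, 500.0),
        "correct": np.ones(n, bool),
        "is_match": np.zeros(n, bool),
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestExclusions:
    def test_error_and_post_error_flagged(self):
        t = _toy_table(correct=np.array([True, False, True, True]))
        out = apply_exclusions(t)
        assert list(out["excluded"]) == [False, True, True, False]
        assert out.loc[1, "exclusion_reason"] == "error"
        assert out.loc[2, "exclusion_reason"] == "post_error"

    def test_fast_rt_flagged(self):
        t = _toy_table(rt=np.array([500.0, 90.0, 120.0]))
        out = apply_exclusions(t)
        assert list(out["excluded"]) == [False, True, False]

    def test_retrieval_rule_only_exp2(self):
        t = _toy_table(rt=np.full(3, 500.0),
                       retrieval_time=np.array([3000.0, 9000.0, 1000.0]))
        assert list(apply_exclusions(t, "exp2")["excluded"]) == [False, True, False]
        assert not apply_exclusions(t, "exp1")["excluded"].any()

    def test_post_error_not_across_blocks(self):
        t = _toy_table(correct=np.array([True, False, True]),
                       block=np.array([0, 0, 1]))
        out = apply_exclusions(t)
        assert not out.loc[2, "excluded"]

    def test_idempotent(self):
        t = _toy_table(correct=np.array([True, False, True, True]),
                       rt=np.array([500.0, 90.0, 500.0, 500.0]))
        once = apply_exclusions(t)
        twice = apply_exclusions(once)
        pd.testing.assert_frame_equal(once, twice)


@pytest.fixture(scope="module")
def multi_subject_behavior():
    design = ExperimentDesign.from_variant("exp1", n_blocks=6)
    tables = []
    for s in range(30):
        sched = assign_probes(build_schedule(design, seed=500 + s, subject=s),
                              seed=600 + s)
        beh = simulate_behavior(sched, BehaviorParams(boundary_cost=14.0,
                                                      boundary_error_cost=0.038),
                                seed=700 + s)
        tables.append(apply_exclusions(beh))
    return pd.concat(tables, ignore_index=True)


class TestContrasts:
    def test_boundary_cost_recovered_in_ci(self, multi_subject_behavior):
        res = {(c.measure, c.contrast): c
               for c in structure_contrasts(multi_subject_behavior)}
        rt = res[("rt", "pos1_vs_23")]
        lo = rt.estimate - 2 * rt.se
        hi = rt.estimate + 2 * rt.se
        assert lo < 14.0 < hi
        assert rt.F == pytest.approx(rt.t**2)
        acc = res[("accuracy", "pos1_vs_23")]
        assert acc.estimate - 2 * acc.se < 0.038 < acc.estimate + 2 * acc.se

    def test_null_boundary_cost(self):
        design = ExperimentDesign.from_variant("exp1", n_blocks=6)
        tables = []
        for s in range(12):
            sched = build_schedule(design, seed=800 + s, subject=s)
            sched = assign_probes(sched, seed=1)
            beh = simulate_behavior(sched, BehaviorParams(boundary_cost=0.0),
                                    seed=900 + s)
            tables.append(apply_exclusions(beh))
        res = {(c.measure, c.contrast): c
               for c in structure_contrasts(pd.concat(tables, ignore_index=True))}
        assert abs(res[("rt", "pos1_vs_23")].t) < 3

    def test_wm_interaction_detected(self):
        design = ExperimentDesign.from_variant("exp1", n_blocks=6)
        tables, groups = [], {}
        for s in range(24):
            g = "low" if s < 12 else "high"
            groups[s] = g
            sched = assign_probes(build_schedule(design, seed=1000 + s, subject=s),
                                  seed=2)
            beh = simulate_behavior(
                sched, BehaviorParams(boundary_cost=20.0, wm_group_scaling=4.0),
                seed=1100 + s, wm_group=g,
            )
            tables.append(apply_exclusions(beh))
        res = {(c.measure, c.contrast): c
               for c in structure_contrasts(pd.concat(tables, ignore_index=True),
                                            wm_groups=groups)}
        inter = res[("rt", "boundary_x_wm")]
        assert inter.estimate > 0 and inter.p < 0.05

    def test_needs_two_subjects(self):
        t = _toy_table(correct=np.ones(6, bool))
        with pytest.raises(ValueError):
            structure_contrasts(t)

    def test_within_subject_ci_positive(self, multi_subject_behavior):
        means = multi_subject_behavior.pivot_table(
            index="subject", columns="within_chunk_position", values="rt")
        ci = within_subject_ci(means)
        assert (ci > 0).all()


class TestResidualize:
    def _schedule_frame(self, n=216, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "subject": np.zeros(n, int),
            "block": np.repeat(np.arange(n // 54), 54)[:n],
            "within_chunk_position": np.tile([1, 2, 3], n // 3),
            "is_match": rng.random(n) < 0.5,
            "correct": np.ones(n, bool),
        })
        return df, rng

    def test_pure_quadratic_trend_removed(self):
        df, _ = self._schedule_frame()
        trial = np.arange(len(df), dtype=float)
        df["rt"] = np.exp(6.0 + 1e-5 * (trial - trial.mean()) ** 2)
        df["excluded"] = False
        resid = residualize_rt(df)
        assert np.nanmax(np.abs(resid)) < 1e-8

    def test_residuals_orthogonal_to_nuisance(self):
        df, rng = self._schedule_frame(seed=1)
        df["rt"] = 400 + 30 * rng.random(len(df))
        df["excluded"] = False
        resid = residualize_rt(df)
        trial = np.arange(len(df), dtype=float)
        trial = (trial - trial.mean()) / trial.std()
        for col in (trial, trial**2,
                    np.where(df["within_chunk_position"] == 1, 2.0, -1.0),
                    df["is_match"].astype(float).to_numpy()):
            assert abs(np.dot(resid, col - col.mean())) < 1e-8

    def test_coupling_preserved(self):
        df, rng = self._schedule_frame(seed=2)
        evid = rng.standard_normal(len(df))
        gamma = -0.3
        df["rt"] = np.exp(np.log(500) + gamma * evid + 0.05 * rng.standard_normal(len(df)))
        df["excluded"] = False
        resid = residualize_rt(df)
        slope = np.polyfit(evid, resid, 1)[0]
        assert slope == pytest.approx(gamma, abs=0.05)


class TestEvidenceRTModel:
    def _simulate(self, slope_el, slope_pos, n_sub=10, n=300, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sub):
            el = rng.standard_normal(n)
            pos = rng.standard_normal(n)
            y = slope_el * el + slope_pos * pos + 0.3 * rng.standard_normal(n)
            rows.append(pd.DataFrame({"subject": s, "alpha_element": el,
                                      "theta_position": pos, "y": y}))
        df = pd.concat(rows, ignore_index=True)
        return df["y"].to_numpy(), df.drop(columns="y")

    def test_slopes_recovered(self):
        y, ev = self._simulate(-0.3, 0.0, seed=3)
        fit = evidence_rt_model(y, ev)
        el = fit.coefficients["alpha_element"]
        assert el["b"] == pytest.approx(-0.3, abs=3 * el["se"] + 0.02)
        assert abs(fit.coefficients["theta_position"]["b"]) < 0.05

    def test_no_coupling_null(self):
        y, ev = self._simulate(0.0, 0.0, seed=4)
        fit = evidence_rt_model(y, ev)
        for v in fit.coefficients.values():
            assert abs(v["b"]) < 0.05

    def test_selective_position_coupling(self):
        y, ev = self._simulate(0.0, -0.2, seed=5)
        fit = evidence_rt_model(y, ev)
        assert fit.coefficients["theta_position"]["b"] == pytest.approx(-0.2, abs=0.05)
        assert abs(fit.coefficients["alpha_element"]["b"]) < 0.05


class TestWMComparison:
    def _summaries(self, rng, chunk_deficit=0.0, n_per_group=10):
        rows = []
        groups = {}
        for s in range(2 * n_per_group):
            g = "low" if s < n_per_group else "high"
            groups[s] = g
            el = 0.42 + 0.02 * rng.standard_normal()
            ch = 0.38 + 0.02 * rng.standard_normal()
            if g == "low":
                ch -= chunk_deficit
            rows.append({"subject": s, "code": "element", "value": el})
            rows.append({"subject": s, "code": "chunk_identity", "value": ch})
        return pd.DataFrame(rows), groups

    def test_injected_chunk_deficit_dissociates(self):
        rng = np.random.default_rng(6)
        summaries, groups = self._summaries(rng, chunk_deficit=0.06)
        res = wm_decoding_comparison(summaries, groups)
        assert res["chunk_identity"]["p"] < 0.05
        assert res["element"]["p"] > 0.05
        assert res["level_x_wm"]["p"] < 0.05 and res["level_x_wm"]["diff"] > 0

    def test_identical_generators_null(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(30):
            summaries, groups = self._summaries(rng, chunk_deficit=0.0)
            res = wm_decoding_comparison(summaries, groups)
            ps.append(res["chunk_identity"]["p"])
        assert 0.4 < np.mean(np.array(ps) > 0.05) <= 1.0
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_small_group_rejected(self):
        rng = np.random.default_rng(8)
        summaries, groups = self._summaries(rng, n_per_group=1)
        with pytest.raises(ValueError):
            wm_decoding_comparison(summaries, groups)
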