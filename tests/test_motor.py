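"""Rotarod summaries, box summaries, regression, association grid, onset."""

import numpy as np
import pandas as pd
import pytest

import cagtrace as ct
from cagtrace.errors import (
    CoverageError,
    DesignError,
    InsufficientDataError,
    MissingDataError,
)
from cagtrace.motor import FEWER_BETTER, MORE_WORSE, NO_ASSOCIATION
from cagtrace.peakfit import SomaticChangeDistribution as SCD


def records(times_by_day, animal="a1", speed=20, grip=None):
    rows = []
    for day, times in enumerate(times_by_day, start=1):
        for attempt, t in enumerate(times, start=1):
            rows.append({"animal_id": animal, "day": day, "attempt": attempt,
                         "speed_rpm": speed, "time_s": t,
                         "grip_pass": grip[day - 1] if grip else False})
    return pd.DataFrame(rows)


class TestSummarizeRotarod:
    def test_ceiling_scores(self):
        perf = ct.summarize_rotarod(records([[120.0] * 3] * 5))
        assert perf.score == 120.0

    def test_mean_of_daily_bests(self):
        days = [[100, 50, 20], [80, 10, 5], [120, 119, 1], [60, 59, 58],
                [90, 89, 88]]
        perf = ct.summarize_rotarod(records(days))
        assert perf.best_daily_times == [100, 80, 120, 60, 90]
        assert perf.score == pytest.approx(90.0)

    def test_missing_speed_error(self):
        with pytest.raises(MissingDataError):
            ct.summarize_rotarod(records([[50.0] * 3] * 5, speed=10), speed=20)

    def test_grip_any_day_pass(self):
        perf = ct.summarize_rotarod(
            records([[50.0] * 3] * 5, grip=[False, False, True, False, False]))
        assert perf.grip_passed

    def test_brute_force_oracle(self, rng):
        # 100 random record sets: score equals max-within-day mean-across-days
        for _ in range(100):
            days = rng.uniform(0, 120, size=(5, 3))
            perf = ct.summarize_rotarod(records(days.tolist()))
            assert perf.score == pytest.approx(days.max(axis=1).mean())


class TestBoxSummary:
    def test_hand_values(self):
        box = ct.box_summary([25, 75, 85, 120])
        assert (box.min, box.median, box.max) == (25, 80, 120)

    def test_degenerate_box(self):
        box = ct.box_summary([90.0] * 6)
        assert box.min == box.q1 == box.median == box.q3 == box.max == 90.0

    def test_too_few_scores(self):
        with pytest.raises(InsufficientDataError):
            ct.box_summary([1.0, 2.0, 3.0])

    def test_matches_sort_oracle(self, rng):
        # Tukey hinges: median of lower/upper half (halves share the median
        # when n is odd)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            x = np.sort(rng.uniform(0, 120, n))
            box = ct.box_summary(x)
            m = (n + 1) // 2
            assert box.q1 == pytest.approx(np.median(x[:m]))
            assert box.q3 == pytest.approx(np.median(x[n - m:]))
            assert box.min <= box.q1 <= box.median <= box.q3 <= box.max


class TestPerformanceRegression:
    @staticmethod
    def _design(n_per_cell=25, effects=(91.9, 7.7, 11.0, -23.7), noise=0.0,
                seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        g0, fem, ogg, hd = effects
        for sex in ("M", "F"):
            for ogg1 in ("+/+", "-/-"):
                for zyg in ("wt/wt", "Q150/Q150"):
                    mu = (g0 + fem * (sex == "F") + ogg * (ogg1 == "-/-")
                          + hd * (zyg == "Q150/Q150"))
                    for i in range(n_per_cell):
                        rows.append({"animal_id": f"{sex}{ogg1}{zyg}{i}",
                                     "sex": sex, "ogg1_status": ogg1,
                                     "hd_zygosity": zyg,
                                     "age_weeks": int(rng.integers(5, 11)),
                                     "score": mu + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_exact_recovery_noiseless(self):
        reg = ct.performance_regression(self._design()).set_index("term")
        assert reg.loc["intercept", "estimate"] == pytest.approx(91.9, abs=1e-6)
        assert reg.loc["female", "estimate"] == pytest.approx(7.7, abs=1e-6)
        assert reg.loc["ogg1_ko", "estimate"] == pytest.approx(11.0, abs=1e-6)
        assert reg.loc["hd_homo", "estimate"] == pytest.approx(-23.7, abs=1e-6)

    def test_null_effects_within_two_se(self):
        reg = ct.performance_regression(
            self._design(effects=(91.9, 0, 0, 0), noise=6.0, seed=3)
        ).set_index("term")
        for term in ("female", "ogg1_ko", "hd_homo"):
            assert abs(reg.loc[term, "estimate"]) <= 2.5 * reg.loc[term, "se"]

    def test_normal_equations_oracle_on_designed_data(self):
        df = self._design(n_per_cell=2, noise=3.0, seed=9)
        reg = ct.performance_regression(df)
        X = np.column_stack([
            np.ones(len(df)), (df.sex == "F"), (df.ogg1_status == "-/-"),
            (df.hd_zygosity == "Q150/Q150"), df.age_weeks,
        ]).astype(float)
        beta = np.linalg.solve(X.T @ X, X.T @ df.score.to_numpy())
        assert np.allclose(reg["estimate"].to_numpy(), beta, atol=1e-8)

    def test_collinear_design_names_terms(self):
        df = self._design(n_per_cell=4)
        df["age_weeks"] = 8  # constant column aliases the intercept
        with pytest.raises(DesignError, match="age"):
            ct.performance_regression(df)

    def test_generator_recovery_default_cohort(self):
        # structural effects recovered from a simulated pre-onset cohort
        genos = tuple(ct.GenotypeSpec(z, o)
                      for z in ("wt/wt", "Q150/wt", "Q150/Q150")
                      for o in ("+/+", "-/-"))
        cfg = ct.CohortConfig(seed=13, animals_per_cell=50,
                              age_groups=((5, 10),), genotypes=genos,
                              tissues=())
        cohort = ct.generate_cohort(cfg)
        scores = ct.summarize_cohort(cohort.performance).merge(
            cohort.metadata(), on="animal_id")
        reg = ct.performance_regression(scores).set_index("term")
        assert reg.loc["intercept", "estimate"] == pytest.approx(91.9, abs=3.0)
        assert reg.loc["female", "estimate"] == pytest.approx(7.7, abs=1.5)
        assert reg.loc["ogg1_ko", "estimate"] == pytest.approx(11.0, abs=2.0)
        assert reg.loc["hd_homo", "estimate"] == pytest.approx(-23.7, abs=3.0)


class TestAssociationGrid:
    @staticmethod
    def _cohort(rng, n=60, coupling=0.0, low_only=False):
        scores, changes = [], {}
        for i in range(n):
            aid = f"a{i}"
            law = ct.somatic_delta_pmf(2.0 + rng.uniform(0, 2))
            shift = int(rng.integers(0, 4))
            freqs = {k + shift: v for k, v in law.items()}
            changes[(aid, "STR")] = SCD(aid, "STR", freqs)
            g = ct.pool_distributions([changes[(aid, "STR")]])
            qs = ct.quantile_values(g, [10])
            driver = qs[10] if low_only else shift
            scores.append({"animal_id": aid, "sex": "MF"[i % 2],
                           "ogg1_status": ("+/+", "-/-")[(i // 2) % 2],
                           "hd_zygosity": ("Q150/wt", "Q150/Q150")[(i // 4) % 2],
                           "age_weeks": int(rng.integers(5, 41)),
                           "score": 90 - coupling * driver + rng.normal(0, 5)})
        return pd.DataFrame(scores), changes

    def test_null_coupling_type_one_error(self):
        rng = np.random.default_rng(41)
        hits = total = 0
        for _ in range(100):
            scores, changes = self._cohort(rng, n=40)
            grid = ct.quantile_performance_association(
                scores, changes, percentiles=(10, 50, 90))
            hits += int((grid["p"] <= 0.05).sum())
            total += len(grid)
        assert hits / total == pytest.approx(0.05, abs=0.03)

    def test_low_percentile_coupling_concentrates_low(self):
        rng = np.random.default_rng(8)
        scores, changes = self._cohort(rng, n=80, coupling=8.0, low_only=True)
        grid = ct.quantile_performance_association(scores, changes)
        sig = grid[grid.p <= 0.01]
        assert not sig.empty
        assert (sig[sig.percentile <= 30]["p"].min()
                <= grid[grid.percentile >= 80]["p"].min())

    def test_sign_semantics(self):
        rng = np.random.default_rng(15)
        scores, changes = self._cohort(rng, n=80, coupling=8.0)
        grid = ct.quantile_performance_association(scores, changes)
        sig = grid[(grid.p <= 0.05) & (grid.slope < 0)]
        assert (sig[sig.percentile <= 50]["label"] == FEWER_BETTER).all()
        assert (sig[sig.percentile > 50]["label"] == MORE_WORSE).all()
        assert (grid[grid.p > 0.05]["label"] == NO_ASSOCIATION).all()


class TestDetectOnset:
    GROUPS = ["5-10", "11-20", "21-30", "31-40", "41-60"]

    def _scores(self, medians, spread=0.0, n=10, rng=None):
        out = {}
        for g, m in zip(self.GROUPS, medians):
            base = np.full(n, float(m))
            if spread and rng is not None:
                base = base + rng.normal(0, spread, n)
            out[g] = base
        return out

    def test_identical_groups_none(self):
        ref = self._scores([100] * 5)
        assert ct.detect_onset(self._scores([100] * 5), ref) is None

    def test_step_decline_detected_exactly(self):
        ref = self._scores([100] * 5)
        geno = self._scores([100, 70, 70, 70, 70])
        assert ct.detect_onset(geno, ref) == "11-20"

    def test_constant_offset_is_not_onset(self):
        # a genotype slower from birth has no detectable *decline*
        ref = self._scores([100] * 5)
        geno = self._scores([80] * 5)
        assert ct.detect_onset(geno, ref) is None

    def test_transient_dip_not_sustained(self):
        ref = self._scores([100] * 5)
        geno = self._scores([100, 70, 100, 100, 100])
        assert ct.detect_onset(geno, ref) is None

    def test_monotone_in_injected_onset(self):
        ref = self._scores([100] * 5)
        detected = []
        for onset_idx in (1, 2, 3):
            medians = [100] * onset_idx + [60] * (5 - onset_idx)
            detected.append(ct.detect_onset(self._scores(medians), ref))
        order = [self.GROUPS.index(d) for d in detected]
        assert order == sorted(order)

    def test_missing_reference_group(self):
        ref = self._scores([100] * 5)
        del ref["21-30"]
        with pytest.raises(CoverageError):
            ct.detect_onset(self._scores([100] * 5), ref)

    def test_default_arms_recover_published_delay(self):
        # simulated Q150/Q150 arms: onset groups 11-20 vs 41-60 (midpoints
        # 15.5 and 50.5 weeks -> delay 35 weeks, inside the stated 30-40)
        groups = ((5, 10), (11, 20), (21, 30), (31, 40), (41, 60))
        genos = (ct.GenotypeSpec("wt/wt", "+/+"),
                 ct.GenotypeSpec("Q150/Q150", "+/+"),
                 ct.GenotypeSpec("Q150/Q150", "-/-"))
        cfg = ct.CohortConfig(seed=1, animals_per_cell=20, age_groups=groups,
                              genotypes=genos, tissues=())
        cohort = ct.generate_cohort(cfg)
        scores = ct.summarize_cohort(cohort.performance).merge(
            cohort.metadata(), on="animal_id")

        def arm(zyg, ogg1):
            sub = scores[(scores.hd_zygosity == zyg)
                         & (scores.ogg1_status == ogg1)]
            return {ct.cohort.age_group_label(g):
                    sub[sub.age_group == ct.cohort.age_group_label(g)]
                    .score.values for g in groups}

        ref = arm("wt/wt", "+/+")
        onset_wt_ogg1 = ct.detect_onset(arm("Q150/Q150", "+/+"), ref)
        onset_ko = ct.detect_onset(arm("Q150/Q150", "-/-"), ref)
        assert onset_wt_ogg1 == "11-20"
        assert onset_ko == "41-60"


class TestGrip:
    def test_all_pass(self):
        assert ct.grip_pass_rate([True] * 8) == 100.0

    def test_hand_arithmetic(self):
        assert ct.grip_pass_rate([True] * 5 + [False] * 3) == pytest.approx(62.5)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            ct.grip_pass_rate([])

    def test_calibrated_forty_week_fail_rate(self):
        # homozygous ogg1+/+ at 40 weeks: ~62% fail the 30 s hold
        cfg = ct.CohortConfig(seed=29, animals_per_cell=400,
                              age_groups=((40, 40),),
                              genotypes=(ct.GenotypeSpec("Q150/Q150", "+/+"),),
                              tissues=())
        cohort = ct.generate_cohort(cfg)
        scores = ct.summarize_cohort(cohort.performance)
        fail_rate = 100.0 - ct.grip_pass_rate(scores.grip_passed)
        assert fail_rate == pytest.approx(62.0, abs=8.0)
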