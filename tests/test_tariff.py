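from dataclasses import replace as dc_replace

import numpy as np
import pytest

from pufval.descriptive_system import DIMENSIONS, Dimension
from pufval.puf_engine import build_pufs
from pufval.qc import find_exclusions
from pufval.synthetic_data import GeneratorConfig, generate
from pufval.tariff import (
    LANGUAGE_GROUPS,
    Tariff,
    aggregate,
    full_value_set,
    monotonicity_audit,
    subgroup_tariffs,
)


def _pufs(n=30, seed=11, **kwargs):
    cohort = generate(GeneratorConfig(n=n, seed=seed, **kwargs))
    return build_pufs(cohort), cohort


class TestAggregate:
    def test_mean_is_arithmetic_mean(self):
        pufs, _ = _pufs(2)
        t = aggregate(pufs, bootstrap_reps=10)
        for i, d in enumerate(DIMENSIONS):
            for j, lev in enumerate((2, 3, 4, 5)):
                expected = 0.5 * (pufs[0].delta[i, lev - 1] + pufs[1].delta[i, lev - 1])
                assert t.mean_delta[i, j] == pytest.approx(expected, abs=1e-15)

    def test_pits_linearity_identity(self):
        pufs, _ = _pufs(40)
        t = aggregate(pufs, bootstrap_reps=10)
        assert 1.0 - t.mean_delta[:, 3].sum() == pytest.approx(t.mean_u55, abs=1e-9)

    def test_needs_two_pufs(self):
        pufs, _ = _pufs(5)
        with pytest.raises(ValueError):
            aggregate(pufs[:1])

    def test_permutation_invariant_means(self):
        pufs, _ = _pufs(25)
        t1 = aggregate(pufs, seed=3)
        t2 = aggregate(list(reversed(pufs)), seed=3)
        np.testing.assert_allclose(t1.mean_delta, t2.mean_delta, atol=1e-14)

    def test_bootstrap_deterministic_given_seed(self):
        pufs, _ = _pufs(25)
        t1 = aggregate(pufs, seed=42)
        t2 = aggregate(pufs, seed=42)
        np.testing.assert_array_equal(t1.ci_low, t2.ci_low)
        np.testing.assert_array_equal(t1.ci_high, t2.ci_high)

    def test_ci_brackets_mean(self):
        pufs, _ = _pufs(50)
        for method in ("bootstrap", "t"):
            t = aggregate(pufs, ci_method=method, seed=1)
            assert np.all(t.ci_low <= t.mean_delta + 1e-15)
            assert np.all(t.mean_delta <= t.ci_high + 1e-15)

    def test_ci_method_changes_interval_not_mean(self):
        pufs, _ = _pufs(50)
        tb = aggregate(pufs, ci_method="bootstrap", seed=1)
        tt = aggregate(pufs, ci_method="t", seed=1)
        np.testing.assert_array_equal(tb.mean_delta, tt.mean_delta)
        assert not np.array_equal(tb.ci_low, tt.ci_low)

    def test_ci_width_shrinks_roughly_as_sqrt_n(self):
        widths = {}
        for n in (50, 800):
            pufs, _ = _pufs(n=n, seed=2)
            t = aggregate(pufs, seed=2, bootstrap_reps=400)
            widths[n] = (t.ci_high - t.ci_low).mean()
        ratio = widths[50] / widths[800]
        assert 2.0 < ratio < 8.0  # ideal sqrt(16) = 4, within broad factors


class TestMonotonicityAudit:
    def test_noise_free_tariff_is_monotone(self):
        pufs, _ = _pufs(200, seed=4, illogical_rate=0.0)
        audit = monotonicity_audit(aggregate(pufs, bootstrap_reps=10))
        assert audit.is_monotone
        assert audit.violations == []

    def test_constructed_violation_is_located(self):
        pufs, _ = _pufs(20)
        t = aggregate(pufs, bootstrap_reps=10)
        delta = t.mean_delta.copy()
        i = DIMENSIONS.index(Dimension.PD)
        delta[i, 1] = 0.10  # level 3
        delta[i, 2] = 0.08  # level 4 smaller: violation on the 3 -> 4 step
        bad = dc_replace(t, mean_delta=delta)
        audit = monotonicity_audit(bad)
        assert len(audit.violations) == 1
        v = audit.violations[0]
        assert v.dimension is Dimension.PD
        assert v.step == (3, 4)
        assert v.decrease == pytest.approx(0.02)

    def test_final_step_reported_for_every_dimension(self):
        pufs, _ = _pufs(50, seed=6)
        audit = monotonicity_audit(aggregate(pufs, bootstrap_reps=10))
        assert set(audit.final_step) == set(DIMENSIONS)
        # Dirichlet(2,2,2,3) gaps make the 4 -> 5 step the largest on average
        assert all(s > 0 for s in audit.final_step.values())

    def test_noisy_cohort_still_audits(self):
        pufs, _ = _pufs(60, seed=8, illogical_rate=0.3)
        audit = monotonicity_audit(aggregate(pufs, bootstrap_reps=10))
        assert isinstance(audit.is_monotone, bool)


class TestFullValueSet:
    def test_shape_and_anchors(self):
        pufs, _ = _pufs(30)
        t = aggregate(pufs, bootstrap_reps=10)
        vs = full_value_set(t, precision=None)
        assert len(vs) == 3125
        assert list(vs["state"]) == sorted(vs["state"])
        assert vs.loc[vs["state"] == "11111", "utility"].iloc[0] == 1.0
        assert vs.loc[vs["state"] == "55555", "utility"].iloc[0] == pytest.approx(
            t.mean_u55, abs=1e-12
        )

    def test_utilities_bounded_above_by_one(self):
        pufs, _ = _pufs(30)
        vs = full_value_set(aggregate(pufs, bootstrap_reps=10), precision=None)
        assert (vs["utility"] <= 1.0 + 1e-12).all()


class TestSubgroups:
    def test_three_language_groups(self, study_cohort, small_pufs):
        excluded = {rid for rid, _ in find_exclusions(study_cohort)}
        kept = [r for r in study_cohort if r.id not in excluded]
        pufs = build_pufs(kept)
        subs = subgroup_tariffs(pufs, kept, bootstrap_reps=10)
        assert {t.label for t in subs} == set(LANGUAGE_GROUPS)
        assert sum(t.n for t in subs) == len(pufs)

    def test_pooled_equals_size_weighted_subgroup_mean(self, study_cohort):
        excluded = {rid for rid, _ in find_exclusions(study_cohort)}
        kept = [r for r in study_cohort if r.id not in excluded]
        pufs = build_pufs(kept)
        pooled = aggregate(pufs, bootstrap_reps=10)
        subs = subgroup_tariffs(pufs, kept, bootstrap_reps=10)
        weighted = sum(t.n * t.mean_delta for t in subs) / sum(t.n for t in subs)
        np.testing.assert_allclose(pooled.mean_delta, weighted, atol=1e-12)
        weighted_u55 = sum(t.n * t.mean_u55 for t in subs) / sum(t.n for t in subs)
        assert pooled.mean_u55 == pytest.approx(weighted_u55, abs=1e-12)

    def test_single_language_cohort_collapses_to_full_aggregate(self, small_cohort):
        kept = [dc_replace(r, language="Tswana") for r in small_cohort]
        pufs = build_pufs(kept)
        subs = subgroup_tariffs(pufs, kept, bootstrap_reps=10, seed=5)
        assert len(subs) == 1
        full = aggregate(pufs, bootstrap_reps=10, seed=5)
        np.testing.assert_allclose(subs[0].mean_delta, full.mean_delta, atol=1e-15)

    def test_small_subgroup_warned_not_dropped(self, small_cohort):
        kept = [dc_replace(r, language="Tswana") for r in small_cohort]
        kept[0] = dc_replace(kept[0], language="Zulu")
        kept[1] = dc_replace(kept[1], language="Zulu")
        pufs = build_pufs(kept)
        with pytest.warns(UserWarning, match="small|imprecise|respondent"):
            subs = subgroup_tariffs(pufs, kept, bootstrap_reps=10)
        assert {t.label for t in subs} == {"Tswana", "Zulu"}

    def test_group_specific_anchor_distributions_are_recovered(self):
        # Tswana generated with a much higher stretched share than the rest:
        # its subgroup mean u55 must come out lowest
        lo = generate(GeneratorConfig(n=120, seed=21, p_stretched=0.8))
        hi = generate(GeneratorConfig(n=120, seed=22, p_stretched=0.05))
        lo = [dc_replace(r, id=f"L{i}", language="Tswana") for i, r in enumerate(lo)]
        hi = [dc_replace(r, id=f"H{i}", language="Zulu") for i, r in enumerate(hi)]
        cohort = lo + hi
        pufs = build_pufs(cohort)
        subs = {t.label: t for t in subgroup_tariffs(pufs, cohort, bootstrap_reps=10)}
        assert subs["Tswana"].mean_u55 < subs["Zulu"].mean_u55


def test_tariff_frame_layout():
    cohort = generate(GeneratorConfig(n=10, seed=1))
    t = aggregate(build_pufs(cohort), bootstrap_reps=10)
    df = t.to_frame()
    assert list(df.columns) == [
        "dimension", "level", "mean_decrement", "ci_low", "ci_high", "n", "cohort",
    ]
    assert len(df) == 20
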