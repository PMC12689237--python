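import warnings
from dataclasses import replace

import numpy as np
import pytest

from pufval.descriptive_system import DIMENSIONS, Dimension, HealthState, parse_state
from pufval.puf_engine import (
    AnchorDivisionByZeroError,
    FlatPUFWarning,
    build_puf,
    build_pufs,
    censor_u55,
    evaluate,
    evaluate_batch,
    implied_u55,
    level_proportions,
    normalize_weights,
)
from pufval.qc import find_exclusions
from pufval.respondent_io import (
    AnchorPreference,
    AnchorResponse,
    LevelResponse,
    SwingResponse,
)
from pufval.synthetic_data import GeneratorConfig, generate

DEAD = AnchorPreference.DEAD_OVER_PITS
PITS = AnchorPreference.PITS_OVER_DEAD_OR_INDIFFERENT


def _swing(*vals):
    rating = dict(zip(DIMENSIONS, map(float, vals)))
    most = next(d for d in DIMENSIONS if rating[d] == 100.0)
    return SwingResponse(most_important=most, rating=rating)


class TestNormalizeWeights:
    def test_all_equal_ratings_give_uniform_weights(self):
        w = normalize_weights(_swing(100, 100, 100, 100, 100))
        assert all(w[d] == pytest.approx(0.2) for d in DIMENSIONS)

    def test_degenerate_single_dimension(self):
        w = normalize_weights(_swing(100, 0, 0, 0, 0))
        assert w[Dimension.MO] == 1.0
        assert sum(w.values()) == 1.0

    def test_proportional_to_ratings(self):
        w = normalize_weights(_swing(100, 80, 60, 40, 20))
        expected = [1 / 3, 4 / 15, 1 / 5, 2 / 15, 1 / 15]
        for d, e in zip(DIMENSIONS, expected):
            assert w[d] == pytest.approx(e)

    def test_weights_sum_to_one(self, small_cohort):
        for r in small_cohort:
            assert sum(normalize_weights(r.swing).values()) == pytest.approx(
                1.0, abs=1e-12
            )


class TestLevelProportions:
    def test_endpoints_and_interpolation(self):
        lr = LevelResponse(
            ratings={d: (100.0, 0.0, 25.0) for d in DIMENSIONS}
        )
        lam = level_proportions(lr)
        for d in DIMENSIONS:
            assert lam[(d, 1)] == 0.0
            assert lam[(d, 2)] == 0.0     # r2 = 100, tied with "no problems"
            assert lam[(d, 3)] == 1.0     # r3 = 0, tied with "extreme"
            assert lam[(d, 4)] == 0.75    # (100 - 25) / 100
            assert lam[(d, 5)] == 1.0


class TestImpliedU55:
    @pytest.mark.parametrize(
        "pref, vas, expected",
        [
            (PITS, 0.0, 0.0),     # indifference between dead and 55555
            (PITS, 100.0, 1.0),
            (PITS, 69.0, 0.69),
            (DEAD, 0.0, 0.0),     # continuity with the indifference case
            (DEAD, 50.0, -1.0),
            (DEAD, 60.0, -1.5),   # -60 / 40
        ],
    )
    def test_branches(self, pref, vas, expected):
        assert implied_u55(AnchorResponse(preference=pref, vas=vas)) == pytest.approx(
            expected
        )

    def test_dead_rated_100_raises(self):
        with pytest.raises(AnchorDivisionByZeroError, match="anchor-division-by-zero"):
            implied_u55(AnchorResponse(preference=DEAD, vas=100.0))


@pytest.mark.parametrize(
    "raw, censored", [(-1.5, -1.0), (-1.0, -1.0), (0.3, 0.3), (-100.0, -1.0), (1.0, 1.0)]
)
def test_censor_u55(raw, censored):
    assert censor_u55(raw) == censored


class TestBuildPuf:
    def _respondent(self, base, swing, levels, anchor):
        return replace(base, swing=swing, levels=levels, anchor=anchor)

    def test_hand_computed_example(self, small_cohort):
        # all swings 100 -> w = 0.2 each; all level ratings 50 -> lam = 0.5;
        # dead preferred with a = 50 -> u55_raw = -1 (censoring fixed point);
        # delta[d, 2..4] = (1 - (-1)) * 0.2 * 0.5 = 0.2, delta[d, 5] = 0.4
        r = self._respondent(
            small_cohort[0],
            _swing(100, 100, 100, 100, 100),
            LevelResponse(ratings={d: (50.0, 50.0, 50.0) for d in DIMENSIONS}),
            AnchorResponse(preference=DEAD, vas=50.0),
        )
        puf = build_puf(r)
        assert puf.u55_raw == -1.0
        assert puf.u55 == -1.0
        for d in DIMENSIONS:
            for lev in (2, 3, 4):
                assert puf.decrement(d, lev) == pytest.approx(0.2)
            assert puf.decrement(d, 5) == pytest.approx(0.4)

    def test_flat_puf_warns_and_zeroes_all_decrements(self, small_cohort):
        r = self._respondent(
            small_cohort[0],
            small_cohort[0].swing,
            small_cohort[0].levels,
            AnchorResponse(preference=PITS, vas=100.0),
        )
        with pytest.warns(FlatPUFWarning):
            puf = build_puf(r)
        assert puf.is_flat
        assert np.all(puf.delta == 0.0)
        assert evaluate(puf, parse_state("55555")) == 1.0

    def test_pits_identity(self, small_pufs):
        # 1 - sum_d delta[d, 5] == u55, exactly by construction
        for puf in small_pufs:
            assert 1.0 - puf.delta[:, 4].sum() == pytest.approx(puf.u55, abs=1e-12)

    def test_division_by_zero_propagates(self, study_cohort):
        bad = [r for r in study_cohort if find_exclusions([r])]
        assert len(bad) == 1
        with pytest.raises(AnchorDivisionByZeroError):
            build_puf(bad[0])


class TestEvaluate:
    def test_full_health_is_exactly_one(self, small_pufs):
        s = parse_state("11111")
        for puf in small_pufs:
            assert evaluate(puf, s) == 1.0

    def test_pits_is_exactly_u55(self, small_pufs):
        s = parse_state("55555")
        for puf in small_pufs:
            assert evaluate(puf, s) == pytest.approx(puf.u55, abs=1e-12)

    def test_worked_single_level_decrement(self, small_cohort):
        # equal weights, r2 = 50 everywhere, u55 = 0 (indifference):
        # U(21111) = 1 - 1 * 0.2 * 0.5 = 0.9
        r = replace(
            small_cohort[0],
            swing=_swing(100, 100, 100, 100, 100),
            levels=LevelResponse(ratings={d: (50.0, 30.0, 10.0) for d in DIMENSIONS}),
            anchor=AnchorResponse(preference=PITS, vas=0.0),
        )
        puf = build_puf(r)
        assert evaluate(puf, parse_state("21111")) == pytest.approx(0.9)

    def test_swap_one_dimension_additivity(self, small_pufs):
        # U depends on each dimension's level only through its own delta:
        # changing one dimension changes U by exactly the delta difference
        rng = np.random.default_rng(1)
        for puf in small_pufs[:10]:
            levels = rng.integers(1, 6, size=5)
            base = evaluate(puf, HealthState(tuple(int(v) for v in levels)))
            for d in range(5):
                for new in range(1, 6):
                    other = levels.copy()
                    other[d] = new
                    u = evaluate(puf, HealthState(tuple(int(v) for v in other)))
                    expected = base - (
                        puf.delta[d, new - 1] - puf.delta[d, levels[d] - 1]
                    )
                    assert u == pytest.approx(expected, abs=1e-12)

    def test_monotone_ratings_give_monotone_utilities(self):
        cohort = generate(GeneratorConfig(n=20, seed=9, illogical_rate=0.0))
        for puf in build_pufs(cohort):
            # worsening any single dimension never raises utility
            for d in range(5):
                col = puf.delta[d]
                assert np.all(np.diff(col) >= -1e-12)

    def test_batch_matches_scalar(self, small_pufs):
        rng = np.random.default_rng(3)
        states = [
            HealthState(tuple(int(v) for v in rng.integers(1, 6, 5)))
            for _ in range(20)
        ]
        U = evaluate_batch(small_pufs, states)
        for i, puf in enumerate(small_pufs):
            for j, s in enumerate(states):
                assert U[i, j] == pytest.approx(evaluate(puf, s), abs=1e-12)


def test_oracle_equivalence_small():
    """evaluate() agrees with a single-expression recomputation from the raw
    responses for random respondents and states."""
    cohort = generate(GeneratorConfig(n=25, seed=77, illogical_rate=0.2))
    pufs = build_pufs(cohort)
    rng = np.random.default_rng(8)
    states = [
        HealthState(tuple(int(v) for v in rng.integers(1, 6, 5)))
        for _ in range(50)
    ]
    for r, puf in zip(cohort, pufs):
        s = np.array([r.swing.rating[d] for d in DIMENSIONS])
        if r.anchor.preference is PITS:
            u55 = r.anchor.vas / 100.0
        else:
            u55 = -r.anchor.vas / (100.0 - r.anchor.vas)
        u55 = max(u55, -1.0)
        for state in states:
            oracle = 1.0 - (1.0 - u55) * sum(
                (s[i] / s.sum())
                * ((100.0 - r.levels.rating(d, state.levels[i])) / 100.0)
                for i, d in enumerate(DIMENSIONS)
            )
            assert evaluate(puf, state) == pytest.approx(oracle, abs=1e-12)
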