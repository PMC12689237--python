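"""Group tariff: aggregation of personal utility functions.

The tariff is calculated directly as the arithmetic mean of the individual
anchored decrement tables — no regression step. Confidence intervals come
from a seeded nonparametric percentile bootstrap over respondents (the
default; a t-interval is available as an alternative). The full value set
tabulates the mean utility of all 3125 states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .descriptive_system import DIMENSIONS, Dimension, enumerate_states
from .puf_engine import PersonalUtilityFunction
from .respondent_io import LANGUAGES, Respondent

#: Language subgroups used in the heterogeneity analysis; English and
#: Afrikaans are merged to overcome their individually small samples.
LANGUAGE_GROUPS = {
    "Tswana": ("Tswana",),
    "Zulu": ("Zulu",),
    "Afrikaans/English": ("Afrikaans", "English"),
}

TARIFF_LEVELS = (2, 3, 4, 5)


@dataclass(frozen=True)
class Tariff:
    """Group-level mean anchored decrements with confidence bounds.

    ``mean_delta``, ``ci_low`` and ``ci_high`` have shape (5 dimensions,
    4 levels) for levels 2..5 in canonical dimension order.
    """

    label: str
    n: int
    mean_delta: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    mean_u55: float
    ci_level: float
    ci_method: str
    bootstrap_reps: int
    seed: int

    def decrement(self, dim: Dimension, level: int) -> float:
        return float(self.mean_delta[DIMENSIONS.index(dim), level - 2])

    def to_frame(self, precision: int | None = 4) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(DIMENSIONS):
            for j, lev in enumerate(TARIFF_LEVELS):
                rows.append(
                    {
                        "dimension": d.value,
                        "level": lev,
                        "mean_decrement": self.mean_delta[i, j],
                        "ci_low": self.ci_low[i, j],
                        "ci_high": self.ci_high[i, j],
                        "n": self.n,
                        "cohort": self.label,
                    }
                )
        df = pd.DataFrame(rows)
        if precision is not None:
            for col in ("mean_decrement", "ci_low", "ci_high"):
                df[col] = df[col].round(precision)
        return df


def _delta_matrix(pufs: list[PersonalUtilityFunction]) -> np.ndarray:
    """(n, 5, 4) stack of per-respondent decrements for levels 2..5."""
    return np.stack([p.delta[:, 1:] for p in pufs])


def aggregate(
    pufs: list[PersonalUtilityFunction],
    ci_level: float = 0.95,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    ci_method: str = "bootstrap",
    label: str = "full sample",
) -> Tariff:
    """Mean tariff over a cohort of PUFs.

    ``ci_method`` is ``"bootstrap"`` (seeded nonparametric percentile
    bootstrap over respondents, the default) or ``"t"`` (per-coefficient
    t-interval). The point estimates are identical under either method.
    """
    if len(pufs) < 2:
        raise ValueError("aggregate requires at least 2 personal utility functions")
    if ci_method not in ("bootstrap", "t"):
        raise ValueError(f"unknown ci_method {ci_method!r}")

    deltas = _delta_matrix(pufs)           # (n, 5, 4)
    n = deltas.shape[0]
    mean_delta = deltas.mean(axis=0)
    mean_u55 = float(np.mean([p.u55 for p in pufs]))

    alpha = 1.0 - ci_level
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(bootstrap_reps, n))
        boot_means = deltas[idx].mean(axis=1)  # (reps, 5, 4)
        ci_low = np.quantile(boot_means, alpha / 2, axis=0)
        ci_high = np.quantile(boot_means, 1 - alpha / 2, axis=0)
    else:
        se = deltas.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
        ci_low = mean_delta - tcrit * se
        ci_high = mean_delta + tcrit * se

    # the mean is always inside its own interval, up to float noise
    ci_low = np.minimum(ci_low, mean_delta)
    ci_high = np.maximum(ci_high, mean_delta)

    return Tariff(
        label=label,
        n=n,
        mean_delta=mean_delta,
        ci_low=ci_low,
        ci_high=ci_high,
        mean_u55=mean_u55,
        ci_level=ci_level,
        ci_method=ci_method,
        bootstrap_reps=bootstrap_reps if ci_method == "bootstrap" else 0,
        seed=seed,
    )


@dataclass(frozen=True)
class MonotonicityViolation:
    dimension: Dimension
    step: tuple[int, int]  # (level, level + 1) with a decreasing decrement
    decrease: float        # mean_delta[level] - mean_delta[level + 1] > 0


@dataclass(frozen=True)
class MonotonicityAudit:
    violations: list[MonotonicityViolation]
    #: size of the level-4 -> level-5 step per dimension (the "larger final
    #: step" diagnostic)
    final_step: dict[Dimension, float]

    @property
    def is_monotone(self) -> bool:
        return not self.violations


def monotonicity_audit(t: Tariff) -> MonotonicityAudit:
    """Check that mean decrements never decrease as a level worsens, and
    report each dimension's 4->5 step size."""
    violations = []
    for i, d in enumerate(DIMENSIONS):
        # level 1 has decrement 0 by construction; start the scan there
        seq = np.concatenate([[0.0], t.mean_delta[i]])
        for j in range(4):
            if seq[j + 1] < seq[j]:
                violations.append(
                    MonotonicityViolation(
                        dimension=d,
                        step=(j + 1, j + 2),
                        decrease=float(seq[j] - seq[j + 1]),
                    )
                )
    final_step = {
        d: float(t.mean_delta[i, 3] - t.mean_delta[i, 2])
        for i, d in enumerate(DIMENSIONS)
    }
    return MonotonicityAudit(violations=violations, final_step=final_step)


def full_value_set(t: Tariff, precision: int | None = 4) -> pd.DataFrame:
    """Utilities of all 3125 states under the mean tariff, sorted by code.

    ``utility(s) = 1 - sum_d mean_delta[d, level_d(s)]``; "11111" maps to
    exactly 1 and "55555" to the mean censored u55.
    """
    states = enumerate_states()
    lev = np.array([s.levels for s in states])  # (3125, 5), values 1..5
    # prepend the level-1 zero column so we can index by level directly
    dec = np.concatenate([np.zeros((5, 1)), t.mean_delta], axis=1)  # (5, 5)
    util = 1.0 - sum(dec[d, lev[:, d] - 1] for d in range(5))
    df = pd.DataFrame({"state": [s.code for s in states], "utility": util})
    if precision is not None:
        df["utility"] = df["utility"].round(precision)
    return df


def subgroup_tariffs(
    pufs: list[PersonalUtilityFunction],
    respondents: list[Respondent],
    grouping: str = "language",
    min_size: int = 5,
    ci_level: float = 0.95,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> list[Tariff]:
    """One tariff per home-language group (Tswana, Zulu, Afrikaans/English).

    Groups smaller than ``min_size`` are still estimated but carry a
    small-sample warning. Only respondents present in ``pufs`` (i.e. not
    excluded) contribute.
    """
    if grouping != "language":
        raise ValueError(f"unsupported grouping {grouping!r}")
    lang_by_id: dict[str, str] = {}
    for r in respondents:
        if r.language not in LANGUAGES:
            raise ValueError(f"respondent {r.id}: unknown language {r.language!r}")
        lang_by_id[r.id] = r.language

    tariffs = []
    for gname, members in LANGUAGE_GROUPS.items():
        group = [
            p
            for p in pufs
            if lang_by_id.get(p.respondent_id) in members
        ]
        if not group:
            continue
        if len(group) < min_size:
            warnings.warn(
                f"subgroup {gname!r} has only {len(group)} respondent(s); "
                f"its tariff is reported but imprecise",
                UserWarning,
                stacklevel=2,
            )
        if len(group) == 1:
            # single respondent: degenerate CI equal to the point estimate
            deltas = _delta_matrix(group)
            t = Tariff(
                label=gname,
                n=1,
                mean_delta=deltas[0],
                ci_low=deltas[0],
                ci_high=deltas[0],
                mean_u55=group[0].u55,
                ci_level=ci_level,
                ci_method=ci_method,
                bootstrap_reps=0,
                seed=seed,
            )
        else:
            t = aggregate(
                group,
                ci_level=ci_level,
                bootstrap_reps=bootstrap_reps,
                seed=seed,
                ci_method=ci_method,
                label=gname,
            )
        tariffs.append(t)
    return tariffs
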