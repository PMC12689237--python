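"""Construction of personal utility functions (PUFs).

Each respondent's elicitation data determine an additive utility function
over the EQ-5D-5L descriptive system in three steps:

1. **Dimension weights.** The swing ratings ``s_d`` (most important
   dimension fixed at 100) are normalized to weights ``w_d = s_d / sum(s)``,
   so ``sum_d w_d = 1``. The denominator is at least 100, so normalization
   is always defined.

2. **Level decrement proportions.** Within a dimension, the VAS rating
   ``r_l`` of level ``l`` (with the implied endpoints r1 = 100, r5 = 0) is
   converted to the proportion of that dimension's full decrement incurred
   at level ``l``: ``lam_{d,l} = (100 - r_{d,l}) / 100``, so lam is 0 at
   level 1 and 1 at level 5.

3. **Anchoring on dead = 0.** The dead-vs-55555 task pins the worst state
   to the QALY scale. If the respondent preferred 55555 (or was
   indifferent), dead sits at 0 on the VAS and the 55555 rating ``b`` gives
   ``u(55555) = b / 100`` directly. If the respondent preferred dead, 55555
   sits at 0 and dead is rated ``a``; re-anchoring the VAS triple
   (full health = 100, dead = a, 55555 = 0) so that dead maps to 0 and
   full health to 1 gives ``u(55555) = -a / (100 - a)``, which is
   unbounded below and undefined at a = 100 (dead rated equal to full
   health — the one response that makes a PUF impossible). Each
   respondent's u(55555) is censored at -1 *before* any averaging.

The anchored utility decrement for level ``l`` of dimension ``d`` is then

    delta_{d,l} = (1 - u55) * w_d * lam_{d,l}

and the utility of any state ``s`` with levels ``l_d`` is

    U(s) = 1 - sum_d delta_{d, l_d}

so that U(11111) = 1 exactly and U(55555) = u55 exactly.

All arithmetic is double precision; nothing is rounded until export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptive_system import DIMENSIONS, Dimension, HealthState
from .respondent_io import (
    AnchorPreference,
    AnchorResponse,
    LevelResponse,
    Respondent,
    SwingResponse,
)


class AnchorDivisionByZeroError(ValueError):
    """Dead rated equal to full health (a = 100): the anchoring transform
    -a/(100-a) is undefined and no PUF can be built."""

    def __init__(self, respondent_id: str = ""):
        who = f" (respondent {respondent_id})" if respondent_id else ""
        super().__init__(
            f"anchor-division-by-zero{who}: dead rated equal to full health "
            f"(a = 100); the implied utility of 55555 is undefined"
        )


class FlatPUFWarning(UserWarning):
    """55555 valued at full health (b = 100): every decrement is zero."""


def normalize_weights(swing: SwingResponse) -> dict[Dimension, float]:
    """Normalized dimension weights ``w_d = s_d / sum(s)``; sums to 1."""
    total = sum(swing.rating[d] for d in DIMENSIONS)
    return {d: swing.rating[d] / total for d in DIMENSIONS}


def level_proportions(levels: LevelResponse) -> dict[tuple[Dimension, int], float]:
    """Level decrement proportions ``lam_{d,l} = (100 - r_{d,l}) / 100``.

    Includes the implied endpoints: lam is 0 at level 1 and 1 at level 5.
    """
    lam: dict[tuple[Dimension, int], float] = {}
    for d in DIMENSIONS:
        for lev in (1, 2, 3, 4, 5):
            lam[(d, lev)] = (100.0 - levels.rating(d, lev)) / 100.0
    return lam


def implied_u55(anchor: AnchorResponse, respondent_id: str = "") -> float:
    """Implied (uncensored) utility of 55555 on the dead = 0 scale.

    ``b/100`` in [0, 1] when 55555 was preferred over dead (or indifferent);
    ``-a/(100-a)`` in (-inf, 0] when dead was preferred. Raises
    :class:`AnchorDivisionByZeroError` when a = 100.
    """
    if anchor.preference is AnchorPreference.PITS_OVER_DEAD_OR_INDIFFERENT:
        return anchor.vas / 100.0
    if anchor.vas == 100.0:
        raise AnchorDivisionByZeroError(respondent_id)
    return -anchor.vas / (100.0 - anchor.vas)


def censor_u55(u55_raw: float) -> float:
    """Censor a respondent's implied u(55555) at -1 (applied per respondent,
    before any averaging)."""
    return max(u55_raw, -1.0)


@dataclass(frozen=True)
class PersonalUtilityFunction:
    """One respondent's anchored additive utility function.

    Arrays are indexed by canonical dimension order; ``lam`` and ``delta``
    have shape (5 dimensions, 5 levels) with the level axis 0-based (column
    ``l - 1`` holds level ``l``).
    """

    respondent_id: str
    w: np.ndarray           # (5,) normalized weights, sums to 1
    lam: np.ndarray         # (5, 5) level decrement proportions
    u55_raw: float          # implied utility of 55555, may be < -1
    u55: float              # censored at -1
    delta: np.ndarray       # (5, 5) anchored decrements (1-u55) * w * lam

    @property
    def is_flat(self) -> bool:
        """True when u55 = 1 (b = 100): all decrements vanish."""
        return self.u55 == 1.0

    def weight(self, dim: Dimension) -> float:
        return float(self.w[DIMENSIONS.index(dim)])

    def decrement(self, dim: Dimension, level: int) -> float:
        return float(self.delta[DIMENSIONS.index(dim), level - 1])

    def decrement_table(self, precision: int | None = 4) -> pd.DataFrame:
        """Long-form export: one row per (dimension, level 2..5)."""
        rows = []
        for i, d in enumerate(DIMENSIONS):
            for lev in (2, 3, 4, 5):
                rows.append(
                    {
                        "respondent_id": self.respondent_id,
                        "dimension": d.value,
                        "level": lev,
                        "w": self.w[i],
                        "lam": self.lam[i, lev - 1],
                        "delta": self.delta[i, lev - 1],
                        "u55": self.u55,
                    }
                )
        df = pd.DataFrame(rows)
        if precision is not None:
            for col in ("w", "lam", "delta", "u55"):
                df[col] = df[col].round(precision)
        return df


def build_puf(r: Respondent) -> PersonalUtilityFunction:
    """Assemble a respondent's PUF from their raw responses.

    Deterministic; raises :class:`AnchorDivisionByZeroError` for the a = 100
    degeneracy and warns (:class:`FlatPUFWarning`) for the valid-but-flat
    b = 100 case.
    """
    w_map = normalize_weights(r.swing)
    lam_map = level_proportions(r.levels)
    u55_raw = implied_u55(r.anchor, r.id)
    u55 = censor_u55(u55_raw)

    w = np.array([w_map[d] for d in DIMENSIONS])
    lam = np.array([[lam_map[(d, lev)] for lev in (1, 2, 3, 4, 5)] for d in DIMENSIONS])
    delta = (1.0 - u55) * w[:, None] * lam
    if u55 == 1.0:
        warnings.warn(
            f"respondent {r.id}: 55555 rated at full health (b = 100); "
            f"the PUF is flat (all decrements zero)",
            FlatPUFWarning,
            stacklevel=2,
        )
    return PersonalUtilityFunction(
        respondent_id=r.id, w=w, lam=lam, u55_raw=u55_raw, u55=u55, delta=delta
    )


def build_pufs(cohort: list[Respondent]) -> list[PersonalUtilityFunction]:
    """Build PUFs for every buildable respondent (excluded ones must already
    have been removed; see :func:`pufval.qc.find_exclusions`)."""
    return [build_puf(r) for r in cohort]


def evaluate(puf: PersonalUtilityFunction, state: HealthState) -> float:
    """Utility of ``state`` under ``puf``: ``1 - sum_d delta[d, l_d]``."""
    idx = np.array(state.levels) - 1
    return float(1.0 - puf.delta[np.arange(5), idx].sum())


def evaluate_batch(
    pufs: list[PersonalUtilityFunction], states: list[HealthState]
) -> np.ndarray:
    """Utility matrix of shape (len(pufs), len(states))."""
    delta = np.stack([p.delta for p in pufs])            # (n, 5, 5)
    lev = np.array([s.levels for s in states]) - 1       # (k, 5)
    out = np.ones((len(pufs), len(states)))
    for d in range(5):
        out -= delta[:, d, :][:, lev[:, d]]
    return out
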