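"""Preference-heterogeneity analyses.

Two views of the same phenomenon: the distribution of each respondent's
implied utility of the worst state (compressed vs stretched preferences,
split by whether they preferred being dead to 55555), and per-respondent
utility profiles over a random sample of health states ranked best-to-worst
by the group mean, with each respondent's Euclidean distance from the group
function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptive_system import (
    FULL_HEALTH,
    N_STATES,
    PITS,
    HealthState,
    enumerate_states,
)
from .puf_engine import PersonalUtilityFunction, evaluate_batch

COMPRESSED = "compressed"
STRETCHED = "stretched"


@dataclass(frozen=True)
class StateSample:
    """A without-replacement sample of states, always anchored by "11111"
    and "55555"."""

    states: list[HealthState]
    seed: int

    def __len__(self) -> int:
        return len(self.states)


def sample_states(k: int, seed: int = 0) -> StateSample:
    """Draw ``k`` distinct states uniformly without replacement, always
    force-including full health and the pits state."""
    if not (1 <= k <= N_STATES):
        raise ValueError(f"k must be in 1..{N_STATES}, got {k}")
    all_states = enumerate_states()
    if k == 1:
        return StateSample(states=[FULL_HEALTH], seed=seed)
    forced = {0, N_STATES - 1}
    rng = np.random.default_rng(seed)
    pool = [i for i in range(N_STATES) if i not in forced]
    extra = rng.choice(len(pool), size=k - 2, replace=False)
    idx = sorted(forced | {pool[i] for i in extra})
    return StateSample(states=[all_states[i] for i in idx], seed=seed)


@dataclass
class HeterogeneityResult:
    sample: StateSample
    utilities: np.ndarray        # (n respondents, k states)
    group_mean: np.ndarray       # (k,)
    ranking: np.ndarray          # permutation of 0..k-1, best state first
    distances: dict[str, float]  # respondent -> Euclidean distance from mean
    latent_group: dict[str, str]
    u55_raw: dict[str, float]
    u55: dict[str, float]

    def respondent_frame(self, precision: int | None = 4) -> pd.DataFrame:
        ids = list(self.distances)
        df = pd.DataFrame(
            {
                "id": ids,
                "u55_raw": [self.u55_raw[i] for i in ids],
                "u55": [self.u55[i] for i in ids],
                "latent_group": [self.latent_group[i] for i in ids],
                "distance": [self.distances[i] for i in ids],
            }
        )
        if precision is not None:
            for col in ("u55_raw", "u55", "distance"):
                df[col] = df[col].round(precision)
        return df

    def state_frame(self, precision: int | None = 4) -> pd.DataFrame:
        order = self.ranking
        df = pd.DataFrame(
            {
                "state": [self.sample.states[i].code for i in order],
                "group_mean": self.group_mean[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )
        if precision is not None:
            df["group_mean"] = df["group_mean"].round(precision)
        return df


def latent_groups(pufs: list[PersonalUtilityFunction]) -> dict[str, str]:
    """Compressed/stretched classification by the censored u(55555).

    ``stretched`` iff u55 < 0 (the respondent preferred dead over 55555
    strongly enough to push the state below dead); u55 = 0 is assigned to
    ``compressed``.
    """
    return {
        p.respondent_id: (STRETCHED if p.u55 < 0 else COMPRESSED) for p in pufs
    }


def utility_profile(
    pufs: list[PersonalUtilityFunction], sample: StateSample
) -> HeterogeneityResult:
    """Per-respondent utilities on the sampled states, group mean, ranking
    and distances from the group function."""
    if not pufs:
        raise ValueError("utility_profile requires at least one PUF")
    U = evaluate_batch(pufs, sample.states)
    group_mean = U.mean(axis=0)
    codes = [s.code for s in sample.states]
    # rank best -> worst by group mean; ties broken lexicographically by code
    ranking = np.array(
        sorted(range(len(codes)), key=lambda i: (-group_mean[i], codes[i]))
    )
    dist = np.sqrt(((U - group_mean) ** 2).sum(axis=1))
    return HeterogeneityResult(
        sample=sample,
        utilities=U,
        group_mean=group_mean,
        ranking=ranking,
        distances={p.respondent_id: float(d) for p, d in zip(pufs, dist)},
        latent_group=latent_groups(pufs),
        u55_raw={p.respondent_id: p.u55_raw for p in pufs},
        u55={p.respondent_id: p.u55 for p in pufs},
    )


@dataclass(frozen=True)
class U55GapSummary:
    """Summary of the distribution of implied u(55555): the mixture means
    and the endpoints of the gap between the negative (stretched) and
    positive (compressed) clusters."""

    mean_u55_raw: float
    mean_u55: float
    n_stretched: int
    n_compressed: int
    min_positive_u55: float | None
    max_negative_u55: float | None


def u55_gap_summary(pufs: list[PersonalUtilityFunction]) -> U55GapSummary:
    if not pufs:
        raise ValueError("u55_gap_summary requires at least one PUF")
    raw = np.array([p.u55_raw for p in pufs])
    cen = np.array([p.u55 for p in pufs])
    groups = latent_groups(pufs)
    n_stretched = sum(1 for g in groups.values() if g == STRETCHED)
    positive = cen[cen > 0]
    negative = cen[cen < 0]
    return U55GapSummary(
        mean_u55_raw=float(raw.mean()),
        mean_u55=float(cen.mean()),
        n_stretched=n_stretched,
        n_compressed=len(pufs) - n_stretched,
        min_positive_u55=float(positive.min()) if positive.size else None,
        max_negative_u55=float(negative.max()) if negative.size else None,
    )


# ---------------------------------------------------------------------------
# Optional figure rendering (data tables above are the contract)

def plot_profiles(result: HeterogeneityResult, path: str) -> None:
    """Line plot of individual utility profiles over the ranked states,
    coloured by distance from the group mean; group mean as a thick line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = result.ranking
    x = np.arange(len(order))
    dists = np.array([result.distances[i] for i in result.distances])
    dmax = dists.max() or 1.0
    fig, ax = plt.subplots(figsize=(9, 5))
    cmap = plt.get_cmap("viridis")
    for row, rid in zip(result.utilities, result.distances):
        ax.plot(
            x,
            row[order],
            lw=0.6,
            alpha=0.6,
            color=cmap(result.distances[rid] / dmax),
        )
    ax.plot(x, result.group_mean[order], lw=2.5, color="crimson", label="group mean")
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("health states, ranked best to worst (group preference)")
    ax.set_ylabel("utility")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_u55_histogram(pufs: list[PersonalUtilityFunction], path: str) -> None:
    """Histogram of censored u(55555) values showing the compressed/stretched
    gap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = [p.u55 for p in pufs]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(vals, bins=np.linspace(-1.0, 1.0, 41), color="steelblue")
    ax.set_xlabel("implied utility of 55555 (censored at -1)")
    ax.set_ylabel("respondents")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
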