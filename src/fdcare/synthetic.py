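"""Synthetic panel-data generator with known ground truth.

Emulates the structure of a CHARLS-like ageing panel: individuals with a
sex and a 10-year age band are followed at survey waves roughly two years
apart; at each wave the observed record is the current FC state (1-5, or 6
once dead) plus a vector of 29 categorical functional indicators emitted
from the latent state's class-conditional distributions.

Latent trajectories are simulated as a continuous-time Markov chain under
sex/age-specific intensity matrices by exact event-time (Gillespie-style)
simulation -- exponential holding times and competing-risk destination
draws -- so the generated panels are exactly Markov at every horizon.
Age is frozen at the entry band within a panel; band promotion belongs to
the projection stage.  Missing data is never generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .states import AGE_BANDS, DEATH, N_STATES, SEXES

#: sentinel stored in indicator columns for waves observed in the death state
MISSING_INDICATOR = -1


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _check_prob_vector(p, what, tol=1e-12):
    p = np.asarray(p, dtype=float)
    if np.any(p < -tol):
        raise ConfigurationError(f"{what} has negative entries")
    if abs(p.sum() - 1.0) > max(tol, 1e-12):
        raise ConfigurationError(f"{what} sums to {p.sum()!r}, expected 1")
    return p


def _check_generator(Q, what):
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (N_STATES, N_STATES):
        raise ConfigurationError(f"{what} must be {N_STATES}x{N_STATES}")
    off = Q[~np.eye(N_STATES, dtype=bool)]
    if np.any(off < 0):
        raise ConfigurationError(f"{what} has negative off-diagonal intensity")
    if np.max(np.abs(Q.sum(axis=1))) > 1e-10:
        raise ConfigurationError(f"{what} rows do not sum to 0")
    if np.any(Q[DEATH - 1] != 0):
        raise ConfigurationError(f"{what} absorbing (death) row must be 0")
    return Q


@dataclass
class SimConfig:
    """Ground-truth configuration for a synthetic cohort.

    ``true_intensities`` and ``initial_state_distribution`` are keyed by
    (sex, age_band) stratum; initial distributions cover living states 1-5.
    ``indicator_model`` is an :class:`~fdcare.lca.LCAParams` whose class k
    (0-based) is the measurement model of latent state k+1; ``None`` skips
    indicator emission.
    """

    n_individuals: int
    wave_times: Sequence[float]
    sex_proportion_female: float
    age_band_proportions: Mapping[str, float]
    true_intensities: Mapping[tuple, np.ndarray]
    initial_state_distribution: Mapping[tuple, np.ndarray]
    indicator_model: object | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 0:
            raise ConfigurationError("n_individuals must be >= 0")
        wt = np.asarray(self.wave_times, dtype=float)
        if wt.size == 0 or np.any(np.diff(wt) <= 0):
            raise ConfigurationError("wave_times must be non-empty and strictly increasing")
        if not 0.0 <= self.sex_proportion_female <= 1.0:
            raise ConfigurationError("sex_proportion_female must lie in [0, 1]")
        _check_prob_vector(
            [self.age_band_proportions[b] for b in AGE_BANDS], "age_band_proportions"
        )
        for stratum in ((s, b) for s in SEXES for b in AGE_BANDS):
            _check_generator(self.true_intensities[stratum], f"true_intensities{stratum}")
            _check_prob_vector(
                self.initial_state_distribution[stratum],
                f"initial_state_distribution{stratum}",
            )


@dataclass
class PanelDataset:
    """Long-format panel of state observations (one row per id x wave).

    ``data`` columns: id, sex, age_band, time, state, and optionally
    ind_01..ind_NN indicator responses (integer codes, -1 once dead).
    """

    data: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return self.data["id"].nunique()

    @property
    def indicator_columns(self) -> list:
        return [c for c in self.data.columns if c.startswith("ind_")]

    def validate(self) -> None:
        g = self.data.groupby("id", sort=False)
        if (g.size() < 1).any():
            raise ValueError("every individual needs at least one observation")
        if (g["time"].diff().dropna() <= 0).any():
            raise ValueError("observation times must be strictly increasing per individual")
        for _, sub in g:
            s = sub["state"].to_numpy()
            dead = np.flatnonzero(s == DEATH)
            if dead.size and np.any(s[dead[0]:] != DEATH):
                raise ValueError("observation after death must remain in the death state")
        if not self.data["state"].isin(range(1, N_STATES + 1)).all():
            raise ValueError("states must lie in 1..6")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PanelDataset":
        return cls(pd.read_csv(path))


def simulate_ctmc_path(Q: np.ndarray, state0: int, t_end: float, rng) -> tuple:
    """Exact event-time simulation of one trajectory on states 1..6.

    Returns (event_times, event_states) with the initial condition at t=0
    included; simulation stops at absorption or ``t_end``.
    """
    times = [0.0]
    states = [state0]
    t, s = 0.0, state0
    while True:
        rate = -Q[s - 1, s - 1]
        if rate <= 0:  # absorbing (death) or frozen state
            break
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        probs = Q[s - 1].clip(min=0.0)
        probs[s - 1] = 0.0
        s = int(rng.choice(N_STATES, p=probs / probs.sum())) + 1
        times.append(t)
        states.append(s)
    return np.array(times), np.array(states, dtype=int)


def _state_at(times, states, t):
    idx = np.searchsorted(times, t, side="right") - 1
    return int(states[idx])


def emit_indicators(states: Sequence[int], params, seed) -> np.ndarray:
    """Draw one indicator vector per latent state in ``states``.

    Each indicator j is drawn independently from the class-conditional
    categorical distribution ``params.rho[j][class]`` where class = state-1.
    Returns an (n_obs, n_indicators) integer array; empty input gives an
    empty (0, J) matrix.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = np.asarray(states, dtype=int)
    J = params.n_indicators
    out = np.empty((states.size, J), dtype=int)
    if states.size == 0:
        return out
    if states.min() < 1 or states.max() > params.K:
        raise ValueError(
            f"latent state outside the measurement model's classes 1..{params.K}"
        )
    for j in range(J):
        rho_j = np.asarray(params.rho[j])  # (K, C_j)
        cdf = rho_j.cumsum(axis=1)[states - 1]  # (n, C_j)
        u = rng.random(states.size)
        out[:, j] = (u[:, None] > cdf[:, :-1]).sum(axis=1)
    return out


def generate_cohort(config: SimConfig) -> PanelDataset:
    """Simulate a full synthetic panel under ``config``; reproducible from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    wave_times = np.asarray(config.wave_times, dtype=float)
    t_end = wave_times[-1]

    sexes = np.where(
        rng.random(config.n_individuals) < config.sex_proportion_female, "female", "male"
    )
    band_p = np.array([config.age_band_proportions[b] for b in AGE_BANDS])
    bands = rng.choice(AGE_BANDS, size=config.n_individuals, p=band_p)

    rows = []
    has_ind = config.indicator_model is not None
    for i in range(config.n_individuals):
        stratum = (sexes[i], bands[i])
        init = np.asarray(config.initial_state_distribution[stratum], dtype=float)
        state0 = int(rng.choice(len(init), p=init)) + 1
        Q = np.asarray(config.true_intensities[stratum], dtype=float)
        times, states = simulate_ctmc_path(Q, state0, t_end, rng)
        obs = [_state_at(times, states, t) for t in wave_times]
        for t, s in zip(wave_times, obs):
            rows.append((i, sexes[i], bands[i], float(t), s))

    df = pd.DataFrame(rows, columns=["id", "sex", "age_band", "time", "state"])
    if has_ind:
        params = config.indicator_model
        J = params.n_indicators
        ind = np.full((len(df), J), MISSING_INDICATOR, dtype=int)
        living = df["state"].to_numpy() != DEATH
        ind[living] = emit_indicators(df.loc[living, "state"].to_numpy(), params, rng)
        for j in range(J):
            df[f"ind_{j + 1:02d}"] = ind[:, j]
    return PanelDataset(df)
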