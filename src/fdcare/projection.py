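"""Time-rescaling of transition matrices and cohort population projection.

An empirical transition matrix P observed over an interval of delta years
is annualized through the embedding relation P(h) = exp(h * Q) with
Q = log(P)/delta (principal matrix logarithm), so e.g. a 3-year matrix
yields a 10-year one as exp(10 * log P(3) / 3).  Empirical matrices need
not be embeddable -- the principal logarithm can carry small negative
off-diagonal rates -- in which case Q is repaired by clipping negatives to
zero and resetting the diagonal, with the repair magnitude reported.

The projection advances sex x age-band cohorts of state-specific counts in
5-year steps using exp(5Q) of the cohort's current band, promotes cohorts
from the 60-69 band to >=70 ten years after entry, injects new entrants
into the 60-69 band at decade boundaries with a configurable initial state
distribution, and accumulates deaths (state 6) as an absorbing total.
A community/home care share (the "90-7-3" policy's 97%) can be applied to
the living-state counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import logm

from .multistate import transition_probability
from .states import DEATH, N_STATES

log = logging.getLogger(__name__)


class EmbeddingError(ValueError):
    """The matrix has no principal-branch generator (log undefined/complex)."""


def embed_generator(
    P: np.ndarray, delta: float, repair_policy: str = "clip"
) -> tuple:
    """Generator Q = log(P)/delta with optional repair of negative rates.

    Returns ``(Q, repair_magnitude)`` where the magnitude is the total
    absolute off-diagonal rate clipped (0 for embeddable P).
    ``repair_policy``: "clip" (default) zeroes negative off-diagonals and
    resets the diagonal to minus the row sum; "error" raises instead.
    """
    P = np.asarray(P, dtype=float)
    if delta <= 0:
        raise ValueError("delta must be > 0")
    n = P.shape[0]
    if P.shape != (n, n):
        raise ValueError("P must be square")
    if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-6:
        raise ValueError("P must be row-stochastic")
    eig = np.linalg.eigvals(P)
    if np.any((np.abs(eig.imag) < 1e-12) & (eig.real <= 0)):
        # a real non-positive eigenvalue puts log(P) off the principal branch
        raise EmbeddingError(
            "P has a non-positive real eigenvalue; no principal-branch generator"
        )
    L = logm(P)
    if np.max(np.abs(L.imag)) > 1e-8:
        raise EmbeddingError("matrix logarithm is not real; P is not embeddable")
    Q = L.real / delta

    off = Q[~np.eye(n, dtype=bool)]
    neg = off[off < 0]
    repair = float(-neg.sum()) if neg.size else 0.0
    if repair > 1e-10:
        if repair_policy == "error":
            raise EmbeddingError(
                f"negative off-diagonal rates (total {repair:.3g}); P not embeddable"
            )
        log.info("embedding repair: clipped %.3g of negative off-diagonal rate", repair)
        Q = Q.copy()
        diag = np.eye(n, dtype=bool)
        Q[(Q < 0) & ~diag] = 0.0
    else:
        repair = 0.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, repair


def rescale_transition(P: np.ndarray, delta: float, h: float) -> np.ndarray:
    """P(h) = exp(h * log(P(delta))/delta); returns P itself when h = delta."""
    Q, _ = embed_generator(P, delta)
    return transition_probability(Q, h)


@dataclass
class EntrantsSchedule:
    """New entrants (millions) into the 60-69 band, keyed (period, sex)."""

    counts: dict

    def __post_init__(self):
        for k, v in self.counts.items():
            if v < 0:
                raise ValueError(f"entrant count for {k} must be >= 0")

    def get(self, period, sex) -> float:
        return float(self.counts.get((period, sex), 0.0))


def project_population(
    initial_counts: pd.DataFrame,
    Q_by_stratum: dict,
    periods=(2020, 2025, 2030, 2035),
    entrants: EntrantsSchedule | None = None,
    entrant_distribution: dict | None = None,
    entrant_periods=(2020, 2030),
    band_promotion_age: float = 10.0,
) -> pd.DataFrame:
    """Cohort-component projection of state-specific population counts.

    ``initial_counts``: tidy frame (sex, age_band, state, millions) at the
    first period.  ``Q_by_stratum``: per (sex, age_band) 6x6 per-year
    generator.  ``entrant_distribution``: per sex, probability vector over
    states 1-5 for new 60-69 entrants.  Entrants are injected at
    ``entrant_periods`` (decade boundaries).  Cohorts are promoted to the
    >=70 band ``band_promotion_age`` years after entering 60-69; deaths
    accumulate in state 6.  Returns a tidy frame
    (period, sex, age_band, state, millions).
    """
    periods = list(periods)
    step = periods[1] - periods[0] if len(periods) > 1 else 5
    if any(b - a != step for a, b in zip(periods, periods[1:])):
        raise ValueError("periods must be evenly spaced")
    from .states import AGE_BANDS, SEXES

    for stratum in ((s, b) for s in SEXES for b in AGE_BANDS):
        if stratum not in Q_by_stratum:
            raise ValueError(f"missing stratum {stratum} in Q_by_stratum")
    if (initial_counts["millions"] < 0).any():
        raise ValueError("negative initial counts")

    P_step = {k: transition_probability(Q, step) for k, Q in Q_by_stratum.items()}

    # cohorts: list of dicts with sex, band-entry period (for promotion), band, state vector
    cohorts = []
    for (sex, band), sub in initial_counts.groupby(["sex", "age_band"]):
        v = np.zeros(N_STATES)
        for _, row in sub.iterrows():
            v[int(row["state"]) - 1] = row["millions"]
        cohorts.append(dict(sex=sex, band=band, entered=periods[0], v=v))

    def add_entrants(period):
        if entrants is None:
            return
        for sex in {c["sex"] for c in cohorts} | {"male", "female"}:
            n = entrants.get(period, sex)
            if n <= 0:
                continue
            dist = np.asarray(entrant_distribution[sex], dtype=float)
            v = np.zeros(N_STATES)
            v[: dist.size] = n * dist
            cohorts.append(dict(sex=sex, band="60-69", entered=period, v=v))

    rows = []

    def record(period):
        agg = {}
        for c in cohorts:
            key = (c["sex"], c["band"])
            agg.setdefault(key, np.zeros(N_STATES))
            agg[key] += c["v"]
        for (sex, band), v in sorted(agg.items()):
            for s in range(1, N_STATES + 1):
                rows.append(dict(period=period, sex=sex, age_band=band,
                                 state=s, millions=float(v[s - 1])))

    if periods[0] in (entrant_periods or ()):
        add_entrants(periods[0])
    record(periods[0])
    for prev, period in zip(periods, periods[1:]):
        for c in cohorts:
            c["v"] = c["v"] @ P_step[(c["sex"], c["band"])]
            if c["band"] == "60-69" and (period - c["entered"]) >= band_promotion_age:
                c["band"] = "70+"
        if period in (entrant_periods or ()):
            add_entrants(period)
        record(period)
    return pd.DataFrame(rows)


def apply_care_pattern(projection: pd.DataFrame, community_home_share: float = 0.97):
    """Scale living-state counts by the community/home care share (97%).

    State-6 (death) counts are untouched.  Returns a new frame with a
    ``care_share`` column recording the provenance.
    """
    if not 0.0 <= community_home_share <= 1.0:
        raise ValueError("community_home_share must lie in [0, 1]")
    out = projection.copy()
    living = out["state"] != DEATH
    out.loc[living, "millions"] = out.loc[living, "millions"] * community_home_share
    out["care_share"] = community_home_share
    return out
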