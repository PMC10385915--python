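"""Embedding, rescaling, and cohort projection."""

import numpy as np
import pandas as pd
import pytest

from fdcare.fixtures import fixture_transition_matrix
from fdcare.multistate import transition_probability
from fdcare.projection import (
    EmbeddingError,
    EntrantsSchedule,
    apply_care_pattern,
    embed_generator,
    project_population,
    rescale_transition,
)


@pytest.fixture(scope="module")
def valid_Q():
    rng = np.random.default_rng(3)
    Q = rng.uniform(0.05, 0.3, (6, 6))
    Q[5] = 0.0
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class TestEmbedding:
    def test_identity_gives_zero_generator(self):
        Q, repair = embed_generator(np.eye(4), delta=2.0)
        assert np.abs(Q).max() < 1e-12 and repair == 0.0

    def test_round_trip_recovers_known_generator(self, valid_Q):
        P = transition_probability(valid_Q, 2.0)
        Q, repair = embed_generator(P, 2.0)
        assert np.abs(Q - valid_Q).max() < 1e-8
        assert repair == 0.0

    def test_two_state_triangular_closed_form(self):
        P = np.array([[np.exp(-0.6), 1 - np.exp(-0.6)], [0.0, 1.0]])
        Q, _ = embed_generator(P, delta=3.0)
        assert Q[0, 1] == pytest.approx(0.2, abs=1e-12)

    def test_non_positive_eigenvalue_rejected(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])  # eigenvalue -1
        with pytest.raises(EmbeddingError):
            embed_generator(P, 1.0)

    def test_non_stochastic_input_rejected(self):
        with pytest.raises(ValueError):
            embed_generator(np.array([[0.5, 0.4], [0.0, 1.0]]), 1.0)

    def test_repair_clips_and_rebalances_printed_matrix(self):
        # the male >=70 one-year fixture matrix is quasi-embeddable: its
        # principal log exists but carries negative off-diagonal rates
        P = fixture_transition_matrix("T5", "male", "70+")
        P = P / P.sum(axis=1, keepdims=True)
        Q, repair = embed_generator(P, 1.0)
        assert repair > 0
        off = Q[~np.eye(6, dtype=bool)]
        assert (off >= 0).all()
        assert np.abs(Q.sum(axis=1)).max() < 1e-10

    def test_repair_policy_error_raises(self):
        P = fixture_transition_matrix("T5", "male", "70+")
        P = P / P.sum(axis=1, keepdims=True)
        with pytest.raises(EmbeddingError):
            embed_generator(P, 1.0, repair_policy="error")


class TestRescaling:
    def test_same_horizon_returns_input(self, valid_Q):
        P = transition_probability(valid_Q, 3.0)
        assert np.abs(rescale_transition(P, 3.0, 3.0) - P).max() < 1e-8

    def test_double_horizon_is_matrix_square(self, valid_Q):
        P = transition_probability(valid_Q, 3.0)
        assert np.abs(rescale_transition(P, 3.0, 6.0) - P @ P).max() < 1e-8

    def test_two_state_rescale_closed_form(self):
        P3 = np.array([[np.exp(-0.6), 1 - np.exp(-0.6)], [0.0, 1.0]])
        P10 = rescale_transition(P3, 3.0, 10.0)
        assert P10[0, 0] == pytest.approx(np.exp(-2.0), abs=1e-10)


def _toy_Q(rate=0.1):
    Q = np.zeros((6, 6))
    Q[3, 5] = rate
    Q[3, 3] = -rate
    return Q


def _init(millions=1.0, state=4):
    return pd.DataFrame([dict(sex="male", age_band="60-69", state=state,
                              millions=millions)])


def _strata(Q):
    return {("male", "60-69"): Q, ("male", "70+"): Q,
            ("female", "60-69"): Q, ("female", "70+"): Q}


class TestProjection:
    def test_identity_transitions_keep_counts_constant(self):
        proj = project_population(_init(), _strata(np.zeros((6, 6))))
        by_period = proj.groupby("period")["millions"].sum()
        assert np.allclose(by_period, 1.0)
        s4 = proj[(proj.state == 4)].groupby("period")["millions"].sum()
        assert np.allclose(s4, 1.0)

    def test_single_step_survival_closed_form(self):
        proj = project_population(_init(), _strata(_toy_Q(0.1)),
                                  periods=(2020, 2025))
        at = proj[proj.period == 2025].groupby("state")["millions"].sum()
        assert at[4] == pytest.approx(np.exp(-0.5), abs=1e-12)
        assert at[6] == pytest.approx(1 - np.exp(-0.5), abs=1e-12)

    def test_closed_cohort_conserves_persons(self, valid_Q):
        proj = project_population(_init(2.5), _strata(valid_Q))
        tot = proj.groupby("period")["millions"].sum()
        assert np.abs(tot - 2.5).max() < 1e-6

    def test_projection_is_linear_in_inputs(self, valid_Q):
        ent = EntrantsSchedule({(2030, "male"): 3.0})
        dist = {"male": np.array([0.2, 0.2, 0.2, 0.2, 0.2]),
                "female": np.full(5, 0.2)}
        p1 = project_population(_init(1.0), _strata(valid_Q), entrants=ent,
                                entrant_distribution=dist)
        ent2 = EntrantsSchedule({(2030, "male"): 6.0})
        p2 = project_population(_init(2.0), _strata(valid_Q), entrants=ent2,
                                entrant_distribution=dist)
        merged = p1.merge(p2, on=["period", "sex", "age_band", "state"])
        assert np.allclose(2 * merged["millions_x"], merged["millions_y"])

    def test_deaths_accumulate_monotonically(self, valid_Q):
        proj = project_population(_init(), _strata(valid_Q))
        d = proj[proj.state == 6].groupby("period")["millions"].sum()
        assert (np.diff(d.to_numpy()) >= -1e-12).all()

    def test_band_promotion_after_ten_years(self):
        proj = project_population(_init(), _strata(_toy_Q(0.0)))
        in_young = proj[(proj.age_band == "60-69") & (proj.state == 4)]
        by_period = in_young.groupby("period")["millions"].sum()
        assert by_period.get(2025, 0.0) == pytest.approx(1.0)
        # promoted at the 2030 step (10 years after entry)
        assert by_period.get(2030, 0.0) == pytest.approx(0.0, abs=1e-12)
        old = proj[(proj.age_band == "70+") & (proj.state == 4)]
        assert old.groupby("period")["millions"].sum()[2030] == pytest.approx(1.0)

    def test_entrants_join_young_band_with_given_distribution(self):
        ent = EntrantsSchedule({(2030, "female"): 4.0})
        dist = {"female": np.array([0.5, 0.5, 0.0, 0.0, 0.0]),
                "male": np.full(5, 0.2)}
        proj = project_population(_init(0.0), _strata(_toy_Q(0.0)),
                                  entrants=ent, entrant_distribution=dist)
        f = proj[(proj.period == 2030) & (proj.sex == "female")
                 & (proj.age_band == "60-69")].set_index("state")["millions"]
        assert f[1] == pytest.approx(2.0) and f[2] == pytest.approx(2.0)

    def test_missing_stratum_and_negative_counts_raise(self, valid_Q):
        with pytest.raises(ValueError):
            project_population(_init(), {("male", "60-69"): valid_Q})
        with pytest.raises(ValueError):
            project_population(_init(-1.0), _strata(valid_Q))


class TestCarePattern:
    def test_share_values(self, valid_Q):
        proj = project_population(_init(), _strata(valid_Q))
        unchanged = apply_care_pattern(proj, 1.0)
        assert np.allclose(unchanged["millions"], proj["millions"])
        scaled = apply_care_pattern(proj, 0.97)
        living = proj["state"] != 6
        assert np.allclose(scaled.loc[living, "millions"],
                           0.97 * proj.loc[living, "millions"])
        assert np.allclose(scaled.loc[~living, "millions"],
                           proj.loc[~living, "millions"])
        zero = apply_care_pattern(proj, 0.0)
        assert (zero.loc[living, "millions"] == 0).all()

    def test_invalid_share_raises(self, valid_Q):
        proj = project_population(_init(), _strata(valid_Q))
        with pytest.raises(ValueError):
            apply_care_pattern(proj, 1.2)
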