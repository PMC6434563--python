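"""Bioenergetic ODE core: functional response, derivatives, season
integration and multi-year simulation."""

import numpy as np
import pytest

from fishweb import dynamics as dyn
from fishweb import trophic, webgen
from fishweb.lifehistory import Community, community_from_web

from conftest import chain_web, web_from_adjacency


def make_community(A, guild, M=None, n=None):
    A = np.asarray(A, dtype=bool)
    S = A.shape[0]
    guild = np.asarray(guild, dtype=object)
    if M is None:
        M = np.ones(S)
    x = trophic.metabolic_rate(np.asarray(M, float), guild)
    if n is None:
        n = np.linspace(0.1, 0.9, S)
    return Community(
        n=np.asarray(n, float), r=np.zeros(S), c=np.zeros(S), A=A,
        guild=guild, M=np.asarray(M, float), x=x, species=np.arange(S),
        stage=np.full(S, -1),
        fish_species=[i for i in range(S) if guild[i] == "fish"],
    )


@pytest.fixture
def single_autotroph():
    return make_community(np.zeros((1, 1)), ["autotroph"])


@pytest.fixture
def pair():
    """Autotroph 0 eaten by invertebrate 1."""
    A = np.zeros((2, 2), dtype=bool)
    A[1, 0] = True
    return make_community(A, ["autotroph", "invertebrate"], M=[1.0, 100.0])


class TestResourceOverlap:
    def test_identical_disjoint_and_partial_diets(self):
        A = np.zeros((5, 5), dtype=bool)
        A[3, [0, 1]] = True  # prey {0, 1}
        A[4, [1, 2]] = True  # prey {1, 2}
        p = dyn.resource_overlap(A)
        assert p[3, 3] == 1.0 and p[4, 4] == 1.0
        assert p[3, 4] == pytest.approx(0.5)
        assert p[4, 3] == pytest.approx(0.5)
        A2 = np.zeros((4, 4), dtype=bool)
        A2[2, 0] = A2[3, 1] = True
        p2 = dyn.resource_overlap(A2)
        assert p2[2, 3] == 0.0


class TestFunctionalResponse:
    def test_half_saturation_symmetry(self, pair):
        params = dyn.DynamicsParams()
        B = np.array([params.B0, 10.0])
        assert dyn.functional_response(B, 1, 0, pair, params) == pytest.approx(0.5)

    def test_zero_prey_biomass_gives_zero(self, pair):
        params = dyn.DynamicsParams()
        B = np.array([0.0, 10.0])
        assert dyn.functional_response(B, 1, 0, pair, params) == 0.0

    def test_two_prey_at_half_saturation(self):
        A = np.zeros((3, 3), dtype=bool)
        A[2, [0, 1]] = True
        com = make_community(
            A, ["autotroph", "autotroph", "invertebrate"], M=[1, 1, 100]
        )
        params = dyn.DynamicsParams()
        B = np.array([params.B0, params.B0, 5.0])
        # 0.5 B0^h / (B0^h + 2 * 0.5 * B0^h) = 0.25
        assert dyn.functional_response(B, 2, 0, com, params) == pytest.approx(0.25)

    def test_matches_literal_transcription(self, staged_community):
        """Vectorized response equals a direct loop transcription of the
        normalized functional response, interference included."""

        def literal(B, i, j, A, B0, c, h):
            prey_i = np.flatnonzero(A[i])
            if j not in prey_i:
                return 0.0
            P_i = prey_i.size
            omega = 1.0 / P_i
            den = B0 ** h
            for k in np.flatnonzero(A[:, j]):  # consumers of j
                prey_k = np.flatnonzero(A[k])
                shared = np.intersect1d(prey_i, prey_k).size
                p_ik = shared / P_i
                den += c * p_ik * B[k] * B0 ** h
            for l in prey_i:
                den += omega * B[l] ** h
            return omega * B[j] ** h / den

        com = staged_community
        rng = np.random.default_rng(11)
        B = rng.uniform(0, 300, com.size)
        for c_val in (0.0, 0.5):
            params = dyn.DynamicsParams(c_interference=c_val)
            consumers = np.flatnonzero(com.A.sum(axis=1) > 0)
            for i in consumers[:5]:
                for j in np.flatnonzero(com.A[i])[:4]:
                    assert dyn.functional_response(
                        B, int(i), int(j), com, params
                    ) == pytest.approx(
                        literal(B, int(i), int(j), com.A, params.B0,
                                c_val, params.hill)
                    )

    def test_monotone_in_prey_and_interferer_biomass(self):
        # F_ij non-decreasing in B_j; non-increasing in an interfering
        # consumer's biomass when c > 0 (finite differences).
        A = np.zeros((4, 4), dtype=bool)
        A[2, [0, 1]] = True
        A[3, [0, 1]] = True
        com = make_community(
            A, ["autotroph", "autotroph", "invertebrate", "fish"],
            M=[1, 1, 100, 1000],
        )
        params = dyn.DynamicsParams(c_interference=1.0)
        base = np.array([50.0, 80.0, 20.0, 30.0])
        f0 = dyn.functional_response(base, 2, 0, com, params)
        up_prey = base.copy(); up_prey[0] += 10
        assert dyn.functional_response(up_prey, 2, 0, com, params) >= f0
        up_rival = base.copy(); up_rival[3] += 10
        assert dyn.functional_response(up_rival, 2, 0, com, params) <= f0


class TestDerivatives:
    def test_logistic_equilibrium_at_carrying_capacity(self, single_autotroph):
        params = dyn.DynamicsParams()
        dB = dyn.derivatives(
            np.array([params.K_cap]), single_autotroph, params, np.array([0.9])
        )
        assert dB[0] == pytest.approx(0.0, abs=1e-12)

    def test_half_capacity_growth_rate(self, single_autotroph):
        params = dyn.DynamicsParams()
        dB = dyn.derivatives(
            np.array([270.0]), single_autotroph, params, np.array([0.9])
        )
        assert dB[0] == pytest.approx(0.9 * 0.5 * 270.0)  # 121.5 µgC/L/d

    def test_starved_consumer_decays(self, pair):
        params = dyn.DynamicsParams()
        B = np.array([0.0, 50.0])
        dB = dyn.derivatives(B, pair, params, np.array([0.9]))
        x1 = pair.x[1]
        assert dB[1] == pytest.approx(-params.f_m * x1 * 50.0)

    def test_efficiency_multiplies_or_divides_predation_loss(self, pair):
        mult = dyn.DynamicsParams(loss_efficiency_form="multiply")
        div = dyn.DynamicsParams(loss_efficiency_form="divide")
        B = np.array([100.0, 50.0])
        r = np.array([0.9])
        loss_mult = dyn.derivatives(B, pair, mult, r)[0]
        loss_div = dyn.derivatives(B, pair, div, r)[0]
        # autotroph prey: divide form loses 1/0.45^2 times more
        growth = 0.9 * (1 - 100 / 540) * 100
        assert (growth - loss_div) / (growth - loss_mult) == pytest.approx(
            1 / 0.45**2
        )


class TestIntegrateSeason:
    def test_single_autotroph_approaches_capacity(self, single_autotroph):
        params = dyn.DynamicsParams()
        B = np.array([5.0])
        for _ in range(5):
            _, B = dyn.integrate_season(B, single_autotroph, params,
                                        np.array([0.9]))
        assert B[0] == pytest.approx(540.0, rel=1e-4)

    def test_all_zero_start_is_absorbing(self, pair):
        params = dyn.DynamicsParams()
        samples, B = dyn.integrate_season(
            np.zeros(2), pair, params, np.array([0.9])
        )
        assert not samples.any() and not B.any()

    def test_shared_capacity_logistic_total(self):
        # autotroph-only web: total biomass equilibrates to K whatever
        # the individual r draws
        com = make_community(np.zeros((3, 3)), ["autotroph"] * 3)
        params = dyn.DynamicsParams()
        r = np.array([0.6, 0.9, 1.2])
        B = np.array([5.0, 20.0, 100.0])
        for _ in range(5):
            _, B = dyn.integrate_season(B, com, params, r)
        assert B.sum() == pytest.approx(540.0, rel=1e-3)

    def test_feeding_off_consumers_decay_exponentially(self, pair):
        # y = 0: closed form B(t) = B0 exp(-f_m x t)
        params = dyn.DynamicsParams(y_max=0.0)
        B0 = np.array([100.0, 50.0])
        samples, B = dyn.integrate_season(B0, pair, params, np.array([0.0]))
        x1 = pair.x[1]
        expected = 50.0 * np.exp(-params.f_m * x1 * params.season_days)
        assert B[1] == pytest.approx(expected, rel=1e-5)

    def test_below_threshold_zeroed_at_season_end(self, pair):
        params = dyn.DynamicsParams(y_max=0.0, extinction_threshold=1e3)
        _, B = dyn.integrate_season(
            np.array([5.0, 50.0]), pair, params, np.array([0.9])
        )
        assert B[1] == 0.0

    def test_tolerance_halving_changes_little(self, standard_web,
                                              standard_annotation):
        com = community_from_web(standard_web, standard_annotation)
        r = dyn.draw_growth_rates(
            int(standard_annotation.is_basal.sum()),
            np.random.default_rng(5), dyn.DynamicsParams(),
        )
        B0 = dyn.initial_biomass(
            com,
            dyn.draw_initial_conditions(com.size, np.random.default_rng(6),
                                        dyn.DynamicsParams()),
        )
        ends = []
        for rtol in (1e-6, 5e-7):
            params = dyn.DynamicsParams(rtol=rtol, atol=rtol * 1e-3)
            B = B0.copy()
            for _ in range(3):
                _, B = dyn.integrate_season(B, com, params, r)
            ends.append(B)
        live = ends[0] > 1e-3
        assert np.max(
            np.abs(ends[0][live] - ends[1][live]) / ends[0][live]
        ) < 1e-3


class TestRunSimulation:
    def test_leslie_pulse_after_first_year(self, staged_community):
        """With feeding off, a stage-0-only fish cohort moves 90% of its
        post-season biomass to stage 1 at the year boundary."""
        com = staged_community
        params = dyn.DynamicsParams(y_max=0.0, extinction_threshold=1e-12)
        sp, idx = next(iter(com.stage_nodes.items()))
        B0 = np.zeros(com.size)
        B0[idx[0]] = 100.0
        n_auto = int(com.is_autotroph.sum())
        traj = dyn.run_simulation(
            com, "linked", 1, params, B0, np.zeros(n_auto)
        )
        decayed = 100.0 * np.exp(
            -params.f_m * com.x[idx[0]] * params.season_days
        )
        assert traj.year_end[0, idx[1]] == pytest.approx(0.9 * decayed, rel=1e-5)
        assert traj.year_end[0, idx[0]] == pytest.approx(0.1 * decayed, rel=1e-5)

    def test_unlinked_model_skips_leslie(self, staged_community):
        com = staged_community
        params = dyn.DynamicsParams(y_max=0.0, extinction_threshold=1e-12)
        sp, idx = next(iter(com.stage_nodes.items()))
        B0 = np.zeros(com.size)
        B0[idx[0]] = 100.0
        n_auto = int(com.is_autotroph.sum())
        traj = dyn.run_simulation(
            com, "unlinked", 1, params, B0, np.zeros(n_auto)
        )
        assert traj.year_end[0, idx[1]] == 0.0

    def test_same_seed_bit_identical(self, staged_community):
        com = staged_community
        params = dyn.DynamicsParams()
        n_auto = int(com.is_autotroph.sum())
        r = dyn.draw_growth_rates(n_auto, np.random.default_rng(1), params)
        B0 = dyn.initial_biomass(
            com, dyn.draw_initial_conditions(30, np.random.default_rng(2),
                                             params)
        )
        t1 = dyn.run_simulation(com, "linked", 3, params, B0, r)
        t2 = dyn.run_simulation(com, "linked", 3, params, B0, r)
        np.testing.assert_array_equal(t1.year_end, t2.year_end)
        np.testing.assert_array_equal(t1.annual_mean, t2.annual_mean)

    def test_non_negative_everywhere(self, staged_community):
        com = staged_community
        params = dyn.DynamicsParams()
        n_auto = int(com.is_autotroph.sum())
        r = dyn.draw_growth_rates(n_auto, np.random.default_rng(1), params)
        B0 = dyn.initial_biomass(
            com, dyn.draw_initial_conditions(30, np.random.default_rng(2),
                                             params)
        )
        traj = dyn.run_simulation(com, "linked", 3, params, B0, r,
                                  record_daily=True)
        assert (traj.daily >= 0).all()
        assert (traj.year_end >= 0).all()

    def test_model_type_community_mismatch_rejected(self, staged_community,
                                                    pair):
        params = dyn.DynamicsParams()
        with pytest.raises(ValueError):
            dyn.run_simulation(pair, "linked", 1, params, np.zeros(2),
                               np.array([0.9]))
        with pytest.raises(ValueError):
            dyn.run_simulation(staged_community, "original", 1, params,
                               np.zeros(39), np.zeros(5))

    def test_original_equals_linked_without_fish(self):
        """A fishless community runs identically under every model type
        label that accepts it (no stages to link)."""
        A = np.zeros((3, 3), dtype=bool)
        A[2, 0] = A[2, 1] = True
        com = make_community(
            A, ["autotroph", "autotroph", "invertebrate"], M=[1, 1, 100]
        )
        params = dyn.DynamicsParams()
        r = np.array([0.8, 1.0])
        B0 = np.array([50.0, 60.0, 10.0])
        orig = dyn.run_simulation(com, "original", 3, params, B0, r)
        com_staged_view = make_community(
            A, ["autotroph", "autotroph", "invertebrate"], M=[1, 1, 100]
        )
        com_staged_view.staged = True  # no fish -> Leslie is a no-op
        linked = dyn.run_simulation(com_staged_view, "linked", 3, params, B0, r)
        np.testing.assert_array_equal(orig.year_end, linked.year_end)
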