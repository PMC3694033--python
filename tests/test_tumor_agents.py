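"""Melanoma-cell rules: analytic formulas, site selection, per-cell stepping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from melanosim import initialize, step
from melanosim.tumor_agents import (
    ACTIVE,
    DEAD,
    QUIESCENT,
    NoViableCandidateError,
    abnormal_glucose_site,
    apoptosis_probability,
    crowding_preference,
    drug_death_rate,
    enters_cell_cycle,
    normalize_ranks,
    proliferation_probability,
    rank_tumor_candidate,
    roulette_select,
)
from conftest import small_config


class TestAnalyticRules:
    def test_no_drug_means_no_drug_death(self):
        assert drug_death_rate(0.0, 5.0, 0.01, 1.0) == 0.0

    def test_drug_death_rate_value(self):
        assert drug_death_rate(10.0, 1.0, 0.01, 1.0) == pytest.approx(0.05, abs=1e-12)

    def test_glucose_is_protective(self):
        rates = [drug_death_rate(10.0, g, 0.01, 1.0) for g in (0, 1, 10, 1e6)]
        assert all(a > b for a, b in zip(rates, rates[1:]))
        assert rates[-1] < 1e-7

    def test_apoptosis_probability_closed_form(self):
        assert apoptosis_probability(2.0, 0.0) == 0.0
        p = apoptosis_probability(2.0, 0.0, 0.05, with_drug=True)
        assert p == pytest.approx(1 - math.exp(-0.1), abs=1e-12)
        # drug ignored when with_drug is False
        assert apoptosis_probability(2.0, 0.0, 0.05, with_drug=False) == 0.0

    def test_proliferation_probability_closed_form(self):
        assert proliferation_probability(2.0, 0.0) == 0.0
        assert proliferation_probability(2.0, 1 / 32) == pytest.approx(
            1 - math.exp(-1 / 16), abs=1e-12
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            drug_death_rate(-1, 0, 0.01, 1)
        with pytest.raises(ValueError):
            apoptosis_probability(2.0, -0.1)
        with pytest.raises(ValueError):
            proliferation_probability(-2.0, 0.1)

    def test_cycle_entry_interval_is_half_open(self):
        assert enters_cell_cycle(0.0, 0.06)
        assert not enters_cell_cycle(0.06, 0.06)  # [p_prol, 1) is OFF
        assert not enters_cell_cycle(0.5, 0.0)
        with pytest.raises(ValueError):
            enters_cell_cycle(1.0, 0.5)

    @given(
        dox=st.floats(0, 1e3), glu=st.floats(0, 1e3),
        d_dox=st.floats(0, 10), d_glu=st.floats(0, 10),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_apoptosis_monotone_in_drug_and_glucose(self, dox, glu, d_dox, d_glu):
        """More drug never lowers, more glucose never raises, the kill rate."""
        base = drug_death_rate(dox, glu, 0.01, 1.0)
        assert drug_death_rate(dox + d_dox, glu, 0.01, 1.0) >= base
        assert drug_death_rate(dox, glu + d_glu, 0.01, 1.0) <= base
        p = apoptosis_probability(2.0, 0.0, base, with_drug=True)
        assert 0.0 <= p < 1.0


class TestCrowdingPreference:
    @pytest.mark.parametrize(
        "cellnum,expected",
        [(0, 1.0), (1, 1.0), (2, 1.0), (3, 0.25), (4, 0.25),
         (5, 1 / 6), (6, 1 / 6), (7, 1 / 7), (10, 0.1), (26, 1 / 26)],
    )
    def test_piecewise_values(self, cellnum, expected):
        assert crowding_preference(cellnum) == pytest.approx(expected, abs=1e-15)

    def test_out_of_range_rejected(self):
        for bad in (-1, 27):
            with pytest.raises(ValueError):
                crowding_preference(bad)


class TestRanking:
    def test_rank_direct_value(self):
        assert rank_tumor_candidate(1.0, 2.0, 0.0, 0.01) == pytest.approx(2.0)

    def test_drug_halves_rank(self):
        free = rank_tumor_candidate(1.0, 2.0, 0.0, 0.01)
        drugged = rank_tumor_candidate(1.0, 2.0, 100.0, 0.01)
        assert drugged == pytest.approx(free / 2)

    def test_no_glucose_means_zero_rank(self):
        assert rank_tumor_candidate(0.5, 0.0, 3.0, 0.01) == 0.0

    def test_normalize_proportions(self):
        np.testing.assert_allclose(normalize_ranks([2, 3, 5]), [0.2, 0.3, 0.5])
        np.testing.assert_allclose(normalize_ranks([7.0]), [1.0])
        np.testing.assert_allclose(normalize_ranks([0.0, 4.0]), [0.0, 1.0])

    def test_all_zero_ranks_signal_no_viable_candidate(self):
        with pytest.raises(NoViableCandidateError):
            normalize_ranks([0.0, 0.0])

    def test_roulette_interval_lookup(self):
        assert roulette_select([0.25, 0.25, 0.5], 0.6) == 2
        assert roulette_select([0.25, 0.25, 0.5], 0.0) == 0
        assert roulette_select([0.25, 0.25, 0.5], 0.25) == 1  # half-open edges
        assert roulette_select([1.0], 0.999) == 0
        with pytest.raises(ValueError):
            roulette_select([1.0], 1.0)

    def test_roulette_frequencies_match_weights(self, rng):
        """Empirical selection frequencies agree with the normalized ranks
        (chi-square goodness of fit over 1e5 draws)."""
        weights = np.array([0.1, 0.2, 0.3, 0.4])
        n = 100_000
        dies = rng.random(n)
        cum = np.cumsum(weights)
        picks = np.searchsorted(cum, dies, side="right")
        # spot-check the scalar implementation agrees with the batch
        for d in dies[:200]:
            assert roulette_select(weights, d) == np.searchsorted(cum, d, "right")
        counts = np.bincount(picks, minlength=4)
        chi2 = ((counts - n * weights) ** 2 / (n * weights)).sum()
        assert stats.chi2.sf(chi2, df=3) > 0.001


class TestAbnormalGlucoseSite:
    def test_uniform_field_has_no_outlier(self, rng):
        glu = np.full((7, 7, 7), 2.0)
        assert abnormal_glucose_site(glu, (3, 3, 3), rng) is None

    def test_extreme_neighbor_is_selected(self, rng):
        glu = np.ones((7, 7, 7))
        glu[3, 3, 4] = 100.0
        # verify the 3-sigma test by direct statistics over the 27-voxel box
        box = [glu[3 + dx, 3 + dy, 3 + dz]
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
        m, s = np.mean(box), np.std(box)
        assert 100.0 - m > 3 * s
        assert abnormal_glucose_site(glu, (3, 3, 3), rng) == (3, 3, 4)

    def test_occupied_outlier_is_excluded(self, rng):
        glu = np.ones((7, 7, 7))
        glu[3, 3, 4] = 100.0
        occupied = np.zeros((7, 7, 7), bool)
        occupied[3, 3, 4] = True
        assert abnormal_glucose_site(glu, (3, 3, 3), rng, occupied=occupied) is None


class TestTumorBehavior:
    def test_no_death_channel_means_nondecreasing_population(self):
        """Without drugs, with lambda0 = 0 and abundant glucose, melanoma can
        only grow."""
        cfg = small_config(t_end_h=80.0)
        cfg.glucose.decay = 0.0          # glucose never decays away
        cfg.field_init.glucose_sd = 0.0  # uniform abundance
        cfg.tumor.starvation_death_rate = 0.0
        state = initialize(cfg)
        counts = [state.counts()["n_alive"]]
        for _ in range(cfg.n_steps):
            step(state)
            counts.append(state.counts()["n_alive"])
        assert counts == sorted(counts)
        assert state.counts()["n_apoptotic"] == 0

    @staticmethod
    def _caged_cell_state():
        """One melanoma cell at the center, walled in by 26 immobile vessel
        nodes (no VEGF anywhere, so the endothelial cage never moves)."""
        cfg = small_config(dims=(7, 7, 7), initial_tumor_count=1,
                           initial_tip_count=0, t_end_h=2.0)
        cfg.glucose.decay = 0.0
        cfg.field_init.glucose_sd = 0.0
        cfg.field_init.vegf_mean = 0.0
        cfg.field_init.vegf_sd = 0.0
        cfg.tumor.lambda2 = 0.0  # the cell cannot leave by cycling
        state = initialize(cfg)
        center = state.cells.pos[0]
        cage = [int(q) for q in state.moore_idx[center]]
        for q in cage:
            state.occupy_vessel(q)
            state.tree.add_node(q, parent=-1)
        return cfg, state, cage

    def test_fully_surrounded_cell_becomes_quiescent(self):
        cfg, state, cage = self._caged_cell_state()
        step(state)
        assert state.cells.state[0] == QUIESCENT

    def test_quiescence_is_reversible(self):
        """A quiescent cell adjacent to a newly freed voxel becomes active."""
        cfg, state, cage = self._caged_cell_state()
        step(state)
        assert state.cells.state[0] == QUIESCENT
        # open one voxel of the cage
        gate = cage[0]
        node = int(np.flatnonzero(state.tree.pos[: state.tree.n] == gate)[0])
        state.tree.remove_tip(node)
        state.free_vessel_voxel(gate)
        step(state)
        assert state.cells.state[0] == ACTIVE
        assert state.cells.pos[0] == gate

    def test_apoptotic_cells_are_absorbing_and_occupy(self):
        cfg = small_config(t_end_h=60.0, initial_tip_count=0)
        cfg.tumor.starvation_limit_h = 4.0
        cfg.tumor.starvation_death_rate = 2.0
        cfg.field_init.glucose_mean = 0.0  # everyone starves immediately
        cfg.field_init.glucose_sd = 0.0
        state = initialize(cfg)
        for _ in range(cfg.n_steps):
            step(state)
        n = state.cells.n
        assert (state.cells.state[:n] == DEAD).all()
        dead_pos = state.cells.pos[:n]
        assert (state.occ[dead_pos] == 1).all()  # necrotic core persists
        # and the dead stop consuming / secreting
        assert not state.live3.any()
        assert not state.secr3.any()

    def test_division_resets_parent_and_creates_offspring(self):
        cfg = small_config(initial_tumor_count=1, initial_tip_count=0,
                           t_end_h=400.0)
        cfg.glucose.decay = 0.0
        cfg.field_init.glucose_sd = 0.0
        state = initialize(cfg)
        for _ in range(cfg.n_steps):
            step(state)
            if state.cells.n > 1:
                break
        assert state.cells.n > 1
        assert state.cells.age_h[1] >= 0.0
        assert not state.cells.in_cycle[0] or state.cells.cycle_h[0] < \
            cfg.tumor.cell_cycle_length_h
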