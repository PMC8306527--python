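"""Engine contracts: division, collection, Tfh selection, bookkeeping."""

import numpy as np
import pytest

from asyncgc.cohort import gc_lifetime
from asyncgc.gc_engine import (
    BCell,
    FDCPool,
    GCParams,
    GCState,
    assign_divisions,
    collect_antigen,
    differentiate_or_recycle,
    divide_cell,
    run_gc,
    tfh_interaction,
    update_feedback,
)
from asyncgc.hypotheses import DEFAULT_EPITOPES
from asyncgc.shape_space import Epitope, FounderSpec

RANDOM = FounderSpec(mode="random")


class TestParamsValidation:
    def test_defaults_are_valid(self):
        GCParams()

    def test_infeasible_polarization_threshold_rejected(self):
        # a threshold above the contact duration could never select any cell
        with pytest.raises(ValueError):
            GCParams(polarization_threshold=0.7, tfh_contact_duration=0.6)

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            GCParams(recycling_prob=1.2)
        with pytest.raises(ValueError):
            GCParams(mutation_prob=-0.1)

    def test_durations_positive(self):
        with pytest.raises(ValueError):
            GCParams(duration=0.0)

    def test_window_must_cover_timestep(self):
        with pytest.raises(ValueError):
            GCParams(collection_window=0.05, dt=0.1)


class TestAssignDivisions:
    def test_single_portion_earns_two_divisions(self):
        assert assign_divisions(1.0, GCParams()) == 2

    def test_monotone_in_collected_antigen(self):
        p = GCParams()
        vals = [assign_divisions(a, p) for a in range(1, 101)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_capped_at_max_divisions(self):
        assert assign_divisions(1e9, GCParams()) == GCParams().max_divisions
        assert assign_divisions(1e9, GCParams(max_divisions=6)) == 6

    def test_zero_antigen_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            assign_divisions(0.0, GCParams())


class TestDivideCell:
    def _cell(self, antigen=10.0):
        return BCell(state="dividing", position=np.array([5, 5, 5, 5]),
                     divisions_left=3, antigen_collected=antigen)

    def test_forced_asymmetry_gives_all_antigen_to_one_daughter(self, rng):
        p = GCParams(asymmetric_fraction=1.0)
        for _ in range(20):
            d1, d2 = divide_cell(self._cell(), p, rng)
            assert (d1.antigen_collected, d2.antigen_collected) == (10.0, 0.0)

    def test_symmetric_division_splits_equally(self, rng):
        p = GCParams(asymmetric_fraction=0.0)
        d1, d2 = divide_cell(self._cell(), p, rng)
        assert d1.antigen_collected == d2.antigen_collected == 5.0

    def test_daughters_lose_one_division(self, rng):
        d1, d2 = divide_cell(self._cell(), GCParams(), rng)
        assert d1.divisions_left == d2.divisions_left == 2

    def test_empirical_asymmetric_fraction(self, rng):
        p = GCParams()
        n = 10_000
        asym = sum(
            divide_cell(self._cell(), p, rng)[1].antigen_collected == 0.0
            for _ in range(n)
        )
        assert asym / n == pytest.approx(0.72, abs=0.01)

    def test_non_dividing_cell_rejected(self, rng):
        cell = self._cell()
        cell.state = "collecting"
        with pytest.raises(ValueError):
            divide_cell(cell, GCParams(), rng)


class TestCollectAntigen:
    def _collecting_cell(self, pos=(5, 5, 5, 5)):
        p = GCParams()
        return BCell(state="collecting", position=np.array(pos),
                     clock=p.collection_window)

    def test_empty_pool_kills_after_window_regardless_of_affinity(self, rng):
        p = GCParams(antigen_per_fdc=0.0)
        pool = FDCPool.from_params(p, DEFAULT_EPITOPES)
        cell = self._collecting_cell()  # at the optimum: affinity 1
        outcomes = [collect_antigen(cell, pool, DEFAULT_EPITOPES, p, rng)
                    for _ in range(p.window_steps)]
        assert outcomes[-1] == "failed"
        assert cell.state == "dead" and cell.antigen_collected == 0.0

    def test_perfect_affinity_full_pool_succeeds_first_attempt(self, rng):
        p = GCParams()
        pool = FDCPool.from_params(p, DEFAULT_EPITOPES)
        for _ in range(50):
            cell = self._collecting_cell()
            collect_antigen(cell, pool, DEFAULT_EPITOPES, p, rng)
            assert cell.antigen_collected == 1.0

    def test_portions_conserved_between_pool_and_cells(self, rng):
        p = GCParams(antigen_per_fdc=5.0, n_fdc=10)
        pool = FDCPool.from_params(p, DEFAULT_EPITOPES)
        initial = pool.total_initial
        cells = [self._collecting_cell() for _ in range(40)]
        for cell in cells:
            while cell.state == "collecting":
                collect_antigen(cell, pool, DEFAULT_EPITOPES, p, rng)
        held = sum(c.antigen_collected for c in cells)
        assert pool.total_remaining + held == initial


class TestTfhInteraction:
    def _cell(self, antigen):
        return BCell(state="tfh_contact", antigen_collected=antigen,
                     position=np.array([5, 5, 5, 5]))

    def test_lone_cell_accrues_full_polarization_and_is_selected(self, rng):
        p = GCParams()
        cell = self._cell(3.0)
        [selected] = tfh_interaction([cell], p, rng)
        assert selected
        assert cell.polarization_time == pytest.approx(0.6)

    def test_highest_antigen_cell_wins_stable_contact(self, rng):
        p = GCParams()
        strong, weak = self._cell(10.0), self._cell(1.0)
        flags = tfh_interaction([strong, weak], p, rng)
        assert flags == [True, False]
        assert weak.polarization_time == 0.0 and weak.state == "dead"

    def test_cells_without_antigen_rejected(self, rng):
        with pytest.raises(ValueError):
            tfh_interaction([self._cell(0.0)], GCParams(), rng)


class TestDifferentiateOrRecycle:
    def test_antigen_retaining_daughter_becomes_output(self, rng):
        cell = BCell(antigen_collected=2.0)
        assert differentiate_or_recycle(cell, GCParams(), rng) == "output_precursor"

    def test_no_recycling_means_loss(self, rng):
        p = GCParams(recycling_prob=0.0)
        for _ in range(20):
            cell = BCell(antigen_collected=0.0)
            assert differentiate_or_recycle(cell, p, rng) == "lost"

    def test_full_recycling_returns_all_to_collection(self, rng):
        p = GCParams(recycling_prob=1.0)
        for _ in range(20):
            cell = BCell(antigen_collected=0.5)
            assert differentiate_or_recycle(cell, p, rng) == "recycled"
            assert cell.antigen_collected == 0.0
            assert cell.state == "collecting"


class TestFeedback:
    def test_no_output_means_no_masking(self):
        p = GCParams(feedback_strength=1.0)
        pool = FDCPool.from_params(p, DEFAULT_EPITOPES)
        update_feedback(pool, p)
        assert np.all(pool.masked_fraction == 0.0)

    def test_half_saturation_identity(self):
        p = GCParams(feedback_strength=1.0)
        pool = FDCPool.from_params(p, DEFAULT_EPITOPES)
        pool.plasma_weighted[:] = p.feedback_halfsat
        update_feedback(pool, p)
        assert np.all(pool.masked_fraction == 0.5)


class TestInitAndInflux:
    def test_pool_totals_and_partition(self):
        p = GCParams()
        eps = (Epitope(optimum=(1, 1, 1, 1), abundance_fraction=0.75),
               Epitope(optimum=(8, 8, 8, 8), abundance_fraction=0.25))
        pool = FDCPool.from_params(p, eps)
        assert pool.total_initial == 600_000.0
        assert tuple(pool.initial) == (450_000.0, 150_000.0)

    def test_invalid_epitope_fractions_rejected(self, rng):
        eps = (Epitope(optimum=(1, 1, 1, 1), abundance_fraction=0.9),)
        with pytest.raises(Exception):
            GCState(GCParams(), eps, RANDOM, rng)

    def test_no_arrivals_after_influx_window(self, rng):
        p = GCParams()
        state = GCState(p, DEFAULT_EPITOPES, RANDOM, rng)
        added = sum(state.influx(t) for t in np.arange(96.0, 200.0, p.dt))
        assert added == 0

    def test_mean_founder_count_matches_rate_times_duration(self):
        # expectation 2/h x 96 h = 192; Poisson CI over seeds
        p = GCParams(duration=97.0, antigen_per_fdc=0.0)
        counts = [
            run_gc(p, DEFAULT_EPITOPES, RANDOM, seed=s).n_founders
            for s in range(12)
        ]
        assert np.mean(counts) == pytest.approx(192.0, abs=3 * np.sqrt(192 / 12))

    def test_zero_influx_never_populates(self):
        p = GCParams(influx_rate=0.0, duration=240.0)
        run = run_gc(p, DEFAULT_EPITOPES, RANDOM, seed=3)
        assert np.all(run.live_cells == 0)


class TestRunGC:
    def test_bitwise_determinism_under_seed(self, fast_params):
        a = run_gc(fast_params, DEFAULT_EPITOPES, RANDOM, seed=42)
        b = run_gc(fast_params, DEFAULT_EPITOPES, RANDOM, seed=42)
        for name in ("times", "live_cells", "cumulative_plasma",
                     "antigen_remaining", "antigen_held", "antigen_output",
                     "antigen_lost", "antigen_decayed"):
            assert np.array_equal(getattr(a, name), getattr(b, name)), name

    def test_antigen_free_gc_collapses_after_founder_expansion(self):
        p = GCParams(antigen_per_fdc=0.0, duration=360.0)
        run = run_gc(p, DEFAULT_EPITOPES, RANDOM, seed=5)
        # founders arrive and divide, but nothing survives selection
        assert run.live_cells.max() > 0
        assert run.live_cells[-1] == 0
        assert run.total_plasma == 0

    def test_antigen_conservation_every_recorded_step(self, fast_params):
        run = run_gc(fast_params, DEFAULT_EPITOPES, RANDOM, seed=7)
        total = (run.antigen_remaining + run.antigen_held + run.antigen_output
                 + run.antigen_lost + run.antigen_decayed)
        assert np.all(total == run.antigen_remaining[0])

    def test_cumulative_plasma_nondecreasing_and_live_nonnegative(self, fast_params):
        run = run_gc(fast_params, DEFAULT_EPITOPES, RANDOM, seed=8)
        assert np.all(np.diff(run.cumulative_plasma) >= 0)
        assert np.all(run.live_cells >= 0)
        assert np.all(np.diff(run.antigen_remaining) <= 0)

    def test_no_mutation_keeps_founder_positions(self):
        # founders start on the distance-5 shell; without mutation every live
        # cell must remain there
        p = GCParams(mutation_prob=0.0, duration=240.0)
        spec = FounderSpec(mode="epitope_specific", target_epitope=0,
                           distance_from_optimum=5)
        rng = np.random.default_rng(9)
        state = GCState(p, DEFAULT_EPITOPES, spec, rng)
        for i in range(int(240.0 / p.dt)):
            state.step(i * p.dt)
        c = state.cells
        alive = np.nonzero(c.alive_mask())[0]
        assert alive.size > 0
        d = np.sqrt(((c.pos[alive].astype(int) - np.array([5, 5, 5, 5])) ** 2).sum(axis=1))
        assert np.all(np.round(d).astype(int) == 5)

    def test_reference_gc_expands_peaks_and_contracts(self):
        run = run_gc(GCParams(), DEFAULT_EPITOPES, RANDOM, seed=2)
        peak = run.live_cells.argmax()
        assert run.live_cells[peak] > 1000
        assert run.live_cells[-1] < run.live_cells[peak] // 10
        assert 0.0 < gc_lifetime(run, 100) < run.times[-1]
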