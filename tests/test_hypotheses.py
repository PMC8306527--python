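"""Scenario construction, antigen decay and sweep plumbing."""

import numpy as np
import pytest

from asyncgc.cohort import build_schedule
from asyncgc.gc_engine import GCParams
from asyncgc.hypotheses import (
    RAO_DECAY,
    THREE_EPITOPES,
    AntigenDecay,
    HypothesisConfig,
    antigen_at_start,
    build_scenario_schedule,
    default_config,
    make_per_gc_params,
    sweep_parameter,
)


class TestAntigenDecay:
    def test_initial_loading_at_immunization(self):
        assert antigen_at_start(0.0, RAO_DECAY) == 20_000.0

    def test_no_decay_is_constant(self):
        d = AntigenDecay(a0=500.0, k=0.0)
        assert antigen_at_start(1000.0, d) == 500.0

    def test_direct_evaluation(self):
        # 20,000 * exp(-0.026 * 100) = 20,000 * 0.0742736
        assert antigen_at_start(100.0, RAO_DECAY) == pytest.approx(1485.47, abs=0.01)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            antigen_at_start(-1.0, RAO_DECAY)


class TestScenarioConfigs:
    def test_unknown_id_rejected_with_valid_list(self):
        with pytest.raises(ValueError, match="H1"):
            HypothesisConfig(id="H9")

    def test_all_defaults_construct(self):
        for hid in [f"H{i}" for i in range(1, 9)]:
            cfg = default_config(hid)
            assert cfg.id == hid

    def test_h3_requires_decay(self):
        with pytest.raises(ValueError, match="scenario"):
            HypothesisConfig(id="H3")

    def test_h6_requires_feedback(self):
        with pytest.raises(ValueError, match="feedback"):
            HypothesisConfig(id="H6")
        assert default_config("H6").base.feedback_strength > 0


class TestPerGCParams:
    def _schedule(self, cfg, seed=0):
        return build_scenario_schedule(cfg, np.random.default_rng(seed))

    def test_h1_representatives_share_parameters(self, rng):
        cfg = default_config("H1")
        params, specs, eps = make_per_gc_params(cfg, self._schedule(cfg), rng)
        assert all(p == cfg.base for p in params)
        assert all(s.mode == "random" for s in specs)

    def test_h2_differs_only_through_schedule(self, rng):
        cfg = default_config("H2")
        sched = self._schedule(cfg)
        assert sched.n_intervals == 15
        assert sched.edges[-1] == pytest.approx(840.0)
        params, _, _ = make_per_gc_params(cfg, sched, rng)
        assert all(p == cfg.base for p in params)

    def test_h3_antigen_decreases_with_initiation_time(self, rng):
        cfg = default_config("H3")
        sched = self._schedule(cfg)
        params, _, _ = make_per_gc_params(cfg, sched, rng)
        loads = [p.antigen_per_fdc for p in params]
        assert np.all(np.diff(loads) < 0)
        expect = [antigen_at_start(t, RAO_DECAY) for t in sched.init_times]
        assert np.allclose(loads, expect)

    def test_h4_variants_assign_founder_specificity_by_interval(self, rng):
        for variant, early_random in (("early_random", True), ("early_specific", False)):
            cfg = default_config("H4", founder_variant=variant)
            params, specs, eps = make_per_gc_params(cfg, self._schedule(cfg), rng)
            assert all(tuple(e) == tuple(THREE_EPITOPES) for e in eps)
            early = [s.mode for s in specs[:4]]
            late = [s.mode for s in specs[4:]]
            if early_random:
                assert set(early) == {"random"} and set(late) == {"epitope_specific"}
            else:
                assert set(early) == {"epitope_specific"} and set(late) == {"random"}
            targeted = {s.target_epitope for s in specs if s.mode == "epitope_specific"}
            assert targeted == {0, 1, 2}  # least-dominant epitope is represented

    def test_h5_degenerate_gaussian_reduces_to_h1(self, rng):
        cfg = default_config("H5", antigen_gauss_sd=0.0)
        params, _, _ = make_per_gc_params(cfg, self._schedule(cfg), rng)
        assert all(p.antigen_per_fdc == 3000.0 for p in params)

    def test_h5_draws_are_floored(self, rng):
        cfg = default_config("H5", antigen_gauss_mean=200.0, antigen_gauss_sd=2000.0)
        params, _, _ = make_per_gc_params(cfg, self._schedule(cfg), rng)
        assert min(p.antigen_per_fdc for p in params) >= cfg.antigen_floor

    def test_h7_h8_vary_per_gc(self, rng):
        cfg7 = default_config("H7")
        p7, _, _ = make_per_gc_params(cfg7, self._schedule(cfg7), rng)
        assert len({p.influx_rate for p in p7}) > 1
        cfg8 = default_config("H8")
        _, s8, _ = make_per_gc_params(cfg8, self._schedule(cfg8), rng)
        assert len({s.distance_from_optimum for s in s8}) > 1


class TestFounderSpecificityScenario:
    def test_least_dominant_epitope_gcs_are_short_lived(self):
        """GCs founded specifically against the rarest epitope exhaust their
        small antigen share and die sooner than random-founder GCs."""
        from asyncgc.hypotheses import run_scenario

        res = run_scenario(default_config("H4"), master_seed=41, repeats=3)
        cfg = default_config("H4")
        sched = build_scenario_schedule(cfg, np.random.default_rng(0))
        # reconstruct the per-representative founder assignment
        _, specs, _ = make_per_gc_params(
            cfg,
            sched,
            np.random.default_rng(0),
        )
        rare = [i for i, s in enumerate(specs)
                if s.mode == "epitope_specific" and s.target_epitope == 2]
        rnd = [i for i, s in enumerate(specs) if s.mode == "random"]
        rare_life = np.median(res.lifetimes_h[rare, :])
        rnd_life = np.median(res.lifetimes_h[rnd, :])
        assert rare_life < rnd_life


class TestSweep:
    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="recycling_prob"):
            sweep_parameter("not_a_param", [1.0], GCParams(), 1, 0)

    def test_reference_value_normalizes_to_exactly_one(self):
        # short, low-antigen runs: the founder expansion alone crosses the
        # counting threshold, so lifetimes are positive but cheap to compute
        base = GCParams(duration=240.0, antigen_per_fdc=150.0)
        df = sweep_parameter(
            "recycling_prob", [0.8, 0.4], base, repeats=2, master_seed=5
        )
        ref_row = df[df["value"] == 0.8].iloc[0]
        assert ref_row["normalized"] == 1.0
        assert set(df.columns) >= {"parameter", "value", "lifetime_mean_h", "normalized"}
        assert len(df) == 2
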