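"""Hydraulic flow split, junction/capture/lysis rules and the simulator."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from depclog.errors import DomainError, StateError, UsageError
from depclog.forces import AdhesionParams, FieldModel
from depclog.transport import (
    BranchState,
    CaptureContext,
    ChannelNetwork,
    SimulationParams,
    branch_entry_probability,
    capture_rule,
    clog_update,
    flow_split,
    lysis_probability,
    lysis_rule,
    margination_factor,
    simulate_separation,
)

NDEP = -0.5


class TestFlowSplit:
    def test_identical_branches_get_equal_flows(self, network):
        fs = flow_split(network)
        q = fs.branch_flows.reshape(-1, 2)
        np.testing.assert_allclose(q[:, 0], q[:, 1], rtol=1e-9)

    def test_volume_conserved_to_solver_precision(self, network):
        fs = flow_split(network)
        total = fs.branch_flows.sum() + fs.blood_outflow
        assert total == pytest.approx(network.inlet_flow, rel=1e-12)
        assert 0 < fs.plasma_fraction < 1

    def test_narrowed_branch_loses_flow_share(self, network):
        states = [BranchState(network.branch_width) for _ in range(network.n_branches)]
        states[4].effective_width = network.branch_width / 2
        fs = flow_split(network, states)
        clean = flow_split(network)
        assert fs.branch_flows[4] < clean.branch_flows[4]

    def test_clogged_branch_carries_no_flow(self, network):
        states = [BranchState(network.branch_width) for _ in range(network.n_branches)]
        states[0].clogged = True
        fs = flow_split(network, states)
        assert fs.branch_flows[0] == 0.0
        assert fs.branch_flows.sum() + fs.blood_outflow == pytest.approx(
            network.inlet_flow, rel=1e-12
        )

    def test_invalid_geometry_rejected(self):
        with pytest.raises(DomainError):
            ChannelNetwork(n_branches=51)
        with pytest.raises(DomainError):
            ChannelNetwork(branch_width=200e-6)


class TestBranchEntry:
    def test_unit_margination_recovers_flow_fraction(self):
        assert branch_entry_probability(7e-6, "core", 0.3, margination=1.0) == 0.3

    def test_zero_margination_blocks_cells(self):
        assert branch_entry_probability(7e-6, "core", 0.3, margination=0.0) == 0.0

    def test_plasma_tracer_follows_the_flow(self):
        assert margination_factor(0.0, "tracer") == 1.0

    def test_entry_monotone_decreasing_in_diameter(self):
        p = [
            branch_entry_probability(d, "near_wall", 0.3)
            for d in np.linspace(1e-6, 15e-6, 20)
        ]
        assert np.all(np.diff(p) < 0)
        assert all(x < 0.3 for x in p)

    def test_bad_flow_fraction_rejected(self):
        with pytest.raises(DomainError):
            branch_entry_probability(7e-6, "core", 1.5)


class TestCaptureRule:
    def ctx(self, voltage):
        return CaptureContext(
            FieldModel(voltage_amplitude=voltage), AdhesionParams(), NDEP
        )

    def test_protected_rbc_not_captured_at_20v(self):
        assert not capture_rule(7e-6, 5e-9, self.ctx(20.0))

    def test_everything_close_captured_without_drive(self):
        assert capture_rule(7e-6, 5e-9, self.ctx(0.0))
        assert capture_rule(2.5e-6, 9e-9, self.ctx(0.0))

    def test_submicron_debris_captured_despite_drive(self):
        # DEP protection fails below ~1 um: adhesion wins close to the wall
        assert capture_rule(0.5e-6, 0.5e-9, self.ctx(20.0))

    def test_outside_capture_window_never_captured(self):
        assert not capture_rule(7e-6, 50e-9, self.ctx(0.0))


class TestLysis:
    def test_no_lysis_at_or_below_threshold(self):
        for v in (0.0, 10.0, 20.0):
            assert lysis_probability(v, 100.0) == 0.0
            assert not lysis_rule(v, 100.0, 0.0)

    def test_probability_increases_with_excess_voltage_and_exposure(self):
        p = [lysis_probability(v, 2.0) for v in (22.0, 25.0, 30.0)]
        assert np.all(np.diff(p) > 0)
        t = [lysis_probability(30.0, s) for s in (0.5, 2.0, 8.0)]
        assert np.all(np.diff(t) > 0)

    def test_longer_exposure_lyses_more_cells_over_seeds(self):
        rng = np.random.default_rng(3)
        draws = rng.random(4000)
        slow = sum(lysis_rule(30.0, 8.0, u) for u in draws)
        fast = sum(lysis_rule(30.0, 1.0, u) for u in draws)
        assert slow > fast


class TestClogUpdate:
    def test_zero_capture_leaves_state_unchanged(self):
        b = BranchState(15e-6)
        clog_update(b, 0.0, 2e-6)
        assert b.effective_width == 15e-6 and b.n_captured == 0

    def test_repeated_captures_narrow_monotonically_then_clog(self):
        b = BranchState(15e-6)
        widths = []
        while not b.clogged:
            clog_update(b, 7.5e-6, 2e-6, time=1.0)
            widths.append(b.effective_width)
        assert np.all(np.diff(widths) < 0)
        assert b.clog_time == 1.0 and b.effective_width < 2e-6

    def test_update_on_clogged_branch_rejected(self):
        b = BranchState(1e-6, clogged=True)
        with pytest.raises(StateError):
            clog_update(b, 7e-6, 2e-6)

    def test_stronger_aggregation_accelerates_capture(self, small_network):
        """With a larger aggregation factor the same seed captures at least
        as many cells (branches clog sooner)."""
        from depclog.synthetic import generate_population

        captured = []
        for agg in (1.0, 5.0):
            total = 0
            for seed in (1, 2, 3):
                pop = generate_population(25.0, 0.05, seed=seed, max_cells=3000)
                out = simulate_separation(
                    pop, small_network, 0.0, duration=10.0, dt=1.0, seed=seed,
                    params=SimulationParams(aggregation_factor=agg),
                )
                total += int(out.counts["captured"].sum())
            captured.append(total)
        assert captured[1] > captured[0]


class TestSimulateSeparation:
    def test_empty_population_yields_zero_counts(self, small_network):
        from depclog.synthetic import CellPopulation

        pop = CellPopulation(
            cells=pd.DataFrame({"species": [], "diameter_m": [], "near_wall": []}),
            haematocrit_pct=25.0,
            volume_ul=1.0,
            concentration={},
            parcel_weight={},
            species_specs={},
        )
        out = simulate_separation(pop, small_network, 20.0, duration=5.0, dt=1.0, seed=0)
        assert out.counts[["inlet", "blood_out", "plasma_out", "captured", "lysed"]].sum().sum() == 0

    def test_identical_seed_and_config_bitwise_reproducible(
        self, small_network, tiny_population
    ):
        runs = [
            simulate_separation(
                tiny_population, small_network, 20.0, duration=10.0, dt=1.0, seed=5
            )
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(runs[0].counts, runs[1].counts)
        pd.testing.assert_frame_equal(runs[0].checkpoints, runs[1].checkpoints)
        assert [b.effective_width for b in runs[0].branch_states] == [
            b.effective_width for b in runs[1].branch_states
        ]
        assert runs[0].plasma_volume_ul == runs[1].plasma_volume_ul

    @pytest.mark.parametrize("voltage", [0.0, 20.0, 30.0])
    def test_exact_per_species_conservation(self, small_network, tiny_population, voltage):
        out = simulate_separation(
            tiny_population, small_network, voltage, duration=10.0, dt=1.0, seed=11
        )
        assert out.conservation_ok()

    def test_lysis_only_above_threshold(self, small_network, tiny_population):
        at20 = simulate_separation(
            tiny_population, small_network, 20.0, duration=10.0, dt=1.0, seed=2
        )
        at30 = simulate_separation(
            tiny_population, small_network, 30.0, duration=10.0, dt=1.0, seed=2
        )
        assert at20.counts["lysed"].sum() == 0
        assert at30.counts["lysed"].sum() > 0
        # debris created by lysis re-enters transport and is accounted for
        assert at30.counts.loc["debris", "inlet"] == at30.counts.drop("debris")["lysed"].sum()

    def test_invalid_time_arguments_rejected(self, small_network, tiny_population):
        with pytest.raises(UsageError):
            simulate_separation(tiny_population, small_network, 20.0, duration=0.0, dt=1.0)
        with pytest.raises(UsageError):
            simulate_separation(tiny_population, small_network, 20.0, duration=5.0, dt=-1.0)

    def test_count_table_feeds_metrics(self, small_network, tiny_population):
        from depclog.metrics import evaluate

        out = simulate_separation(
            tiny_population, small_network, 20.0, duration=10.0, dt=1.0, seed=4
        )
        rep = evaluate(out.count_table)
        assert np.isfinite(rep.table["purity_efficiency_pct"]).all()
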