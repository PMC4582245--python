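"""Synthetic-data generators: exactness, ground truth and pipeline recovery."""

import numpy as np
import pytest

from ssbwrap.landscape import EnergyLandscape, WrappingLandscapeModel
from ssbwrap.polymer import TetherComposition, wrapped_extension
from ssbwrap.simulate import (
    SimulationConfig,
    fixture_wrapping_path,
    gillespie_states,
    sample_state_occupancy,
    simulate_constant_force_trace,
    simulate_force_ramp,
    simulate_reca_displacement,
    simulate_reptation_fret,
)
from ssbwrap.traces import boxcar, detect_states


def toy_fast_landscape(k0: float = 1e8) -> EnergyLandscape:
    """Reference thermodynamics with a faster attempt rate and without the
    unresolved fast 56/65 exchange, so dwells sit comfortably above the
    0.3 s detectability bound at the analysis bandwidth."""
    ref = EnergyLandscape.reference()
    return EnergyLandscape(
        energies=dict(ref.energies),
        barriers={k: v for k, v in ref.barriers.items() if k != (56, 65)},
        barrier_x={k: v for k, v in ref.barrier_x.items() if k != (56, 65)},
        k0=k0, x_ssb=dict(ref.x_ssb))


class TestSeedDiscipline:
    def test_seed_is_mandatory(self, landscape):
        with pytest.raises(ValueError):
            SimulationConfig(seed=None)

    def test_bit_reproducible(self):
        kwargs = dict(seed=9, force=5.0, duration_s=5.0, native_rate_hz=500.0)
        t1, truth1 = simulate_constant_force_trace(SimulationConfig(**kwargs))
        t2, truth2 = simulate_constant_force_trace(SimulationConfig(**kwargs))
        assert np.array_equal(t1.dx, t2.dx)
        assert np.array_equal(truth1["event_times"], truth2["event_times"])


class TestConstantForce:
    def test_frozen_rates_give_static_trace(self):
        frozen = EnergyLandscape(energies={0: 0.0, 17: -5.0}, barriers={},
                                 barrier_x={})
        cfg = SimulationConfig(seed=1, landscape=frozen, force=5.0,
                               duration_s=1.0, native_rate_hz=100.0,
                               noise_sd_nm=0.0, initial_state=17)
        with pytest.warns(UserWarning, match="static"):
            trace, truth = simulate_constant_force_trace(cfg)
        assert np.ptp(trace.dx) == 0.0
        assert list(truth["states"]) == [17]

    def test_long_run_matches_boltzmann_occupancy(self):
        """Empirical state occupancy of the exact sampler agrees with the
        tilted Boltzmann weights within 2% at 1e5 dwells."""
        toy = toy_fast_landscape()
        rng = np.random.default_rng(5)
        ev_t, ev_s = gillespie_states(toy, 5.0, 1e12, rng, initial_state=35,
                                      max_events=100_000)
        durs = np.diff(ev_t)
        total = durs.sum()
        exact = toy.occupancies(5.0)
        for s in (0, 17, 35, 56):
            emp = durs[ev_s[:-1] == s].sum() / total
            assert emp == pytest.approx(exact[s], abs=0.02)

    def test_low_force_binding_is_stable(self, landscape):
        """At 2 pN the SSB binds, compacts to the high-wrap modes and stays
        bound indefinitely (no dissociation within a minute)."""
        cfg = SimulationConfig(seed=3, landscape=landscape, force=2.0,
                               duration_s=60.0, native_rate_hz=200.0)
        _trace, truth = simulate_constant_force_trace(cfg)
        states, times = truth["states"], truth["event_times"]
        bound_at = int(np.argmax(states != 0))
        assert 65 in states
        assert np.all(states[bound_at:] != 0)  # indefinitely bound
        durs = np.diff(np.concatenate([times, [60.0]]))
        high = durs[bound_at:][np.isin(states[bound_at:], (56, 65))].sum()
        assert high / durs[bound_at:].sum() > 0.9

    def test_occupancy_sampler_normalises(self, landscape, rng):
        counts = sample_state_occupancy(landscape, 5.0, 1000, rng)
        assert sum(counts.values()) == 1000


class TestForceRamp:
    def test_infinite_barriers_trace_fixed_state_model(self, params):
        frozen = EnergyLandscape(
            energies=dict(EnergyLandscape.reference().energies),
            barriers={p: 1e3 for p in ((0, 17), (17, 35), (35, 56), (56, 65))},
            barrier_x={p: 5.0 for p in ((0, 17), (17, 35), (35, 56), (56, 65))})
        cfg = SimulationConfig(seed=2, landscape=frozen, protocol="ramp",
                               noise_sd_nm=0.0, f_max=15.0)
        out = simulate_force_ramp(cfg)
        fec = out["fec"]
        assert set(fec["state"]) == {65}
        assert np.isnan(out["rupture_force"])
        comp = TetherComposition(n_ds=3260, n_ss=70, n_wrapped=65)
        for _, row in fec.iloc[5::200].iterrows():
            expected = wrapped_extension(row.force_pN, comp,
                                         frozen.x_ssb[65], params)
            assert row.extension_nm == pytest.approx(expected, abs=0.3)

    def test_rupture_recorded_and_absorbing(self, landscape):
        cfg = SimulationConfig(seed=4, landscape=landscape, protocol="ramp",
                               noise_sd_nm=0.0)
        out = simulate_force_ramp(cfg)
        assert np.isfinite(out["rupture_force"])
        states = out["truth"]["states"]
        assert states[-1] == 0 and np.all(states[:-1] != 0)

    def test_post_rupture_curve_is_bare(self, landscape, params):
        from ssbwrap.polymer import bare_extension

        cfg = SimulationConfig(seed=4, landscape=landscape, protocol="ramp",
                               noise_sd_nm=0.0)
        fec = simulate_force_ramp(cfg)["fec"]
        after = fec[fec["state"] == 0]
        comp = TetherComposition(n_ds=3260, n_ss=70)
        for _, row in after.iloc[:: max(len(after) // 5, 1)].iterrows():
            assert row.extension_nm == pytest.approx(
                bare_extension(row.force_pN, comp, params), abs=0.3)


class TestReptation:
    def test_zero_diffusion_static(self):
        cfg = SimulationConfig(seed=6, diffusion_nt2_s=0.0, lattice_nt=10,
                               duration_s=5.0)
        trace, truth = simulate_reptation_fret(cfg)
        assert np.ptp(truth["positions"]) == 0
        assert trace.acceptor.mean() > trace.donor.mean()  # parked at junction

    def test_lattice_too_small(self):
        with pytest.raises(ValueError):
            simulate_reptation_fret(SimulationConfig(seed=1, lattice_nt=1))

    def test_msd_slope_recovers_2d(self):
        """Interior MSD slope equals 2 D within 5% at ~1e5 hops."""
        d_true = 25.0
        cfg = SimulationConfig(seed=8, diffusion_nt2_s=d_true, lattice_nt=2000,
                               duration_s=2000.0, reptation_start_nt=1000)
        _trace, truth = simulate_reptation_fret(cfg)
        times, pos = truth["times"], truth["positions"].astype(float)
        grid = np.arange(0.0, 2000.0, 0.5)
        p = pos[np.searchsorted(times, grid, side="right") - 1]
        lags = np.array([2, 4, 8, 16])  # in grid steps (1-8 s)
        msd = np.array([np.mean((p[l:] - p[:-l]) ** 2) for l in lags])
        slope = np.polyfit(lags * 0.5, msd, 1)[0]
        assert slope == pytest.approx(2 * d_true, rel=0.05)

    def test_photon_channels_reflect_position(self):
        cfg = SimulationConfig(seed=9, diffusion_nt2_s=27.0, lattice_nt=35,
                               duration_s=200.0)
        trace, truth = simulate_reptation_fret(cfg)
        eff = trace.acceptor / np.maximum(trace.acceptor + trace.donor, 1)
        pos_at = truth["positions"][np.searchsorted(truth["times"], trace.time,
                                                    side="right") - 1]
        near = eff[pos_at < 5]
        far = eff[pos_at > 25]
        assert near.mean() > 0.8 > 0.3 > far.mean()


class TestRecADisplacement:
    def test_zero_nucleation_pure_hopping(self):
        cfg = SimulationConfig(seed=10, force=5.0, duration_s=30.0,
                               native_rate_hz=100.0,
                               reca_rates={"i_ii": 1.0, "ii_i": 1.0,
                                           "nucleation": 0.0, "iii_iv": 1.0,
                                           "iv_v": 1.0})
        _trace, truth = simulate_reca_displacement(cfg)
        assert set(truth["states"]) <= {"i", "ii"}

    def test_staircase_levels_match_model(self):
        """Plateaus of the displacement staircase sit on the five predicted
        levels within 1 nm."""
        cfg = SimulationConfig(seed=12, force=5.0, duration_s=80.0,
                               native_rate_hz=500.0, noise_sd_nm=3.0,
                               reca_rates={"i_ii": 0.3, "ii_i": 0.3,
                                           "nucleation": 0.15, "iii_iv": 0.15,
                                           "iv_v": 0.15})
        trace, truth = simulate_reca_displacement(cfg)
        seg = detect_states(boxcar(trace, 10.0),
                            expected_levels=truth["levels"])
        levels = np.array(sorted(truth["levels"].values()))
        for s in seg.segments:
            assert np.min(np.abs(levels - s.mean_dx)) < 1.0

    def test_final_level_is_full_filament(self):
        cfg = SimulationConfig(seed=13, force=5.0, duration_s=200.0,
                               native_rate_hz=100.0, noise_sd_nm=0.0)
        _trace, truth = simulate_reca_displacement(cfg)
        assert truth["states"][-1] == "v"
        assert truth["levels"]["v"] == pytest.approx(10.0, abs=2.0)


class TestFixturePath:
    def test_deterministic_and_sized(self):
        a = fixture_wrapping_path(70)
        b = fixture_wrapping_path(70)
        assert np.array_equal(a.positions_nm, b.positions_nm)
        assert len(a) == 70
        assert len(fixture_wrapping_path(40)) == 40

    def test_uniform_arc_steps(self, fixture_structure):
        steps = np.linalg.norm(np.diff(fixture_structure.positions_nm, axis=0),
                               axis=1)
        # chords of equal 0.56 nm arc steps; shorter only where the seam
        # bends tightly near the poles
        assert steps.max() < 0.561
        assert np.median(steps) > 0.52
        assert steps.min() > 0.3

    def test_hotspot_group_sizes(self, fixture_structure):
        for g in fixture_structure.hotspot_groups:
            assert 6 <= len(g) <= 7


class TestFullPipelineRecovery:
    def test_energies_barriers_and_adjacency(self):
        """simulate -> boxcar -> segment -> dwell stats -> landscape fit
        recovers the generating energies and barrier positions, and nearly
        all observed transitions are between pathway-adjacent states."""
        toy = toy_fast_landscape()
        plan = [(3.5, 56, 500.0), (4.5, 56, 500.0),
                (9.0, 17, 1500.0), (10.0, 17, 1500.0)]
        segs = []
        for i, (force, init, dur) in enumerate(plan):
            cfg = SimulationConfig(seed=50 + i, landscape=toy, force=force,
                                   duration_s=dur, native_rate_hz=200.0,
                                   noise_sd_nm=4.5, initial_state=init)
            trace, truth = simulate_constant_force_trace(cfg)
            levels = {str(s): truth["levels"][s] for s in toy.energies}
            segs.append(detect_states(boxcar(trace, 10.0),
                                      expected_levels=levels))
        level_map = {str(s): s for s in toy.energies}
        model = WrappingLandscapeModel.from_segments(segs, level_map, k0=toy.k0)
        res = model.fit()
        for s in (17, 35, 56):
            se = max(res.landscape.energy_se[s], 0.15)
            assert abs(res.landscape.energies[s] - toy.energies[s]) < 2 * se
        for pair in ((0, 17), (17, 35), (35, 56)):
            got = res.barrier_fit["barrier_x"][pair]
            assert got == pytest.approx(toy.barrier_x[pair], rel=0.20, abs=0.5)
        # adjacency of observed transitions (misses of brief intermediates
        # create the rare apparent long jumps)
        adjacent = {(0, 17), (17, 35), (35, 56)}
        n_adj = n_tot = 0
        for st in segs:
            for a, b, _t in st.transitions:
                n_tot += 1
                n_adj += tuple(sorted((int(a), int(b)))) in adjacent
        assert n_tot > 300
        assert n_adj / n_tot > 0.9
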