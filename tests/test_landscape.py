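"""Energy-landscape reconstruction: energies, barriers, tilts, model fit."""

import numpy as np
import pandas as pd
import pytest

from ssbwrap.landscape import (
    EnergyLandscape,
    PathwayError,
    WrappingLandscapeModel,
    combine_state_energies,
    equilibrium_mean_dx,
    fit_barriers,
    free_energy_difference,
    half_unwrapping_force,
    landscape_at_force,
    transition_rate,
    wrap_free_energy_from_area,
)
from ssbwrap.simulate import sample_state_occupancy


class TestFreeEnergyDifference:
    def test_equal_occupancy_no_stretch(self):
        assert free_energy_difference(0.3, 0.3, 0.0) == 0.0

    def test_log_ratio(self):
        # p65/p56 = 2.05 with no stretch difference -> -0.72 kBT
        assert free_energy_difference(2.05, 1.0, 0.0) == pytest.approx(-0.718, abs=2e-3)

    def test_censored_state_rejected(self):
        with pytest.raises(ValueError):
            free_energy_difference(0.0, 0.5, 0.0)

    def test_stretch_term_in_kbt(self):
        got = free_energy_difference(1.0, 1.0, 8.18, thermal_energy=4.09)
        assert got == pytest.approx(-2.0)


class TestCombineStateEnergies:
    def test_noiseless_chain_exact(self, landscape):
        ests = [(b, a, landscape.energies[b] - landscape.energies[a])
                for a, b in zip((0, 17, 35, 56), (17, 35, 56, 65))]
        out = combine_state_energies(ests)
        for s, (g, _se) in out.items():
            assert g == pytest.approx(landscape.energies[s], abs=1e-12)

    def test_missing_link_named(self):
        with pytest.raises(ValueError, match="35<->56"):
            combine_state_energies([(17, 0, -6.8), (35, 17, -8.6), (65, 56, -0.7)])

    def test_non_adjacent_rejected(self):
        with pytest.raises(ValueError, match="not pathway-adjacent"):
            combine_state_energies([(56, 17, -13.6)])

    def test_recovery_from_sampled_occupancies(self, landscape):
        """Multinomial occupancy samples at several forces chain back to the
        generating state energies within two standard errors."""
        rows = []
        for i, force in enumerate((2.0, 3.0, 5.0, 7.0, 9.0)):
            rng = np.random.default_rng(100 + i)
            for s, c in sample_state_occupancy(landscape, force, 10_000, rng).items():
                rows.append((force, s, c))
        occ = pd.DataFrame(rows, columns=["force_pN", "state", "count"])
        res = WrappingLandscapeModel(occ).fit(fit_barrier_pairs=())
        for s in (17, 35, 56, 65):
            g = res.landscape.energies[s]
            se = max(res.landscape.energy_se[s], 0.02)
            assert abs(g - landscape.energies[s]) < 2 * se

    def test_recovered_full_wrap_energy_magnitude(self, landscape):
        """|G_65| ~ 21 kBT, the free energy of wrapping into the 65-nt mode."""
        rows = []
        for i, force in enumerate((2.0, 3.0, 5.0, 7.0, 9.0)):
            rng = np.random.default_rng(200 + i)
            for s, c in sample_state_occupancy(landscape, force, 10_000, rng).items():
                rows.append((force, s, c))
        occ = pd.DataFrame(rows, columns=["force_pN", "state", "count"])
        res = WrappingLandscapeModel(occ).fit(fit_barrier_pairs=())
        assert abs(res.landscape.energies[65]) == pytest.approx(21.1, abs=1.0)


class TestTransitionRates:
    def test_zero_force_wrapping_rate(self, landscape):
        # k0 exp(-(G_35/56 - G_35)) = 1e7 exp(-12.48) ~ 38 1/s
        assert transition_rate(35, 56, 0.0, landscape) == pytest.approx(38.0, rel=0.01)

    def test_force_direction(self, landscape):
        # in the force range where the transitions are observed (the state
        # compaction exceeds the transition-state extension there)
        f = np.array([3.0, 5.0, 7.0, 9.0])
        wrapping = transition_rate(35, 56, f, landscape)
        unwrapping = transition_rate(56, 35, f, landscape)
        assert np.all(np.diff(wrapping) < 0)
        assert np.all(np.diff(unwrapping) > 0)

    def test_high_force_kills_wrapping(self, landscape):
        f = np.array([5.0, 10.0, 25.0, 60.0])
        k = transition_rate(17, 35, f, landscape)
        assert np.all(np.diff(k) < 0)
        assert k[-1] < 1e-12

    def test_detailed_balance_against_occupancies(self, landscape):
        for f in np.arange(0.5, 12.0, 0.5):
            for a, b in ((0, 17), (17, 35), (35, 56), (56, 65)):
                lhs = transition_rate(a, b, f, landscape) / transition_rate(b, a, f, landscape)
                rhs = np.exp(-(landscape.tilted_energy(b, f)
                               - landscape.tilted_energy(a, f)))
                assert abs(lhs / rhs - 1.0) < 1e-8

    def test_pathway_violation(self, landscape):
        with pytest.raises(PathwayError):
            transition_rate(17, 56, 5.0, landscape)


class TestFitBarriers:
    @staticmethod
    def synthetic_rates(landscape, noise_sd=0.0, seed=7):
        rng = np.random.default_rng(seed)
        recs = []
        for pair in ((0, 17), (17, 35), (35, 56)):
            for f in np.arange(3.0, 8.01, 0.5):
                for a, b in (pair, pair[::-1]):
                    k = transition_rate(a, b, f, landscape)
                    if noise_sd:
                        k *= rng.lognormal(0.0, noise_sd)
                    recs.append((a, b, f, k))
        return recs

    def test_noiseless_self_consistency(self, landscape):
        fit = fit_barriers(self.synthetic_rates(landscape), landscape)
        assert fit["residual"] < 1e-6
        for pair in ((0, 17), (17, 35), (35, 56)):
            assert fit["barriers"][pair] == pytest.approx(
                landscape.barriers[pair], abs=1e-6)
            assert fit["barrier_x"][pair] == pytest.approx(
                landscape.barrier_x[pair], abs=1e-6)

    def test_noisy_recovery_of_transition_state(self, landscape):
        """20% lognormal rate noise still recovers x(35/56) within 15%."""
        fit = fit_barriers(self.synthetic_rates(landscape, noise_sd=0.2), landscape)
        assert fit["barrier_x"][(35, 56)] == pytest.approx(11.7, rel=0.15)

    def test_barrier_ordering_preserved(self, landscape):
        fit = fit_barriers(self.synthetic_rates(landscape, noise_sd=0.2), landscape)
        b = fit["barriers"]
        assert b[(0, 17)] > b[(17, 35)] > b[(35, 56)]

    def test_underdetermined_errors(self, landscape):
        one_force = [(35, 56, 5.0, 1.0), (56, 35, 5.0, 2.0)]
        with pytest.raises(ValueError, match="underdetermined"):
            fit_barriers(one_force, landscape, pairs=((35, 56),))


class TestTiltedLandscape:
    def test_zero_force_is_raw(self, landscape):
        tilted = landscape_at_force(landscape, 0.0)
        for s, g in landscape.energies.items():
            assert tilted["states"][s] == pytest.approx(g, abs=1e-12)

    def test_minimum_migrates_with_force(self, landscape):
        """The tilted minimum walks 65 -> 56 -> 35 -> 17 -> 0 as force grows."""
        seen = []
        for f in np.arange(0.0, 14.01, 0.05):
            states = landscape_at_force(landscape, f)["states"]
            lowest = min(states, key=states.get)
            if not seen or seen[-1] != lowest:
                seen.append(lowest)
        assert seen == [65, 56, 35, 17, 0]

    def test_barriers_exceed_flanking_states_when_transitions_observed(self, landscape):
        # near 4 pN the 35/56 transition is active
        tilted = landscape_at_force(landscape, 4.0)
        assert tilted["barriers"][(35, 56)] > tilted["states"][35]
        assert tilted["barriers"][(35, 56)] > tilted["states"][56]

    def test_occupancy_mode_shifts_with_force(self, landscape):
        modes = [max(landscape.occupancies(f), key=landscape.occupancies(f).get)
                 for f in (1.0, 3.0, 7.0, 9.5, 13.0)]
        assert modes == [65, 56, 35, 17, 0]


class TestWrapFreeEnergy:
    def test_zero_curve(self):
        f = np.linspace(0, 10, 50)
        assert wrap_free_energy_from_area((f, np.zeros(50)), 8.0) == 0.0

    def test_rectangle(self):
        f = np.linspace(0, 10, 1001)
        got = wrap_free_energy_from_area((f, np.full(1001, 10.0)), 8.18, 4.09)
        assert got == pytest.approx(20.0, rel=1e-6)

    def test_domain_error(self):
        f = np.linspace(0, 5, 10)
        with pytest.raises(ValueError):
            wrap_free_energy_from_area((f, np.zeros(10)), 8.0)

    def test_area_equals_minus_g65_within_ten_percent(self, landscape):
        """Tilt-integral identity: the FEC-area free energy matches the
        depth of the fully wrapped state."""
        fh = half_unwrapping_force(landscape)
        f = np.arange(0.0, fh + 0.01, 0.01)
        g = wrap_free_energy_from_area((f, equilibrium_mean_dx(landscape, f)), fh)
        assert g == pytest.approx(-landscape.energies[65], rel=0.10)


class TestHalfUnwrappingForce:
    def test_two_state_analytic(self):
        """Toy two-state system: G = -10 kBT, dx = 10 nm -> F_1/2 = 4.09 pN."""

        class Toy(EnergyLandscape):
            def dx_state(self, state, force):
                return (np.full_like(np.asarray(force, float), 10.0)
                        if state else np.zeros_like(np.asarray(force, float)))

        toy = Toy(energies={0: 0.0, 65: -10.0}, barriers={}, barrier_x={})
        assert half_unwrapping_force(toy) == pytest.approx(4.09, abs=1e-3)

    def test_printed_landscape_in_dissociation_range(self, landscape):
        fh = half_unwrapping_force(landscape)
        assert 9.0 < fh < 12.0

    def test_deepening_the_wells_raises_f_half(self, landscape):
        # deepen every bound state: at F_1/2 the bound weight is carried by
        # the partially wrapped states, so the shift must be applied to all
        # of them to move the crossing measurably
        deeper = EnergyLandscape(
            energies={s: (g - 2.0 if s else 0.0)
                      for s, g in landscape.energies.items()},
            barriers=dict(landscape.barriers), barrier_x=dict(landscape.barrier_x),
            x_ssb=dict(landscape.x_ssb), params=landscape.params)
        assert half_unwrapping_force(deeper) > half_unwrapping_force(landscape) + 0.1

    def test_no_crossing_errors(self):
        shallow = EnergyLandscape(energies={0: 0.0, 65: 5.0}, barriers={},
                                  barrier_x={})
        with pytest.raises(ValueError):
            half_unwrapping_force(shallow)


class TestModelResults:
    @pytest.fixture()
    def fitted(self, landscape):
        rows = []
        for i, force in enumerate((3.0, 5.0, 7.0, 9.0)):
            rng = np.random.default_rng(300 + i)
            for s, c in sample_state_occupancy(landscape, force, 10_000, rng).items():
                rows.append((force, s, c))
        occ = pd.DataFrame(rows, columns=["force_pN", "state", "count"])
        rates = pd.DataFrame(TestFitBarriers.synthetic_rates(landscape, 0.1),
                             columns=["from_state", "to_state", "force_pN", "k_per_s"])
        return WrappingLandscapeModel(occ, rates=rates).fit()

    def test_params_and_bse_aligned(self, fitted):
        assert set(fitted.bse.index) <= set(fitted.params.index) | set(fitted.bse.index)
        assert fitted.params["G_35"] == pytest.approx(-15.38, abs=0.5)
        assert fitted.params["xb_35/56"] == pytest.approx(11.7, rel=0.2)

    def test_summary_renders(self, fitted):
        text = fitted.summary()
        assert "state (nt)" in text and "barrier" in text
        assert "k0" in text

    def test_predict_occupancy_normalised(self, fitted):
        df = fitted.predict_occupancy([2.0, 6.0, 10.0])
        total = sum(df[f"p_{s}"] for s in (0, 17, 35, 56, 65))
        assert np.allclose(total, 1.0)

    def test_json_round_trip(self, fitted, tmp_path):
        path = tmp_path / "landscape.json"
        fitted.landscape.to_json(path)
        back = EnergyLandscape.from_json(path)
        assert back.energies == pytest.approx(fitted.landscape.energies)
        assert back.barrier_x == pytest.approx(fitted.landscape.barrier_x)
        assert back.metadata == fitted.landscape.metadata
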