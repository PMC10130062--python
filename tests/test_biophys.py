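"""EPR rhombicity, voltammetry, binding, optics, hydrodynamics."""

import math

import numpy as np
import pytest

from minimet import fixtures
from minimet.biophys import (
    BOLTZMANN,
    BiophysError,
    TitrationCurve,
    ZfsParams,
    analyze_voltammogram,
    bead_model_diffusion,
    beer_lambert_concentration,
    estimate_rhombicity,
    extinction_coefficient,
    fit_binding_isotherm,
    randles_sevcik_fit,
    zfs_effective_g,
)
from minimet.structure_io import Atom, Residue, Structure


class TestZfsEffectiveG:
    def test_axial_limit_ground_doublet(self):
        g = zfs_effective_g(ZfsParams(D=1.0, E=0.0, g0=2.0))
        np.testing.assert_allclose(g[0], [6.0, 6.0, 2.0], atol=1e-3)

    def test_axial_limit_top_doublet(self):
        g = zfs_effective_g(ZfsParams(D=1.0, E=0.0, g0=2.0))
        np.testing.assert_allclose(g[2], [0.0, 0.0, 10.0], atol=1e-3)

    def test_axial_gz_ladder(self):
        g0 = 2.0023
        g = zfs_effective_g(ZfsParams(D=2.5, E=0.0, g0=g0))
        np.testing.assert_allclose(g[:, 2], np.array([2.0, 6.0, 10.0]) * g0 / 2, atol=1e-3)

    def test_rhombic_limit_middle_doublet_isotropic(self):
        g = zfs_effective_g(ZfsParams(D=1.0, E=1.0 / 3.0, g0=2.0))
        assert np.ptp(g[1]) < 0.05
        assert g[1].mean() == pytest.approx(4.29, abs=0.05)

    def test_negative_d_reverses_doublet_order(self):
        gp = zfs_effective_g(ZfsParams(D=1.0, E=0.0, g0=2.0))
        gm = zfs_effective_g(ZfsParams(D=-1.0, E=0.0, g0=2.0))
        np.testing.assert_allclose(gm[0], gp[0], atol=1e-3)  # ground is ground either way
        np.testing.assert_allclose(gm[2], gp[2], atol=1e-3)

    def test_e_sign_symmetry_up_to_axis_permutation(self):
        gp = zfs_effective_g(ZfsParams(D=1.0, E=0.2, g0=2.0))
        gm = zfs_effective_g(ZfsParams(D=1.0, E=-0.2, g0=2.0))
        np.testing.assert_allclose(np.sort(gp, axis=1), np.sort(gm, axis=1), atol=1e-3)

    def test_non_kramers_rejected(self):
        with pytest.raises(BiophysError):
            ZfsParams(S=2.0, D=1.0)

    def test_zero_d_rejected(self):
        with pytest.raises(BiophysError):
            ZfsParams(D=0.0)


class TestRhombicityEstimation:
    def test_isotropic_430_signal_maps_to_the_rhombic_limit(self):
        est = estimate_rhombicity([4.29], g0=2.0)
        assert est.e_over_d == pytest.approx(1.0 / 3.0, abs=0.002)

    def test_observed_resonances_give_rhombic_ferric_site(self):
        """g_eff = 9.15 and 4.26 place the ferric tetrathiolate site at
        E/D about 0.2 with D > 0."""
        est = estimate_rhombicity([9.15, 4.26])
        assert est.e_over_d == pytest.approx(0.22, abs=0.02)
        assert est.d_positive
        low = next(a for a in est.assignments if a["observed"] == 9.15)
        assert low["doublet"] == 0 and a_in_objective(low)
        mid = next(a for a in est.assignments if a["observed"] == 4.26)
        assert mid["doublet"] == 1 and not a_in_objective(mid)

    @pytest.mark.parametrize("truth", [0.05, 0.15, 0.27])
    def test_self_consistency_on_synthetic_observations(self, truth):
        df = fixtures.make_measurements("geff_set", {"e_over_d": truth})
        est = estimate_rhombicity(list(df["g_eff"]))
        assert est.e_over_d == pytest.approx(truth, abs=0.0015)

    def test_empty_observations_rejected(self):
        with pytest.raises(BiophysError):
            estimate_rhombicity([])


def a_in_objective(assignment):
    return assignment["in_objective"]


class TestVoltammetry:
    def test_midpoint_vs_she_recovered(self):
        """A reversible couple at -0.085 V vs Ag/AgCl (3 M NaCl) reads
        out at E_half = +0.121 V vs SHE."""
        v = fixtures.make_cv_trace(e0_vs_ref=-0.085, reference_offset=0.206)
        out = analyze_voltammogram(v)
        assert out.ok
        assert out.E_half == pytest.approx(0.121, abs=0.001)

    def test_nernstian_peak_separation(self):
        v = fixtures.make_cv_trace(e0_vs_ref=0.0)
        out = analyze_voltammogram(v)
        assert out.delta_Ep == pytest.approx(0.059, abs=0.002)

    def test_flat_trace_is_flagged_not_raised(self):
        from minimet.biophys import Voltammogram

        E = np.linspace(-0.3, 0.3, 100)
        v = Voltammogram(np.concatenate([E, E[::-1]]), np.zeros(200), scan_rate=0.02)
        out = analyze_voltammogram(v)
        assert not out.ok
        assert any("no peaks" in f or "peak" in f for f in out.flags)

    def test_smoothing_does_not_shift_ideal_peaks(self):
        clean = analyze_voltammogram(fixtures.make_cv_trace(e0_vs_ref=0.0, n_points=2000))
        noisy = analyze_voltammogram(
            fixtures.make_cv_trace(e0_vs_ref=0.0, n_points=2000, noise=0.01, seed=4)
        )
        assert abs(noisy.E_pa - clean.E_pa) <= 0.001
        assert abs(noisy.E_pc - clean.E_pc) <= 0.001


class TestRandlesSevcik:
    A, C, T = 0.0707, 8.0e-8, 288.15

    def _peaks(self, D, noise=0.0, seed=0, rates=None):
        truth = {"D": D, "A": self.A, "C": self.C, "T": self.T}
        if rates is not None:
            truth["scan_rates"] = rates
        df = fixtures.make_measurements("voltammogram", truth, noise=noise, seed=seed)
        return list(zip(df["scan_rate_V_s"], df["i_p_A"]))

    def test_noise_free_recovery_to_numerical_precision(self):
        fit = randles_sevcik_fit(self._peaks(1.0e-6), n=1, A=self.A, C=self.C, T=self.T)
        assert fit.ok
        assert fit.params["D"] == pytest.approx(1.0e-6, rel=1e-9)

    def test_concentration_linearity_leaves_d_unchanged(self):
        peaks = self._peaks(1.0e-6)
        doubled = [(v, 2 * i) for v, i in peaks]
        fit1 = randles_sevcik_fit(peaks, n=1, A=self.A, C=self.C, T=self.T)
        fit2 = randles_sevcik_fit(doubled, n=1, A=self.A, C=2 * self.C, T=self.T)
        assert fit2.params["D"] == pytest.approx(fit1.params["D"], rel=1e-12)

    def test_noisy_simulation_study(self):
        """2% current noise at 6 scan rates: median |D_err|/D <= 5%
        over 100 seeds."""
        rates = [2.5e-3, 5e-3, 10e-3, 20e-3, 35e-3, 50e-3]
        errors = []
        for seed in range(100):
            peaks = self._peaks(1.0e-6, noise=0.02, seed=seed, rates=rates)
            fit = randles_sevcik_fit(peaks, n=1, A=self.A, C=self.C, T=self.T)
            errors.append(abs(fit.params["D"] - 1.0e-6) / 1.0e-6)
        assert np.median(errors) <= 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(BiophysError):
            randles_sevcik_fit([(0.01, 1e-6), (0.02, 2e-6)], n=1, A=1.0, C=1e-6)


class TestBindingIsotherm:
    P = 30e-6

    def test_stoichiometric_limit_breaks_at_one_equivalent(self):
        df = fixtures.make_measurements("titration", {"K_D": 0.0, "protein_total": self.P})
        L, sig = df["ligand_total_M"].to_numpy(), df["absorbance"].to_numpy()
        plateau = sig.max()
        breakpoint_L = L[np.argmax(sig >= plateau - 1e-12)]
        assert breakpoint_L / self.P == pytest.approx(1.0, abs=1e-9)
        fit = fit_binding_isotherm(TitrationCurve(L, sig, protein_total=self.P))
        assert any("upper-limit" in f for f in fit.flags)

    def test_noise_free_kd_recovery(self):
        df = fixtures.make_measurements(
            "titration", {"K_D": 2e-6, "protein_total": self.P, "eps_complex": 7730.0}
        )
        fit = fit_binding_isotherm(
            TitrationCurve(df["ligand_total_M"].to_numpy(), df["absorbance"].to_numpy(),
                           protein_total=self.P)
        )
        assert fit.params["K_D"] == pytest.approx(2e-6, rel=1e-6)
        assert fit.params["eps_complex"] == pytest.approx(7730.0, rel=1e-6)

    def test_fitted_curve_is_monotone_in_ligand(self):
        from minimet.biophys import binding_signal_1to1

        L = np.linspace(0, 4 * self.P, 200)
        sig = binding_signal_1to1(L, 300e-9, 7730.0, 0.0, self.P, 1.0)
        assert np.all(np.diff(sig) >= -1e-15)

    def test_tight_binding_recovery_within_factor_two(self):
        """K_D = 300 nM at 30 uM protein (deep tight-binding regime),
        1% noise: the fit brackets the truth within a factor of 2 in at
        least 90 of 100 seeds."""
        truth = 300e-9
        ok = 0
        for seed in range(100):
            df = fixtures.make_measurements(
                "titration",
                {"K_D": truth, "protein_total": self.P, "eps_complex": 7730.0},
                noise=0.01,
                seed=seed,
            )
            fit = fit_binding_isotherm(
                TitrationCurve(df["ligand_total_M"].to_numpy(), df["absorbance"].to_numpy(),
                               protein_total=self.P)
            )
            kd = fit.params["K_D"]
            if truth / 2 <= kd <= truth * 2:
                ok += 1
        assert ok >= 90

    def test_monotonicity_precondition(self):
        with pytest.raises(BiophysError):
            TitrationCurve(np.array([0.0, 2e-6, 1e-6]), np.zeros(3), protein_total=self.P)


class TestOptics:
    @pytest.mark.parametrize(
        "seq,cystine,expected",
        [("GGGG", 0, 0.0), ("W", 0, 5500.0), ("YY", 0, 2980.0), ("WYC", 1, 7115.0)],
    )
    def test_extinction_coefficient(self, seq, cystine, expected):
        assert extinction_coefficient(seq, cystine) == pytest.approx(expected)

    def test_miniprotein_sequence_has_two_tyrosines(self):
        seq = fixtures.METPSC1_LIKE_SEQUENCE
        assert len(seq) == 28 and seq.count("Y") == 2 and seq.count("W") == 0
        assert extinction_coefficient(seq, n_cystine=0) == pytest.approx(2980.0)

    def test_unknown_code_rejected(self):
        with pytest.raises(BiophysError, match="Z"):
            extinction_coefficient("AZA")

    def test_beer_lambert(self):
        assert beer_lambert_concentration(0.0, 6.54) == 0.0
        assert beer_lambert_concentration(0.2616, 6.54, 1.0) == pytest.approx(40.0)
        assert beer_lambert_concentration(0.2616, 6.54, 0.5) == pytest.approx(80.0)


def _bead_structure(coords):
    st = Structure(name="beads")
    res = Residue(name="GLB", seq_id=1, chain_id="A")
    for i, p in enumerate(coords):
        res.add_atom(Atom(f"C{i+1}", "C", p))
    st.add_residue(res)
    return st


class TestBeadModel:
    T, eta = 288.0, 1.138e-3

    def test_single_bead_is_stokes_einstein(self):
        st = _bead_structure([[0.0, 0.0, 0.0]])
        expected = BOLTZMANN * self.T / (6 * math.pi * self.eta * 3.1e-10) * 1e4
        for method in ("kirkwood", "shell"):
            d = bead_model_diffusion(st, T=self.T, viscosity=self.eta, method=method)
            tol = 1e-9 if method == "kirkwood" else 0.05 * expected
            assert d == pytest.approx(expected, abs=tol)

    def test_two_bead_kirkwood_closed_form(self):
        R = 8.0e-10
        st = _bead_structure([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0]])
        sigma = 3.1e-10
        expected = (
            BOLTZMANN * self.T / 2
            * (1 / (6 * math.pi * self.eta * sigma) + 1 / (6 * math.pi * self.eta * R))
        ) * 1e4
        d = bead_model_diffusion(st, T=self.T, viscosity=self.eta, method="kirkwood")
        assert d == pytest.approx(expected, rel=1e-12)

    def test_diffusion_decreases_with_growing_body(self):
        coords = [[3.0 * i, 0.0, 0.0] for i in range(10)]
        prev = None
        for n in range(2, 11):
            d = bead_model_diffusion(
                _bead_structure(coords[:n]), T=self.T, viscosity=self.eta, method="kirkwood"
            )
            if prev is not None:
                assert d < prev
            prev = d

    def test_duplicate_beads_rejected(self):
        st = _bead_structure([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(Exception, match="duplicate"):
            bead_model_diffusion(st, method="kirkwood")

    def test_shell_slower_than_kirkwood_on_compact_body(self):
        """The interaction-screened shell treatment must predict slower
        diffusion than the Kirkwood double-sum on a compact globule."""
        st = fixtures.make_compact_globule(n_residues=10, seed=2)
        dk = bead_model_diffusion(st, T=self.T, viscosity=self.eta, method="kirkwood")
        ds = bead_model_diffusion(st, T=self.T, viscosity=self.eta, method="shell")
        assert ds < dk
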