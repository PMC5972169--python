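import numpy as np
import pytest

import quenchmcr as qm
from quenchmcr.matrix_resolution import (
    match_components,
    mcr_als,
    resolve_multi_excitation,
    resolve_spectra,
    series_from_excitation,
    to_fractional,
    white_classical,
    white_fractional,
)
from quenchmcr.simulate import ComponentSpec, NoiseSpec

K_TRUE = np.array([5.0, 20.0, 100.0])   # ascending
K0_STANDARD = np.array([4.0, 120.0, 15.0])


class TestResolveSpectra:
    def test_exact_recovery(self, exact):
        series, truth = exact
        ST = resolve_spectra(truth["C"], series.intensities)
        assert np.allclose(ST, truth["S"].T, atol=1e-9 * truth["S"].max())

    def test_single_component_closed_form(self):
        Q = np.linspace(0, 0.2, 21)
        c = 1 / (1 + 20.0 * Q)
        s_true = np.array([1.0, 2.0, 3.0])
        Y = np.outer(c, s_true)
        ST = resolve_spectra(c[:, None], Y)
        assert np.allclose(ST[0], s_true)

    def test_equal_constants_rejected(self):
        Q = np.linspace(0, 0.2, 21)
        C = qm.sv_decay_matrix([20.0, 20.0], Q)
        with pytest.raises(ValueError, match="collinear|rank"):
            resolve_spectra(C, np.ones((21, 5)))


class TestWhiteClassical:
    def test_noise_free_identifiability(self, exact):
        series, truth = exact
        res = white_classical(series, K0_STANDARD)
        assert res.converged
        assert np.allclose(res.K, K_TRUE, rtol=1e-6)
        S_true = truth["S"][:, np.argsort(truth["K"])]
        assert (np.linalg.norm(res.S - S_true)
                <= 1e-8 * np.linalg.norm(S_true))

    def test_single_component(self):
        comp = [ComponentSpec(bands=[(450.0, 15.0, 1.0)], K=20.0)]
        series, _ = qm.synthesize_series(comp)
        res = white_classical(series, [10.0])
        assert res.K[0] == pytest.approx(20.0, rel=1e-6)
        assert np.allclose(res.S[:, 0], series.y0, rtol=1e-6)

    def test_initialization_independence_on_noisy_data(self, noisy):
        series, _ = noisy
        inits = [[5.0, 20.0, 100.0], [4.0, 15.0, 120.0], [49.0, 50.0, 51.0]]
        Ks = np.array([white_classical(series, K0).K for K0 in inits])
        assert np.all(Ks.max(axis=0) - Ks.min(axis=0) <= 0.1)


class TestFractional:
    def test_row0_all_ones(self, exact):
        series, _ = exact
        frac = to_fractional(series)
        assert np.allclose(frac.intensities[0], 1.0)

    def test_single_component_columns_identical(self):
        comp = [ComponentSpec(bands=[(450.0, 15.0, 1.0)], K=20.0)]
        series, _ = qm.synthesize_series(comp)
        frac = to_fractional(series)
        expected = 1 / (1 + 20.0 * frac.quencher_concs)
        assert np.allclose(frac.intensities,
                           expected[:, None] * np.ones(frac.wavelengths.size))

    def test_threshold_drops_tails(self, exact):
        series, _ = exact
        frac = to_fractional(series, threshold=0.05)
        assert frac.wavelengths.size < series.wavelengths.size
        kept_y0 = series.y0[np.isin(series.wavelengths, frac.wavelengths)]
        assert np.all(kept_y0 > 0.05 * series.y0.max())

    def test_fraction_closure_on_exact_data(self, exact):
        series, _ = exact
        res = white_fractional(series, K0_STANDARD)
        assert np.allclose(res.fractions.sum(axis=1), 1.0, atol=1e-10)

    def test_entrywise_spectra_match_pseudoinverse_spectra(self, exact):
        # spectra rebuilt from fractions times the reference row equal
        # the directly resolved spectra on the same window
        series, truth = exact
        rf = white_fractional(series, K0_STANDARD)
        rc = white_classical(series, K0_STANDARD)
        keep = np.isin(series.wavelengths, rf.wavelengths)
        assert np.allclose(rf.K, rc.K, rtol=1e-6)
        assert np.allclose(rf.S, rc.S[keep], rtol=1e-6,
                           atol=1e-8 * rc.S.max())

    def test_reduced_range_beats_full_range_on_noisy_data(self):
        # restricting the fit to the informative window improves the
        # resolved spectra; full range includes noise-exploded columns
        wins = 0
        for seed in range(20):
            noise = NoiseSpec(spectral_permille=0.5,
                              concentration_percent=5.0, seed=seed)
            series, truth = qm.synthesize_series(noise=noise)
            red = white_fractional(series, K0_STANDARD, window=(420.0, 500.0))
            full = white_fractional(series, K0_STANDARD, threshold=0.0)
            order = np.argsort(truth["K"])
            keep = ((series.wavelengths >= 420) & (series.wavelengths <= 500))
            S_true = truth["S"][keep][:, order]
            sel = np.isin(full.wavelengths, series.wavelengths[keep])
            e_red = np.linalg.norm(red.S - S_true)
            e_full = np.linalg.norm(full.S[sel] - S_true)
            wins += e_red < e_full
        assert wins >= 15


class TestMcrAls:
    def test_truth_is_fixed_point(self, exact):
        series, truth = exact
        C0 = qm.sv_decay_matrix(truth["K"], series.quencher_concs)
        res = mcr_als(series, C0)
        assert res.ssq < 1e-20
        assert res.n_iter <= 2

    def test_recovery_from_perturbed_initialization(self, exact):
        series, truth = exact
        C0 = qm.sv_decay_matrix(truth["K"] * 1.2, series.quencher_concs)
        res = mcr_als(series, C0, max_iter=500)
        match = match_components(res, reference_S=truth["S"])
        assert np.all(match.similarity > 0.99)

    def test_monotone_nonnegative_anchored(self, noisy):
        series, _ = noisy
        C0 = qm.sv_decay_matrix(K0_STANDARD, series.quencher_concs)
        res = mcr_als(series, C0)
        assert np.all(np.diff(res.ssq_trace) <= 1e-12)
        assert np.all(res.C >= 0) and np.all(res.S >= 0)
        assert np.allclose(res.C[0], 1.0)

    def test_shape_mismatch_rejected(self, exact):
        series, _ = exact
        with pytest.raises(ValueError):
            mcr_als(series, np.ones((5, 3)))


class TestMatchComponents:
    def test_self_match_identity(self, exact):
        series, truth = exact
        res = white_classical(series, K0_STANDARD)
        match = match_components(res, reference_S=res.S, reference_K=res.K)
        assert np.array_equal(match.permutation, [0, 1, 2])
        assert np.allclose(match.similarity, 1.0)
        assert np.allclose(match.K_errors, 0.0)

    def test_permuted_copy_recovered(self, exact):
        series, _ = exact
        res = white_classical(series, K0_STANDARD)
        perm = [2, 0, 1]
        match = match_components(res, reference_S=res.S[:, perm])
        assert np.array_equal(match.permutation, perm)

    def test_noisy_similarity_below_one_and_degrades(self):
        sims = []
        for y in (0.5, 5.0):
            vals = []
            for seed in range(5):
                noise = NoiseSpec(spectral_permille=y, seed=seed)
                series, truth = qm.synthesize_series(noise=noise)
                res = white_classical(series, K0_STANDARD)
                m = match_components(res, reference_S=truth["S"])
                vals.append(np.mean(m.similarity))
            sims.append(np.mean(vals))
        assert sims[0] < 1.0
        assert sims[1] < sims[0]


class TestMultiExcitationResolution:
    def test_averaged_spectra_match_truth_on_exact_data(self, exact_mset):
        mset, truth = exact_mset
        S_mean, results = resolve_multi_excitation(mset, K0_STANDARD)
        assert len(results) == mset.n_excitations
        ref = truth["S"][:, np.argsort(truth["K"])]
        ref = ref / ref.max(axis=0)
        assert np.allclose(S_mean, ref, atol=1e-6)

    def test_series_extraction(self, exact_mset):
        mset, truth = exact_mset
        s = series_from_excitation(mset, 2)
        assert s.excitation == mset.excitations[2]
        assert np.array_equal(s.intensities[0], mset.M0[2])
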