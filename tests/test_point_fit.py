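import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quenchmcr as qm
from quenchmcr.point_fit import (
    UnphysicalRootsError,
    aggregate_pointwise,
    dif_coefficients,
    dif_extract_constants,
    dif_extract_fractions,
    dif_model,
    fit_point,
    fit_series,
    fra_model,
)
from quenchmcr.simulate import ComponentSpec

Q21 = np.linspace(0.0, 0.2, 21)

# distinct positive constants / simplex-ish fractions for property tests
k_triples = st.lists(st.floats(0.5, 300.0), min_size=3, max_size=3,
                     unique=True).filter(
    lambda ks: min(abs(a - b) for i, a in enumerate(ks)
                   for b in ks[i + 1:]) > 0.05 * max(ks))
f_triples = st.lists(st.floats(0.05, 1.0), min_size=3, max_size=3)


class TestModels:
    def test_fra_at_zero_is_fraction_sum(self):
        f = np.array([0.2, 0.3, 0.4])
        assert fra_model([0.0], f, [5, 100, 20])[0] == pytest.approx(0.9)

    def test_fra_single_hyperbola(self):
        out = fra_model(Q21, [1.0, 0.0, 0.0], [20.0, 5.0, 100.0])
        assert np.allclose(out, 1 / (1 + 20.0 * Q21))

    def test_fra_direct_value(self):
        val = fra_model([0.2], [1 / 3] * 3, [5.0, 100.0, 20.0])[0]
        assert val == pytest.approx((0.5 + 1 / 21 + 0.2) / 3, rel=1e-12)

    def test_dif_at_zero_is_zero(self):
        p = dif_coefficients([1 / 3] * 3, [5.0, 100.0, 20.0])
        assert dif_model([0.0], p)[0] == 0.0

    def test_dif_saturates_at_one(self):
        # shared cubic coefficient forces the Q -> infinity limit to 1
        p = dif_coefficients([1 / 3] * 3, [5.0, 100.0, 20.0])
        assert dif_model([1e9], p)[0] == pytest.approx(1.0, rel=1e-6)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(f=f_triples, K=k_triples)
    def test_duality_dif_equals_one_minus_fra(self, f, K):
        # normalized fractions: the difference curve is the exact
        # complement of the sum-of-hyperbolas curve
        f = np.asarray(f) / np.sum(f)
        p = dif_coefficients(f, K)
        assert np.allclose(dif_model(Q21, p), 1 - fra_model(Q21, f, K),
                           rtol=1e-9, atol=1e-12)


class TestExtraction:
    def test_vieta_example(self):
        K = dif_extract_constants(125.0, 2600.0, 10000.0)
        assert np.allclose(K, [5.0, 20.0, 100.0])

    def test_triple_root(self):
        K = dif_extract_constants(3.0, 3.0, 1.0)
        assert np.allclose(K, [1.0, 1.0, 1.0], rtol=1e-4)

    def test_complex_roots_raise(self):
        with pytest.raises(UnphysicalRootsError):
            dif_extract_constants(1.0, 1.0, 5.0)

    def test_vieta_round_trip_bulk(self):
        # 1000 random positive triples: coefficients built by Vieta are
        # inverted exactly by the cubic root extraction
        rng = np.random.default_rng(42)
        for _ in range(1000):
            K = np.sort(rng.uniform(0.5, 300.0, size=3))
            if K[1] - K[0] < 0.02 * K[2] or K[2] - K[1] < 0.02 * K[2]:
                continue
            b1 = K.sum()
            b2 = K[0] * K[1] + K[1] * K[2] + K[0] * K[2]
            b3 = K.prod()
            assert np.allclose(dif_extract_constants(b1, b2, b3), K,
                               rtol=1e-6)

    def test_fraction_system_example(self):
        f = np.array([1 / 3] * 3)
        K = np.array([5.0, 100.0, 20.0])
        a = dif_coefficients(f, K)
        assert a[0] == pytest.approx(125.0 / 3.0)
        out, total = dif_extract_fractions(a[0], a[1], a[2], K)
        assert np.allclose(out, f)
        assert total == pytest.approx(1.0)

    def test_single_component_fraction(self):
        K = np.array([5.0, 100.0, 20.0])
        a = dif_coefficients([1.0, 0.0, 0.0], K)
        assert a[0] == pytest.approx(5.0)
        out, _ = dif_extract_fractions(a[0], a[1], a[2], K)
        assert np.allclose(out, [1.0, 0.0, 0.0], atol=1e-12)

    def test_duplicate_constants_rejected(self):
        with pytest.raises(ValueError):
            dif_extract_fractions(1.0, 1.0, 1.0, [5.0, 5.0, 20.0])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(f=f_triples, K=k_triples)
    def test_full_round_trip_identity(self, f, K):
        # (f, K) -> coefficients -> (f, K) is the identity
        f = np.asarray(f) / np.sum(f)
        K = np.sort(K)
        a1, a2, a3, b1, b2 = dif_coefficients(f, K)
        K_back = dif_extract_constants(b1, b2, a3)
        f_back, _ = dif_extract_fractions(a1, a2, a3, K_back)
        assert np.allclose(K_back, K, rtol=1e-6)
        assert np.allclose(f_back, f, atol=1e-6)


def selective_components():
    """Three emitters with a window (<=415 nm) where only A emits."""
    return [
        ComponentSpec(bands=[(405.0, 6.0, 1.0)], K=5.0, label="A"),
        ComponentSpec(bands=[(470.0, 10.0, 1.0)], K=100.0, label="B"),
        ComponentSpec(bands=[(445.0, 8.0, 1.0)], K=20.0, label="C"),
    ]


class TestFitPoint:
    def test_exact_data_both_models_agree(self, exact):
        series, _ = exact
        wl = 450.0
        fra = fit_point(series, wl, model="fra", tol=1e-12, max_iter=200)
        dif = fit_point(series, wl, model="dif", tol=1e-12, max_iter=200)
        assert fra.valid and dif.valid
        assert np.allclose(np.sort(fra.K), [5.0, 20.0, 100.0], rtol=1e-4)
        assert np.allclose(np.sort(dif.K), [5.0, 20.0, 100.0], rtol=1e-4)
        assert fra.ssq < 1e-16 and dif.ssq < 1e-16

    def test_selective_region_recovers_single_component(self):
        series, _ = qm.synthesize_series(selective_components())
        rec = fit_point(series, 405.0, model="fra", tol=1e-12, max_iter=200)
        j = int(np.argmax(rec.f))
        assert rec.K[j] == pytest.approx(5.0, rel=1e-3)
        assert rec.f[j] == pytest.approx(1.0, abs=1e-3)
        others = np.delete(rec.f, j)
        assert np.all(np.abs(others) < 1e-3)

    def test_identical_fractions_jittered_with_warning(self, exact):
        series, _ = exact
        with pytest.warns(UserWarning, match="jittered"):
            rec = fit_point(series, 450.0, model="fra",
                            f0=[1 / 3] * 3, K0=[4.0, 15.0, 120.0])
        assert rec.converged

    def test_off_grid_wavelength_rejected(self, exact):
        series, _ = exact
        with pytest.raises(ValueError):
            fit_point(series, 450.3, model="fra")


class TestAggregate:
    def test_identical_records_mean_is_record(self):
        rec = qm.PointFitRecord(450.0, "fra", np.array([5.0, 20.0, 100.0]),
                                np.array([0.2, 0.3, 0.5]), 0.0, True, True)
        agg = aggregate_pointwise([rec, rec, rec])
        assert np.allclose(agg.K_mean, [5.0, 20.0, 100.0])
        assert agg.n_used == 3

    def test_swapped_labels_same_aggregate(self):
        a = qm.PointFitRecord(450.0, "fra", np.array([5.0, 20.0, 100.0]),
                              np.array([0.2, 0.3, 0.5]), 0.0, True, True)
        b = qm.PointFitRecord(451.0, "fra", np.array([100.0, 20.0, 5.0]),
                              np.array([0.5, 0.3, 0.2]), 0.0, True, True)
        agg = aggregate_pointwise([a, b])
        assert np.allclose(agg.K_mean, [5.0, 20.0, 100.0])
        assert np.allclose(agg.fractions[0], agg.fractions[1])

    def test_invalid_records_excluded(self):
        good = qm.PointFitRecord(450.0, "fra", np.array([5.0, 20.0, 100.0]),
                                 np.zeros(3), 0.0, True, True)
        bad = qm.PointFitRecord(451.0, "fra", np.array([-1.0, 20.0, 100.0]),
                                np.zeros(3), 0.0, True, False)
        agg = aggregate_pointwise([good, bad])
        assert agg.n_used == 1 and agg.n_total == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_pointwise([])

    def test_exact_data_fraction_profiles_match_truth(self, exact):
        # on exact data the recovered fractions equal s_j(λ) / Σ s(λ)
        series, truth = exact
        wls = series.wavelengths[
            series.y0 > 0.05 * series.y0.max()][::20]
        recs = fit_series(series, model="fra", wavelengths=wls,
                          tol=1e-12, max_iter=200)
        agg = aggregate_pointwise(recs)
        S = truth["S"][:, np.argsort(truth["K"])]
        for wl, f in zip(agg.wavelengths, agg.fractions):
            i = int(np.argmin(np.abs(series.wavelengths - wl)))
            f_true = S[i] / S[i].sum()
            assert np.allclose(f, f_true, atol=5e-3)
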