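import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import gaussian_kde

from cortasym.cai import (
    CaiResult,
    DensitySettings,
    compute_cai,
    compute_cohort_cai,
    estimate_density,
    js_divergence,
    kld,
    shared_grid,
    silverman_bandwidth,
)
from cortasym.regions import N_REGIONS

from conftest import make_record


def kld_oracle(p, q):
    """Independent term-by-term summation in pure python."""
    return math.fsum(pi * math.log(pi / qi) for pi, qi in zip(p, q))


def js_oracle(p, q):
    m = [(pi + qi) / 2 for pi, qi in zip(p, q)]
    return 0.5 * kld_oracle(p, m) + 0.5 * kld_oracle(q, m)


class TestDivergences:
    def test_kld_matches_hand_computed_example(self):
        # 0.5 ln 2 + 0.5 ln(2/3)
        assert kld([0.5, 0.5], [0.25, 0.75]) == pytest.approx(0.14384103622589045, abs=1e-12)

    def test_kld_self_is_zero(self, rng):
        p = rng.uniform(0.01, 2.0, size=10)
        assert kld(p, p) == 0.0

    def test_matches_bruteforce_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            n = rng.integers(2, 17)
            p = rng.uniform(1e-6, 3.0, size=n)
            q = rng.uniform(1e-6, 3.0, size=n)
            assert kld(p, q) == pytest.approx(kld_oracle(p, q), abs=1e-12)
            assert js_divergence(p, q) == pytest.approx(js_oracle(p, q), abs=1e-12)

    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=12))
    def test_gibbs_inequality_on_simplex(self, raw):
        """KL >= 0 for normalised distributions (Gibbs' inequality)."""
        rng = np.random.default_rng(abs(hash(tuple(raw))) % 2**31)
        p = np.asarray(raw) / np.sum(raw)
        q = rng.dirichlet(np.ones(len(raw)))
        q = np.maximum(q, 1e-12)
        q = q / q.sum()
        assert kld(p, q) >= -1e-15

    def test_js_symmetric_bitwise(self, rng):
        for _ in range(50):
            p = rng.uniform(1e-3, 2.0, size=16)
            q = rng.uniform(1e-3, 2.0, size=16)
            assert js_divergence(p, q) == js_divergence(q, p)

    def test_js_self_is_zero(self, rng):
        p = rng.uniform(0.1, 1.0, size=8)
        assert js_divergence(p, p) == 0.0

    def test_disjoint_support_gives_ln2(self):
        floor = 1e-12
        p = np.array([1.0 - floor, floor])
        q = np.array([floor, 1.0 - floor])
        assert js_divergence(p, q) == pytest.approx(math.log(2), abs=1e-9)

    def test_length_mismatch_and_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="length"):
            kld([0.5, 0.5], [1.0])
        with pytest.raises(ValueError, match="finite"):
            kld([0.5, math.inf], [0.5, 0.5])
        with pytest.raises(ValueError):
            js_divergence([0.5, 0.0], [0.5, 0.5])


class TestDensity:
    def test_output_length_and_floor(self, rng):
        settings = DensitySettings(grid_points=64)
        sample = rng.uniform(2.0, 3.0, size=34)
        grid = shared_grid(sample, sample, settings)
        est = estimate_density(sample, grid, settings)
        assert est.values.shape == (64,)
        assert est.values.min() >= settings.floor

    def test_unimodal_sample_peaks_at_mode(self):
        rng = np.random.default_rng(7)
        sample = 2.5 + 0.05 * rng.standard_normal(34)
        settings = DensitySettings()
        grid = shared_grid(sample, sample, settings)
        est = estimate_density(sample, grid, settings)
        step = grid[1] - grid[0]
        assert abs(grid[np.argmax(est.values)] - 2.5) <= step + 0.05

    def test_deterministic(self, rng):
        sample = rng.uniform(2.0, 3.0, size=34)
        settings = DensitySettings()
        grid = shared_grid(sample, sample, settings)
        a = estimate_density(sample, grid, settings).values
        b = estimate_density(sample, grid, settings).values
        np.testing.assert_array_equal(a, b)

    def test_matches_scipy_kde_with_matched_bandwidth(self, rng):
        """Cross-check the Gaussian KDE against the scipy implementation."""
        sample = rng.uniform(2.0, 3.0, size=34)
        h = 0.08
        settings = DensitySettings(bandwidth_rule="fixed", fixed_bandwidth=h)
        grid = shared_grid(sample, sample, settings)
        ours = estimate_density(sample, grid, settings).values
        ref = gaussian_kde(sample, bw_method=h / sample.std(ddof=1))(grid)
        np.testing.assert_allclose(ours, np.maximum(ref, settings.floor), rtol=1e-10)

    def test_histogram_density_integrates_to_one(self, rng):
        sample = rng.uniform(2.0, 3.0, size=34)
        settings = DensitySettings(estimator="histogram")
        grid = shared_grid(sample, sample, settings)
        est = estimate_density(sample, grid, settings)
        step = grid[1] - grid[0]
        assert est.values.sum() * step == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_falls_back_to_fixed_bandwidth(self):
        sample = np.full(34, 2.5)
        grid = np.linspace(2.0, 3.0, 128)
        with pytest.raises(ValueError, match="fixed_bandwidth"):
            estimate_density(sample, grid, DensitySettings())
        settings = DensitySettings(fixed_bandwidth=0.1)
        est = estimate_density(sample, grid, settings)
        assert np.isfinite(est.values).all()

    def test_silverman_uses_smaller_of_sd_and_iqr(self, rng):
        sample = rng.standard_normal(34)
        h = silverman_bandwidth(sample)
        sd = sample.std(ddof=1)
        q75, q25 = np.percentile(sample, [75, 25])
        assert h == pytest.approx(0.9 * min(sd, (q75 - q25) / 1.34) * 34 ** (-0.2))


class TestSharedGrid:
    def test_padded_span_formula(self):
        settings = DensitySettings(grid_padding_fraction=0.10)
        grid = shared_grid(np.array([2.0, 2.5]), np.array([2.4, 3.0]), settings)
        assert grid[0] == pytest.approx(1.9)
        assert grid[-1] == pytest.approx(3.1)

    def test_strictly_increasing_constant_step(self, rng):
        grid = shared_grid(rng.uniform(1, 4, 34), rng.uniform(1, 4, 34), DensitySettings())
        steps = np.diff(grid)
        assert (steps > 0).all()
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)

    def test_zero_range_uses_mean_based_pad(self):
        settings = DensitySettings(grid_padding_fraction=0.10)
        grid = shared_grid(np.full(34, 2.0), np.full(34, 2.0), settings)
        assert grid[0] == pytest.approx(2.0 - 0.2)
        assert grid[-1] == pytest.approx(2.0 + 0.2)


class TestComputeCai:
    def test_identical_hemispheres_give_zero(self, rng):
        rec = make_record(rng)
        rec.rh_thickness = rec.lh_thickness.copy()
        assert compute_cai(rec).cai == 0.0

    def test_larger_shift_gives_larger_cai(self):
        results = []
        for shift in (0.1, 0.2):
            shifted = make_record(np.random.default_rng(3))
            shifted.rh_thickness = shifted.lh_thickness + shift
            results.append(compute_cai(shifted).cai)
        assert results[1] > results[0] > 0

    def test_nonnegative_and_finite_random_records(self):
        rng = np.random.default_rng(99)
        for i in range(100):
            r = compute_cai(make_record(rng, subject_id=f"R{i}"))
            assert r.cai >= 0 and math.isfinite(r.cai)

    def test_region_permutation_invariance(self, rng):
        """The index depends only on the multiset of values per hemisphere."""
        rec = make_record(rng)
        base = compute_cai(rec).cai
        perm = rng.permutation(N_REGIONS)
        rec.lh_thickness = rec.lh_thickness[perm]
        rec.rh_thickness = rec.rh_thickness[perm]
        assert compute_cai(rec).cai == base

    def test_normalised_disjoint_supports_approach_sqrt_ln2(self, rng):
        rec = make_record(rng)
        rec.lh_thickness = 2.0 + 0.001 * rng.standard_normal(N_REGIONS)
        rec.rh_thickness = 3.0 + 0.001 * rng.standard_normal(N_REGIONS)
        settings = DensitySettings(normalise=True)
        assert compute_cai(rec, settings).cai == pytest.approx(math.sqrt(math.log(2)), abs=1e-4)

    def test_settings_recorded_in_result(self, rng):
        settings = DensitySettings(grid_points=32)
        res = compute_cai(make_record(rng), settings)
        assert isinstance(res, CaiResult)
        assert res.settings.grid_points == 32


class TestCohortCai:
    def test_empty_records_empty_table(self):
        table = compute_cohort_cai([])
        assert list(table.columns) == ["subject_id", "visit", "cai"]
        assert len(table) == 0

    def test_record_order_irrelevant(self, rng):
        records = [make_record(rng, subject_id=f"S{i}") for i in range(5)]
        a = compute_cohort_cai(records).set_index("subject_id")["cai"]
        b = compute_cohort_cai(records[::-1]).set_index("subject_id")["cai"]
        assert (a.sort_index() == b.sort_index()).all()

    def test_error_carries_subject_id(self, rng):
        rec = make_record(rng, subject_id="BAD")
        rec.lh_thickness = rec.lh_thickness.copy()
        rec.lh_thickness[:] = 2.5
        rec.rh_thickness = rec.lh_thickness.copy()
        # zero-variance both hemispheres with silverman rule and no fallback
        with pytest.raises(RuntimeError, match="BAD"):
            compute_cohort_cai([rec], DensitySettings())


def test_tracks_classical_laterality_index_ranking():
    """Comparator check: across a cohort of records with graded rightward
    shifts, the index ranks subjects like the classical mean laterality
    index 2(L-R)/(L+R) (not a supported output, used only as a reference)."""
    from scipy.stats import spearmanr

    cais, lis = [], []
    for i, shift in enumerate(np.linspace(0.0, 0.25, 12)):
        rec = make_record(np.random.default_rng(50 + i), subject_id=f"C{i}")
        rec.rh_thickness = rec.lh_thickness - shift
        cais.append(compute_cai(rec).cai)
        li = 2 * (rec.lh_thickness - rec.rh_thickness) / (rec.lh_thickness + rec.rh_thickness)
        lis.append(np.abs(li).mean())
    assert spearmanr(cais, lis).statistic > 0.9
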