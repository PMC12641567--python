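"""Histogram construction and Gaussian mixture decomposition."""

import numpy as np
import pytest

from cdmspipe.histograms import (
    GaussianMixtureModel,
    Histogram,
    centroid,
    charge_histogram,
    fit_gaussian_mixture,
    histogram1d,
    histogram2d,
    mass_histogram,
)
from cdmspipe.rayleigh import rayleigh_charge_for_mass


class TestHistogram1d:
    def test_integer_centered_counting(self):
        h = histogram1d([165, 165, 150], 1.0)
        by_center = dict(zip(h.centers, h.counts))
        assert by_center[165.0] == 2 and by_center[150.0] == 1

    def test_boundary_value_right_open(self):
        h = histogram1d([164.5], 1.0)
        assert h.centers[np.argmax(h.counts)] == 165.0

    def test_counts_conserved(self, rng):
        v = rng.normal(100, 10, 5000)
        assert histogram1d(v, 1.0).n == 5000
        assert mass_histogram(rng.normal(5e6, 5e4, 1234)).n == 1234

    def test_empty_input_gives_empty_histogram(self):
        h = histogram1d([], 1.0)
        assert h.n == 0
        assert np.all(h.counts == 0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            histogram1d([1.0], 0.0)


class TestHistogram2d:
    def test_single_ion_single_cell(self):
        h2 = histogram2d([4.93e6], [165.0])
        assert h2.counts.sum() == 1
        assert np.count_nonzero(h2.counts) == 1

    def test_marginals_match_1d(self, rng):
        m = rng.normal(5e6, 1e5, 2000)
        z = rng.normal(160, 5, 2000)
        h2 = histogram2d(m, z)
        hm = np.histogram(m, bins=h2.mass_edges)[0]
        hz = np.histogram(z, bins=h2.charge_edges)[0]
        assert np.array_equal(h2.counts.sum(axis=1).astype(int), hm)
        assert np.array_equal(h2.counts.sum(axis=0).astype(int), hz)

    def test_rayleigh_band_fragments_sit_below_overlay(self, rng):
        m = rng.uniform(1e6, 8e6, 3000)
        z = rayleigh_charge_for_mass(m) * rng.uniform(0.82, 1.0, 3000)
        h2 = histogram2d(m, z)
        # ions below/at the overlay line at their own mass bin
        centers = h2.mass_centers
        idx = np.clip(np.searchsorted(h2.mass_edges, m) - 1, 0, len(centers) - 1)
        frac_below = np.mean(z <= h2.rayleigh_overlay_e[idx] * 1.02)
        assert frac_below >= 0.90

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            histogram2d([1.0, 2.0], [1.0])


class TestGaussianMixture:
    def test_seven_component_recovery(self, rng):
        centers = [171, 159, 147, 137, 128, 117, 102]
        v = np.concatenate([rng.normal(c, 4, 1000) for c in centers])
        init = np.array(centers) + rng.uniform(-3, 3, 7)
        res = fit_gaussian_mixture(charge_histogram(v), k=7, init=init)
        assert np.all(np.abs(res.centroids - sorted(centers, reverse=True)) <= 2.0)

    def test_single_gaussian_matches_moment_estimate(self, rng):
        v = rng.normal(165, 4, 8000)
        res = fit_gaussian_mixture(charge_histogram(v), k=1)
        assert res.centroids[0] == pytest.approx(v.mean(), abs=0.2)

    def test_one_bin_histogram_degenerate(self):
        h = histogram1d([165.2] * 10, 1.0)
        with pytest.raises(ValueError):
            fit_gaussian_mixture(h, k=1)

    def test_scale_equivariance(self, rng):
        v = np.concatenate([rng.normal(120, 3, 3000), rng.normal(160, 3, 3000)])
        h = charge_histogram(v)
        res1 = fit_gaussian_mixture(h, k=2)
        h5 = Histogram(bin_edges=h.bin_edges, counts=h.counts * 5)
        res5 = fit_gaussian_mixture(h5, k=2)
        assert np.allclose(res1.centroids, res5.centroids, atol=0.05)
        assert np.allclose(res1.sigmas, res5.sigmas, atol=0.05)
        assert np.allclose(res5.areas, 5 * res1.areas, rtol=0.02)

    def test_auto_k_recovers_true_component_count(self):
        """k='auto' picks k0 for well-separated mixtures (scaled: 30 seeds)."""
        hits = tries = 0
        cases = {1: [150], 2: [120, 160], 3: [100, 130, 165]}
        for k0, centers in cases.items():
            for s in range(10):
                r = np.random.default_rng(1000 + 17 * k0 + s)
                v = np.concatenate([r.normal(c, 3, 3000) for c in centers])
                res = fit_gaussian_mixture(charge_histogram(v), k="auto")
                tries += 1
                hits += res.k == k0
        assert hits >= 0.9 * tries

    def test_centroids_invariant_to_halved_bin_width(self, rng):
        v = np.concatenate([rng.normal(120, 4, 5000), rng.normal(160, 4, 5000)])
        r1 = fit_gaussian_mixture(histogram1d(v, 1.0), k=2)
        r2 = fit_gaussian_mixture(histogram1d(v, 0.5), k=2)
        assert np.all(np.abs(r1.centroids - r2.centroids) <= 0.1)

    def test_components_sorted_descending(self, rng):
        v = np.concatenate([rng.normal(c, 3, 2000) for c in (110, 140, 170)])
        res = fit_gaussian_mixture(charge_histogram(v), k=3)
        assert np.all(np.diff(res.centroids) < 0)

    def test_summary_renders(self, rng):
        res = fit_gaussian_mixture(charge_histogram(rng.normal(150, 4, 2000)), k=1)
        s = res.summary()
        assert "centroid" in s and "BIC" in s


class TestCentroid:
    def test_symmetric_histogram(self, rng):
        v = rng.normal(150.0, 5.0, 20_000)
        assert centroid(charge_histogram(v)) == pytest.approx(150.0, abs=0.15)

    def test_mass_ensemble_recovery(self, rng):
        v = rng.normal(4.93e6, 4.93e6 * 0.007, 2000)
        assert centroid(mass_histogram(v)) == pytest.approx(4.93e6, rel=0.003)

    def test_bimodal_falls_back_flagged(self, rng):
        v = np.concatenate([rng.normal(100, 2, 3000), rng.normal(160, 2, 1500)])
        value, flagged = centroid(charge_histogram(v), full_output=True)
        assert flagged
        assert value == pytest.approx(np.mean(v), abs=1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            centroid(histogram1d([], 1.0))
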