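"""WHAM reconstruction, error estimators and binding free-energy extraction."""

import numpy as np
import pytest

import s100kit as sk
from s100kit.structure import Selection
from s100kit.wham import RT_300K


# ---------------------------------------------------------------------------
# reaction coordinate

class TestReactionCoordinate:
    def _structure(self, entries):
        atoms = [sk.Atom("CA", "C", rn, "ALA", ch, np.asarray(xyz, float), mass)
                 for rn, ch, xyz, mass in entries]
        return sk.Structure(atoms)

    def test_three_four_five(self):
        s = self._structure([(1, "P", (0, 0, 0), 12.0),
                             (1, "A", (3, 4, 0), 12.0)])
        rc = sk.RCDefinition(Selection.of(chain_id="P"), Selection.of(chain_id="A"))
        assert sk.reaction_coordinate(s, rc) == pytest.approx(5.0)

    def test_com_of_symmetric_pair(self):
        s = self._structure([(1, "P", (-1, 0, 0), 12.0),
                             (2, "P", (1, 0, 0), 12.0),
                             (1, "A", (10, 0, 0), 12.0)])
        rc = sk.RCDefinition(Selection.of(chain_id="P"), Selection.of(chain_id="A"))
        assert sk.reaction_coordinate(s, rc) == pytest.approx(10.0)

    def test_unequal_masses_hand_computed(self):
        entries = [(1, "P", (0, 0, 0), 12.0), (2, "P", (3, 0, 0), 1.0),
                   (3, "P", (0, 6, 0), 16.0),
                   (1, "A", (10, 0, 0), 14.0), (2, "A", (10, 4, 0), 14.0),
                   (3, "A", (18, 0, 0), 32.0)]
        s = self._structure(entries)
        com1 = (12 * np.array([0, 0, 0]) + 1 * np.array([3, 0, 0])
                + 16 * np.array([0, 6, 0])) / 29
        com2 = (14 * np.array([10, 0, 0]) + 14 * np.array([10, 4, 0])
                + 32 * np.array([18, 0, 0])) / 60
        rc = sk.RCDefinition(Selection.of(chain_id="P"), Selection.of(chain_id="A"))
        assert sk.reaction_coordinate(s, rc) == \
               pytest.approx(float(np.linalg.norm(com1 - com2)))

    def test_empty_group_raises(self):
        s = self._structure([(1, "P", (0, 0, 0), 12.0)])
        rc = sk.RCDefinition(Selection.of(chain_id="P"), Selection.of(chain_id="Z"))
        with pytest.raises(ValueError):
            sk.reaction_coordinate(s, rc)


# ---------------------------------------------------------------------------
# WHAM core

def _gaussian_window_samples(rng, a, z0, center, k_bias, rt, n):
    """Exact Boltzmann samples of U(z)=a(z-z0)^2 under a half-convention bias."""
    curv = 2 * a + k_bias
    mean = (2 * a * z0 + k_bias * center) / curv
    return rng.normal(mean, np.sqrt(rt / curv), size=n)


def _parabola_windows(a=0.4, z0=5.0, k=10.0, n=4000, rt=RT_300K, seed=0,
                      centers=None):
    rng = np.random.default_rng(seed)
    centers = np.arange(2.0, 8.5, 0.5) if centers is None else centers
    return [sk.UmbrellaWindow(c, _gaussian_window_samples(rng, a, z0, c, k, rt, n),
                              force_constant=k) for c in centers]


class TestWham:
    def test_unbiased_window_reduces_to_histogram(self):
        samples = np.concatenate([np.full(10, 1.05), np.full(20, 1.15),
                                  np.full(40, 1.25)])
        w = sk.UmbrellaWindow(0.0, samples, force_constant=0.0)
        prof = sk.wham([w], bin_width=0.1, rt=1.0)
        counts = np.array([10, 20, 40])
        expected = -np.log(counts / counts.sum())
        expected -= expected.min()
        np.testing.assert_allclose(prof.G, expected, atol=1e-9)

    def test_recovers_generating_parabola(self):
        a, z0 = 0.4, 5.0
        windows = _parabola_windows(a=a, z0=z0, seed=1)
        prof = sk.wham(windows, bin_width=0.1)
        truth = a * (prof.z - z0) ** 2
        truth -= truth.min()
        # compare where sampling is adequate
        total = np.concatenate([w.samples for w in windows])
        counts, _ = np.histogram(total, bins=np.append(prof.z - 0.05,
                                                       prof.z[-1] + 0.05))
        well = counts > 200
        assert np.sqrt(np.mean((prof.G[well] - truth[well]) ** 2)) < 0.1

    def test_duplicated_window_invariance(self):
        """Duplicating every window (same samples, same centres) changes the
        statistical weights uniformly, so the profile is unchanged."""
        windows = _parabola_windows(n=1000, seed=2)
        prof1 = sk.wham(windows, bin_width=0.1)
        prof2 = sk.wham(windows + windows, bin_width=0.1)
        np.testing.assert_allclose(prof1.G, prof2.G, atol=1e-8)

    def test_window_order_invariance(self):
        windows = _parabola_windows(n=1000, seed=3)
        prof1 = sk.wham(windows, bin_width=0.1)
        prof2 = sk.wham(windows[::-1], bin_width=0.1)
        np.testing.assert_allclose(prof1.G, prof2.G, atol=1e-8)

    def test_empty_windows_raise(self):
        with pytest.raises(ValueError):
            sk.wham([])

    def test_gap_warns(self):
        w1 = sk.UmbrellaWindow(0.0, np.full(50, 0.0), 10.0)
        w2 = sk.UmbrellaWindow(5.0, np.full(50, 5.0), 10.0)
        with pytest.warns(UserWarning, match="gap"):
            sk.wham([w1, w2], bin_width=0.1)

    def test_error_shrinks_with_sample_size(self):
        a, z0 = 0.4, 5.0

        def rms_at(n, seed):
            windows = _parabola_windows(a=a, z0=z0, n=n, seed=seed)
            prof = sk.wham(windows, bin_width=0.1)
            truth = a * (prof.z - z0) ** 2
            truth -= truth.min()
            total = np.concatenate([w.samples for w in windows])
            counts, _ = np.histogram(
                total, bins=np.append(prof.z - 0.05, prof.z[-1] + 0.05))
            good = counts > 0.01 * n
            return np.sqrt(np.mean((prof.G[good] - truth[good]) ** 2))

        assert rms_at(8000, seed=4) < rms_at(250, seed=4)

    def test_agrees_with_reference_wham_iteration(self):
        """Solver vs a plainly-written textbook WHAM iteration, all bins."""
        rt = RT_300K
        k = 10.0
        windows = _parabola_windows(k=k, n=400, seed=5,
                                    centers=np.arange(3.0, 7.5, 0.5))
        prof = sk.wham(windows, bin_width=0.1, rt=rt)

        # reference: direct probability-space fixed-point iteration
        edges = np.append(prof.z - 0.05, prof.z[-1] + 0.05)
        counts = np.stack([np.histogram(w.samples, bins=edges)[0]
                           for w in windows]).astype(float)
        N = counts.sum(axis=1)
        M = counts.sum(axis=0)
        c = np.exp(-np.stack([0.5 * k * (prof.z - w.center) ** 2
                              for w in windows]) / rt)
        Zi = np.ones(len(windows))
        for _ in range(200000):
            p = M / ((N / Zi)[:, None] * c).sum(axis=0)
            p /= p.sum()
            Zi_new = (c * p[None, :]).sum(axis=1)
            if np.max(np.abs(np.log(Zi_new / Zi))) < 1e-13:
                Zi = Zi_new
                break
            Zi = Zi_new
        G_ref = -rt * np.log(p)
        G_ref -= G_ref.min()
        np.testing.assert_allclose(prof.G, G_ref, atol=0.05)
        assert np.max(np.abs(prof.G - G_ref)) < 1e-5

    def test_agrees_with_unbinned_mbar_on_well_sampled_bins(self):
        """Binned WHAM vs independent sample-based MBAR where counts are
        high enough that binning discretisation is negligible."""
        rt = RT_300K
        k = 10.0
        windows = _parabola_windows(k=k, n=2000, seed=5,
                                    centers=np.arange(3.0, 7.5, 0.5))
        prof = sk.wham(windows, bin_width=0.1, rt=rt)

        x = np.concatenate([w.samples for w in windows])
        N = np.array([w.samples.size for w in windows], float)
        u = np.stack([0.5 * k * (x - w.center) ** 2 for w in windows]) / rt
        f = np.zeros(len(windows))
        for _ in range(20000):
            log_denom = np.logaddexp.reduce(
                np.log(N)[:, None] + f[:, None] - u, axis=0)
            f_new = -np.logaddexp.reduce(-u - log_denom, axis=1)
            f_new -= f_new[0]
            converged = np.max(np.abs(f_new - f)) < 1e-12
            f = f_new
            if converged:
                break
        logw = -np.logaddexp.reduce(np.log(N)[:, None] + f[:, None] - u, axis=0)
        edges = np.append(prof.z - 0.05, prof.z[-1] + 0.05)
        which = np.digitize(x, edges) - 1
        counts = np.bincount(which[(which >= 0) & (which < prof.z.size)],
                             minlength=prof.z.size)
        G_oracle = np.full(prof.z.size, np.nan)
        for b in np.where(counts >= 100)[0]:
            G_oracle[b] = -rt * np.logaddexp.reduce(logw[which == b])
        ok = ~np.isnan(G_oracle)
        shift = np.mean(prof.G[ok] - G_oracle[ok])
        assert np.max(np.abs(prof.G[ok] - G_oracle[ok] - shift)) < 0.05


# ---------------------------------------------------------------------------
# error estimators

class TestBlockVariance:
    def test_constant_series_zero(self):
        res = sk.block_variance(np.full(1000, 3.14), 200)
        assert res.variance_of_mean == 0.0
        assert res.n_blocks == 5

    def test_alternating_series_zero(self):
        s = np.tile([1.0, -1.0], 100)
        assert sk.block_variance(s, 2).variance_of_mean == pytest.approx(0.0)

    def test_ar1_matches_direct_recomputation(self):
        rng = np.random.default_rng(6)
        n, phi = 5000, 0.8
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal()
        res = sk.block_variance(x, 200)
        n_blocks = n // 200
        means = [x[i * 200:(i + 1) * 200].mean() for i in range(n_blocks)]
        expected = np.var(means, ddof=1) / n_blocks
        assert res.variance_of_mean == pytest.approx(expected, rel=1e-12)

    def test_trailing_partial_block_dropped(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=450)
        assert sk.block_variance(x, 200).variance_of_mean == \
               sk.block_variance(x[:400], 200).variance_of_mean

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            sk.block_variance(np.ones(250), 200)


class TestPropagatedError:
    def _windows(self, sigmas, k=18.0, spacing=0.5):
        rng = np.random.default_rng(8)
        out = []
        for i, s in enumerate(sigmas):
            center = 10.0 + i * spacing
            samples = center + rng.normal(0, max(s, 1e-12), 400)
            out.append(sk.UmbrellaWindow(center, samples, k))
        return out

    def test_zero_sigma_zero_error(self):
        windows = [sk.UmbrellaWindow(10.0 + 0.5 * i, np.full(400, 10.0 + 0.5 * i))
                   for i in range(5)]
        blocks = [sk.block_variance(w.samples, 200) for w in windows]
        grid = np.linspace(10, 12, 21)
        np.testing.assert_array_equal(
            sk.propagate_pmf_error(windows, blocks, grid), 0.0)

    def test_single_noisy_window_localised_step(self):
        windows = self._windows([0.0, 0.0, 0.3, 0.0, 0.0])
        blocks = [sk.block_variance(w.samples, 200) for w in windows]
        grid = np.array([10.0, 10.5, 11.0, 11.5, 12.0])
        eps = sk.propagate_pmf_error(windows, blocks, grid)
        np.testing.assert_allclose(eps[:2], 0.0, atol=1e-9)
        assert eps[2] > 1e-3
        np.testing.assert_allclose(eps[2:], eps[2])

    def test_equal_sigma_sqrt_growth(self):
        k, spacing = 18.0, 0.5
        windows = self._windows([0.2] * 6, k=k, spacing=spacing)
        blocks = [sk.BlockAverageResult(200, 2, 1e-4) for _ in windows]
        grid = np.array([10.0 + spacing * i for i in range(6)])
        eps = sk.propagate_pmf_error(windows, blocks, grid)
        # closed form of the quadrature sum: first window is the reference
        expected = k * spacing * 1e-2 * np.sqrt(np.arange(6))
        np.testing.assert_allclose(eps, expected, rtol=1e-12)
        assert np.all(np.diff(eps) >= 0)


class TestBootstrap:
    def test_deterministic_under_seed(self):
        windows = _parabola_windows(n=500, seed=9,
                                    centers=np.arange(3.5, 6.6, 0.5))
        e1 = sk.bootstrap_error(windows, n_trials=5, seed=77).error
        e2 = sk.bootstrap_error(windows, n_trials=5, seed=77).error
        np.testing.assert_array_equal(e1, e2)

    def test_constant_windows_zero_error(self):
        windows = [sk.UmbrellaWindow(c, np.full(300, c), 10.0)
                   for c in (2.0, 2.1, 2.2)]
        prof = sk.bootstrap_error(windows, n_trials=10, seed=1)
        np.testing.assert_allclose(prof.error, 0.0, atol=1e-12)

    def test_single_window_matches_multinomial_standard_error(self):
        """Bootstrap ε vs the closed-form histogram error, within factor 2."""
        rng = np.random.default_rng(10)
        rt = RT_300K
        samples = rng.normal(5.0, 0.6, size=3000)
        w = sk.UmbrellaWindow(0.0, samples, force_constant=0.0)
        import warnings
        with warnings.catch_warnings():
            # sparse Gaussian tail bins legitimately trigger gap warnings
            warnings.simplefilter("ignore", UserWarning)
            prof = sk.bootstrap_error([w], n_trials=30, seed=3, rt=rt)
        edges = np.append(prof.z - 0.05, prof.z[-1] + 0.05)
        counts, _ = np.histogram(samples, bins=edges)
        p = counts / counts.sum()
        mid = (p > 0.02) & (p < 0.8 * p.max())
        analytic = rt * np.sqrt((1 - p[mid]) / (counts.sum() * p[mid]))
        ratio = prof.error[mid] / analytic
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)


# ---------------------------------------------------------------------------
# binding free energy

class TestBindingDg:
    def _profile(self, z, G, err=None):
        return sk.PMFProfile(np.asarray(z, float),
                             np.asarray(G, float) - np.min(G),
                             None if err is None else np.asarray(err, float))

    def test_flat_profile_zero(self):
        prof = self._profile(np.linspace(10, 30, 50), np.zeros(50))
        assert sk.binding_dg(prof, (12, 16), (25, 30))[0] == 0.0

    def test_constructed_well_depth(self):
        z = np.linspace(10, 30, 201)
        G = 9.5 - 9.5 * np.exp(-((z - 14) ** 2) / 2.0)
        prof = self._profile(z, G)
        dg, _ = sk.binding_dg(prof, (12, 16), (28, 30))
        assert dg == pytest.approx(-9.5, abs=1e-6)

    def test_double_well_hand_read(self):
        z = np.linspace(0, 10, 101)
        G = np.full_like(z, 4.0)
        G[20] = 1.0      # local well at z=2
        G[60] = 0.0      # global well at z=6
        prof = sk.PMFProfile(z, G)
        dg, _ = sk.binding_dg(prof, (0, 8), (9, 10))
        assert dg == pytest.approx(0.0 - 4.0)

    def test_region_outside_grid_raises(self):
        prof = self._profile(np.linspace(10, 20, 11), np.zeros(11))
        with pytest.raises(ValueError):
            sk.binding_dg(prof, (30, 40), (10, 20))


# ---------------------------------------------------------------------------
# double-well study fixture (shared with acceptance)

class TestDoubleWellRecovery:
    def test_pmf_rms_within_tolerance(self, double_well, umbrella_windows,
                                      wham_profile):
        u = double_well.u(wham_profile.z)
        u -= u.min()
        assert np.sqrt(np.mean((wham_profile.G - u) ** 2)) < 0.15

    def test_binding_dg_recovers_well_depth(self, wham_profile):
        dg, _ = sk.binding_dg(wham_profile, (12, 16), (28, 33.5))
        assert dg == pytest.approx(-9.5, abs=0.2)
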