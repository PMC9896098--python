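"""Seed-based FC maps, Fisher z, group t-maps, cluster labeling."""

import numpy as np
import pytest
from scipy import ndimage, stats

import fcfwer as f


@pytest.fixture(scope="module")
def subject():
    cfg = f.SyntheticConfig(grid_shape=(32, 32), n_subjects=1, fwhm_true=5.0,
                            n_frames=240, frame_rate=1.0, ar1_coeff=0.3,
                            rng_seed=17)
    return f.simulate_timeseries(cfg)[0]


class TestGlobalSignalRegression:
    def test_global_trace_data_regresses_to_zero(self, subject):
        g = np.sin(np.arange(subject.stack.shape[0]) / 5.0) + 2.0
        stack = np.tile(g[:, None, None], (1, *subject.valid_mask.shape))
        ds = f.SubjectDataset("x", stack, subject.valid_mask, 1.0)
        out = f.global_signal_regress(ds)
        assert np.abs(out.stack[:, out.valid_mask]).max() < 1e-10

    def test_framewise_mask_mean_is_zero(self, subject):
        out = f.global_signal_regress(subject)
        means = out.stack[:, out.valid_mask].mean(axis=1)
        assert np.abs(means).max() < 1e-10

    def test_matches_per_pixel_ols_oracle(self, subject):
        out = f.global_signal_regress(subject)
        mask = subject.valid_mask
        g = subject.stack[:, mask].mean(axis=1)
        rows, cols = np.where(mask)
        for i in (0, 57, 200):
            y = subject.stack[:, rows[i], cols[i]]
            X = np.column_stack([np.ones_like(g), g])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ beta
            np.testing.assert_allclose(out.stack[:, rows[i], cols[i]], resid, atol=1e-9)


class TestBandpass:
    def make_sine(self, freq, n=600, fs=1.0):
        t = np.arange(n) / fs
        stack = np.zeros((n, 8, 8))
        stack[:] = np.sin(2 * np.pi * freq * t)[:, None, None]
        return f.SubjectDataset("s", stack, np.ones((8, 8), bool), fs)

    def test_in_band_sinusoid_preserved(self):
        out = f.bandpass_filter(self.make_sine(0.05), 0.01, 0.1)
        amp = out.stack[100:-100, 0, 0].std() * np.sqrt(2)
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_sinusoid_attenuated(self):
        out = f.bandpass_filter(self.make_sine(0.3), 0.01, 0.1)
        amp = out.stack[100:-100, 0, 0].std() * np.sqrt(2)
        assert amp < 0.1

    def test_dc_offset_removed(self):
        ds = self.make_sine(0.05)
        ds.stack += 7.0
        out = f.bandpass_filter(ds, 0.01, 0.1)
        assert abs(out.stack[100:-100].mean()) < 0.01

    def test_near_idempotent_in_band(self):
        once = f.bandpass_filter(self.make_sine(0.05), 0.01, 0.1)
        twice = f.bandpass_filter(once, 0.01, 0.1)
        a1 = once.stack[100:-100, 0, 0].std()
        a2 = twice.stack[100:-100, 0, 0].std()
        assert a2 == pytest.approx(a1, rel=0.05)


class TestSeedTrace:
    def test_uniform_image_gives_constant_trace(self, subject):
        stack = np.full_like(subject.stack, 3.5)
        ds = f.SubjectDataset("u", stack, np.ones(subject.valid_mask.shape, bool), 1.0)
        seed = f.SeedSpec("center", 0.0, 0.0, radius=5)
        trace = f.extract_seed_trace(ds, seed, mm_per_pixel=0.078, bregma_pixel=(16, 16))
        np.testing.assert_allclose(trace, 3.5)

    def test_disk_contains_81_lattice_points(self):
        # |{(dx,dy): dx^2 + dy^2 <= 25}| = 81
        from fcfwer.connectivity import seed_disk
        disk = seed_disk((16, 16), 5, (33, 33))
        assert disk.sum() == 81

    def test_masked_half_disk_averages_remaining_pixels(self):
        n = 33
        stack = np.arange(n * n, dtype=float).reshape(1, n, n)
        mask = np.ones((n, n), bool)
        mask[:, 17:] = False  # censor right half
        ds = f.SubjectDataset("h", stack, mask, 1.0)
        seed = f.SeedSpec("c", 0.0, 0.0, radius=5)
        trace = f.extract_seed_trace(ds, seed, 0.078, (16, 16))
        from fcfwer.connectivity import seed_disk
        disk = seed_disk((16, 16), 5, (n, n)) & mask
        assert trace[0] == pytest.approx(stack[0][disk].mean())

    def test_empty_disk_names_seed(self, subject):
        ds = f.SubjectDataset("e", subject.stack, np.zeros_like(subject.valid_mask), 1.0)
        with pytest.raises(ValueError, match="motor"):
            f.extract_seed_trace(ds, f.SeedSpec("motor", 0.0, 0.0), 0.078, (16, 16))


class TestSeedCorrelation:
    def test_self_and_anti_correlation(self, subject):
        mask = subject.valid_mask
        trace = subject.stack[:, 10, 10].copy()
        stack = subject.stack.copy()
        stack[:, 10, 11] = -trace
        ds = f.SubjectDataset("s", stack, mask, 1.0)
        r = f.seed_correlation_map(ds, trace)
        assert r[10, 10] == pytest.approx(1.0)
        assert r[10, 11] == pytest.approx(-1.0)

    def test_matches_textbook_oracle(self, subject):
        trace = subject.stack[:, 12, 12]
        r = f.seed_correlation_map(subject, trace)
        rows, cols = np.where(subject.valid_mask)
        for i in (3, 99, 401):
            y = subject.stack[:, rows[i], cols[i]]
            assert r[rows[i], cols[i]] == pytest.approx(stats.pearsonr(y, trace)[0], abs=1e-10)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert f.fisher_z(np.array([[0.0]]), eta=50)[0, 0] == 0.0

    def test_closed_form(self):
        z = f.fisher_z(np.array([[0.5]]), eta=103.0)[0, 0]
        assert z == pytest.approx(np.arctanh(0.5) * 10.0, rel=1e-12)
        assert z == pytest.approx(5.4931, abs=1e-4)

    def test_r_near_one_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clip"):
            z = f.fisher_z(np.array([[1.0]]), eta=50)
        assert np.isfinite(z).all()

    def test_null_variance_near_unity(self, rng):
        """z-maps built with the Bartlett eta have ~unit variance under the
        null for AR(1) data."""
        n, phi, reps = 600, 0.4, 200
        def ar1():
            e = rng.standard_normal(n)
            out = np.empty(n)
            out[0] = e[0] / np.sqrt(1 - phi**2)
            for t in range(1, n):
                out[t] = phi * out[t - 1] + e[t]
            return out
        zs = []
        for _ in range(reps):
            a, b = ar1(), ar1()
            eta = f.bartlett_dof(a, b)
            r = stats.pearsonr(a, b)[0]
            zs.append(float(f.fisher_z(np.array([[r]]), eta=eta)[0, 0]))
        assert np.var(zs) == pytest.approx(1.0, abs=0.25)


class TestGroupTmap:
    def test_identical_groups_give_zero(self):
        a = np.tile(np.arange(9.0).reshape(1, 3, 3), (4, 1, 1))
        with pytest.warns(UserWarning, match="zero pooled variance"):
            sm = f.groupwise_tmap(a, a.copy(), min_per_group=2)
        np.testing.assert_array_equal(sm.t_values, 0.0)

    def test_three_vs_three_textbook_value(self):
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        b = np.array([2.0, 3.0, 4.0]).reshape(3, 1, 1)
        sm = f.groupwise_tmap(a, b, min_per_group=2)
        assert sm.t_values[0, 0] == pytest.approx(-1.2247, abs=1e-4)
        assert sm.dof_map[0, 0] == 4

    def test_full_data_dof_and_mask(self, cohort16):
        _, mask, maps = cohort16
        sm = f.groupwise_tmap(maps[:8], maps[8:], min_per_group=6)
        assert np.all(sm.dof_map == 14)
        assert sm.analysis_mask.all()

    def test_per_pixel_subject_exclusion(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((8, 4, 4))
        b = rng.standard_normal((8, 4, 4))
        a[0, 1, 1] = np.nan  # subject 0 has no data at (1,1)
        sm = f.groupwise_tmap(a, b, min_per_group=6)
        assert sm.dof_map[1, 1] == 7 + 8 - 2
        assert sm.dof_map[0, 0] == 14
        assert sm.analysis_mask[1, 1]  # 7 >= 6 subjects still present

    def test_vectorized_splits_match_reference(self, cohort16, rng):
        _, _, maps = cohort16
        assignments = [tuple(sorted(rng.choice(16, 8, replace=False))) for _ in range(5)]
        fast = f.group_tmaps_for_splits(maps, assignments)
        for i, a in enumerate(assignments):
            b = [j for j in range(16) if j not in a]
            slow = f.groupwise_tmap(maps[list(a)], maps[b], min_per_group=2)
            np.testing.assert_allclose(fast[i], slow.t_values, atol=1e-8)


class TestClusterLabeling:
    def test_no_suprathreshold_pixels(self):
        assert f.label_excursions(np.zeros((8, 8)), np.ones((8, 8), bool), 2.0) == []

    def test_diagonal_blocks_merge_under_8_connectivity(self):
        t = np.zeros((8, 8))
        t[1:3, 1:3] = 5.0
        t[3:5, 3:5] = 5.0
        clusters = f.label_excursions(t, np.ones((8, 8), bool), 2.0, connectivity=8)
        assert len(clusters) == 1 and clusters[0][0] == 8
        clusters4 = f.label_excursions(t, np.ones((8, 8), bool), 2.0, connectivity=4)
        assert len(clusters4) == 2

    def test_signs_never_merge(self):
        t = np.zeros((4, 4))
        t[1, 1], t[1, 2] = 5.0, -5.0
        clusters = f.label_excursions(t, np.ones((4, 4), bool), 2.0, sidedness=2)
        assert sorted(c[1] for c in clusters) == ["+", "-"]

    def test_matches_floodfill_oracle(self, rng):
        t = rng.standard_normal((20, 20))
        mask = rng.random((20, 20)) < 0.8
        clusters = f.label_excursions(t, mask, 1.0, sidedness=2)
        lab_p, n_p = ndimage.label((t > 1.0) & mask, structure=np.ones((3, 3)))
        lab_n, n_n = ndimage.label((t < -1.0) & mask, structure=np.ones((3, 3)))
        assert len(clusters) == n_p + n_n
        sizes = sorted(c[0] for c in clusters)
        oracle = sorted(
            [int((lab_p == i).sum()) for i in range(1, n_p + 1)]
            + [int((lab_n == i).sum()) for i in range(1, n_n + 1)]
        )
        assert sizes == oracle


class TestNullCalibration:
    def test_uncorrected_positive_rate_is_five_percent(self, cohort16):
        """Before any FWER correction the per-pixel test is exact."""
        _, mask, maps = cohort16
        plan = f.sample_splits(16, 8, 200, 55)
        tmaps = f.group_tmaps_for_splits(maps, plan.iter_assignments())
        crit = stats.t.isf(0.025, 14)
        frac = np.mean(np.abs(tmaps[:, mask]) > crit)
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_r_and_z_maps_give_similar_fwer(self):
        """FWER of one fixed method is nearly identical on r-maps and z-maps."""
        cfg = f.SyntheticConfig(grid_shape=(32, 32), n_subjects=12, fwhm_true=6.0,
                                n_frames=120, ar1_coeff=0.3, rng_seed=23)
        subjects = f.simulate_timeseries(cfg)
        mask = subjects[0].valid_mask
        seed = f.SeedSpec("c", 0.0, 0.0, radius=3)
        r_maps, z_maps = [], []
        for ds in subjects:
            trace = f.extract_seed_trace(ds, seed, cfg.mm_per_pixel, (16, 8))
            r = f.seed_correlation_map(ds, trace)
            eta = f.bartlett_dof(trace, trace)
            r_maps.append(np.where(mask, np.nan_to_num(r), 0.0))
            z_maps.append(np.where(mask, f.fisher_z(np.nan_to_num(r), eta), 0.0))
        plan = f.sample_splits(12, 6, 500, 3)
        spec = f.MethodSpec(
            "gauss_pixel", "rft_pixel",
            rft_config=f.RFTConfig(sidedness=2, fwhm=6.0))
        fw = {}
        for name, stack in (("r", np.array(r_maps)), ("z", np.array(z_maps))):
            res = f.run_mass_fwer(stack, plan, [spec], mask)
            fw[name] = res[0].fwer
        assert abs(fw["r"] - fw["z"]) < 0.03


def test_seed_table_roundtrip(tmp_path):
    path = tmp_path / "seeds.csv"
    path.write_text("name,ml_mm,ap_mm\nmotor,1.68,2.27\nvisual,2.38,-3.35\n")
    seeds = f.connectivity.read_seed_table(str(path))
    assert [s.name for s in seeds] == ["motor", "visual"]
    assert seeds[0].radius == 5
    assert seeds[1].ap_offset == -3.35
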