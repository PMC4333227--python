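import numpy as np
import pytest

import soundmvpa as sm
from conftest import make_clean_dataset


class TestMakeDesign:
    def test_full_scale_design(self, full_design):
        d = full_design
        assert d.n_runs == 7 and d.trials_per_run == 42
        tokens = set(d.tokens())
        assert len(tokens) == 42
        for order in d.run_orders:
            assert len(order) == 42 and set(order) == tokens
        # pseudo-randomization: orders pairwise distinct
        assert len({tuple(o) for o in d.run_orders}) == 7
        assert d.volumes_per_run == 210

    def test_single_run_two_tokens(self):
        d = sm.make_design(1, 2, 1, seed=3)
        assert d.run_orders[0] in (
            [("EN", 1), ("NE", 1)],
            [("NE", 1), ("EN", 1)],
        )

    def test_seed_determinism(self):
        a = sm.make_design(7, 7, 6, seed=5)
        b = sm.make_design(7, 7, 6, seed=5)
        assert a.run_orders == b.run_orders
        c = sm.make_design(7, 7, 6, seed=6)
        assert a.run_orders != c.run_orders

    @pytest.mark.parametrize("args", [(0, 7, 6), (7, 1, 6), (7, 7, 0)])
    def test_invalid_counts(self, args):
        with pytest.raises(ValueError):
            sm.make_design(*args, seed=0)

    def test_more_runs_than_distinct_orders(self):
        # 2 tokens admit only 2 distinct orders
        with pytest.raises(ValueError):
            sm.make_design(3, 2, 1, seed=0)


class TestGroundTruth:
    def test_disjoint_sets_and_counts(self, small_grid):
        t = sm.make_ground_truth(small_grid, 5, 1.0, 0.0, seed=1)
        sets = list(t.informative_sets.values())
        assert all(len(s) == 5 for s in sets)
        assert len(t.all_informative()) == 7 * 5  # fully disjoint
        for c, tpl in t.pattern_means.items():
            on = t.informative_sets[c]
            assert np.all(tpl[on] == 1.0)
            off = np.setdiff1d(np.arange(small_grid.p), on)
            assert np.all(tpl[off] == 0.0)

    def test_full_overlap_shares_one_set(self, small_grid):
        t = sm.make_ground_truth(small_grid, 5, 1.0, 1.0, seed=1)
        sets = [tuple(s) for s in t.informative_sets.values()]
        assert len(set(sets)) == 1

    def test_zero_effect_zero_templates(self, small_grid):
        t = sm.make_ground_truth(small_grid, 5, 0.0, 0.0, seed=1)
        for tpl in t.pattern_means.values():
            assert np.all(tpl == 0.0)

    def test_too_many_informative_rejected(self, small_grid):
        with pytest.raises(ValueError):
            sm.make_ground_truth(small_grid, small_grid.p, 1.0, 0.0, seed=1)


class TestSimulateBetas:
    def test_noiseless_samples_equal_templates(self, small_grid):
        ds, design, truth, _ = make_clean_dataset(
            small_grid, sigma_noise=0.0
        )
        for c in design.categories:
            rows = ds.X[(ds.labels["category"] == c).to_numpy()]
            assert np.allclose(rows, truth.pattern_means[c][None, :])

    def test_bit_identical_under_same_seed(self, small_grid):
        a, *_ = make_clean_dataset(small_grid, sigma_noise=1.0, seed=9)
        b, *_ = make_clean_dataset(small_grid, sigma_noise=1.0, seed=9)
        assert np.array_equal(a.X, b.X)
        assert a.labels.equals(b.labels)

    def test_negative_sd_rejected(self, small_grid):
        design = sm.make_design(2, 2, 1, seed=0)
        truth = sm.make_ground_truth(
            small_grid, 2, 1.0, seed=0, categories=design.categories
        )
        subs = sm.make_subjects(small_grid, 1, categories=design.categories)
        with pytest.raises(ValueError):
            sm.simulate_betas(design, truth, subs, sigma_noise=-1.0, grid=small_grid)

    def test_item_variance_component(self, small_grid):
        """Between-item within-category variance on informative voxels
        matches sigma_item^2 (items are fixed effects reused across runs)."""
        design = sm.make_design(8, 7, 6, seed=21)
        truth = sm.make_ground_truth(
            small_grid, 8, effect_size=1.0, seed=21, categories=design.categories
        )
        subs = sm.make_subjects(
            small_grid, 1, categories=design.categories,
            spatial_jitter_voxels=0, gain_sd=0.0, offset_sd=0.0, seed=21,
        )
        ds = sm.simulate_betas(
            design, truth, subs, sigma_item=1.0, sigma_run=0.0,
            sigma_noise=0.0, seed=21, grid=small_grid,
        )
        lab = ds.labels
        variances = []
        for c in design.categories:
            vox = truth.informative_sets[c]
            item_means = np.stack([
                ds.X[((lab.category == c) & (lab.item == i)).to_numpy()][:, vox].mean(axis=0)
                for i in range(1, 7)
            ])  # items x voxels; identical across runs by construction
            variances.append(item_means.var(axis=0, ddof=1))
        v = float(np.mean(np.concatenate(variances)))
        assert abs(v - 1.0) < 0.2

    def test_total_variance_decomposition(self, small_grid):
        """With no category signal, total per-voxel variance on informative
        voxels approaches sigma_item^2/K + sigma_run^2 + sigma_noise^2 (an
        informative voxel carries its item effect only for the 1/K of samples
        belonging to its own category)."""
        design = sm.make_design(12, 7, 6, seed=22)  # 504 samples
        truth = sm.make_ground_truth(
            small_grid, 8, effect_size=0.0, seed=22, categories=design.categories
        )
        subs = sm.make_subjects(
            small_grid, 1, categories=design.categories,
            spatial_jitter_voxels=0, gain_sd=0.0, offset_sd=0.0, seed=22,
        )
        si, sr, sn = 0.8, 0.5, 1.0
        ds = sm.simulate_betas(
            design, truth, subs, sigma_item=si, sigma_run=sr, sigma_noise=sn,
            seed=22, grid=small_grid,
        )
        vox = truth.all_informative()
        v = float(ds.X[:, vox].var(axis=0, ddof=1).mean())
        expected = si**2 / 7 + sr**2 + sn**2
        assert abs(v - expected) / expected < 0.2


class TestSimulateBold:
    def test_single_event_is_scaled_hrf(self, small_grid):
        design = sm.make_design(1, 2, 1, seed=4)
        truth = sm.make_ground_truth(
            small_grid, 1, effect_size=2.0, seed=4, categories=design.categories
        )
        sub = sm.make_subjects(
            small_grid, 1, categories=design.categories,
            spatial_jitter_voxels=0, gain_sd=0.0, offset_sd=0.0, seed=4,
        )[0]
        bold = sm.simulate_bold(
            design, truth, sub, sigma_noise=0.0, drift_amp=0.0, seed=4,
            grid=small_grid,
        )
        series = bold.series[(sub.subject_id, 0)]
        (c0, _), (c1, _) = design.run_orders[0]
        vox = truth.informative_sets[c0][0]
        onset0 = design.onsets_s()[0]
        t = np.arange(design.volumes_per_run) * design.tr_s
        expected = np.zeros_like(t)
        pos = t >= onset0
        expected[pos] = 2.0 * sm.canonical_hrf(t[pos] - onset0)
        # the category-c1 trial contributes nothing at c0's voxels
        assert np.allclose(series[:, vox], expected, atol=1e-12)

    def test_zero_amplitudes_pure_noise_free(self, small_grid):
        design = sm.make_design(1, 2, 1, seed=4)
        truth = sm.make_ground_truth(
            small_grid, 1, effect_size=0.0, seed=4, categories=design.categories
        )
        sub = sm.make_subjects(
            small_grid, 1, categories=design.categories,
            spatial_jitter_voxels=0, gain_sd=0.0, offset_sd=0.0, seed=4,
        )[0]
        bold = sm.simulate_bold(
            design, truth, sub, sigma_noise=0.0, drift_amp=0.0, seed=4,
            grid=small_grid,
        )
        assert np.all(bold.series[(sub.subject_id, 0)] == 0.0)
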