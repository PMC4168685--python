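import numpy as np
import pytest
from scipy import stats

from sockeica.eica import (
    EicaError,
    build_fir_design,
    deconvolve,
    eica_decompose,
    flip_lr,
    mixture_zmap,
    stack_group,
    threshold_zmap,
)
from sockeica.imaging_io import EventTrain, Mask3D, Volume4D
from sockeica.phantom import (
    NeuralSource,
    PhantomSpec,
    generate_phantom,
    match_components,
)


class TestFirDesign:
    def test_single_event_bin_indices(self):
        ev = EventTrain(onsets=np.array([60.0]))
        design = build_fir_design(ev, n_volumes=50, tr=3.0)
        # bin -30 s -> volume (60-30)/3 = 10; bin +30 s -> volume 30
        assert design.matrix[10, 0] == 1.0
        assert design.matrix[30, 20] == 1.0
        assert design.fir_columns.sum() == 21

    def test_n_bins_21_for_tr3_pm30(self):
        ev = EventTrain(onsets=np.array([60.0]))
        design = build_fir_design(ev, n_volumes=50, tr=3.0, window=(-30.0, 30.0))
        assert design.n_bins == 21
        np.testing.assert_allclose(design.bin_times, np.arange(-30, 33, 3))

    def test_shifted_copy_structure(self):
        one = build_fir_design(EventTrain(onsets=np.array([60.0])), 60, 3.0)
        two = build_fir_design(EventTrain(onsets=np.array([60.0, 66.0])), 60, 3.0)
        overlap = np.minimum(two.fir_columns, 1)
        for j in range(two.n_bins):
            expected = one.fir_columns[:, j].copy()
            expected[2:] = np.maximum(expected[2:], one.fir_columns[:-2, j])
            np.testing.assert_array_equal(overlap[:, j], expected)

    def test_cap_vs_accumulate(self):
        ev = EventTrain(onsets=np.array([60.0, 60.0]))
        cap = build_fir_design(ev, 50, 3.0, overlap_policy="cap")
        acc = build_fir_design(ev, 50, 3.0, overlap_policy="accumulate")
        assert cap.fir_columns.max() == 1.0
        assert acc.fir_columns.max() == 2.0

    def test_partial_window_zero_filled_vs_dropped(self):
        ev = EventTrain(onsets=np.array([6.0]))  # window starts before t=0
        partial = build_fir_design(ev, 50, 3.0, allow_partial=True)
        assert partial.events_used == 1
        assert partial.fir_columns[:, 0].sum() == 0  # bin -30 s cut off
        with pytest.raises(EicaError, match="no usable events"):
            build_fir_design(ev, 50, 3.0, allow_partial=False)

    def test_sub_tr_offset_nearest_volume(self):
        ev = EventTrain(onsets=np.array([61.0]))  # 1 s past a volume start
        design = build_fir_design(ev, 50, 3.0)
        assert design.matrix[10, 0] == 1.0  # (61-30)/3 = 10.33 -> 10

    def test_zero_usable_events_error(self):
        ev = EventTrain(onsets=np.array([1000.0]))
        with pytest.raises(EicaError, match="no usable events"):
            build_fir_design(ev, 50, 3.0)

    def test_window_not_divisible_error(self):
        ev = EventTrain(onsets=np.array([60.0]))
        with pytest.raises(EicaError, match="align to tr"):
            build_fir_design(ev, 50, 3.0, window=(-30.0, 29.0))

    def test_confound_columns(self):
        ev = EventTrain(onsets=np.array([60.0]))
        design = build_fir_design(ev, 50, 3.0, drift_order=2)
        assert design.n_confounds == 3  # intercept + linear + quadratic
        np.testing.assert_allclose(design.confound_columns[:, 0], 1.0)


class TestDeconvolve:
    def test_noiseless_identity(self):
        onsets = np.array([60.0, 150.0, 240.0, 330.0, 420.0])
        spec = PhantomSpec(
            grid=(16, 16, 8), n_volumes=170, seed=0, artifact_sources=(),
            noise_sd=0.0, events=EventTrain(onsets=onsets),
        )
        vol, truth = generate_phantom(spec)
        design = build_fir_design(truth.events, vol.n_volumes, vol.tr)
        per = deconvolve(vol, design, truth.brain)
        expected = truth.masked_source_maps().T @ np.stack(truth.source_responses)
        err = np.linalg.norm(per.responses - expected) / np.linalg.norm(expected)
        assert err <= 1e-8

    def test_noise_rms_scales_with_events(self, rng):
        # OLS variance law: response RMS ~ 1/sqrt(n_events) for white noise
        tr, n_bins_span = 3.0, 63.0

        def run(n_events):
            onsets = 60.0 + (n_bins_span + tr) * np.arange(n_events)
            n_volumes = int(onsets[-1] / tr) + 25
            Y = rng.standard_normal((n_volumes, 200))
            vol = Volume4D(Y.T.reshape(200, 1, 1, n_volumes), tr=tr)
            mask = Mask3D(np.ones((200, 1, 1), dtype=bool))
            design = build_fir_design(EventTrain(onsets=onsets), n_volumes, tr)
            per = deconvolve(vol, design, mask)
            return np.sqrt((per.responses**2).mean())

        ratio = run(12) / run(48)
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_collinear_duplicate_events_no_crash(self):
        ev = EventTrain(onsets=np.array([60.0, 60.0, 90.0]))
        spec = PhantomSpec(
            grid=(16, 16, 8), n_volumes=60, seed=0, artifact_sources=(),
            noise_sd=0.1, events=EventTrain(onsets=np.array([60.0, 90.0])),
        )
        vol, truth = generate_phantom(spec)
        design = build_fir_design(ev, vol.n_volumes, vol.tr, overlap_policy="accumulate")
        per = deconvolve(vol, design, truth.brain)
        assert np.isfinite(per.responses).all()

    def test_row_mismatch_error(self, clean_phantom):
        vol, truth = clean_phantom
        design = build_fir_design(truth.events, vol.n_volumes + 5, vol.tr)
        with pytest.raises(EicaError, match="rows"):
            deconvolve(vol, design, truth.brain)


class TestEicaDecompose:
    def test_two_source_recovery(self, clean_phantom):
        vol, truth = clean_phantom
        design = build_fir_design(truth.events, vol.n_volumes, vol.tr)
        per = deconvolve(vol, design, truth.brain)
        res = eica_decompose(per, 2, seed=0, n_runs=4)
        matches = match_components(
            res.spatial_maps, truth.masked_source_maps(),
            res.time_courses, np.stack(truth.source_responses),
        )
        assert all(m["spatial_r"] >= 0.9 for m in matches)
        assert all(m["temporal_r"] >= 0.9 for m in matches)
        assert res.stability_index.min() >= 0.8

    def test_determinism(self, clean_phantom):
        vol, truth = clean_phantom
        design = build_fir_design(truth.events, vol.n_volumes, vol.tr)
        per = deconvolve(vol, design, truth.brain)
        a = eica_decompose(per, 2, seed=5, n_runs=3)
        b = eica_decompose(per, 2, seed=5, n_runs=3)
        np.testing.assert_array_equal(a.spatial_maps, b.spatial_maps)
        np.testing.assert_array_equal(a.stability_index, b.stability_index)

    def test_n_components_too_large(self, clean_phantom):
        vol, truth = clean_phantom
        design = build_fir_design(truth.events, vol.n_volumes, vol.tr)
        per = deconvolve(vol, design, truth.brain)
        with pytest.raises(EicaError, match="exceeds"):
            eica_decompose(per, 50, seed=0)

    def test_n_runs_minimum(self, clean_phantom):
        vol, truth = clean_phantom
        design = build_fir_design(truth.events, vol.n_volumes, vol.tr)
        per = deconvolve(vol, design, truth.brain)
        with pytest.raises(EicaError, match="n_runs"):
            eica_decompose(per, 2, n_runs=1)

    def test_zmaps_preserve_ranking(self, clean_phantom):
        vol, truth = clean_phantom
        design = build_fir_design(truth.events, vol.n_volumes, vol.tr)
        per = deconvolve(vol, design, truth.brain)
        res = eica_decompose(per, 2, seed=0, n_runs=3)
        for i in range(res.n_components):
            order_map = np.argsort(res.spatial_maps[i])
            order_z = np.argsort(res.z_maps[i], kind="stable")
            np.testing.assert_array_equal(
                res.spatial_maps[i][order_map], res.spatial_maps[i][order_z]
            )


def _subject_phantom(seed):
    spec = PhantomSpec(
        grid=(16, 16, 8), n_volumes=150, seed=seed, artifact_sources=(),
        noise_sd=0.1,
        neural_sources=[NeuralSource(center=(0.4, 0.45, 0.5), kind="canonical_like")],
    )
    vol, truth = generate_phantom(spec)
    design = build_fir_design(truth.events, vol.n_volumes, vol.tr)
    return deconvolve(vol, design, truth.brain), truth


class TestGroup:
    def test_shared_source_three_subjects(self):
        pers, truths = zip(*(_subject_phantom(s) for s in (1, 2, 3)))
        stack = stack_group(list(pers))
        res = eica_decompose(stack, 1, seed=0, n_runs=4)
        assert res.n_components == 1
        assert len(res.subject_slices) == 3
        truth_map = truths[0].source_maps[0][stack.mask.data]
        m = match_components(res.spatial_maps, truth_map[None, :])
        assert m[0]["spatial_r"] >= 0.9
        for s, truth in enumerate(truths):
            tc = res.subject_time_courses(s)[:, 0]
            resp = truth.source_responses[0]
            r = abs(np.corrcoef(tc, resp)[0, 1])
            assert r >= 0.85, f"subject {s}: |r|={r:.3f}"

    def test_single_subject_group_matches_single(self):
        per, truth = _subject_phantom(4)
        single = eica_decompose(per, 1, seed=0, n_runs=3)
        grouped = eica_decompose(stack_group([per]), 1, seed=0, n_runs=3)
        r = abs(np.corrcoef(single.spatial_maps[0], grouped.spatial_maps[0])[0, 1])
        assert r >= 0.95

    def test_grid_mismatch_error(self):
        per, _ = _subject_phantom(1)
        spec = PhantomSpec(grid=(16, 16, 10), n_volumes=150, seed=2, artifact_sources=(), noise_sd=0.1)
        vol, truth = generate_phantom(spec)
        design = build_fir_design(truth.events, vol.n_volumes, vol.tr)
        other = deconvolve(vol, design, truth.brain)
        with pytest.raises(EicaError, match="different grids"):
            stack_group([per, other])


class TestMixtureZmap:
    def test_standard_normal_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10_000)
        z = mixture_zmap(x)
        # recover the affine transform applied: z = (x - mu)/sigma
        sigma = (x[1] - x[0]) / (z[1] - z[0])
        mu = x[0] - z[0] * sigma
        # oracle: sample moments of the draw itself
        assert abs(mu - x.mean()) <= 0.05
        assert 0.9 <= sigma <= 1.1

    def test_contaminated_mixture(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.standard_normal(9500), 8.0 + rng.standard_normal(500)])
        z = mixture_zmap(x)
        assert z[9500:].min() >= 5.0

    def test_monotonicity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        z = mixture_zmap(x)
        np.testing.assert_array_equal(np.argsort(x), np.argsort(z))

    def test_degenerate_falls_back_to_robust_z(self):
        x = np.zeros(200)
        x[:3] = [1.0, 2.0, 3.0]
        z, fallback = mixture_zmap(x, return_fallback=True)
        assert fallback
        assert np.isfinite(z).all()

    def test_min_size(self):
        with pytest.raises(EicaError, match="at least 100"):
            mixture_zmap(np.zeros(50))


class TestThresholdZmap:
    def test_quantile_boundary_survives(self):
        z = np.array([stats.norm.ppf(0.975), -stats.norm.ppf(0.975), 1.0])
        out = threshold_zmap(z, p=0.05, correction="none")
        assert out[0] != 0 and out[1] != 0 and out[2] == 0

    def test_fdr_null_survivors(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(10_000)
        out = threshold_zmap(z, p=0.05, correction="fdr")
        assert (out != 0).sum() <= 5

    def test_uncorrected_null_fraction(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(10_000)
        out = threshold_zmap(z, p=0.05, correction="none")
        assert 0.03 <= (out != 0).mean() <= 0.07

    def test_signed_values_kept(self):
        z = np.array([5.0, -5.0, 0.1])
        out = threshold_zmap(z, p=0.05, correction="none")
        assert out[0] == 5.0 and out[1] == -5.0 and out[2] == 0.0

    def test_bad_p(self):
        with pytest.raises(EicaError):
            threshold_zmap(np.zeros(10), p=1.5)


class TestFlipLr:
    def test_involution_volume(self, rng):
        vol = Volume4D(rng.standard_normal((6, 5, 4, 8)), tr=2.0)
        np.testing.assert_array_equal(flip_lr(flip_lr(vol)).data, vol.data)

    def test_single_voxel_moves(self):
        data = np.zeros((6, 5, 4, 2))
        data[0, 2, 2, :] = 1.0
        flipped = flip_lr(Volume4D(data, tr=1.0))
        assert flipped.data[5, 2, 2, 0] == 1.0
        assert flipped.data[0, 2, 2, 0] == 0.0

    def test_lateralized_source_mirrors(self):
        spec = PhantomSpec(
            grid=(16, 16, 8), n_volumes=120, seed=0, artifact_sources=(), noise_sd=0.0,
            neural_sources=[NeuralSource(center=(0.3, 0.5, 0.5))],
        )
        vol, truth = generate_phantom(spec)
        mirror = truth.source_maps[0][::-1]
        flipped_vol = flip_lr(vol)
        # the flipped data's source sits exactly at the mirrored location
        design = build_fir_design(truth.events, vol.n_volumes, vol.tr)
        mask = Mask3D(truth.brain.data[::-1], kind="brain")
        per = deconvolve(flipped_vol, design, mask)
        peak_bin = np.argmax(np.abs(truth.source_responses[0]))
        est_map = per.to_grid()[..., peak_bin]
        r = np.corrcoef(est_map.ravel(), mirror.ravel())[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_flip_response_involution(self, clean_phantom):
        vol, truth = clean_phantom
        design = build_fir_design(truth.events, vol.n_volumes, vol.tr)
        per = deconvolve(vol, design, truth.brain)
        back = flip_lr(flip_lr(per))
        np.testing.assert_array_equal(back.responses, per.responses)
        np.testing.assert_array_equal(back.mask.data, per.mask.data)
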