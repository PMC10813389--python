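import numpy as np
import pytest

from cecounter.dataset_io import AnnotatedImage
from cecounter.detection import DetectionConfig
from cecounter.synthetic import SceneSpec, generate_scene
from cecounter.trainer import (
    CorrectionPolicy,
    LossCurve,
    TrainConfig,
    pseudo_label,
    run_semi_supervised,
    select_epoch,
    simulate_correction,
    train,
)
from cecounter.unet import UNet, UNetConfig


def scene_records(n, base_seed, size=64):
    recs = []
    for i in range(n):
        spec = SceneSpec.for_regime("middle", seed=base_seed + i,
                                    width_px=size, height_px=size)
        recs.append(generate_scene(spec).to_annotated(f"s{base_seed + i}"))
    return recs


def tiny_train_cfg(**kw):
    base = dict(max_epochs=2, lr=2e-3, batch_size=2, crop_size=32, seed=0,
                fg_weight=2.0, disk_radius_px=2)
    base.update(kw)
    return TrainConfig(**base)


class TestSelectEpoch:
    def test_argmin(self):
        assert select_epoch(LossCurve(val_loss=[0.50, 0.30, 0.35], train_loss=[0] * 3)) == 2

    def test_tie_goes_earlier(self):
        assert select_epoch(LossCurve(val_loss=[0.4, 0.3, 0.3], train_loss=[0] * 3)) == 2

    def test_strictly_decreasing_boundary(self):
        vals = list(np.linspace(1.0, 0.1, 30))
        assert select_epoch(LossCurve(val_loss=vals, train_loss=vals)) == 30

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            select_epoch(LossCurve())


class TestTrain:
    def test_overfit_fixture_reaches_low_loss(self):
        # memorization sanity check: depth-2 net drives train loss < 0.05
        recs = scene_records(10, 100, size=32)
        model = UNet(UNetConfig(depth=2, base_channels=4, seed=0))
        cfg = tiny_train_cfg(max_epochs=40, batch_size=10, crop_size=32, lr=5e-3,
                            fg_weight=1.0, steps_per_epoch=5)
        res = train(model, recs, recs, cfg)  # 40 epochs x 5 steps = 200 steps
        assert res.curve.train_loss[-1] < 0.05

    def test_val_equals_train_when_sets_identical(self):
        recs = scene_records(4, 200, size=32)
        model = UNet(UNetConfig(depth=2, base_channels=4, seed=1))
        res = train(model, recs, recs, tiny_train_cfg(max_epochs=3))
        np.testing.assert_allclose(res.curve.train_loss, res.curve.val_loss, atol=1e-6)

    def test_same_seed_identical_curves(self):
        recs = scene_records(4, 300, size=32)
        curves = []
        for _ in range(2):
            model = UNet(UNetConfig(depth=2, base_channels=4, seed=2))
            res = train(model, recs[:3], recs[3:], tiny_train_cfg(max_epochs=2, seed=5))
            curves.append((res.curve.train_loss, res.curve.val_loss))
        assert curves[0] == curves[1]

    def test_curve_lengths_match_epochs(self):
        recs = scene_records(3, 400, size=32)
        model = UNet(UNetConfig(depth=2, base_channels=4, seed=0))
        res = train(model, recs[:2], recs[2:], tiny_train_cfg(max_epochs=3))
        assert len(res.curve.train_loss) == len(res.curve.val_loss) == 3
        assert all(v >= 0 for v in res.curve.val_loss)

    def test_best_epoch_is_val_argmin(self):
        recs = scene_records(4, 500, size=32)
        model = UNet(UNetConfig(depth=2, base_channels=4, seed=0))
        res = train(model, recs[:3], recs[3:], tiny_train_cfg(max_epochs=4))
        assert res.best_epoch == select_epoch(res.curve)

    def test_empty_sets_rejected(self):
        model = UNet(UNetConfig(depth=2, base_channels=4, seed=0))
        with pytest.raises(ValueError):
            train(model, [], [], tiny_train_cfg())


class TestPseudoLabel:
    def test_blank_image_gives_no_centers(self):
        recs = scene_records(6, 600, size=32)
        model = UNet(UNetConfig(depth=2, base_channels=4, seed=0))
        train(model, recs, recs, tiny_train_cfg(max_epochs=8, steps_per_epoch=8))
        blank = AnnotatedImage("blank", np.full((32, 32), 180, np.uint8), [])
        out = pseudo_label(model, [blank])
        assert out[0].n_centers <= 2  # essentially nothing on a uniform field

    def test_labels_every_image_with_model_source(self):
        recs = scene_records(3, 700, size=32)
        model = UNet(UNetConfig(depth=2, base_channels=4, seed=0))
        out = pseudo_label(model, recs)
        assert len(out) == 3
        assert all(r.source == "model" for r in out)

    def test_deterministic(self):
        recs = scene_records(2, 800, size=32)
        model = UNet(UNetConfig(depth=2, base_channels=4, seed=3))
        a = pseudo_label(model, recs)
        b = pseudo_label(model, recs)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.centers, y.centers)


class TestSimulateCorrection:
    def make_pair(self, pred_pts, true_pts, size=64):
        img = np.zeros((size, size), np.uint8)
        pseudo = AnnotatedImage("im", img, pred_pts, source="model")
        truth = AnnotatedImage("im", img, true_pts, source="manual")
        return pseudo, truth

    def test_perfect_policy_one_point_per_truth(self):
        pseudo, truth = self.make_pair(
            [(10.0, 10.0), (50.0, 50.0)],          # one near a truth, one spurious
            [(11.0, 10.0), (30.0, 30.0)],
        )
        out = simulate_correction(pseudo, truth, CorrectionPolicy(1.0, 1.0, 0.0), 5.0)
        assert out.n_centers == 2
        assert out.source == "model_corrected"
        # matched point kept at the predicted position; missed truth added exactly
        assert (10.0, 10.0) in {tuple(c) for c in out.centers}
        assert (30.0, 30.0) in {tuple(c) for c in out.centers}

    def test_no_correction_policy_keeps_pseudo(self):
        pseudo, truth = self.make_pair([(5.0, 5.0), (50.0, 50.0)], [(20.0, 20.0)])
        out = simulate_correction(pseudo, truth, CorrectionPolicy(0.0, 0.0, 0.0), 5.0)
        np.testing.assert_array_equal(np.sort(out.centers, axis=0),
                                      np.sort(pseudo.centers, axis=0))

    def test_tp_fp_fn_instance(self):
        # 1 TP, 1 FP, 1 FN vs 2 truths; perfect policy -> exactly 2 points
        pseudo, truth = self.make_pair(
            [(10.0, 10.0), (40.0, 40.0)], [(10.5, 10.0), (25.0, 25.0)]
        )
        out = simulate_correction(pseudo, truth, CorrectionPolicy(1.0, 1.0, 0.0), 3.0)
        assert out.n_centers == 2

    def test_mismatched_ids_rejected(self):
        pseudo, truth = self.make_pair([(1.0, 1.0)], [(1.0, 1.0)])
        truth = truth.with_(image_id="other")
        with pytest.raises(ValueError):
            simulate_correction(pseudo, truth, CorrectionPolicy(), 3.0)

    def test_jitter_stays_in_bounds_and_is_seeded(self):
        pseudo, truth = self.make_pair([], [(0.5, 0.5), (62.0, 62.0)])
        a = simulate_correction(pseudo, truth, CorrectionPolicy(1.0, 1.0, 2.0), 3.0, rng=9)
        b = simulate_correction(pseudo, truth, CorrectionPolicy(1.0, 1.0, 2.0), 3.0, rng=9)
        np.testing.assert_array_equal(a.centers, b.centers)
        assert (a.centers >= 0).all() and (a.centers <= 63).all()

    def test_invalid_policy(self):
        with pytest.raises(ValueError):
            CorrectionPolicy(p_fix_miss=1.5)
        with pytest.raises(ValueError):
            CorrectionPolicy(jitter_px=-1.0)


@pytest.fixture(scope="module")
def small_run():
    labeled = scene_records(8, 1000, size=64)
    unlabeled = scene_records(8, 2000, size=64)
    test = scene_records(4, 3000, size=64)
    return run_semi_supervised(
        labeled, unlabeled, test,
        UNetConfig(depth=2, base_channels=4, seed=0),
        tiny_train_cfg(max_epochs=2, steps_per_epoch=4),
        DetectionConfig(),
        CorrectionPolicy(),
        match_radius_px=4.0,
        bootstrap_reps=50,
    )


class TestRunSemiSupervised:
    def test_produces_both_models_and_metrics(self, small_run):
        assert small_run.initial.metrics.n_images == 4
        assert small_run.cellcount.metrics.n_images == 4
        assert small_run.initial.selected_epoch >= 1
        assert small_run.cellcount.selected_epoch >= 1

    def test_stage_curves_recorded(self, small_run):
        assert small_run.initial.curve.n_epochs == 2
        assert small_run.cellcount.curve.n_epochs == 2

    def test_perfect_correction_reduces_to_ground_truth_labels(self):
        # with policy (1,1,0) every corrected set has exactly one point per
        # true center (the semi-supervised stage sees ground-truth-equivalent labels)
        labeled = scene_records(4, 4000, size=64)
        unlabeled = scene_records(4, 5000, size=64)
        model = UNet(UNetConfig(depth=2, base_channels=4, seed=0))
        train(model, labeled, labeled, tiny_train_cfg(max_epochs=2, steps_per_epoch=4))
        pseudo = pseudo_label(model, unlabeled)
        rng = np.random.default_rng(0)
        for ps, tr in zip(pseudo, unlabeled):
            out = simulate_correction(ps, tr, CorrectionPolicy(1.0, 1.0, 0.0), 4.0, rng)
            assert out.n_centers == tr.n_centers

    def test_empty_unlabeled_pool_warns(self):
        labeled = scene_records(6, 6000, size=64)
        test = scene_records(3, 7000, size=64)
        with pytest.warns(UserWarning, match="unlabeled"):
            run_semi_supervised(
                labeled, [], test,
                UNetConfig(depth=2, base_channels=4, seed=0),
                tiny_train_cfg(max_epochs=1, steps_per_epoch=2),
                DetectionConfig(),
                CorrectionPolicy(),
                match_radius_px=4.0,
                bootstrap_reps=50,
            )

    def test_reproducible_end_to_end(self):
        def run_once():
            labeled = scene_records(4, 8000, size=64)
            unlabeled = scene_records(4, 9000, size=64)
            test = scene_records(3, 9900, size=64)
            r = run_semi_supervised(
                labeled, unlabeled, test,
                UNetConfig(depth=2, base_channels=4, seed=1),
                tiny_train_cfg(max_epochs=1, steps_per_epoch=3, seed=1),
                DetectionConfig(),
                CorrectionPolicy(),
                match_radius_px=4.0,
                bootstrap_reps=50,
            )
            return (r.initial.metrics.f_value, r.cellcount.metrics.f_value,
                    r.initial.curve.val_loss, r.cellcount.curve.val_loss)

        assert run_once() == run_once()
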