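"""Training loop: schedule, determinism, history, prediction, checkpoints."""

import numpy as np
import pytest

from dosecast import (
    DomainError,
    PhantomConfig,
    TrainConfig,
    VoxelGrid,
    build_model,
    cosine_lr,
    generate_cohort,
    generate_phantom,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)
from dosecast.errors import ConfigError
from dosecast.losses import dvh_loss, mae_loss
from dosecast.network import ModelConfig
from dosecast.training import _case_losses, assemble_input


@pytest.fixture(scope="module")
def tiny_setup(request):
    g = VoxelGrid((16, 16, 16))
    cfg = PhantomConfig(grid=g, seed=21, missing_structure_rate=0.0)
    train_cases = generate_cohort(cfg, 2)
    val_cases = [generate_phantom(PhantomConfig(grid=g, seed=22), 0)]
    mcfg = ModelConfig(grid=g, base_width_a=2, base_width_b=4)
    return g, train_cases, val_cases, mcfg


@pytest.mark.parametrize(
    "epoch,total,lr_min,lr_max,expected",
    [
        (0, 100, 0.0, 1e-3, 1e-3),
        (100, 100, 0.0, 1e-3, 0.0),
        (50, 100, 0.0, 1e-3, 5e-4),
        (25, 100, 2e-4, 1e-3, 2e-4 + 0.5 * 8e-4 * (1 + np.cos(np.pi / 4))),
    ],
)
def test_cosine_schedule_values(epoch, total, lr_min, lr_max, expected):
    assert cosine_lr(epoch, total, lr_min, lr_max) == pytest.approx(expected)


def test_cosine_schedule_domain():
    with pytest.raises(DomainError):
        cosine_lr(101, 100, 0.0, 1e-3)


def test_train_config_validation():
    with pytest.raises(ConfigError):
        TrainConfig(lr_max=0.0)
    with pytest.raises(ConfigError):
        TrainConfig(mode="mse")


def test_history_length_and_lr_trace(tiny_setup):
    g, train_cases, val_cases, mcfg = tiny_setup
    tcfg = TrainConfig(epochs=2, seed=3, mode="dual_dvh")
    model, std, hist = train(train_cases, val_cases, mcfg, tcfg)
    assert len(hist.records) == 2
    expected = [cosine_lr(e, 2, 0.0, 1e-3) for e in range(2)]
    np.testing.assert_allclose(hist.lrs(), expected)
    assert all(r.val_total is not None for r in hist.records)


def test_training_is_bit_reproducible(tiny_setup):
    g, train_cases, val_cases, mcfg = tiny_setup
    tcfg = TrainConfig(epochs=2, seed=11, mode="dual_dvh")
    m1, _, h1 = train(train_cases, val_cases, mcfg, tcfg)
    m2, _, h2 = train(train_cases, val_cases, mcfg, tcfg)
    for p, q in zip(m1.all_params(), m2.all_params()):
        np.testing.assert_array_equal(p.data, q.data)
    assert h1.to_json() == h2.to_json()


def test_logged_components_reconcile_with_loss_modules(tiny_setup, rng):
    """The trainer's per-case components equal standalone loss calls."""
    g, train_cases, _, mcfg = tiny_setup
    case = train_cases[0]
    model = build_model(mcfg, init_seed=2)
    from dosecast.preprocess import fit_standardizer

    std = fit_standardizer(train_cases)
    x = assemble_input(case, std)
    va, vb, tot, _ = _case_losses(model, x, case, "dual_dvh", want_grads=False)
    from dosecast.network import forward

    dose_a, _, dose_b = forward(model, x)
    assert va == pytest.approx(
        mae_loss(dose_a.data[0], case.reference_dose, case.possible_dose_mask),
        abs=1e-6)
    assert vb == pytest.approx(
        dvh_loss(dose_b.data[0], case.reference_dose, case.masks), abs=1e-6)
    assert tot == pytest.approx(0.5 * va + vb, abs=1e-9)


@pytest.mark.parametrize("mode", ["single_mae", "dual_mae"])
def test_ablation_modes_run(tiny_setup, mode):
    g, train_cases, val_cases, mcfg = tiny_setup
    tcfg = TrainConfig(epochs=1, seed=5, mode=mode)
    model, std, hist = train(train_cases, val_cases, mcfg, tcfg)
    assert len(hist.records) == 1
    if mode == "single_mae":
        assert model.model_a is None
        assert hist.records[0].train_loss_a is None
    else:
        assert model.model_a is not None


def test_grid_mismatch_rejected(tiny_setup):
    g, train_cases, val_cases, mcfg = tiny_setup
    other = generate_phantom(
        PhantomConfig(grid=VoxelGrid((32, 32, 32)), seed=0), 0)
    with pytest.raises(ConfigError):
        train(train_cases + [other], val_cases, mcfg, TrainConfig(epochs=1))


def test_predict_nonnegative_and_masked(tiny_setup):
    g, train_cases, val_cases, mcfg = tiny_setup
    tcfg = TrainConfig(epochs=1, seed=1, mode="dual_dvh")
    model, std, _ = train(train_cases, val_cases, mcfg, tcfg)
    case = val_cases[0]
    dose = predict(model, std, case)
    assert dose.shape == case.grid.shape
    assert dose.min() >= 0.0
    assert np.all(dose[case.possible_dose_mask == 0] == 0.0)


def test_zeroed_head_predicts_zero(tiny_setup):
    g, train_cases, val_cases, mcfg = tiny_setup
    model = build_model(mcfg, init_seed=0)
    model.model_b.head_w.data[:] = 0.0
    from dosecast.preprocess import Standardizer

    dose = predict(model, Standardizer(900.0, 100.0), val_cases[0])
    assert np.all(dose == 0.0)


def test_checkpoint_round_trip_is_bit_identical(tiny_setup, tmp_path):
    g, train_cases, val_cases, mcfg = tiny_setup
    tcfg = TrainConfig(epochs=1, seed=9, mode="dual_dvh")
    model, std, hist = train(train_cases, val_cases, mcfg, tcfg)
    save_checkpoint(tmp_path / "ck.npz", model, std, hist)
    model2, std2, hist2 = load_checkpoint(tmp_path / "ck.npz")
    assert (std2.mu, std2.sigma) == (std.mu, std.sigma)
    assert hist2.to_json() == hist.to_json()
    case = val_cases[0]
    np.testing.assert_array_equal(predict(model, std, case),
                                  predict(model2, std2, case))
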