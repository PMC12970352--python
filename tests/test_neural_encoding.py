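"""Feature extraction, encoder fits, and the BPS / R^2 scoring oracles."""

import numpy as np
import pytest

from beast import (extract_cls_features, motion_energy, fit_rrr,
                   fit_tcn_encoder, bits_per_spike, pc_r2, time_split,
                   neural_pcs)
from beast.neural_encoding import FeatureSeries, NeuralBins, TCNEncoder


# ------------------------------------------------------------------ features

def test_cls_features_constant_video(tiny_model):
    frames = np.full((4, 32, 32, 3), 0.4, dtype=np.float32)
    fs = extract_cls_features(frames, tiny_model)
    assert fs.X.shape[0] == 4
    assert np.allclose(fs.X, fs.X[0])


def test_cls_batched_equals_looped(tiny_model, tiny_scene):
    frames = tiny_scene.frames[:7]
    batched = extract_cls_features(frames, tiny_model, batch_size=3).X
    looped = np.concatenate([
        extract_cls_features(frames[i:i + 1], tiny_model).X for i in range(7)])
    assert np.allclose(batched, looped, atol=1e-12)


def test_motion_energy_examples(rng):
    const = np.full((5, 6, 6, 3), 0.3)
    assert np.all(motion_energy(const).X == 0.0)
    two = np.zeros((2, 4, 4, 3))
    two[1, 0, 0, 0] = 1.0
    two[1, 1, 2, 0] = 1.0
    me = motion_energy(two).X.ravel()
    assert me[0] == 0.0 and me[1] == pytest.approx(2.0)
    vid = rng.uniform(size=(6, 5, 5, 3))
    expected = [0.0] + [np.abs(vid[t] - vid[t - 1]).sum() for t in range(1, 6)]
    assert np.allclose(motion_energy(vid).X.ravel(), expected)


def test_motion_energy_empty_crop():
    with pytest.raises(ValueError, match="crop"):
        motion_energy(np.zeros((3, 4, 4, 3)), crop=(2, 2, 0, 4))


# ----------------------------------------------------------------------- RRR

def test_full_rank_rrr_equals_ols(rng):
    X = rng.standard_normal((150, 5))
    Y = X @ rng.standard_normal((5, 3)) + 0.1 * rng.standard_normal((150, 3))
    m = fit_rrr(X, Y, rank=3, ridge=1e-12)
    Xc, Yc = X - X.mean(0), Y - Y.mean(0)
    ols = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
    assert np.abs(m.coef - ols).max() < 1e-6


def test_rrr_recovers_planted_rank_one(rng):
    X = rng.standard_normal((200, 6))
    Y = X @ np.outer(rng.standard_normal(6), rng.standard_normal(4))
    m = fit_rrr(X, Y, rank=1, ridge=1e-12)
    pred = m.predict(X)
    r2 = 1 - ((Y - pred) ** 2).sum() / ((Y - Y.mean(0)) ** 2).sum()
    assert r2 > 0.999


def test_rrr_rank_validation(rng):
    X, Y = rng.standard_normal((50, 4)), rng.standard_normal((50, 3))
    with pytest.raises(ValueError, match="rank"):
        fit_rrr(X, Y, rank=0)
    with pytest.raises(ValueError, match="rank"):
        fit_rrr(X, Y, rank=4)


def test_rrr_singular_design_advises_ridge():
    X = np.zeros((30, 3))
    X[:, 0] = np.arange(30)
    X[:, 1] = 2 * X[:, 0]          # collinear
    Y = np.ones((30, 2))
    with pytest.raises(np.linalg.LinAlgError, match="ridge"):
        fit_rrr(X, Y, rank=1, ridge=0.0)


def test_rrr_train_error_monotone_in_rank(rng):
    X = rng.standard_normal((120, 6))
    Y = X @ rng.standard_normal((6, 5)) + rng.standard_normal((120, 5))
    errs = []
    for r in range(1, 6):
        m = fit_rrr(X, Y, rank=r, ridge=1e-9)
        errs.append(((Y - m.predict(X)) ** 2).sum())
    assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))


# ----------------------------------------------------------------------- TCN

def test_tcn_beats_null_on_learnable_data(rng):
    T = 200
    x = rng.standard_normal((T, 2))
    rates = np.exp(0.5 * x[:, 0] - 0.3 * x[:, 1])
    y = rng.poisson(rates)[:, None]
    model = fit_tcn_encoder(x, y, window=5, hidden=16, seed=0, epochs=150)
    pred = model.predict(x)
    null = np.full_like(pred, y.mean())
    ll = lambda r: (y * np.log(r) - r).sum()
    assert ll(pred) > ll(null)


def test_tcn_deterministic(rng):
    x = rng.standard_normal((80, 3))
    y = rng.poisson(1.0, size=(80, 2))
    a = fit_tcn_encoder(x, y, window=5, seed=4, epochs=20).predict(x)
    b = fit_tcn_encoder(x, y, window=5, seed=4, epochs=20).predict(x)
    assert np.array_equal(a, b)


def test_tcn_window_one_is_pointwise(rng):
    """window=1 output at t depends only on x[t]."""
    x = rng.standard_normal((30, 2))
    m = fit_tcn_encoder(x, rng.poisson(1.0, (30, 1)), window=1, seed=0, epochs=5)
    x2 = x.copy()
    x2[10] += 100.0
    a, b = m.predict(x), m.predict(x2)
    changed = np.flatnonzero(np.abs(a - b).max(axis=1) > 1e-12)
    assert np.array_equal(changed, [10])


def test_tcn_even_window_rejected():
    with pytest.raises(ValueError, match="odd"):
        TCNEncoder(2, 1, window=4)


# -------------------------------------------------------------------- scores

def test_bps_null_predictor_is_exactly_zero(rng):
    y = rng.poisson(2.0, size=(50, 3))
    mean = y.mean(axis=0)
    score = bits_per_spike(np.tile(mean, (50, 1)), y, mean)
    assert np.all(score.per_unit == 0.0)


def test_bps_hand_computed_value():
    y = np.array([[0], [1], [2]])
    pred = np.array([[0.5], [1.0], [2.0]])
    ll_pred = (y[:, 0] * np.log(pred[:, 0]) - pred[:, 0]).sum()
    ll_null = (y[:, 0] * np.log(1.0) - 1.0).sum()
    expected = (ll_pred - ll_null) / (3 * np.log(2))
    score = bits_per_spike(pred, y, np.array([1.0]))
    assert score.per_unit[0] == pytest.approx(expected)


def test_bps_positive_under_true_rates(rng):
    rates = np.exp(rng.standard_normal((2000, 4)) * 0.5)
    y = rng.poisson(rates)
    score = bits_per_spike(rates, y, y.mean(axis=0))
    assert score.mean > 0.0


def test_bps_excludes_silent_neurons(rng):
    y = np.zeros((20, 2), dtype=int)
    y[:, 0] = rng.poisson(1.0, 20)
    score = bits_per_spike(np.full((20, 2), 0.5), y, np.array([1.0, 0.5]))
    assert 1 in score.excluded
    assert np.isnan(score.per_unit[1])


def test_bps_rejects_nonpositive_rates():
    with pytest.raises(ValueError, match="floor"):
        bits_per_spike(np.zeros((3, 1)), np.ones((3, 1), dtype=int), np.array([1.0]))


def test_pc_r2_identities_and_oracle(rng):
    yc = rng.standard_normal((40, 3))
    assert np.allclose(pc_r2(yc, yc).per_unit, 1.0)
    mean_pred = np.tile(yc.mean(axis=0), (40, 1))
    assert np.allclose(pc_r2(mean_pred, yc).per_unit, 0.0)
    pred = rng.standard_normal((40, 3))
    from sklearn.metrics import r2_score
    ours = pc_r2(pred, yc).per_unit
    ref = [r2_score(yc[:, k], pred[:, k]) for k in range(3)]
    assert np.allclose(ours, ref)


def test_nonlinear_encoder_beats_linear_on_nonlinear_rates(rng):
    """With a non-monotone rate map a linear read-out is structurally blind;
    the TCN captures it (directional check on held-out bins)."""
    T = 900
    x = rng.uniform(-2, 2, size=(T, 1))
    rates = np.exp(1.2 * np.cos(np.pi * x[:, 0]))
    y = rng.poisson(rates)[:, None]
    tr, va, te = time_split(T)
    null = np.maximum(y[tr].mean(axis=0), 1e-9)
    lin = fit_rrr(x[tr], y[tr].astype(float), rank=1, ridge=1e-6)
    bps_lin = bits_per_spike(np.maximum(lin.predict(x[te]), 1e-9), y[te], null)
    tcn = fit_tcn_encoder(x[tr], y[tr], window=1, hidden=16, seed=0,
                          epochs=300, X_val=x[va], Y_val=y[va])
    bps_tcn = bits_per_spike(tcn.predict(x[te]), y[te], null)
    assert bps_tcn.mean > bps_lin.mean
    assert bps_tcn.mean > 0


# --------------------------------------------------------------------- utils

def test_time_split_contiguous_blocks():
    tr, va, te = time_split(100)
    assert len(tr) == 70 and len(va) == 15 and len(te) == 15
    assert tr.max() < va.min() < te.min()


def test_neural_pcs_capture_variance(rng):
    latent = rng.standard_normal((300, 2))
    counts = rng.poisson(np.exp(latent @ rng.standard_normal((2, 6)) * 0.3))
    pcs, comps, mu = neural_pcs(counts, k=2)
    assert pcs.shape == (300, 2) and comps.shape == (2, 6)
    recon = pcs @ comps + mu
    full_var = ((counts - mu) ** 2).sum()
    assert ((counts - recon) ** 2).sum() < full_var


def test_neural_bins_validation():
    with pytest.raises(ValueError, match="integer"):
        NeuralBins(Y=np.array([[0.5]]), is_counts=True)
    with pytest.raises(ValueError, match="missing"):
        FeatureSeries(X=np.array([[np.nan]]))
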