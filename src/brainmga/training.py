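"""Training protocol for brain-age regression.

Implements the published recipe: hybrid rank + MSE loss, random
rotation/translation augmentation, Adam with step-decayed learning rate,
stratified 70/15/15 split, epoch-wise validation with best-checkpoint
retention, linear age-bias correction, and MAE/PCC evaluation.

The rank term of the loss uses a differentiable soft-rank Spearman
surrogate (pairwise sigmoids, temperature 0.1); the exact rank-based
Spearman coefficient is kept alongside as a non-differentiable oracle.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

logger = logging.getLogger("brainmga")

__all__ = [
    "TrainConfig",
    "BiasModel",
    "soft_spearman",
    "hard_spearman",
    "hybrid_loss",
    "augment",
    "fit_bias",
    "apply_bias",
    "metrics",
    "stratified_split",
    "learning_rate_at",
    "train_loop",
]


@dataclass
class TrainConfig:
    """Hyperparameters of the published training protocol.

    batch size 12, Adam at initial learning rate 0.005 with weight decay
    1e-4, learning rate ×0.1 every 70 epochs, rotations within ±20° and
    integer translations within ±6 voxels per axis.
    """

    epochs: int = 30
    batch_size: int = 12
    lr: float = 0.005
    weight_decay: float = 0.0001
    lr_decay: float = 0.1
    lr_step_epochs: int = 70
    rotation_deg: float = 20.0
    translation_vox: int = 6
    lam: float = 1.0  # weight of the rank term in the hybrid loss
    rank_temperature: float = 0.1
    augment: bool = True
    split: tuple = (0.70, 0.15, 0.15)
    age_bin_years: float = 10.0  # stratification bin width for the split
    seed: int = 0


@dataclass
class BiasModel:
    """predicted_age ≈ slope · chronological_age + intercept on held-out data."""

    slope: float
    intercept: float


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def soft_spearman(pred: Tensor, target: np.ndarray, temperature: float = 0.1) -> Tensor:
    """Differentiable Spearman surrogate.

    Soft ranks r_i = Σ_j sigmoid((x_i − x_j)/τ) replace the hard ranks of
    the predictions; the targets keep exact ranks (they carry no gradient).
    Returns the Pearson correlation of the two rank vectors, → the exact
    Spearman coefficient as τ → 0 (ties absent).
    """
    n = pred.shape[0]
    diffs = pred.reshape((n, 1)) - pred.reshape((1, n))
    soft_ranks = ad.sigmoid(diffs * (1.0 / temperature)).sum(axis=1)
    t_ranks = np.argsort(np.argsort(target)).astype(float)
    sr = soft_ranks - soft_ranks.mean()
    tr = t_ranks - t_ranks.mean()
    cov = (sr * tr).sum()
    var_s = (sr * sr).sum()
    var_t = float((tr * tr).sum())
    return cov / (ad.sqrt(var_s * var_t + 1e-12))


def hard_spearman(pred: np.ndarray, target: np.ndarray) -> float:
    """Exact rank-based Spearman coefficient (test oracle)."""
    from scipy.stats import spearmanr

    return float(spearmanr(pred, target).statistic)


def hybrid_loss(
    pred: Tensor,
    target: np.ndarray,
    lam: float = 1.0,
    temperature: float = 0.1,
) -> Tensor:
    """MSE + λ·(1 − soft-Spearman).

    Zero exactly when predictions equal targets; the rank term is invariant
    to monotone shifts of the predictions.  With fewer than two samples, or
    a constant target vector (rank undefined), the loss falls back to MSE.
    """
    target = np.asarray(target, dtype=float)
    diff = pred - target
    mse = (diff * diff).mean()
    if pred.shape[0] < 2:
        return mse
    if np.ptp(target) == 0:
        logger.warning("constant target batch: rank term skipped")
        return mse
    rho = soft_spearman(pred, target, temperature)
    return mse + lam * (1.0 - rho)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _rotation_matrix(angles_rad: np.ndarray) -> np.ndarray:
    """Sequential rotations about the H, W, D axes."""
    ah, aw, dd = angles_rad
    ch, sh = np.cos(ah), np.sin(ah)
    cw, sw = np.cos(aw), np.sin(aw)
    cd, sd = np.cos(dd), np.sin(dd)
    Rh = np.array([[1, 0, 0], [0, ch, -sh], [0, sh, ch]])
    Rw = np.array([[cw, 0, sw], [0, 1, 0], [-sw, 0, cw]])
    Rd = np.array([[cd, -sd, 0], [sd, cd, 0], [0, 0, 1]])
    return Rd @ Rw @ Rh


def augment(
    volume: np.ndarray,
    rng: np.random.Generator,
    rotation_deg: float = 20.0,
    translation_vox: int = 6,
) -> np.ndarray:
    """Random rigid augmentation of one 3D volume.

    One angle per axis ~ Uniform(−rotation_deg, rotation_deg), composed
    about H, W, D in sequence; one integer shift per axis
    ~ Uniform{−translation_vox, …, translation_vox}.  Trilinear resampling,
    zero fill outside the field of view; extents unchanged.
    """
    volume = np.asarray(volume)
    angles = np.deg2rad(rng.uniform(-rotation_deg, rotation_deg, 3))
    shift = rng.integers(-translation_vox, translation_vox + 1, 3)
    R = _rotation_matrix(angles)
    c = (np.asarray(volume.shape) - 1) / 2.0
    Rinv = R.T  # rotations are orthogonal
    # output[o] = input[Rinv @ (o - c - t) + c]
    offset = c - Rinv @ (c + shift)
    return scipy.ndimage.affine_transform(
        volume, Rinv, offset=offset, order=1, mode="constant", cval=0.0
    )


# ---------------------------------------------------------------------------
# bias correction and metrics
# ---------------------------------------------------------------------------


def fit_bias(pred: np.ndarray, chron: np.ndarray) -> BiasModel:
    """OLS fit of predicted age on chronological age (held-out data)."""
    pred = np.asarray(pred, dtype=float)
    chron = np.asarray(chron, dtype=float)
    if len(np.unique(chron)) < 2:
        raise ValueError("bias fit needs at least two distinct chronological ages")
    slope, intercept = np.polyfit(chron, pred, 1)
    if abs(slope) < 1e-12:
        raise ValueError("fitted slope is zero; bias correction is not applicable")
    return BiasModel(slope=float(slope), intercept=float(intercept))


def apply_bias(pred: np.ndarray, model: BiasModel) -> np.ndarray:
    """Invert the fitted linear bias: corrected = (pred − b)/a."""
    if model.slope == 0:
        raise ValueError("bias model has zero slope")
    return (np.asarray(pred, dtype=float) - model.intercept) / model.slope


def metrics(pred: np.ndarray, target: np.ndarray) -> tuple:
    """(MAE in years, Pearson correlation); PCC is nan when degenerate."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("prediction/target length mismatch")
    mae = float(np.abs(pred - target).mean())
    if pred.size < 2 or np.ptp(pred) == 0 or np.ptp(target) == 0:
        return mae, float("nan")
    return mae, float(np.corrcoef(pred, target)[0, 1])


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------


def stratified_split(
    ages: np.ndarray,
    fractions: tuple = (0.70, 0.15, 0.15),
    seed: int = 0,
    bin_years: float = 10.0,
) -> tuple:
    """Train/val/test indices, stratified by age bins.

    Each decade-of-age bin is shuffled and divided by the given fractions,
    so the three splits have similar age distributions.  Per-bin rounding
    remainders go to the training split.
    """
    ages = np.asarray(ages, dtype=float)
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    n_total = len(ages)
    rng = np.random.default_rng(seed)
    bins = np.floor(ages / bin_years).astype(int)
    uniq = np.unique(bins)
    bin_idx = []
    for b in uniq:
        idx = np.flatnonzero(bins == b)
        rng.shuffle(idx)
        bin_idx.append(list(idx))

    def allocate(counts, frac):
        """Largest-remainder allocation of round(n·frac) across bins."""
        want = int(round(n_total * frac))
        raw = np.array([c * frac for c in counts])
        base = np.floor(raw).astype(int)
        base = np.minimum(base, counts)
        short = want - base.sum()
        order = np.argsort(-(raw - np.floor(raw)))
        for j in order:
            if short <= 0:
                break
            if base[j] < counts[j]:
                base[j] += 1
                short -= 1
        return base

    counts = [len(ix) for ix in bin_idx]
    n_val = allocate(counts, fractions[1])
    remaining = [c - v for c, v in zip(counts, n_val)]
    n_test = allocate(remaining, fractions[2])
    train, val, test = [], [], []
    for ix, nv, nt in zip(bin_idx, n_val, n_test):
        val.extend(ix[:nv])
        test.extend(ix[nv : nv + nt])
        train.extend(ix[nv + nt :])
    return (np.sort(np.array(train, dtype=int)),
            np.sort(np.array(val, dtype=int)),
            np.sort(np.array(test, dtype=int)))


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """Step decay: lr · decay^(epoch // step)."""
    return config.lr * config.lr_decay ** (epoch // config.lr_step_epochs)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _predict_batched(model, volumes: np.ndarray, sex: np.ndarray | None,
                     batch_size: int) -> np.ndarray:
    preds = []
    was_training = model.training
    model.eval()
    try:
        with ad.no_grad():
            for i in range(0, len(volumes), batch_size):
                xb = Tensor(volumes[i : i + batch_size, None].astype(nn.DTYPE))
                sb = None if sex is None else sex[i : i + batch_size].astype(nn.DTYPE)
                preds.append(model(xb, sb).data)
    finally:
        model.train(was_training)
    return np.concatenate(preds)


def train_loop(model, cohort, config: TrainConfig):
    """Train on a cohort, validate each epoch, keep the best checkpoint.

    ``cohort`` needs ``volumes`` (n, H, W, D), ``ages`` (n,), and optionally
    ``sex_onehot`` (n, 2) when the model takes a sex input.  The cohort is
    split 70/15/15 stratified by age decade; augmentation applies to the
    training split only; the age-bias model is fitted on validation
    predictions of the best epoch.

    Returns ``(model, history, aux)`` where history is a list of per-epoch
    dicts (epoch, lr, loss, train_mae, val_mae) and aux carries the split
    indices, the bias model, and test metrics before/after correction.
    """
    volumes = np.asarray(cohort.volumes, dtype=np.float32)
    ages = np.asarray(cohort.ages, dtype=float)
    sex = getattr(cohort, "sex_onehot", None)
    use_sex = model.spec.with_sex
    if use_sex and sex is None:
        raise ValueError("model requires sex input but cohort has none")
    sex_arr = np.asarray(sex, dtype=np.float32) if use_sex else None

    tr, va, te = stratified_split(
        ages, config.split, seed=config.seed, bin_years=config.age_bin_years
    )
    rng = np.random.default_rng(config.seed + 1)
    # start the regression head at the mean training age (standard practice
    # in brain-age models); skipped when resuming a trained head
    if np.all(model.head.bias.data == 0):
        model.head.bias.data = np.array([ages[tr].mean()], dtype=nn.DTYPE)
    opt = nn.Adam(model.parameters(), lr=config.lr,
                  weight_decay=config.weight_decay)

    history = []
    best_val = np.inf
    best_state = None
    model.train()
    for epoch in range(config.epochs):
        opt.lr = learning_rate_at(epoch, config)
        order = rng.permutation(tr)
        epoch_losses = []
        train_preds, train_targets = [], []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            if config.augment:
                xb = np.stack([
                    augment(volumes[j], rng, config.rotation_deg,
                            config.translation_vox)
                    for j in idx
                ])
            else:
                xb = volumes[idx]
            x = Tensor(xb[:, None].astype(nn.DTYPE))
            sb = sex_arr[idx] if use_sex else None
            pred = model(x, sb)
            loss = hybrid_loss(pred, ages[idx], config.lam,
                               config.rank_temperature)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: loss={loss.data!r}, "
                    f"pred range=({pred.data.min()}, {pred.data.max()})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            train_preds.append(pred.data.copy())
            train_targets.append(ages[idx])

        train_mae, _ = metrics(np.concatenate(train_preds),
                               np.concatenate(train_targets))
        val_pred = _predict_batched(model, volumes[va],
                                    sex_arr[va] if use_sex else None,
                                    config.batch_size)
        val_mae, _ = metrics(val_pred, ages[va])
        row = {
            "epoch": epoch,
            "lr": opt.lr,
            "loss": float(np.mean(epoch_losses)),
            "train_mae": train_mae,
            "val_mae": val_mae,
        }
        history.append(row)
        logger.info(
            "epoch %d lr %.2e loss %.3f train MAE %.2f val MAE %.2f",
            epoch, opt.lr, row["loss"], train_mae, val_mae,
        )
        if val_mae < best_val:
            best_val = val_mae
            best_state = copy.deepcopy(model.state_dict())

    if best_state is not None:
        model.load_state_dict(best_state)

    # bias correction fitted on validation predictions of the best model
    val_pred = _predict_batched(model, volumes[va],
                                sex_arr[va] if use_sex else None,
                                config.batch_size)
    try:
        bias = fit_bias(val_pred, ages[va])
    except ValueError as err:
        logger.warning("bias correction unavailable: %s", err)
        bias = None

    test_pred = _predict_batched(model, volumes[te],
                                 sex_arr[te] if use_sex else None,
                                 config.batch_size)
    test_mae, test_pcc = metrics(test_pred, ages[te])
    aux = {
        "splits": {"train": tr, "val": va, "test": te},
        "bias": bias,
        "best_val_mae": float(best_val),
        "test_mae": test_mae,
        "test_pcc": test_pcc,
    }
    if bias is not None:
        corrected = apply_bias(test_pred, bias)
        aux["test_mae_corrected"], aux["test_pcc_corrected"] = metrics(
            corrected, ages[te]
        )
    return model, history, aux
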