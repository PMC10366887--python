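"""Training protocol and evaluation metrics.

Training follows the standard supervised denoising recipe: one whole
volume held out for validation, axial slices shuffled, random horizontal
and vertical flips (plus singular-vector sign flips in the transform
domain), Adam at learning rate 2e-4 with batch size 8, a plateau
scheduler that halves the learning rate after 10 epochs without a new
validation-loss minimum, and early stopping after 20; the
best-validation weights are restored.

Metrics: water-ROI bias and noise in Hounsfield units, volume RMSE in HU
against a reference reconstruction, per-material RMSE of decompositions,
and per-slice SSIM / PSNR.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import MaterialMaps, SpectralVolume
from .denoise_nets import NetConfig, UNet2D, build_unet, predict_slices, predict_volume
from .losses import LossConfig, SliceBatch, make_loss_config, mse_loss_grad, unetu_loss_grad
from .spectral_materials import ROISpec, SensitivityMatrix
from .u_transform import forward_transform, project_label

__all__ = [
    "TrainConfig", "PlateauEarlyStop", "make_splits", "augment", "train",
    "attenuation_to_hu", "roi_bias_noise", "rmse", "rmse_hu", "material_rmse",
    "ssim_psnr", "UnetUDenoiser", "UnetWFBPDenoiser",
]


@dataclass
class TrainConfig:
    max_epochs: int = 2000
    batch_size: int = 8
    learning_rate: float = 2e-4
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    stop_patience: int = 20
    flip_prob: float = 0.5
    sign_flip_prob: float = 0.5  # transform-domain training only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_patience <= 0 or self.stop_patience <= 0:
            raise ValueError("patiences must be positive")
        if self.stop_patience < self.plateau_patience:
            raise ValueError("early-stop patience must be >= plateau patience")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class PlateauEarlyStop:
    """Validation-loss plateau scheduler + early stopping.

    "Fails to decrease" means no new running minimum (strict); both the
    plateau counter and the stop counter run concurrently and reset on
    any new minimum.
    """

    def __init__(self, plateau_patience: int = 10, stop_patience: int = 20):
        self.plateau_patience = plateau_patience
        self.stop_patience = stop_patience
        self.best = np.inf
        self._plateau = 0
        self._stall = 0

    def update(self, val_loss: float) -> tuple[bool, bool, bool]:
        """Returns (improved, halve_lr_now, stop_now)."""
        improved = val_loss < self.best
        if improved:
            self.best = val_loss
            self._plateau = 0
            self._stall = 0
            return True, False, False
        self._plateau += 1
        self._stall += 1
        halve = self._plateau >= self.plateau_patience
        if halve:
            self._plateau = 0
        return False, halve, self._stall >= self.stop_patience


def make_splits(volumes: list, seed: int = 0) -> tuple[list, list]:
    """Hold out one whole volume; shuffle slice references.

    ``volumes`` is a list of objects exposing ``grid_shape`` (or plain
    slice counts).  Returns (train_refs, val_refs) where each ref is a
    ``(volume_index, slice_index)`` pair.
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes to split")
    rng = np.random.default_rng(seed)
    held_out = int(rng.integers(len(volumes)))

    def n_slices(v):
        return v if isinstance(v, int) else v.grid_shape[0]

    train_refs, val_refs = [], []
    for i, v in enumerate(volumes):
        refs = [(i, z) for z in range(n_slices(v))]
        (val_refs if i == held_out else train_refs).extend(refs)
    rng.shuffle(train_refs)
    rng.shuffle(val_refs)
    return train_refs, val_refs


def augment(
    inp: np.ndarray,
    label: np.ndarray,
    rng: np.random.Generator,
    flip_prob: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Random horizontal/vertical flips, identical for input and label.

    Slices are (C, H, W).  Returns the pair plus the (flip_v, flip_h)
    decisions so callers can transform side information the same way.
    """
    flip_v = bool(rng.random() < flip_prob)
    flip_h = bool(rng.random() < flip_prob)
    axes = tuple(
        ax for ax, f in ((-2, flip_v), (-1, flip_h)) if f
    )
    if axes:
        inp = np.flip(inp, axis=axes).copy()
        label = np.flip(label, axis=axes).copy()
    return inp, label, (flip_v, flip_h)


# ---------------------------------------------------------------------------
# slice datasets


class TransformSliceDataset:
    """Transform-domain slices of paired volumes with per-slice inversion data."""

    def __init__(self, noisy_volumes, clean_volumes, flip_prob=0.5, sign_flip_prob=0.5):
        self.u_in, self.u_lab, self.states = [], [], []
        self.flip_prob = flip_prob
        self.sign_flip_prob = sign_flip_prob
        for noisy, clean in zip(noisy_volumes, clean_volumes):
            U, state = forward_transform(noisy)
            self.u_in.append(U)
            self.u_lab.append(project_label(clean, state))
            self.states.append(state)

    def volumes(self):
        return self.states  # expose grid shapes for make_splits

    def batch(self, refs: list, rng: np.random.Generator | None = None):
        """Assemble (input, SliceBatch) for slice refs; rng enables augmentation."""
        xs, ys, lps, variances, svts, scales = [], [], [], [], [], []
        for vol, z in refs:
            x = self.u_in[vol][:, z]
            y = self.u_lab[vol][:, z]
            state = self.states[vol]
            lp = state.lowpass[:, z].astype(np.float64)
            svt = state.svt()
            if rng is not None:
                x, y, flips = augment(x, y, rng, self.flip_prob)
                if flips[0] or flips[1]:
                    axes = tuple(ax for ax, f in ((-2, flips[0]), (-1, flips[1])) if f)
                    lp = np.flip(lp, axis=axes).copy()
                signs = np.where(
                    rng.random(state.n_components) < self.sign_flip_prob, -1.0, 1.0
                )
                x = x * signs[:, None, None].astype(x.dtype)
                y = y * signs[:, None, None].astype(y.dtype)
                lp = lp * signs[:, None, None]
                svt = svt * signs[:, None]
            xs.append(x)
            ys.append(y)
            lps.append(lp)
            variances.append(state.variances)
            svts.append(svt)
            scales.append(state.scales)
        batch = SliceBatch(
            u_in=np.stack(xs).astype(np.float32),
            u_label=np.stack(ys).astype(np.float32),
            lowpass=np.stack(lps),
            variances=np.stack(variances),
            svt=np.stack(svts),
            scales=np.stack(scales),
        )
        return batch.u_in, batch


class PairSliceDataset:
    """Reconstruction-domain slice pairs (conventional denoiser training)."""

    def __init__(self, noisy_volumes, clean_volumes, flip_prob=0.5):
        self.noisy = [v.data for v in noisy_volumes]
        self.clean = [v.data for v in clean_volumes]
        self.flip_prob = flip_prob
        self._shapes = [v for v in noisy_volumes]

    def volumes(self):
        return self._shapes

    def batch(self, refs: list, rng: np.random.Generator | None = None):
        xs, ys = [], []
        for vol, z in refs:
            x = self.noisy[vol][:, z]
            y = self.clean[vol][:, z]
            if rng is not None:
                x, y, _ = augment(x, y, rng, self.flip_prob)
            xs.append(x)
            ys.append(y)
        return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32)


# ---------------------------------------------------------------------------
# training loop


def train(
    net: UNet2D,
    loss_grad_fn,
    dataset,
    splits: tuple,
    cfg: TrainConfig,
):
    """Train a network; returns (best_state_dict, history).

    ``loss_grad_fn(pred, aux) -> (loss, grad, parts)`` where ``aux`` is
    whatever ``dataset.batch`` returned alongside the input. Validation
    uses the same loss without augmentation; the best-validation weights
    are returned and also restored into ``net``.
    """
    from .nn import Adam

    train_refs, val_refs = splits
    if not train_refs or not val_refs:
        raise ValueError("empty training or validation split")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params, lr=cfg.learning_rate)
    sched = PlateauEarlyStop(cfg.plateau_patience, cfg.stop_patience)
    best_state = net.state_dict()
    history = {"train_loss": [], "val_loss": [], "lr": [], "parts": []}

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_refs))
        epoch_loss, n_seen = 0.0, 0
        part_acc: dict = {}
        for start in range(0, len(order), cfg.batch_size):
            refs = [train_refs[i] for i in order[start:start + cfg.batch_size]]
            x, aux = dataset.batch(refs, rng)
            pred = net.forward(x, train=True)
            loss, grad, parts = loss_grad_fn(pred, aux)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            net.zero_grad()
            net.backward(grad.astype(np.float32))
            opt.step(net.grads)
            epoch_loss += loss * len(refs)
            n_seen += len(refs)
            for k, v in (parts or {}).items():
                part_acc[k] = part_acc.get(k, 0.0) + v * len(refs)

        val_loss = evaluate_loss(net, loss_grad_fn, dataset, val_refs, cfg.batch_size)
        history["train_loss"].append(epoch_loss / n_seen)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        history["parts"].append({k: v / n_seen for k, v in part_acc.items()})

        improved, halve, stop = sched.update(val_loss)
        if improved:
            best_state = net.state_dict()
        if halve:
            opt.lr *= cfg.plateau_factor
        if stop:
            break

    net.load_state_dict(best_state)
    return best_state, history


def calibrate_loss_weights(dataset, refs, sensitivity, batch_size=8,
                           max_slices=64) -> tuple:
    """Loss weights that equalize the first three terms at the identity.

    The four-term loss is designed so that its reconstruction, transform
    and decomposition terms have similar magnitude; the term magnitudes
    depend on the data (noise level, transform scales, sensitivity
    conditioning), so the weights are measured on the training slices
    with the network replaced by the identity map.  Returns
    ``(lambda1, lambda2)``.
    """
    from .losses import unetu_loss

    cfg = make_loss_config(sensitivity, lambda1=1.0, lambda2=1.0)
    t1 = t2 = t3 = 0.0
    n = 0
    for start in range(0, min(len(refs), max_slices), batch_size):
        chunk = refs[start:start + batch_size]
        _, batch = dataset.batch(chunk, rng=None)
        _, parts = unetu_loss(batch.u_in, batch, cfg, return_parts=True)
        t1 += parts["reconstruction"] * len(chunk)
        t2 += parts["transform"] * len(chunk)
        t3 += parts["decomposition"] * len(chunk)
        n += len(chunk)
    tiny = np.finfo(np.float64).tiny
    return t1 / max(t2, tiny), t1 / max(t3, tiny)


def evaluate_loss(net, loss_grad_fn, dataset, refs, batch_size=8) -> float:
    total, n = 0.0, 0
    for start in range(0, len(refs), batch_size):
        chunk = refs[start:start + batch_size]
        x, aux = dataset.batch(chunk, rng=None)
        pred = net.forward(x, train=False)
        loss, _, _ = loss_grad_fn(pred, aux)
        total += loss * len(chunk)
        n += len(chunk)
    return total / n


def write_history_csv(history: dict, path: str | Path) -> None:
    """Per-epoch loss curves (train, validation, lr, loss terms) as CSV."""
    part_keys = sorted({k for p in history["parts"] for k in p})
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["epoch", "train_loss", "val_loss", "lr", *part_keys])
        for i in range(len(history["train_loss"])):
            parts = history["parts"][i]
            writer.writerow(
                [i, history["train_loss"][i], history["val_loss"][i],
                 history["lr"][i], *[parts.get(k, "") for k in part_keys]]
            )


# ---------------------------------------------------------------------------
# metrics


def attenuation_to_hu(data: np.ndarray, water_mu: np.ndarray) -> np.ndarray:
    """HU = 1000 (mu - mu_water) / mu_water per energy channel.

    ``data`` is (E, ...) attenuation; ``water_mu`` the per-energy water
    attenuation (the calibrated water row of the sensitivity matrix).
    """
    water_mu = np.asarray(water_mu, dtype=np.float64)
    extra = (slice(None),) + (None,) * (data.ndim - 1)
    return 1000.0 * (data - water_mu[extra]) / water_mu[extra]


def roi_bias_noise(
    denoised: SpectralVolume,
    reference_noisy: SpectralVolume,
    roi: ROISpec,
    water_mu: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Water-ROI bias and noise per energy.

    Bias is the absolute difference between the ROI mean of the denoised
    volume and of the noisy reference; noise is the ROI standard
    deviation of the denoised volume.  In HU when ``water_mu`` is given,
    otherwise in 1/cm.
    """
    d = roi.extract(denoised)
    r = roi.extract(reference_noisy)
    if water_mu is not None:
        d = attenuation_to_hu(d, water_mu)
        r = attenuation_to_hu(r, water_mu)
    bias = np.abs(d.mean(axis=1) - r.mean(axis=1))
    noise = d.std(axis=1, ddof=1)
    return bias, noise


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    return float(np.sqrt(np.mean(d * d)))


def rmse_hu(volume: SpectralVolume, reference: SpectralVolume,
            water_mu: np.ndarray) -> float:
    """Volume RMSE in HU relative to a reference reconstruction."""
    return rmse(
        attenuation_to_hu(volume.data, water_mu),
        attenuation_to_hu(reference.data, water_mu),
    )


def material_rmse(maps: MaterialMaps, reference: MaterialMaps) -> dict:
    """Per-material RMSE in native units (g/mL water, mg/mL others)."""
    if maps.materials != reference.materials:
        raise ValueError("material lists differ")
    return {
        m: rmse(maps.data[i], reference.data[i])
        for i, m in enumerate(maps.materials)
    }


def ssim_psnr(
    image: np.ndarray, reference: np.ndarray, data_range: float | None = None
) -> tuple[float, float]:
    """SSIM (Gaussian window, sigma 1.5) and PSNR of a slice vs a reference.

    Identical images give (1.0, inf).  ``data_range`` defaults to the
    reference max - min.
    """
    image = np.asarray(image, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if data_range is None:
        data_range = float(reference.max() - reference.min())
    mse = np.mean((image - reference) ** 2)
    psnr = np.inf if mse == 0 else 10.0 * np.log10(data_range**2 / mse)
    if min(image.shape) >= 11:
        ssim = structural_similarity(
            image, reference, data_range=data_range,
            gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        )
    elif min(image.shape) >= 3:  # smaller than the Gaussian window: uniform
        win = min(image.shape) - (1 - min(image.shape) % 2)
        ssim = structural_similarity(
            image, reference, data_range=data_range, win_size=win,
        )
    else:  # degenerate image: single global window
        c1 = (0.01 * data_range) ** 2
        c2 = (0.03 * data_range) ** 2
        mx, my = image.mean(), reference.mean()
        vx, vy = image.var(), reference.var()
        cov = ((image - mx) * (reference - my)).mean()
        ssim = ((2 * mx * my + c1) * (2 * cov + c2)) / (
            (mx**2 + my**2 + c1) * (vx + vy + c2)
        )
    return float(ssim), float(psnr)


# ---------------------------------------------------------------------------
# estimators


class _UnetDenoiserBase(BaseEstimator, TransformerMixin):
    def __init__(self, levels=4, base_filters=64, convs_per_level=2,
                 batch_norm=True, max_epochs=2000, batch_size=8,
                 learning_rate=2e-4, plateau_patience=10, stop_patience=20,
                 flip_prob=0.5, seed=0):
        self.levels = levels
        self.base_filters = base_filters
        self.convs_per_level = convs_per_level
        self.batch_norm = batch_norm
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.plateau_patience = plateau_patience
        self.stop_patience = stop_patience
        self.flip_prob = flip_prob
        self.seed = seed

    def _train_config(self, sign_flip_prob=0.5) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            plateau_patience=self.plateau_patience,
            stop_patience=self.stop_patience, flip_prob=self.flip_prob,
            sign_flip_prob=sign_flip_prob, seed=self.seed,
        )

    def _net_config(self, n_energies: int, output_activation: str,
                    residual: bool) -> NetConfig:
        return NetConfig(
            levels=self.levels, convs_per_level=self.convs_per_level,
            in_channels=n_energies, out_channels=n_energies,
            base_filters=self.base_filters, residual=residual,
            output_activation=output_activation, batch_norm=self.batch_norm,
            seed=self.seed,
        )

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted")


class UnetWFBPDenoiser(_UnetDenoiserBase):
    """Conventional residual U-net denoiser trained with MSE.

    Input and labels live directly in the reconstruction domain; a
    residual connection from input to output handles the non-zero-
    centered attenuation data.
    """

    def fit(self, noisy_volumes: list, clean_volumes: list):
        cfg = self._train_config()
        net = build_unet(
            self._net_config(noisy_volumes[0].n_energies, "identity", residual=True)
        )
        dataset = PairSliceDataset(noisy_volumes, clean_volumes, cfg.flip_prob)
        splits = make_splits(dataset.volumes(), cfg.seed)
        self.validation_index_ = splits[1][0][0]

        def loss_grad(pred, label):
            loss, grad = mse_loss_grad(pred, label)
            return loss, grad, {"mse": loss}

        _, self.history_ = train(net, loss_grad, dataset, splits, cfg)
        self.net_ = net
        return self

    def transform(self, volume: SpectralVolume) -> SpectralVolume:
        self._check_fitted()
        return predict_volume(self.net_, volume, self.batch_size)


class UnetUDenoiser(_UnetDenoiserBase):
    """Transform-domain U-net denoiser (Tanhshrink output, four-term loss).

    ``fit`` takes paired noisy/clean volumes plus the sensitivity matrix
    whose rescaled inverse drives the decomposition loss term;
    ``transform`` runs noisy volume -> channel transform -> network ->
    exact inverse transform.

    Parameters beyond the base ones: ``lambda1``/``lambda2`` loss
    weights, ``loss`` ("custom" four-term or "mse" transform-domain MSE),
    ``sign_flip_prob`` for singular-vector sign-flip augmentation.
    """

    def __init__(self, levels=4, base_filters=64, convs_per_level=2,
                 batch_norm=True, max_epochs=2000, batch_size=8,
                 learning_rate=2e-4, plateau_patience=10, stop_patience=20,
                 flip_prob=0.5, seed=0, lambda1=15.0, lambda2=0.2,
                 sign_flip_prob=0.5, loss="custom", lambda_calibration="fixed"):
        super().__init__(levels, base_filters, convs_per_level, batch_norm,
                         max_epochs, batch_size, learning_rate,
                         plateau_patience, stop_patience, flip_prob, seed)
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.sign_flip_prob = sign_flip_prob
        self.loss = loss
        self.lambda_calibration = lambda_calibration

    def fit(self, noisy_volumes: list, clean_volumes: list,
            sensitivity: SensitivityMatrix | None = None):
        if self.loss == "custom" and sensitivity is None:
            raise ValueError("the four-term loss requires a sensitivity matrix")
        cfg = self._train_config(self.sign_flip_prob)
        net = build_unet(
            self._net_config(noisy_volumes[0].n_energies, "tanhshrink", residual=False)
        )
        dataset = TransformSliceDataset(
            noisy_volumes, clean_volumes, cfg.flip_prob, cfg.sign_flip_prob
        )
        splits = make_splits(dataset.volumes(), cfg.seed)
        self.validation_index_ = splits[1][0][0]

        if self.loss == "custom":
            if self.lambda_calibration == "balanced":
                self.lambda1_, self.lambda2_ = calibrate_loss_weights(
                    dataset, splits[0], sensitivity, cfg.batch_size
                )
            elif self.lambda_calibration == "fixed":
                self.lambda1_, self.lambda2_ = self.lambda1, self.lambda2
            else:
                raise ValueError(
                    f"unknown lambda_calibration {self.lambda_calibration!r}"
                )
            loss_cfg = make_loss_config(sensitivity, lambda1=self.lambda1_,
                                        lambda2=self.lambda2_)

            def loss_grad(pred, aux: SliceBatch):
                return unetu_loss_grad(pred, aux, loss_cfg)
        elif self.loss == "mse":

            def loss_grad(pred, aux: SliceBatch):
                loss, grad = mse_loss_grad(pred, aux.u_label)
                return loss, grad, {"mse": loss}
        else:
            raise ValueError(f"unknown loss {self.loss!r}")

        _, self.history_ = train(net, loss_grad, dataset, splits, cfg)
        self.net_ = net
        return self

    def transform(self, volume: SpectralVolume) -> SpectralVolume:
        self._check_fitted()
        U, state = forward_transform(volume)
        U_pred = predict_slices(self.net_, U, self.batch_size)
        from .u_transform import inverse_transform

        return inverse_transform(U_pred, state)
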