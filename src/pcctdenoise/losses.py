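"""Training losses: plain MSE and the four-term transform-domain loss.

The four-term loss compares prediction and label in four coupled domains:

    L = 1/N ||X - X_l||^2_F                  (reconstruction)
      + lambda1 * 1/N ||U - U_l||^2_F        (transform domain)
      + lambda2 * 1/N ||X M^-1 - X_l M^-1||^2_F   (material decomposition)
      + 1/N ||X_blur - X_blur,l||^2_F        (blurred reconstruction)

where X is obtained from the network output U by the per-slice inverse
channel transform, M is the sensitivity matrix with each row rescaled by
its calibration vial concentration (so every material map sits near unit
scale), the decomposition is the plain matrix inverse (no non-negativity
constraint inside the loss), and the blur is a 2D 19x19 Gaussian of FWHM 5
applied to each energy channel of the axial slices.  Each term is
normalized by its own element count.  Defaults lambda1=15, lambda2=0.2 put
the first three terms on a similar magnitude.

Because every map from U to the loss is affine with fixed coefficients,
the gradient w.r.t. the network output is assembled from the exact
adjoints of the inverse transform, the decomposition, and the blur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import blur2d
from .spectral_materials import SensitivityMatrix

__all__ = ["LossConfig", "SliceBatch", "rescale_sensitivity", "mse_loss",
           "mse_loss_grad", "unetu_loss", "unetu_loss_grad"]


@dataclass
class LossConfig:
    lambda1: float = 15.0
    lambda2: float = 0.2
    blur_fwhm: float = 5.0
    blur_radius: int = 9  # 19-tap kernel
    sensitivity_inv: np.ndarray | None = None  # (E, M) inverse of rescaled M

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


def rescale_sensitivity(M: SensitivityMatrix, vial_concentrations=None) -> np.ndarray:
    """Multiply each row of M by its calibration vial concentration.

    Decomposing with the rescaled matrix yields maps near 1.0 at the
    calibration concentration, which keeps the decomposition loss term on
    a comparable scale for every material.
    """
    if vial_concentrations is None:
        vial_concentrations = M.vial_concentrations
    try:
        conc = np.array([float(vial_concentrations[m]) for m in M.materials])
    except KeyError as exc:
        raise ValueError(f"missing calibration concentration for {exc.args[0]!r}") from None
    return conc[:, None] * M.matrix


def make_loss_config(M: SensitivityMatrix, vial_concentrations=None,
                     lambda1: float = 15.0, lambda2: float = 0.2) -> LossConfig:
    """LossConfig with the inverse of the rescaled sensitivity matrix baked in."""
    rescaled = rescale_sensitivity(M, vial_concentrations)
    if rescaled.shape[0] == rescaled.shape[1]:
        inv = np.linalg.inv(rescaled)
    else:
        inv = np.linalg.pinv(rescaled)
    return LossConfig(lambda1=lambda1, lambda2=lambda2, sensitivity_inv=inv)


@dataclass
class SliceBatch:
    """A batch of axial slices with everything needed for per-slice inversion.

    All arrays are per-sample so slices from different volumes (different
    transform states, flips, sign flips) can share a batch:

    - ``u_in``/``u_label``: (B, E, H, W) transform-domain input and label
    - ``lowpass``: (B, E, H, W) stored low-pass content added back at inversion
    - ``variances``, ``scales``: (B, E)
    - ``svt``: (B, E, E) diag(S) @ V^T with any augmentation sign flips applied
    """

    u_in: np.ndarray
    u_label: np.ndarray
    lowpass: np.ndarray
    variances: np.ndarray
    svt: np.ndarray
    scales: np.ndarray

    def invert(self, U: np.ndarray) -> np.ndarray:
        """Per-slice inverse transform: (B, E, H, W) U-images -> attenuation."""
        comps = U.astype(np.float64) * self.scales[:, :, None, None] + self.lowpass
        x = np.einsum("bkhw,bke->behw", comps, self.svt, optimize=True)
        return x * self.variances[:, :, None, None]

    def invert_adjoint(self, gx: np.ndarray) -> np.ndarray:
        """Adjoint of the linear part of :meth:`invert`."""
        g = gx * self.variances[:, :, None, None]
        g = np.einsum("behw,bke->bkhw", g, self.svt, optimize=True)
        return g * self.scales[:, :, None, None]


def mse_loss(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean squared error over all elements."""
    d = pred.astype(np.float64) - label.astype(np.float64)
    return float(np.mean(d * d))


def mse_loss_grad(pred: np.ndarray, label: np.ndarray) -> tuple[float, np.ndarray]:
    d = pred.astype(np.float64) - label.astype(np.float64)
    return float(np.mean(d * d)), (2.0 / d.size) * d


def unetu_loss(
    U_pred: np.ndarray,
    batch: SliceBatch,
    cfg: LossConfig,
    return_parts: bool = False,
):
    """Four-term loss for a batch of transform-domain slices.

    Returns the scalar loss, or ``(loss, parts)`` with the individual
    weighted terms when ``return_parts`` is set.
    """
    loss, parts, _ = _unetu_loss_core(U_pred, batch, cfg, want_grad=False)
    if return_parts:
        return loss, parts
    return loss


def unetu_loss_grad(
    U_pred: np.ndarray, batch: SliceBatch, cfg: LossConfig
) -> tuple[float, np.ndarray, dict]:
    """Loss, analytic gradient w.r.t. ``U_pred``, and per-term values."""
    return _unetu_loss_core(U_pred, batch, cfg, want_grad=True)


def _unetu_loss_core(U_pred, batch, cfg, want_grad):
    if cfg.sensitivity_inv is None:
        raise ValueError("LossConfig.sensitivity_inv is required (see make_loss_config)")
    minv = np.asarray(cfg.sensitivity_inv, dtype=np.float64)  # (E, M)

    U_pred = np.asarray(U_pred, dtype=np.float64)
    U_label = np.asarray(batch.u_label, dtype=np.float64)
    x_pred = batch.invert(U_pred)
    x_label = batch.invert(U_label)
    dx = x_pred - x_label  # (B, E, H, W)
    du = U_pred - U_label

    dc = np.einsum("behw,em->bmhw", dx, minv, optimize=True)
    db = blur2d(dx, cfg.blur_fwhm, cfg.blur_radius)

    t_recon = float(np.mean(dx * dx))
    t_u = cfg.lambda1 * float(np.mean(du * du))
    t_decomp = cfg.lambda2 * float(np.mean(dc * dc))
    t_blur = float(np.mean(db * db))
    total = t_recon + t_u + t_decomp + t_blur
    parts = {
        "reconstruction": t_recon,
        "transform": t_u,
        "decomposition": t_decomp,
        "blur": t_blur,
    }
    if not want_grad:
        return total, parts, None

    gx = (2.0 / dx.size) * dx
    gx += cfg.lambda2 * (2.0 / dc.size) * np.einsum(
        "bmhw,em->behw", dc, minv, optimize=True
    )
    gx += (2.0 / db.size) * blur2d(db, cfg.blur_fwhm, cfg.blur_radius, transpose=True)
    grad = batch.invert_adjoint(gx) + cfg.lambda1 * (2.0 / du.size) * du
    return total, grad, parts
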