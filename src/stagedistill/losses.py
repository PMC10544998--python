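"""Loss functions for stage-wise knowledge distillation.

Three terms make up the training objective for the student classifier:

* a feature-matching loss — mean squared error between each of the four
  teacher stage feature maps and the (adapter-projected) student maps;
* a soft-target loss — cross-entropy between the temperature-smoothed
  teacher and student class distributions;
* a focal loss — class-weighted, hard-example-focused cross-entropy
  between the student prediction and the ground-truth label.

The total objective is ``alpha * L_feat + (1 - alpha) * L_soft +
beta * L_focal``.

Everything here is plain NumPy: each loss returns its scalar value and,
on request, the analytic gradient with respect to the *student* inputs
(teacher quantities are constants — no gradient ever flows to the
teacher). The training engine chains these gradients through the
network by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FocalParams",
    "LossWeights",
    "tempered_softmax",
    "softmax_backward",
    "entropy",
    "soft_target_loss",
    "focal_loss",
    "feature_match_loss",
    "bilinear_resize",
    "total_loss",
]

#: floor applied to predicted true-class probabilities before the log
PROB_FLOOR = 1e-12

#: number of backbone stages feature distillation operates on
N_STAGES = 4


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class FocalParams:
    """Focusing exponent and per-class weights of the focal loss.

    ``gamma`` down-weights well-classified examples; ``class_weights``
    (one positive weight per class, conventionally inverse class
    frequency normalised to mean 1) up-weights rare classes.
    """

    gamma: float = 2.0
    class_weights: np.ndarray = field(default_factory=lambda: np.ones(5))

    def __post_init__(self) -> None:
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.class_weights.ndim != 1 or self.class_weights.size < 2:
            raise ValueError("class_weights must be a 1-D array of length >= 2")
        if not np.all(self.class_weights > 0):
            raise ValueError("all class weights must be positive")


@dataclass
class LossWeights:
    """Coefficients of the combined objective.

    ``alpha`` balances feature matching against soft targets, ``beta``
    scales the supervised focal term, ``temperature`` smooths the
    distillation distributions.
    """

    alpha: float = 0.5
    beta: float = 1.0
    temperature: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


# ---------------------------------------------------------------------------
# tempered softmax
# ---------------------------------------------------------------------------

def tempered_softmax(logits: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    """Softmax of ``logits / temperature`` along the last axis.

    Larger temperatures yield smoother distributions, which carry more
    inter-class information when used as soft targets. Computed with
    max-subtraction for numerical stability.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    z = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    if z.shape[-1] < 2:
        raise ValueError("need at least 2 classes")
    z = z / float(temperature)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(probs: np.ndarray, grad_probs: np.ndarray) -> np.ndarray:
    """Pull a gradient w.r.t. softmax outputs back to the logits.

    Uses the softmax Jacobian ``diag(p) - p p^T`` row-wise:
    ``g_z = p * (g_p - <g_p, p>)``.
    """
    inner = np.sum(grad_probs * probs, axis=-1, keepdims=True)
    return probs * (grad_probs - inner)


def entropy(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) along the last axis, with 0·log 0 = 0."""
    p = np.asarray(probs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=-1)


# ---------------------------------------------------------------------------
# soft-target (logit distillation) loss
# ---------------------------------------------------------------------------

def soft_target_loss(
    student_logits: np.ndarray,
    teacher_logits: np.ndarray,
    temperature: float,
    *,
    t_squared: bool = False,
    return_grad: bool = False,
):
    """Cross-entropy between tempered teacher and student distributions.

    ``mean_b sum_i -p_i(z_t; T) * log p_i(z_s; T)``; the batch mean is
    taken over the leading axis. The teacher side is a constant. By
    default no ``T**2`` rescaling is applied — the tempered
    cross-entropy is used literally; set ``t_squared=True`` for the
    classic variant that keeps gradient magnitudes comparable across
    temperatures.

    Returns the scalar loss, or ``(loss, grad)`` with ``grad`` the
    gradient w.r.t. ``student_logits``.
    """
    zs = np.atleast_2d(np.asarray(student_logits, dtype=float))
    zt = np.atleast_2d(np.asarray(teacher_logits, dtype=float))
    if zs.shape != zt.shape:
        raise ValueError(
            f"student/teacher logit shapes differ: {zs.shape} vs {zt.shape}"
        )
    pt = tempered_softmax(zt, temperature)
    # log-softmax of the student, stable form
    z = zs / float(temperature)
    z = z - z.max(axis=-1, keepdims=True)
    log_ps = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    batch = zs.shape[0]
    scale = float(temperature) ** 2 if t_squared else 1.0
    loss = scale * float(-(pt * log_ps).sum() / batch)
    if not return_grad:
        return loss
    ps = np.exp(log_ps)
    grad = scale * (ps - pt) / (float(temperature) * batch)
    if np.asarray(student_logits).ndim == 1:
        grad = grad[0]
    return loss, grad


# ---------------------------------------------------------------------------
# focal loss
# ---------------------------------------------------------------------------

def focal_loss(
    student_probs: np.ndarray,
    labels: np.ndarray,
    params: FocalParams,
    *,
    return_grad: bool = False,
):
    """Class-weighted focal loss over a batch of probability vectors.

    ``mean_b -alpha_t * (1 - p_t)**gamma * log(p_t)`` where ``p_t`` is
    each sample's predicted probability of its true class and
    ``alpha_t`` the weight of that class. ``p_t`` is floored at 1e-12
    before the log so confident mistakes stay finite.

    With ``return_grad=True`` also returns the gradient with respect to
    the probability array (nonzero only at the true-class entries).
    """
    p = np.atleast_2d(np.asarray(student_probs, dtype=float))
    y = np.atleast_1d(np.asarray(labels))
    if y.shape[0] != p.shape[0]:
        raise ValueError("labels and probabilities disagree on batch size")
    n_classes = p.shape[1]
    if y.dtype.kind not in "iu":
        raise ValueError("labels must be integer class indices")
    if np.any((y < 0) | (y >= n_classes)):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    if params.class_weights.size != n_classes:
        raise ValueError("class_weights length must equal number of classes")

    batch = p.shape[0]
    idx = np.arange(batch)
    pt = np.clip(p[idx, y], PROB_FLOOR, None)
    alpha = params.class_weights[y]
    gamma = float(params.gamma)
    one_minus = np.clip(1.0 - pt, 0.0, None)
    loss = float(np.mean(-alpha * one_minus**gamma * np.log(pt)))
    if not return_grad:
        return loss

    # dL/dp_t = alpha * [ gamma (1-p)^{gamma-1} log p - (1-p)^gamma / p ] / B
    if gamma == 0.0:
        dpt = -alpha / pt
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            focus_term = gamma * one_minus ** (gamma - 1.0) * np.log(pt)
        focus_term = np.where(one_minus > 0, focus_term, 0.0)
        dpt = alpha * (focus_term - one_minus**gamma / pt)
    grad = np.zeros_like(p)
    grad[idx, y] = dpt / batch
    if np.asarray(student_probs).ndim == 1:
        grad = grad[0]
    return loss, grad


# ---------------------------------------------------------------------------
# feature-matching loss
# ---------------------------------------------------------------------------

def _bilinear_matrix(out_len: int, in_len: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel-centre convention)."""
    A = np.zeros((out_len, in_len))
    if in_len == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(out_len) + 0.5) * (in_len / out_len) - 0.5
    src = np.clip(src, 0.0, in_len - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, in_len - 1)
    w = src - lo
    A[np.arange(out_len), lo] += 1.0 - w
    A[np.arange(out_len), hi] += w
    return A


def bilinear_resize(x: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a (batch, channels, H, W) array to ``size``."""
    Ah = _bilinear_matrix(size[0], x.shape[2])
    Aw = _bilinear_matrix(size[1], x.shape[3])
    return np.einsum("ij,bcjk,lk->bcil", Ah, x, Aw, optimize=True)


def feature_match_loss(
    student_feats: Sequence[np.ndarray],
    teacher_feats: Sequence[np.ndarray],
    adapters,
    *,
    return_grads: bool = False,
):
    """Stage-wise L2 matching between student and teacher feature maps.

    For each of the four stages the learnable 1x1 adapter projects the
    student map into the teacher's channel space (the teacher-side
    transform is the identity); if the spatial sizes still differ the
    adapted map is bilinearly resized to the teacher's. The loss is the
    mean squared elementwise difference per stage, averaged over the
    four stages, so its magnitude is independent of feature-map size.

    ``adapters`` is any sequence of four objects exposing ``weight``
    of shape (teacher_channels, student_channels) and ``bias`` of shape
    (teacher_channels,).

    With ``return_grads=True`` returns
    ``(loss, feat_grads, adapter_grads)`` where ``feat_grads`` are the
    gradients w.r.t. each student feature map and ``adapter_grads`` is
    a list of ``(grad_weight, grad_bias)`` pairs.
    """
    if len(student_feats) != N_STAGES or len(teacher_feats) != N_STAGES:
        raise ValueError(f"expected {N_STAGES} stages on both sides")
    if len(adapters) != N_STAGES:
        raise ValueError(f"expected {N_STAGES} adapters")

    stage_losses = []
    feat_grads: list[np.ndarray] = []
    adapter_grads: list[tuple[np.ndarray, np.ndarray]] = []
    for fs, ft, ad in zip(student_feats, teacher_feats, adapters):
        fs = np.asarray(fs, dtype=float)
        ft = np.asarray(ft, dtype=float)
        if fs.ndim != 4 or ft.ndim != 4:
            raise ValueError("feature maps must be 4-D (batch, C, H, W)")
        if fs.shape[0] != ft.shape[0]:
            raise ValueError("student/teacher batch sizes differ")
        W = np.asarray(ad.weight, dtype=float)
        b = np.asarray(ad.bias, dtype=float)
        if W.shape != (ft.shape[1], fs.shape[1]):
            raise ValueError(
                f"adapter maps {W.shape[1]}->{W.shape[0]} channels but stage has "
                f"student {fs.shape[1]} / teacher {ft.shape[1]}"
            )
        projected = np.einsum("oc,bchw->bohw", W, fs, optimize=True)
        projected += b[None, :, None, None]
        resized = projected.shape[2:] != ft.shape[2:]
        matched = (
            bilinear_resize(projected, ft.shape[2:]) if resized else projected
        )
        diff = matched - ft
        stage_losses.append(float(np.mean(diff**2)))
        if return_grads:
            g_matched = 2.0 * diff / (diff.size * N_STAGES)
            if resized:
                Ah = _bilinear_matrix(ft.shape[2], projected.shape[2])
                Aw = _bilinear_matrix(ft.shape[3], projected.shape[3])
                g_proj = np.einsum(
                    "ji,bcjk,kl->bcil", Ah, g_matched, Aw, optimize=True
                )
            else:
                g_proj = g_matched
            feat_grads.append(np.einsum("oc,bohw->bchw", W, g_proj, optimize=True))
            adapter_grads.append(
                (
                    np.einsum("bohw,bchw->oc", g_proj, fs, optimize=True),
                    g_proj.sum(axis=(0, 2, 3)),
                )
            )
    loss = float(np.mean(stage_losses))
    if not return_grads:
        return loss
    return loss, feat_grads, adapter_grads


# ---------------------------------------------------------------------------
# combined objective
# ---------------------------------------------------------------------------

def total_loss(
    loss_feature: float,
    loss_soft: float,
    loss_focal: float,
    weights: LossWeights,
) -> float:
    """Weighted combination ``alpha*L1 + (1 - alpha)*L2 + beta*L3``."""
    for name, v in (
        ("loss_feature", loss_feature),
        ("loss_soft", loss_soft),
        ("loss_focal", loss_focal),
    ):
        if not np.isfinite(v):
            raise ValueError(f"{name} is not finite: {v}")
    return (
        weights.alpha * loss_feature
        + (1.0 - weights.alpha) * loss_soft
        + weights.beta * loss_focal
    )
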