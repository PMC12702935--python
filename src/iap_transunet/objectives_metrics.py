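"""Training objective (cross-entropy + Dice) and evaluation metrics
(Dice similarity coefficient, Hausdorff distance).

The training loss is the equal-weight average

    L = (L_CE + L_Dice) / 2

with L_CE the mean pixel-wise negative log-likelihood and L_Dice the soft
Dice loss ``1 - mean_c (2|X_c ∩ Y_c| + eps) / (|X_c| + |Y_c| + eps)``
computed from softmax probabilities against one-hot labels, averaged over
all classes (background included by default, as in the TransUNet lineage).

Evaluation works on hard label maps: per-class binary masks are scored by
the Dice coefficient 2|A∩B|/(|A|+|B|) and by the symmetric Hausdorff
distance between boundary-pixel point sets (max over both directions of
the max-min Euclidean distance, in pixel units).  An empty point set makes
the Hausdorff distance undefined; it is reported as NaN and excluded from
means, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .nn import Tensor

__all__ = [
    "cross_entropy_loss", "dice_loss", "total_loss",
    "softmax_cross_entropy_logits", "soft_dice_loss_logits", "total_loss_logits",
    "dsc_metric", "hausdorff", "UndefinedDistanceError", "mask_boundary",
    "MetricReport", "evaluate_case",
]

DICE_EPS = 1e-5


# -- validation helpers ---------------------------------------------------

def _check_prob_label(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    if p.ndim != y.ndim + 1:
        raise ValueError(f"prob map rank {p.ndim} does not fit label rank {y.ndim}")
    M = p.shape[1]
    if p.shape[0] != y.shape[0] or p.shape[2:] != y.shape[1:]:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {y.shape}")
    if not np.issubdtype(y.dtype, np.integer):
        raise ValueError("labels must be integral")
    if y.min() < 0 or y.max() >= M:
        raise ValueError(f"label values must lie in [0, {M}); "
                         f"found range [{y.min()}, {y.max()}]")
    return p, y


def _one_hot(y: np.ndarray, M: int) -> np.ndarray:
    return np.moveaxis(np.eye(M, dtype=np.float64)[y], -1, 1)


# -- reference (NumPy) losses --------------------------------------------

def cross_entropy_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean over pixels of -log p at the true class.

    ``p``: (B, M, ...) softmax probabilities; ``y``: (B, ...) integer labels.
    """
    p, y = _check_prob_label(p, y)
    true_p = np.take_along_axis(p, y[:, None], axis=1)[:, 0]
    return float(-np.log(np.clip(true_p, 1e-12, None)).mean())


def dice_loss(p: np.ndarray, y: np.ndarray, *, include_background: bool = True,
              eps: float = DICE_EPS) -> float:
    """Soft Dice loss averaged over classes, in [0, 1]."""
    p, y = _check_prob_label(p, y)
    M = p.shape[1]
    oh = _one_hot(y, M)
    axes = (0,) + tuple(range(2, p.ndim))
    inter = (p * oh).sum(axis=axes)
    denom = p.sum(axis=axes) + oh.sum(axis=axes)
    dice = (2.0 * inter + eps) / (denom + eps)
    if not include_background:
        dice = dice[1:]
    return float(1.0 - dice.mean())


def total_loss(p: np.ndarray, y: np.ndarray, **kwargs) -> float:
    """(L_CE + L_Dice) / 2."""
    return 0.5 * (cross_entropy_loss(p, y) + dice_loss(p, y, **kwargs))


# -- differentiable (Tensor) losses for training --------------------------

def softmax_cross_entropy_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Pixel-mean cross entropy straight from logits (log-softmax form)."""
    B, M = logits.shape[:2]
    oh = _one_hot(np.asarray(y), M).astype(np.float32)
    ls = logits.log_softmax(axis=1)
    return -(ls * Tensor(oh)).sum() * (1.0 / (np.asarray(y).size))


def soft_dice_loss_logits(logits: Tensor, y: np.ndarray, *,
                          include_background: bool = True,
                          eps: float = DICE_EPS) -> Tensor:
    """Soft Dice loss from logits via softmax probabilities."""
    B, M = logits.shape[:2]
    oh = Tensor(_one_hot(np.asarray(y), M).astype(np.float32))
    p = logits.softmax(axis=1)
    axes = (0,) + tuple(range(2, logits.ndim))
    inter = (p * oh).sum(axis=axes)
    denom = p.sum(axis=axes) + oh.sum(axis=axes)
    dice = (inter * 2.0 + eps) / (denom + eps)
    if not include_background:
        dice = dice[1:]
    return 1.0 - dice.mean()


def total_loss_logits(logits: Tensor, y: np.ndarray, **kwargs) -> Tensor:
    """Differentiable (L_CE + L_Dice) / 2 used by the trainer."""
    return (softmax_cross_entropy_logits(logits, y)
            + soft_dice_loss_logits(logits, y, **kwargs)) * 0.5


# -- evaluation metrics ---------------------------------------------------

class UndefinedDistanceError(ValueError):
    """Raised when a Hausdorff distance is requested for an empty point set."""


def dsc_metric(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|) of two binary masks.

    Convention: both masks empty -> 1.0 (perfect agreement); exactly one
    empty -> 0.0.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (sa + sb)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two (N, d) point sets.

    max over both directions of the max-min Euclidean distance; 0 iff the
    sets are equal.  Raises :class:`UndefinedDistanceError` on empty input.
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise UndefinedDistanceError("Hausdorff distance of an empty point set "
                                     "is undefined")
    d_ab = cKDTree(b).query(a, k=1)[0].max()
    d_ba = cKDTree(a).query(b, k=1)[0].max()
    return float(max(d_ab, d_ba))


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """(N, 2) coordinates of the 8-connectivity boundary pixels of a mask.

    A pixel is boundary if it is foreground and not in the erosion by the
    3x3 structuring element; for finite masks the Hausdorff distance over
    boundaries equals the one over full foreground sets, since interior
    points never attain the max-min.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool),
                                    border_value=0)
    return np.argwhere(mask & ~eroded)


@dataclass
class MetricReport:
    """Per-class segmentation scores for one case.

    ``class_hd`` is NaN where undefined (empty prediction or reference);
    the foreground means skip NaN entries and ``n_undefined_hd`` counts
    them.
    """
    class_dsc: np.ndarray           # (M,)
    class_hd: np.ndarray            # (M,), NaN = undefined
    hd_defined: np.ndarray          # (M,) bool
    mean_dsc: float                 # over foreground classes
    mean_hd: float                  # over foreground classes with defined HD
    n_undefined_hd: int

    def to_dict(self) -> dict:
        return {
            "class_dsc": [float(v) for v in self.class_dsc],
            "class_hd": [None if not d else float(v)
                         for v, d in zip(self.class_hd, self.hd_defined)],
            "mean_dsc": float(self.mean_dsc),
            "mean_hd": None if np.isnan(self.mean_hd) else float(self.mean_hd),
            "n_undefined_hd": int(self.n_undefined_hd),
        }

    def rows(self, case_id: str) -> list[dict]:
        """One CSV row per class: case_id, class, dsc, hd, hd_defined."""
        return [{"case_id": case_id, "class": c,
                 "dsc": float(self.class_dsc[c]),
                 "hd": "" if not self.hd_defined[c] else float(self.class_hd[c]),
                 "hd_defined": bool(self.hd_defined[c])}
                for c in range(len(self.class_dsc))]


def evaluate_case(pred: np.ndarray, ref: np.ndarray, n_classes: int) -> MetricReport:
    """Score one predicted label map against its reference.

    Per class: Dice on the binary masks and Hausdorff distance between
    boundary point sets.  Foreground means run over classes 1..M-1.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs ref {ref.shape}")
    class_dsc = np.zeros(n_classes)
    class_hd = np.full(n_classes, np.nan)
    hd_defined = np.zeros(n_classes, dtype=bool)
    for c in range(n_classes):
        pm, rm = pred == c, ref == c
        class_dsc[c] = dsc_metric(pm, rm)
        try:
            class_hd[c] = hausdorff(mask_boundary(pm), mask_boundary(rm))
            hd_defined[c] = True
        except UndefinedDistanceError:
            pass
    fg_dsc = class_dsc[1:]
    fg_hd = class_hd[1:][hd_defined[1:]]
    return MetricReport(
        class_dsc=class_dsc, class_hd=class_hd, hd_defined=hd_defined,
        mean_dsc=float(fg_dsc.mean()) if fg_dsc.size else float("nan"),
        mean_hd=float(fg_hd.mean()) if fg_hd.size else float("nan"),
        n_undefined_hd=int((~hd_defined[1:]).sum()),
    )
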