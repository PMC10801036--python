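"""Confidence-filtered pseudo-labels for background pixels under class increments.

In class-incremental segmentation the step-``t`` ground truth only annotates
the current class set ``C^t``; everything else — including regions that belong
to classes learned earlier — is labeled background.  Training naively on such
masks teaches the model that old-class tissue is background ("background
shift").  The remedy implemented here asks the frozen old model to re-label
background pixels, but keeps a pseudo-label only where the old model is
confident: per-pixel predictive entropy must fall below a per-class threshold
``tau_c``, set to the median entropy of the pixels the old model assigns to
class ``c`` over the incoming dataset.

The accepted fraction ``v`` (accepted / candidate background pixels) weights
the pseudo cross-entropy loss, so noisy old models contribute less.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ClassSchedule",
    "ProbabilityMap",
    "GroundTruthMask",
    "ClassThresholds",
    "PseudoTarget",
    "pixel_entropy",
    "compute_class_thresholds",
    "build_pseudo_labels",
    "pseudo_ce_loss",
    "total_loss",
]

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-5
_EPS = 1e-12


@dataclass(frozen=True)
class ClassSchedule:
    """Partition of foreground labels into incremental steps ``C^1 .. C^T``.

    Background is always label 0 and belongs to no step.  ``steps`` are
    pairwise-disjoint ordered sets of integer foreground labels.
    """

    steps: tuple[tuple[int, ...], ...]

    def __init__(self, steps: Sequence[Iterable[int]]):
        norm = tuple(tuple(sorted(int(c) for c in s)) for s in steps)
        seen: set[int] = set()
        for s in norm:
            if not s:
                raise ValueError("each incremental step must introduce >= 1 class")
            for c in s:
                if c == 0:
                    raise ValueError("label 0 is reserved for background")
                if c in seen:
                    raise ValueError(f"class {c} appears in more than one step")
                seen.add(c)
        object.__setattr__(self, "steps", norm)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def classes_through(self, t: int) -> tuple[int, ...]:
        """All foreground labels introduced in steps 1..t, in schedule order."""
        if not 1 <= t <= self.n_steps:
            raise ValueError(f"step {t} outside 1..{self.n_steps}")
        out: list[int] = []
        for s in self.steps[:t]:
            out.extend(s)
        return tuple(out)

    def old_classes(self, t: int) -> tuple[int, ...]:
        """Labels introduced strictly before step t (empty at t=1)."""
        return self.classes_through(t - 1) if t > 1 else ()

    def current_classes(self, t: int) -> tuple[int, ...]:
        return self.steps[t - 1]

    def channel_index(self, t: int) -> dict[int, int]:
        """Label -> channel for a step-t probability map (background = 0)."""
        mapping = {0: 0}
        for i, c in enumerate(self.classes_through(t), start=1):
            mapping[c] = i
        return mapping

    def n_channels(self, t: int) -> int:
        return 1 + len(self.classes_through(t))


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel class distribution, shape ``H x W x K``.

    Channel 0 is background; channels 1.. follow the schedule order of all
    classes seen through ``step``.  Rows must sum to 1 within 1e-5.
    """

    values: np.ndarray
    step: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"probability map must be H x W x K, got {arr.shape}")
        if np.any(arr < -_PROB_TOL):
            raise ValueError("probabilities must be nonnegative")
        sums = arr.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > _PROB_TOL):
            raise ValueError("per-pixel probabilities must sum to 1 (tol 1e-5)")
        object.__setattr__(self, "values", arr)

    @property
    def n_classes(self) -> int:
        return self.values.shape[-1]


@dataclass(frozen=True)
class GroundTruthMask:
    """Integer label mask whose nonzero labels all belong to ``C^t``."""

    labels: np.ndarray
    step: int = 1
    allowed: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("mask labels must be integers")
        if self.allowed is not None:
            bad = set(np.unique(arr)) - {0} - set(self.allowed)
            if bad:
                raise ValueError(
                    f"mask contains labels {sorted(bad)} outside current step set"
                )
        object.__setattr__(self, "labels", arr)


@dataclass(frozen=True)
class ClassThresholds:
    """Per-class entropy thresholds ``tau_c`` in nats."""

    tau: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, t in self.tau.items():
            if not np.isfinite(t) or t < 0:
                raise ValueError(f"threshold for class {c} must be finite and >= 0")

    def to_json(self) -> str:
        return json.dumps({str(k): v for k, v in sorted(self.tau.items())})

    @classmethod
    def from_json(cls, text: str) -> "ClassThresholds":
        return cls(tau={int(k): float(v) for k, v in json.loads(text).items()})


@dataclass(frozen=True)
class PseudoTarget:
    """One-hot-or-ignored training target plus the acceptance ratio ``v``."""

    onehot: np.ndarray  # H x W x K in {0,1}
    ignore: np.ndarray  # H x W bool
    v: float
    accepted_count: int
    candidate_count: int = 0

    @property
    def label_map(self) -> np.ndarray:
        """Argmax labels as channel indices; ignored pixels get -1."""
        lab = self.onehot.argmax(axis=-1)
        lab[self.ignore] = -1
        return lab


def pixel_entropy(
    probs: ProbabilityMap | np.ndarray,
    channel_subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-pixel Shannon entropy ``-sum_k p_k ln p_k`` in nats (0*ln0 = 0).

    With ``channel_subset`` the distribution is restricted to those channels
    and renormalized before the entropy is taken.
    """
    arr = probs.values if isinstance(probs, ProbabilityMap) else np.asarray(probs, float)
    if channel_subset is not None:
        arr = arr[..., list(channel_subset)]
        norm = arr.sum(axis=-1, keepdims=True)
        arr = arr / np.maximum(norm, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(arr > 0, arr * np.log(arr), 0.0)
    return -term.sum(axis=-1)


def compute_class_thresholds(
    old_probs_over_dataset: Iterable[ProbabilityMap | np.ndarray],
) -> ClassThresholds:
    """Median old-model entropy per predicted class, pooled over a dataset.

    For every foreground class ``c`` that the old model predicts (argmax) at
    least once, ``tau_c`` is the median of the per-pixel entropies of those
    pixels.  Classes never predicted get no entry — no pixel can then require
    them.  Even-sized pools use the midpoint of the two central order
    statistics (numpy's default).
    """
    pooled: dict[int, list[np.ndarray]] = {}
    n_maps = 0
    for probs in old_probs_over_dataset:
        arr = probs.values if isinstance(probs, ProbabilityMap) else np.asarray(probs, float)
        n_maps += 1
        ent = pixel_entropy(arr)
        pred = arr.argmax(axis=-1)
        for c in np.unique(pred):
            if c == 0:
                continue  # background needs no threshold
            pooled.setdefault(int(c), []).append(ent[pred == c])
    if n_maps == 0:
        raise ValueError("need at least one probability map")
    tau = {
        c: float(np.median(np.concatenate(chunks))) for c, chunks in pooled.items()
    }
    return ClassThresholds(tau=tau)


def build_pseudo_labels(
    gt: GroundTruthMask | np.ndarray,
    old_probs: ProbabilityMap | np.ndarray,
    schedule: ClassSchedule,
    tau: ClassThresholds,
    step: int | None = None,
) -> PseudoTarget:
    """Merge step-``t`` ground truth with uncertainty-filtered old-model labels.

    Per pixel:

    * ground-truth label in the current class set -> one-hot at that label;
    * ground-truth background, old-model argmax is an old foreground class
      ``c*`` and entropy ``u < tau_{c*}`` -> one-hot at ``c*``;
    * ground-truth background with ``u >= tau_{c*}`` (or no threshold known
      for ``c*``) -> ignored;
    * ground-truth background with old-model argmax = background -> labeled
      background (the old model is the only authority on non-current content);
      such pixels are not candidates for ``v``.

    ``v = accepted / candidates`` where candidates are background pixels whose
    old-model argmax is an old foreground class; ``v = 0`` with no candidates.
    """
    if step is None:
        step = gt.step if isinstance(gt, GroundTruthMask) else schedule.n_steps
    labels = gt.labels if isinstance(gt, GroundTruthMask) else np.asarray(gt)
    probs = old_probs.values if isinstance(old_probs, ProbabilityMap) else np.asarray(
        old_probs, float
    )
    if labels.shape != probs.shape[:-1]:
        raise ValueError(
            f"mask shape {labels.shape} != probability grid {probs.shape[:-1]}"
        )
    current = set(schedule.current_classes(step))
    old = schedule.old_classes(step)
    chan = schedule.channel_index(step)
    k = schedule.n_channels(step)
    if probs.shape[-1] != 1 + len(old):
        raise ValueError(
            f"old model must cover background + {len(old)} old classes, "
            f"got {probs.shape[-1]} channels"
        )

    bad = set(np.unique(labels)) - {0} - current
    if bad:
        raise ValueError(f"ground truth contains non-current labels {sorted(bad)}")

    onehot = np.zeros(labels.shape + (k,), dtype=np.int8)
    ignore = np.zeros(labels.shape, dtype=bool)

    fg = labels != 0
    for c in current:
        onehot[..., chan[c]][labels == c] = 1

    bg = ~fg
    accepted = 0
    candidates = 0
    if old:
        # old-model channel i (i>=1) is old class old[i-1]
        argmax = probs.argmax(axis=-1)
        ent = pixel_entropy(probs)
        cand_mask = bg & (argmax > 0)
        candidates = int(cand_mask.sum())
        for i, c in enumerate(old, start=1):
            sel = bg & (argmax == i)
            if not sel.any():
                continue
            if c not in tau.tau:
                logger.warning(
                    "no entropy threshold for old class %d; ignoring %d pixels",
                    c,
                    int(sel.sum()),
                )
                ignore[sel] = True
                continue
            confident = sel & (ent < tau.tau[c])
            onehot[..., chan[c]][confident] = 1
            ignore[sel & ~confident] = True
            accepted += int(confident.sum())
        onehot[..., 0][bg & (argmax == 0)] = 1
    else:
        onehot[..., 0][bg] = 1

    v = accepted / candidates if candidates > 0 else 0.0
    return PseudoTarget(
        onehot=onehot,
        ignore=ignore,
        v=float(v),
        accepted_count=accepted,
        candidate_count=candidates,
    )


def pseudo_ce_loss(
    pred: ProbabilityMap | np.ndarray, target: PseudoTarget
) -> float:
    """Pseudo-labelled cross-entropy ``-(v / N_eff) * sum ln p[target]``.

    ``N_eff`` is the number of non-ignored pixels (the WH normalizer is
    decremented once per discarded pixel).  Predicted probabilities of zero at
    a target channel are clamped at 1e-12.  At step 1 (no pseudo-labels)
    callers pass a target with ``v`` forced to 1.
    """
    probs = pred.values if isinstance(pred, ProbabilityMap) else np.asarray(pred, float)
    if probs.shape != target.onehot.shape:
        raise ValueError(
            f"prediction shape {probs.shape} != target shape {target.onehot.shape}"
        )
    keep = ~target.ignore
    n_eff = int(keep.sum())
    if n_eff == 0:
        warnings.warn("all pixels ignored; pseudo CE loss is vacuously 0")
        return 0.0
    p_at_target = (probs * target.onehot).sum(axis=-1)[keep]
    if np.any(p_at_target <= 0):
        logger.warning(
            "clamped %d zero predicted probabilities at target channels",
            int((p_at_target <= 0).sum()),
        )
        p_at_target = np.maximum(p_at_target, _EPS)
    return float(-(target.v / n_eff) * np.log(p_at_target).sum())


def total_loss(l_pseudo: float, l_localpod: float, lam: float = 0.01) -> float:
    """Composite objective ``L = L_pseudo + lambda * L_localPOD``."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    for name, val in (("l_pseudo", l_pseudo), ("l_localpod", l_localpod)):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite")
    return float(l_pseudo + lam * l_localpod)
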