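"""Class-incremental training loop with distillation and pseudo-labels.

Protocol: the foreground classes are partitioned into steps ``C^1 .. C^T``.
At step ``t`` the model sees only images containing a class of ``C^t``, with
all other labels remapped to background.  For ``t >= 2`` the previous model
is frozen; its confident predictions pseudo-label the background pixels
(entropy below the per-class median threshold) and its intermediate features
anchor the new model through the local pooled-output distillation loss.  The
step objective is

    L = L_pseudo + lambda * L_localPOD

optimized with SGD (momentum 0.9) under a poly learning-rate schedule
``lr0 * (1 - iter/total)^power``.  Step 1 degenerates to plain supervised
cross-entropy: there is no old model to distill from or to pseudo-label with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _autograd as ag
from .pseudo_label import (
    ClassSchedule,
    ClassThresholds,
    PseudoTarget,
    build_pseudo_labels,
    compute_class_thresholds,
)
from .seg_metrics import aggregate_reports, evaluate_case
from .seg_model import ModelConfig, SegModel, build_model, extend_head

__all__ = [
    "TrainConfig",
    "StepReport",
    "ClassSchedule",
    "partition_dataset",
    "poly_lr",
    "run_step",
    "predict_labels",
    "per_class_dice",
    "ablation_run",
    "ARM_SETTINGS",
]

logger = logging.getLogger(__name__)

Case = tuple[np.ndarray, np.ndarray]  # (M x H x W image, H x W labels)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one incremental step.

    Defaults follow the reference training recipe: initial learning rate
    0.0325 under a poly schedule with power 0.9, SGD momentum 0.9, roughly 30
    epochs per step, distillation weight ``lam`` 0.01 and local POD scales
    (1, 2, 4).  ``epochs_per_step`` is scaled down for desk-scale runs.
    """

    lr0: float = 0.0325
    momentum: float = 0.9
    epochs_per_step: int = 30
    poly_power: float = 0.9
    lam: float = 0.01
    scales: tuple[int, ...] = (1, 2, 4)
    batch_size: int = 4
    seed: int = 0
    use_pseudo_labels: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)
    tap_names: tuple[str, ...] | None = None  # None = all configured taps

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs_per_step < 1:
            raise ValueError("epochs_per_step must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class StepReport:
    """Loss trajectory and diagnostics of one incremental step."""

    step: int
    epoch_losses: list[dict[str, float]] = field(default_factory=list)
    thresholds: ClassThresholds | None = None
    v_mean: float = 1.0
    val_dice_per_class: dict[int, float] = field(default_factory=dict)
    forgetting_delta: dict[int, float] | None = None

    def check_decomposition(self, lam: float, tol: float = 1e-6) -> bool:
        """total = pseudo + lam * distill at every logged epoch."""
        return all(
            abs(e["total"] - (e["pseudo"] + lam * e["distill"])) <= tol
            for e in self.epoch_losses
        )


def partition_dataset(
    cases: Sequence[Case], schedule: ClassSchedule
) -> list[list[Case]]:
    """Split cases into per-step datasets ``D_t`` and remap their masks.

    A case enters ``D_t`` iff its mask contains at least one pixel of a class
    in ``C^t`` (so mixed cases appear in several steps); within ``D_t`` every
    label outside ``C^t`` becomes background.
    """
    out: list[list[Case]] = []
    for t in range(1, schedule.n_steps + 1):
        current = schedule.current_classes(t)
        d_t: list[Case] = []
        for img, mask in cases:
            if not np.isin(mask, current).any():
                continue
            remapped = np.where(np.isin(mask, current), mask, 0).astype(mask.dtype)
            d_t.append((img, remapped))
        if not d_t:
            raise ValueError(f"step {t}: no case contains a class of {current}")
        out.append(d_t)
    return out


def poly_lr(iteration: int, total_iterations: int, lr0: float, power: float = 0.9) -> float:
    """Poly decay ``lr0 * (1 - iteration/total_iterations)^power``."""
    frac = 1.0 - iteration / total_iterations
    return lr0 * max(frac, 0.0) ** power


def _old_probs(old_model: SegModel, images: np.ndarray) -> np.ndarray:
    logits, _, _ = old_model.forward(images, train=False)
    return ag.softmax(logits.data, axis=1)  # N x K_old x H x W


def _gt_target(mask: np.ndarray, schedule: ClassSchedule, t: int) -> PseudoTarget:
    """Plain ground-truth target (step 1 / pseudo-labels disabled)."""
    chan = schedule.channel_index(t)
    k = schedule.n_channels(t)
    onehot = np.zeros(mask.shape + (k,), dtype=np.int8)
    onehot[..., 0][mask == 0] = 1
    for lab, ch in chan.items():
        if lab != 0:
            onehot[..., ch][mask == lab] = 1
    return PseudoTarget(
        onehot=onehot, ignore=np.zeros(mask.shape, bool), v=1.0,
        accepted_count=0, candidate_count=0,
    )


def _prepare_targets(
    d_t: Sequence[Case],
    schedule: ClassSchedule,
    t: int,
    old_model: SegModel | None,
    use_pseudo_labels: bool,
) -> tuple[list[PseudoTarget], ClassThresholds | None]:
    if old_model is None or not use_pseudo_labels:
        return [_gt_target(mask, schedule, t) for _, mask in d_t], None
    probs = [_old_probs(old_model, img[None])[0] for img, _ in d_t]
    prob_maps = [np.moveaxis(p, 0, -1) for p in probs]
    tau = compute_class_thresholds(prob_maps)
    targets = [
        build_pseudo_labels(mask, pm, schedule, tau, step=t)
        for (_, mask), pm in zip(d_t, prob_maps)
    ]
    return targets, tau


def run_step(
    t: int,
    d_t: Sequence[Case],
    old_model: SegModel | None,
    cfg: TrainConfig,
    schedule: ClassSchedule,
    val_cases: Sequence[Case] | None = None,
) -> tuple[SegModel, StepReport]:
    """Train the step-``t`` model and return it with its report.

    For ``t >= 2`` ``old_model`` is the frozen step ``t-1`` model; its
    parameters are never touched (hash-checked in tests).  Per-class entropy
    thresholds are computed once, before training, from the old model's
    predictions over ``D_t``.
    """
    if (t == 1) != (old_model is None):
        raise ValueError("old_model must be given exactly when t >= 2")
    k = schedule.n_channels(t)
    seed = cfg.seed + 1000 * t
    if old_model is None:
        model = build_model(replace(cfg.model, head_classes=k), seed)
    else:
        k_old = schedule.n_channels(t - 1)
        if old_model.cfg.head_classes != k_old:
            raise ValueError(
                f"old model head has {old_model.cfg.head_classes} channels, "
                f"schedule expects {k_old} through step {t - 1}"
            )
        model = extend_head(old_model, list(schedule.current_classes(t)), seed)

    targets, tau = _prepare_targets(
        d_t, schedule, t, old_model, cfg.use_pseudo_labels
    )
    # an image with no pseudo-label candidates degenerates to plain
    # supervision: its loss keeps weight 1 rather than v = 0
    v_eff = np.array(
        [tg.v if tg.candidate_count > 0 else 1.0 for tg in targets], dtype=np.float64
    )
    report = StepReport(step=t, thresholds=tau, v_mean=float(v_eff.mean()))

    baseline_dice: dict[int, float] = {}
    old_classes = schedule.old_classes(t)
    if val_cases and old_model is not None:
        baseline_dice = per_class_dice(old_model, val_cases, old_classes,
                                       schedule, t - 1)

    onehots = [tg.onehot for tg in targets]
    n_cases = len(d_t)
    images = np.stack([img for img, _ in d_t]).astype(np.float32)
    rng = np.random.default_rng(seed + 17)
    n_batches = int(np.ceil(n_cases / cfg.batch_size))
    total_iters = cfg.epochs_per_step * n_batches
    velocity: dict[str, np.ndarray] = {}
    tap_names = cfg.tap_names or model.cfg.tap_names
    iteration = 0

    for epoch in range(cfg.epochs_per_step):
        order = rng.permutation(n_cases)
        ep_pseudo, ep_distill = [], []
        for b in range(n_batches):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            batch = images[idx]
            nb = len(idx)
            k_hw = targets[0].onehot.shape
            onehot = np.zeros((nb, k) + k_hw[:2], dtype=np.float32)
            weight = np.zeros((nb,) + k_hw[:2], dtype=np.float32)
            for j, ci in enumerate(idx):
                tg = targets[ci]
                onehot[j] = np.moveaxis(tg.onehot, -1, 0)
                keep = ~tg.ignore
                n_eff = max(int(keep.sum()), 1)
                weight[j][keep] = v_eff[ci] / n_eff / nb

            logits, taps, store = model.forward(batch, train=True)
            ce = ag.weighted_ce_loss(logits, onehot, weight)
            terms: list[tuple[ag.Tensor, float]] = [(ce, 1.0)]
            distill_val = 0.0
            if old_model is not None and cfg.lam > 0:
                _, old_taps, _ = old_model.forward(batch, train=False)
                layer_terms = [
                    (
                        ag.local_pod_pair_loss(
                            taps[name], old_taps[name].data, cfg.scales
                        ),
                        1.0 / len(tap_names),
                    )
                    for name in tap_names
                ]
                pod = ag.add_losses(layer_terms)
                distill_val = float(pod.data)
                terms.append((pod, cfg.lam))
            loss = ag.add_losses(terms)
            loss.backward()

            lr = poly_lr(iteration, total_iters, cfg.lr0, cfg.poly_power)
            for name, tensor in store.items():
                if tensor.grad is None:
                    continue
                vel = velocity.setdefault(name, np.zeros_like(tensor.data))
                vel *= cfg.momentum
                vel -= lr * tensor.grad
                model.params[name] = model.params[name] + vel
            iteration += 1
            ep_pseudo.append(float(ce.data))
            ep_distill.append(distill_val)
        entry = {
            "pseudo": float(np.mean(ep_pseudo)),
            "distill": float(np.mean(ep_distill)),
        }
        entry["total"] = entry["pseudo"] + cfg.lam * entry["distill"]
        report.epoch_losses.append(entry)
        logger.info(
            "step %d epoch %d: pseudo=%.4f distill=%.4f total=%.4f",
            t, epoch, entry["pseudo"], entry["distill"], entry["total"],
        )

    if val_cases:
        all_classes = schedule.classes_through(t)
        report.val_dice_per_class = per_class_dice(
            model, val_cases, all_classes, schedule, t
        )
        if baseline_dice:
            report.forgetting_delta = {
                c: report.val_dice_per_class[c] - baseline_dice[c]
                for c in old_classes
            }
    return model, report


def predict_labels(
    model: SegModel, image: np.ndarray, schedule: ClassSchedule, t: int
) -> np.ndarray:
    """Argmax prediction mapped back to the original integer labels."""
    logits, _, _ = model.forward(np.asarray(image, np.float32)[None], train=False)
    pred_ch = logits.data[0].argmax(axis=0)
    chan = schedule.channel_index(t)
    inv = np.zeros(max(chan.values()) + 1, dtype=np.int16)
    for lab, ch in chan.items():
        inv[ch] = lab
    return inv[pred_ch]


def per_class_dice(
    model: SegModel,
    cases: Sequence[Case],
    classes: Sequence[int],
    schedule: ClassSchedule,
    t: int,
) -> dict[int, float]:
    """Mean binary Dice per foreground class over a case list.

    Cases where both prediction and reference are empty for a class are
    skipped (Dice undefined-by-convention there would dilute the mean).
    """
    sums: dict[int, list[float]] = {c: [] for c in classes}
    for img, mask in cases:
        pred = predict_labels(model, img, schedule, t)
        for c in classes:
            p, g = pred == c, mask == c
            denom = p.sum() + g.sum()
            if denom == 0:
                continue
            sums[c].append(2.0 * np.sum(p & g) / denom)
    return {c: float(np.mean(v)) if v else float("nan") for c, v in sums.items()}


#: Ablation arm settings: (use distillation, use pseudo-labels).
ARM_SETTINGS: dict[str, tuple[bool, bool]] = {
    "baseline": (False, False),
    "+SD": (True, False),
    "+PL": (False, True),
    "+SD+PL": (True, True),
}


def ablation_run(
    benchmark,
    arms: Sequence[str] = ("baseline", "+SD", "+PL", "+SD+PL"),
    seeds: Sequence[int] = (0, 1, 2),
    cfg: TrainConfig | None = None,
) -> dict:
    """Train every arm on the two-step benchmark with paired seeds.

    Step 1 is identical across arms and trained once per seed; arms differ
    only in the step-2 objective.  Returns per-arm per-seed Dice on the
    step-1 (old) and step-2 (new) classes plus aggregated region metrics.
    """
    cfg = cfg or TrainConfig()
    schedule = benchmark.schedule
    parts = partition_dataset(benchmark.train, schedule)
    results: dict[str, dict] = {arm: {"old_dice": [], "new_dice": [],
                                      "regions": []} for arm in arms}
    for seed in seeds:
        base_cfg = replace(cfg, seed=seed)
        model1, _ = run_step(1, parts[0], None, base_cfg, schedule)
        frozen = model1.clone()
        for arm in arms:
            use_sd, use_pl = ARM_SETTINGS[arm]
            arm_cfg = replace(
                base_cfg,
                lam=cfg.lam if use_sd else 0.0,
                use_pseudo_labels=use_pl,
            )
            model2, rep = run_step(2, parts[1], frozen, arm_cfg, schedule,
                                   val_cases=benchmark.val)
            old = schedule.old_classes(2)
            new = schedule.current_classes(2)
            results[arm]["old_dice"].append(
                float(np.nanmean([rep.val_dice_per_class[c] for c in old]))
            )
            results[arm]["new_dice"].append(
                float(np.nanmean([rep.val_dice_per_class[c] for c in new]))
            )
            case_reports = [
                evaluate_case(predict_labels(model2, img, schedule, 2), mask)
                for img, mask in benchmark.val
            ]
            results[arm]["regions"].append(aggregate_reports(case_reports))
    for arm in arms:
        od, nd = results[arm]["old_dice"], results[arm]["new_dice"]
        results[arm]["old_dice_mean"] = float(np.mean(od))
        results[arm]["old_dice_sd"] = float(np.std(od))
        results[arm]["new_dice_mean"] = float(np.mean(nd))
        results[arm]["new_dice_sd"] = float(np.std(nd))
    results["seeds"] = list(seeds)
    return results
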