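"""Overlap and surface-distance metrics for BraTS-style tumor regions.

Evaluation follows the BraTS convention of three nested regions composed from
the integer label map: enhancing tumor (ET = {4}), tumor core (TC = {1, 4})
and whole tumor (WT = {1, 2, 4}).  For each region we report

* Dice = 2 TP / (FN + FP + 2 TP)
* Sensitivity = TP / (TP + FN)
* Specificity = TN / (TN + FP)
* Hausdorff95: the 95th percentile of the pooled directed nearest-neighbor
  surface distances; at percentile 100 this is the classical Hausdorff
  distance max{sup_t inf_p d(t,p), sup_p inf_t d(p,t)}.

Undefined values (empty masks, zero denominators) are returned as NaN and
flagged, never silently substituted, so aggregation can skip them; the one
conventional exception is Dice = 1.0 for two empty masks, which is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "BinaryMask",
    "ConfusionCounts",
    "MetricReport",
    "DEFAULT_REGION_LABELS",
    "compose_region",
    "confusion",
    "dice",
    "sensitivity",
    "specificity",
    "surface_points",
    "hausdorff95",
    "evaluate_case",
    "aggregate_reports",
    "compare_arms",
]

#: Default BraTS label convention: 1 necrotic core, 2 edema, 4 enhancing.
DEFAULT_REGION_LABELS: dict[str, frozenset[int]] = {
    "ET": frozenset({4}),
    "TC": frozenset({1, 4}),
    "WT": frozenset({1, 2, 4}),
}

REGIONS = ("ET", "WT", "TC")
METRICS = ("dice", "sensitivity", "specificity", "haus95")


@dataclass(frozen=True)
class BinaryMask:
    """Boolean mask over a 2-D or 3-D grid with optional physical spacing."""

    values: np.ndarray
    spacing: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=bool)
        sp = self.spacing
        if sp is None:
            sp = (1.0,) * arr.ndim
        sp = tuple(float(s) for s in sp)
        if len(sp) != arr.ndim:
            raise ValueError("spacing must have one entry per axis")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", sp)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    """Per-region metric table; ``flags`` records undefined entries."""

    per_region: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict[str, float]:
        """Flatten to Table-style columns: metric_region, e.g. ``dice_ET``."""
        return {
            f"{m}_{r}": self.per_region[r][m]
            for m in METRICS
            for r in REGIONS
            if r in self.per_region
        }


def _as_bool(mask: BinaryMask | np.ndarray) -> np.ndarray:
    return mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)


def compose_region(
    labels: np.ndarray,
    region: str,
    label_map: Mapping[str, frozenset[int] | set[int]] | None = None,
) -> BinaryMask:
    """Binary mask of one evaluation region (ET / WT / TC) from a label map."""
    table = DEFAULT_REGION_LABELS if label_map is None else label_map
    if region not in table:
        raise ValueError(f"unknown region {region!r}; expected one of {sorted(table)}")
    labels = np.asarray(labels)
    return BinaryMask(values=np.isin(labels, sorted(table[region])))


def confusion(pred: BinaryMask | np.ndarray, gt: BinaryMask | np.ndarray) -> ConfusionCounts:
    """Voxelwise confusion counts between same-shape binary masks."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    return ConfusionCounts(
        TP=int(np.sum(p & g)),
        TN=int(np.sum(~p & ~g)),
        FP=int(np.sum(p & ~g)),
        FN=int(np.sum(~p & g)),
    )


def dice(c: ConfusionCounts, flags: list[str] | None = None) -> float:
    """Dice overlap ``2 TP / (FN + FP + 2 TP)``; 1.0 (flagged) for two empty masks."""
    denom = c.FN + c.FP + 2 * c.TP
    if denom == 0:
        if flags is not None:
            flags.append("dice: both masks empty, returning 1.0 by convention")
        return 1.0
    return 2.0 * c.TP / denom


def sensitivity(c: ConfusionCounts, flags: list[str] | None = None) -> float:
    """True-positive rate ``TP / (TP + FN)``; NaN when the ground truth is empty."""
    if c.TP + c.FN == 0:
        if flags is not None:
            flags.append("sensitivity: no positive ground truth, undefined")
        return float("nan")
    return c.TP / (c.TP + c.FN)


def specificity(c: ConfusionCounts, flags: list[str] | None = None) -> float:
    """True-negative rate ``TN / (TN + FP)``; NaN when there are no negatives."""
    if c.TN + c.FP == 0:
        if flags is not None:
            flags.append("specificity: no negative ground truth, undefined")
        return float("nan")
    return c.TN / (c.TN + c.FP)


def surface_points(mask: BinaryMask | np.ndarray) -> np.ndarray:
    """Coordinates (scaled by spacing) of border voxels of the foreground.

    A border voxel is foreground with at least one background face-neighbor
    (or on the grid edge).
    """
    arr = _as_bool(mask)
    spacing = mask.spacing if isinstance(mask, BinaryMask) else (1.0,) * arr.ndim
    if not arr.any():
        return np.empty((0, arr.ndim))
    structure = ndimage.generate_binary_structure(arr.ndim, 1)  # face connectivity
    interior = ndimage.binary_erosion(arr, structure=structure, border_value=0)
    border = arr & ~interior
    coords = np.argwhere(border).astype(float)
    return coords * np.asarray(spacing)


def hausdorff95(
    t_surface: np.ndarray,
    p_surface: np.ndarray,
    percentile: float = 95.0,
    pool_directions: bool = True,
    flags: list[str] | None = None,
) -> float:
    """Percentile Hausdorff distance between two surface point sets.

    Directed nearest-neighbor distances are computed both ways; by default the
    two directions are pooled and the percentile taken over the pooled sample
    (the common toolkit behavior).  With ``pool_directions=False`` the result
    is the max of the per-direction percentiles.  ``percentile=100`` recovers
    the classical sup-inf Hausdorff distance exactly.
    """
    t = np.atleast_2d(np.asarray(t_surface, dtype=float))
    p = np.atleast_2d(np.asarray(p_surface, dtype=float))
    if t.size == 0 or p.size == 0:
        if flags is not None:
            flags.append("haus95: empty surface, undefined")
        return float("nan")
    d_t_to_p = cKDTree(p).query(t, k=1)[0]
    d_p_to_t = cKDTree(t).query(p, k=1)[0]
    if pool_directions:
        return float(np.percentile(np.concatenate([d_t_to_p, d_p_to_t]), percentile))
    return float(
        max(np.percentile(d_t_to_p, percentile), np.percentile(d_p_to_t, percentile))
    )


def evaluate_case(
    pred_labels: np.ndarray,
    gt_labels: np.ndarray,
    label_map: Mapping[str, frozenset[int] | set[int]] | None = None,
    spacing: tuple[float, ...] | None = None,
    percentile: float = 95.0,
) -> MetricReport:
    """All four metrics for every region of one predicted / reference pair."""
    pred_labels = np.asarray(pred_labels)
    gt_labels = np.asarray(gt_labels)
    if pred_labels.shape != gt_labels.shape:
        raise ValueError("prediction and ground truth shapes differ")
    table = DEFAULT_REGION_LABELS if label_map is None else label_map
    report = MetricReport()
    for region in table:
        pm = compose_region(pred_labels, region, table)
        gm = compose_region(gt_labels, region, table)
        if spacing is not None:
            pm = BinaryMask(pm.values, spacing)
            gm = BinaryMask(gm.values, spacing)
        c = confusion(pm, gm)
        prefix = f"{region}/"
        local_flags: list[str] = []
        entry = {
            "dice": dice(c, local_flags),
            "sensitivity": sensitivity(c, local_flags),
            "specificity": specificity(c, local_flags),
            "haus95": hausdorff95(
                surface_points(gm), surface_points(pm), percentile, flags=local_flags
            ),
        }
        report.per_region[region] = entry
        report.flags.extend(prefix + f for f in local_flags)
    return report


def aggregate_reports(reports: Sequence[MetricReport]) -> MetricReport:
    """Mean over cases per region/metric, skipping undefined (NaN) entries."""
    if not reports:
        raise ValueError("no reports to aggregate")
    out = MetricReport()
    regions = reports[0].per_region.keys()
    for region in regions:
        out.per_region[region] = {}
        for metric in METRICS:
            vals = np.array([r.per_region[region][metric] for r in reports])
            defined = vals[~np.isnan(vals)]
            if defined.size == 0:
                out.per_region[region][metric] = float("nan")
                out.flags.append(f"{region}/{metric}: undefined in every case")
            else:
                out.per_region[region][metric] = float(defined.mean())
                if defined.size < vals.size:
                    out.flags.append(
                        f"{region}/{metric}: {vals.size - defined.size} undefined "
                        "case(s) skipped"
                    )
    return out


def compare_arms(
    arm_a: Mapping[str, Mapping[str, float]],
    arm_b: Mapping[str, Mapping[str, float]],
) -> dict[str, dict[str, float]]:
    """Derived comparison numbers between two ablation arms (b relative to a).

    For the overlap metrics (Dice, sensitivity, specificity) the improvement is
    the relative gain in percent, ``100 * (b - a) / a``; for Hausdorff95 the
    reduction is absolute, ``a - b`` (a positive number means arm b has the
    smaller boundary error).  Input mappings are region -> metric -> value, as
    produced by :class:`MetricReport` or entered from a published table.
    """
    out: dict[str, dict[str, float]] = {}
    for region in arm_a:
        entry: dict[str, float] = {}
        for metric, a_val in arm_a[region].items():
            b_val = arm_b[region][metric]
            if metric == "haus95":
                entry["haus95_reduction"] = float(a_val - b_val)
            else:
                entry[f"{metric}_rel_improvement_pct"] = float(
                    100.0 * (b_val - a_val) / a_val
                )
        out[region] = entry
    return out
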