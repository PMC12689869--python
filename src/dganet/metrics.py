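"""Segmentation evaluation metrics: overlap, volume and surface distances.

All surface metrics are spacing-aware.  Boundaries are foreground pixels with
at least one background face-neighbor (4-connectivity in 2-D, 6-connectivity
in 3-D; outside the array counts as background).  HD95 is the 95th
percentile, with linear interpolation, of the merged set of both directed
nearest-boundary distance lists.

Metrics that are undefined on empty masks are returned as NaN and excluded
from aggregation with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "BinaryMask",
    "MetricReport",
    "dice",
    "dpc",
    "dg",
    "voe",
    "ravd",
    "assd",
    "hd95",
    "surface_distances",
    "extract_class_masks",
    "evaluate_cases",
    "CLASS_NAMES",
]

CLASS_NAMES = ("liver", "tumor")


@dataclass
class BinaryMask:
    """Boolean mask plus physical spacing (mm per pixel along each axis)."""

    data: np.ndarray
    spacing: tuple[float, ...] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim not in (2, 3):
            raise ValueError("BinaryMask must be 2-D or 3-D")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing must have one entry per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


def _pair(a, b) -> tuple[BinaryMask, BinaryMask]:
    a = a if isinstance(a, BinaryMask) else BinaryMask(a)
    b = b if isinstance(b, BinaryMask) else BinaryMask(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"mask shape mismatch: {a.data.shape} vs {b.data.shape}")
    return a, b


# ---------------------------------------------------------------------------
# Overlap and volume metrics
# ---------------------------------------------------------------------------


def dice(a, b) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a, b = _pair(a, b)
    na, nb = int(a.data.sum()), int(b.data.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a.data & b.data).sum()) / (na + nb)


def dpc(cases) -> float:
    """Mean of per-case Dice values."""
    cases = list(cases)
    if not cases:
        raise ValueError("need at least one case")
    return float(np.mean([dice(a, b) for a, b in cases]))


def dg(cases) -> float:
    """Pooled (global) Dice over all cases."""
    cases = list(cases)
    if not cases:
        raise ValueError("need at least one case")
    inter = tot = 0
    for a, b in cases:
        a, b = _pair(a, b)
        inter += int((a.data & b.data).sum())
        tot += int(a.data.sum()) + int(b.data.sum())
    if tot == 0:
        return 1.0
    return 2.0 * inter / tot


def voe(a, b) -> float:
    """Volumetric overlap error 1 - |A∩B|/|A∪B|; 0.0 when both empty."""
    a, b = _pair(a, b)
    union = int((a.data | b.data).sum())
    if union == 0:
        return 0.0
    return 1.0 - int((a.data & b.data).sum()) / union


def ravd(a, b) -> float:
    """Relative absolute volume difference ||A|-|B|| / |A| (unsigned)."""
    a, b = _pair(a, b)
    na = int(a.data.sum())
    if na == 0:
        warnings.warn("RAVD undefined for empty ground truth; returning NaN")
        return float("nan")
    return abs(na - int(b.data.sum())) / na


# ---------------------------------------------------------------------------
# Surface metrics
# ---------------------------------------------------------------------------


def _boundary_points(mask: BinaryMask) -> np.ndarray:
    """Physical coordinates (mm) of boundary pixels (face-connectivity)."""
    structure = ndimage.generate_binary_structure(mask.data.ndim, 1)
    interior = ndimage.binary_erosion(mask.data, structure=structure, border_value=0)
    boundary = mask.data & ~interior
    coords = np.argwhere(boundary).astype(np.float64)
    return coords * np.asarray(mask.spacing)


def surface_distances(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Directed nearest-boundary distance lists (A→B, B→A) in mm."""
    a, b = _pair(a, b)
    pa, pb = _boundary_points(a), _boundary_points(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("surface distances undefined for an empty mask")
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return d_ab, d_ba


def assd(a, b) -> float:
    """Average symmetric surface distance; NaN (with warning) on empty masks."""
    try:
        d_ab, d_ba = surface_distances(a, b)
    except ValueError:
        warnings.warn("ASSD undefined for empty mask; returning NaN")
        return float("nan")
    return 0.5 * (d_ab.mean() + d_ba.mean())


def hd95(a, b) -> float:
    """95th percentile (linear interpolation) of merged directed distances."""
    try:
        d_ab, d_ba = surface_distances(a, b)
    except ValueError:
        warnings.warn("HD95 undefined for empty mask; returning NaN")
        return float("nan")
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


# ---------------------------------------------------------------------------
# Label handling and report assembly
# ---------------------------------------------------------------------------


def extract_class_masks(labels: np.ndarray, class_spec: str,
                        spacing=None) -> BinaryMask:
    """Binary mask for a target class from an integer {0,1,2} label volume.

    The liver mask includes tumor pixels (label in {1, 2}); the tumor mask is
    label == 2.
    """
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {0, 1, 2}
    if bad:
        raise ValueError(f"unexpected label values: {sorted(bad)}")
    if class_spec == "liver":
        return BinaryMask(labels >= 1, spacing)
    if class_spec == "tumor":
        return BinaryMask(labels == 2, spacing)
    raise ValueError(f"unknown class {class_spec!r}; expected 'liver' or 'tumor'")


@dataclass
class MetricReport:
    """Per-case metric table plus per-class aggregates."""

    per_case: pd.DataFrame
    aggregate: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.aggregate is None:
            rows = []
            for cls, grp in self.per_case.groupby("class", sort=False):
                row = {"class": cls,
                       "dpc": grp["dice"].mean(),
                       "dg": 2.0 * grp["intersection"].sum()
                             / max(grp["size_a"].sum() + grp["size_b"].sum(), 1)}
                for m in ("voe", "ravd", "assd", "hd95"):
                    vals = grp[m].dropna()
                    if len(vals) < len(grp):
                        warnings.warn(
                            f"{m}: {len(grp) - len(vals)} case(s) undefined and excluded")
                    row[m] = vals.mean() if len(vals) else float("nan")
                rows.append(row)
            self.aggregate = pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            self.per_case.to_csv(fh, index=False)
            fh.write("\n# aggregate\n")
            self.aggregate.to_csv(fh, index=False)

    def to_json(self, path=None):
        payload = {
            "per_case": self.per_case.to_dict(orient="records"),
            "aggregate": self.aggregate.to_dict(orient="records"),
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
        return payload

    def aggregate_value(self, cls: str, metric: str) -> float:
        row = self.aggregate[self.aggregate["class"] == cls]
        if row.empty:
            raise KeyError(f"no aggregate row for class {cls!r}")
        return float(row.iloc[0][metric])


def evaluate_cases(truths, predictions, case_ids=None, spacing=None) -> MetricReport:
    """Build a MetricReport from paired integer label volumes.

    ``truths`` and ``predictions`` are sequences of {0,1,2} label arrays;
    liver and tumor masks are extracted per the union convention.
    """
    truths, predictions = list(truths), list(predictions)
    if len(truths) != len(predictions):
        raise ValueError("case count mismatch")
    if not truths:
        raise ValueError("need at least one case")
    if case_ids is None:
        case_ids = [f"case_{i:03d}" for i in range(len(truths))]
    rows = []
    for cid, t, p in zip(case_ids, truths, predictions):
        for cls in CLASS_NAMES:
            ma = extract_class_masks(t, cls, spacing)
            mb = extract_class_masks(p, cls, spacing)
            rows.append({
                "case": cid,
                "class": cls,
                "dice": dice(ma, mb),
                "voe": voe(ma, mb),
                "ravd": ravd(ma, mb),
                "assd": assd(ma, mb),
                "hd95": hd95(ma, mb),
                "intersection": int((ma.data & mb.data).sum()),
                "size_a": int(ma.data.sum()),
                "size_b": int(mb.data.sum()),
            })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MetricReport(pd.DataFrame(rows))
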