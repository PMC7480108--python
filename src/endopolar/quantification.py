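"""Scalar assay readouts with control normalization.

Three end-point quantifications:

* **invadopodia area ratio** — marker-positive surface divided by the
  total cell surface, per cell;
* **degradation index** — number of collagen-degradation spots divided
  by the number of cells in the field, per field;
* **invasion fraction** — the share of total nuclear signal found at
  depths >= 30 µm in a serial-section z-stack of an inverted invasion
  assay.

The first two are reported relative to a control condition whose mean is
set to exactly 100; the normalization is linear, hence idempotent when
re-applied with the same control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scene import ImageScene
from .segmentation import LabelMask

__all__ = [
    "QuantResult",
    "normalize_to_control",
    "invadopodia_area_ratio",
    "degradation_index",
    "invasion_fraction",
    "mean_masked_intensity",
]


@dataclass
class QuantResult:
    """Per-object assay values plus their control-normalized percentages."""

    values: pd.DataFrame          # columns: condition, value, normalized_pct
    control_label: str
    control_mean: float

    @property
    def n(self) -> int:
        return len(self.values)

    def condition_summary(self) -> pd.DataFrame:
        g = self.values.groupby("condition")["normalized_pct"]
        out = g.agg(mean="mean", n="size")
        out["sem"] = g.sem()
        return out.reset_index()


def normalize_to_control(values: Sequence[float], conditions: Sequence[str],
                         control_label: str) -> QuantResult:
    """Scale values so the control condition's mean equals exactly 100."""
    df = pd.DataFrame(dict(condition=list(conditions),
                           value=np.asarray(values, dtype=float)))
    ctrl = df.loc[df["condition"] == control_label, "value"]
    if ctrl.empty:
        raise ValueError(f"no values for control condition {control_label!r}")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean == 0:
        raise ValueError("control mean is zero: normalization undefined")
    df["normalized_pct"] = 100.0 * df["value"] / ctrl_mean
    return QuantResult(values=df, control_label=control_label,
                       control_mean=ctrl_mean)


# ---------------------------------------------------------------------------
# invadopodia
# ---------------------------------------------------------------------------

def invadopodia_area_ratio(marker_mask: LabelMask,
                           cell_mask: LabelMask) -> pd.DataFrame:
    """Marker-covered surface over total cell surface, per cell.

    For every labelled cell, the ratio of marker-positive pixels falling
    inside the cell to the cell's area.  Returns a frame with columns
    ``cell_label``, ``cell_area_px``, ``marker_area_px``, ``ratio``.
    """
    if marker_mask.labels.shape != cell_mask.labels.shape:
        raise ValueError("masks must be aligned (identical shape)")
    if cell_mask.n_labels == 0:
        raise ValueError("empty cell mask")
    marker = marker_mask.labels > 0
    rows = []
    for _, cell in cell_mask.table.iterrows():
        region = cell_mask.labels == cell["label"]
        area = int(region.sum())
        marker_px = int((marker & region).sum())
        rows.append(dict(cell_label=int(cell["label"]), cell_area_px=area,
                         marker_area_px=marker_px, ratio=marker_px / area))
    return pd.DataFrame(rows)


def mean_masked_intensity(plane: np.ndarray, cell_mask: LabelMask) -> pd.DataFrame:
    """Mean intensity of a signal channel per labelled cell.

    Companion metric to the spot-count degradation index: the mean
    cleaved-collagen signal per cell, reported separately.
    """
    if cell_mask.n_labels == 0:
        raise ValueError("empty cell mask")
    img = np.asarray(plane, dtype=float)
    rows = []
    for _, cell in cell_mask.table.iterrows():
        region = cell_mask.labels == cell["label"]
        rows.append(dict(cell_label=int(cell["label"]),
                         mean_intensity=float(img[region].mean())))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pericellular collagenolysis
# ---------------------------------------------------------------------------

def degradation_index(spot_counts: Sequence[float], cell_counts: Sequence[float],
                      conditions: Sequence[str],
                      control_label: str) -> QuantResult:
    """Degradation spots per cell, normalized to the control mean = 100.

    One entry per imaged field.  Fields with zero cells are excluded
    with a warning.
    """
    spots = np.asarray(spot_counts, dtype=float)
    cells = np.asarray(cell_counts, dtype=float)
    cond = np.asarray(list(conditions))
    if not (len(spots) == len(cells) == len(cond)):
        raise ValueError("spot_counts, cell_counts, conditions must align")
    ok = cells >= 1
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} field(s) with zero cells",
                      stacklevel=2)
    ratio = spots[ok] / cells[ok]
    return normalize_to_control(ratio, cond[ok], control_label)


# ---------------------------------------------------------------------------
# 3D invasion
# ---------------------------------------------------------------------------

def invasion_fraction(zstack: ImageScene | np.ndarray,
                      z_step: Optional[float] = None,
                      depth_threshold: float = 30.0,
                      surface_index: int | str = 0,
                      background: str | float | None = None,
                      channel: int = 0) -> float:
    """Percentage of nuclear signal at depths >= ``depth_threshold`` µm.

    The stack's slices are summed; the invasion fraction is
    100 x sum(slice sums at depth >= threshold) / sum(all slice sums),
    with depth measured from the surface slice ("beyond 30 µm" is
    inclusive of 30 µm).

    ``surface_index`` selects the depth-0 slice: an integer index
    (default 0, the acquisition's gel surface) or ``"auto"`` to use the
    slice of maximal total signal (the non-invading monolayer).

    ``background`` subtracts a per-slice offset before summing: a float
    (constant offset), ``"corner"`` (median of a 10 x 10 cell-free
    corner patch per slice), or None.
    """
    if isinstance(zstack, ImageScene):
        data = zstack.data[channel, 0]          # (Z, Y, X)
        z_step = zstack.z_step if z_step is None else z_step
    else:
        data = np.asarray(zstack, dtype=float)
        if data.ndim != 3:
            raise ValueError("expected a (Z, Y, X) array")
        if z_step is None:
            raise ValueError("z_step required for a bare array")
    n_z = data.shape[0]
    if n_z < 2:
        raise ValueError("need at least 2 slices")

    data = data.astype(float)
    if background is not None:
        if background == "corner":
            offs = np.median(data[:, :10, :10], axis=(1, 2))
        else:
            offs = np.full(n_z, float(background))
        data = np.clip(data - offs[:, None, None], 0.0, None)

    slice_sums = data.sum(axis=(1, 2))
    total = slice_sums.sum()
    if total <= 0:
        raise ValueError("total intensity is zero")
    if surface_index == "auto":
        surf = int(slice_sums.argmax())
    else:
        surf = int(surface_index)
    depths = (np.arange(n_z) - surf) * z_step
    invading = slice_sums[depths >= depth_threshold].sum()
    return 100.0 * float(invading / total)
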