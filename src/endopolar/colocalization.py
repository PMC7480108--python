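"""Colocalization of invadopodial markers.

Three complementary measures:

* width-averaged linescans along user-drawn polylines (e.g. along
  collagen fibers), with each channel normalized to its maximum set to
  100, plus Pearson correlation and an ordinary least-squares regression
  of one marker against the other;
* thresholded Manders coefficients M1/M2 — the proportion of one
  channel's supra-threshold intensity found in pixels where the other
  channel is also supra-threshold;
* the normalized mean deviation product (nMDP) map, a per-pixel
  correlation index in [-1, 1] used to render colocalization colormaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import linregress
from skimage.filters import threshold_otsu

__all__ = [
    "LinescanProfile", "ColocResult",
    "extract_linescan", "profile_correlation",
    "manders_coefficients", "nmdp_map",
]


@dataclass
class LinescanProfile:
    """Two-channel intensity profile sampled along a polyline.

    ``raw`` and ``normalized`` are (2, n_samples); the normalized scale
    puts each channel's maximum at exactly 100 (when the raw maximum is
    positive).  ``positions`` is the arc-length coordinate (pixels).
    """

    vertices: np.ndarray          # (V, 2) polyline (y, x) in pixels
    positions: np.ndarray         # (n,) arc length in pixels
    raw: np.ndarray               # (2, n)
    normalized: np.ndarray        # (2, n), max = 100 per channel
    width: int


@dataclass
class ColocResult:
    m1: float
    m2: float
    threshold_a: float
    threshold_b: float
    n_pixels: int


# ---------------------------------------------------------------------------
# linescans
# ---------------------------------------------------------------------------

def _polyline_samples(vertices: np.ndarray, spacing: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-spaced sample points along a polyline with per-sample tangents."""
    v = np.asarray(vertices, dtype=float)
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    if total <= 0:
        raise ValueError("polyline has zero length")
    n = int(math.floor(total / spacing)) + 1
    s = np.arange(n) * spacing
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    pts = v[idx] + seg[idx] * frac[:, None]
    tangents = seg[idx] / seg_len[idx, None]
    return s, pts, tangents


def extract_linescan(plane_a: np.ndarray, plane_b: np.ndarray,
                     polyline: np.ndarray, width: int = 6) -> LinescanProfile:
    """Width-averaged two-channel linescan along a segmented line.

    Samples are taken at unit arc-length spacing; at each sample the
    intensity is averaged over ``width`` points spaced 1 px apart along
    the perpendicular to the local tangent, read by bilinear
    interpolation.  Each channel is then normalized so its maximum is
    100.  Raises if any sample (including the perpendicular extent)
    falls outside the image.
    """
    a = np.asarray(plane_a, dtype=float)
    b = np.asarray(plane_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel planes must have identical shape")
    v = np.asarray(polyline, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
        raise ValueError("polyline must be (V >= 2, 2) of (y, x) vertices")
    s, pts, tang = _polyline_samples(v)
    normals = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    offsets = np.arange(width) - (width - 1) / 2.0
    # (n, width, 2) sample coordinates
    coords = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    h, w = a.shape
    ys, xs = coords[..., 0], coords[..., 1]
    if ys.min() < 0 or xs.min() < 0 or ys.max() > h - 1 or xs.max() > w - 1:
        raise ValueError("linescan exits the image bounds")
    flat = np.stack([ys.ravel(), xs.ravel()])
    prof_a = ndi.map_coordinates(a, flat, order=1).reshape(ys.shape).mean(axis=1)
    prof_b = ndi.map_coordinates(b, flat, order=1).reshape(ys.shape).mean(axis=1)
    raw = np.stack([prof_a, prof_b])
    norm = raw.copy()
    for c in range(2):
        m = norm[c].max()
        if m > 0:
            norm[c] = norm[c] * (100.0 / m)
    return LinescanProfile(vertices=v, positions=s, raw=raw,
                           normalized=norm, width=width)


def profile_correlation(profile: LinescanProfile) -> tuple[float, float, float]:
    """Pearson r and OLS line (slope, intercept) of channel B vs channel A.

    Computed on the normalized profiles; undefined (raises) when either
    channel has zero variance or fewer than 3 samples.
    """
    x, y = profile.normalized
    if len(x) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a channel: correlation undefined")
    res = linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)


# ---------------------------------------------------------------------------
# Manders coefficients
# ---------------------------------------------------------------------------

def manders_coefficients(img_a: np.ndarray, img_b: np.ndarray,
                         threshold_a: Optional[float] = None,
                         threshold_b: Optional[float] = None,
                         mask: Optional[np.ndarray] = None) -> ColocResult:
    """Thresholded Manders colocalization coefficients.

    M1 = sum of A over pixels with A > tA and B > tB, divided by the sum
    of A over pixels with A > tA; M2 symmetrically with the roles
    swapped.  Both channels are gated, i.e. only "significant" signal in
    both channels counts as colocalized.  Thresholds default to Otsu's
    method per channel.  An optional boolean ``mask`` restricts the
    computation to a region (e.g. collagen-proximal pixels).

    Raises when a denominator channel has no supra-threshold pixel.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have identical shape")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape mismatch")
        a = a[mask]
        b = b[mask]
    ta = threshold_otsu(a) if threshold_a is None else float(threshold_a)
    tb = threshold_otsu(b) if threshold_b is None else float(threshold_b)
    if ta < 0 or tb < 0:
        raise ValueError("thresholds must be >= 0")
    sup_a = a > ta
    sup_b = b > tb
    denom_a = a[sup_a].sum()
    denom_b = b[sup_b].sum()
    if denom_a <= 0 or denom_b <= 0:
        raise ValueError("no supra-threshold signal in a channel: "
                         "Manders coefficient undefined")
    m1 = a[sup_a & sup_b].sum() / denom_a
    m2 = b[sup_a & sup_b].sum() / denom_b
    return ColocResult(m1=float(m1), m2=float(m2), threshold_a=ta,
                       threshold_b=tb, n_pixels=int(a.size))


# ---------------------------------------------------------------------------
# nMDP colormap
# ---------------------------------------------------------------------------

def nmdp_map(img_a: np.ndarray, img_b: np.ndarray) -> np.ndarray:
    """Normalized mean deviation product map (Jaskolski), values in [-1, 1].

    nMDP_i = (A_i - mean(A)) (B_i - mean(B)) /
             ((max(A) - mean(A)) (max(B) - mean(B)))

    Positive values mark pixels where both channels deviate from their
    means in the same direction (correlated signal); the pixel that is
    maximal in both channels maps to exactly 1.  Raises for a constant
    channel (undefined denominator).  By construction the map is
    invariant to a positive affine rescaling of either channel.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have identical shape")
    da = a - a.mean()
    db = b - b.mean()
    denom = da.max() * db.max()
    if denom <= 0:
        raise ValueError("constant channel: nMDP undefined")
    out = da * db / denom
    return np.clip(out, -1.0, 1.0)
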