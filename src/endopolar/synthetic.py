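"""Synthetic microscopy scene generators with exported ground truth.

Every analysis stage of the package is exercised against fixtures built
here: time-lapse movies of fluorescent nuclei performing a persistent
random walk with punctate endosomes placed around them in the
nucleus-velocity frame, two-channel fiber images with a controllable
pixelwise overlap fraction, fields of small degradation spots with a
countable density, and z-stacks with a known per-depth signal profile.

The image model is deliberately minimal but realistic for fluorescence
microscopy: expected photons = PSF-blurred object intensity + uniform
background, followed by Poisson shot noise and additive Gaussian read
noise.  A fixed seed makes every generator byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .scene import ImageScene

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "sample_von_mises",
    "generate_polarity_movie",
    "generate_coloc_fixture",
    "generate_degradation_field",
    "generate_invasion_stack",
]


# ---------------------------------------------------------------------------
# configuration and ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Parameters of a synthetic polarity movie.

    Defaults emulate a spinning-disk acquisition of single breast-cancer
    cells migrating in a dense 3D collagen gel: frames every 10 minutes,
    nucleus speeds of a few tenths of µm/min, and ~20 MT1-MMP-positive
    late endosomes/lysosomes per cell placed at 3-10 µm from the nucleus
    centroid.

    ``angular_model`` is either ``"uniform"`` (no polarization, the
    silenced-cell null) or ``("von_mises", mu_deg, kappa)`` where ``mu``
    is measured from the instantaneous direction of nucleus movement
    (0 deg = front) and ``kappa`` is the angular concentration.
    """

    image_shape: tuple[int, int] = (384, 384)        # (y, x) pixels
    pixel_size: float = 0.25                          # µm / pixel
    frame_interval: float = 10.0                      # min
    n_frames: int = 40
    n_cells: int = 1
    nucleus_speed: float = 0.3                        # µm / min
    nucleus_persistence: float = 0.7                  # [0, 1]
    nucleus_radius: float = 4.0                       # µm
    endosomes_per_cell: int = 20
    angular_model: tuple | str = "uniform"
    radial_mean: float = 6.0                          # µm from nucleus centroid
    radial_sd: float = 1.5                            # µm
    radial_min: float = 2.0                           # µm, keeps spots off the nucleus
    psf_sigma: float = 0.3                            # µm
    background: float = 20.0                          # photons / pixel
    nucleus_amplitude: float = 150.0
    endosome_amplitude: float = 400.0
    poisson_scale: float = 1.0                        # photons per intensity unit
    gaussian_sd: float = 2.0                          # read noise, counts
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "nucleus_radius", "psf_sigma",
                     "radial_mean", "radial_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.endosomes_per_cell < 0:
            raise ValueError("endosomes_per_cell must be >= 0")
        if not 0.0 <= self.nucleus_persistence <= 1.0:
            raise ValueError("nucleus_persistence must lie in [0, 1]")
        if self.nucleus_speed < 0:
            raise ValueError("nucleus_speed must be >= 0")
        mu, kappa = self.angular_params()
        if kappa < 0:
            raise ValueError("kappa must be >= 0")
        step_px = self.nucleus_speed * self.frame_interval / self.pixel_size
        if step_px >= min(self.image_shape):
            raise ValueError("per-frame nucleus displacement exceeds the image size")

    def angular_params(self) -> tuple[float, float]:
        """Return (mu_deg, kappa); the uniform law is kappa = 0."""
        if self.angular_model == "uniform":
            return 0.0, 0.0
        kind, mu, kappa = self.angular_model
        if kind != "von_mises":
            raise ValueError(f"unknown angular model {kind!r}")
        return float(mu), float(kappa)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        if isinstance(self.angular_model, tuple):
            d["angular_model"] = list(self.angular_model)
        return d


@dataclass
class GroundTruth:
    """Planted object records accompanying a synthetic scene.

    Tables are keyed by frame and object id so that any detection or
    tracking output can be matched back to the truth.
    """

    nuclei: Optional[pd.DataFrame] = None      # frame, cell_id, y_px, x_px, vy_px, vx_px
    endosomes: Optional[pd.DataFrame] = None   # frame, cell_id, endosome_id, theta_deg, radius_um, y_px, x_px
    spots: Optional[pd.DataFrame] = None       # spot_id, y_px, x_px
    coloc_masks: Optional[dict] = None         # channel name -> boolean mask
    depth_fractions: Optional[pd.DataFrame] = None  # z, depth_um, weight, fraction
    config: dict = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        """Serialize all tables as CSV plus the generating config as YAML."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("nuclei", "endosomes", "spots", "depth_fractions"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(directory / f"{name}.csv", index=False)
        if self.config:
            with open(directory / "config.yaml", "w") as fh:
                yaml.safe_dump(self.config, fh)


# ---------------------------------------------------------------------------
# angular sampling
# ---------------------------------------------------------------------------

def sample_von_mises(mu_deg: float, kappa: float, n: int,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` angles (degrees, in (-180, 180]) from a von Mises law.

    ``kappa = 0`` reduces exactly to the circular uniform distribution.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kappa == 0:
        rad = rng.uniform(-math.pi, math.pi, size=n)
    else:
        rad = rng.vonmises(math.radians(mu_deg), kappa, size=n)
    return wrap_degrees(np.degrees(rad))


def wrap_degrees(angles: np.ndarray | float) -> np.ndarray:
    """Wrap angles to the interval (-180, 180]."""
    a = np.asarray(angles, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _splat(canvas: np.ndarray, y: np.ndarray, x: np.ndarray,
           amplitude: float) -> None:
    """Deposit unit impulses at sub-pixel positions by bilinear splatting."""
    h, w = canvas.shape
    y0 = np.floor(y).astype(int)
    x0 = np.floor(x).astype(int)
    fy = y - y0
    fx = x - x0
    for dy, dx, wgt in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                        (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        yy = y0 + dy
        xx = x0 + dx
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        np.add.at(canvas, (yy[ok], xx[ok]), amplitude * wgt[ok])


def _disk(canvas: np.ndarray, cy: float, cx: float, radius_px: float,
          amplitude: float) -> None:
    h, w = canvas.shape
    r = int(math.ceil(radius_px)) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
    canvas[y0:y1, x0:x1][inside] += amplitude


def _render(photon_image: np.ndarray, psf_sigma_px: float, background: float,
            poisson_scale: float, gaussian_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    """PSF blur + background, Poisson shot noise, Gaussian read noise."""
    blurred = ndi.gaussian_filter(photon_image, psf_sigma_px) + background
    if poisson_scale > 0:
        img = rng.poisson(np.maximum(blurred * poisson_scale, 0)).astype(float)
        img /= poisson_scale
    else:
        img = blurred
    if gaussian_sd > 0:
        img = img + rng.normal(0.0, gaussian_sd, size=img.shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# persistent random walk
# ---------------------------------------------------------------------------

def _persistent_walk(start: np.ndarray, step_px: float, persistence: float,
                     n_steps: int, bounds: tuple[float, float, float, float],
                     rng: np.random.Generator) -> np.ndarray:
    """Positions (n_steps+1, 2) as (y, x) pixels; reflecting margins.

    Turning angles between consecutive steps follow a von Mises law whose
    concentration grows with ``persistence``: p = 0 gives uncorrelated
    directions, p = 1 a straight line.
    """
    ylo, yhi, xlo, xhi = bounds
    pos = np.empty((n_steps + 1, 2))
    pos[0] = start
    heading = rng.uniform(-math.pi, math.pi)
    for t in range(1, n_steps + 1):
        if persistence >= 1.0:
            turn = 0.0
        elif persistence <= 0.0:
            turn = rng.uniform(-math.pi, math.pi)
        else:
            kappa_turn = 4.0 * persistence / (1.0 - persistence)
            turn = rng.vonmises(0.0, kappa_turn)
        heading += turn
        # image coordinates: y grows downward, so a heading angle phi in
        # math convention maps to displacement (dy, dx) = (-sin, cos)
        dy = -math.sin(heading) * step_px
        dx = math.cos(heading) * step_px
        y, x = pos[t - 1, 0] + dy, pos[t - 1, 1] + dx
        # reflect at the margins; the realized displacement (recorded in
        # the ground truth) is whatever the reflection produced
        if y < ylo:
            y = 2 * ylo - y
            heading = -heading
        elif y > yhi:
            y = 2 * yhi - y
            heading = -heading
        if x < xlo:
            x = 2 * xlo - x
            heading = math.pi - heading
        elif x > xhi:
            x = 2 * xhi - x
            heading = math.pi - heading
        pos[t] = (y, x)
    return pos


# ---------------------------------------------------------------------------
# polarity movie
# ---------------------------------------------------------------------------

def generate_polarity_movie(config: SceneConfig) -> tuple[ImageScene, GroundTruth]:
    """Simulate a two-channel time-lapse of migrating nuclei with endosomes.

    Channel 0 carries the nuclear signal, channel 1 the endosome puncta.
    At each frame ``t >= 1`` endosome angles are drawn from the configured
    angular model measured from the *realized* nucleus displacement of the
    interval ``t-1 -> t`` (frame 0 uses the direction of the first step),
    so the polarity pipeline's frame convention can be tested exactly.
    The exported ground truth records, per frame and per object, nucleus
    centroids and velocities and the true endosome angle and radius.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    px = cfg.pixel_size
    step_px = cfg.nucleus_speed * cfg.frame_interval / px
    mu_deg, kappa = cfg.angular_params()
    # keep the whole endosome cloud inside the field of view
    margin = (cfg.radial_mean + 4 * cfg.radial_sd + cfg.nucleus_radius) / px
    margin = min(margin, 0.45 * min(h, w))
    bounds = (margin, h - 1 - margin, margin, w - 1 - margin)

    # seed nuclei positions well apart when possible
    starts = []
    for _ in range(cfg.n_cells):
        for _attempt in range(200):
            cand = np.array([rng.uniform(bounds[0], bounds[1]),
                             rng.uniform(bounds[2], bounds[3])])
            if all(np.hypot(*(cand - s)) > 2.5 * margin for s in starts):
                break
        starts.append(cand)

    walks = [_persistent_walk(s, step_px, cfg.nucleus_persistence,
                              cfg.n_frames - 1, bounds, rng)
             for s in starts]

    psf_px = cfg.psf_sigma / px
    nuc_r_px = cfg.nucleus_radius / px
    movie = np.zeros((2, cfg.n_frames, 1, h, w))
    nuc_rows, endo_rows = [], []
    for t in range(cfg.n_frames):
        nuc_obj = np.zeros((h, w))
        endo_obj = np.zeros((h, w))
        for cid, walk in enumerate(walks):
            cy, cx = walk[t]
            # velocity of the interval ending at t (frame 0: first step)
            t_ref = max(t, 1)
            vy, vx = walk[t_ref] - walk[t_ref - 1]
            nuc_rows.append(dict(frame=t, cell_id=cid, y_px=cy, x_px=cx,
                                 vy_px=vy, vx_px=vx))
            _disk(nuc_obj, cy, cx, nuc_r_px, cfg.nucleus_amplitude)
            if cfg.endosomes_per_cell == 0:
                continue
            theta = sample_von_mises(mu_deg, kappa, cfg.endosomes_per_cell, rng)
            radius = np.clip(
                rng.normal(cfg.radial_mean, cfg.radial_sd, cfg.endosomes_per_cell),
                cfg.radial_min, None)
            # direction of movement in math coordinates (x right, y up)
            phi_v = math.atan2(-vy, vx)
            ang = phi_v + np.radians(theta)
            ex = cx + radius / px * np.cos(ang)
            ey = cy - radius / px * np.sin(ang)      # flip back to raster y
            _splat(endo_obj, ey, ex, cfg.endosome_amplitude)
            for j in range(cfg.endosomes_per_cell):
                endo_rows.append(dict(frame=t, cell_id=cid, endosome_id=j,
                                      theta_deg=theta[j], radius_um=radius[j],
                                      y_px=ey[j], x_px=ex[j]))
        movie[0, t, 0] = _render(nuc_obj, psf_px, cfg.background,
                                 cfg.poisson_scale, cfg.gaussian_sd, rng)
        movie[1, t, 0] = _render(endo_obj, psf_px, cfg.background,
                                 cfg.poisson_scale, cfg.gaussian_sd, rng)

    scene = ImageScene(movie, pixel_size=px, frame_interval=cfg.frame_interval,
                       channel_names=("nucleus", "endosome"))
    truth = GroundTruth(nuclei=pd.DataFrame(nuc_rows),
                        endosomes=pd.DataFrame(endo_rows),
                        config=cfg.to_dict())
    return scene, truth


# ---------------------------------------------------------------------------
# colocalization fixture
# ---------------------------------------------------------------------------

def generate_coloc_fixture(shape: tuple[int, int] = (256, 256),
                           rho: float = 0.5,
                           n_fibers: int = 12,
                           intensity: float = 200.0,
                           noise_sd: float = 0.0,
                           seed: int = 0) -> tuple[ImageScene, GroundTruth]:
    """Two-channel image of fiber-like structures with planted overlap.

    A set of smooth curvilinear fibers is rasterized; each fiber pixel is
    then assigned to channel A only, channel B only, or both, such that
    the fraction of each channel's above-threshold pixels shared with the
    other channel equals ``rho``.  On noiseless output, thresholded
    Manders coefficients M1 = M2 = rho by construction.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    fiber = np.zeros((h, w), dtype=bool)
    for _ in range(n_fibers):
        y = rng.uniform(10, h - 10)
        x = rng.uniform(10, w - 10)
        heading = rng.uniform(0, 2 * math.pi)
        for _step in range(rng.integers(60, 140)):
            heading += rng.normal(0, 0.15)
            y += math.sin(heading)
            x += math.cos(heading)
            iy, ix = int(round(y)), int(round(x))
            if not (1 <= iy < h - 1 and 1 <= ix < w - 1):
                break
            fiber[iy - 1:iy + 2, ix - 1:ix + 2] = True

    idx = np.flatnonzero(fiber.ravel())
    rng.shuffle(idx)
    n = len(idx)
    # shared / A-only / B-only split so that shared / (shared + only) = rho
    n_shared = int(round(rho * n / (2 - rho))) if rho < 1 else n
    n_only = int(round(n_shared * (1 - rho) / rho)) if rho > 0 else (n - n_shared) // 2
    n_only = min(n_only, (n - n_shared) // 2)
    shared = idx[:n_shared]
    a_only = idx[n_shared:n_shared + n_only]
    b_only = idx[n_shared + n_only:n_shared + 2 * n_only]

    mask_a = np.zeros(h * w, dtype=bool)
    mask_b = np.zeros(h * w, dtype=bool)
    mask_a[shared] = mask_a[a_only] = True
    mask_b[shared] = mask_b[b_only] = True
    mask_a = mask_a.reshape(h, w)
    mask_b = mask_b.reshape(h, w)

    img_a = np.where(mask_a, intensity, 0.0)
    img_b = np.where(mask_b, intensity, 0.0)
    if noise_sd > 0:
        img_a = np.clip(img_a + rng.normal(0, noise_sd, (h, w)), 0, None)
        img_b = np.clip(img_b + rng.normal(0, noise_sd, (h, w)), 0, None)

    scene = ImageScene(np.stack([img_a, img_b])[:, None, None],
                       pixel_size=0.1, channel_names=("marker_a", "marker_b"))
    truth = GroundTruth(coloc_masks={"marker_a": mask_a, "marker_b": mask_b},
                        config=dict(shape=list(shape), rho=rho, seed=seed,
                                    n_fibers=n_fibers, noise_sd=noise_sd))
    return scene, truth


# ---------------------------------------------------------------------------
# degradation field
# ---------------------------------------------------------------------------

def generate_degradation_field(shape: tuple[int, int] = (512, 512),
                               n_cells: int = 10,
                               spots_per_cell: float = 5,
                               spot_sigma_px: float = 2.0,
                               psf_sigma_px: float = 1.0,
                               spot_amplitude: float = 300.0,
                               nucleus_amplitude: float = 200.0,
                               nucleus_radius_px: float = 10.0,
                               background: float = 20.0,
                               gaussian_sd: float = 2.0,
                               pixel_size: float = 0.5,
                               seed: int = 0) -> tuple[ImageScene, GroundTruth]:
    """Field of nuclei plus planted degradation spots of known count.

    Channel 0 holds ``n_cells`` nuclei, channel 1 exactly
    ``round(n_cells * spots_per_cell)`` isotropic Gaussian spots with a
    minimum pairwise separation of 4 x psf_sigma.  Raises when the
    requested density cannot be packed.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    n_spots = int(round(n_cells * spots_per_cell))
    min_sep = 4.0 * psf_sigma_px
    # crude packing bound
    if n_spots * math.pi * (min_sep / 2) ** 2 > 0.5 * h * w:
        raise ValueError("requested spot density exceeds the packing limit")

    margin = 6 * spot_sigma_px + 2
    points: list[tuple[float, float]] = []
    attempts = 0
    while len(points) < n_spots:
        attempts += 1
        if attempts > 200 * max(n_spots, 1):
            raise ValueError("could not place spots at the requested density")
        cand = (rng.uniform(margin, h - 1 - margin),
                rng.uniform(margin, w - 1 - margin))
        if all(math.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep
               for p in points):
            points.append(cand)

    nuc_obj = np.zeros((h, w))
    nuc_pts = []
    for _ in range(n_cells):
        cy = rng.uniform(nucleus_radius_px + 2, h - nucleus_radius_px - 3)
        cx = rng.uniform(nucleus_radius_px + 2, w - nucleus_radius_px - 3)
        _disk(nuc_obj, cy, cx, nucleus_radius_px, nucleus_amplitude)
        nuc_pts.append((cy, cx))

    spot_obj = np.zeros((h, w))
    for cy, cx in points:
        _splat(spot_obj, np.array([cy]), np.array([cx]),
               spot_amplitude * 2 * math.pi * spot_sigma_px ** 2)
    # spots have their own physical size before the PSF
    spot_obj = ndi.gaussian_filter(spot_obj, spot_sigma_px)

    nuc_img = _render(nuc_obj, psf_sigma_px, background, 1.0, gaussian_sd, rng)
    deg_img = _render(spot_obj, psf_sigma_px, background, 1.0, gaussian_sd, rng)

    scene = ImageScene(np.stack([nuc_img, deg_img])[:, None, None],
                       pixel_size=pixel_size,
                       channel_names=("nucleus", "degradation"))
    spots = pd.DataFrame([dict(spot_id=i, y_px=p[0], x_px=p[1])
                          for i, p in enumerate(points)])
    nuclei = pd.DataFrame([dict(frame=0, cell_id=i, y_px=p[0], x_px=p[1])
                           for i, p in enumerate(nuc_pts)])
    truth = GroundTruth(spots=spots, nuclei=nuclei,
                        config=dict(shape=list(shape), n_cells=n_cells,
                                    spots_per_cell=spots_per_cell, seed=seed,
                                    spot_sigma_px=spot_sigma_px,
                                    psf_sigma_px=psf_sigma_px))
    return scene, truth


# ---------------------------------------------------------------------------
# invasion stack
# ---------------------------------------------------------------------------

def generate_invasion_stack(n_slices: int = 5,
                            z_step_um: float = 10.0,
                            depth_profile: Optional[np.ndarray] = None,
                            shape: tuple[int, int] = (128, 128),
                            n_nuclei_per_unit: int = 30,
                            nucleus_sigma_px: float = 3.0,
                            background: float = 0.0,
                            gaussian_sd: float = 0.0,
                            pixel_size: float = 1.0,
                            seed: int = 0) -> tuple[ImageScene, GroundTruth]:
    """Z-stack of nuclear signal with slice totals proportional to a profile.

    ``depth_profile`` gives non-negative per-slice weights (default:
    uniform).  On noiseless output, the total intensity of slice k is
    exactly proportional to ``depth_profile[k]``, so the planted invasion
    fraction at any depth threshold is known in closed form.
    """
    if depth_profile is None:
        depth_profile = np.ones(n_slices)
    depth_profile = np.asarray(depth_profile, dtype=float)
    if len(depth_profile) != n_slices:
        raise ValueError("depth_profile length must equal n_slices")
    if np.any(depth_profile < 0):
        raise ValueError("depth_profile weights must be >= 0")
    if not np.any(depth_profile > 0):
        raise ValueError("depth_profile must contain at least one positive weight")
    if z_step_um <= 0:
        raise ValueError("z_step_um must be > 0")

    rng = np.random.default_rng(seed)
    h, w = shape
    stack = np.zeros((n_slices, h, w))
    margin = 4 * nucleus_sigma_px
    for k, wgt in enumerate(depth_profile):
        if wgt == 0:
            continue
        obj = np.zeros((h, w))
        ys = rng.uniform(margin, h - 1 - margin, n_nuclei_per_unit)
        xs = rng.uniform(margin, w - 1 - margin, n_nuclei_per_unit)
        _splat(obj, ys, xs, 1000.0)
        obj = ndi.gaussian_filter(obj, nucleus_sigma_px, truncate=6.0)
        # exact per-slice total regardless of blur truncation
        obj *= wgt * 1000.0 * n_nuclei_per_unit / max(obj.sum(), 1e-12)
        stack[k] = obj + background
    if gaussian_sd > 0:
        stack = np.clip(stack + rng.normal(0, gaussian_sd, stack.shape), 0, None)

    depths = np.arange(n_slices) * z_step_um
    fractions = depth_profile / depth_profile.sum()
    scene = ImageScene(stack[None, None], pixel_size=pixel_size,
                       z_step=z_step_um, channel_names=("dapi",))
    truth = GroundTruth(
        depth_fractions=pd.DataFrame(dict(z=np.arange(n_slices),
                                          depth_um=depths,
                                          weight=depth_profile,
                                          fraction=fractions)),
        config=dict(n_slices=n_slices, z_step_um=z_step_um,
                    depth_profile=depth_profile.tolist(), seed=seed))
    return scene, truth
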