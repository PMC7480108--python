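"""Nucleus tracking and trajectory kinematics.

Detections are linked frame-to-frame by greedy nearest-neighbour
assignment: candidate pairs between consecutive frames are considered in
order of increasing distance, each detection is used at most once, and
links longer than ``max_disp`` are rejected (the track terminates and
unmatched detections open new tracks).  Ties are broken by the lowest
detection index, which makes the linking deterministic.

From each trajectory the per-interval speed (µm/min) and two
directionality measures are computed: the whole-track persistence (net
displacement over total path length, the headline measure) and a
per-interval turning persistence (mean cosine of successive turning
angles), exported alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NucleusTrack", "link_nuclei", "track_kinematics", "tracks_to_table"]


@dataclass
class NucleusTrack:
    """One nucleus trajectory: frames and centroids in pixels."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    centroids_px: list[tuple[float, float]] = field(default_factory=list)  # (y, x)
    detection_indices: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def positions(self) -> np.ndarray:
        return np.asarray(self.centroids_px, dtype=float)

    def displacements_px(self) -> np.ndarray:
        """(n-1, 2) per-interval displacement vectors (dy, dx) in pixels."""
        return np.diff(self.positions(), axis=0)


def link_nuclei(detections: list[np.ndarray], max_disp: float,
                pixel_size: float = 1.0) -> list[NucleusTrack]:
    """Link per-frame centroid detections into tracks.

    Parameters
    ----------
    detections
        One ``(N_t, 2)`` array of (y, x) pixel centroids per frame.
    max_disp
        Maximum link distance in µm; longer candidate links are rejected.
    pixel_size
        µm per pixel, used to express ``max_disp`` in pixels.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    if len(detections) < 2:
        raise ValueError("need at least 2 frames to link")
    max_disp_px = max_disp / pixel_size

    tracks: list[NucleusTrack] = []
    # active[i] = track currently ending at detection i of the previous frame
    active: dict[int, NucleusTrack] = {}
    prev = np.asarray(detections[0], dtype=float).reshape(-1, 2)
    for i in range(len(prev)):
        tr = NucleusTrack(track_id=len(tracks))
        tr.frames.append(0)
        tr.centroids_px.append(tuple(prev[i]))
        tr.detection_indices.append(i)
        tracks.append(tr)
        active[i] = tr

    for t in range(1, len(detections)):
        curr = np.asarray(detections[t], dtype=float).reshape(-1, 2)
        pairs = []
        for i in range(len(prev)):
            if i not in active:
                continue
            d = np.hypot(*(curr - prev[i]).T) if len(curr) else np.empty(0)
            for j in range(len(curr)):
                if d[j] <= max_disp_px:
                    pairs.append((d[j], i, j))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_prev: set[int] = set()
        used_curr: set[int] = set()
        new_active: dict[int, NucleusTrack] = {}
        for dist, i, j in pairs:
            if i in used_prev or j in used_curr:
                continue
            used_prev.add(i)
            used_curr.add(j)
            tr = active[i]
            tr.frames.append(t)
            tr.centroids_px.append(tuple(curr[j]))
            tr.detection_indices.append(j)
            new_active[j] = tr
        for j in range(len(curr)):
            if j not in used_curr:
                tr = NucleusTrack(track_id=len(tracks))
                tr.frames.append(t)
                tr.centroids_px.append(tuple(curr[j]))
                tr.detection_indices.append(j)
                tracks.append(tr)
                new_active[j] = tr
        active = new_active
        prev = curr
    return tracks


def track_kinematics(track: NucleusTrack, pixel_size: float,
                     frame_interval: float) -> dict:
    """Per-interval speeds and directionality of one trajectory.

    Returns a dict with ``speeds_um_min`` (one entry per interval),
    ``mean_speed_um_min``, ``persistence`` (net displacement / path
    length, in [0, 1]) and ``turning_persistence`` (mean cosine of the
    turning angle between consecutive displacement vectors; NaN for
    tracks with < 3 points or degenerate steps).
    """
    if len(track) < 2:
        raise ValueError("kinematics undefined for a track of length < 2")
    disp_um = track.displacements_px() * pixel_size
    step_len = np.hypot(disp_um[:, 0], disp_um[:, 1])
    # intervals may span more than one frame if detections were missed
    gaps = np.diff(np.asarray(track.frames))
    speeds = step_len / (gaps * frame_interval)
    path = step_len.sum()
    net = np.hypot(*(track.positions()[-1] - track.positions()[0])) * pixel_size
    persistence = float(net / path) if path > 0 else 0.0

    turning = np.nan
    if len(disp_um) >= 2:
        a, b = disp_um[:-1], disp_um[1:]
        na = np.hypot(a[:, 0], a[:, 1])
        nb = np.hypot(b[:, 0], b[:, 1])
        ok = (na > 0) & (nb > 0)
        if ok.any():
            cosang = (a[ok] * b[ok]).sum(axis=1) / (na[ok] * nb[ok])
            turning = float(np.clip(cosang, -1, 1).mean())

    return dict(track_id=track.track_id,
                n_frames=len(track),
                speeds_um_min=speeds,
                mean_speed_um_min=float(speeds.mean()),
                persistence=min(persistence, 1.0),
                turning_persistence=turning)


def tracks_to_table(tracks: list[NucleusTrack], pixel_size: float,
                    frame_interval: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-point and per-track summary tables (positions in µm)."""
    rows, summaries = [], []
    for tr in tracks:
        pos = tr.positions() * pixel_size
        for k, f in enumerate(tr.frames):
            rows.append(dict(track_id=tr.track_id, frame=f,
                             y_um=pos[k, 0], x_um=pos[k, 1]))
        if len(tr) >= 2:
            kin = track_kinematics(tr, pixel_size, frame_interval)
            summaries.append(dict(track_id=tr.track_id, n_frames=len(tr),
                                  mean_speed_um_min=kin["mean_speed_um_min"],
                                  persistence=kin["persistence"],
                                  turning_persistence=kin["turning_persistence"]))
    return pd.DataFrame(rows), pd.DataFrame(summaries)
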