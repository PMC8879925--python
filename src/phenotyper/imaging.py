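"""Track segmentation and rasterization to fixed-size grayscale images.

Each 30-s window of a track becomes one image: positions are affinely
mapped from the fixed maze bounding box onto the pixel grid (aspect
preserved, centered), consecutive points are joined by Bresenham lines, and
intensity grades linearly with time within the window (oldest 0.2, newest
1.0) so recency survives rasterization. Integer line drawing keeps the
output deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MazeGeometry
from .tracking import Track


@dataclass
class TrackSegment:
    fish_id: str
    day: str
    dose: str
    window_idx: int
    start_s: float
    end_s: float
    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class TrackImage:
    pixels: np.ndarray      # (H, W) float in [0, 1]
    label: tuple[str, str]  # (day, dose)
    fish_id: str
    window_idx: int

    def __post_init__(self):
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2-D grid")
        if not (self.pixels > 0).any():
            raise ValueError("image must have at least one nonzero pixel")


def segment_track(track: Track, window_s: float = 30.0, drop_partial: bool = True) -> list[TrackSegment]:
    """Cut a track into non-overlapping consecutive windows of ``window_s``."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if len(track) == 0:
        return []
    t0 = float(track.time_s[0])
    # covered duration includes one sampling interval past the last sample
    dt = float(np.median(np.diff(track.time_s))) if len(track) > 1 else 0.0
    duration = float(track.time_s[-1]) - t0 + dt
    segments: list[TrackSegment] = []
    idx = 0
    while True:
        lo = t0 + idx * window_s
        hi = lo + window_s
        mask = (track.time_s >= lo) & (track.time_s < hi)
        n_in = int(mask.sum())
        if n_in == 0:
            break
        is_partial = hi > t0 + duration + 1e-9
        if is_partial and drop_partial:
            break
        segments.append(
            TrackSegment(
                fish_id=track.fish_id, day=track.day, dose=track.dose,
                window_idx=idx, start_s=lo, end_s=hi,
                time_s=track.time_s[mask], x_cm=track.x_cm[mask], y_cm=track.y_cm[mask],
            )
        )
        if is_partial:
            break
        idx += 1
    return segments


def _bresenham(r0: int, c0: int, r1: int, c1: int):
    """Integer line from (r0,c0) to (r1,c1) inclusive."""
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    r, c = r0, c0
    while True:
        yield r, c
        if r == r1 and c == c1:
            return
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr


def rasterize_segment(
    seg: TrackSegment,
    geometry: MazeGeometry,
    size: int = 64,
    binary: bool = False,
    min_intensity: float = 0.2,
) -> TrackImage:
    """Rasterize one segment onto a ``size`` x ``size`` grid.

    ``binary=True`` switches to occupancy-only encoding (all trace pixels 1).
    """
    if len(seg) < 1:
        raise ValueError("cannot rasterize an empty segment")
    xmin, ymin, xmax, ymax = geometry.bounds
    span = max(xmax - xmin, ymax - ymin)
    scale = (size - 1) / span
    # center the shorter axis
    xoff = ((size - 1) - (xmax - xmin) * scale) / 2.0
    yoff = ((size - 1) - (ymax - ymin) * scale) / 2.0
    cols = np.rint((seg.x_cm - xmin) * scale + xoff).astype(int)
    rows = (size - 1) - np.rint((seg.y_cm - ymin) * scale + yoff).astype(int)
    cols = np.clip(cols, 0, size - 1)
    rows = np.clip(rows, 0, size - 1)

    n = len(seg)
    if n == 1:
        fracs = np.array([1.0])
    else:
        fracs = np.arange(n) / (n - 1)
    intensities = np.ones(n) if binary else min_intensity + (1.0 - min_intensity) * fracs

    img = np.zeros((size, size))
    img[rows[0], cols[0]] = intensities[0]
    for k in range(1, n):
        path = list(_bresenham(rows[k - 1], cols[k - 1], rows[k], cols[k]))
        # intensity interpolates along the drawn pixels between the endpoints
        steps = max(len(path) - 1, 1)
        v0, v1 = intensities[k - 1], intensities[k]
        for s, (r, c) in enumerate(path):
            v = v0 + (v1 - v0) * (s / steps)
            if img[r, c] < v:
                img[r, c] = v
    return TrackImage(pixels=img, label=(seg.day, seg.dose), fish_id=seg.fish_id,
                      window_idx=seg.window_idx)


def rasterize_study(tracks, geometry: MazeGeometry, window_s: float = 30.0,
                    size: int = 64, binary: bool = False) -> list[TrackImage]:
    """Segment and rasterize every track; segments with <2 samples skipped."""
    images: list[TrackImage] = []
    for tr in tracks:
        for seg in segment_track(tr, window_s=window_s):
            if len(seg) < 2:
                continue
            images.append(rasterize_segment(seg, geometry, size=size, binary=binary))
    return images


def save_images(images: list[TrackImage], outdir, index_csv) -> None:
    """Persist images as PNG plus an index CSV (image_path,fish_id,day,dose,window_idx)."""
    import csv
    from pathlib import Path

    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(index_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_path", "fish_id", "day", "dose", "window_idx"])
        for im in images:
            name = f"{im.fish_id}_{im.label[0]}_{im.window_idx:03d}.png"
            arr = (im.pixels * 255).round().astype(np.uint8)
            Image.fromarray(arr, mode="L").save(outdir / name)
            w.writerow([str(outdir / name), im.fish_id, im.label[0], im.label[1], im.window_idx])


def load_images(index_csv) -> list[TrackImage]:
    import pandas as pd
    from PIL import Image

    idx = pd.read_csv(index_csv)
    images = []
    for row in idx.itertuples():
        arr = np.asarray(Image.open(row.image_path), dtype=float) / 255.0
        images.append(TrackImage(pixels=arr, label=(str(row.day), str(row.dose)),
                                 fish_id=str(row.fish_id), window_idx=int(row.window_idx)))
    return images
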