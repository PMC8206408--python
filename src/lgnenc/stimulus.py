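"""Binary visual stimulation sequences on a coarse pixel grid.

All generators produce millisecond-resolution binary pixel movies organised
in fixed-length trial blocks: every block shows one spatial pattern turned ON
for ``on_ms`` and OFF for ``off_ms`` (defaults 200/300 ms, i.e. a 2 Hz
cycle).  Four protocols are provided:

* :func:`make_single_pixel` -- one pixel at a time, cycling row-major from
  the top-left to the bottom-right of the grid;
* :func:`make_checkerboard` -- balanced random patterns of several
  simultaneously flickering pixels, every pixel flickering the same total
  number of times;
* :func:`make_full_field` -- the whole grid ON/OFF together;
* :func:`make_shapes` -- full-resolution geometric shapes (rectangle,
  circle, triangle, cross) at one of five canvas locations, to be projected
  onto the coarse grid with :func:`project_to_grid`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, polygon

__all__ = [
    "StimulusSequence",
    "ShapeStimulus",
    "make_single_pixel",
    "make_checkerboard",
    "make_full_field",
    "make_shapes",
    "project_to_grid",
    "bin_stimulus",
]

SHAPE_NAMES = ("rectangle", "circle", "triangle", "cross")
LOCATION_NAMES = ("top-left", "top-right", "bottom-left", "bottom-right", "center")


@dataclass
class StimulusSequence:
    """A binary pixel movie at 1 ms resolution with trial markers.

    Attributes
    ----------
    frames : ndarray of uint8, shape (T, P)
        Pixel intensities per millisecond; entries are 0 or 1. Pixels are
        flattened row-major from the grid.
    grid_shape : (rows, cols)
    on_ms, off_ms : int
        ON/OFF durations of every trial block.
    markers : list of (trial_index, pattern_id, onset_ms)
        One marker per trial block, strictly increasing in onset.
    """

    frames: np.ndarray
    grid_shape: tuple[int, int]
    on_ms: int
    off_ms: int
    markers: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def trial_len_ms(self) -> int:
        return self.on_ms + self.off_ms

    @property
    def n_pixels(self) -> int:
        return int(self.frames.shape[1])

    @property
    def duration_ms(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frequency_hz(self) -> float:
        """Fundamental stimulation frequency, 1000 / (on_ms + off_ms)."""
        return 1000.0 / self.trial_len_ms

    def validate(self) -> None:
        vals = np.unique(self.frames)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("frames must be binary")
        onsets = [m[2] for m in self.markers]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("markers must be strictly increasing in onset_ms")


@dataclass
class ShapeStimulus:
    """Full-resolution shapes sequence stored compactly as pattern masks.

    The per-millisecond movie at canvas resolution would be enormous, so only
    the ``n_patterns`` binary masks plus the presentation ``order`` are kept;
    :func:`project_to_grid` expands the sequence at grid resolution.
    """

    masks: np.ndarray  # (n_patterns, H, W) uint8
    pattern_info: list[tuple[str, str]]  # (shape, location) per pattern
    order: np.ndarray  # pattern index per trial block
    canvas: tuple[int, int]
    on_ms: int
    off_ms: int
    markers: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def trial_len_ms(self) -> int:
        return self.on_ms + self.off_ms

    @property
    def n_patterns(self) -> int:
        return int(self.masks.shape[0])


def _check_durations(on_ms: int, off_ms: int) -> None:
    if on_ms <= 0 or off_ms <= 0:
        raise ValueError(f"durations must be positive, got on_ms={on_ms}, off_ms={off_ms}")


def _assemble(
    patterns: np.ndarray,
    order: np.ndarray,
    on_ms: int,
    off_ms: int,
    grid_shape: tuple[int, int],
) -> StimulusSequence:
    """Expand per-block pattern rows into the millisecond movie."""
    n_blocks = len(order)
    trial_len = on_ms + off_ms
    P = patterns.shape[1]
    movie = np.zeros((n_blocks, trial_len, P), dtype=np.uint8)
    movie[:, :on_ms, :] = patterns[order][:, None, :]
    markers = [(i, int(order[i]), i * trial_len) for i in range(n_blocks)]
    return StimulusSequence(
        frames=movie.reshape(n_blocks * trial_len, P),
        grid_shape=grid_shape,
        on_ms=on_ms,
        off_ms=off_ms,
        markers=markers,
    )


def make_single_pixel(
    grid: tuple[int, int] = (4, 8),
    on_ms: int = 200,
    off_ms: int = 300,
    trials_per_pixel: int = 100,
) -> StimulusSequence:
    """Single-pixel protocol: each pixel flickers ``trials_per_pixel`` times
    consecutively, cycling row-major from top-left to bottom-right.

    The ``pattern_id`` of each trial block is the flattened pixel index.
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {grid}")
    _check_durations(on_ms, off_ms)
    if trials_per_pixel <= 0:
        raise ValueError("trials_per_pixel must be positive")
    P = rows * cols
    patterns = np.eye(P, dtype=np.uint8)
    order = np.repeat(np.arange(P), trials_per_pixel)
    return _assemble(patterns, order, on_ms, off_ms, grid)


def _balanced_patterns(
    P: int, n_patterns: int, pixels_per_pattern: int, rng: np.random.Generator
) -> np.ndarray:
    """Balanced incidence design: each pixel appears in exactly
    ``n_patterns * pixels_per_pattern / P`` patterns, all patterns distinct
    with no pixel repeated within a pattern.  Built by shuffling the balanced
    multiset and resampling until the partition is valid.
    """
    reps = n_patterns * pixels_per_pattern // P
    pool = np.repeat(np.arange(P), reps)
    for _ in range(100_000):
        rng.shuffle(pool)
        groups = pool.reshape(n_patterns, pixels_per_pattern)
        if any(len(set(g)) != pixels_per_pattern for g in groups):
            continue
        keys = {tuple(sorted(g)) for g in groups}
        if len(keys) != n_patterns:
            continue
        patterns = np.zeros((n_patterns, P), dtype=np.uint8)
        for i, g in enumerate(groups):
            patterns[i, g] = 1
        return patterns
    raise RuntimeError("could not sample a valid balanced design (too constrained)")


def make_checkerboard(
    grid: tuple[int, int] = (4, 8),
    n_patterns: int = 32,
    pixels_per_pattern: int = 4,
    trials: int = 100,
    on_ms: int = 200,
    off_ms: int = 300,
    seed: int | None = 0,
) -> StimulusSequence:
    """Balanced checkerboard protocol.

    One pass presents ``n_patterns`` distinct patterns consecutively, each
    lighting ``pixels_per_pattern`` distinct pixels; the pass is repeated for
    ``trials`` passes.  Every pixel is guaranteed to flicker in exactly
    ``n_patterns * pixels_per_pattern / P`` patterns.
    """
    rows, cols = grid
    _check_durations(on_ms, off_ms)
    if trials <= 0 or n_patterns <= 0 or pixels_per_pattern <= 0:
        raise ValueError("trials, n_patterns and pixels_per_pattern must be positive")
    P = rows * cols
    if pixels_per_pattern > P:
        raise ValueError("pixels_per_pattern exceeds number of pixels")
    if (n_patterns * pixels_per_pattern) % P != 0:
        raise ValueError(
            "balance infeasible: n_patterns * pixels_per_pattern "
            f"({n_patterns}*{pixels_per_pattern}) must be divisible by P={P}"
        )
    rng = np.random.default_rng(seed)
    patterns = _balanced_patterns(P, n_patterns, pixels_per_pattern, rng)
    order = np.tile(np.arange(n_patterns), trials)
    return _assemble(patterns, order, on_ms, off_ms, grid)


def make_full_field(
    grid: tuple[int, int] = (4, 8),
    on_ms: int = 200,
    off_ms: int = 300,
    repeats: int = 80,
) -> StimulusSequence:
    """Full-field protocol: all pixels ON together for ``repeats`` cycles."""
    rows, cols = grid
    _check_durations(on_ms, off_ms)
    if repeats <= 0:
        raise ValueError("repeats must be positive")
    patterns = np.ones((1, rows * cols), dtype=np.uint8)
    order = np.zeros(repeats, dtype=int)
    return _assemble(patterns, order, on_ms, off_ms, grid)


def _render_shape(shape: str, canvas: tuple[int, int], location: str) -> np.ndarray:
    """Rasterize one shape on a zero canvas.

    Conventions (fixed defaults, configurable only through the canvas size):
    the shape bounding box is half the canvas in each dimension (quarter
    area); quadrant locations anchor the box in the matching corner, center
    places it mid-canvas; the triangle points up; cross arms are one fifth of
    the box.
    """
    H, W = canvas
    bh, bw = H // 2, W // 2
    offsets = {
        "top-left": (0, 0),
        "top-right": (0, W - bw),
        "bottom-left": (H - bh, 0),
        "bottom-right": (H - bh, W - bw),
        "center": ((H - bh) // 2, (W - bw) // 2),
    }
    if location not in offsets:
        raise ValueError(f"unknown location {location!r}; choose from {LOCATION_NAMES}")
    r0, c0 = offsets[location]
    mask = np.zeros((H, W), dtype=np.uint8)
    if shape == "rectangle":
        mask[r0 : r0 + bh, c0 : c0 + bw] = 1
    elif shape == "circle":
        rad = min(bh, bw) // 2
        rr, cc = disk((r0 + bh / 2, c0 + bw / 2), rad, shape=(H, W))
        mask[rr, cc] = 1
    elif shape == "triangle":
        rr, cc = polygon(
            [r0, r0 + bh - 1, r0 + bh - 1],
            [c0 + bw / 2, c0, c0 + bw - 1],
            shape=(H, W),
        )
        mask[rr, cc] = 1
    elif shape == "cross":
        arm_h, arm_w = max(1, bh // 5), max(1, bw // 5)
        rc, cc_ = r0 + bh // 2, c0 + bw // 2
        mask[rc - arm_h // 2 : rc + (arm_h + 1) // 2, c0 : c0 + bw] = 1
        mask[r0 : r0 + bh, cc_ - arm_w // 2 : cc_ + (arm_w + 1) // 2] = 1
    else:
        raise ValueError(f"unknown shape {shape!r}; choose from {SHAPE_NAMES}")
    return mask


def make_shapes(
    canvas: tuple[int, int] = (900, 1600),
    shapes: tuple[str, ...] = SHAPE_NAMES,
    locations: tuple[str, ...] = LOCATION_NAMES,
    n_patterns: int = 20,
    trials: int = 50,
    on_ms: int = 200,
    off_ms: int = 300,
    seed: int | None = 0,
) -> ShapeStimulus:
    """Geometric-shapes protocol at full canvas resolution.

    Each pattern shows one shape at one location; ``n_patterns`` distinct
    (shape, location) combinations are drawn without replacement and the
    whole sequence is repeated for ``trials`` passes.
    """
    _check_durations(on_ms, off_ms)
    for s in shapes:
        if s not in SHAPE_NAMES:
            raise ValueError(f"unknown shape {s!r}; choose from {SHAPE_NAMES}")
    for loc in locations:
        if loc not in LOCATION_NAMES:
            raise ValueError(f"unknown location {loc!r}; choose from {LOCATION_NAMES}")
    combos = list(itertools.product(shapes, locations))
    if n_patterns > len(combos):
        raise ValueError(
            f"n_patterns={n_patterns} exceeds {len(combos)} distinct shape/location combinations"
        )
    rng = np.random.default_rng(seed)
    chosen = [combos[i] for i in rng.permutation(len(combos))[:n_patterns]]
    masks = np.stack([_render_shape(s, canvas, loc) for s, loc in chosen])
    order = np.tile(np.arange(n_patterns), trials)
    trial_len = on_ms + off_ms
    markers = [(i, int(order[i]), i * trial_len) for i in range(len(order))]
    return ShapeStimulus(
        masks=masks,
        pattern_info=chosen,
        order=order,
        canvas=canvas,
        on_ms=on_ms,
        off_ms=off_ms,
        markers=markers,
    )


def _block_mean(frame: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Mean of each grid block; trailing rows/cols not filling a block are cropped."""
    rows, cols = grid
    H, W = frame.shape
    if H < rows or W < cols:
        raise ValueError(f"canvas {frame.shape} smaller than grid {grid}")
    h, w = H // rows, W // cols
    cropped = frame[: rows * h, : cols * w].astype(float)
    return cropped.reshape(rows, h, cols, w).mean(axis=(1, 3))


def project_to_grid(
    source: np.ndarray | ShapeStimulus,
    grid: tuple[int, int] = (4, 8),
    threshold: float = 0.25,
) -> StimulusSequence:
    """Project full-resolution frames to the coarse grid.

    Each grid cell takes the mean of its canvas block, binarized at
    ``threshold`` (cell is 1 when mean coverage exceeds the threshold).
    Accepts either an ndarray of frames (T, H, W) -- temporal structure
    preserved, no markers -- or a :class:`ShapeStimulus`, whose trial
    structure and markers carry over.
    """
    rows, cols = grid
    if isinstance(source, ShapeStimulus):
        proj = np.stack([_block_mean(m, grid) for m in source.masks])
        patterns = (proj > threshold).astype(np.uint8).reshape(source.n_patterns, rows * cols)
        return _assemble(patterns, source.order, source.on_ms, source.off_ms, grid)
    frames = np.asarray(source)
    if frames.size == 0:
        raise ValueError("empty frames")
    if frames.ndim != 3:
        raise ValueError("expected frames of shape (T, H, W)")
    out = np.stack([_block_mean(f, grid) for f in frames])
    binary = (out > threshold).astype(np.uint8).reshape(len(frames), rows * cols)
    return StimulusSequence(
        frames=binary, grid_shape=grid, on_ms=0, off_ms=0, markers=[]
    )


def bin_stimulus(frames: np.ndarray, w_ms: int) -> np.ndarray:
    """Average 1 ms pixel intensities into w-ms bins (trailing partial bin dropped)."""
    if w_ms <= 0:
        raise ValueError("w_ms must be positive")
    T, P = frames.shape
    n_bins = T // w_ms
    return frames[: n_bins * w_ms].reshape(n_bins, w_ms, P).astype(float).mean(axis=1)
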