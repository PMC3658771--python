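"""Phantom generator: nested sharp-edged intensity plateaus plus uniform noise.

The multipass algorithm assumes images whose informative structure is a
hierarchy of increasingly bright, sharply bounded regions.  These
phantoms realize exactly that structure -- nested squares, concentric
disks, or offset nested blobs at strictly increasing plateau intensities
-- together with the ground-truth nested region masks the pipeline is
expected to recover.  "p% uniform noise" is interpreted as additive
i.i.d. noise uniform on +/- p% of the full 0-255 range, clamped to
[0, 255].  Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["PhantomSpec", "make_nested_phantom", "add_uniform_noise"]

_GEOMETRIES = ("nested_squares", "nested_disks", "offset_blobs")
_FULL_RANGE = 255.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom image.

    Attributes
    ----------
    shape : (int, int)
        Image height and width.
    levels : tuple of float
        Plateau intensities, darkest first, strictly increasing, 2-8 of
        them, on the 0-255 scale.  Level i fills nested region i.
    geometry : str
        One of ``nested_squares``, ``nested_disks``, ``offset_blobs``.
    noise_frac : float
        Amplitude of the additive uniform noise as a fraction of the full
        0-255 range (0.05 = "5% uniform noise"); in [0, 0.5).
    seed : int
        Seed for the noise generator (and blob offsets).
    """

    shape: tuple[int, int] = (128, 128)
    levels: tuple[float, ...] = (40.0, 100.0, 160.0, 220.0)
    geometry: str = "nested_squares"
    noise_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 8 or w < 8:
            raise ParameterError(f"phantom shape must be at least 8x8, got {self.shape}")
        if not 2 <= len(self.levels) <= 8:
            raise ParameterError(f"need 2-8 intensity levels, got {len(self.levels)}")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ParameterError(f"levels must be strictly increasing, got {self.levels}")
        if not 0 <= self.noise_frac < 0.5:
            raise ParameterError(f"noise_frac must be in [0, 0.5), got {self.noise_frac}")
        if self.geometry not in _GEOMETRIES:
            raise ParameterError(
                f"unknown geometry {self.geometry!r}; expected one of {_GEOMETRIES}"
            )


def add_uniform_noise(image, frac: float, seed: int) -> np.ndarray:
    """Add i.i.d. uniform noise on [-frac*255, +frac*255], clamped to [0, 255]."""
    if frac < 0:
        raise ParameterError(f"noise fraction must be non-negative, got {frac}")
    img = np.asarray(image, dtype=float)
    if frac == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    amp = frac * _FULL_RANGE
    return np.clip(img + rng.uniform(-amp, amp, size=img.shape), 0.0, _FULL_RANGE)


def _square_masks(shape: tuple[int, int], n: int) -> list[np.ndarray]:
    h, w = shape
    step = min(h, w) // (2 * n)
    if step < 2 or min(h, w) - 2 * (n - 1) * step < 8:
        raise ParameterError(f"shape {shape} too small for {n} nested squares")
    masks = [np.ones(shape, dtype=bool)]
    for i in range(1, n):
        m = np.zeros(shape, dtype=bool)
        margin = i * step
        m[margin : h - margin, margin : w - margin] = True
        masks.append(m)
    return masks


def _disk_masks(shape: tuple[int, int], n: int, offsets=None) -> list[np.ndarray]:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    r_outer = (min(h, w) - 2) / 2.0
    radii = [r_outer * (n - i) / n for i in range(1, n)]
    if radii and radii[-1] < 4:
        raise ParameterError(f"shape {shape} too small for {n} nested disks")
    masks = [np.ones(shape, dtype=bool)]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    for i, r in enumerate(radii):
        c = center + (offsets[i] if offsets is not None else 0.0)
        masks.append((rr - c[0]) ** 2 + (cc - c[1]) ** 2 <= r * r)
    return masks


def _blob_offsets(shape: tuple[int, int], n: int, seed: int) -> np.ndarray:
    """Seeded per-level center offsets that keep the disks strictly nested."""
    rng = np.random.default_rng(seed + 1)
    r_outer = (min(shape) - 2) / 2.0
    gap = r_outer / n  # radius decrement between consecutive disks
    offsets = np.zeros((n - 1, 2))
    drift = np.zeros(2)
    for i in range(n - 1):
        theta = rng.uniform(0, 2 * np.pi)
        drift = drift + 0.4 * gap * np.array([np.cos(theta), np.sin(theta)])
        offsets[i] = drift
    return offsets


def make_nested_phantom(spec: PhantomSpec) -> tuple[np.ndarray, list[np.ndarray]]:
    """Build the phantom image and its ground-truth nested region masks.

    Returns
    -------
    image : 2-D float array
        Piecewise-constant plateaus at ``spec.levels`` plus uniform noise.
    masks : list of bool arrays
        ``masks[i]`` marks the region at intensity level i *and brighter*;
        ``masks[0]`` is the full domain and the masks are strictly nested.
    """
    n = len(spec.levels)
    if spec.geometry == "nested_squares":
        masks = _square_masks(spec.shape, n)
    elif spec.geometry == "nested_disks":
        masks = _disk_masks(spec.shape, n)
    else:
        masks = _disk_masks(spec.shape, n, offsets=_blob_offsets(spec.shape, n, spec.seed))
    clean = np.full(spec.shape, float(spec.levels[0]))
    for level, m in zip(spec.levels[1:], masks[1:]):
        clean[m] = float(level)
    return add_uniform_noise(clean, spec.noise_frac, spec.seed), masks
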