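"""Synthetic visual stimuli.

Every experiment in this package runs on stimuli built here: disk-and-ring
(DAR) matching displays, square-wave gratings carrying gray test bars
(lightness-assimilation stimuli), constant fields, and synthetic
high-dynamic-range radiance maps with natural-image statistics (a power-law
spatial spectrum and a lognormal, heavily right-skewed luminance histogram).

Images are plain 2-D ``float64`` numpy arrays, row-major, origin at the
top-left, pixel-centred integer coordinates, nominal range [0, 1].  Radiance
maps are nonnegative floats on an arbitrary linear scale.  All generators are
pure functions of their parameters (plus an integer seed where randomness is
involved), so reruns are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "DarGeometry",
    "GratingSpec",
    "BarGrating",
    "make_constant",
    "make_dar_display",
    "dar_masks",
    "make_bar_grating",
    "make_synthetic_hdr",
]


def _check_lum(name: str, v: float) -> None:
    if not np.isfinite(v) or not (0.0 <= v <= 1.0):
        raise ValueError(f"{name} must be a finite luminance in [0, 1], got {v!r}")


@dataclass(frozen=True)
class DarGeometry:
    """Disk-and-ring matching display.

    Two mirror configurations on a uniform background ``B``: the *match*
    pattern on the left (disk ``D_M`` inside ring ``R_M``) and the *test*
    pattern on the right (disk ``D_T`` inside ring ``R_T``).  Centers are
    (row, col) pixel coordinates.
    """

    image_height: int
    image_width: int
    disk_radius: float
    ring_width: float
    left_center: tuple[float, float]
    right_center: tuple[float, float]
    B: float
    D_T: float
    R_T: float
    D_M: float
    R_M: float

    def __post_init__(self) -> None:
        if self.disk_radius <= 0 or self.ring_width <= 0:
            raise ValueError("disk_radius and ring_width must be positive")
        for name in ("B", "D_T", "R_T", "D_M", "R_M"):
            _check_lum(name, getattr(self, name))
        r_out = self.disk_radius + self.ring_width
        for cy, cx in (self.left_center, self.right_center):
            if not (r_out <= cy <= self.image_height - 1 - r_out
                    and r_out <= cx <= self.image_width - 1 - r_out):
                raise ValueError("disk+ring annulus does not fit inside the image")
        dy = self.left_center[0] - self.right_center[0]
        dx = self.left_center[1] - self.right_center[1]
        if float(np.hypot(dy, dx)) <= 2 * r_out:
            raise ValueError("left and right disk+ring configurations overlap")

    def with_values(self, **lum: float) -> "DarGeometry":
        """Copy of the geometry with some of B/D_T/R_T/D_M/R_M replaced."""
        from dataclasses import replace

        return replace(self, **lum)


@dataclass(frozen=True)
class GratingSpec:
    """Square-wave grating with gray test bars.

    The background alternates black (0) and white (1) vertical stripes of
    width ``stripe_period // 2``.  Inside the horizontal band ``band_rows``
    (a half-open row range), gray bars of luminance ``bar_value`` and width
    ``bar_width`` are centred in the black stripes on the left half of the
    image and in the white stripes on the right half, so the two bar
    populations share one luminance but opposite surrounds.
    """

    height: int
    width: int
    stripe_period: int
    bar_value: float
    bar_width: int
    band_rows: tuple[int, int]

    def __post_init__(self) -> None:
        if self.stripe_period < 2 or self.stripe_period % 2:
            raise ValueError("stripe_period must be an even integer >= 2")
        if not (0.0 < self.bar_value < 1.0):
            raise ValueError("bar_value must be strictly between 0 and 1")
        if not (0 < self.bar_width < self.stripe_period // 2):
            raise ValueError("bar_width must be positive and narrower than a stripe")
        r0, r1 = self.band_rows
        if not (0 <= r0 < r1 <= self.height):
            raise ValueError("band_rows must be a nonempty row range inside the image")


class BarGrating(NamedTuple):
    image: np.ndarray
    bars_on_black: np.ndarray  # boolean mask
    bars_on_white: np.ndarray  # boolean mask


def make_constant(height: int, width: int, value: float) -> np.ndarray:
    """Constant field of the given luminance."""
    _check_lum("value", value)
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be positive")
    return np.full((height, width), float(value))


def _dar_distance(geom: DarGeometry, center: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0 : geom.image_height, 0 : geom.image_width]
    return np.hypot(yy - center[0], xx - center[1])


def dar_masks(geom: DarGeometry) -> dict[str, np.ndarray]:
    """Boolean region masks partitioning the display.

    Disk membership is Euclidean distance <= disk_radius from the centre;
    the ring is disk_radius < distance <= disk_radius + ring_width.  No
    anti-aliasing, so every region is an exact constant in the display.
    """
    d_left = _dar_distance(geom, geom.left_center)
    d_right = _dar_distance(geom, geom.right_center)
    r, w = geom.disk_radius, geom.ring_width
    masks = {
        "left_disk": d_left <= r,
        "left_ring": (d_left > r) & (d_left <= r + w),
        "right_disk": d_right <= r,
        "right_ring": (d_right > r) & (d_right <= r + w),
    }
    masks["background"] = ~(
        masks["left_disk"] | masks["left_ring"] | masks["right_disk"] | masks["right_ring"]
    )
    return masks


def make_dar_display(geom: DarGeometry) -> np.ndarray:
    """Render the disk-and-ring display as a grayscale image."""
    masks = dar_masks(geom)
    img = np.full((geom.image_height, geom.image_width), float(geom.B))
    img[masks["left_disk"]] = geom.D_M
    img[masks["left_ring"]] = geom.R_M
    img[masks["right_disk"]] = geom.D_T
    img[masks["right_ring"]] = geom.R_T
    return img


def make_bar_grating(spec: GratingSpec) -> BarGrating:
    """Render the assimilation grating and the two bar masks."""
    half = spec.stripe_period // 2
    img = np.zeros((spec.height, spec.width))
    cols = np.arange(spec.width)
    stripe_idx = cols // half
    white = stripe_idx % 2 == 1
    img[:, white] = 1.0

    bars_black = np.zeros_like(img, dtype=bool)
    bars_white = np.zeros_like(img, dtype=bool)
    r0, r1 = spec.band_rows
    n_stripes = spec.width // half
    for k in range(n_stripes):
        c0, c1 = k * half, (k + 1) * half
        if c1 > spec.width:
            break
        on_left = c1 <= spec.width // 2
        on_right = c0 >= spec.width // 2
        is_black = k % 2 == 0
        if (is_black and on_left) or ((not is_black) and on_right):
            center = c0 + half // 2
            b0 = center - spec.bar_width // 2
            b1 = b0 + spec.bar_width
            mask = bars_black if is_black else bars_white
            mask[r0:r1, b0:b1] = True

    if not bars_black.any() or not bars_white.any():
        raise ValueError("grating too narrow: one of the bar populations is empty")
    img[bars_black] = spec.bar_value
    img[bars_white] = spec.bar_value
    return BarGrating(img, bars_black, bars_white)


def make_synthetic_hdr(
    height: int,
    width: int,
    spectral_exponent: float = 2.0,
    log_std: float = 1.5,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic radiance map with natural-image statistics.

    A Gaussian random field with radially averaged power spectrum
    proportional to ``1/f**spectral_exponent`` is synthesised in the Fourier
    domain (white noise shaped by ``f**(-e/2)``, DC removed), standardised to
    mean 0 and standard deviation ``log_std``, and exponentiated.  The result
    has a lognormal single-pixel luminance distribution -- the strongly
    right-skewed ("lopsided") histogram typical of linear-light natural
    scenes -- and an approximately power-law spatial spectrum in the log
    domain.  ``log_std = 0`` yields the constant map 1.
    """
    if spectral_exponent < 0 or log_std < 0:
        raise ValueError("spectral_exponent and log_std must be nonnegative")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((height, width))
    F = np.fft.fft2(white)
    fy = np.fft.fftfreq(height) * height
    fx = np.fft.fftfreq(width) * width
    radius = np.hypot(fy[:, None], fx[None, :])
    with np.errstate(divide="ignore"):
        amp = np.where(radius > 0, radius ** (-spectral_exponent / 2.0), 0.0)
    G = np.fft.ifft2(F * amp).real
    sd = G.std()
    if log_std > 0 and sd > 0:
        G = (G - G.mean()) / sd * log_std
    else:
        G = np.zeros_like(G)
    return np.exp(G)
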