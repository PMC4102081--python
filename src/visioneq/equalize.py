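"""Histogram equalization: look-up-table and variational.

Two routes to a flat histogram.  The classical one substitutes each gray
level ``g`` by the value of the image's normalized cumulative histogram
``H(g)``, computed in one shot through a look-up table.  The variational one
descends the global equalization energy

    E(I) = 2 * sum_x (I(x) - 1/2)^2  -  (1/(A*B)) * sum_x sum_y |I(x) - I(y)|

whose minimiser has a flat histogram: the first term penalises dispersion
around middle gray (the gray-world anchor), the second rewards global
contrast.  Descending E step by step gives a whole family of partially
equalized images; run to convergence it reproduces the LUT result up to
discretisation.  The double sum runs over ordered pixel pairs, so the descent
update for pixel x is

    I(x) <- I(x) + dt * ( -4*(I(x) - 1/2) + (2/(A*B)) * sum_y sgn(I(x) - I(y)) )

with sgn(0) = 0.  The global sign sum is evaluated exactly in O(N log N) by
ranking: sum_y sgn(I(x)-I(y)) = #{y: I(y) < I(x)} - #{y: I(y) > I(x)}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Histogram",
    "image_histogram",
    "lut_equalize",
    "equalization_energy",
    "variational_equalize",
    "histogram_flatness",
]


def _check_unit_range(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return img


@dataclass(frozen=True)
class Histogram:
    """Binned histogram of a [0,1] image with its normalized cumulative."""

    bin_edges: np.ndarray  # nbins+1 edges partitioning [0, 1]
    counts: np.ndarray     # integer counts per bin
    cumulative: np.ndarray  # H at each bin's upper edge; H[-1] == 1


def _bin_index(img: np.ndarray, nbins: int) -> np.ndarray:
    # half-open bins [k/nbins, (k+1)/nbins), last bin closed at 1
    return np.minimum((img * nbins).astype(int), nbins - 1)


def image_histogram(img: np.ndarray, nbins: int = 256) -> Histogram:
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    img = _check_unit_range(img)
    counts = np.bincount(_bin_index(img, nbins).ravel(), minlength=nbins)
    cum = np.cumsum(counts) / img.size
    edges = np.linspace(0.0, 1.0, nbins + 1)
    return Histogram(edges, counts, cum)


def lut_equalize(img: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Replace each level g by the normalized cumulative histogram H(g)."""
    img = _check_unit_range(img)
    hist = image_histogram(img, nbins)
    return hist.cumulative[_bin_index(img, nbins)]


def equalization_energy(img: np.ndarray) -> float:
    """The global equalization energy E(I), exactly, in O(N log N).

    The all-pairs absolute-difference sum over ordered pairs equals
    ``2 * sum_i (2i + 1 - N) * v_i`` for sorted values ``v_0 <= ... <= v_{N-1}``.
    """
    v = np.sort(np.asarray(img, dtype=float).ravel())
    n = v.size
    pair_sum = 2.0 * np.sum((2.0 * np.arange(n) + 1.0 - n) * v)
    return float(2.0 * np.sum((v - 0.5) ** 2) - pair_sum / n)


def _rank_sign_sum(img: np.ndarray) -> np.ndarray:
    """Per-pixel #{smaller} - #{larger}, ties contributing zero."""
    flat = img.ravel()
    uniq, inv, counts = np.unique(flat, return_inverse=True, return_counts=True)
    cum = np.cumsum(counts)
    less = cum - counts
    greater = flat.size - cum
    return (less - greater)[inv].reshape(img.shape).astype(float)


def variational_equalize(
    img: np.ndarray,
    dt: float = 0.05,
    steps: int | None = None,
    tol: float = 1e-6,
    max_steps: int = 5000,
    track_energy: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Explicit gradient descent on the equalization energy.

    Iterates the descent update with values clamped back to [0, 1] after each
    step (for ``dt < 1/2`` the update never leaves the box, so the clamp is a
    safeguard only).  Stops after ``steps`` iterations if given, else when the
    maximum absolute per-step change drops below ``tol`` or at ``max_steps``.
    Returns the final image and a per-step trace (step, energy, max_change).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    I = _check_unit_range(img).copy()
    n = I.size
    rows = []
    n_steps = steps if steps is not None else max_steps
    for it in range(n_steps):
        s = _rank_sign_sum(I)
        new = I + dt * (-4.0 * (I - 0.5) + 2.0 * s / n)
        np.clip(new, 0.0, 1.0, out=new)
        if not np.all(np.isfinite(new)):
            raise FloatingPointError("variational equalization diverged")
        max_change = float(np.abs(new - I).max())
        I = new
        rows.append(
            {
                "step": it + 1,
                "energy": equalization_energy(I) if track_energy else np.nan,
                "max_change": max_change,
            }
        )
        if steps is None and max_change < tol:
            break
    return I, pd.DataFrame(rows)


def histogram_flatness(img: np.ndarray, nbins: int = 256) -> float:
    """Normalized Shannon entropy of the gray-level histogram, in [0, 1].

    1 means a perfectly flat (equalized) histogram, 0 a single occupied
    level.  Values are clipped into [0, 1] before binning so the metric is
    defined for model outputs that overshoot the nominal range slightly.
    """
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    vals = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    counts, _ = np.histogram(vals, bins=nbins, range=(0.0, 1.0))
    p = counts[counts > 0] / vals.size
    return float(-(p * np.log(p)).sum() / np.log(nbins))
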