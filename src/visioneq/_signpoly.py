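"""Sign-type nonlinearities for the contrast term, and odd-polynomial fits.

The nonlocal contrast term sums a sign-type response of pixel differences
against a spatial kernel.  The discontinuous sign itself makes uniform
regions of the flows linearly unstable at any useful contrast weight (its
infinite slope at zero turns the term into an unbounded anti-diffusion), so
the response the flows use is the saturating ramp

    s(d) = clip(slope * d, -1, 1)

an odd, sigmoid-like function that agrees with sgn for large differences
and is graded near zero; uniform regions are then stable whenever
``gamma * (1 + sigma^c) * slope < alpha + beta``.  The true sign remains
available as an oracle (``response="sign"`` in exact mode).

For large images the ramp is replaced by a fixed odd polynomial p fitted to
it by discrete minimax (linear programming) on [-1, 1]; the binomial
expansion of p(I(x) - I(y)) turns the kernel sum into a handful of
convolutions of powers of I.  At the default degree 9 and slope 2 the fit
error is about 0.027.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "DEFAULT_DEGREE",
    "DEFAULT_SLOPE",
    "ramp",
    "ramp_antiderivative",
    "sign_poly",
    "sign_poly_error",
    "eval_odd_poly",
    "expand_binomial",
    "antiderivative_coeffs",
]

DEFAULT_DEGREE = 9
DEFAULT_SLOPE = 2.0


def ramp(d: np.ndarray, slope: float = DEFAULT_SLOPE) -> np.ndarray:
    """Saturating ramp response clip(slope * d, -1, 1)."""
    return np.clip(slope * np.asarray(d, dtype=float), -1.0, 1.0)


def ramp_antiderivative(d: np.ndarray, slope: float = DEFAULT_SLOPE) -> np.ndarray:
    """R(d) = integral_0^d s: the smooth |d|-type potential of the ramp."""
    d = np.abs(np.asarray(d, dtype=float))
    knee = 1.0 / slope
    return np.where(d <= knee, 0.5 * slope * d * d, d - 0.5 * knee)


@lru_cache(maxsize=None)
def _fit(degree: int, slope: float, npts: int = 800) -> tuple[tuple[float, ...], float]:
    if degree < 3 or degree % 2 == 0:
        raise ValueError("sign_degree must be an odd integer >= 3")
    if slope <= 0:
        raise ValueError("saturation slope must be positive")
    theta = np.linspace(0.0, np.pi, npts)
    t = 0.5 * (1.0 - np.cos(theta))  # Chebyshev-distributed on [0, 1]
    target = np.clip(slope * t, -1.0, 1.0)
    odd_powers = np.arange(1, degree + 1, 2)
    V = t[:, None] ** odd_powers[None, :]
    ncoef = odd_powers.size
    c = np.zeros(ncoef + 1)
    c[-1] = 1.0
    A_ub = np.vstack(
        [
            np.hstack([V, -np.ones((npts, 1))]),
            np.hstack([-V, -np.ones((npts, 1))]),
        ]
    )
    b_ub = np.concatenate([target, -target])
    bounds = [(None, None)] * ncoef + [(0.0, None)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"minimax ramp fit failed: {res.message}")
    return tuple(float(a) for a in res.x[:ncoef]), float(res.x[-1])


def sign_poly(degree: int = DEFAULT_DEGREE, slope: float = DEFAULT_SLOPE) -> dict[int, float]:
    """Coefficients {power: coefficient} of the odd polynomial surrogate."""
    coeffs, _ = _fit(degree, slope)
    return {int(k): a for k, a in zip(range(1, degree + 1, 2), coeffs)}


def sign_poly_error(degree: int = DEFAULT_DEGREE, slope: float = DEFAULT_SLOPE) -> float:
    """Achieved minimax error of the polynomial against the ramp on [-1, 1]."""
    _, eps = _fit(degree, slope)
    return eps


def eval_odd_poly(d: np.ndarray, coeffs: dict[int, float]) -> np.ndarray:
    """Evaluate the fitted polynomial for an arbitrary array of differences."""
    out = np.zeros_like(np.asarray(d, dtype=float))
    for k, a in coeffs.items():
        out += a * d**k
    return out


def antiderivative_coeffs(coeffs: dict[int, float]) -> dict[int, float]:
    """Coefficients of P(d) = integral_0^d p (even polynomial, P(0) = 0)."""
    return {k + 1: a / (k + 1) for k, a in coeffs.items()}


def expand_binomial(coeffs: dict[int, float]) -> dict[tuple[int, int], float]:
    """Expand sum_m a_m (u - v)^m into {(i, j): coefficient of u^i v^j}.

    Used to turn sum_y w(x,y) p(I(x) - I(y)) into
    sum_j [sum_i c_{ij} I(x)^i] * (w * I^j)(x).
    """
    out: dict[tuple[int, int], float] = {}
    for m, a in coeffs.items():
        for j in range(m + 1):
            key = (m - j, j)
            out[key] = out.get(key, 0.0) + a * comb(m, j) * (-1.0) ** j
    return out
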