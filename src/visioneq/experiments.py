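"""Experiment harness: induction matching, spectra and efficiency metrics.

Disk-and-ring (DAR) matching.  The test pattern (right disk D_T inside ring
R_T) is compared with the match pattern (left disk D_M inside ring R_M) on a
shared background B.  For each R_T the model is run to steady state on the
display and probed at the centre of the right disk, the middle of the right
ring and the middle of the left ring; the predicted perceived lightness of
the match disk is

    perceived_D_M = perceived_D_T - perceived_R_T + perceived_R_M

and the physical match luminance is recovered by inverting the (monotone)
map from the left-disk luminance to its steady-state probe value.  Plotting
matched D_M against R_T and fitting a parabola quantifies the induction
regime: negative curvature with an initial rising branch is assimilation
turning into contrast; a straight falling line is pure contrast.

Grating induction index: difference between the mean steady-state values of
the gray bars lying on black stripes and on white stripes.  Positive index
means lightness contrast, negative means assimilation; the input grating has
index 0 by construction.

Spectrum whitening.  The rotational average of the power spectrum of natural
images falls roughly as 1/f^2; a log-log line fit gives its slope.  The
whitening gain W of a transformation is the output slope minus the input
slope (W > 0: flatter, more decorrelated output).  Sweeping the contrast
exponent c of the induction flow traces the curve W(c) and its interior
optimum c*.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import ModelParams, evolve_base, evolve_induction
from .stimuli import DarGeometry, make_dar_display

__all__ = [
    "DarPrediction",
    "QuadraticFit",
    "RadialSpectrum",
    "WhiteningCurve",
    "InversionResult",
    "sample_probe",
    "dar_probe_points",
    "invert_disk_luminance",
    "calibrate_match_probe",
    "predict_dar_match",
    "fit_quadratic",
    "linear_fit",
    "grating_induction_index",
    "radial_power_spectrum",
    "loglog_slope",
    "whitening_gain",
    "sweep_whitening",
]


# --------------------------------------------------------------------------
# probes and the DAR matching procedure


def sample_probe(img: np.ndarray, point: tuple[float, float], probe_radius: float = 1.0) -> float:
    """Mean of the image over pixels within ``probe_radius`` of ``point``."""
    h, w = img.shape
    cy, cx = point
    if not (probe_radius <= cy <= h - 1 - probe_radius and probe_radius <= cx <= w - 1 - probe_radius):
        raise ValueError("probe disk extends outside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.hypot(yy - cy, xx - cx) <= probe_radius
    return float(img[mask].mean())


def dar_probe_points(geom: DarGeometry) -> dict[str, tuple[float, float]]:
    """Probe locations: disk centres and ring middles (outward, horizontal)."""
    mid = geom.disk_radius + geom.ring_width / 2.0
    ly, lx = geom.left_center
    ry, rx = geom.right_center
    return {
        "left_disk": (ly, lx),
        "left_ring": (ly, lx - mid),
        "right_disk": (ry, rx),
        "right_ring": (ry, rx + mid),
    }


def _steady(img: np.ndarray, params: ModelParams, model: str, init: np.ndarray | None):
    if model == "induction":
        return evolve_induction(img, params, init=init)
    if model == "base":
        return evolve_base(img, params, init=init)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class InversionResult:
    luminance: float
    at_bracket_edge: bool  # target outside the attainable probe range
    n_evaluations: int


def invert_disk_luminance(
    target_perceived: float,
    geom: DarGeometry,
    params: ModelParams,
    model: str = "induction",
    bracket: tuple[float, float] = (0.0, 1.0),
    probe_radius: float = 1.0,
    probe_tol: float = 1e-4,
    bracket_tol: float = 1e-5,
    warm_start: np.ndarray | None = None,
) -> InversionResult:
    """Recover the match-disk luminance producing a target perceived value.

    Bisects the map D_M -> steady-state probe value at the left-disk centre,
    which is checked to be increasing over the bracket; stops when the probe
    is within ``probe_tol`` of the target or the bracket is narrower than
    ``bracket_tol``.  Targets outside the attainable range return the nearer
    bracket endpoint with ``at_bracket_edge`` set.  Consecutive evaluations
    reuse the previous steady state as the iteration start (continuation),
    which does not change the fixed point but reaches it in far fewer steps.
    """
    point = dar_probe_points(geom)["left_disk"]
    state = warm_start
    n_eval = 0

    def probe_at(dm: float) -> float:
        nonlocal state, n_eval
        img = make_dar_display(geom.with_values(D_M=dm))
        state, _ = _steady(img, params, model, init=state)
        n_eval += 1
        return sample_probe(state, point, probe_radius)

    lo, hi = bracket
    p_lo = probe_at(lo)
    p_hi = probe_at(hi)
    if p_lo >= p_hi:
        raise RuntimeError(
            "left-disk probe is not increasing over the bracket: "
            f"probe({lo}) = {p_lo:.5f} >= probe({hi}) = {p_hi:.5f}"
        )
    if target_perceived <= p_lo:
        return InversionResult(lo, True, n_eval)
    if target_perceived >= p_hi:
        return InversionResult(hi, True, n_eval)
    while hi - lo > bracket_tol:
        mid = 0.5 * (lo + hi)
        p_mid = probe_at(mid)
        if abs(p_mid - target_perceived) < probe_tol:
            return InversionResult(mid, False, n_eval)
        if p_mid < target_perceived:
            lo = mid
        else:
            hi = mid
    return InversionResult(0.5 * (lo + hi), False, n_eval)


@dataclass
class DarPrediction:
    R_T: float
    perceived_D_T: float
    perceived_R_T: float
    perceived_R_M: float
    perceived_D_M: float  # = perceived_D_T - perceived_R_T + perceived_R_M
    matched_D_M: float
    inversion_flagged: bool


def calibrate_match_probe(
    geom: DarGeometry,
    params: ModelParams,
    model: str = "induction",
    n_points: int = 17,
    probe_radius: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Left-disk probe value as a function of the match luminance D_M.

    Evaluates the steady-state probe on an even D_M grid (continuing each
    run from the previous steady state) and checks monotonicity.  Because
    the two display halves are farther apart than any neighborhood reach,
    this calibration is independent of R_T and can be shared by a whole
    sweep.
    """
    point = dar_probe_points(geom)["left_disk"]
    dm_grid = np.linspace(0.0, 1.0, n_points)
    state = None
    vals = []
    for dm in dm_grid:
        img = make_dar_display(geom.with_values(D_M=float(dm)))
        state, _ = _steady(img, params, model, init=state)
        vals.append(sample_probe(state, point, probe_radius))
    cal = np.array(vals)
    if np.any(np.diff(cal) <= 0):
        raise RuntimeError("left-disk probe is not increasing in D_M; cannot calibrate")
    return dm_grid, cal


def predict_dar_match(
    geom_template: DarGeometry,
    R_T_values,
    params: ModelParams,
    model: str = "induction",
    probe_radius: float = 1.0,
    inversion: str = "bisect",
) -> list[DarPrediction]:
    """Predicted match luminance for each test-ring luminance R_T.

    For each R_T the display is rebuilt, the selected flow run to steady
    state, the three probes read, combined into the perceived match value,
    and inverted back to a physical luminance.  Successive sweep points
    continue from the previous steady state.  ``inversion="bisect"`` solves
    each point with :func:`invert_disk_luminance`; ``"calibrate"`` inverts
    through one shared monotone calibration curve
    (:func:`calibrate_match_probe`), which is several times faster and
    accurate to the calibration grid's interpolation error.
    """
    if inversion not in ("bisect", "calibrate"):
        raise ValueError(f"unknown inversion strategy {inversion!r}")
    points = dar_probe_points(geom_template)
    if inversion == "calibrate":
        dm_grid, cal = calibrate_match_probe(
            geom_template, params, model=model, probe_radius=probe_radius
        )
    preds: list[DarPrediction] = []
    state: np.ndarray | None = None
    for rt in R_T_values:
        if not (0.0 <= rt <= 1.0):
            raise ValueError(f"R_T value {rt!r} outside [0, 1]")
        geom = geom_template.with_values(R_T=float(rt))
        img = make_dar_display(geom)
        state, _ = _steady(img, params, model, init=state)
        p_dt = sample_probe(state, points["right_disk"], probe_radius)
        p_rt = sample_probe(state, points["right_ring"], probe_radius)
        p_rm = sample_probe(state, points["left_ring"], probe_radius)
        target = p_dt - p_rt + p_rm
        if inversion == "bisect":
            inv = invert_disk_luminance(
                target, geom, params, model=model, probe_radius=probe_radius, warm_start=state
            )
            matched, flagged = inv.luminance, inv.at_bracket_edge
        else:
            flagged = not (cal[0] <= target <= cal[-1])
            matched = float(np.interp(target, cal, dm_grid))
        preds.append(
            DarPrediction(
                R_T=float(rt),
                perceived_D_T=p_dt,
                perceived_R_T=p_rt,
                perceived_R_M=p_rm,
                perceived_D_M=target,
                matched_D_M=matched,
                inversion_flagged=flagged,
            )
        )
    return preds


# --------------------------------------------------------------------------
# curve fitting and the grating index


@dataclass
class QuadraticFit:
    a: float
    b: float
    c0: float
    curvature: float  # 2a
    r_squared: float


def fit_quadratic(x, y) -> QuadraticFit:
    """Ordinary least squares of y on (x^2, x, 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points for a quadratic fit")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal (rank-deficient design)")
    coef = np.polyfit(x, y, 2)
    resid = y - np.polyval(coef, x)
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else 1.0
    a, b, c0 = (float(v) for v in coef)
    return QuadraticFit(a=a, b=b, c0=c0, curvature=2.0 * a, r_squared=r2)


def linear_fit(x, y) -> tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else 1.0
    return float(slope), float(intercept), r2


def grating_induction_index(
    result: np.ndarray, bars_on_black: np.ndarray, bars_on_white: np.ndarray
) -> float:
    """mean(result | bars on black) - mean(result | bars on white).

    Positive: contrast regime (bars on dark surrounds look/end lighter);
    negative: assimilation.  Zero for the input grating itself.
    """
    if not bars_on_black.any() or not bars_on_white.any():
        raise ValueError("bar masks must be nonempty")
    if (bars_on_black & bars_on_white).any():
        raise ValueError("bar masks must be disjoint")
    return float(result[bars_on_black].mean() - result[bars_on_white].mean())


# --------------------------------------------------------------------------
# spectra and whitening


@dataclass
class RadialSpectrum:
    freq: np.ndarray   # integer annulus radii, cycles per image
    power: np.ndarray  # mean squared Fourier magnitude per annulus
    fit_range: tuple[float, float]


def radial_power_spectrum(img: np.ndarray, window: str = "hann") -> RadialSpectrum:
    """Rotational average of the power spectrum.

    The mean is removed, an optional 2-D Hann window applied (reduces
    leakage from the non-periodic borders), and squared FFT magnitudes are
    averaged over annuli of integer-rounded radius in frequency pixels.  The
    default fit range [4, min(h, w)/4] excludes DC, the lowest scalloped
    bins and the Nyquist fold.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    if min(h, w) < 16:
        raise ValueError("image must be at least 16x16 for a radial spectrum")
    f = img - img.mean()
    if window == "hann":
        f = f * np.outer(np.hanning(h), np.hanning(w))
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    P = np.abs(np.fft.fft2(f)) ** 2
    fy = np.fft.fftfreq(h) * h
    fx = np.fft.fftfreq(w) * w
    r = np.rint(np.hypot(fy[:, None], fx[None, :])).astype(int)
    rmax = min(h, w) // 2
    sel = r <= rmax
    counts = np.bincount(r[sel].ravel(), minlength=rmax + 1)
    sums = np.bincount(r[sel].ravel(), weights=P[sel].ravel(), minlength=rmax + 1)
    power = sums / np.maximum(counts, 1)
    freq = np.arange(rmax + 1)
    return RadialSpectrum(freq=freq, power=power, fit_range=(4.0, min(h, w) / 4.0))


def loglog_slope(spec: RadialSpectrum, f_min: float | None = None, f_max: float | None = None) -> float:
    """Least-squares slope of log power against log frequency."""
    lo = spec.fit_range[0] if f_min is None else f_min
    hi = spec.fit_range[1] if f_max is None else f_max
    sel = (spec.freq >= lo) & (spec.freq <= hi) & (spec.freq > 0)
    if sel.sum() < 5:
        raise ValueError("need at least 5 frequency bins inside the fit range")
    p = spec.power[sel]
    if np.any(p <= 0):
        raise ValueError("nonpositive power inside the fit range; try window='hann'")
    slope, _, _ = linear_fit(np.log(spec.freq[sel]), np.log(p))
    return slope


def whitening_gain(
    img_in: np.ndarray,
    img_out: np.ndarray,
    f_min: float | None = None,
    f_max: float | None = None,
    window: str = "hann",
) -> float:
    """W = slope(output spectrum) - slope(input spectrum) over one fit range.

    Positive W means the output spectrum is flatter (whitened) relative to
    the input.
    """
    if img_in.shape != img_out.shape:
        raise ValueError("images must share a shape")
    s_in = loglog_slope(radial_power_spectrum(img_in, window), f_min, f_max)
    s_out = loglog_slope(radial_power_spectrum(img_out, window), f_min, f_max)
    return s_out - s_in


@dataclass
class WhiteningCurve:
    c_grid: np.ndarray
    W: np.ndarray
    slope_in: float
    slope_out: np.ndarray
    c_star: float
    W_star: float


def sweep_whitening(
    I0: np.ndarray,
    c_grid,
    params: ModelParams,
    f_range: tuple[float, float] | None = None,
    exclude_below: float = 0.05,
    window: str = "hann",
) -> WhiteningCurve:
    """Whitening gain of the induction flow as a function of the exponent c.

    Runs the flow on I0 (normally a Naka-Rushton output) for every c in the
    grid and measures W(c).  ``c_star`` is the argmax after discarding the
    low-c zone ``c < exclude_below``, where the curve is unreliable; if the
    whole grid lies in the excluded zone the argmax is over everything.
    """
    c_grid = np.asarray(sorted(float(c) for c in c_grid))
    if c_grid.size == 0:
        raise ValueError("c_grid must be nonempty")
    spec_in = radial_power_spectrum(I0, window)
    fmin, fmax = f_range if f_range is not None else (None, None)
    s_in = loglog_slope(spec_in, fmin, fmax)
    slopes = np.empty_like(c_grid)
    for i, c in enumerate(c_grid):
        out, _ = evolve_induction(I0, replace(params, c=c))
        slopes[i] = loglog_slope(radial_power_spectrum(out, window), fmin, fmax)
    W = slopes - s_in
    valid = c_grid >= exclude_below
    if not valid.any():
        valid = np.ones_like(valid)
    idx = np.flatnonzero(valid)[np.argmax(W[valid])]
    return WhiteningCurve(
        c_grid=c_grid,
        W=W,
        slope_in=s_in,
        slope_out=slopes,
        c_star=float(c_grid[idx]),
        W_star=float(W[idx]),
    )
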