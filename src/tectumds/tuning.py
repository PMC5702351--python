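"""Per-cell tuning analysis: preprocessing, von Mises fits, selectivity.

The pipeline mirrors standard calcium-imaging practice for drifting-grating
experiments: optional spatial smoothing of the image stack, cubic-spline
baseline correction of each trace from inter-epoch gray intervals, integral
responses per stimulus epoch, least-squares von Mises fits (a unimodal
direction-tuned model and an axial period-180 orientation-tuned model),
direction/orientation selectivity indices from the fitted profiles, and
threshold classification into direction-selective (DS), orientation-
selective (OS) and untuned cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .angles import vm_shape, wrap_deg, fwhm_from_kappa

__all__ = [
    "Trace",
    "ResponseVector",
    "VonMisesFit",
    "SelectivityProfile",
    "smooth_stack",
    "baseline_correct",
    "epoch_integrals",
    "fit_tuning",
    "selectivity_indices",
    "dsi_from_responses",
    "classify_cell",
    "preferred_direction",
    "fwhm_bandwidth",
    "analyze_response_vector",
]


@dataclass
class Trace:
    """One cell's fluorescence time series with epoch metadata.

    ``epoch_windows`` holds half-open frame windows ``(start, end, direction)``
    with ``direction=None`` for the blank epoch; ``interepoch_windows`` holds
    the gray intervals used for baseline estimation.  ``baseline`` is filled
    by :func:`baseline_correct`.
    """

    values: np.ndarray
    sampling_rate_hz: float
    epoch_windows: list
    interepoch_windows: list
    baseline: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.size
        wins = sorted((int(s), int(e)) for s, e, *_ in self.epoch_windows)
        for (s, e), (s2, _) in zip(wins, wins[1:] + [(n, n)]):
            if not (0 <= s < e <= n):
                raise ValueError("epoch window outside trace bounds")
            if e > s2:
                raise ValueError("epoch windows must not overlap")


@dataclass
class ResponseVector:
    """Integral response per stimulus direction for one cell or voxel."""

    directions: np.ndarray
    responses: np.ndarray
    blank_response: float = None  # retained for QC, excluded from fitting

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.directions.size != self.responses.size:
            raise ValueError("one response per direction required")
        if np.unique(self.directions).size != self.directions.size:
            raise ValueError("directions must be distinct")
        if np.any(self.directions < 0) or np.any(self.directions >= 360):
            raise ValueError("directions must lie in [0, 360)")


@dataclass
class VonMisesFit:
    """Fitted tuning profile b + A * exp(kappa * (cos(d) - 1)).

    ``modality`` is "unimodal" for direction tuning (d = theta - center) or
    "bimodal" for the axial period-180 variant (d doubled).  ``r_squared`` is
    1 - SS_res/SS_tot; it is NaN and ``degenerate`` is set when the responses
    carry no variance to explain.
    """

    center_deg: float
    kappa: float
    amplitude: float
    baseline: float
    r_squared: float
    modality: str = "unimodal"
    degenerate: bool = False

    def predict(self, theta_deg):
        return self.baseline + self.amplitude * vm_shape(
            theta_deg, self.center_deg, self.kappa, period180=(self.modality == "bimodal"))

    def predict_floored(self, theta_deg):
        """Fitted curve floored at 0, for index computation."""
        return np.maximum(self.predict(theta_deg), 0.0)


@dataclass
class SelectivityProfile:
    dsi: float
    osi: float
    cell_class: str
    preferred_direction_deg: float
    fwhm_deg: float
    r_squared: float


# ---------------------------------------------------------------------------
# preprocessing

def smooth_stack(frames, median_size: int = 3, gaussian_sigma: float = 2.0):
    """Median then Gaussian filtering applied to each frame of a stack.

    ``median_size`` is the square kernel edge in voxels (1 disables the
    median step); ``gaussian_sigma`` is the Gaussian SD in voxels (0 disables
    smoothing).  The stack's leading axis indexes frames.
    """
    from scipy import ndimage

    frames = np.asarray(frames, dtype=float)
    if frames.size == 0:
        raise ValueError("empty image stack")
    if frames.ndim == 2:
        frames = frames[None]
    out = np.empty_like(frames)
    for i, fr in enumerate(frames):
        x = ndimage.median_filter(fr, size=median_size) if median_size > 1 else fr
        out[i] = ndimage.gaussian_filter(x, sigma=gaussian_sigma) if gaussian_sigma > 0 else x
    return out


def baseline_correct(trace: Trace, knot_window_s: float = 5.0, divide: bool = False) -> Trace:
    """Remove slow baseline drift using a cubic spline through inter-epoch knots.

    Each knot is the mean fluorescence over a ``knot_window_s`` window taken
    from the tail end of an inter-epoch interval (farthest from the preceding
    epoch, where indicator transients have decayed most), placed at the
    window's center time; a natural cubic spline through the knots is
    evaluated over all frames and subtracted (optionally divided, giving
    dF/F).  The estimated baseline is stored on the returned trace.
    """
    from scipy.interpolate import CubicSpline

    fs = trace.sampling_rate_hz
    n_win = int(round(knot_window_s * fs))
    knots_t, knots_v = [], []
    for s, e in trace.interepoch_windows:
        if e - s < n_win:
            continue
        ws, we = e - n_win, e
        knots_t.append((ws + we - 1) / 2.0)
        knots_v.append(trace.values[ws:we].mean())
    if len(knots_t) < 2:
        raise ValueError(
            "baseline correction needs at least 2 inter-epoch intervals of "
            f"{knot_window_s} s; record longer inter-epoch intervals")
    spline = CubicSpline(knots_t, knots_v, bc_type="natural")
    baseline = spline(np.arange(trace.values.size))
    corrected = trace.values - baseline
    if divide:
        corrected = corrected / np.where(baseline == 0, 1.0, baseline)
    return Trace(values=corrected, sampling_rate_hz=fs,
                 epoch_windows=trace.epoch_windows,
                 interepoch_windows=trace.interepoch_windows,
                 baseline=baseline)


def epoch_integrals(trace: Trace, include_fades: bool = True,
                    fade_frames: int = 0) -> ResponseVector:
    """Integral response per stimulus epoch (rectangle rule, fluorescence*s).

    Expects a baseline-corrected trace.  The blank epoch is excluded from the
    response vector but its integral is retained as ``blank_response``.  With
    ``include_fades=False`` the first and last ``fade_frames`` frames of each
    epoch are dropped from the integral.
    """
    fs = trace.sampling_rate_hz
    dirs, resp, blank = [], [], None
    for s, e, lab in trace.epoch_windows:
        a, b = (s, e) if include_fades else (s + fade_frames, e - fade_frames)
        if not (0 <= a <= b <= trace.values.size):
            raise ValueError("epoch window outside trace")
        integral = trace.values[a:b].sum() / fs
        if lab is None:
            blank = integral
        else:
            dirs.append(float(lab))
            resp.append(integral)
    order = np.argsort(dirs)
    return ResponseVector(directions=np.asarray(dirs)[order],
                          responses=np.asarray(resp)[order],
                          blank_response=blank)


# ---------------------------------------------------------------------------
# von Mises fitting

_KAPPA_BOUNDS = (1e-3, 1e3)


def _fit_vm(dirs, resp, period180: bool, n_starts=None):
    """Multi-start bounded least squares for one von Mises model.

    Starts are placed at every measured direction; the best SS_res wins, with
    near-ties broken toward the lower concentration.
    """
    span = resp.max() - resp.min()
    starts = dirs if n_starts is None else dirs[:: max(len(dirs) // n_starts, 1)]
    best = None
    for mu0 in starts:
        def residuals(p):
            mu, log_k, amp, base = p
            return base + amp * vm_shape(dirs, mu, np.exp(log_k), period180) - resp

        sol = least_squares(
            residuals,
            x0=[mu0, np.log(2.0), span, resp.min()],
            bounds=([-360.0, np.log(_KAPPA_BOUNDS[0]), 0.0, -np.inf],
                    [720.0, np.log(_KAPPA_BOUNDS[1]), np.inf, np.inf]),
        )
        if best is None:
            best = sol
            continue
        tie = abs(sol.cost - best.cost) <= 1e-9 * max(best.cost, 1e-30)
        if (not tie and sol.cost < best.cost) or (tie and sol.x[1] < best.x[1]):
            best = sol
    mu, log_k, amp, base = best.x
    pred = base + amp * vm_shape(dirs, mu, np.exp(log_k), period180)
    ss_res = float(np.sum((pred - resp) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    return VonMisesFit(center_deg=float(wrap_deg(mu)), kappa=float(np.exp(log_k)),
                       amplitude=float(amp), baseline=float(base),
                       r_squared=1.0 - ss_res / ss_tot,
                       modality="bimodal" if period180 else "unimodal")


def fit_tuning(rv: ResponseVector):
    """Fit the unimodal and the period-180 von Mises models to one cell.

    Returns ``(unimodal, bimodal)`` fits.  Constant response vectors cannot
    constrain either model; both fits come back flagged degenerate with
    kappa=0 and undefined (NaN) r_squared.
    """
    dirs = rv.directions
    if np.unique(dirs).size < 5:
        raise ValueError("tuning fits need at least 5 distinct directions")
    resp = rv.responses
    if np.all(resp == resp[0]):
        deg = [VonMisesFit(center_deg=0.0, kappa=0.0, amplitude=0.0, baseline=float(resp[0]),
                           r_squared=float("nan"), modality=m, degenerate=True)
               for m in ("unimodal", "bimodal")]
        return deg[0], deg[1]
    return _fit_vm(dirs, resp, False), _fit_vm(dirs, resp, True)


# ---------------------------------------------------------------------------
# selectivity indices and classification

def dsi_from_responses(r_pref: float, r_null: float) -> float:
    """(R_pref - R_null) / (R_pref + R_null); NaN when both are zero."""
    tot = r_pref + r_null
    return float("nan") if tot == 0 else (r_pref - r_null) / tot


def selectivity_indices(rv: ResponseVector, unimodal: VonMisesFit,
                        bimodal: VonMisesFit = None):
    """DSI and OSI from the better-fitting von Mises profile.

    Both indices are evaluated on the fitted curve of whichever model
    (unimodal direction-tuned vs period-180 orientation-tuned) explains more
    variance, with fitted values floored at 0:

    * DSI = (R_pref - R_null)/(R_pref + R_null), R_pref at the curve's peak
      and R_null 180 degrees away.
    * OSI = (R_prefori - R_orth)/(R_prefori + R_orth), where the response at
      an orientation is the response shared by its two opposite motion
      directions (the minimum of the fitted curve at theta and theta+180),
      evaluated at the preferred orientation and 90 degrees from it.

    Under this reading a purely direction-tuned cell scores OSI ~ 0 (its
    opposite-direction response is ~ 0) and a purely axial cell scores
    DSI = 0, so the DS/OS threshold gates are mutually exclusive.  Degenerate
    fits yield (0, 0) — a flat cell is neither direction- nor orientation-
    selective.
    """
    if bimodal is None:
        bimodal = unimodal
    if unimodal.degenerate and bimodal.degenerate:
        return 0.0, 0.0
    fits = [f for f in (unimodal, bimodal) if not f.degenerate]
    best = max(fits, key=lambda f: f.r_squared)

    grid = np.arange(0.0, 360.0, 1.0)
    curve = best.predict_floored(grid)
    mu = float(grid[int(np.argmax(curve))])
    g = lambda t: float(best.predict_floored(np.asarray([t % 360.0]))[0])

    r_pref, r_null = g(mu), g(mu + 180.0)
    dsi = dsi_from_responses(r_pref, r_null)
    r_prefori = min(g(mu), g(mu + 180.0))
    r_orth = min(g(mu + 90.0), g(mu + 270.0))
    osi = dsi_from_responses(r_prefori, r_orth)
    dsi = 0.0 if not np.isfinite(dsi) else max(dsi, 0.0)
    osi = 0.0 if not np.isfinite(osi) else max(osi, 0.0)
    return dsi, osi


def classify_cell(dsi: float, osi: float, r_squared_best: float) -> str:
    """Threshold classification: DS, OS or untuned.

    DS: DSI > 0.5, OSI < 0.5 and R^2 > 0.7;  OS: DSI < 0.5, OSI > 0.5 and
    R^2 > 0.7; everything else (including undefined R^2) is untuned.
    """
    if not np.isfinite(r_squared_best):
        return "untuned"
    if dsi > 0.5 and osi < 0.5 and r_squared_best > 0.7:
        return "DS"
    if dsi < 0.5 and osi > 0.5 and r_squared_best > 0.7:
        return "OS"
    return "untuned"


def preferred_direction(fit: VonMisesFit) -> float:
    """Preferred direction of motion: the fitted curve's center, in [0, 360)."""
    if fit.degenerate:
        raise ValueError("preferred direction undefined for a degenerate fit")
    return float(wrap_deg(fit.center_deg))


def fwhm_bandwidth(fit: VonMisesFit) -> float:
    """Tuning bandwidth: full width at half the baseline-subtracted peak.

    Closed form for the fitted von Mises: 2*arccos(1 - ln2/kappa) degrees
    when kappa >= ln2/2, else 360 (the curve never falls to half maximum).
    """
    if fit.degenerate or fit.amplitude <= 0:
        raise ValueError("FWHM undefined for zero-amplitude or degenerate fits")
    return float(fwhm_from_kappa(fit.kappa))


def analyze_response_vector(rv: ResponseVector) -> SelectivityProfile:
    """Full per-cell analysis: fits, indices, class, preference and bandwidth."""
    uni, bi = fit_tuning(rv)
    dsi, osi = selectivity_indices(rv, uni, bi)
    r2_best = np.nanmax([uni.r_squared, bi.r_squared]) if not (uni.degenerate and bi.degenerate) \
        else float("nan")
    cls = classify_cell(dsi, osi, r2_best)
    pref = float("nan") if uni.degenerate else preferred_direction(uni)
    try:
        fwhm = fwhm_bandwidth(uni)
    except ValueError:
        fwhm = float("nan")
    return SelectivityProfile(dsi=dsi, osi=osi, cell_class=cls,
                              preferred_direction_deg=pref, fwhm_deg=fwhm,
                              r_squared=float(r2_best))
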