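"""Population-level structure of preferred directions.

Preferred angles of direction-selective cells are binned into a histogram
over [0, 360) and decomposed into subtypes by fitting a sum of von Mises
bumps (free center, height and concentration per component) with bounded
least squares.  Each component's FWHM defines the angle bounds within which
its member cells lie; per-subtype summaries (mean normalized tuning curve,
mean DSI, mean bandwidth, population preferred direction) follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .angles import vm_shape, wrap_deg, circ_dist_deg, circ_mean_deg, fwhm_from_kappa

__all__ = [
    "AngleHistogram",
    "MixtureComponent",
    "MixtureFit",
    "PopulationSummary",
    "build_histogram",
    "fit_mixture",
    "scan_components",
    "assign_subtypes",
    "summarize_population",
    "UNASSIGNED",
]

UNASSIGNED = -1


@dataclass
class AngleHistogram:
    bin_edges: np.ndarray  # length n_bins + 1, spanning [0, 360]
    counts: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts must have one entry per bin")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be nonnegative")

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class MixtureComponent:
    center_deg: float
    height: float
    concentration: float
    bounds_deg: tuple  # (low, high), circular interval center +/- FWHM/2

    @property
    def fwhm_deg(self) -> float:
        return float(fwhm_from_kappa(self.concentration))

    def contains(self, angle_deg: float) -> bool:
        """Circular membership in [low, high]."""
        return circ_dist_deg(angle_deg, self.center_deg) <= self.fwhm_deg / 2.0


@dataclass
class MixtureFit:
    components: list  # sorted by center_deg
    r_squared: float

    def predict(self, theta_deg):
        theta = np.asarray(theta_deg, dtype=float)
        out = np.zeros_like(theta)
        for c in self.components:
            out += c.height * vm_shape(theta, c.center_deg, c.concentration)
        return out


@dataclass
class PopulationSummary:
    """Per-subtype polar summary over the measured directions."""

    directions: np.ndarray
    mean_curves: dict  # label -> per-direction mean of min-max normalized responses
    sd_curves: dict
    mean_dsi: dict
    mean_fwhm_deg: dict
    preferred_direction_deg: dict  # circular mean of member preferences
    n_cells: dict


def build_histogram(angles_deg, bin_width_deg: float = 10.0) -> AngleHistogram:
    """Histogram of preferred angles with half-open bins [edge, edge + width)."""
    if 360.0 % bin_width_deg != 0:
        raise ValueError("bin width must divide 360 degrees")
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size and (np.any(angles < 0) or np.any(angles >= 360)):
        raise ValueError("angles must lie in [0, 360)")
    edges = np.arange(0.0, 360.0 + bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(angles, bins=edges)
    return AngleHistogram(bin_edges=edges, counts=counts)


def _component_from_params(center, height, kappa):
    fwhm = float(fwhm_from_kappa(kappa))
    lo = wrap_deg(center - fwhm / 2.0)
    hi = wrap_deg(center + fwhm / 2.0)
    return MixtureComponent(center_deg=float(wrap_deg(center)), height=float(height),
                            concentration=float(kappa), bounds_deg=(float(lo), float(hi)))


def _mixture_predict(params, centers_deg, n):
    out = np.zeros_like(centers_deg)
    for i in range(n):
        mu, h, k = params[3 * i: 3 * i + 3]
        out += h * vm_shape(centers_deg, mu, k)
    return out


def fit_mixture(hist: AngleHistogram, n_components: int, n_starts: int = 8,
                init_params=None) -> MixtureFit:
    """Constrained least-squares fit of n von Mises bumps to bin counts.

    Heights and concentrations are bounded below at 0; centers are free.
    Multi-start: centers initialized at the ``n_components`` highest bins and
    at rotations of an even placement (plus ``init_params`` if given, which
    allows nested refits).  Raises if no start converges.
    """
    if n_components < 1:
        raise ValueError("need at least one mixture component")
    counts = hist.counts.astype(float)
    if counts.sum() <= 0:
        raise ValueError("cannot fit a mixture to an empty histogram")
    centers = hist.centers
    n = n_components

    top = centers[np.argsort(counts)[::-1][:n]]
    starts = [np.sort(top)]
    for shift in np.linspace(0.0, 360.0 / n, n_starts, endpoint=False):
        starts.append(wrap_deg(shift + np.arange(n) * 360.0 / n))

    h0 = max(counts.max(), 1.0)
    lower = [-360.0, 0.0, 0.0] * n
    upper = [720.0, np.inf, 1e3] * n
    candidates = []
    if init_params is not None:
        candidates.append(np.clip(np.asarray(init_params, dtype=float), lower, upper))
    for mus in starts:
        p0 = []
        for mu in mus:
            p0.extend([mu, h0, 4.0])
        candidates.append(np.asarray(p0))

    best = None
    for p0 in candidates:
        try:
            sol = least_squares(lambda p: _mixture_predict(p, centers, n) - counts,
                                x0=p0, bounds=(lower, upper))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            f"mixture fit failed to converge from any of {len(candidates)} starts "
            f"(n_components={n}, total count={counts.sum():.0f})")

    comps = [_component_from_params(*best.x[3 * i: 3 * i + 3]) for i in range(n)]
    comps.sort(key=lambda c: c.center_deg)
    pred = _mixture_predict(best.x, centers, n)
    ss_res = float(np.sum((pred - counts) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    return MixtureFit(components=comps, r_squared=1.0 - ss_res / ss_tot)


def scan_components(hist: AngleHistogram, max_components: int):
    """Fit 1..max_components mixtures with nested starts; returns list of fits.

    Each fit of size n+1 is additionally seeded with the size-n solution plus
    one zero-height component at the largest residual bin, so the achieved
    r_squared is non-decreasing in n.  This is a diagnostic aid — component
    count selection stays with the user.
    """
    fits = []
    prev = None
    for n in range(1, max_components + 1):
        init = None
        if prev is not None:
            resid = hist.counts.astype(float) - prev.predict(hist.centers)
            extra_mu = float(hist.centers[int(np.argmax(resid))])
            init = []
            for c in prev.components:
                init.extend([c.center_deg, c.height, c.concentration])
            init.extend([extra_mu, max(float(resid.max()), 0.0), 4.0])
        fits.append(fit_mixture(hist, n, init_params=init))
        prev = fits[-1]
    return fits


def assign_subtypes(angles_deg, fit: MixtureFit) -> np.ndarray:
    """Component index per angle, or UNASSIGNED when no bounds contain it.

    Membership is circular distance to a component center within FWHM/2;
    overlaps resolve to the circularly nearest center.
    """
    angles = np.asarray(angles_deg, dtype=float)
    labels = np.full(angles.size, UNASSIGNED)
    for i, a in enumerate(angles):
        dists = [(circ_dist_deg(a, c.center_deg), j)
                 for j, c in enumerate(fit.components) if c.contains(a)]
        if dists:
            labels[i] = min(dists)[1]
    return labels


def summarize_population(response_vectors, profiles, labels) -> PopulationSummary:
    """Per-subtype mean polar tuning, DSI and bandwidth.

    Each cell's response vector is min-max normalized to [0, 1]; subtypes
    are the distinct non-negative labels.  Empty subtypes never occur by
    construction (labels enumerate members); cells labeled UNASSIGNED are
    skipped.
    """
    labels = np.asarray(labels)
    if len(response_vectors) != len(profiles) or len(profiles) != labels.size:
        raise ValueError("response_vectors, profiles and labels must align")
    dirs = response_vectors[0].directions
    mean_curves, sd_curves, mean_dsi, mean_fwhm, pref, n_cells = {}, {}, {}, {}, {}, {}
    for lab in sorted(set(labels.tolist()) - {UNASSIGNED}):
        idx = np.flatnonzero(labels == lab)
        curves = []
        for i in idx:
            r = response_vectors[i].responses
            span = r.max() - r.min()
            curves.append((r - r.min()) / span if span > 0 else np.zeros_like(r))
        curves = np.asarray(curves)
        mean_curves[lab] = curves.mean(axis=0)
        sd_curves[lab] = curves.std(axis=0, ddof=0)
        mean_dsi[lab] = float(np.mean([profiles[i].dsi for i in idx]))
        mean_fwhm[lab] = float(np.nanmean([profiles[i].fwhm_deg for i in idx]))
        pref[lab] = circ_mean_deg([profiles[i].preferred_direction_deg for i in idx])
        n_cells[lab] = int(idx.size)
    return PopulationSummary(directions=dirs, mean_curves=mean_curves, sd_curves=sd_curves,
                             mean_dsi=mean_dsi, mean_fwhm_deg=mean_fwhm,
                             preferred_direction_deg=pref, n_cells=n_cells)
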