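"""Three-layer rate model of the direction-selective retinotectal circuit.

Ten rate units with rectified-linear activation: three retinal ganglion cell
(RGC) drives R1-R3 with von Mises direction tuning, three reciprocally
inhibiting superficial interneurons (SINs) S1-S3, and four periventricular
neurons (PVNs) P1-P4.  Rate dynamics:

    tau dr_i/dt = -r_i + f(theta; theta_i, kappa_i)
    tau ds_i/dt = -s_i + sigma(sum_j w^sr_ij r_j - sum_j w^ss_ij s_j)
    tau dp_i/dt = -p_i + sigma(sum_j w^pr_ij r_j - sum_j w^ps_ij s_j)

with sigma(x) = max(x, 0) and f the von Mises density.  Weights are 1 where
an edge exists and each matrix is divisively normalized to sum to 1, so all
connections leaving a cell type have equal strength.  In the default circuit
P2 pools excitation from the upward- and downward-tuned RGCs (R1, R2) and is
inhibited by all three SINs; by integrating the two retinal pathways it
develops an emergent preference for rostral-to-caudal (90 degree) motion
that neither input carries.

Tuning curves are the stabilized (fixed-point) responses over a direction
grid; the in-silico perturbation battery removes reciprocal SIN coupling or
ablates SIN subsets and tracks P2's amplitude, preferred direction, DSI,
bandwidth and tuning error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .angles import vm_pdf_deg, wrap_deg, circ_dist_deg, kappa_from_fwhm, fwhm_from_kappa

__all__ = [
    "UnitSpec",
    "CircuitSpec",
    "WeightMatrices",
    "SimulationConfig",
    "RateState",
    "TuningCurve",
    "TuningMetrics",
    "PerturbationSpec",
    "default_circuit",
    "DEFAULT_RGC_MEANS_DEG",
    "DEFAULT_RGC_FWHM_DEG",
    "OBSERVED_P2_PREF_DEG",
    "calibrate_kappa",
    "refine_kappas",
    "build_weights",
    "rgc_drive",
    "steady_state",
    "solve_fixed_point",
    "tuning_curves",
    "apply_perturbation",
    "perturbed_weights",
    "tuning_metrics",
    "perturbation_battery",
    "BATTERY_PERTURBATIONS",
]

RGC_IDS = ("R1", "R2", "R3")
SIN_IDS = ("S1", "S2", "S3")
PVN_IDS = ("P1", "P2", "P3", "P4")

# Default circuit parameters: RGC von Mises means (the upward, downward and
# caudal-to-rostral retinal channels) and the printed mean RGC bandwidths
# from which the default concentrations are inverted.
DEFAULT_RGC_MEANS_DEG = (24.0, 124.0, 256.0)
DEFAULT_RGC_FWHM_DEG = (107.0, 155.0, 156.0)
# Experimentally identified preference of the emergent PVN population.
OBSERVED_P2_PREF_DEG = 90.0


@dataclass(frozen=True)
class UnitSpec:
    id: str
    layer: str  # RGC | SIN | PVN
    theta_deg: float = None
    kappa: float = None

    def __post_init__(self):
        if self.layer not in ("RGC", "SIN", "PVN"):
            raise ValueError("layer must be RGC, SIN or PVN")
        has_tuning = self.theta_deg is not None and self.kappa is not None
        if (self.layer == "RGC") != has_tuning:
            raise ValueError("theta/kappa must be present exactly for RGC units")


@dataclass(frozen=True)
class CircuitSpec:
    units: tuple
    excitatory_edges: frozenset  # (RGC id, SIN or PVN id)
    inhibitory_edges: frozenset  # (SIN id, SIN or PVN id)

    def __post_init__(self):
        ids = [u.id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("unit ids must be unique")
        layer = {u.id: u.layer for u in self.units}
        for src, dst in self.excitatory_edges | self.inhibitory_edges:
            if src == dst:
                raise ValueError("self-edges are not allowed")
            if src not in layer or dst not in layer:
                raise ValueError(f"edge references unknown unit: {src}->{dst}")
        for src, _ in self.excitatory_edges:
            if layer[src] != "RGC":
                raise ValueError("excitatory edges must originate from RGC units")
        for src, _ in self.inhibitory_edges:
            if layer[src] != "SIN":
                raise ValueError("inhibitory edges must originate from SIN units")

    def by_layer(self, layer: str):
        return tuple(u for u in self.units if u.layer == layer)

    def unit(self, uid: str) -> UnitSpec:
        for u in self.units:
            if u.id == uid:
                return u
        raise KeyError(uid)

    def with_kappas(self, kappas) -> "CircuitSpec":
        """Copy of the circuit with RGC concentrations replaced (in RGC order)."""
        rgc = self.by_layer("RGC")
        if len(kappas) != len(rgc):
            raise ValueError("one kappa per RGC unit required")
        lut = {u.id: float(k) for u, k in zip(rgc, kappas)}
        units = tuple(replace(u, kappa=lut[u.id]) if u.id in lut else u for u in self.units)
        return CircuitSpec(units=units, excitatory_edges=self.excitatory_edges,
                           inhibitory_edges=self.inhibitory_edges)


@dataclass
class WeightMatrices:
    """Nonnegative synaptic strengths, indexed [target, source].

    Each matrix is divisively normalized so its entries sum to 1 (matrices
    without any edge stay all-zero).
    """

    w_sr: np.ndarray  # SIN x RGC
    w_ss: np.ndarray  # SIN x SIN
    w_pr: np.ndarray  # PVN x RGC
    w_ps: np.ndarray  # PVN x SIN


@dataclass(frozen=True)
class SimulationConfig:
    tau: float = 1.0
    dt: float = 0.01
    tol: float = 1e-9  # max |rate change| per unit time at the fixed point
    max_steps: int = 1_000_000
    direction_grid_deg: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0 or self.dt <= 0 or self.tol <= 0:
            raise ValueError("tau, dt and tol must be positive")
        if self.dt >= self.tau:
            raise ValueError("dt must be smaller than tau")

    @property
    def direction_grid(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.direction_grid_deg)


@dataclass
class RateState:
    r: np.ndarray
    s: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        for x in (self.r, self.s, self.p):
            if np.any(np.asarray(x) < -1e-12):
                raise ValueError("rates must be nonnegative")


@dataclass
class TuningCurve:
    directions: np.ndarray
    response: np.ndarray  # unnormalized stabilized rate per direction

    @property
    def normalized(self) -> np.ndarray:
        span = self.response.max() - self.response.min()
        if span == 0:
            return np.zeros_like(self.response)
        return (self.response - self.response.min()) / span


@dataclass
class TuningMetrics:
    amplitude: float
    preferred_deg: float
    dsi: float
    fwhm_deg: float
    tuning_error_deg: float


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str  # intact | no_reciprocal_SIN | ablate
    ablated: frozenset = frozenset()

    def __post_init__(self):
        if self.kind not in ("intact", "no_reciprocal_SIN", "ablate"):
            raise ValueError("unknown perturbation kind")
        if self.kind == "ablate" and not self.ablated:
            raise ValueError("ablation requires a nonempty unit subset")

    @property
    def label(self) -> str:
        if self.kind == "ablate":
            return "ablate_" + "+".join(sorted(self.ablated))
        return self.kind


BATTERY_PERTURBATIONS = (
    PerturbationSpec("intact"),
    PerturbationSpec("no_reciprocal_SIN"),
    PerturbationSpec("ablate", frozenset({"S1"})),
    PerturbationSpec("ablate", frozenset({"S1", "S2"})),
    PerturbationSpec("ablate", frozenset({"S1", "S2", "S3"})),
)


def default_circuit(rgc_means_deg=DEFAULT_RGC_MEANS_DEG,
                    rgc_fwhm_deg=DEFAULT_RGC_FWHM_DEG) -> CircuitSpec:
    """The default 10-unit circuit.

    R1/R2/R3 drive S1/S2/S3 one-to-one and P1/P3/P4 one-to-one; P2 pools R1
    and R2.  SINs inhibit each other reciprocally (all ordered pairs) and all
    three inhibit P2.  RGC concentrations are inverted from the printed mean
    RGC bandwidths.
    """
    kappas = [calibrate_kappa(f) for f in rgc_fwhm_deg]
    units = tuple(
        [UnitSpec(rid, "RGC", theta_deg=float(m), kappa=float(k))
         for rid, m, k in zip(RGC_IDS, rgc_means_deg, kappas)]
        + [UnitSpec(sid, "SIN") for sid in SIN_IDS]
        + [UnitSpec(pid, "PVN") for pid in PVN_IDS]
    )
    excit = {("R1", "S1"), ("R2", "S2"), ("R3", "S3"),
             ("R1", "P1"), ("R2", "P3"), ("R3", "P4"),
             ("R1", "P2"), ("R2", "P2")}
    inhib = {(a, b) for a in SIN_IDS for b in SIN_IDS if a != b}
    inhib |= {(s, "P2") for s in SIN_IDS}
    return CircuitSpec(units=units, excitatory_edges=frozenset(excit),
                       inhibitory_edges=frozenset(inhib))


def calibrate_kappa(fwhm_deg: float) -> float:
    """Concentration whose peak-normalized von Mises has the given FWHM."""
    return float(kappa_from_fwhm(fwhm_deg))


def build_weights(spec: CircuitSpec) -> WeightMatrices:
    """Edge indicator matrices, each divisively normalized to sum to 1."""
    rgc = [u.id for u in spec.by_layer("RGC")]
    sin = [u.id for u in spec.by_layer("SIN")]
    pvn = [u.id for u in spec.by_layer("PVN")]
    idx = {**{u: i for i, u in enumerate(rgc)},
           **{u: i for i, u in enumerate(sin)},
           **{u: i for i, u in enumerate(pvn)}}
    layer = {u.id: u.layer for u in spec.units}

    w_sr = np.zeros((len(sin), len(rgc)))
    w_pr = np.zeros((len(pvn), len(rgc)))
    for src, dst in spec.excitatory_edges:
        (w_sr if layer[dst] == "SIN" else w_pr)[idx[dst], idx[src]] = 1.0
    w_ss = np.zeros((len(sin), len(sin)))
    w_ps = np.zeros((len(pvn), len(sin)))
    for src, dst in spec.inhibitory_edges:
        (w_ss if layer[dst] == "SIN" else w_ps)[idx[dst], idx[src]] = 1.0
    for w in (w_sr, w_ss, w_pr, w_ps):
        total = w.sum()
        if total > 0:
            w /= total
    return WeightMatrices(w_sr=w_sr, w_ss=w_ss, w_pr=w_pr, w_ps=w_ps)


def rgc_drive(theta_stim, unit: UnitSpec):
    """Von Mises density drive of one RGC unit at a stimulus direction."""
    if unit.layer != "RGC":
        raise ValueError("only RGC units carry a stimulus drive")
    return vm_pdf_deg(theta_stim, unit.theta_deg, unit.kappa)


def _drive_matrix(spec: CircuitSpec, thetas: np.ndarray) -> np.ndarray:
    """RGC drives, shape (n_rgc, n_thetas)."""
    return np.stack([rgc_drive(thetas, u) for u in spec.by_layer("RGC")])


def _euler(f, weights: WeightMatrices, config: SimulationConfig):
    """Explicit-Euler integration to the fixed point, vectorized over columns.

    ``f`` has shape (n_rgc, n_cols).  Convergence: max absolute rate change
    per unit time below ``config.tol``.
    """
    relu = lambda x: np.maximum(x, 0.0)
    r = np.zeros_like(f)
    s = np.zeros((weights.w_ss.shape[0], f.shape[1]))
    p = np.zeros((weights.w_pr.shape[0], f.shape[1]))
    dt, tau = config.dt, config.tau
    for _ in range(config.max_steps):
        dr = (-r + f) / tau
        ds = (-s + relu(weights.w_sr @ r - weights.w_ss @ s)) / tau
        dp = (-p + relu(weights.w_pr @ r - weights.w_ps @ s)) / tau
        r = r + dt * dr
        s = s + dt * ds
        p = p + dt * dp
        resid = max(np.abs(dr).max(), np.abs(ds).max(), np.abs(dp).max())
        if resid < config.tol:
            return r, s, p
    raise RuntimeError(
        f"steady state not reached in {config.max_steps} steps (residual {resid:.3e})")


def steady_state(spec: CircuitSpec, weights: WeightMatrices, theta_stim: float,
                 config: SimulationConfig = SimulationConfig()) -> RateState:
    """Stabilized rates under a constant stimulus direction (Euler integration)."""
    f = _drive_matrix(spec, np.asarray([float(theta_stim)]))
    r, s, p = _euler(f, weights, config)
    return RateState(r=r[:, 0], s=s[:, 0], p=p[:, 0])


def solve_fixed_point(spec: CircuitSpec, weights: WeightMatrices, thetas,
                      damping: float = 0.5, tol: float = 1e-13,
                      max_iter: int = 100_000):
    """Damped Picard iteration on the rectified fixed-point equations.

    Fast algebraic alternative to ODE integration: r* = f exactly, then
    s = (1-d) s + d relu(w_sr r* - w_ss s) to convergence, and p follows in
    closed form.  Returns (r, s, p) arrays with one column per stimulus.
    """
    relu = lambda x: np.maximum(x, 0.0)
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    r = _drive_matrix(spec, thetas)
    s = np.zeros((weights.w_ss.shape[0], thetas.size))
    drive = weights.w_sr @ r
    for _ in range(max_iter):
        s_new = relu(drive - weights.w_ss @ s)
        if np.abs(s_new - s).max() < tol:
            s = s_new
            break
        s = (1.0 - damping) * s + damping * s_new
    else:
        raise RuntimeError("Picard iteration did not converge")
    p = relu(weights.w_pr @ r - weights.w_ps @ s)
    return r, s, p


def tuning_curves(spec: CircuitSpec, config: SimulationConfig = SimulationConfig(),
                  weights: WeightMatrices = None, solver: str = "euler") -> dict:
    """Stabilized tuning curve of every unit over the direction grid.

    ``solver`` is "euler" (the rate ODEs, default) or "picard" (direct
    fixed-point solution; the two agree to solver tolerance).
    """
    if weights is None:
        weights = build_weights(spec)
    grid = config.direction_grid
    if solver == "euler":
        f = _drive_matrix(spec, grid)
        r, s, p = _euler(f, weights, config)
    elif solver == "picard":
        r, s, p = solve_fixed_point(spec, weights, grid)
    else:
        raise ValueError("solver must be 'euler' or 'picard'")
    out = {}
    for block, ids in ((r, [u.id for u in spec.by_layer("RGC")]),
                       (s, [u.id for u in spec.by_layer("SIN")]),
                       (p, [u.id for u in spec.by_layer("PVN")])):
        for i, uid in enumerate(ids):
            out[uid] = TuningCurve(directions=grid.copy(), response=block[i].copy())
    return out


def apply_perturbation(spec: CircuitSpec, perturbation: PerturbationSpec) -> CircuitSpec:
    """Perturbed circuit: SIN-SIN edges removed, or units and their edges removed."""
    if perturbation.kind == "intact":
        return spec
    if perturbation.kind == "no_reciprocal_SIN":
        layer = {u.id: u.layer for u in spec.units}
        inhib = frozenset((a, b) for a, b in spec.inhibitory_edges if layer[b] != "SIN")
        return CircuitSpec(units=spec.units, excitatory_edges=spec.excitatory_edges,
                           inhibitory_edges=inhib)
    bad = [u for u in perturbation.ablated if spec.unit(u).layer != "SIN"]
    if bad:
        raise ValueError(f"only SIN units can be ablated, got {sorted(bad)}")
    gone = perturbation.ablated
    units = tuple(u for u in spec.units if u.id not in gone)
    excit = frozenset(e for e in spec.excitatory_edges if e[0] not in gone and e[1] not in gone)
    inhib = frozenset(e for e in spec.inhibitory_edges if e[0] not in gone and e[1] not in gone)
    return CircuitSpec(units=units, excitatory_edges=excit, inhibitory_edges=inhib)


def perturbed_weights(spec: CircuitSpec, perturbation: PerturbationSpec,
                      renormalize: bool = False) -> WeightMatrices:
    """Weight matrices of the perturbed circuit, in the intact index space.

    By default an ablation simply zeroes every weight touching the ablated
    units and removing reciprocal coupling zeroes w_ss, leaving all surviving
    synapses at their intact strengths — removing a population does not
    strengthen the synapses that remain.  With ``renormalize=True`` the
    matrices are instead rebuilt (and re-normalized) on the perturbed circuit.
    """
    if renormalize:
        sub = apply_perturbation(spec, perturbation)
        w = build_weights(sub)
        return _embed_weights(spec, sub, w)
    w = build_weights(spec)
    if perturbation.kind == "intact":
        return w
    if perturbation.kind == "no_reciprocal_SIN":
        return WeightMatrices(w_sr=w.w_sr, w_ss=np.zeros_like(w.w_ss),
                              w_pr=w.w_pr, w_ps=w.w_ps)
    sin_ids = [u.id for u in spec.by_layer("SIN")]
    mask = np.array([uid not in perturbation.ablated for uid in sin_ids], dtype=float)
    return WeightMatrices(w_sr=w.w_sr * mask[:, None], w_ss=w.w_ss * np.outer(mask, mask),
                          w_pr=w.w_pr, w_ps=w.w_ps * mask[None, :])


def _embed_weights(full: CircuitSpec, sub: CircuitSpec, w: WeightMatrices) -> WeightMatrices:
    """Embed a reduced circuit's weights back into the full circuit's index space."""
    def embed(mat, rows_full, rows_sub, cols_full, cols_sub):
        out = np.zeros((len(rows_full), len(cols_full)))
        ri = [rows_full.index(u) for u in rows_sub]
        ci = [cols_full.index(u) for u in cols_sub]
        out[np.ix_(ri, ci)] = mat
        return out

    rf = [u.id for u in full.by_layer("RGC")]
    sf = [u.id for u in full.by_layer("SIN")]
    pf = [u.id for u in full.by_layer("PVN")]
    rs = [u.id for u in sub.by_layer("RGC")]
    ss = [u.id for u in sub.by_layer("SIN")]
    ps = [u.id for u in sub.by_layer("PVN")]
    return WeightMatrices(
        w_sr=embed(w.w_sr, sf, ss, rf, rs),
        w_ss=embed(w.w_ss, sf, ss, sf, ss),
        w_pr=embed(w.w_pr, pf, ps, rf, rs),
        w_ps=embed(w.w_ps, pf, ps, sf, ss),
    )


def tuning_metrics(curve: TuningCurve, observed_pref_deg: float) -> TuningMetrics:
    """Amplitude, preferred direction, DSI, FWHM and tuning error of one curve.

    All metrics come from the unnormalized response.  Preferred direction is
    the argmax over the grid (lowest angle on exact ties); DSI contrasts the
    responses at the preferred direction and 180 degrees opposite; FWHM is
    found by half-maximum crossing search on the grid with linear
    interpolation at the crossings; tuning error is the circular absolute
    difference from the observed preference.
    """
    resp = curve.response
    if np.all(resp == resp[0]):
        raise ValueError("tuning metrics undefined for a constant curve")
    grid = curve.directions
    i_max = int(np.argmax(resp))  # np.argmax returns the first (lowest-angle) maximum
    amplitude = float(resp[i_max])
    preferred = float(grid[i_max])
    n = grid.size
    r_null = float(resp[(i_max + n // 2) % n])
    dsi = (amplitude - r_null) / (amplitude + r_null) if amplitude + r_null > 0 else float("nan")
    fwhm = _fwhm_on_grid(grid, resp, i_max)
    err = float(circ_dist_deg(observed_pref_deg, preferred))
    return TuningMetrics(amplitude=amplitude, preferred_deg=preferred, dsi=float(dsi),
                         fwhm_deg=fwhm, tuning_error_deg=err)


def _fwhm_on_grid(grid: np.ndarray, resp: np.ndarray, i_max: int) -> float:
    """Width at half max around the peak, linear interpolation at crossings."""
    half = resp[i_max] / 2.0
    n = grid.size
    step = 360.0 / n

    def walk(direction):
        dist = 0.0
        i = i_max
        for _ in range(n):
            j = (i + direction) % n
            if resp[j] < half:
                frac = (resp[i] - half) / (resp[i] - resp[j])
                return dist + frac * step
            dist += step
            i = j
        return 360.0  # never falls below half max

    up, down = walk(+1), walk(-1)
    return float(min(up + down, 360.0))


def perturbation_battery(spec: CircuitSpec, config: SimulationConfig = SimulationConfig(),
                         observed_pref_deg: float = OBSERVED_P2_PREF_DEG,
                         perturbations=BATTERY_PERTURBATIONS, units=("P2",),
                         renormalize: bool = False, solver: str = "euler") -> pd.DataFrame:
    """Tuning metrics of the chosen PVN units under each circuit perturbation.

    Returns one row per (perturbation, unit) with columns perturbation, unit,
    amplitude, preferred_deg, dsi, fwhm_deg, tuning_error_deg.
    """
    rows = []
    for pert in perturbations:
        weights = perturbed_weights(spec, pert, renormalize=renormalize)
        curves = tuning_curves(spec, config, weights=weights, solver=solver)
        for uid in units:
            m = tuning_metrics(curves[uid], observed_pref_deg)
            rows.append(dict(perturbation=pert.label, unit=uid, amplitude=m.amplitude,
                             preferred_deg=m.preferred_deg, dsi=m.dsi,
                             fwhm_deg=m.fwhm_deg, tuning_error_deg=m.tuning_error_deg))
    return pd.DataFrame(rows)


def refine_kappas(spec: CircuitSpec, reference_deg: float = OBSERVED_P2_PREF_DEG,
                  target_unit: str = "P2", scale_unit: str = "R1",
                  factors=None, config: SimulationConfig = SimulationConfig()) -> np.ndarray:
    """Adjust RGC concentrations to align the target PVN's preference.

    The default concentrations (inverted from mean population bandwidths)
    leave the intact-circuit preference of the emergent PVN far from the
    experimentally identified direction, because the relative concentration
    of its two RGC drives sets where between their means its peak falls.
    This searches a multiplicative grid of factors on ``scale_unit``'s kappa,
    minimizing the circular distance between the intact ``target_unit``
    preference (argmax on the direction grid, via the fixed-point solver) and
    ``reference_deg``; among equally good factors the midpoint of the longest
    contiguous run is taken, which keeps the solution away from knife-edge
    plateau boundaries.  Returns the refined kappas in RGC order.
    """
    if factors is None:
        factors = np.arange(0.2, 2.0 + 1e-9, 0.005)
    rgc = spec.by_layer("RGC")
    base = np.array([u.kappa for u in rgc])
    j = [u.id for u in rgc].index(scale_unit)
    weights = build_weights(spec)
    grid = config.direction_grid

    dists = np.empty(len(factors))
    for i, c in enumerate(factors):
        kappas = base.copy()
        kappas[j] = base[j] * c
        trial = spec.with_kappas(kappas)
        _, _, p = solve_fixed_point(trial, weights, grid)
        k_target = [u.id for u in spec.by_layer("PVN")].index(target_unit)
        pref = grid[int(np.argmax(p[k_target]))]
        dists[i] = circ_dist_deg(pref, reference_deg)

    best = dists.min()
    optimal = dists <= best
    # midpoint of the longest contiguous run of optimal factors
    runs, start = [], None
    for i, ok in enumerate(optimal):
        if ok and start is None:
            start = i
        if (not ok or i == len(optimal) - 1) and start is not None:
            end = i if ok else i - 1
            runs.append((end - start, start, end))
            start = None
    _, s0, e0 = max(runs)
    pick = factors[(s0 + e0) // 2]
    refined = base.copy()
    refined[j] = base[j] * pick
    return refined
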