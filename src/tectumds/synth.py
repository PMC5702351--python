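"""Synthetic tuned-cell populations, epoch-response tables and traces.

This module is the generative counterpart of the analysis pipeline: cells
carry von Mises direction tuning (DS), axial period-180 tuning (OS) or no
tuning, and produce either per-direction integral responses directly or a
full fluorescence time series with slow drift, an indicator-like transient
kernel and frame noise.  Every draw is seeded; per-cell streams are derived
deterministically from (master seed, cell index) so datasets regenerate
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .angles import vm_shape, wrap_deg
from .protocol import StimulusProtocol, make_protocol
from .tuning import Trace, ResponseVector

__all__ = [
    "CellSpec",
    "SyntheticDataset",
    "sample_population",
    "set_noise_from_snr",
    "epoch_responses",
    "synth_trace",
    "make_dataset",
    "SIN_PEAKS_DEG",
    "SIN_FWHM_DEG",
    "RGC_PEAKS_DEG",
    "RGC_FWHM_DEG",
    "PVN_PEAKS_DEG",
    "SIN_COUNTS",
]

# Population constants of the emulated recordings: preferred-direction peaks
# and mean tuning bandwidths of the direction-selective subtypes at each
# layer, and the composition of the superficial-interneuron sample.
SIN_PEAKS_DEG = (9.0, 156.0, 257.0)
SIN_FWHM_DEG = (69.0, 83.0, 125.0)
RGC_PEAKS_DEG = (24.0, 131.0, 256.0)
RGC_FWHM_DEG = (107.0, 155.0, 156.0)
PVN_PEAKS_DEG = (27.0, 90.0, 136.0, 268.0)
SIN_COUNTS = {"DS": 177, "OS": 8, "untuned": 5}

CELL_CLASSES = ("DS", "OS", "untuned")


@dataclass(frozen=True)
class CellSpec:
    """Generative parameters of one cell (or voxel).

    ``baseline`` is both the flat fluorescence level of the cell's trace and
    the direction-independent offset of its integral responses; ``amplitude``
    scales the peak-normalized tuning shape, so peak response = baseline +
    amplitude.  ``noise_sd`` is the response-level Gaussian noise SD.
    """

    cell_class: str
    mu_deg: float = 0.0
    kappa: float = 2.0
    amplitude: float = 10.0
    baseline: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"cell_class must be one of {CELL_CLASSES}")
        object.__setattr__(self, "mu_deg", float(wrap_deg(self.mu_deg)))
        if self.kappa < 0 or self.amplitude < 0 or self.baseline < 0 or self.noise_sd < 0:
            raise ValueError("kappa, amplitude, baseline and noise_sd must be >= 0")

    def tuned_response(self, theta_deg):
        """Noiseless tuned response component, amplitude * shape(theta)."""
        theta = np.asarray(theta_deg, dtype=float)
        if self.cell_class == "DS":
            return self.amplitude * vm_shape(theta, self.mu_deg, self.kappa)
        if self.cell_class == "OS":
            return self.amplitude * vm_shape(theta, self.mu_deg, self.kappa, period180=True)
        return np.zeros_like(theta)

    def noiseless_response(self, theta_deg):
        """baseline + tuned component; what epoch_responses returns at noise_sd=0."""
        return self.baseline + self.tuned_response(theta_deg)


def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    """Per-cell random stream derived from (master seed, cell index)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(cell_index),)))


def sample_population(
    counts: dict,
    subtype_peaks=SIN_PEAKS_DEG,
    spread_deg: float = 15.0,
    seed: int = 0,
    subtype_fwhm_deg=SIN_FWHM_DEG,
    subtype_weights=None,
    amplitude: float = 10.0,
    baseline: float = 1.0,
    noise_sd: float = 0.0,
    os_kappa: float = 3.0,
) -> list:
    """Draw a mixed population of DS, OS and untuned cells.

    DS preferred directions are wrapped-normal draws around ``subtype_peaks``
    with circular SD ``spread_deg``; each DS cell inherits the concentration
    matching its subtype's mean bandwidth.  ``subtype_weights`` sets the
    relative subtype sizes (default: equal split).  OS cells get uniform
    preferred orientations; untuned cells have zero amplitude.
    """
    from .angles import kappa_from_fwhm

    counts = {**{c: 0 for c in CELL_CLASSES}, **counts}
    if any(v < 0 for v in counts.values()):
        raise ValueError("cell counts must be nonnegative")
    if counts["DS"] > 0 and len(subtype_peaks) == 0:
        raise ValueError("subtype_peaks must be nonempty when DS cells are requested")

    rng = np.random.default_rng(seed)
    peaks = np.asarray(subtype_peaks, dtype=float)
    kappas = np.asarray([kappa_from_fwhm(f) for f in subtype_fwhm_deg], dtype=float)
    if len(kappas) != len(peaks):
        raise ValueError("subtype_fwhm_deg must match subtype_peaks in length")
    if subtype_weights is None:
        subtype_weights = np.ones(len(peaks))
    w = np.asarray(subtype_weights, dtype=float)
    w = w / w.sum()

    cells = []
    subtype_of = rng.choice(len(peaks), size=counts["DS"], p=w)
    for s in subtype_of:
        mu = peaks[s] if spread_deg == 0 else rng.normal(peaks[s], spread_deg)
        cells.append(CellSpec("DS", mu_deg=wrap_deg(mu), kappa=float(kappas[s]),
                              amplitude=amplitude, baseline=baseline, noise_sd=noise_sd))
    for _ in range(counts["OS"]):
        cells.append(CellSpec("OS", mu_deg=rng.uniform(0, 360), kappa=os_kappa,
                              amplitude=amplitude, baseline=baseline, noise_sd=noise_sd))
    for _ in range(counts["untuned"]):
        cells.append(CellSpec("untuned", mu_deg=0.0, kappa=0.0, amplitude=0.0,
                              baseline=baseline, noise_sd=noise_sd))
    return cells


def set_noise_from_snr(cells, protocol: StimulusProtocol, snr: float) -> list:
    """Return cells with noise_sd set for a given signal-to-noise ratio.

    SNR is the ratio of the signal's RMS amplitude to the noise SD, the
    signal being the noiseless tuned response across the protocol's
    directions: ``noise_sd = std_theta(tuned response) / SNR`` ("SNR 5" means
    the tuned modulation is five times the noise).  Untuned cells have no
    signal of their own and receive the population median noise SD, so their
    responses are as noisy as everyone else's.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    dirs = np.asarray(protocol.directions, dtype=float)
    sds, tuned_idx = [], []
    out = list(cells)
    for i, c in enumerate(out):
        sig = c.tuned_response(dirs)
        sd = float(np.std(sig)) / snr
        if sd > 0:
            out[i] = CellSpec(c.cell_class, c.mu_deg, c.kappa, c.amplitude, c.baseline, sd)
            sds.append(sd)
            tuned_idx.append(i)
    fallback = float(np.median(sds)) if sds else 0.0
    for i, c in enumerate(out):
        if i not in tuned_idx:
            out[i] = CellSpec(c.cell_class, c.mu_deg, c.kappa, c.amplitude, c.baseline, fallback)
    return out


def epoch_responses(cell: CellSpec, protocol: StimulusProtocol, seed: int = 0,
                    n_repeats: int = 1) -> ResponseVector:
    """Per-direction integral responses: baseline + tuned shape + noise.

    With ``n_repeats > 1`` the returned response is the mean over that many
    independently noisy repeats, emulating trial averaging.  Directions follow
    the protocol's canonical (ascending) order, not the presentation order.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    dirs = np.asarray(sorted(protocol.directions), dtype=float)
    rng = np.random.default_rng(seed)
    clean = cell.noiseless_response(dirs)
    noise = rng.normal(0.0, cell.noise_sd, size=(n_repeats, dirs.size)) if cell.noise_sd > 0 \
        else np.zeros((n_repeats, dirs.size))
    return ResponseVector(directions=dirs, responses=clean + noise.mean(axis=0))


def _epoch_layout(protocol: StimulusProtocol, rng: np.random.Generator):
    """Frame-level layout: per-epoch windows and inter-epoch windows.

    The trace starts and ends with an inter-epoch interval; a blank epoch is
    inserted at a random position among the stimulus epochs.
    """
    fs = protocol.sampling_rate_hz
    n_ep = int(round(protocol.epoch_duration_s * fs))
    n_blank = int(round(protocol.blank_duration_s * fs))
    n_gap = int(round(protocol.interepoch_duration_s * fs))

    labels = list(protocol.presentation_order)
    blank_pos = int(rng.integers(0, len(labels) + 1))
    labels.insert(blank_pos, None)

    epoch_windows, inter_windows = [], []
    t = 0
    inter_windows.append((t, t + n_gap))
    t += n_gap
    for lab in labels:
        n = n_blank if lab is None else n_ep
        epoch_windows.append((t, t + n, lab))
        t += n
        inter_windows.append((t, t + n_gap))
        t += n_gap
    return epoch_windows, inter_windows, t


def _indicator_kernel(tau_s: float, fs: float) -> np.ndarray:
    n = max(int(round(6.0 * tau_s * fs)), 1)
    t = np.arange(n) / fs
    return np.exp(-t / tau_s)


def synth_trace(cell: CellSpec, protocol: StimulusProtocol, drift_amplitude: float = 0.0,
                seed: int = 0, indicator_tau_s: float = 1.5,
                frame_noise_sd: float = None) -> Trace:
    """Synthesize a fluorescence time series for one cell.

    Each stimulus epoch contributes a transient: the stimulus envelope
    (linear fade-in, plateau, fade-out) convolved with a single-exponential
    indicator kernel, scaled so its rectangle-rule integral over the epoch
    window equals the cell's tuned response ``amplitude * shape(direction)``.
    On top sit the cell's flat baseline, a smooth low-frequency drift (sum of
    two incommensurate sinusoids scaled by ``drift_amplitude``) and i.i.d.
    Gaussian frame noise (``frame_noise_sd``, defaulting to the cell's
    ``noise_sd``).  Baseline correction followed by epoch integration should
    therefore recover the tuned responses up to kernel-tail leakage.
    """
    rng = np.random.default_rng(seed)
    fs = protocol.sampling_rate_hz
    epoch_windows, inter_windows, n_frames = _epoch_layout(protocol, rng)

    values = np.full(n_frames, float(cell.baseline))

    kernel = _indicator_kernel(indicator_tau_s, fs)
    n_fade = int(round(protocol.fade_duration_s * fs))
    for start, end, lab in epoch_windows:
        if lab is None:
            continue
        resp = float(cell.tuned_response(float(lab)))
        if resp == 0.0:
            continue
        env = np.ones(end - start)
        if n_fade > 0:
            ramp = np.linspace(0.0, 1.0, n_fade, endpoint=False)
            env[:n_fade] = ramp
            env[-n_fade:] = ramp[::-1]
        full = np.zeros(n_frames)
        full[start:end] = env
        transient = np.convolve(full, kernel)[:n_frames]
        mass = transient[start:end].sum() / fs  # in-window integral of template
        values += resp * transient / mass

    if drift_amplitude != 0.0:
        t = np.arange(n_frames) / fs
        total = n_frames / fs
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        values += drift_amplitude * (np.sin(2 * np.pi * t / (total / 1.5) + ph1)
                                     + 0.5 * np.sin(2 * np.pi * t / (total / 3.7) + ph2))

    sd = cell.noise_sd if frame_noise_sd is None else frame_noise_sd
    if sd > 0:
        values += rng.normal(0.0, sd, size=n_frames)

    return Trace(values=values, sampling_rate_hz=fs,
                 epoch_windows=epoch_windows, interepoch_windows=inter_windows)


@dataclass
class SyntheticDataset:
    """A generated population with its response table and ground truth."""

    protocol: StimulusProtocol
    cells: list
    responses: pd.DataFrame  # columns: cell_id, direction_deg, response
    truth: dict
    seed: int

    def write(self, out_dir, stem: str = "synthetic"):
        """Write responses as CSV and ground truth as JSON; return the paths."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / f"{stem}_responses.csv"
        json_path = out / f"{stem}_truth.json"
        self.responses.to_csv(csv_path, index=False)
        with open(json_path, "w") as fh:
            json.dump(self.truth, fh, indent=1)
        return csv_path, json_path


def make_dataset(cells, protocol: StimulusProtocol = None, seed: int = 0,
                 n_repeats: int = 1) -> SyntheticDataset:
    """Generate the per-cell response table and ground-truth record."""
    if protocol is None:
        protocol = make_protocol(seed=seed)
    rows = []
    for i, cell in enumerate(cells):
        rv = epoch_responses(cell, protocol, seed=_cell_seed(seed, i), n_repeats=n_repeats)
        for d, r in zip(rv.directions, rv.responses):
            rows.append((i, d, r))
    responses = pd.DataFrame(rows, columns=["cell_id", "direction_deg", "response"])
    truth = {
        "seed": int(seed),
        "n_repeats": int(n_repeats),
        "cells": [dict(cell_id=i, **asdict(c)) for i, c in enumerate(cells)],
    }
    return SyntheticDataset(protocol=protocol, cells=list(cells), responses=responses,
                            truth=truth, seed=int(seed))


def _cell_seed(master_seed: int, cell_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(cell_index),))
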