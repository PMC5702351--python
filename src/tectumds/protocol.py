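"""Drifting-grating stimulus protocols.

The experiments this package emulates present sinusoidal gratings drifting
in 12 evenly spaced directions in pseudo-random order, with 3 s fade-in/out
per epoch, a randomly placed 2 s blank (mean-gray) epoch used for baseline
estimation, 0.05 cycles/degree spatial and 1 Hz temporal frequency, imaged
at roughly 4 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusProtocol", "make_protocol"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Epoch structure of one direction-tuning experiment.

    ``epoch_duration_s`` covers a full stimulus epoch including both fades;
    ``interepoch_duration_s`` is the gray interval separating epochs, from
    which baseline knots are taken (it must be at least as long as the
    baseline knot window, 5 s by default downstream).
    """

    directions: tuple = field(default=tuple(range(0, 360, 30)))
    presentation_order: tuple = None
    fade_duration_s: float = 3.0
    blank_duration_s: float = 2.0
    epoch_duration_s: float = 12.0
    interepoch_duration_s: float = 6.0
    sampling_rate_hz: float = 4.0
    spatial_frequency_cyc_per_deg: float = 0.05
    temporal_frequency_hz: float = 1.0

    def __post_init__(self):
        dirs = tuple(float(d) for d in self.directions)
        if len(dirs) < 2:
            raise ValueError("a protocol needs at least 2 stimulus directions")
        if len(set(dirs)) != len(dirs):
            raise ValueError("stimulus directions must be distinct")
        if any(d < 0.0 or d >= 360.0 for d in dirs):
            raise ValueError("directions must lie in [0, 360)")
        object.__setattr__(self, "directions", dirs)
        order = self.presentation_order
        if order is None:
            order = dirs
        order = tuple(float(d) for d in order)
        if sorted(order) != sorted(dirs):
            raise ValueError("presentation_order must be a permutation of directions")
        object.__setattr__(self, "presentation_order", order)
        for name in ("fade_duration_s", "blank_duration_s", "epoch_duration_s",
                     "interepoch_duration_s", "sampling_rate_hz",
                     "spatial_frequency_cyc_per_deg", "temporal_frequency_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if 2.0 * self.fade_duration_s > self.epoch_duration_s:
            raise ValueError("epoch_duration_s must accommodate both fades")

    @property
    def n_directions(self) -> int:
        return len(self.directions)


def make_protocol(n_directions: int = 12, seed: int = 0, **overrides) -> StimulusProtocol:
    """Build a protocol with evenly spaced directions in pseudo-random order.

    Directions are ``k * 360/n`` for k = 0..n-1; the presentation order is a
    permutation drawn from a generator seeded with ``seed``, so the same seed
    always yields the same order.
    """
    if n_directions < 2:
        raise ValueError("n_directions must be at least 2")
    dirs = tuple(float(k) * 360.0 / n_directions for k in range(n_directions))
    rng = np.random.default_rng(seed)
    order = tuple(dirs[i] for i in rng.permutation(n_directions))
    return StimulusProtocol(directions=dirs, presentation_order=order, **overrides)
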