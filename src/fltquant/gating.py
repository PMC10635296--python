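"""Core time-gating types shared by the simulator and the fitting stages.

A gated intensified camera samples a fluorescence decay by opening a gate of
fixed width at a sequence of delays after the excitation pulse. Counts in a
gate are the integral of the decay over the gate window, not point samples.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GateSequence", "DecaySpec", "TDImageStack"]


@dataclass(frozen=True)
class GateSequence:
    """Camera gating scheme.

    Parameters
    ----------
    gate_width : float
        Gate open duration in ns (default 0.5 ns, i.e. 500 ps).
    step : float
        Delay increment between consecutive gates in ns (default 0.2 ns).
    n_gates : int
        Number of gates (default 30).
    t0 : float
        Opening time of the first gate in ns.
    irf_sigma : float
        Gaussian instrument-response width in ns; 0 means ideal gating.
    """

    gate_width: float = 0.5
    step: float = 0.2
    n_gates: int = 30
    t0: float = 0.0
    irf_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.gate_width <= 0:
            raise ValueError("gate_width must be > 0")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.n_gates < 3:
            raise ValueError("n_gates must be >= 3")
        if self.irf_sigma < 0:
            raise ValueError("irf_sigma must be >= 0")

    @property
    def times(self) -> np.ndarray:
        """Gate opening times in ns (strictly increasing)."""
        return self.t0 + self.step * np.arange(self.n_gates)

    @property
    def duration(self) -> float:
        """Time from first gate opening to last gate closing, ns."""
        return self.step * (self.n_gates - 1) + self.gate_width


@dataclass(frozen=True)
class DecaySpec:
    """Multi-exponential decay: constant offset plus amplitude/lifetime pairs.

    ``components`` is a tuple of ``(amplitude, lifetime_ns)`` pairs. The
    amplitude is a photon rate (counts per ns at t=0 for that component);
    the per-gate expectation is its integral over the gate window.
    """

    a0: float = 0.0
    components: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.a0 < 0:
            raise ValueError("offset a0 must be >= 0")
        for amp, tau in self.components:
            if amp < 0:
                raise ValueError("component amplitudes must be >= 0")
            if tau <= 0:
                raise ValueError("component lifetimes must be > 0")


@dataclass
class TDImageStack:
    """Gated photon-count image cube, shape ``(n_gates, rows, cols)``."""

    data: np.ndarray
    gates: GateSequence = field(default_factory=GateSequence)
    exposure: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3-D (gate, row, col)")
        if self.data.shape[0] != self.gates.n_gates:
            raise ValueError(
                f"gate axis length {self.data.shape[0]} != n_gates "
                f"{self.gates.n_gates}"
            )
        if np.nanmin(self.data) < 0:
            raise ValueError("counts must be >= 0")
        if self.exposure <= 0:
            raise ValueError("exposure must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape
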