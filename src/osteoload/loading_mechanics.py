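"""Three-point-bending mechanics and loading-quality metrics.

A cortical explant resting on two holding points a span ``L`` apart is
deflected at mid-span by a sinusoidally driven indenter. For a beam of
thickness ``t`` the peak surface strain relates to the central deflection
through the Euler-Bernoulli flexure relation

    epsilon = 12 * c * delta / L**2,   c = t / 2

equivalently ``delta = epsilon * L**2 / (6 t)``. Strain is expressed in
microstrain (1 µɛ = 1e-6 absolute strain), geometry in mm, deflection in µm.

Session quality is summarised by two percentages: *contact preservation*
(force at the end of loading relative to the initial pre-load — contact
loss shows up as the final-cycle trough dropping below the pre-load) and
*displacement preservation* (peak indenter amplitude of the cycle at half
duration relative to the first cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ExplantGeometry

__all__ = [
    "LoadingProtocol",
    "LoadingTrace",
    "DoseResponseFit",
    "effective_thickness",
    "strain_to_displacement",
    "displacement_to_strain",
    "sinusoidal_waveform",
    "contact_preservation",
    "displacement_preservation",
    "dose_response_fit",
]


@dataclass(frozen=True)
class LoadingProtocol:
    """One cyclic loading session: 5 min of sinusoidal bending by default.

    ``preload`` (N) is the static force applied before cycling to guarantee
    indenter-explant contact (0.5 or 1 N in practice); ``frequency`` is one
    of 1, 1.5, 2 or 5 Hz in the characterised regimes.
    """

    target_strain: float = 1600.0  # µɛ
    frequency: float = 1.0  # Hz
    duration: float = 300.0  # s
    preload: float = 1.0  # N
    sample_rate: float = 100.0  # Hz
    geometry: ExplantGeometry = field(default_factory=ExplantGeometry)

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("frequency, duration and sample_rate must be > 0")
        if self.preload < 0:
            raise ValueError("preload must be >= 0")
        if self.target_strain < 0:
            raise ValueError("target_strain must be >= 0")

    @property
    def n_cycles(self) -> int:
        return int(np.floor(self.duration * self.frequency))


@dataclass
class LoadingTrace:
    """Synchronously recorded indenter displacement (µm) and force (N)."""

    time: np.ndarray  # s
    displacement: np.ndarray  # µm
    force: np.ndarray  # N
    protocol: LoadingProtocol

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if self.displacement.size != n or self.force.size != n:
            raise ValueError("time, displacement and force must have equal length")
        if n == 0:
            raise ValueError("trace is empty")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class DoseResponseFit:
    """OLS line through (magnitude, peak force) points."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def effective_thickness(t_end1: float, t_end2: float, t_center: float) -> float:
    """Mean of the two end thicknesses and the center thickness (mm)."""
    if t_end1 <= 0 or t_end2 <= 0 or t_center <= 0:
        raise ValueError("thickness measurements must be > 0")
    return (t_end1 + t_end2 + t_center) / 3.0


def strain_to_displacement(geometry: ExplantGeometry, strain_ue: float) -> float:
    """Central deflection (µm) producing ``strain_ue`` µɛ peak surface strain.

    delta = epsilon * L**2 / (6 t) with L = loading span, t = mean thickness.
    """
    if strain_ue < 0:
        raise ValueError("strain must be >= 0")
    L = geometry.loading_length
    t = geometry.mean_thickness
    if L <= 0 or t <= 0:
        raise ValueError("loading_length and thickness must be > 0")
    delta_mm = (strain_ue * 1e-6) * L**2 / (6.0 * t)
    return delta_mm * 1000.0


def displacement_to_strain(geometry: ExplantGeometry, displacement_um: float) -> float:
    """Exact inverse of :func:`strain_to_displacement`: epsilon = 6 t delta / L**2."""
    if displacement_um < 0:
        raise ValueError("displacement must be >= 0")
    L = geometry.loading_length
    t = geometry.mean_thickness
    if L <= 0 or t <= 0:
        raise ValueError("loading_length and thickness must be > 0")
    delta_mm = displacement_um / 1000.0
    return 6.0 * t * delta_mm / L**2 * 1e6


def sinusoidal_waveform(protocol: LoadingProtocol, amplitude_um: float) -> LoadingTrace:
    """Commanded indenter displacement: d(t) = (A/2)(1 - cos(2 pi f t)).

    Displacement starts at 0 (indenter at pre-load contact), rises first and
    peaks at A once per cycle. The force channel is filled with the constant
    pre-load (an ideal, infinitely stiff recording); generators add the
    specimen response on top.
    """
    if amplitude_um < 0:
        raise ValueError("amplitude must be >= 0")
    if protocol.sample_rate < 2 * protocol.frequency:
        raise ValueError("sample_rate must be at least twice the loading frequency")
    n = int(round(protocol.duration * protocol.sample_rate)) + 1
    t = np.arange(n) / protocol.sample_rate
    d = amplitude_um / 2.0 * (1.0 - np.cos(2.0 * np.pi * protocol.frequency * t))
    f = np.full(n, protocol.preload, dtype=float)
    return LoadingTrace(t, d, f, protocol)


def _cycle_slices(trace: LoadingTrace) -> list[np.ndarray]:
    """Index windows of complete cycles, from the protocol frequency."""
    period = 1.0 / trace.protocol.frequency
    t0 = trace.time[0]
    n_cycles = int(np.floor((trace.time[-1] - t0) / period + 1e-9))
    windows = []
    for k in range(n_cycles):
        sel = (trace.time >= t0 + k * period - 1e-12) & (
            trace.time <= t0 + (k + 1) * period + 1e-12
        )
        idx = np.flatnonzero(sel)
        if idx.size >= 2:
            windows.append(idx)
    return windows


def contact_preservation(trace: LoadingTrace) -> float:
    """Force at the end of loading as a percentage of the initial pre-load.

    The "force at the end" is the trough of the final cycle (the force when
    the indenter returns toward pre-load contact); 100% means contact was
    fully preserved, < 100% indicates contact loss.
    """
    if trace.protocol.preload <= 0:
        raise ValueError("contact preservation is undefined for zero pre-load")
    windows = _cycle_slices(trace)
    if not windows:
        raise ValueError("trace does not contain a complete cycle")
    final_trough = float(np.min(trace.force[windows[-1]]))
    return 100.0 * final_trough / trace.protocol.preload


def displacement_preservation(trace: LoadingTrace) -> float:
    """Peak amplitude of the cycle at half duration vs the first cycle, in %.

    Amplitude is measured per cycle as max - min of the displacement channel;
    the half-duration cycle is the one containing t = duration / 2.
    """
    windows = _cycle_slices(trace)
    if len(windows) < 2:
        raise ValueError("trace must span at least 2 complete cycles")
    t_half = trace.time[0] + (trace.time[-1] - trace.time[0]) / 2.0
    mid = windows[-1]
    for w in windows:
        if trace.time[w[0]] <= t_half <= trace.time[w[-1]]:
            mid = w
            break
    amp0 = float(np.ptp(trace.displacement[windows[0]]))
    if amp0 <= 0:
        raise ValueError("first-cycle amplitude is zero")
    amp_half = float(np.ptp(trace.displacement[mid]))
    return 100.0 * amp_half / amp0


def dose_response_fit(magnitudes: np.ndarray, peak_forces: np.ndarray) -> DoseResponseFit:
    """OLS line through (loading magnitude, peak force) with R² and slope p.

    Magnitudes may be displacements (µm) or strains (µɛ); the slope then
    carries N/µm or N/µɛ respectively.
    """
    x = np.asarray(magnitudes, dtype=float)
    y = np.asarray(peak_forces, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("magnitudes and peak_forces must be equal-length 1D arrays")
    if x.size < 3:
        raise ValueError("at least 3 points are required")
    if np.ptp(x) == 0:
        raise ValueError("magnitudes have zero variance")
    if np.ptp(y) == 0:
        return DoseResponseFit(0.0, float(y[0]), 0.0, 1.0)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue)
    if not np.isfinite(p) or p <= 0.0:
        p = 1.0 if r2 == 0.0 else np.nextafter(0.0, 1.0)
    return DoseResponseFit(float(res.slope), float(res.intercept), r2, min(p, 1.0))
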