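"""Blood properties, inlet waveform, numerics configuration and results.

The 1D model couples mass and momentum balance in each vessel with the
elastic tube law

    P(A) = Pext + beta (sqrt(A/A0) - 1),   beta = sqrt(pi/A0) E h0 / (1 - nu^2)

whose pulse wave speed is c(A) = sqrt(beta / (2 rho sqrt(A0))) A^(1/4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class BloodProperties:
    """Newtonian blood.

    ``profile_exponent`` (gamma_v) sets the velocity-profile shape in the
    viscous friction term (2 = parabolic/Poiseuille); ``coriolis_coefficient``
    (alpha) is the momentum-flux correction.  alpha = 1 keeps the
    total-pressure junction coupling exact.
    """

    density: float = 1060.0  # kg/m^3
    viscosity: float = 4.0e-3  # Pa s
    profile_exponent: float = 2.0
    coriolis_coefficient: float = 1.0

    def __post_init__(self):
        if not self.density > 0 or not self.viscosity > 0:
            raise ValueError("density and viscosity must be positive")
        if self.profile_exponent < 2 or self.coriolis_coefficient < 1:
            raise ValueError("require gamma_v >= 2 and alpha >= 1")


@dataclass
class NumericsConfig:
    target_cell_size: float = 7.5e-3  # m
    min_cells_per_vessel: int = 3
    cfl_number: float = 0.9
    convergence_tolerance: float = 0.01  # relative, cycle-to-cycle
    max_cycles: int = 50
    samples_per_cycle: int = 200

    def __post_init__(self):
        if not 0 < self.cfl_number <= 1:
            raise ValueError("CFL number must be in (0, 1]")
        if self.min_cells_per_vessel < 3:
            raise ValueError("need at least 3 cells per vessel")
        if not self.convergence_tolerance > 0:
            raise ValueError("convergence tolerance must be positive")


@dataclass
class InletWaveform:
    """One period of prescribed volumetric inflow (periodic, m^3/s)."""

    period: float
    flow_samples: np.ndarray  # uniform samples on [0, T)
    cardiac_output: float  # cycle mean, m^3/s

    def __post_init__(self):
        self.flow_samples = np.asarray(self.flow_samples, dtype=float)
        if not self.period > 0:
            raise ValueError("period must be positive")
        mean = float(self.flow_samples.mean())
        if abs(mean - self.cardiac_output) > 1e-3 * abs(self.cardiac_output):
            raise ValueError(
                f"cycle mean {mean} deviates from declared cardiac output "
                f"{self.cardiac_output} by more than 0.1%")

    def __call__(self, t):
        """Periodic linear interpolation of the flow at time ``t``."""
        s = np.mod(t, self.period) / self.period * len(self.flow_samples)
        i0 = np.asarray(np.floor(s), dtype=int) % len(self.flow_samples)
        i1 = (i0 + 1) % len(self.flow_samples)
        w = s - np.floor(s)
        return (1 - w) * self.flow_samples[i0] + w * self.flow_samples[i1]

    def scaled(self, factor: float) -> "InletWaveform":
        return InletWaveform(self.period, self.flow_samples * factor,
                             self.cardiac_output * factor)


# systolic-lobe fractions of the aortic template: ejection duration,
# early-diastolic reverse lobe duration and relative amplitude
_SYS_FRAC = 0.38
_REV_FRAC = 0.06
_REV_AMP = 0.12


def generate_inlet_waveform(cardiac_output: float, heart_rate: float = 70.0,
                            shape: str = "aortic", n_samples: int = 512) -> InletWaveform:
    """Aortic root flow template scaled to a cardiac output and heart rate.

    The template has a half-sine systolic ejection lobe, a small reverse
    lobe at valve closure, and zero flow in late diastole; the amplitude is
    set so the cycle mean equals ``cardiac_output`` (m^3/s) exactly.
    """
    if shape != "aortic":
        raise ValueError(f"unknown waveform template '{shape}'")
    if not cardiac_output > 0 or not heart_rate > 0:
        raise ValueError("cardiac output and heart rate must be positive")
    T = 60.0 / heart_rate
    t = np.arange(n_samples) / n_samples  # fraction of cycle
    lobe = np.where(t < _SYS_FRAC, np.sin(np.pi * np.minimum(t, _SYS_FRAC) / _SYS_FRAC), 0.0)
    rev_phase = (t - _SYS_FRAC) / _REV_FRAC
    rev = np.where((rev_phase > 0) & (rev_phase < 1),
                   -_REV_AMP * np.sin(np.pi * np.clip(rev_phase, 0, 1)), 0.0)
    samples = lobe + rev
    samples *= cardiac_output / samples.mean()
    return InletWaveform(T, samples, cardiac_output)


def read_inlet_waveform(path) -> InletWaveform:
    """Read one period of inflow from two-column text (time_s, flow_m3_s).

    Times must be uniformly spaced starting at 0; the declared cardiac
    output is the cycle mean of the samples.
    """
    data = np.loadtxt(path, delimiter=",", comments="#")
    if data.ndim != 2 or data.shape[1] != 2 or len(data) < 4:
        raise ValueError("expected two columns (time_s, flow_m3_s)")
    t, q = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if t[0] != 0.0 or np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0]:
        raise ValueError("times must be uniform and start at 0")
    period = t[-1] + dt[0]
    return InletWaveform(float(period), q, float(q.mean()))


def write_inlet_waveform(waveform: InletWaveform, path) -> None:
    t = np.arange(len(waveform.flow_samples)) / len(waveform.flow_samples) \
        * waveform.period
    np.savetxt(path, np.column_stack([t, waveform.flow_samples]),
               delimiter=",", header="time_s,flow_m3_s")


def tube_law_beta(youngs_modulus: float, wall_thickness: float,
                  poisson_ratio: float, reference_area: float) -> float:
    """Stiffness coefficient beta = sqrt(pi/A0) E h0 / (1 - nu^2), Pa."""
    return (math.sqrt(math.pi / reference_area) * youngs_modulus * wall_thickness
            / (1.0 - poisson_ratio ** 2))


def tube_law_pressure(area, reference_area, beta, external_pressure=0.0):
    """Transmural tube law P = Pext + beta (sqrt(A/A0) - 1)."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0) or np.any(np.asarray(reference_area) <= 0):
        raise ValueError("areas must be positive")
    return external_pressure + beta * (np.sqrt(area / reference_area) - 1.0)


def wave_speed(area, reference_area, beta, density):
    """Pulse wave speed c = sqrt(beta/(2 rho sqrt(A0))) A^(1/4).

    Follows from c^2 = (A/rho) dP/dA applied to the tube law.
    """
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    return np.sqrt(beta / (2.0 * density * np.sqrt(reference_area))) * area ** 0.25


@dataclass
class SimulationResult:
    """Final-cycle waveforms at the network probes.

    All per-probe series have ``samples_per_cycle`` entries covering one
    period; velocity is flow/area pointwise.
    """

    t: np.ndarray
    pressure: dict[str, np.ndarray]
    flow: dict[str, np.ndarray]
    area: dict[str, np.ndarray]
    cycles_to_convergence: int = 0
    converged: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def velocity(self) -> dict[str, np.ndarray]:
        return {k: self.flow[k] / self.area[k] for k in self.flow}

    @property
    def probe_names(self) -> list[str]:
        return list(self.pressure)
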