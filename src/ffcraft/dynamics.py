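"""Langevin dynamics on an arbitrary force callable.

BAOAB-split velocity-Verlet integrator with an Ornstein-Uhlenbeck
thermostat step. Units: Å, ps, amu, kJ/mol (1 kJ/mol = 100 amu Å²/ps²).
The integrator is deterministic under a seeded Generator and supports a
per-step callback used for snapshotting and error monitoring.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .data import KB_KJMOL

# kJ/mol -> amu Å^2 / ps^2
_ENERGY_TO_INTERNAL = 100.0


class DynamicsError(RuntimeError):
    """Numerical blow-up during integration; names the offending step."""


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Velocities in Å/ps drawn from the Maxwell-Boltzmann distribution."""
    sigma = np.sqrt(_ENERGY_TO_INTERNAL * KB_KJMOL * temperature / masses)
    return rng.standard_normal((len(masses), 3)) * sigma[:, None]


def langevin(
    x0: np.ndarray,
    masses: np.ndarray,
    force_fn: Callable[[np.ndarray], np.ndarray],
    n_steps: int,
    timestep_fs: float = 0.5,
    temperature: float = 300.0,
    friction_per_ps: float = 5.0,
    rng: np.random.Generator | None = None,
    callback: Callable[[int, np.ndarray], bool | None] | None = None,
    blowup_limit: float = 1e5,
) -> np.ndarray:
    """Propagate and return the final coordinates.

    ``force_fn`` maps coordinates (Å) to forces (kJ/mol/Å). The callback
    receives (step index, coordinates) after each step; returning True
    stops the run early. Coordinates or forces exceeding
    ``blowup_limit`` raise :class:`DynamicsError`.
    """
    rng = rng or np.random.default_rng()
    dt = timestep_fs * 1e-3  # ps
    x = np.array(x0, dtype=float)
    m = np.asarray(masses, dtype=float)[:, None]
    v = maxwell_boltzmann_velocities(np.asarray(masses, dtype=float), temperature, rng)
    c1 = np.exp(-friction_per_ps * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * _ENERGY_TO_INTERNAL * KB_KJMOL * temperature / m)
    f = force_fn(x)
    for step in range(n_steps):
        v = v + 0.5 * dt * f * _ENERGY_TO_INTERNAL / m
        x = x + 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x = x + 0.5 * dt * v
        f = force_fn(x)
        if not np.all(np.isfinite(x)) or np.abs(x).max() > blowup_limit or not np.all(
            np.isfinite(f)
        ):
            raise DynamicsError(f"integration blew up at step {step}")
        v = v + 0.5 * dt * f * _ENERGY_TO_INTERNAL / m
        if callback is not None and callback(step, x):
            break
    return x
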