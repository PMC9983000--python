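"""Independent numerical oracles used only by the tests.

These deliberately avoid the closed-form expressions in the package: the
trajectory oracle integrates the equations of motion step by step with a
velocity-Verlet scheme, and the spectral oracle evaluates the O(N^2) DFT
definition directly.
"""

from __future__ import annotations

import numpy as np

ELEMENTARY_CHARGE = 1.602176634e-19
ATOMIC_MASS = 1.66053906660e-27


def integrate_uniform_gap(
    mz: float,
    charge: int,
    potential: float,
    gap: float = 0.010,
    n_steps: int = 2000,
):
    """Velocity-Verlet integration of an ion from rest through a uniform
    field gap (field = potential/gap), returning (exit speed, transit time).

    Uses adaptive fixed steps in time chosen from the analytic transit-time
    scale only to size the step, never to set the answer.
    """
    m = mz * charge * ATOMIC_MASS
    a = charge * ELEMENTARY_CHARGE * (potential / gap) / m
    if a == 0.0:
        return 0.0, np.inf
    # time scale from s = a t^2 / 2 just to size dt
    t_scale = np.sqrt(2.0 * gap / a)
    dt = t_scale / n_steps
    x = 0.0
    v = 0.0
    t = 0.0
    while x < gap:
        x_new = x + v * dt + 0.5 * a * dt * dt
        v_new = v + a * dt
        if x_new >= gap:
            # interpolate the crossing inside the last step
            disc = v * v + 2.0 * a * (gap - x)
            dt_last = (np.sqrt(disc) - v) / a
            v = v + a * dt_last
            t = t + dt_last
            x = gap
            break
        x, v, t = x_new, v_new, t + dt
    return v, t


def drift_position(speed: float, delay: float, zone_start: float) -> float:
    """Field-free lateral drift oracle (trivially integrated)."""
    n = 1000
    dt = delay / n if delay > 0 else 0.0
    x = 0.0
    for _ in range(n):
        x += speed * dt
    return x - zone_start


def integrate_deflection(
    mz: float,
    charge: int,
    field: float,
    pulse_length: float,
    entry_speed: float,
    entry_angle: float,
    drift: float,
    n_steps: int = 5000,
):
    """Step-by-step integration of the pulsed-deflection exit geometry.

    The orthogonal acceleration acts for ``pulse_length``; afterwards the
    ion drifts a forward distance ``drift``.  Returns (exit angle,
    orthogonal displacement relative to the undeflected path, final speed).
    """
    m = mz * charge * ATOMIC_MASS
    a = charge * ELEMENTARY_CHARGE * field / m
    vx = entry_speed * np.cos(entry_angle)  # forward
    vy = entry_speed * np.sin(entry_angle)  # orthogonal
    dt = pulse_length / n_steps if pulse_length > 0 else 0.0
    y = 0.0
    for _ in range(n_steps):
        y += vy * dt + 0.5 * a * dt * dt
        vy += a * dt
    theta_f = np.arctan2(vy, vx)
    # drift a further forward distance; compare against the undeflected ion
    t_drift = drift / vx
    y_final = y + vy * t_drift
    y_undeflected = entry_speed * np.sin(entry_angle) * (
        pulse_length + t_drift
    )
    v_final = np.hypot(vx, vy)
    return theta_f, y_final - y_undeflected, v_final


def direct_dft_magnitude(x: np.ndarray, n_out: int | None = None) -> np.ndarray:
    """O(N^2) one-sided DFT magnitude straight from the definition."""
    x = np.asarray(x, dtype=float)
    n = x.size if n_out is None else n_out
    xp = np.zeros(n)
    xp[: x.size] = x
    k = np.arange(n // 2 + 1)
    j = np.arange(n)
    kernel = np.exp(-2j * np.pi * np.outer(k, j) / n)
    return np.abs(kernel @ xp)
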