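"""Trajectory-level check of the capture predictor.

Integrates the overdamped transport law

    dx/dt = μEK · E + μDEP · ∇|E|²   (+ optional Brownian term)

through a solved field with reflecting walls.  Mobilities are *signed*:
trapping corresponds to a dielectrophoretic term that opposes electrokinetic
motion into a gate (negative ``mu_dep`` with the field oriented inlet →
outlet), in which case the particle stalls just upstream of the first gate
whose peak capture parameter meets or exceeds ``μEK/|μDEP|``.  That stall
point is what the gate-threshold predictor claims; this module recomputes it
from the velocity field with no reference to thresholds.

Euler–Maruyama stepping with bilinear field interpolation; the time step is
adapted so no step exceeds half a grid cell.  A particle is *captured* when
its mean displacement over a trailing window falls below a small fraction of
a cell, *exited* when it crosses the outlet face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .field import FieldSolution
from .geometry import DomainMask

__all__ = ["TrajectoryResult", "advect"]

_UM = 1e-6


@dataclass(frozen=True)
class TrajectoryResult:
    """Outcome of one integrated trajectory.

    ``status`` is ``"captured"``, ``"exited"`` or ``"max_steps"``;
    ``gate`` is the 1-based index of the gate a captured particle stalled
    against (None otherwise).  ``path`` holds subsampled (t, x, y) rows in
    (s, μm, μm).
    """

    status: str
    gate: int | None
    position_um: tuple[float, float]
    path: np.ndarray
    n_steps: int
    seed: int | None
    time_s: float = 0.0


def _interpolators(solution: FieldSolution):
    mask = solution.mask
    h = mask.spacing
    nx, ny = mask.shape
    xs = (np.arange(nx) + 0.5) * h
    ys = (np.arange(ny) + 0.5) * h
    fields = []
    for grid in (solution.ex, solution.ey, solution.grad_e2_x, solution.grad_e2_y):
        g = np.where(mask.fluid, grid, 0.0)  # zero velocity inside walls
        fields.append(
            RegularGridInterpolator(
                (xs, ys), g, bounds_error=False, fill_value=0.0
            )
        )
    return fields


def _gate_of(mask: DomainMask, x_um: float) -> int | None:
    """First gate whose throat lies at/downstream of ``x_um``."""
    for g, (ix, _) in enumerate(mask.throats):
        if (ix + 0.5) * mask.spacing >= x_um - mask.spacing:
            return g + 1
    return None


def advect(
    mu_ek: float,
    mu_dep: float,
    solution: FieldSolution,
    *,
    start_um: tuple[float, float] | None = None,
    dt: float = 1e-3,
    max_steps: int = 200_000,
    diffusion: float = 0.0,
    seed: int | None = None,
    stagnation_window: int = 500,
    stagnation_frac: float = 0.01,
    path_stride: int = 200,
) -> TrajectoryResult:
    """Integrate one particle through the solved field.

    Parameters
    ----------
    mu_ek, mu_dep:
        Signed mobilities, m²/(V·s) and m⁴/(V²·s).  For a trapping particle
        pass ``mu_dep < 0`` (dielectrophoresis opposing motion up the field
        gradient).
    start_um:
        Launch point in μm; defaults to the inlet on the channel centerline.
    dt:
        Nominal time step, s; shortened adaptively so a step never exceeds
        half a grid cell.
    diffusion:
        Isotropic diffusion coefficient, m²/s (0 disables the Brownian term).
    stagnation_window, stagnation_frac:
        Capture is declared when mean displacement per step over the trailing
        window drops below ``stagnation_frac`` grid cells.
    """
    mask = solution.mask
    h = mask.spacing
    nx, ny = mask.shape
    if start_um is None:
        start_um = (0.5 * h, (ny / 2.0) * h)
    x, y = float(start_um[0]), float(start_um[1])
    if not _in_fluid(mask, x, y):
        raise ValueError("particle initialized outside the fluid domain")

    fx, fy, gx, gy = _interpolators(solution)
    rng = np.random.default_rng(seed) if diffusion > 0 else None
    # exit at the last cell center: beyond it the interpolated field is not
    # defined, and a particle that got this far has cleared every gate
    length_um = (nx - 0.5) * h

    path = [(0.0, x, y)]
    t = 0.0
    recent = np.zeros(stagnation_window)
    step_disp_sum = 0.0
    for step in range(max_steps):
        p = np.array([[x, y]])
        vx = mu_ek * fx(p)[0] + mu_dep * gx(p)[0]   # m/s
        vy = mu_ek * fy(p)[0] + mu_dep * gy(p)[0]
        speed_um = np.hypot(vx, vy) / _UM
        dt_eff = dt if speed_um * dt <= 0.5 * h else 0.5 * h / speed_um
        ddx = vx * dt_eff / _UM
        ddy = vy * dt_eff / _UM
        if rng is not None:
            s = np.sqrt(2.0 * diffusion * dt_eff) / _UM
            ddx += s * rng.standard_normal()
            ddy += s * rng.standard_normal()

        nx_, ny_ = x + ddx, y + ddy
        if nx_ >= length_um:
            t += dt_eff
            path.append((t, nx_, y + ddy))
            return TrajectoryResult(
                "exited", None, (x, y), np.array(path), step + 1, seed, t
            )
        # reflecting walls: cancel components that would enter insulator
        if not _in_fluid(mask, nx_, ny_):
            if _in_fluid(mask, nx_, y):
                ny_ = y
            elif _in_fluid(mask, x, ny_):
                nx_ = x
            else:
                nx_, ny_ = x, y
        moved = float(np.hypot(nx_ - x, ny_ - y))
        x, y, t = nx_, ny_, t + dt_eff

        i = step % stagnation_window
        step_disp_sum += moved - recent[i]
        recent[i] = moved
        if step % path_stride == 0:
            path.append((t, x, y))
        if step + 1 >= stagnation_window:
            if step_disp_sum / stagnation_window < stagnation_frac * h:
                path.append((t, x, y))
                return TrajectoryResult(
                    "captured", _gate_of(mask, x), (x, y), np.array(path),
                    step + 1, seed, t,
                )
    path.append((t, x, y))
    return TrajectoryResult(
        "max_steps", None, (x, y), np.array(path), max_steps, seed, t
    )


def _in_fluid(mask: DomainMask, x_um: float, y_um: float) -> bool:
    i = int(x_um / mask.spacing)
    j = int(y_um / mask.spacing)
    nx, ny = mask.shape
    if i < 0 or j < 0 or j >= ny:
        return False
    if i >= nx:
        return True  # past the outlet face counts as fluid (about to exit)
    return bool(mask.fluid[i, j])
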