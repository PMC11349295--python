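"""Electrostatics in the rasterized channel and gate capture thresholds.

The potential solves Laplace's equation on the fluid region with the applied
voltage on the inlet face, ground on the outlet face, and insulating
(zero normal flux) walls and teeth.  From the potential we derive

* the field ``E = -∇φ`` (V/m),
* its squared magnitude gradient ``∇|E|²`` (V²/m³), and
* the *capture parameter* ``c = (∇|E|² · E) / |E|²`` (V/m²),

the field-side quantity that a particle's electrokinetic-to-dielectrophoretic
mobility ratio (EKMr) is compared against: a particle is trapped at a gate
whose peak capture parameter meets or exceeds its EKMr.

Because the Laplace problem is linear in the applied voltage, ``c`` scales
linearly with voltage; gate thresholds are stored at 1 V applied and scaled
on demand.

Internally the grid spacing is in μm; derived fields are converted to SI
(V/m, V/m², ...) so that EKMr values compare directly to the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import DomainMask

__all__ = [
    "FieldSolution",
    "GateProfile",
    "solve_potential",
    "capture_parameter",
    "gate_thresholds",
    "thresholds_at",
]

_UM = 1e-6  # metres per micrometre


@dataclass(frozen=True)
class FieldSolution:
    """Potential and derived grids on the fluid raster (NaN on insulator).

    Grids are indexed ``[ix, iy]`` with x the axial (inlet → outlet)
    direction.  ``potential`` is in V; ``ex, ey, e_mag`` in V/m;
    ``grad_e2_x/y`` in V²/m³; ``reference_voltage`` is the applied
    inlet-outlet potential difference.
    """

    mask: DomainMask
    potential: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    e_mag: np.ndarray
    grad_e2_x: np.ndarray
    grad_e2_y: np.ndarray
    reference_voltage: float
    residual: float


@dataclass(frozen=True)
class GateProfile:
    """Per-gate capture-parameter thresholds at 1 V applied (V/m² per volt).

    ``calibration`` is a single multiplicative factor applied to all
    thresholds (default 1), provided because the absolute capture-parameter
    scale depends on tooth-shape details that are configurable rather than
    measured.
    """

    unit_thresholds: np.ndarray
    mask: DomainMask
    calibration: float = 1.0

    @property
    def n_gates(self) -> int:
        return len(self.unit_thresholds)

    def __len__(self) -> int:
        return self.n_gates


def _masked_gradient(f: np.ndarray, fluid: np.ndarray, spacing_m: float):
    """Gradient of ``f`` over the fluid mask.

    Central differences where both neighbours are fluid, one-sided at walls,
    zero where a cell has no fluid neighbour along the axis.  ``f`` must be
    finite on fluid cells; insulator cells are ignored.
    """
    grads = []
    for axis in (0, 1):
        fw = np.roll(f, -1, axis=axis)   # value at i+1
        bw = np.roll(f, 1, axis=axis)    # value at i-1
        has_fw = np.roll(fluid, -1, axis=axis) & fluid
        has_bw = np.roll(fluid, 1, axis=axis) & fluid
        # roll wraps around: sever the wrap at the array edges
        edge_lo = [slice(None), slice(None)]
        edge_hi = [slice(None), slice(None)]
        edge_lo[axis] = slice(0, 1)
        edge_hi[axis] = slice(-1, None)
        has_bw[tuple(edge_lo)] = False
        has_fw[tuple(edge_hi)] = False

        g = np.zeros_like(f)
        both = has_fw & has_bw
        only_fw = has_fw & ~has_bw
        only_bw = has_bw & ~has_fw
        g[both] = (fw[both] - bw[both]) / (2 * spacing_m)
        g[only_fw] = (fw[only_fw] - f[only_fw]) / spacing_m
        g[only_bw] = (f[only_bw] - bw[only_bw]) / spacing_m
        g[~fluid] = np.nan
        grads.append(g)
    return grads


def solve_potential(
    mask: DomainMask,
    voltage: float,
    *,
    tol: float = 1e-8,
) -> FieldSolution:
    """Solve Laplace's equation on the fluid raster.

    Five-point finite differences on cell centers; Dirichlet inlet/outlet
    faces are imposed through ghost cells (face value held at ``voltage``
    resp. 0), insulating boundaries through zero-flux ghosts.  The sparse
    system is solved by direct LU factorization; the relative residual is
    checked against ``tol``.

    Parameters
    ----------
    mask:
        Rasterized fluid domain.
    voltage:
        Applied inlet-outlet potential difference, V (> 0).
    """
    if voltage <= 0:
        raise ValueError("applied voltage must be positive")
    fluid = mask.fluid
    nx, ny = fluid.shape
    n = int(fluid.sum())
    if n == 0:
        raise ValueError("empty fluid domain")

    num = -np.ones(fluid.shape, dtype=np.int64)
    num[fluid] = np.arange(n)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    b = np.zeros(n)

    for axis, step in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb_fluid = np.roll(fluid, -step, axis=axis)
        sl = [slice(None), slice(None)]
        sl[axis] = slice(-1, None) if step == 1 else slice(0, 1)
        nb_fluid[tuple(sl)] = False  # neighbours beyond the array edge

        here = fluid & nb_fluid
        i = num[here]
        j = np.roll(num, -step, axis=axis)[here]
        rows.append(i)
        cols.append(j)
        vals.append(-np.ones(i.size))
        diag[i] += 1.0

    # Dirichlet faces: inlet (x = 0) at `voltage`, outlet (x = L) at 0.
    inlet_ids = num[0, mask.inlet_cells]
    outlet_ids = num[-1, mask.outlet_cells]
    diag[inlet_ids] += 2.0
    b[inlet_ids] += 2.0 * voltage
    diag[outlet_ids] += 2.0
    # outlet ghost value is 0 → no RHS contribution

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ) + sp.diags(diag)

    lu = spla.splu(A.tocsc())
    phi_v = lu.solve(b)
    res = float(np.linalg.norm(A @ phi_v - b) / np.linalg.norm(b))
    if res > tol:
        raise RuntimeError(f"Laplace solve did not converge: residual {res:.2e}")

    phi = np.full(fluid.shape, np.nan)
    phi[fluid] = phi_v

    h_m = mask.spacing * _UM
    dphix, dphiy = _masked_gradient(phi, fluid, h_m)
    ex, ey = -dphix, -dphiy
    e2 = ex**2 + ey**2
    e2_filled = np.where(fluid, e2, 0.0)
    gx, gy = _masked_gradient(e2_filled, fluid, h_m)

    return FieldSolution(
        mask=mask,
        potential=phi,
        ex=ex,
        ey=ey,
        e_mag=np.sqrt(e2),
        grad_e2_x=gx,
        grad_e2_y=gy,
        reference_voltage=float(voltage),
        residual=res,
    )


def capture_parameter(
    solution: FieldSolution,
    *,
    e_floor_rel: float = 1e-6,
) -> np.ndarray:
    """Capture parameter ``c = (∇|E|² · E) / |E|²`` per cell, V/m².

    Positive where the field-magnitude gradient points along the local field
    (the situation a particle moving electrokinetically toward a gate
    encounters on the approach side).  Cells whose field magnitude falls
    below ``e_floor_rel`` times the median fluid |E| are flagged NaN rather
    than divided through.
    """
    e2 = solution.e_mag**2
    num = solution.grad_e2_x * solution.ex + solution.grad_e2_y * solution.ey
    fluid = solution.mask.fluid
    floor = (e_floor_rel * np.nanmedian(solution.e_mag[fluid])) ** 2
    c = np.full(e2.shape, np.nan)
    ok = fluid & (e2 > floor)
    c[ok] = num[ok] / e2[ok]
    return c


def gate_thresholds(
    solution: FieldSolution,
    mask: DomainMask | None = None,
    *,
    calibration: float = 1.0,
    window_cells: int | None = None,
) -> GateProfile:
    """Per-gate capture thresholds, rescaled to 1 V applied.

    The threshold of gate *g* is the maximum positive capture parameter a
    particle travelling along the channel centerline encounters while
    crossing the gate: ``c`` is evaluated on the center row of the gate
    opening over an axial window covering the gate's approach region — the
    tooth footprint plus the constriction length scale, since the field
    magnitude starts rising upstream of the teeth themselves (or
    ``window_cells`` cells each side of the throat if given) — and the
    maximum is divided by the applied voltage.

    Returns an empty profile for a gate-free mask.
    """
    if mask is None:
        mask = solution.mask
    c = capture_parameter(solution)
    nx, _ = mask.shape
    geometry = mask.geometry
    thresholds = []
    for g, (ix, rows) in enumerate(mask.throats):
        if window_cells is None:
            if geometry is not None:
                gate = geometry.gates[g]
                half = max(
                    geometry.tooth_base_half_length(gate),
                    geometry.tooth_depth(gate),
                )
                w = max(2, int(np.ceil(half / mask.spacing)) + 5)
            else:
                w = 2
        else:
            w = int(window_cells)
        iy = int(rows[len(rows) // 2])  # center row of the opening
        lo, hi = max(0, ix - w), min(nx, ix + w + 1)
        seg = c[lo:hi, iy]
        seg = seg[np.isfinite(seg) & (seg > 0)]
        if seg.size == 0:
            raise ValueError(f"gate {g + 1}: no defined capture parameter at throat")
        thresholds.append(seg.max() / solution.reference_voltage)
    return GateProfile(
        unit_thresholds=np.asarray(thresholds) * calibration,
        mask=mask,
        calibration=calibration,
    )


def thresholds_at(profile: GateProfile, voltage: float) -> np.ndarray:
    """Thresholds (V/m²) at an applied voltage: elementwise ``voltage × c_g``."""
    if voltage < 0:
        raise ValueError("voltage must be non-negative")
    return profile.unit_thresholds * voltage
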