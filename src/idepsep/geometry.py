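"""Sawtooth separation-channel geometry and rasterization.

The separation channel is a long, shallow microchannel whose side walls carry
pairs of insulating triangular teeth.  Each opposing pair leaves a narrow
opening — a *gate* — on the channel centerline.  Gate openings shrink from
inlet to outlet, so the electric-field concentration (and with it the
dielectrophoretic trapping strength) increases gate by gate.  The model is
two-dimensional: channel depth is carried as metadata only.

Units: all in-plane lengths are micrometres unless a name says otherwise
(``length_cm``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GateSpec",
    "ChannelGeometry",
    "DomainMask",
    "build_reference_geometry",
    "rasterize",
]

#: Width schedule of the reference device: nine widths, each used by three
#: consecutive gates, stepping linearly from the widest (inlet) to the
#: narrowest (outlet) opening.
REFERENCE_WIDTHS_UM = (73.0, 67.0, 61.0, 55.0, 49.0, 43.0, 37.0, 31.0, 25.0)
REFERENCE_GATE_COUNT = 27
REFERENCE_GROUP_SIZE = 3
REFERENCE_LENGTH_CM = 3.5
REFERENCE_DEPTH_UM = 20.0


@dataclass(frozen=True)
class GateSpec:
    """One constriction: 1-based ordinal, opening width and axial position (μm)."""

    index: int
    width: float
    axial_position: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"gate index must be >= 1, got {self.index}")
        if self.width <= 0:
            raise ValueError(f"gate width must be positive, got {self.width}")
        if self.axial_position <= 0:
            raise ValueError("gate axial position must be positive")


@dataclass(frozen=True)
class ChannelGeometry:
    """Ordered gate list plus the channel envelope.

    Parameters
    ----------
    gates:
        Gate specifications ordered inlet → outlet.  Axial positions must be
        strictly increasing and widths non-increasing.
    length_cm:
        Inlet-to-outlet channel length in centimetres.
    depth_um:
        Channel depth (metadata only; the field model is 2-D).
    background_width:
        Unconstricted channel width in μm.
    triangle_pitch:
        Axial distance between consecutive gates in μm.
    group_size:
        Number of consecutive gates sharing one width (3 in the reference
        device, giving 9 width groups).
    apex_half_angle_deg:
        Half the opening angle at a tooth tip, in degrees.
    """

    gates: tuple[GateSpec, ...]
    length_cm: float = REFERENCE_LENGTH_CM
    depth_um: float = REFERENCE_DEPTH_UM
    background_width: float = 200.0
    triangle_pitch: float = field(default=0.0)
    group_size: int = REFERENCE_GROUP_SIZE
    apex_half_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        if not self.gates:
            raise ValueError("geometry needs at least one gate")
        if self.length_cm <= 0 or self.background_width <= 0:
            raise ValueError("channel envelope dimensions must be positive")
        if self.group_size < 1 or len(self.gates) % self.group_size:
            raise ValueError(
                f"group_size {self.group_size} does not divide "
                f"gate count {len(self.gates)}"
            )
        widths = [g.width for g in self.gates]
        pos = [g.axial_position for g in self.gates]
        if any(w2 > w1 for w1, w2 in zip(widths, widths[1:])):
            raise ValueError("gate widths must be non-increasing inlet → outlet")
        if any(p2 <= p1 for p1, p2 in zip(pos, pos[1:])):
            raise ValueError("gate axial positions must be strictly increasing")
        if max(w for w in widths) >= self.background_width:
            raise ValueError("gate openings must be narrower than the channel")
        if pos[-1] >= self.length_um:
            raise ValueError("gates must fit within the channel length")
        groups = self.width_groups()
        for grp in groups:
            ws = {self.gates[i].width for i in grp}
            if len(ws) != 1:
                raise ValueError("gates within a width group must share one width")

    @property
    def length_um(self) -> float:
        return self.length_cm * 1e4

    @property
    def n_gates(self) -> int:
        return len(self.gates)

    def width_groups(self) -> list[list[int]]:
        """0-based gate indices partitioned into consecutive equal-width groups."""
        k = self.group_size
        return [list(range(i, i + k)) for i in range(0, len(self.gates), k)]

    def tooth_depth(self, gate: GateSpec) -> float:
        """Penetration of one tooth from the wall toward the centerline (μm)."""
        return (self.background_width - gate.width) / 2.0

    def tooth_base_half_length(self, gate: GateSpec) -> float:
        """Axial half-extent of a tooth at the wall (μm)."""
        return self.tooth_depth(gate) * math.tan(
            math.radians(self.apex_half_angle_deg)
        )

    def to_dict(self) -> dict:
        return {
            "gates": [
                {"index": g.index, "width": g.width, "axial_position": g.axial_position}
                for g in self.gates
            ],
            "length_cm": self.length_cm,
            "depth_um": self.depth_um,
            "background_width": self.background_width,
            "triangle_pitch": self.triangle_pitch,
            "group_size": self.group_size,
            "apex_half_angle_deg": self.apex_half_angle_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelGeometry":
        gates = tuple(
            GateSpec(int(g["index"]), float(g["width"]), float(g["axial_position"]))
            for g in d["gates"]
        )
        return cls(
            gates=gates,
            length_cm=float(d.get("length_cm", REFERENCE_LENGTH_CM)),
            depth_um=float(d.get("depth_um", REFERENCE_DEPTH_UM)),
            background_width=float(d.get("background_width", 200.0)),
            triangle_pitch=float(d.get("triangle_pitch", 0.0)),
            group_size=int(d.get("group_size", REFERENCE_GROUP_SIZE)),
            apex_half_angle_deg=float(d.get("apex_half_angle_deg", 30.0)),
        )


def build_reference_geometry(
    *,
    widths: Sequence[float] | None = None,
    group_size: int | None = None,
    length_cm: float = REFERENCE_LENGTH_CM,
    depth_um: float = REFERENCE_DEPTH_UM,
    background_width: float = 200.0,
    apex_half_angle_deg: float = 30.0,
) -> ChannelGeometry:
    """Construct the reference 27-gate device, or a variant of it.

    By default this is the reference separation channel: 27 gates in 9
    equal-width groups of 3, openings stepping linearly 73 → 25 μm along a
    3.5 cm channel.  Pass ``widths`` (one entry per width group) and/or
    ``group_size`` to build toy variants; the gate count is
    ``len(widths) * group_size``.

    Parameters
    ----------
    widths:
        One opening width per group, μm, non-increasing.  Defaults to the
        reference nine-step schedule.
    group_size:
        Consecutive gates per width group (default 3).
    """
    if widths is None:
        widths = REFERENCE_WIDTHS_UM
    if group_size is None:
        group_size = REFERENCE_GROUP_SIZE
    widths = [float(w) for w in widths]
    if any(w <= 0 for w in widths):
        raise ValueError("gate widths must be positive")
    if any(w2 > w1 for w1, w2 in zip(widths, widths[1:])):
        raise ValueError("group widths must be non-increasing")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")

    n_gates = len(widths) * group_size
    length_um = length_cm * 1e4
    pitch = length_um / (n_gates + 1)
    gates = tuple(
        GateSpec(
            index=i + 1,
            width=widths[i // group_size],
            axial_position=(i + 1) * pitch,
        )
        for i in range(n_gates)
    )
    return ChannelGeometry(
        gates=gates,
        length_cm=length_cm,
        depth_um=depth_um,
        background_width=background_width,
        triangle_pitch=pitch,
        group_size=group_size,
        apex_half_angle_deg=apex_half_angle_deg,
    )


@dataclass(frozen=True)
class DomainMask:
    """Cell-centered raster of the fluid domain.

    ``fluid[i, j]`` is True where cell center ``((i + 0.5) h, (j + 0.5) h)``
    lies in liquid; teeth and anything outside the envelope are insulator.
    ``throats[g]`` holds, for 0-based gate ``g``, the axial column index and
    the fluid row indices spanning the gate opening.
    """

    spacing: float
    fluid: np.ndarray
    inlet_cells: np.ndarray  # row indices j of fluid cells on the inlet face
    outlet_cells: np.ndarray
    throats: tuple[tuple[int, np.ndarray], ...]
    geometry: ChannelGeometry | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.fluid.shape

    def throat_width_um(self, g: int) -> float:
        _, rows = self.throats[g]
        return len(rows) * self.spacing

    def to_text(self) -> str:
        """Plain-text raster (``.`` fluid, ``#`` insulator), y up, x right."""
        art = np.where(self.fluid.T[::-1], ".", "#")
        return "\n".join("".join(row) for row in art)

    def to_graymap(self) -> str:
        """Portable grey-map (PGM, P2 ASCII): fluid 255, insulator 0."""
        img = np.where(self.fluid.T[::-1], 255, 0)
        head = f"P2\n{img.shape[1]} {img.shape[0]}\n255\n"
        return head + "\n".join(" ".join(map(str, r)) for r in img) + "\n"


def _tooth_interior(
    xs: np.ndarray, ys: np.ndarray, x_gate: float, depth: float, half_base: float,
    from_bottom: bool, width_total: float,
) -> np.ndarray:
    """Boolean mask of cell centers inside one triangular tooth."""
    if depth <= 0:
        return np.zeros((xs.size, ys.size), dtype=bool)
    y = ys[None, :] if from_bottom else (width_total - ys)[None, :]
    dx = np.abs(xs[:, None] - x_gate)
    # Linear taper: axial half-width shrinks from half_base at the wall to 0
    # at the tip, which sits ``depth`` into the channel.
    inside = (y < depth) & (dx < half_base * (1.0 - y / depth))
    return inside


def rasterize(geometry: ChannelGeometry, spacing: float) -> DomainMask:
    """Rasterize a channel geometry onto a square grid.

    Parameters
    ----------
    spacing:
        Grid spacing in μm.  Must resolve the narrowest gate with at least
        8 cells.

    Raises
    ------
    ValueError
        If the spacing is too coarse, the teeth seal the channel, or the
        fluid region is not a single inlet-to-outlet connected component.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    narrowest = min(g.width for g in geometry.gates)
    if narrowest / spacing < 8:
        raise ValueError(
            f"spacing {spacing} μm too coarse: narrowest gate ({narrowest} μm) "
            f"spans fewer than 8 cells"
        )
    if narrowest <= 0:
        raise ValueError("teeth close the channel completely")

    nx = int(round(geometry.length_um / spacing))
    ny = int(round(geometry.background_width / spacing))
    xs = (np.arange(nx) + 0.5) * spacing
    ys = (np.arange(ny) + 0.5) * spacing

    fluid = np.ones((nx, ny), dtype=bool)
    # Snap each gate onto the nearest cell center (≤ h/2 shift) so that
    # equal-width gates share one local raster; otherwise sub-cell offsets
    # alias into spurious threshold differences between identical gates.
    snapped_x = [
        (np.clip(round(g.axial_position / spacing - 0.5), 0, nx - 1) + 0.5) * spacing
        for g in geometry.gates
    ]
    for gate, xg in zip(geometry.gates, snapped_x):
        depth = geometry.tooth_depth(gate)
        half_base = geometry.tooth_base_half_length(gate)
        for from_bottom in (True, False):
            fluid &= ~_tooth_interior(
                xs, ys, xg, depth, half_base,
                from_bottom, geometry.background_width,
            )

    labels, n_comp = ndimage.label(fluid)
    if n_comp != 1:
        keep = labels[0, ny // 2]
        if keep == 0 or labels[-1, ny // 2] != keep:
            raise ValueError("fluid region is disconnected between inlet and outlet")
        fluid = labels == keep  # drop enclosed pockets (possible at coarse rasters)

    throats = []
    for g, xg in enumerate(snapped_x):
        ix = int(round(xg / spacing - 0.5))
        rows = np.flatnonzero(fluid[ix])
        if rows.size == 0:
            raise ValueError(f"gate {g + 1} throat is fully masked")
        throats.append((ix, rows))

    return DomainMask(
        spacing=float(spacing),
        fluid=fluid,
        inlet_cells=np.flatnonzero(fluid[0]),
        outlet_cells=np.flatnonzero(fluid[-1]),
        throats=tuple(throats),
        geometry=geometry,
    )
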