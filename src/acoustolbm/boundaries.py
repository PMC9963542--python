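"""Boundary-condition handlers for the D2Q9 lattice.

Handlers are applied after streaming and receive ``(f, f_post_collision,
state)``; each repairs the populations that streamed across its domain edge.
Three wall treatments are provided:

* half-way bounce-back — the reflected population returns to the node it left
  with reversed direction, placing the no-slip wall half a cell outside the
  last fluid row; exactly mass-conserving.
* Zou-He distribution reconstruction — the wall node lies on the boundary row;
  its density is rebuilt from the known populations and the three unknowns are
  set so the node's moments equal (rho_wall, wall_velocity) exactly.  Used for
  the lid-driven cavity (moving lid plus stationary walls).
* auxiliary open-flow handlers (equilibrium inflow, zero-gradient outflow,
  free-slip) used by the cylinder-drag scenario.

Periodic edges need no handler: streaming wraps by construction, so a
``PeriodicAxis`` entry only declares intent and is validated at plan build.

Direction indices follow ``lbm_core``: 0 rest; 1 E, 2 N, 3 W, 4 S;
5 NE, 6 NW, 7 SW, 8 SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError
from .lbm_core import D2Q9, equilibrium

__all__ = [
    "BoundarySpec", "PeriodicAxis", "BounceBackWall", "MovingBounceBackWall",
    "ZouHeWall", "CavityCorners", "FreeSlipWall", "EquilibriumInlet",
    "VelocityInlet", "PressureOutlet", "OutflowCopy",
    "apply_periodic", "apply_bounce_back", "apply_moving_lid",
    "apply_stationary_reconstruction", "build_plan",
]

# Incoming (unknown) directions per side and their bounce-back sources.
_SIDES = {
    # side: (row/col selector axis, index, unknown dirs, their opposites)
    "bottom": (1, 0, (2, 5, 6), (4, 7, 8)),
    "top": (1, -1, (4, 7, 8), (2, 5, 6)),
    "left": (0, 0, (1, 5, 8), (3, 7, 6)),
    "right": (0, -1, (3, 6, 7), (1, 8, 5)),
}


@dataclass(frozen=True)
class BoundarySpec:
    """Declarative description of one domain edge."""

    side: str                       # top | bottom | left | right
    kind: str                       # periodic | bounce_back | moving_wall
    wall_velocity: tuple = (0.0, 0.0)  # lattice units; zero unless moving_wall

    def __post_init__(self):
        if self.side not in _SIDES:
            raise ConfigurationError(f"unknown side {self.side!r}")
        if self.kind not in ("periodic", "bounce_back", "moving_wall"):
            raise ConfigurationError(f"unknown boundary kind {self.kind!r}")
        speed = float(np.hypot(*self.wall_velocity))
        if self.kind != "moving_wall" and speed != 0.0:
            raise ConfigurationError(f"{self.side}: wall_velocity nonzero for kind {self.kind!r}")
        if speed >= np.sqrt(D2Q9.cs2):
            raise ConfigurationError(
                f"{self.side}: |wall_velocity|={speed:.3f} exceeds the lattice "
                "sound speed (low-Mach validity)"
            )


class PeriodicAxis:
    """Declares an axis periodic; streaming already wraps, so apply is a no-op."""

    def __init__(self, axis: str):
        if axis not in ("x", "y"):
            raise ConfigurationError(f"axis must be 'x' or 'y', got {axis!r}")
        self.axis = axis

    def apply(self, f, fpc, state):  # noqa: ARG002 - uniform handler signature
        return f


class BounceBackWall:
    """Half-way bounce-back no-slip wall on one edge."""

    def __init__(self, side: str):
        if side not in _SIDES:
            raise ConfigurationError(f"unknown side {side!r}")
        self.side = side

    def apply(self, f, fpc, state):
        axis, idx, unknown, opposite = _SIDES[self.side]
        for d, o in zip(unknown, opposite):
            if axis == 0:
                f[d][idx, :] = fpc[o][idx, :]
            else:
                f[d][:, idx] = fpc[o][:, idx]
        return f


class MovingBounceBackWall:
    """Half-way bounce-back with a tangential wall-velocity correction.

    f_i'(x, t+1) = f_i^pc(x, t) - 2 w_i rho_w (e_i . u_w) / c_s^2 for each
    link crossing the wall.  The correction terms cancel in the sum over the
    three reflected directions, so total mass is conserved exactly — which is
    why the closed-cavity scenario uses this lid instead of the on-node
    reconstruction.  Top side, tangential motion only.
    """

    def __init__(self, side: str, u_x: float):
        if side != "top":
            raise ConfigurationError("moving bounce-back lid supported on top only")
        if abs(u_x) >= np.sqrt(D2Q9.cs2):
            raise ConfigurationError("lid speed exceeds the lattice sound speed")
        self.u_x = float(u_x)

    def apply(self, f, fpc, state):
        # wall density from the valid post-stream populations of the lid row
        # (the wall-crossing directions 4, 7, 8 are about to be overwritten)
        rho_w = (f[0][:, -1] + f[1][:, -1] + f[3][:, -1]
                 + 2.0 * (f[2][:, -1] + f[5][:, -1] + f[6][:, -1]))
        corr = rho_w * self.u_x / 6.0  # 2 w_diag (e . u)/c_s^2, w_diag = 1/36
        # the two corner nodes belong to the side walls: reflect without the
        # velocity correction there (injecting lid momentum into a blocked
        # corner feeds a sawtooth instability)
        corr[0] = 0.0
        corr[-1] = 0.0
        f[4][:, -1] = fpc[2][:, -1]
        f[7][:, -1] = fpc[5][:, -1] - corr
        f[8][:, -1] = fpc[6][:, -1] + corr
        return f


def apply_bounce_back(f, fpc, wall: BoundarySpec):
    """Functional form of half-way bounce-back for one edge (spec: f2=f4,
    f5=f7, f6=f8 at a bottom wall, translated to this package's indexing)."""
    if wall.kind != "bounce_back":
        raise ConfigurationError(f"apply_bounce_back on kind {wall.kind!r}")
    return BounceBackWall(wall.side).apply(f, fpc, None)


def apply_periodic(f, axis: str, specs: Sequence[BoundarySpec] = ()):
    """Validate that both sides of the axis are periodic; streaming wraps."""
    sides = ("left", "right") if axis == "x" else ("bottom", "top")
    declared = {s.side: s.kind for s in specs}
    if specs:
        for s in sides:
            if declared.get(s) != "periodic":
                raise ConfigurationError(
                    f"axis {axis!r} declared periodic but side {s!r} is "
                    f"{declared.get(s, 'undeclared')!r}"
                )
    return f


class ZouHeWall:
    """Zou-He moment reconstruction at an on-node wall, stationary or moving.

    For a top lid moving tangentially with velocity (U, 0) the wall density is
    rho_N = f0 + f1 + f3 + 2 (f2 + f5 + f6) and the unknowns follow the
    momentum-exchange relations; a zero-velocity wall is the special case
    U = 0.  Only tangential wall motion is supported.  The two end nodes of
    the edge are corners and are left to ``CavityCorners``.
    """

    def __init__(self, side: str, velocity=(0.0, 0.0)):
        if side not in _SIDES:
            raise ConfigurationError(f"unknown side {side!r}")
        u = np.asarray(velocity, dtype=float)
        normal = {"bottom": 1, "top": 1, "left": 0, "right": 0}[side]
        if u[normal] != 0.0:
            raise ConfigurationError(
                f"{side}: normal wall-velocity component unsupported (tangential only)"
            )
        if side in ("left", "right") and u[0] == 0.0 and u[1] != 0.0:
            raise ConfigurationError("moving vertical walls are not supported")
        self.side = side
        self.speed = float(u[0] if side in ("top", "bottom") else u[1])

    def apply(self, f, fpc, state):
        side, U = self.side, self.speed
        sl = slice(1, -1)  # interior of the edge; corners handled separately
        if side == "top":
            f0, f1, f3 = f[0][sl, -1], f[1][sl, -1], f[3][sl, -1]
            f2, f5, f6 = f[2][sl, -1], f[5][sl, -1], f[6][sl, -1]
            rho = f0 + f1 + f3 + 2.0 * (f2 + f5 + f6)
            d = 0.5 * (f1 - f3)
            f[4][sl, -1] = f2
            f[7][sl, -1] = f5 + d - 0.5 * rho * U
            f[8][sl, -1] = f6 - d + 0.5 * rho * U
        elif side == "bottom":
            f0, f1, f3 = f[0][sl, 0], f[1][sl, 0], f[3][sl, 0]
            f4, f7, f8 = f[4][sl, 0], f[7][sl, 0], f[8][sl, 0]
            rho = f0 + f1 + f3 + 2.0 * (f4 + f7 + f8)
            d = 0.5 * (f1 - f3)
            f[2][sl, 0] = f4
            f[5][sl, 0] = f7 - d + 0.5 * rho * U
            f[6][sl, 0] = f8 + d - 0.5 * rho * U
        elif side == "left":
            f0, f2, f4 = f[0][0, sl], f[2][0, sl], f[4][0, sl]
            f3, f6, f7 = f[3][0, sl], f[6][0, sl], f[7][0, sl]
            d = 0.5 * (f2 - f4)
            f[1][0, sl] = f3
            f[5][0, sl] = f7 - d
            f[8][0, sl] = f6 + d
        else:  # right
            f2, f4 = f[2][-1, sl], f[4][-1, sl]
            f1, f5, f8 = f[1][-1, sl], f[5][-1, sl], f[8][-1, sl]
            d = 0.5 * (f2 - f4)
            f[3][-1, sl] = f1
            f[7][-1, sl] = f5 + d
            f[6][-1, sl] = f8 - d
        return f


def apply_moving_lid(f, lid: BoundarySpec):
    """Top-lid Zou-He reconstruction (interior columns) from a BoundarySpec."""
    if lid.kind != "moving_wall" or lid.side != "top":
        raise ConfigurationError("moving lid supported on the top side only")
    return ZouHeWall("top", lid.wall_velocity).apply(f, None, None)


def apply_stationary_reconstruction(f, wall: BoundarySpec):
    """Stationary-wall Zou-He reconstruction (zero-velocity limit)."""
    if wall.kind not in ("bounce_back", "moving_wall"):
        raise ConfigurationError(f"cannot reconstruct a {wall.kind!r} side")
    return ZouHeWall(wall.side, (0.0, 0.0)).apply(f, None, None)


class CavityCorners:
    """Corner closure for a fully walled (cavity) domain.

    Every population that streamed out through either adjoining wall is
    bounced back from the post-collision value of its reverse direction —
    i.e. the corner node is treated as a stationary bounce-back node for all
    of its unknown directions.  This keeps the corner mass-neutral, which an
    equilibrium-residual split (assigning the corner a neighbour's density)
    does not.
    """

    def apply(self, f, fpc, state):
        nx, ny = f[0].shape
        corners = {
            (0, 0): (1, 2, 5, 6, 8),
            (nx - 1, 0): (2, 3, 5, 6, 7),
            (0, ny - 1): (1, 4, 5, 7, 8),
            (nx - 1, ny - 1): (3, 4, 6, 7, 8),
        }
        for (i, j), dirs in corners.items():
            for d in dirs:
                f[d][i, j] = fpc[D2Q9.opposite[d]][i, j]
        return f


class FreeSlipWall:
    """Specular-reflection (zero-shear) wall on a horizontal edge."""

    def __init__(self, side: str):
        if side not in ("top", "bottom"):
            raise ConfigurationError("free-slip supported on top/bottom only")
        self.side = side

    def apply(self, f, fpc, state):
        if self.side == "top":
            f[4][:, -1] = fpc[2][:, -1]
            f[7][:, -1] = fpc[6][:, -1]
            f[8][:, -1] = fpc[5][:, -1]
        else:
            f[2][:, 0] = fpc[4][:, 0]
            f[6][:, 0] = fpc[7][:, 0]
            f[5][:, 0] = fpc[8][:, 0]
        return f


class EquilibriumInlet:
    """Dirichlet inlet: the edge column is pinned at equilibrium(rho0, u).

    Soft — the realized influx drops below the nominal velocity when the
    interior pressurizes; prefer :class:`VelocityInlet` when the approach
    velocity must be exact (it is for the drag benchmark).
    """

    def __init__(self, side: str, velocity, rho0: float = 1.0):
        if side != "left":
            raise ConfigurationError("equilibrium inlet supported on the left side only")
        self.feq = equilibrium(np.float64(rho0), np.asarray(velocity, dtype=float))

    def apply(self, f, fpc, state):
        for d in range(9):
            f[d][0, :] = self.feq[d]
        return f


class VelocityInlet:
    """Zou-He velocity inlet on the left edge: enforces the streamwise
    velocity exactly against any downstream pressure, with an optional smooth
    (cubic) start-up ramp to keep acoustic transients small."""

    def __init__(self, u_x: float, ramp_steps: int = 0):
        if abs(u_x) >= np.sqrt(D2Q9.cs2):
            raise ConfigurationError("inlet speed exceeds the lattice sound speed")
        self.u_x = float(u_x)
        self.ramp_steps = int(ramp_steps)
        self._it = 0

    def apply(self, f, fpc, state):
        self._it += 1
        ux = self.u_x
        if self.ramp_steps and self._it < self.ramp_steps:
            s = self._it / self.ramp_steps
            ux *= s * s * (3.0 - 2.0 * s)
        rho = (f[0][0, :] + f[2][0, :] + f[4][0, :]
               + 2.0 * (f[3][0, :] + f[6][0, :] + f[7][0, :])) / (1.0 - ux)
        d = 0.5 * (f[2][0, :] - f[4][0, :])
        f[1][0, :] = f[3][0, :] + (2.0 / 3.0) * rho * ux
        f[5][0, :] = f[7][0, :] - d + rho * ux / 6.0
        f[8][0, :] = f[6][0, :] + d + rho * ux / 6.0
        return f


class PressureOutlet:
    """Zou-He constant-density outlet on the right edge (rho = rho0)."""

    def __init__(self, rho0: float = 1.0):
        self.rho0 = float(rho0)

    def apply(self, f, fpc, state):
        r = self.rho0
        ux = -1.0 + (f[0][-1, :] + f[2][-1, :] + f[4][-1, :]
                     + 2.0 * (f[1][-1, :] + f[5][-1, :] + f[8][-1, :])) / r
        d = 0.5 * (f[2][-1, :] - f[4][-1, :])
        f[3][-1, :] = f[1][-1, :] - (2.0 / 3.0) * r * ux
        f[6][-1, :] = f[8][-1, :] - d - r * ux / 6.0
        f[7][-1, :] = f[5][-1, :] + d - r * ux / 6.0
        return f


class OutflowCopy:
    """Zero-gradient outflow: the edge column copies its upstream neighbour."""

    def __init__(self, side: str):
        if side != "right":
            raise ConfigurationError("outflow supported on the right side only")

    def apply(self, f, fpc, state):
        for d in range(9):
            f[d][-1, :] = f[d][-2, :]
        return f


def build_plan(specs: Sequence[BoundarySpec], reconstruction: bool = False):
    """Translate edge declarations into an ordered handler list.

    Periodic sides must come in opposite pairs.  ``reconstruction=True``
    selects the on-node Zou-He treatment for stationary walls (cavity style,
    with corner closure); otherwise stationary walls use half-way bounce-back.
    """
    by_side = {}
    for s in specs:
        if s.side in by_side:
            raise ConfigurationError(f"side {s.side!r} declared twice")
        by_side[s.side] = s
    for a, b in (("left", "right"), ("bottom", "top")):
        ka = by_side.get(a) and by_side[a].kind
        kb = by_side.get(b) and by_side[b].kind
        if ("periodic" in (ka, kb)) and ka != kb:
            raise ConfigurationError(
                f"periodic sides must pair: {a}={ka!r} vs {b}={kb!r}"
            )
    plan = []
    needs_corners = False
    for side, s in by_side.items():
        if s.kind == "periodic":
            plan.append(PeriodicAxis("x" if side in ("left", "right") else "y"))
        elif s.kind == "bounce_back" and not reconstruction:
            plan.append(BounceBackWall(side))
        elif s.kind == "bounce_back":
            plan.append(ZouHeWall(side, (0.0, 0.0)))
            needs_corners = True
        elif not reconstruction:  # moving_wall, link bounce-back variant
            plan.append(MovingBounceBackWall(side, s.wall_velocity[0]))
        else:  # moving_wall, on-node reconstruction
            plan.append(ZouHeWall(side, s.wall_velocity))
            needs_corners = True
    if needs_corners:
        if set(by_side) != {"top", "bottom", "left", "right"} or any(
            s.kind == "periodic" for s in specs
        ):
            raise ConfigurationError(
                "Zou-He reconstruction requires four walled sides (closed cavity)"
            )
        plan.append(CavityCorners())
    return plan
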