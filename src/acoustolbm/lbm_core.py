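"""D2Q9 BGK lattice Boltzmann core with Shan-Chen velocity-shift forcing.

The solver evolves nine discrete particle-distribution functions f_i on a
rectangular lattice by alternating a single-relaxation-time (BGK) collision
with nearest-neighbour streaming:

    f_i(X + e_i, t+1) - f_i(X, t) = -(1/tau) [f_i - f_i^eq](X, t)

Macroscopic density and momentum are the zeroth and first moments of f_i.
Body forces (the spread immersed-boundary forces and any uniform driving
force) enter through the Shan-Chen scheme: the equilibrium is evaluated at a
shifted velocity u_eq = u + tau F / rho, which adds exactly F to the node's
momentum per step.

The direction ordering is fixed once for the whole package:

    index   0    1     2     3     4     5      6      7      8
    e_i   (0,0)(1,0) (0,1)(-1,0)(0,-1)(1,1) (-1,1)(-1,-1)(1,-1)

Arrays are laid out as f[direction, x, y]; velocity fields as u[component, x, y].
The collide-and-stream update runs through a fused numba kernel when numba is
importable and falls back to an equivalent vectorized numpy path otherwise;
both produce the same arithmetic to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, StabilityError

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

__all__ = ["D2Q9", "D2Q9Stencil", "LatticeState", "equilibrium", "moments",
           "tau_from_viscosity", "step"]


@dataclass(frozen=True)
class D2Q9Stencil:
    """The nine-velocity 2D stencil: velocities, weights, sound speed, reversal map."""

    e: np.ndarray
    w: np.ndarray
    cs2: float
    opposite: np.ndarray


D2Q9 = D2Q9Stencil(
    e=np.array(
        [[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1],
         [1, 1], [-1, 1], [-1, -1], [1, -1]],
        dtype=np.int64,
    ),
    w=np.array([4 / 9] + [1 / 9] * 4 + [1 / 36] * 4),
    cs2=1.0 / 3.0,
    opposite=np.array([0, 3, 4, 1, 2, 7, 8, 5, 6], dtype=np.int64),
)

_EX = D2Q9.e[:, 0].copy()
_EY = D2Q9.e[:, 1].copy()
_W = D2Q9.w.copy()


def tau_from_viscosity(nu_lbm: float) -> float:
    """Relaxation time from lattice viscosity: nu = c_s^2 (tau - 1/2), so
    tau = 3 nu + 1/2 (unit time step).  Requires nu > 0 (tau > 1/2)."""
    if not nu_lbm > 0:
        raise InvalidParameterError(
            f"nu_lbm must be strictly positive (tau > 0.5), got {nu_lbm!r}"
        )
    return nu_lbm / D2Q9.cs2 + 0.5


def equilibrium(rho, u, stencil: D2Q9Stencil = D2Q9) -> np.ndarray:
    """Second-order Maxwellian equilibrium.

    f_i^eq = w_i rho [1 + e_i.u/c_s^2 + (e_i.u)^2/(2 c_s^4) - u^2/(2 c_s^2)]

    ``rho`` may be a scalar or an (Nx, Ny) field; ``u`` a length-2 vector or a
    (2, Nx, Ny) field.  Returns an array with a leading direction axis.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    inv_cs2 = 1.0 / stencil.cs2
    eu = np.tensordot(stencil.e, u, axes=([1], [0])) * inv_cs2  # (9, ...)
    usq = 0.5 * np.sum(u * u, axis=0) * inv_cs2
    shape = (9,) + (1,) * rho.ndim
    w = stencil.w.reshape(shape)
    return w * rho * (1.0 + eu * (1.0 + 0.5 * eu) - usq)


def moments(f: np.ndarray, stencil: D2Q9Stencil = D2Q9):
    """Density and velocity moments: rho = sum_i f_i, u = sum_i f_i e_i / rho."""
    rho = f.sum(axis=0)
    if np.any(~(rho > 0)) or not np.all(np.isfinite(rho)):
        flat = np.atleast_1d(rho)
        bad = np.argwhere(~(flat > 0) | ~np.isfinite(flat))
        loc = tuple(int(v) for v in bad[0]) if bad.size else "scalar"
        raise StabilityError(f"non-positive or non-finite density at node {loc}")
    mom = np.tensordot(stencil.e.T.astype(float), f, axes=([1], [0]))
    return rho, mom / rho


if _HAVE_NUMBA:
    @_njit(cache=False)
    def _collide_stream(f, fpc, fnew, body, tau, ex, ey, w):  # pragma: no cover
        nx, ny = f.shape[1], f.shape[2]
        omega = 1.0 / tau
        status = 0
        for i in range(nx):
            for j in range(ny):
                r = 0.0
                mx = 0.0
                my = 0.0
                for q in range(9):
                    v = f[q, i, j]
                    r += v
                    mx += v * ex[q]
                    my += v * ey[q]
                if not r > 0.0:
                    status = 1
                    r = 1.0  # keep the kernel finite; caller raises
                ux = (mx + tau * body[0, i, j]) / r
                uy = (my + tau * body[1, i, j]) / r
                usq = 1.5 * (ux * ux + uy * uy)
                for q in range(9):
                    eu = 3.0 * (ex[q] * ux + ey[q] * uy)
                    feq = w[q] * r * (1.0 + eu * (1.0 + 0.5 * eu) - usq)
                    pc = f[q, i, j] * (1.0 - omega) + omega * feq
                    fpc[q, i, j] = pc
                    ii = i + ex[q]
                    if ii == nx:
                        ii = 0
                    elif ii == -1:
                        ii = nx - 1
                    jj = j + ey[q]
                    if jj == ny:
                        jj = 0
                    elif jj == -1:
                        jj = ny - 1
                    fnew[q, ii, jj] = pc
        return status


class LatticeState:
    """Eulerian field state of a D2Q9 run.

    ``f`` has shape (9, Nx, Ny); ``rho`` and ``u`` are the moments of the
    current ``f``, evaluated lazily and cached; ``body_force`` accumulates
    force density for the next step and is cleared after use; ``tau`` is the
    BGK relaxation time (> 1/2).
    """

    def __init__(self, f: np.ndarray, tau: float, step_index: int = 0):
        if not tau > 0.5:
            raise InvalidParameterError(f"tau must exceed 0.5, got {tau!r}")
        self.f = np.ascontiguousarray(f, dtype=float)
        self.tau = float(tau)
        self.step_index = step_index
        self.body_force = np.zeros((2,) + self.f.shape[1:])
        self._fpc = np.empty_like(self.f)
        self._fnew = np.empty_like(self.f)
        self._rho = None
        self._u = None
        self._dirty = True
        _ = self.rho  # validate the initial state

    @classmethod
    def quiescent(cls, nx: int, ny: int, tau: float, rho0: float = 1.0,
                  u0=(0.0, 0.0)) -> "LatticeState":
        """State initialized at equilibrium for uniform (rho0, u0)."""
        rho = np.full((nx, ny), float(rho0))
        u = np.zeros((2, nx, ny))
        u[0] += u0[0]
        u[1] += u0[1]
        return cls(f=equilibrium(rho, u), tau=tau)

    def _refresh(self):
        self._rho, self._u = moments(self.f)
        self._dirty = False

    @property
    def rho(self) -> np.ndarray:
        if self._dirty:
            self._refresh()
        return self._rho

    @property
    def u(self) -> np.ndarray:
        if self._dirty:
            self._refresh()
        return self._u

    def invalidate_moments(self):
        self._dirty = True

    @property
    def shape(self):
        return self.f.shape[1:]

    def total_mass(self) -> float:
        return float(self.f.sum())

    def total_momentum(self) -> np.ndarray:
        return np.tensordot(D2Q9.e.T.astype(float), self.f,
                            axes=([1], [0])).sum(axis=(1, 2))


def step(state: LatticeState, stencil: D2Q9Stencil = D2Q9,
         boundary_plan=()) -> LatticeState:
    """Advance the lattice by one collide-then-stream update, in place.

    Order of operations: moments -> Shan-Chen velocity shift u_eq = u +
    tau F / rho -> BGK relaxation -> streaming (periodic wrap by
    construction) -> boundary handlers in declared order -> clear body force.
    Handlers receive ``(f, f_post_collision, state)`` and repair the
    populations that streamed across a domain edge.
    """
    f, fpc, fnew = state.f, state._fpc, state._fnew
    if _HAVE_NUMBA and stencil is D2Q9:
        status = _collide_stream(f, fpc, fnew, state.body_force, state.tau,
                                 _EX, _EY, _W)
        if status:
            raise StabilityError(
                f"non-positive or non-finite density at step {state.step_index}"
            )
    else:
        rho = f.sum(axis=0)
        if np.any(~(rho > 0)) or not np.all(np.isfinite(rho)):
            raise StabilityError(
                f"non-positive or non-finite density at step {state.step_index}"
            )
        mom = np.tensordot(stencil.e.T.astype(float), f, axes=([1], [0]))
        ueq = (mom + state.tau * state.body_force) / rho
        feq = equilibrium(rho, ueq, stencil)
        omega = 1.0 / state.tau
        np.multiply(f, 1.0 - omega, out=fpc)
        fpc += omega * feq
        for i in range(9):
            ex, ey = stencil.e[i]
            fnew[i] = np.roll(fpc[i], shift=(ex, ey), axis=(0, 1))
    state.f, state._fnew = fnew, f
    state.invalidate_moments()
    for handler in boundary_plan:
        handler.apply(state.f, fpc, state)
    state.invalidate_moments()
    state.body_force[:] = 0.0
    state.step_index += 1
    return state
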