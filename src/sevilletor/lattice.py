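"""Explicit finite-difference engine on a 2D rectangular lattice.

Forward-Euler time stepping of the reaction-diffusion system with a
first-order 5-point discrete Laplacian.  Zero-flux (Neumann) boundaries are
implemented with mirror ghost cells, periodic boundaries treat opposite
edges as direct neighbours, and masked cells act as internal zero-flux
boundaries whose values never change.  Only ``u`` diffuses by default;
an optional ``Dv`` lets ``v`` diffuse as well.

The x axis is the anterior-posterior axis of the virtual tail: column 0 is
the anterior-most column and column ``Lx - 1`` the posterior tip.  Tail
growth appends one column at the tip at fixed model-time intervals; the new
column inherits the (u, v) concentrations of the previous tip column and
the per-column parameter profiles are re-evaluated over the enlarged
domain so that profiles anchored to the tip translate with it.

Hot loops are JIT-compiled with numba; the public :func:`discrete_laplacian`
and :func:`euler_step` are plain numpy and define the reference arithmetic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **kw):  # type: ignore
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = [
    "NumericalScheme",
    "GridState",
    "ParameterFields",
    "SimulationRecord",
    "discrete_laplacian",
    "euler_step",
    "grow_posterior",
    "run_simulation",
]

ZERO_FLUX = "zero-flux"
PERIODIC = "periodic"


@dataclass(frozen=True)
class NumericalScheme:
    """Time/space discretisation and output cadence.

    ``growth_period`` is the model time between posterior column additions
    (0 disables growth).  The explicit 2D stability bound
    ``dt < dx**2 / (4 D)`` is enforced when the scheme is paired with a
    diffusion coefficient in :func:`run_simulation`.
    """

    dt: float = 0.01
    dx: float = 1.0
    duration: float = 200.0
    snapshot_interval: float = 2.0
    growth_period: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dx <= 0:
            raise ValueError("dt and dx must be positive")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot_interval must be positive")

    def check_stability(self, D: float, Dv: float = 0.0) -> None:
        dmax = max(D, Dv)
        if dmax > 0 and not self.dt < self.dx**2 / (4.0 * dmax):
            raise ValueError(
                f"dt={self.dt} violates the 2D explicit stability bound "
                f"dx^2/(4 D) = {self.dx**2 / (4 * dmax):.4g}"
            )


@dataclass
class GridState:
    """Concentration fields on the lattice, indexed (x, y).

    ``mask`` marks participating cells; masked-out cells keep their values
    and exchange no flux with neighbours.
    """

    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray | None = None
    boundary_mode: str = ZERO_FLUX

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ValueError("u and v must be 2D arrays of identical shape")
        if self.mask is None:
            self.mask = np.ones(self.u.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.u.shape:
                raise ValueError("mask shape must match the fields")
        if self.boundary_mode not in (ZERO_FLUX, PERIODIC):
            raise ValueError(f"unknown boundary mode {self.boundary_mode!r}")

    @property
    def Lx(self) -> int:
        return self.u.shape[0]

    @property
    def Ly(self) -> int:
        return self.u.shape[1]

    def copy(self) -> "GridState":
        return GridState(self.u.copy(), self.v.copy(), self.mask.copy(), self.boundary_mode)


@dataclass
class ParameterFields:
    """Kinetic parameters over the domain.

    ``k1``, ``k3`` and ``k4`` are per-column profiles along x (length Lx)
    or full 2D fields (for radial explant layouts); ``k2``, ``D`` and
    ``Dv`` are scalars.  ``v`` is immobile by default (``Dv = 0``).
    """

    k1: np.ndarray
    k3: np.ndarray
    k4: np.ndarray
    k2: float = 1.0
    D: float = 0.3
    Dv: float = 0.0
    #: multiplier on the cubic saturation terms; 0 disables the reaction
    #: entirely (with the rates) for pure-diffusion runs
    saturation: float = 1.0

    def __post_init__(self) -> None:
        self.k1 = np.asarray(self.k1, dtype=float)
        self.k3 = np.asarray(self.k3, dtype=float)
        self.k4 = np.asarray(self.k4, dtype=float)
        for name in ("k1", "k3", "k4"):
            arr = getattr(self, name)
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} profile must be finite and non-negative")
        if self.D < 0 or self.Dv < 0:
            raise ValueError("diffusion coefficients must be non-negative")

    def expand(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcast the three k-profiles to full (Lx, Ly) fields."""
        out = []
        for arr in (self.k1, self.k3, self.k4):
            if arr.ndim == 0:
                out.append(np.full(shape, float(arr)))
            elif arr.ndim == 1:
                if arr.shape[0] != shape[0]:
                    raise ValueError(
                        f"profile length {arr.shape[0]} does not match Lx={shape[0]}"
                    )
                out.append(np.repeat(arr[:, None], shape[1], axis=1))
            else:
                if arr.shape != shape:
                    raise ValueError("2D parameter field shape must match the grid")
                out.append(arr.astype(float))
        return tuple(out)


# ---------------------------------------------------------------------------
# Reference numpy operators
# ---------------------------------------------------------------------------

def discrete_laplacian(
    fieldarr: np.ndarray,
    dx: float = 1.0,
    boundary_mode: str = ZERO_FLUX,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """First-order 5-point discrete Laplacian.

    Zero-flux boundaries mirror the edge cell into the ghost cell (so a
    missing neighbour contributes no flux); periodic boundaries wrap.
    Masked cells exchange no flux with their neighbours and report 0.
    """
    f = np.asarray(fieldarr, dtype=float)
    if f.ndim != 2:
        raise ValueError("field must be 2D")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != f.shape:
            raise ValueError("mask shape must match field")
    wrap = boundary_mode == PERIODIC
    if boundary_mode not in (ZERO_FLUX, PERIODIC):
        raise ValueError(f"unknown boundary mode {boundary_mode!r}")
    out = np.zeros_like(f)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb = np.roll(f, shift, axis=axis)
        valid = np.ones(f.shape, dtype=bool)
        if not wrap:
            if axis == 0 and shift == 1:
                valid[0, :] = False
            elif axis == 0 and shift == -1:
                valid[-1, :] = False
            elif axis == 1 and shift == 1:
                valid[:, 0] = False
            else:
                valid[:, -1] = False
        if mask is not None:
            valid &= np.roll(mask, shift, axis=axis)
        out += np.where(valid, nb, f)
    out -= 4.0 * f
    if mask is not None:
        out = np.where(mask, out, 0.0)
    return out / dx**2


def euler_step(g: GridState, p: ParameterFields, s: NumericalScheme) -> GridState:
    """One forward-Euler update of (u, v); masked cells are left unchanged.

    Reference implementation: one reaction update plus diffusion of ``u``
    (and of ``v`` when ``Dv > 0``).  The JIT path used by
    :func:`run_simulation` reproduces this arithmetic.
    """
    s.check_stability(p.D, p.Dv)
    K1, K3, K4 = p.expand(g.u.shape)
    with np.errstate(over="ignore", invalid="ignore"):
        lap_u = discrete_laplacian(g.u, s.dx, g.boundary_mode, g.mask)
        du = K1 * g.u - K3 * g.v - p.saturation * g.u**3 + p.D * lap_u
        dv = p.k2 * g.v + K4 * g.u - p.saturation * g.v**3
        if p.Dv > 0:
            dv = dv + p.Dv * discrete_laplacian(g.v, s.dx, g.boundary_mode, g.mask)
        u = np.where(g.mask, g.u + s.dt * du, g.u)
        v = np.where(g.mask, g.v + s.dt * dv, g.v)
    if not (np.all(np.isfinite(u[g.mask])) and np.all(np.isfinite(v[g.mask]))):
        bad = np.argwhere(~np.isfinite(u) | ~np.isfinite(v))
        raise FloatingPointError(f"field diverged at cell {tuple(bad[0])}")
    return GridState(u, v, g.mask.copy(), g.boundary_mode)


# ---------------------------------------------------------------------------
# JIT kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _integrate_kernel(u, v, mask, K1, K3, K4, k2, D, Dv, sat, dt, dx2, nsteps, periodic):
    Nx, Ny = u.shape
    for _ in range(nsteps):
        un = np.empty_like(u)
        vn = np.empty_like(v)
        for i in range(Nx):
            for j in range(Ny):
                if not mask[i, j]:
                    un[i, j] = u[i, j]
                    vn[i, j] = v[i, j]
                    continue
                c = u[i, j]
                lap = 0.0
                lapv = 0.0
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    ii = i + di
                    jj = j + dj
                    if periodic:
                        ii = ii % Nx
                        jj = jj % Ny
                        inside = True
                    else:
                        inside = 0 <= ii < Nx and 0 <= jj < Ny
                    if inside and mask[ii, jj]:
                        lap += u[ii, jj]
                        lapv += v[ii, jj]
                    else:
                        lap += c
                        lapv += v[i, j]
                lap = lap - 4.0 * c
                lapv = lapv - 4.0 * v[i, j]
                un[i, j] = c + dt * (
                    K1[i, j] * c - K3[i, j] * v[i, j] - sat * c**3 + D * lap / dx2
                )
                dv = k2 * v[i, j] + K4[i, j] * c - sat * v[i, j] ** 3
                if Dv > 0.0:
                    dv += Dv * lapv / dx2
                vn[i, j] = v[i, j] + dt * dv
        u, v = un, vn
    return u, v


def _integrate(g: GridState, p: ParameterFields, s: NumericalScheme, nsteps: int) -> GridState:
    """Advance ``nsteps`` Euler steps, preferring the JIT kernel."""
    if nsteps <= 0:
        return g
    K1, K3, K4 = p.expand(g.u.shape)
    u, v = _integrate_kernel(
        np.ascontiguousarray(g.u),
        np.ascontiguousarray(g.v),
        np.ascontiguousarray(g.mask),
        np.ascontiguousarray(K1),
        np.ascontiguousarray(K3),
        np.ascontiguousarray(K4),
        float(p.k2),
        float(p.D),
        float(p.Dv),
        float(p.saturation),
        float(s.dt),
        float(s.dx**2),
        nsteps,
        g.boundary_mode == PERIODIC,
    )
    return GridState(u, v, g.mask, g.boundary_mode)


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

ProfileBuilder = Callable[[int], ParameterFields]


def grow_posterior(
    g: GridState, p: ParameterFields, builder: ProfileBuilder | None = None
) -> tuple[GridState, ParameterFields]:
    """Append one column at the posterior tip (x = Lx).

    The new column copies (u, v) from the previous tip column; when a
    ``builder`` is given the per-column profiles are re-evaluated on the
    enlarged domain (profiles anchored to the tip translate with it),
    otherwise 1D profiles are extended by repeating their last value.
    """
    u = np.vstack([g.u, g.u[-1:, :]])
    v = np.vstack([g.v, g.v[-1:, :]])
    mask = np.vstack([g.mask, g.mask[-1:, :]])
    new_g = GridState(u, v, mask, g.boundary_mode)
    if builder is not None:
        new_p = builder(new_g.Lx)
    else:
        def ext(arr):
            return np.append(arr, arr[-1]) if arr.ndim == 1 else arr
        new_p = ParameterFields(
            k1=ext(p.k1), k3=ext(p.k3), k4=ext(p.k4),
            k2=p.k2, D=p.D, Dv=p.Dv, saturation=p.saturation,
        )
    return new_g, new_p


# ---------------------------------------------------------------------------
# Simulation record and driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationRecord:
    """Snapshots plus full provenance of one simulation run."""

    times: list[float]
    u_snapshots: list[np.ndarray]
    v_snapshots: list[np.ndarray]
    scheme: NumericalScheme
    seed: int | None
    config: dict
    masks: list[np.ndarray] = field(default_factory=list)
    k1_history: list[np.ndarray] = field(default_factory=list)
    diverged: bool = False

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @property
    def final(self) -> tuple[np.ndarray, np.ndarray]:
        return self.u_snapshots[-1], self.v_snapshots[-1]


def run_simulation(
    initial: GridState,
    params: ParameterFields | ProfileBuilder,
    scheme: NumericalScheme,
    noise=None,
    seed: int | None = None,
    record_k1: bool = False,
) -> SimulationRecord:
    """Integrate a full lattice simulation with optional growth and noise.

    ``params`` is either a fixed :class:`ParameterFields` or a builder
    ``Lx -> ParameterFields`` (required when growth re-anchors profiles).
    Multiplicative noise (a :class:`~sevilletor.models.NoiseSpec`) is
    applied only at growth events.  Deterministic for a given seed.
    Divergence aborts the run but preserves the partial record.
    """
    builder: ProfileBuilder | None
    if callable(params):
        builder = params
        p = builder(initial.Lx)
    else:
        builder = None
        p = params
    scheme.check_stability(p.D, p.Dv)
    rng = np.random.default_rng(seed)
    g = initial.copy()

    grow_every = (
        int(round(scheme.growth_period / scheme.dt)) if scheme.growth_period > 0 else 0
    )
    snap_every = int(round(scheme.snapshot_interval / scheme.dt))
    nsteps = int(round(scheme.duration / scheme.dt))

    # accumulated multiplicative noise on the k-profiles survives profile
    # re-evaluation after growth
    k1_noise = np.ones(g.Lx)
    k34_noise = np.ones(g.Lx)

    def noisy(pf: ParameterFields) -> ParameterFields:
        if noise is None or (pf.k1.ndim != 1):
            return pf
        return ParameterFields(
            k1=pf.k1 * k1_noise,
            k3=pf.k3 * k34_noise,
            k4=pf.k4 * k34_noise,
            k2=pf.k2,
            D=pf.D,
            Dv=pf.Dv,
            saturation=pf.saturation,
        )

    config = {
        "scheme": dataclasses.asdict(scheme),
        "seed": seed,
        "boundary_mode": g.boundary_mode,
        "k2": p.k2,
        "D": p.D,
        "Dv": p.Dv,
        "noise": dataclasses.asdict(noise) if noise is not None else None,
        "Lx0": g.Lx,
        "Ly": g.Ly,
    }
    rec = SimulationRecord(
        times=[0.0],
        u_snapshots=[g.u.copy()],
        v_snapshots=[g.v.copy()],
        scheme=scheme,
        seed=seed,
        config=config,
    )
    if record_k1:
        rec.k1_history.append(noisy(p).expand(g.u.shape)[0][:, 0].copy())
    rec.masks.append(g.mask.copy())

    step = 0
    while step < nsteps:
        # integrate to the next event (growth or snapshot)
        nexts = [nsteps]
        if grow_every:
            nexts.append(((step // grow_every) + 1) * grow_every)
        nexts.append(((step // snap_every) + 1) * snap_every)
        target = min(nexts)
        try:
            g = _integrate(g, noisy(p), scheme, target - step)
        except FloatingPointError:
            rec.diverged = True
            break
        step = target
        if not (np.all(np.isfinite(g.u[g.mask])) and np.all(np.isfinite(g.v[g.mask]))):
            rec.diverged = True
            rec.times.append(step * scheme.dt)
            rec.u_snapshots.append(g.u.copy())
            rec.v_snapshots.append(g.v.copy())
            rec.masks.append(g.mask.copy())
            break
        if grow_every and step % grow_every == 0 and step < nsteps:
            g, p = grow_posterior(g, p, builder)
            k1_noise = np.append(k1_noise, 1.0)
            k34_noise = np.append(k34_noise, 1.0)
            if noise is not None:
                du = noise.delta_uv
                if du > 0:
                    g.u *= 1.0 + du * rng.standard_normal(g.u.shape)
                    g.v *= 1.0 + du * rng.standard_normal(g.v.shape)
                dk = noise.delta_k
                if dk > 0:
                    k1_noise *= 1.0 + dk * rng.standard_normal(k1_noise.shape)
                    # k3 and k4 share the same draws by construction
                    k34_noise *= 1.0 + dk * rng.standard_normal(k34_noise.shape)
        if step % snap_every == 0 or step == nsteps:
            rec.times.append(step * scheme.dt)
            rec.u_snapshots.append(g.u.copy())
            rec.v_snapshots.append(g.v.copy())
            rec.masks.append(g.mask.copy())
            if record_k1:
                rec.k1_history.append(noisy(p).expand(g.u.shape)[0][:, 0].copy())
    return rec
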