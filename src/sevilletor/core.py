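"""Reaction kinetics and phase-plane analysis of the Sevilletor system.

The Sevilletor couples two self-enhancing reactants ``u`` and ``v`` through
a negative feedback loop, with cubic terms that saturate excursions far from
the central fixed point::

    du/dt = k1*u - k3*v - u**3   (+ D * laplacian(u) in space)
    dv/dt = k2*v + k4*u - v**3

``k1`` and ``k2`` are the self-enhancement rates, ``k3`` the strength of the
inhibitory v->u arm and ``k4`` the strength of the activating u->v arm of
the feedback loop.  All terms are odd, so the origin is a fixed point for
every parameter choice and non-trivial steady states occur in +/- pairs.

Raising the self-enhancement of ``u`` drives a bifurcation from a single
unstable state (a limit-cycle oscillator) to a quintet of states whose two
outermost members are stable; the distance between stable and unstable
states then sets how easily diffusion can excite a resting cell.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "KineticParams",
    "PhasePoint",
    "SteadyState",
    "reaction_rates",
    "jacobian",
    "nullclines",
    "find_steady_states",
    "steady_state_polynomial_roots",
    "classify_stability",
    "bifurcation_scan_1d",
    "bifurcation_scan_2d",
    "count_states_grid",
    "states_to_csv",
]

#: Euclidean distance below which two roots are considered the same state.
DEDUP_TOL = 1e-6
#: Max-norm residual below which a point counts as a steady state.
RESIDUAL_TOL = 1e-10
#: |det| or |trace| below this is reported as marginal, not stable/unstable.
MARGINAL_TOL = 1e-8
#: Half-width of the seeding box for the Newton search.
SEED_BOX = 3.0
#: Seeds per axis for the Newton search.
SEED_N = 41


@dataclass(frozen=True)
class KineticParams:
    """Kinetic rates of the two-variable system.

    Parameters are dimensionless model units; ``D`` is the diffusion
    coefficient of ``u`` (model length^2 / model time).  The defaults
    ``k2 = k3 = k4 = 1`` and ``D = 0.3`` are the reference regime in which
    ``k1`` alone selects the patterning behaviour.
    """

    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    k4: float = 1.0
    D: float = 0.3

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "D"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val!r}")
            if val < 0:
                raise ValueError(f"{name} must be non-negative, got {val!r}")

    def replace(self, **kw) -> "KineticParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class PhasePoint:
    """A point (u, v) in phase space, centred on the fixed point (0, 0)."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError(f"phase point must be finite, got ({self.u}, {self.v})")

    def distance_to(self, other: "PhasePoint") -> float:
        return float(np.hypot(self.u - other.u, self.v - other.v))

    @property
    def radius(self) -> float:
        return float(np.hypot(self.u, self.v))


@dataclass(frozen=True)
class SteadyState:
    """A steady state with its linear-stability classification."""

    location: PhasePoint
    det: float
    trace: float
    stable: bool
    kind_label: str
    marginal: bool = False


def reaction_rates(p: PhasePoint | tuple, k: KineticParams):
    """Non-diffusive right-hand sides (du/dt, dv/dt) at a phase point.

    The function is odd: ``reaction_rates((-u, -v)) == -reaction_rates((u, v))``.
    """
    if isinstance(p, PhasePoint):
        u, v = p.u, p.v
    else:
        u, v = p
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("reaction_rates requires finite input concentrations")
    du = k.k1 * u - k.k3 * v - u**3
    dv = k.k2 * v + k.k4 * u - v**3
    if du.ndim == 0:
        return float(du), float(dv)
    return du, dv


def jacobian(p: PhasePoint | tuple, k: KineticParams) -> np.ndarray:
    """Jacobian matrix of the reaction terms at a phase point."""
    u, v = (p.u, p.v) if isinstance(p, PhasePoint) else p
    return np.array(
        [
            [k.k1 - 3.0 * u**2, -k.k3],
            [k.k4, k.k2 - 3.0 * v**2],
        ]
    )


def nullclines(k: KineticParams) -> tuple[Callable, Callable]:
    """Return the two nullcline evaluators.

    The u-nullcline is returned as ``v = f(u)`` (where du/dt = 0) and the
    v-nullcline as ``u = g(v)`` (where dv/dt = 0).  Both curves pass through
    the origin and every intersection is a steady state.

    For ``k3 = 0`` (or ``k4 = 0``) the corresponding nullcline degenerates
    to a set of vertical (horizontal) lines; a ``ZeroDivisionError`` is
    raised in that case since the curve is not a function.
    """
    if k.k3 == 0 or k.k4 == 0:
        raise ZeroDivisionError("nullclines are not single-valued when k3 or k4 is 0")

    def u_nullcline(u):
        u = np.asarray(u, dtype=float)
        out = (k.k1 * u - u**3) / k.k3
        return float(out) if out.ndim == 0 else out

    def v_nullcline(v):
        v = np.asarray(v, dtype=float)
        out = (v**3 - k.k2 * v) / k.k4
        return float(out) if out.ndim == 0 else out

    return u_nullcline, v_nullcline


# ---------------------------------------------------------------------------
# Root finding
# ---------------------------------------------------------------------------

def _newton_batch(u, v, k1, k2, k3, k4, max_iter: int = 80):
    """Damped Newton iteration on batches of seeds (all arrays broadcast).

    Returns (u, v, converged).  The 2x2 linear solve is closed-form so the
    whole batch advances in lock-step; steps are clipped to stay inside a
    generous bounding box, which is all the damping this polynomial system
    needs in practice.
    """
    u = np.array(u, dtype=float)
    v = np.array(v, dtype=float)
    for it in range(max_iter):
        fu = k1 * u - k3 * v - u**3
        fv = k2 * v + k4 * u - v**3
        if it % 8 == 7 and np.max(np.maximum(np.abs(fu), np.abs(fv))) < RESIDUAL_TOL:
            break
        a = k1 - 3.0 * u**2
        b = -k3 * np.ones_like(u) if np.ndim(k3) == 0 else -k3
        c = k4 * np.ones_like(u) if np.ndim(k4) == 0 else k4
        d = k2 - 3.0 * v**2
        det = a * d - b * c
        det = np.where(np.abs(det) < 1e-14, np.sign(det) * 1e-14 + (det == 0) * 1e-14, det)
        du = (d * fu - b * fv) / det
        dv = (a * fv - c * fu) / det
        step = np.hypot(du, dv)
        damp = np.where(step > 1.0, 1.0 / np.maximum(step, 1.0), 1.0)  # trust-region damping
        u = u - damp * du
        v = v - damp * dv
        np.clip(u, -3.0 * SEED_BOX, 3.0 * SEED_BOX, out=u)
        np.clip(v, -3.0 * SEED_BOX, 3.0 * SEED_BOX, out=v)
    fu = k1 * u - k3 * v - u**3
    fv = k2 * v + k4 * u - v**3
    converged = np.maximum(np.abs(fu), np.abs(fv)) < RESIDUAL_TOL
    return u, v, converged


def _seed_grid() -> tuple[np.ndarray, np.ndarray]:
    g = np.linspace(-SEED_BOX, SEED_BOX, SEED_N)
    uu, vv = np.meshgrid(g, g)
    return uu.ravel(), vv.ravel()


def _dedup(us: np.ndarray, vs: np.ndarray, tol: float = DEDUP_TOL):
    """Greedy deduplication of converged roots, nearest-to-origin first."""
    order = np.argsort(np.hypot(us, vs), kind="stable")
    out: list[tuple[float, float]] = []
    for i in order:
        u, v = us[i], vs[i]
        if not any(np.hypot(u - a, v - b) <= tol for a, b in out):
            out.append((float(u), float(v)))
    return out


def find_steady_states(k: KineticParams, warn: Callable[[str], None] | None = None) -> list[SteadyState]:
    """Enumerate all real steady states of the reaction system.

    Newton iterations are seeded on a dense grid over the phase-space box
    that contains every root of the cubic system; converged roots are
    deduplicated and classified.  The list is sorted by distance from the
    origin.  Seeds that fail to converge are reported through ``warn``
    (they are expected: some seeds sit on separatrices).
    """
    su, sv = _seed_grid()
    u, v, ok = _newton_batch(su, sv, k.k1, k.k2, k.k3, k.k4)
    n_fail = int((~ok).sum())
    if n_fail and warn is not None:
        warn(f"{n_fail} of {ok.size} Newton seeds did not converge for {k}")
    roots = _dedup(u[ok], v[ok])
    return [classify_stability(PhasePoint(ru, rv), k) for ru, rv in roots]


def steady_state_polynomial_roots(k: KineticParams) -> list[PhasePoint]:
    """Steady states via the exact degree-9 resolvent polynomial in v.

    Substituting ``u = (v^3 - k2 v)/k4`` (the v-nullcline) into the
    u-equation yields a degree-9 polynomial whose real roots are exactly
    the steady states.  This is an independent enumeration used to
    cross-check the Newton search; it requires ``k4 > 0``.
    """
    if k.k4 == 0:
        raise ValueError("polynomial route requires k4 > 0")
    # p(v) = k1*k4^2*(v^3 - k2 v) - k3*k4^3*v - (v^3 - k2 v)^3
    g = np.array([1.0, 0.0, -k.k2, 0.0])  # v^3 - k2 v
    g3 = np.polymul(np.polymul(g, g), g)
    p = np.polyadd(k.k1 * k.k4**2 * g, np.array([-k.k3 * k.k4**3, 0.0]))
    p = np.polysub(np.pad(p, (len(g3) - len(p), 0)), g3)
    roots = np.roots(p)
    pts = []
    for r in roots:
        if abs(r.imag) < 1e-8:
            v = float(r.real)
            u = (v**3 - k.k2 * v) / k.k4
            # polish with a few Newton steps and verify residual
            uu, vv, ok = _newton_batch(np.array([u]), np.array([v]), k.k1, k.k2, k.k3, k.k4, max_iter=20)
            if ok[0]:
                pts.append((float(uu[0]), float(vv[0])))
    out = _dedup(np.array([p[0] for p in pts] or [np.nan]), np.array([p[1] for p in pts] or [np.nan])) if pts else []
    return [PhasePoint(u, v) for u, v in out]


def classify_stability(s: PhasePoint, k: KineticParams) -> SteadyState:
    """Linear-stability classification of a steady state.

    Stability follows the determinant/trace rule of the 2x2 linearisation:
    stable iff ``det > 0`` and ``trace < 0``.  ``kind_label`` uses the
    standard phase-plane taxonomy (saddle / node / focus / center).  States
    with |det| or |trace| below the marginality tolerance are flagged
    marginal and never reported stable.
    """
    fu, fv = reaction_rates(s, k)
    if max(abs(fu), abs(fv)) > 1e-6:
        raise ValueError(
            f"({s.u}, {s.v}) is not a steady state (residual {max(abs(fu), abs(fv)):.2e})"
        )
    J = jacobian(s, k)
    det = float(np.linalg.det(J))
    tr = float(np.trace(J))
    marginal = abs(det) < MARGINAL_TOL or abs(tr) < MARGINAL_TOL
    disc = tr**2 - 4.0 * det
    if det < 0:
        label = "saddle"
    elif abs(tr) < MARGINAL_TOL and det > 0:
        label = "center"
    elif disc >= 0:
        label = "node"
    else:
        label = "focus"
    stable = (det > 0) and (tr < 0) and not marginal
    return SteadyState(location=s, det=det, trace=tr, stable=stable, kind_label=label, marginal=marginal)


# ---------------------------------------------------------------------------
# Bifurcation scans
# ---------------------------------------------------------------------------

def _count_batch(k1: np.ndarray, k2: np.ndarray, k3: float, k4: float) -> np.ndarray:
    """Number of distinct steady states for each (k1, k2) pair (flat arrays)."""
    su, sv = _seed_grid()
    n = k1.size
    counts = np.zeros(n, dtype=int)
    # batch all seeds for a chunk of parameter points at once
    chunk = max(1, int(2_000_000 // su.size))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        kk1 = k1[lo:hi, None]
        kk2 = k2[lo:hi, None]
        u, v, ok = _newton_batch(su[None, :], sv[None, :], kk1, kk2, k3, k4, max_iter=60)
        # dedup by rounding: distinct roots of the cubic system are far
        # apart relative to the 1e-6 dedup tolerance
        key = np.round(u, 4) + 1j * np.round(v, 4)
        for i in range(hi - lo):
            counts[lo + i] = np.unique(key[i][ok[i]]).size
    return counts


def bifurcation_scan_1d(
    k1_values: Sequence[float],
    k2: float = 1.0,
    k3: float = 1.0,
    k4: float = 1.0,
    refine: bool = True,
) -> dict:
    """Scan k1 and report steady states, counts and the bifurcation threshold.

    Returns a dict with per-k1 state lists, the threshold at scan
    resolution (smallest scanned k1 with more than one state), the
    threshold at one-decimal resolution (smallest multiple of 0.1 with
    more than one state) and, optionally, the fold location refined by
    bisection to 1e-4.
    """
    k1_values = np.asarray(k1_values, dtype=float)
    if np.any(np.diff(k1_values) < 0):
        raise ValueError("k1 values must be sorted ascending")
    states = []
    counts = np.zeros(k1_values.size, dtype=int)
    for i, k1 in enumerate(k1_values):
        st = find_steady_states(KineticParams(k1=float(k1), k2=k2, k3=k3, k4=k4, D=0.0))
        states.append(st)
        counts[i] = len(st)
    multi = counts > 1
    threshold = float(k1_values[multi][0]) if multi.any() else None

    def n_states(k1: float) -> int:
        return len(find_steady_states(KineticParams(k1=k1, k2=k2, k3=k3, k4=k4, D=0.0)))

    threshold_one_decimal = None
    if threshold is not None:
        t = np.floor(threshold * 10.0) / 10.0
        threshold_one_decimal = float(t if n_states(float(t)) > 1 else np.round(t + 0.1, 10))

    threshold_refined = None
    if refine and threshold is not None:
        lo = float(k1_values[multi.argmax() - 1]) if multi.argmax() > 0 else threshold - 0.1
        hi = threshold
        while hi - lo > 1e-4:
            mid = 0.5 * (lo + hi)
            if n_states(mid) > 1:
                hi = mid
            else:
                lo = mid
        threshold_refined = 0.5 * (lo + hi)
    return {
        "k1": k1_values,
        "states": states,
        "counts": counts,
        "threshold": threshold,
        "threshold_one_decimal": threshold_one_decimal,
        "threshold_refined": threshold_refined,
    }


def bifurcation_scan_2d(
    k1_values: Sequence[float],
    k2_values: Sequence[float],
    k3: float = 1.0,
    k4: float = 1.0,
) -> np.ndarray:
    """Grid of steady-state counts over (k1, k2); shape (len(k1), len(k2))."""
    k1_values = np.asarray(k1_values, dtype=float)
    k2_values = np.asarray(k2_values, dtype=float)
    if np.any(np.diff(k1_values) < 0) or np.any(np.diff(k2_values) < 0):
        raise ValueError("scan grids must be sorted ascending")
    kk1, kk2 = np.meshgrid(k1_values, k2_values, indexing="ij")
    counts = _count_batch(kk1.ravel(), kk2.ravel(), k3, k4)
    return counts.reshape(k1_values.size, k2_values.size)


def count_states_grid(k1_values, k2_values, k3: float = 1.0, k4: float = 1.0) -> np.ndarray:
    """Alias of :func:`bifurcation_scan_2d` (kept for scripting clarity)."""
    return bifurcation_scan_2d(k1_values, k2_values, k3=k3, k4=k4)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def states_to_csv(rows: list[tuple[KineticParams, SteadyState]]) -> str:
    """Serialize (params, state) pairs to CSV text."""
    buf = _io.StringIO()
    buf.write("k1,k2,k3,k4,u,v,det,trace,stable,kind_label\n")
    for k, s in rows:
        buf.write(
            f"{k.k1:.17g},{k.k2:.17g},{k.k3:.17g},{k.k4:.17g},"
            f"{s.location.u:.17g},{s.location.v:.17g},"
            f"{s.det:.17g},{s.trace:.17g},{s.stable},{s.kind_label}\n"
        )
    return buf.getvalue()
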