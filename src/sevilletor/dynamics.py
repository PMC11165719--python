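"""Two-cell simulations, phase computation and oscillation counting.

A pair of cells coupled by diffusion of ``u`` is the smallest system in
which the Sevilletor's diffusion-driven behaviours appear: depending on the
self-enhancement ``k1``, coupling can freeze two anti-phase oscillators
(lateral inhibition), synchronise them, or repeatedly excite two resting
bistable cells onto a new limit cycle (diffusion-driven excitability).

The phase of a cell is the unsigned angle in [0, pi] between the vector
from the origin to its initial position and the vector to its current
position; one full loop takes the phase from 0 up to pi and back to 0, so
oscillations are counted as near-zero local minima of the phase series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import KineticParams, PhasePoint, find_steady_states

__all__ = [
    "TwoCellTrajectory",
    "PhaseSeries",
    "BehaviorMap",
    "simulate_two_cells",
    "phase_of",
    "count_oscillations",
    "behavior_map",
    "excitability_probe",
    "notch_inhibition_probe",
]

#: Phase minima below this angle (radians) count as completed loops.
NEAR_ZERO_TOL = 0.15
#: A run with at least this many counted loops is "sustained".
SUSTAINED_MIN_COUNT = 3
DEFAULT_DURATION = 200.0
DEFAULT_DT = 0.005
DEFAULT_SPACING = 1.0
#: Two-cell distance used for the in-vitro density probes: comfortably
#: inside the coupling window where the reference excitable regime
#: (k1 = 2.3) sustains oscillations, see docs/methods.md.
HIGH_DENSITY_SPACING = 1.5


@dataclass
class TwoCellTrajectory:
    """Time courses of two diffusively coupled cells."""

    times: np.ndarray
    cellA: np.ndarray  # shape (n, 2): columns u, v
    cellB: np.ndarray
    params: KineticParams
    spacing: float
    dt: float

    def cell(self, index: int) -> np.ndarray:
        return (self.cellA, self.cellB)[index]


@dataclass
class PhaseSeries:
    """Phase angle in [0, pi] per time sample; phase[0] == 0."""

    times: np.ndarray
    phase: np.ndarray
    degenerate: np.ndarray = field(default=None)  # samples where the point hit the origin

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros(self.phase.shape, dtype=bool)


@dataclass
class BehaviorMap:
    """Oscillation counts and behaviour classes over a (k1, k2) grid."""

    k1_values: np.ndarray
    k2_values: np.ndarray
    oscillation_count: np.ndarray  # shape (len(k1), len(k2)); -1 marks divergent runs
    class_label: np.ndarray  # same shape, dtype=object
    bifurcation_boundary: np.ndarray  # bool: >1 reaction-only steady state


def simulate_two_cells(
    k: KineticParams,
    spacing: float = DEFAULT_SPACING,
    init: tuple[PhasePoint, PhasePoint] = (PhasePoint(0.1, 0.0), PhasePoint(-0.1, 0.0)),
    duration: float = DEFAULT_DURATION,
    dt: float = DEFAULT_DT,
) -> TwoCellTrajectory:
    """Integrate two cells coupled by diffusion of ``u``.

    The coupling is the two-node discrete Laplacian with zero-flux ends:
    each cell receives ``D * (u_other - u_self) / spacing**2``, so ``D = 0``
    decouples the cells exactly and identical initial conditions evolve
    with zero diffusive exchange.
    """
    if k.D > 0 and not dt < spacing**2 / (2.0 * k.D):
        raise ValueError(
            f"dt={dt} violates the explicit stability bound spacing^2/(2 D) = "
            f"{spacing**2 / (2 * k.D):.4g}"
        )
    n = int(round(duration / dt))
    out = np.empty((n + 1, 4))
    a, b = init
    u1, v1, u2, v2 = a.u, a.v, b.u, b.v
    out[0] = (u1, v1, u2, v2)
    k1, k2, k3, k4 = k.k1, k.k2, k.k3, k.k4
    c = k.D / spacing**2
    for i in range(n):
        du1 = k1 * u1 - k3 * v1 - u1**3 + c * (u2 - u1)
        dv1 = k2 * v1 + k4 * u1 - v1**3
        du2 = k1 * u2 - k3 * v2 - u2**3 + c * (u1 - u2)
        dv2 = k2 * v2 + k4 * u2 - v2**3
        u1 += dt * du1
        v1 += dt * dv1
        u2 += dt * du2
        v2 += dt * dv2
        if not (abs(u1) + abs(v1) + abs(u2) + abs(v2) < 1e12):
            raise FloatingPointError(
                f"two-cell integration diverged at step {i + 1} (t={(i + 1) * dt:.4g})"
            )
        out[i + 1] = (u1, v1, u2, v2)
    times = np.arange(n + 1) * dt
    return TwoCellTrajectory(
        times=times, cellA=out[:, :2], cellB=out[:, 2:], params=k, spacing=spacing, dt=dt
    )


def phase_of(traj: np.ndarray, times: np.ndarray | None = None) -> PhaseSeries:
    """Phase series of one cell's (u, v) trajectory.

    The phase at time t is the unsigned angle between origin->initial point
    and origin->current point, clipped to [0, pi].  If the trajectory hits
    the origin the previous phase is carried over and the sample flagged.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise ValueError("trajectory must have shape (n, 2)")
    p0 = traj[0]
    r0 = np.hypot(p0[0], p0[1])
    if r0 == 0.0:
        raise ValueError("phase is undefined for an initial point at the origin")
    r = np.hypot(traj[:, 0], traj[:, 1])
    degenerate = r == 0.0
    denom = np.where(degenerate, 1.0, r * r0)
    cosang = np.clip((traj[:, 0] * p0[0] + traj[:, 1] * p0[1]) / denom, -1.0, 1.0)
    phase = np.arccos(cosang)
    if degenerate.any():
        idx = np.where(degenerate)[0]
        for i in idx:
            phase[i] = phase[i - 1] if i > 0 else 0.0
    if times is None:
        times = np.arange(traj.shape[0], dtype=float)
    return PhaseSeries(times=np.asarray(times, dtype=float), phase=phase, degenerate=degenerate)


def count_oscillations(ps: PhaseSeries, near_zero_tol: float = NEAR_ZERO_TOL) -> int:
    """Number of completed loops: near-zero local minima of the phase.

    A local minimum is a sample (or plateau of equal samples) strictly
    below both neighbours with phase below ``near_zero_tol``; the minimum
    at t = 0 is excluded.
    """
    ph = np.asarray(ps.phase, dtype=float)
    if ph.size < 3:
        return 0
    count = 0
    i = 1
    n = ph.size
    while i < n - 1:
        j = i
        while j + 1 < n and ph[j + 1] == ph[j]:
            j += 1
        if j < n - 1 and ph[i - 1] > ph[i] and ph[j + 1] > ph[j] and ph[i] < near_zero_tol:
            count += 1
        i = j + 1
    return count


def _count_minima_streaming(prev2, prev1, cur, counts, tol):
    """Vectorised minima update used by the batched map scan."""
    is_min = (prev2 > prev1) & (cur > prev1) & (prev1 < tol)
    counts += is_min.astype(counts.dtype)


def behavior_map(
    k1_values,
    k2_values,
    D: float = 0.3,
    init: tuple[PhasePoint, PhasePoint] = (PhasePoint(0.1, 0.0), PhasePoint(-0.1, 0.0)),
    duration: float = DEFAULT_DURATION,
    dt: float = DEFAULT_DT,
    spacing: float = DEFAULT_SPACING,
    k3: float = 1.0,
    k4: float = 1.0,
    sample_every: float = 0.05,
) -> BehaviorMap:
    """One two-cell simulation per (k1, k2) grid point, batched.

    Counts oscillations of cell A on the fly and overlays the reaction-only
    bifurcation boundary (grid points with more than one steady state).
    Divergent runs are recorded with count -1, never raised.
    """
    k1_values = np.asarray(k1_values, dtype=float)
    k2_values = np.asarray(k2_values, dtype=float)
    if np.any(np.diff(k1_values) < 0) or np.any(np.diff(k2_values) < 0):
        raise ValueError("behaviour-map grids must be sorted ascending")
    kk1, kk2 = np.meshgrid(k1_values, k2_values, indexing="ij")
    kk1 = kk1.ravel()
    kk2 = kk2.ravel()
    m = kk1.size
    a, b = init
    u1 = np.full(m, a.u)
    v1 = np.full(m, a.v)
    u2 = np.full(m, b.u)
    v2 = np.full(m, b.v)
    c = D / spacing**2
    nstep = int(round(duration / dt))
    stride = max(1, int(round(sample_every / dt)))
    p0u, p0v = a.u, a.v
    r0 = float(np.hypot(p0u, p0v))
    counts = np.zeros(m, dtype=np.int64)
    alive = np.ones(m, dtype=bool)
    prev1 = np.zeros(m)
    prev2 = np.zeros(m)
    first = True
    for i in range(nstep):
        du1 = kk1 * u1 - k3 * v1 - u1**3 + c * (u2 - u1)
        dv1 = kk2 * v1 + k4 * u1 - v1**3
        du2 = kk1 * u2 - k3 * v2 - u2**3 + c * (u1 - u2)
        dv2 = kk2 * v2 + k4 * u2 - v2**3
        u1 += dt * du1
        v1 += dt * dv1
        u2 += dt * du2
        v2 += dt * dv2
        if (i + 1) % stride == 0:
            bad = ~np.isfinite(u1) | ~np.isfinite(v1)
            if bad.any():
                alive &= ~bad
                u1[bad] = v1[bad] = u2[bad] = v2[bad] = 0.0
            r = np.hypot(u1, v1)
            cosang = np.clip((u1 * p0u + v1 * p0v) / np.maximum(r * r0, 1e-300), -1.0, 1.0)
            ph = np.arccos(cosang)
            if not first:
                _count_minima_streaming(prev2, prev1, ph, counts, NEAR_ZERO_TOL)
            prev2, prev1 = prev1, ph
            first = False
    counts = np.where(alive, counts, -1)
    labels = np.empty(m, dtype=object)
    labels[counts >= SUSTAINED_MIN_COUNT] = "sustained"
    labels[(counts > 0) & (counts < SUSTAINED_MIN_COUNT)] = "transient"
    labels[counts == 0] = "none"
    labels[counts < 0] = "divergent"
    boundary = np.zeros(m, dtype=bool)
    for j in range(m):
        st = find_steady_states(KineticParams(k1=kk1[j], k2=kk2[j], k3=k3, k4=k4, D=D))
        boundary[j] = len(st) > 1
    shape = (k1_values.size, k2_values.size)
    return BehaviorMap(
        k1_values=k1_values,
        k2_values=k2_values,
        oscillation_count=counts.reshape(shape),
        class_label=labels.reshape(shape),
        bifurcation_boundary=boundary.reshape(shape),
    )


def excitability_probe(
    k: KineticParams,
    spacings,
    init: tuple[PhasePoint, PhasePoint] = (PhasePoint(0.1, 0.0), PhasePoint(-0.1, 0.0)),
    duration: float = DEFAULT_DURATION,
    dt: float = DEFAULT_DT,
) -> dict:
    """Oscillation count as a function of inter-cell distance.

    In the excitable regime the diffusive push weakens as cells move apart,
    so counts fall with spacing; the probe reports the smallest spacing
    with no sustained oscillation (density at which the virtual culture
    arrests), or None if every spacing sustains.
    """
    spacings = np.asarray(spacings, dtype=float)
    if np.any(np.diff(spacings) < 0):
        raise ValueError("spacings must be sorted ascending")
    counts = []
    for s in spacings:
        traj = simulate_two_cells(k, spacing=float(s), init=init, duration=duration, dt=dt)
        ps = phase_of(traj.cellA, traj.times)
        counts.append(count_oscillations(ps))
    counts = np.array(counts)
    arrested = counts < SUSTAINED_MIN_COUNT
    arrest_spacing = float(spacings[arrested][0]) if arrested.any() else None
    return {"spacings": spacings, "counts": counts, "arrest_spacing": arrest_spacing}


def _stable_unstable_distance(k: KineticParams) -> float | None:
    """Distance from a stable state to its nearest unstable non-origin state.

    This is the excitability threshold statistic: the jolt a resting cell
    needs to be kicked onto the trajectory of the nearest unstable point.
    """
    states = find_steady_states(k)
    stable = [s for s in states if s.stable]
    unstable = [s for s in states if not s.stable and s.location.radius > 1e-9]
    if not stable or not unstable:
        return None
    return min(
        s.location.distance_to(t.location) for s in stable for t in unstable
    )


def notch_inhibition_probe(
    k: KineticParams,
    spacing: float = HIGH_DENSITY_SPACING,
    init: tuple[PhasePoint, PhasePoint] = (PhasePoint(0.1, 0.0), PhasePoint(-0.1, 0.0)),
    duration: float = DEFAULT_DURATION,
    dt: float = DEFAULT_DT,
) -> dict:
    """Effect of Notch inhibition (k2 = 0) on two-cell excitability.

    Runs the probe at the given spacing with ``k2`` forced to zero and
    reports the oscillation count together with the stable-to-unstable
    state distance (the excitability threshold), which grows when the
    self-enhancement of ``v`` is removed.
    """
    k0 = k.replace(k2=0.0)
    traj = simulate_two_cells(k0, spacing=spacing, init=init, duration=duration, dt=dt)
    ps = phase_of(traj.cellA, traj.times)
    count = count_oscillations(ps)
    return {
        "count": count,
        "sustained": count >= SUSTAINED_MIN_COUNT,
        "excitability_threshold": _stable_unstable_distance(k0),
        "control_excitability_threshold": _stable_unstable_distance(k),
        "params": k0,
    }
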