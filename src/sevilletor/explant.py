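"""Virtual tail explants: radial projection onto a disc, mixing, ablation.

An explant is built by projecting a stretch of the anterior-posterior axis
of a simulated tail onto a masked circular domain: the posterior-most
column of the source region maps to the disc centre and the anterior-most
column to the rim, so zone identity (the k1 regionalisation) becomes
radial.  Cells may inherit the (u, v) phase values they had in the tail or
start from one uniform phase; the frequency-gradient profile (k3/k4) may
likewise be inherited or flattened.  Positions can be randomised to mimic
centrifuged, re-aggregated explants, and a central disc can be ablated
(masked out, acting as a zero-flux internal boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import GridState, NumericalScheme, ParameterFields, SimulationRecord, run_simulation
from .models import ModelPreset, parameter_builder

__all__ = [
    "ExplantLayout",
    "project_tail_to_disc",
    "randomize_positions",
    "ablate_center",
    "run_explant",
]

WHOLE_POSTERIOR = "whole-posterior"
MIDDLE_ONLY = "middle-only"


@dataclass(frozen=True)
class ExplantLayout:
    """Geometry and inheritance options of a virtual explant.

    ``source_region`` selects the stretch of tail that is projected:
    'whole-posterior' covers everything from the tip to the anterior zone
    boundary, 'middle-only' just the excitable middle zone.
    """

    disc_radius: int = 50
    source_region: str = WHOLE_POSTERIOR
    inherit_phase: bool = True
    inherit_FG: bool = True
    mixed: bool = False
    mix_seed: int = 0
    ablation_radius: int = 0
    uniform_phase: tuple[float, float] = (0.1, 0.0)
    #: columns dropped at the anterior end of a whole-posterior source so
    #: the dissection stays posterior of the determination front's rise
    front_margin: int = 3

    def __post_init__(self) -> None:
        if self.source_region not in (WHOLE_POSTERIOR, MIDDLE_ONLY):
            raise ValueError(f"unknown source region {self.source_region!r}")
        if self.ablation_radius >= self.disc_radius:
            raise ValueError("ablation radius must be smaller than the disc radius")


def _source_interval(
    Lx: int, posterior_zone: int, middle_zone: int, region: str, front_margin: int = 0
) -> tuple[int, int]:
    """(anterior column, posterior column) of the source region, inclusive."""
    tip = Lx - 1
    if region == MIDDLE_ONLY:
        lo = tip - (posterior_zone + middle_zone)
        hi = tip - posterior_zone
    else:
        lo = tip - (posterior_zone + middle_zone) + front_margin
        hi = tip
    lo = max(lo, 0)
    if hi <= lo:
        raise ValueError("source region is empty for this tail")
    return lo, hi


def project_tail_to_disc(
    tail: GridState,
    layout: ExplantLayout,
    preset: ModelPreset,
    tail_params: ParameterFields | None = None,
) -> tuple[GridState, ParameterFields]:
    """Project a tail snapshot onto a disc-masked grid.

    Each disc cell at radius r samples the tail column at the AP position
    linearly interpolated between the posterior end of the source region
    (r = 0) and its anterior end (r = disc radius); the tail's lateral (y)
    dimension is averaged out, making the projection purely radial.  The
    regionalisation profile k1 is always projected (zone identity travels
    with the cells); the frequency-gradient profile follows
    ``layout.inherit_FG`` and the (u, v) fields ``layout.inherit_phase``.
    """
    if tail_params is None:
        tail_params = parameter_builder(preset)(tail.Lx)
    lo, hi = _source_interval(
        tail.Lx,
        preset.posterior_zone,
        preset.middle_zone,
        layout.source_region,
        layout.front_margin,
    )

    R = layout.disc_radius
    N = 2 * R + 1
    yy, xx = np.mgrid[0:N, 0:N]
    r = np.hypot(xx - R, yy - R)
    mask = r <= R
    # radius -> fractional AP column (posterior at the centre)
    ap = hi - np.clip(r / R, 0.0, 1.0) * (hi - lo)
    i0 = np.floor(ap).astype(int)
    i1 = np.minimum(i0 + 1, hi)
    w = ap - i0

    def sample(profile_1d: np.ndarray) -> np.ndarray:
        return (1.0 - w) * profile_1d[i0] + w * profile_1d[i1]

    u_cols = tail.u.mean(axis=1)
    v_cols = tail.v.mean(axis=1)
    if layout.inherit_phase:
        u = np.where(mask, sample(u_cols), 0.0)
        v = np.where(mask, sample(v_cols), 0.0)
    else:
        u = np.where(mask, layout.uniform_phase[0], 0.0)
        v = np.where(mask, layout.uniform_phase[1], 0.0)

    k1p, k3p, k4p = tail_params.expand(tail.u.shape)
    k1 = np.where(mask, sample(k1p[:, 0]), 0.0)
    if layout.inherit_FG:
        k3 = np.where(mask, sample(k3p[:, 0]), preset.k3_base)
        k4 = np.where(mask, sample(k4p[:, 0]), preset.k4_base)
    else:
        k3 = np.full((N, N), preset.k3_base)
        k4 = np.full((N, N), preset.k4_base)

    disc = GridState(u, v, mask)
    params = ParameterFields(k1=k1, k3=k3, k4=k4, k2=preset.k2, D=preset.D, Dv=preset.Dv)
    if layout.mixed:
        # cells carry their state AND their regional identity with them,
        # so the kinetic fields are permuted alongside (u, v)
        idx = np.where(mask.ravel())[0]
        perm = np.random.default_rng(layout.mix_seed).permutation(idx.size)
        arrays = [disc.u, disc.v, params.k1]
        if layout.inherit_FG:
            arrays += [params.k3, params.k4]
        for arr in arrays:
            flat = arr.ravel()
            flat[idx] = flat[idx][perm]
    if layout.ablation_radius > 0:
        disc = ablate_center(disc, layout.ablation_radius)
    return disc, params


def randomize_positions(disc: GridState, seed: int | None) -> GridState:
    """Uniformly permute the (u, v) pairs among unmasked cells.

    The multiset of values is preserved exactly; only positions change.
    """
    out = disc.copy()
    idx = np.where(out.mask.ravel())[0]
    perm = np.random.default_rng(seed).permutation(idx.size)
    u = out.u.ravel()
    v = out.v.ravel()
    u[idx] = u[idx][perm]
    v[idx] = v[idx][perm]
    return GridState(u.reshape(disc.u.shape), v.reshape(disc.v.shape), out.mask, disc.boundary_mode)


def ablate_center(disc: GridState, radius: float) -> GridState:
    """Mask out the cells within ``radius`` of the disc centre.

    Masked cells freeze and their boundary behaves as zero-flux
    (lattice mask contract).  ``radius = 0`` is the identity.
    """
    if radius == 0:
        return disc.copy()
    cx = (disc.Lx - 1) / 2.0
    cy = (disc.Ly - 1) / 2.0
    xx, yy = np.mgrid[0 : disc.Lx, 0 : disc.Ly]
    r = np.hypot(xx - cx, yy - cy)
    mask = disc.mask & ~(r < radius)
    return GridState(disc.u.copy(), disc.v.copy(), mask, disc.boundary_mode)


def run_explant(
    layout: ExplantLayout,
    preset: ModelPreset,
    tail: GridState,
    scheme: NumericalScheme | None = None,
    seed: int | None = 0,
    tail_params: ParameterFields | None = None,
) -> tuple[SimulationRecord, str]:
    """Project, integrate and classify a virtual explant.

    Returns the simulation record and the pattern class from
    :func:`sevilletor.metrics.classify_explant` (circular-waves /
    rotating-waves / chessboard / homogeneous-oscillation / frozen).
    """
    from .metrics import classify_explant  # local import: metrics imports lattice

    disc, params = project_tail_to_disc(tail, layout, preset, tail_params)
    if scheme is None:
        scheme = NumericalScheme(dt=0.01, dx=1.0, duration=150.0, snapshot_interval=1.0)
    rec = run_simulation(disc, params, scheme, noise=None, seed=seed)
    rec.config["preset"] = preset.name
    rec.config["layout"] = {
        "disc_radius": layout.disc_radius,
        "source_region": layout.source_region,
        "inherit_phase": layout.inherit_phase,
        "inherit_FG": layout.inherit_FG,
        "mixed": layout.mixed,
        "ablation_radius": layout.ablation_radius,
    }
    return rec, classify_explant(rec)
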