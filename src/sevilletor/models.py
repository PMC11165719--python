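"""Spatial modulation profiles, noise protocol and the somitogenesis presets.

Two sigmoidal functions modulate the kinetics along the anterior-posterior
axis of the growing tail:

* ``R`` (regionalisation) shifts the self-enhancement ``k1`` step-wise in
  space, splitting the axis into oscillatory / excitable / bistable zones.
* ``FG`` (frequency gradient) shifts the feedback strengths ``k3`` and
  ``k4`` together; oscillation frequency grows linearly with them, so an
  anteriorly decreasing FG is a frequency profile.

Both are sigmoids ``delta_k / (1 + exp(-a * s))`` of the distance ``s``
from a zone boundary; the boundaries are measured from the posterior tip
and therefore travel with it as the tail grows.

Model presets:

``CW``
    Clock and Wavefront: oscillatory PSM (k1 = 1) with an anterior
    bistable determination front (delta_k1 = 3, a = 1); no FG.
``CG``
    Clock and Gradient: the CW front plus an anteriorly decreasing
    frequency gradient (delta_k34 = 2, a = 0.1) that produces phase waves.
``PORD``
    Progressive Oscillatory Reaction-Diffusion: lateral-inhibition relay
    (k1 = 0, D = 1) seeded by an anterior pre-patterned somite, with a
    weak frequency gradient (delta_k34 = 0.3, a = 0.1).
``CWS``
    Clock and Wavefront Self-Organizing: a two-step change of k1 from the
    excitable baseline 2.3 (posterior -1.3 -> 1.0 oscillatory, anterior
    +1.7 -> 4.0 bistable) and no frequency gradient; phase waves arise
    from diffusion-driven excitation of the middle region.
``CWS_graded``
    CWS with k1 ramped linearly across the middle region instead of a
    plateau; waves thin as they travel anteriorly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .lattice import (
    GridState,
    NumericalScheme,
    ParameterFields,
    SimulationRecord,
    run_simulation,
)

__all__ = [
    "SigmoidSpec",
    "NoiseSpec",
    "ModelPreset",
    "sigmoid_profile",
    "build_R",
    "build_FG",
    "apply_multiplicative_noise",
    "load_preset",
    "PRESET_NAMES",
    "run_tail",
]

PRESET_NAMES = ("CW", "PORD", "CG", "CWS", "CWS_graded")


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


@dataclass(frozen=True)
class SigmoidSpec:
    """One sigmoidal step of amplitude ``delta_k`` along the axis.

    ``anchor`` names the zone boundary the midpoint sits on ('posterior'
    or 'anterior'); ``offset`` displaces the midpoint from that boundary
    (in cells, positive toward the posterior tip); ``rises`` gives the
    side on which the profile saturates at ``delta_k`` ('posterior' or
    'anterior'); ``sign`` multiplies the whole contribution.
    """

    delta_k: float
    a: float = 1.0
    anchor: str = "anterior"
    offset: float = 0.0
    rises: str = "posterior"
    sign: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("sigmoid steepness a must be positive")
        if self.anchor not in ("posterior", "anterior"):
            raise ValueError("anchor must be 'posterior' or 'anterior'")
        if self.rises not in ("posterior", "anterior"):
            raise ValueError("rises must be 'posterior' or 'anterior'")


def boundary_coordinates(Lx: int, posterior_zone: int, middle_zone: int) -> tuple[float, float]:
    """(x_posterior, x_anterior) boundary columns, measured from the tip.

    x increases anterior -> posterior; the tip is column Lx - 1.  The
    posterior boundary sits ``posterior_zone`` cells from the tip and the
    anterior boundary ``posterior_zone + middle_zone`` cells from it.
    """
    tip = Lx - 1
    return tip - posterior_zone, tip - (posterior_zone + middle_zone)


def sigmoid_profile(
    x: np.ndarray,
    spec: SigmoidSpec,
    x_posterior: float,
    x_anterior: float,
) -> np.ndarray:
    """Evaluate one sigmoid contribution at the column positions ``x``.

    Saturates to 0 on one side of the anchored midpoint and to
    ``sign * delta_k`` on the other; steepness ``a`` sets the transition
    width (~4/a cells between the 12% and 88% levels).
    """
    x = np.asarray(x, dtype=float)
    x0 = (x_posterior if spec.anchor == "posterior" else x_anterior) + spec.offset
    s = (x - x0) if spec.rises == "posterior" else (x0 - x)
    return spec.sign * spec.delta_k * _expit(spec.a * s)


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative noise amplitudes applied at growth events.

    Every time a posterior column is added, each cell's u and v are scaled
    by ``1 + delta_uv * mu`` (mu standard normal) and the full k1 and
    k3/k4 profiles by ``1 + delta_k * mu_j`` per column; k3 and k4 share
    the same draws.  Because the whole profile is perturbed each event,
    anterior and posterior columns accumulate the same expected noise.
    """

    delta_uv: float = 0.05
    delta_k: float = 0.005

    def __post_init__(self) -> None:
        if self.delta_uv < 0 or self.delta_k < 0:
            raise ValueError("noise amplitudes must be non-negative")


def apply_multiplicative_noise(values: np.ndarray, delta: float, rng: np.random.Generator) -> np.ndarray:
    """Return ``values * (1 + delta * mu)`` with independent standard-normal mu."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    values = np.asarray(values, dtype=float)
    if delta == 0:
        return values.copy()
    return values * (1.0 + delta * rng.standard_normal(values.shape))


@dataclass(frozen=True)
class ModelPreset:
    """A complete tail-simulation configuration."""

    name: str
    k1_base: float
    k2: float
    k3_base: float
    k4_base: float
    D: float
    Dv: float
    R_specs: tuple[SigmoidSpec, ...]
    FG_spec: SigmoidSpec | None
    graded_middle: bool
    noise: NoiseSpec
    posterior_zone: int
    middle_zone: int
    Ly: int
    Lx0: int
    growth_period: float
    duration: float
    init: str  # 'noise' or 'prepatterned-somite'
    init_amplitude: float

    def scheme(self, dt: float = 0.01, dx: float = 1.0, duration: float | None = None,
               snapshot_interval: float = 1.0) -> NumericalScheme:
        return NumericalScheme(
            dt=dt,
            dx=dx,
            duration=self.duration if duration is None else duration,
            snapshot_interval=snapshot_interval,
            growth_period=self.growth_period,
        )


def build_R(preset: ModelPreset, Lx: int) -> np.ndarray:
    """The k1 profile over a domain of ``Lx`` columns."""
    x = np.arange(Lx, dtype=float)
    xp, xa = boundary_coordinates(Lx, preset.posterior_zone, preset.middle_zone)
    k1 = np.full(Lx, preset.k1_base)
    for spec in preset.R_specs:
        k1 = k1 + sigmoid_profile(x, spec, xp, xa)
    if preset.graded_middle:
        # replace the middle plateau by a linear ramp between the
        # posterior plateau (value at the tip) and the anterior plateau
        # (value at column 0)
        lo = float(k1[-1])
        hi = float(k1[0])
        inside = (x >= xa) & (x <= xp)
        frac = (xp - x[inside]) / max(xp - xa, 1.0)
        k1[inside] = lo + (hi - lo) * frac
    return np.clip(k1, 0.0, None)


def build_FG(preset: ModelPreset, Lx: int) -> tuple[np.ndarray, np.ndarray]:
    """(k3, k4) profiles; the same FG contribution is used for both."""
    x = np.arange(Lx, dtype=float)
    xp, xa = boundary_coordinates(Lx, preset.posterior_zone, preset.middle_zone)
    fg = sigmoid_profile(x, preset.FG_spec, xp, xa) if preset.FG_spec is not None else 0.0
    k3 = np.full(Lx, preset.k3_base) + fg
    k4 = np.full(Lx, preset.k4_base) + fg
    return np.clip(k3, 0.0, None), np.clip(k4, 0.0, None)


def parameter_builder(preset: ModelPreset):
    """``Lx -> ParameterFields`` closure used by the growth machinery."""

    def build(Lx: int) -> ParameterFields:
        k3, k4 = build_FG(preset, Lx)
        return ParameterFields(
            k1=build_R(preset, Lx), k3=k3, k4=k4, k2=preset.k2, D=preset.D, Dv=preset.Dv
        )

    return build


# ---------------------------------------------------------------------------
# Preset loading
# ---------------------------------------------------------------------------

def _preset_from_dict(d: dict) -> ModelPreset:
    R_specs = tuple(SigmoidSpec(**s) for s in d.get("R", []))
    fg = d.get("FG")
    return ModelPreset(
        name=d["name"],
        k1_base=float(d.get("k1", 1.0)),
        k2=float(d.get("k2", 1.0)),
        k3_base=float(d.get("k3", 1.0)),
        k4_base=float(d.get("k4", 1.0)),
        D=float(d.get("D", 0.3)),
        Dv=float(d.get("Dv", 0.0)),
        R_specs=R_specs,
        FG_spec=SigmoidSpec(**fg) if fg else None,
        graded_middle=bool(d.get("graded_middle", False)),
        noise=NoiseSpec(**d.get("noise", {})),
        posterior_zone=int(d.get("posterior_zone", 25)),
        middle_zone=int(d.get("middle_zone", 40)),
        Ly=int(d.get("Ly", 10)),
        Lx0=int(d.get("Lx0", 70)),
        growth_period=float(d.get("growth_period", 2.0)),
        duration=float(d.get("duration", 400.0)),
        init=d.get("init", "noise"),
        init_amplitude=float(d.get("init_amplitude", 0.1)),
    )


def load_preset(name_or_path: str, **overrides) -> ModelPreset:
    """Load a shipped preset by name (case-insensitive) or a YAML file by path."""
    lowered = name_or_path.lower()
    shipped = {n.lower(): n for n in PRESET_NAMES}
    if lowered in shipped:
        ref = resources.files("sevilletor.presets").joinpath(f"{lowered}.yaml")
        text = ref.read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    d = yaml.safe_load(text)
    d.update(overrides)
    return _preset_from_dict(d)


# ---------------------------------------------------------------------------
# Tail simulations
# ---------------------------------------------------------------------------

def initial_tail_state(preset: ModelPreset, seed: int | None) -> GridState:
    """Initial (u, v) fields for a tail run.

    'noise' draws uniform values on [-amp, amp]^2 per cell; the PORD
    'prepatterned-somite' start is all-zero except the anterior-most
    column, which is set to a high-u value that triggers the relay.
    """
    rng = np.random.default_rng(seed)
    shape = (preset.Lx0, preset.Ly)
    if preset.init == "prepatterned-somite":
        u = np.zeros(shape)
        v = np.zeros(shape)
        u[0, :] = 1.0
    else:
        amp = preset.init_amplitude
        u = rng.uniform(-amp, amp, shape)
        v = rng.uniform(-amp, amp, shape)
    return GridState(u, v)


def run_tail(
    preset: ModelPreset,
    scheme: NumericalScheme | None = None,
    seed: int | None = 0,
    with_noise: bool = False,
    cut_at: int | None = None,
    posterior_zone: int | None = None,
    record_k1: bool = False,
) -> SimulationRecord:
    """Simulate a growing tail under a model preset.

    ``cut_at`` masks one column at the given distance from the initial
    tip, bisecting the tail (the mask column is frozen and exchanges no
    flux).  ``posterior_zone`` overrides the preset's oscillatory-zone
    length.  Noise draws are derived from ``seed``; runs are deterministic.
    """
    if posterior_zone is not None:
        preset = dataclasses.replace(preset, posterior_zone=posterior_zone)
    if scheme is None:
        scheme = preset.scheme()
    if scheme.growth_period != preset.growth_period:
        scheme = dataclasses.replace(scheme, growth_period=preset.growth_period)
    state = initial_tail_state(preset, seed)
    if cut_at is not None:
        col = state.Lx - 1 - cut_at
        if not 0 < col < state.Lx - 1:
            raise ValueError(f"cut position {cut_at} outside the initial tail")
        state.mask[col, :] = False
    rec = run_simulation(
        state,
        parameter_builder(preset),
        scheme,
        noise=preset.noise if with_noise else None,
        seed=seed,
        record_k1=record_k1,
    )
    rec.config["preset"] = preset.name
    rec.config["posterior_zone"] = preset.posterior_zone
    rec.config["middle_zone"] = preset.middle_zone
    rec.config["with_noise"] = with_noise
    return rec
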