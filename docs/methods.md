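# Methods

## The model

The Sevilletor is a two-variable reaction-diffusion system built to study how
genetic oscillations synchronise in space during somitogenesis. Two
self-enhancing reactants *u* and *v* (read as Wnt and Notch signalling
activity, centred on an intermediate level so that concentrations deviate
around 0) are coupled by a negative feedback loop and saturated by cubic
terms:

    ∂u/∂t = k1 u − k3 v − u³ + D ∇²u
    ∂v/∂t = k2 v + k4 u − v³            (v immobile by default)

* `k1`, `k2` — self-enhancement rates of *u* and *v*. The system is analysed
  in the non-dimensionalised form `k2 = 1`.
* `k3`, `k4` — the two arms of the negative feedback (v inhibits u, u
  activates v). With `k1 = k2` small, the feedback drives a limit cycle
  around the unstable origin; the oscillation frequency grows linearly with
  `k3 = k4`, which is how a frequency gradient is imposed.
* `D` — diffusion coefficient of *u* (model length² / model time), default
  0.3. All quantities are in model units; calibration to µm and hours is out
  of scope here.

The cubic terms are symmetric saturations, not degradation: they bound
excursions without affecting the dynamics near the origin.

### Bifurcation structure

With `k2 = k3 = k4 = 1`, the origin is a steady state for every `k1` and is
always unstable. At `k1 ≈ 2.234` (fold located by bisection; 2.3 at the
one-decimal resolution used for reporting) four additional steady states
appear: the two outermost are stable, the inner pair are saddles. `k1` also
sets the distance between the stable states and their nearest unstable
states, which is the excitability threshold of the resting system. Scanning
`(k1, k2)` over [0, 4]² yields regions with 1, 5 and 9 coexisting states.

Steady states are enumerated by a damped Newton iteration seeded on a 41×41
grid over [−3, 3]² (all roots lie well inside this box), deduplicated at
1e-6 and accepted below a 1e-10 residual; an independent degree-9 resolvent
polynomial in *v* (solved with `numpy.roots`) cross-checks the enumeration
in the tests. Stability follows the det/trace rule of the 2×2 linearisation;
|det| or |trace| below 1e-8 is flagged marginal and never counted stable.

### Patterning regimes

From seeded random initial conditions (uniform on [−0.1, 0.1]² per cell) on
a 100×100 zero-flux lattice with `D = 0.3`, varying `k1` alone produces five
behaviours: lateral-inhibition chessboards (`k1 = 0`), rotating waves
(`k1 = 1`), diffusion-driven excitable periodic waves with spirals
(`k1 = 2.3`), bistable fronts coarsening to a homogeneous state (`k1 = 3`)
and frozen salt-and-pepper bistability (`k1 = 4`). Two-cell simulations from
(±0.1, 0) isolate the role of diffusion: at `k1 = 2.3` isolated cells rest
at stable states, but coupling at close range repeatedly excites them onto a
new limit cycle on which *u* and *v* dwell near the in-phase stable states —
the diffusion-driven excitability that the mouse presomitic mesoderm shows
in vitro. Increasing the inter-cell distance weakens the coupling and
arrests the oscillation without any parameter change; removing the
self-enhancement of *v* (`k2 = 0`, Notch inhibition) enlarges the
stable-to-unstable distance and arrests oscillation even at high density.
The density probes default to spacing 1.5, comfortably inside the window
where the `k2 = 1` control sustains (up to ≈2.5) while the `k2 = 0` system
arrests (above ≈1.1); a calibration of these distances to physical µm is
not attempted here.

## Numerical scheme

Explicit forward Euler in time and a first-order 5-point discrete Laplacian
in space, `dx = dy = 1`, `dt = 0.01` by default (stability bound
`dt < dx²/(4D) = 0.83` for `D = 0.3`; the bound is enforced). Zero-flux
boundaries are mirror ghost cells (a missing neighbour contributes no flux);
periodic boundaries treat opposite edges as direct neighbours; masked cells
freeze and act as internal zero-flux walls. Halving `dt` changes the final
phase of the oscillatory two-cell runs by <1%; in the excitable regime the
final-phase error instead converges at the expected first order (error ratio
≈2 per halving), because period error accumulates over the run. The hot
loops are numba-compiled; the plain-numpy `euler_step`/`discrete_laplacian`
define the reference arithmetic and the kernel is pinned to them by a parity
test at 1e-13.

## The growing tail and the model presets

The tail is a rectangular lattice (default 10 cells wide, 70 columns at
start) whose x axis is the anterior-posterior axis, column 0 anterior-most.
Every `growth_period = 2.0` time units one column is appended at the
posterior tip, inheriting the tip's (u, v). Two sigmoidal profiles,
re-evaluated on the enlarged domain so they travel with the tip, modulate
the kinetics per column:

* **R** (regionalisation) shifts `k1` step-wise with steepness `a = 1`;
  midpoints sit exactly on the zone boundaries (posterior oscillatory zone
  25 columns from the tip, middle zone 40 more).
* **FG** (frequency gradient) shifts `k3` and `k4` together with `a = 0.1`,
  spanning the whole PSM.

| preset | k1 profile | FG | D | notes |
|---|---|---|---|---|
| CW  | 1 → 4 at the front (Δk1 = 3, a = 1) | — | 0.3 | clock + determination front |
| CG  | as CW | Δk3,4 = 2, a = 0.1 | 0.3 | frequency gradient makes phase waves |
| PORD | k1 ≡ 0 | Δk3,4 = 0.3, a = 0.1 | 1.0 | lateral-inhibition relay; starts from an anterior pre-patterned somite (one column at u = 1) |
| CWS | 1.0 / 2.3 / 4.0 two-step (Δpost = 1.3, Δant = 1.7) | 0 | 0.3 | excitable middle region; phase waves without any gradient |
| CWS_graded | middle plateau replaced by a linear 1.0→4.0 ramp | 0 | 0.3 | waves thin travelling anteriorly |

Zone lengths (25/40) were chosen once so that at least two simultaneous
waves fit in the middle region; the tail geometry is otherwise qualitative.

**Noise protocol.** At every growth event each cell's u and v are scaled by
`1 + δ·μ` (μ standard normal, δ = 5%) and the complete k1 and k3/k4 profiles
by `1 + δk·μj` per column (δk = 0.5%, k3 and k4 sharing draws; PORD's k1 = 0
is unaffected). Because the whole profile is perturbed each event, columns
of equal age accumulate identical expected noise. Runs without growth apply
no noise.

Under this noise the CWS tail keeps a laterally coherent periodic anterior
pattern, while PORD's fine (1–2 cell) somite stripes shatter into
salt-and-pepper: its formed region develops strong period-2 alternation
transverse to the axis (index 0.4–0.6 vs ≈0 noise-free). That transverse
alternation is the salt-and-pepper statistic used in the tests; the plain
chessboard index (4-neighbour anti-correlation) targets true 2D
checkerboards as in the `k1 = 0` square-domain regime.

## Virtual explants

An explant projects a stretch of the tail radially onto a disc (radius 50
cells, square lattice with circular mask, zero-flux): the posterior end of
the source region maps to the centre, the anterior end to the rim, and the
lateral dimension is averaged out. The regionalisation (k1) is always
projected — zone identity travels with the cells — while the frequency
gradient (`inherit_FG`) and the phase values (`inherit_phase`, otherwise a
single uniform (0.1, 0)) are optional guiding cues. A whole-posterior
dissection stops three columns short of the determination-front rise, so the
explanted tissue is PSM only. Mixing permutes (u, v) *and* the per-cell
kinetic parameters among unmasked cells (centrifuged cells carry their
identity); ablation masks a central disc, whose edge behaves as a zero-flux
wall.

Outcomes are classified on the disc interior (3-cell rim margin) over the
last quarter of the run: static patterns split into chessboard vs frozen by
an orientation-free opposite-sign neighbour fraction (>0.4); oscillatory
patterns split into homogeneous oscillation (relative spatial SD < 0.1),
circular waves (variance carried by the radial profile, resolved with 1-cell
annuli) and rotating waves otherwise. Spiral cores are counted as phase
singularities of atan2(v, u) (plaquette winding numbers): mixed discs carry
tens of cores, target-wave discs at most a few, homogeneous discs none. The
signed ring-drift statistic (`angular_wave_flux`) is also reported but
cancels when spirals of both chiralities coexist.

## Pattern classification on square domains

A decision tree over statistics from the last quarter of the run, all
normalised by the mean |u| scale; thresholds live in
`metrics.DEFAULT_THRESHOLDS` and were calibrated once on noise-free control
runs of the five regimes: temporal SD 0.10 separates oscillatory from
static; static fields split on chessboard index 0.5 then spatial SD 0.10;
oscillatory fields split on spatial SD 0.10 and then on the in-phase dwell
fraction P(u·v > 0) = 0.60, which separates excitable waves (cells dwell
near the in-phase stable states; ≈0.78 measured) from rotation about the
origin (≈0.49). Runs near a boundary carry a low-confidence flag.

The five-regime classification runs use 600 time units: the `k1 = 3`
bistable fronts need ≈500 to finish coarsening on 100×100, and roughly one
random initialisation in five leaves a flat domain wall pinned forever — a
real property of discrete bistable media, which is why the robustness check
asks for 4 of 5 seeds rather than all.

Wave detection in kymographs uses the time-shifted spatial cross-correlation
with sub-cell (parabolic) lag refinement; a stripe drift above 0.3 cells per
snapshot row with peak correlation above 0.2 counts as a travelling wave,
and ties resolve toward zero lag so synchronised oscillations are not
mistaken for waves. The snapshot cadence (1.0 time unit) keeps the
per-row drift of every preset below half a stripe wavelength.

## Known limitations

* Somite size in this configuration is pinned by the intrinsic wavelength of
  the excitable middle region (~7 cells): changing the growth period (1–4)
  or the clock strength (k3 = k4 down to 0.6) leaves the frozen stripe
  period nearly unchanged, so no proportionality between growth speed and
  somite length emerges at these settings.
* Physical-unit calibration (µm, hours, µm²/s) is deliberately out of scope;
  all distances, times and rates are model units.
* PORD's phase waves are transient and region-dependent; the wave detector
  applied to the end of a long run may miss them even though they are
  visible mid-run in the kymograph.
* The three-variable Wnt–Notch extension, cell movement, hexagonal lattices
  and analysis of experimental reporter movies are not implemented.
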