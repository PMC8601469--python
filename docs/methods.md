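# Methods

## Model

The medium is an `N x N` square lattice. A fraction `phi1` of the sites is
occupied by cells; among the occupied sites a fraction `phi2` carries the
*reactive* (non-amplifying) phenotype and the rest are *proactive*
(amplifying). Every site — occupied or not — carries the extracellular
messenger concentration `u` (cAMP), which diffuses across the whole grid;
occupied sites additionally carry a receptor/recovery variable `v` and a
colored-noise value `eta`.

Proactive cells obey Barkley-type excitable kinetics

    du/dt = (1/eps) * u (1 - u)(u - u_th) + D_u lap(u)
    dv/dt = u - v + eta
    u_th  = (v + b) / a

and reactive cells replace the cubic by the linear, non-amplifying term

    du/dt = (u - u_th) + D_u lap(u)

with the same recovery equation. The missing `1/eps` factor makes reactive
responses slow: they relay and deform incoming waves rather than regenerate
them. Empty sites only diffuse `u` (an optional linear degradation rate is
exposed and defaults to 0 — the messenger is transported, not destroyed,
between cells).

`eta` is an Ornstein–Uhlenbeck process, `deta/dt = -lam eta +
sqrt(2 D lam) xi(t)`, with stationary law N(0, D) and correlation time
`1/lam`. Noise enters only the recovery equation, independently per occupied
site (a shared-noise mode exists for sensitivity analysis but is off by
default).

### Boundary layer and the reactive clamp

For proactive cells, values `u < delta` (`delta = 1e-4`) are treated as "at
rest": the cubic reaction is skipped and the site's dynamics reduces to
diffusion plus exponential decay of `v` — the standard fast–slow
simplification.

Reactive cells keep their linear reaction active at all `u`, but its output
is clamped to the physical concentration range `[0, max(u, 1)]`. Both ends
matter structurally:

- *floor at 0*: the linear kinetics has its equilibrium at
  `u = b/(a-1) < 0`, so unclamped resting reactive cells would drain the
  whole medium to a negative messenger level. Pinned at the floor, a
  resting reactive cell is inert — until noise pushes its threshold
  `u_th = (v + b)/a` negative, at which point it fires spontaneously from
  `u = 0`. These noise-gated reactive pacemakers are what re-seed activity
  after a synchronous global excursion and what lets reactive admixtures
  nucleate wave sources of their own.
- *cap at the excited plateau* `u = 1` (where the cubic's growth also
  stops): the linear (u, v) system has a trace-zero Jacobian — a neutrally
  stable center — so in a dense, wave-driven medium the oscillation is
  resonantly pumped to arbitrary amplitude unless secretion saturates.
  The cap only limits the reaction's growth; decay and diffusion are
  unrestricted.

## Numerical scheme

- **Proactive reaction** (`u >= delta`): the Barkley semi-implicit update.
  With `alpha = (dt/eps)(u - u_th)` frozen over the step, the decaying
  branch uses `u' = u / (1 - alpha(1-u))` and the growing branch
  `1 - u' = (1-u) / (1 + alpha u)`. Both maps are contractions onto
  `[0, 1]` for any `dt/eps`, which preserves the character of the fast
  jumps without resolving them.
- **Reactive reaction**: explicit Euler — the linear term is mild (rate ~1)
  at the stable time step.
- **Diffusion**: explicit 5-point stencil, evaluated on the pre-step field
  and added to the reaction update. No-flux boundaries mirror the edge
  value; periodic boundaries wrap. Stability `D_u dt / h^2 <= 1/4` is
  enforced at parameter construction.
- **Noise**: the exact OU transition
  `eta' = eta e^{-lam dt} + sqrt(D (1 - e^{-2 lam dt})) z`, so the discrete
  process has the continuous process's stationary law at any `dt`.
- **Guards**: any non-finite field value aborts with the iteration and site
  in the message; an optional ceiling `u_cap` (off by default) aborts
  rather than clips, because bounded `u` is a model prediction we verify,
  not a constraint we enforce.

One "iteration" in all recorded series is one integration step `dt`.

## Statistics

Per iteration, over all `N^2` sites (empty sites included, matching the
`1/N^2` normalisation of the definitions):

- `ubar(t)`: spatial mean of `u`.
- `sigma(t)`: population standard deviation of `u`.
- `Cov(t)`: mean centered product with the 4 von Neumann neighbors,
  `N^-2 sum_ij (1/4) sum_b (u_ij - ubar)(u_b - ubar)`; edge neighbors follow
  the simulator's boundary convention (this changes Cov at O(1/N), so the
  conventions are kept identical).
- Synchrony index `S = < Cov/sigma^2 >_t`, averaged over iterations after
  the growth transient (default: after the first 300), excluding samples
  with `sigma^2 <= 1e-12`; a window with no valid sample raises an explicit
  "undefined synchrony" error. `S = 1` for a perfectly synchronized field;
  a +-1 checkerboard gives `S = -1`.
- Growth line: OLS fit of `log sigma(t)` over the first 300 iterations
  (natural log; the base rescales slope and intercept jointly and cancels
  in `T`). Plateau: mean of `log sigma` over the last 3000 iterations.
  Crossover `T = (plateau - intercept)/slope` — where the early exponential
  fit meets the late saturation level.
- Kymograph: `sqrt(max(u, 0))` along one row (default the middle row) of
  the snapshots in the last 2000 iterations.

## Pattern classification (advisory)

The reference analysis classifies snapshots by eye; this package ships a
transparent topological stand-in, not a learned classifier. A local phase
`theta = atan2(v - v_ref, u - u_ref)` is computed per site with the
reference point `(0.3, 0.05)` inside the excursion loop of the (u, v)
plane, after a light Gaussian smoothing (sigma = 2 sites) that prevents
single-site occupancy noise from registering as singularities. Spiral tips
are plaquettes whose wrapped phase differences wind by +-2 pi. The label
rule: `NONE` when the late-sigma plateau is below an activity floor
(1e-3); otherwise `SPIRAL` when at least 50% of window snapshots contain a
tip, `CIRCULAR` when fewer than 10% do, `NOISY` in between. All thresholds
are configurable, and the label is advisory: it feeds the survey table and
qualitative checks, never a hard gate.

## Calibration of the default parameters

The exact kinetic constants behind the reference simulations are not
available, so the defaults were fixed once by calibrating the model to the
reference circular-wave regime and its summary statistics, then frozen:

- `delta = 1e-4` is stated explicitly and is not a calibration choice.
- `a = 0.75, b = 0.04, eps = 0.02`: a standard excitable (non-oscillatory)
  Barkley corner; `b` was lowered from the more common 0.06 so that
  noise-driven firing persists in amplifier-poor mixtures, which the
  reference synchrony table requires (S remains defined up to `phi2 = 0.5`).
  With these values a pure population propagates waves for occupancies of
  0.4 and up and fails below — the reference density threshold.
- `dt = 0.01, h = 0.55, D_u = 1`: the diffusion length per cell diameter
  sets wave fronts several sites wide, which places S in the reference
  0.93–0.95 band — sharper fronts (larger `h`) push S well below it,
  smoother ones (smaller `h`) push it above.
- `D = 0.005, lam = 0.3`: the noise is slow and weak. Recovery-variable
  fluctuations (std `sqrt(D/(1+lam))` ~ 0.06) occasionally push a cell's
  threshold below the residual messenger level, renucleating waves in the
  pure medium ("appearing and disappearing" target waves) and sustaining
  local flicker in mixtures too dilute in amplifiers to propagate. The
  noise-cutoff alternatives `lam = 1/eps` and `lam = eps` are available as
  presets (`ModelParams.fast_noise` / `ModelParams.slow_noise`); the fast
  preset leaves half-reactive media dead.
- `f_fire = 0.01, u_fire = 1.0`: initial excitation — 1% of occupied cells
  start on the excited branch. No reference value exists for this density;
  it mainly sets the growth-line intercept.

One known residual of this calibration: the time-averaged mean field of the
noise-sustained mixtures sits somewhat above the band the pure circular-wave
regime occupies; activity high enough to keep amplifier-poor media alive
also inflates `ubar` in the propagating media. The acceptance suite states
the band check at its stated tolerance rather than hiding the tension.

Run lengths for reproduction protocols: `N = 200`, 6000 iterations - half
the 400-pixel reference linear size, chosen as the package's reproduction scale so a
full survey completes in minutes on one core; all reported statistics are
bulk quantities and are stable between 120 <= N <= 200 to within their
seed-to-seed spread, except for a small upward shift of S with N (~+0.01
from 120 to 200) that the calibration absorbs at N = 200.

## What the generator emulates — and what it does not

The synthetic lattices emulate a starving population scattered uniformly at
random: no spatial clustering, no chemotaxis, no cell movement, no birth or
death. Real aggregation fields violate all four (cells stream toward
centers and densify). Passing reproduction tests therefore shows that the
*signaling* layer — excitable relay, colored noise, mixed phenotypes —
reproduces the reference statistics on static geometry; it says nothing
about motile reorganisation, which the model deliberately excludes.

## Numerical choices and degenerate inputs

- Ties/rounding: occupancy counts use `round(phi1 N^2)` and
  `round(phi2 n_occ)` exactly; sampling is without replacement, so counts
  are deterministic and only placement is random.
- A dead medium (all `sigma^2` at the floor) raises rather than returning
  `S = 0`; survey cells catch per-cell failures and tabulate the reason.
- `sigma = 0` anywhere in the head window makes the growth fit undefined;
  the error suggests seeding more firing cells.
- Negative round-off in `u` is clipped to 0 only in the kymograph's square
  root, never in the dynamics.
- Seeds: `simulate` derives independent initial-condition and noise streams
  from one seed via `SeedSequence.spawn`, so runs are bit-reproducible.

## Known limitations

- The pattern labels are heuristic; near regime boundaries (e.g. a pure
  medium at occupancy 0.4) they disagree with visual judgment more often
  than inside regimes, and the visual category boundaries themselves
  are explicitly informal.
- The synchrony index is nearly blind to the circular/spiral distinction —
  a limitation of the index itself — so S-based checks constrain the
  calibration only weakly, and the qualitative pattern checks are advisory.
- Explicit diffusion limits `dt`; no adaptive stepping is provided.
- 2-D square lattices only; no chemotaxis or cell motion.
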