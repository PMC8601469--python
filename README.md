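# dictywaves

Stochastic excitable-medium simulation of cAMP signaling in mixed
populations of *Dictyostelium discoideum*-like cells.

When starving *Dictyostelium* amoebae aggregate, they relay pulses of cyclic
AMP through the colony, producing expanding circular (target) waves and
self-sustaining spiral waves. `dictywaves` asks what happens when the
population is *not* uniformly cooperative: a fraction of the cells are
"reactive" — they sense and pass on the signal but do not amplify it. The
package simulates that mixed population on a lattice and computes the
statistics used to quantify the emerging patterns.

## Model

Cells occupy a random fraction `phi1` of an `N x N` grid; a fraction `phi2`
of them is reactive. Each occupied site carries the local messenger level
`u` (extracellular cAMP, which also diffuses across empty sites) and a
receptor/recovery variable `v`, with colored noise on the recovery dynamics:

    proactive:  du/dt = eps^-1 u (1 - u)(u - u_th) + D_u lap(u)
    reactive:   du/dt = (u - u_th) + D_u lap(u)
    both:       dv/dt = u - v + eta,     u_th = (v + b)/a
    noise:      deta/dt = -lam eta + sqrt(2 D lam) xi(t)     (OU process)

Proactive cells have fast cubic (Barkley-type) kinetics — they regenerate
the pulse. Reactive cells respond linearly and slowly. Integration uses the
Barkley fast–slow semi-implicit scheme with a boundary layer `delta = 1e-4`
below which a site is at rest. Summary statistics per iteration: the mean
field `ubar(t)`, the spatial deviation `sigma(t)` (whose log shows an
exponential-growth phase, a plateau, and a crossover time `T` between them),
the von Neumann neighbor covariance `Cov(t)`, and the synchrony index

    S = < Cov(t) / sigma^2(t) >_t        (S = 1: perfect synchrony)

plus kymographs and a topological spiral-tip counter that labels each run
CIRCULAR / SPIRAL / NOISY / NONE.

## Worked example

```python
import dictywaves as dw

lattice = dw.generate_lattice(N=120, phi1=0.5, phi2=0.1, seed=1)
traj = dw.simulate(lattice, dw.ModelParams(), n_iter=4000, seed=1)
print(dw.summarize(traj, n_tail=2000))
```

Running `python examples/01_single_run.py` (this exact computation) prints:

```
occupied cells        : 7200 (720 reactive)
synchrony index S     : 0.939   (1 = perfectly synchronized)
mean cAMP level ubar  : 0.134   (time average, oscillatory phase)
log-sigma growth slope: 0.0070 per iteration
crossover time T      : 217 iterations
```

Half the grid is occupied, every tenth cell is non-amplifying. The medium
ignites from 1% initially firing cells, `sigma` grows exponentially for the
first ~200 iterations (slope 0.0070) and then saturates — waves now span
the system — and neighboring sites co-vary at S = 0.939, the narrow band
(~0.93–0.95) characteristic of coherent wave states in this model. The
other scripts in `examples/` sweep the reactive fraction, classify patterns
and draw kymographs, and run a (phi1, phi2) survey.

A thin CLI wraps the same library calls:

```
dictywaves simulate --config run.yaml --out traj.h5 --seed 1
dictywaves analyze  --traj traj.h5 --out summary.csv
dictywaves classify --traj traj.h5 --out report.json
dictywaves survey   --config run.yaml --out table.csv
```

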