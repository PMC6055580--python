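# daphnia-ifd

An optimizing individual-based model (IBM) of the vertical distribution of
*Daphnia* in a laboratory water column with overlapping gradients of algal
food and visual-predation risk, together with the parameter-estimation
fits and distribution statistics that surround it.

## The problem

Planktonic animals choose a depth by trading off food intake against the
risk of being seen and eaten by fish. The interference ideal free
distribution (IFD) with costs predicts that, at equilibrium, no individual
can improve its fitness by relocating — where fitness is the
Werner–Gilliam ratio of somatic growth rate to per-capita mortality,

    W(s) = GR(s) / mu(s),

evaluated at each sector *s* of a discrete 10-sector, 1-m column. Growth
saturates in food (Monod form), declines linearly with conspecific density
(interference) and with log light (more steeply for adults), and carries a
flat cost under predator chemical cues:

    GR = g0 + a1*F/(a2 + F) - b*D - (c + u*[adult])*log10(1 + I) - kappa*[kairomone]

Mortality is a constant background rate 1/L (longevity L = 50 d) plus
predation derived from the fish's visual reaction distance RD (which grows
with light, prey size, and the green/blue vs. red spectral bands), a
cylindrical search volume pi·RD²·v, and a threshold disc equation:

    C(N) = a*max(N - gamma, 0)^n / (1 + a*h*max(N - gamma, 0)^n),   mu_fish = P * C(N)/N

With gamma = 0 and n = 1 this is Holling's type II disc equation; a
foraging-initiation threshold gamma > 0 gives a type III response with a
low-density prey refuge (fitted juvenile threshold 3.4158 ind/L; the adult
value 0.0342 is that fit reduced by two orders of magnitude).

Virtual animals are updated asynchronously in random order; each compares
the *perceived* fitness of staying vs. moving one sector up or down
(relative food/light differences below the detection thresholds
ae_F = 0.19 (juvenile) / 0.08 (adult) and ae_I = 0.10 are invisible), moves
to the strict maximizer, and ties are broken uniformly at random.

## Layout

- `src/daphnia_ifd/` — the library: `column` (geometry, gradients,
  treatment presets), `rates` (vital rates), `ibm` (the simulator),
  `estimation` (fits), `analysis` (ANCOVA batteries), `generate`
  (synthetic data), `config`/`pipeline`/`cli` (orchestration).
- `analysis/01…04_*.py` — numbered drivers: generate trial data, fit
  parameters, simulate the treatment grid, compare distributions.
- `tests/` — pytest suite, including end-to-end behavioral checks.

## Worked example

```
$ python analysis/01_generate_trial_data.py --seed 1
$ python analysis/02_fit_parameters.py
functional response: selected type III (F=351.3, p=1.52e-19)
  juvenile threshold 3.0639 ind/L -> adult 0.0306 ind/L
reaction distance: red-vs-green p=4.24e-21, blue-vs-green p=0.64
perception cost: 8.9% slowdown (CI 6.2-11.6); SD gradient 0.0156 vs homogeneous 0.0148
```

The extra-sum-of-squares F-test rejects the nested type II model on the
synthetic feeding sessions (the planted threshold is recovered near its
true 3.4158 ind/L); the reaction distance is shorter in red than in green
light but indistinguishable between blue and green; and animals in a food
gradient grow ~9% slower and more variably than in the same food mixed
evenly — the cost of imperfect depth assessment.

```
$ python analysis/03_simulate_distributions.py --seed 1
$ python analysis/04_compare_distributions.py
...
4 of 28 comparisons significant at the Bonferroni-adjusted levels
```

Simulated mean depths sit near 0.5 m with no gradients, near the surface
in a food gradient (deeper at higher density), deepest under predation
risk alone, and in between when both gradients overlap; adults sit deeper
than juveniles. Pseudo-experiments generated under the type III response
are statistically indistinguishable from the type III simulations while
differing from type II in several cells.

A `daphnia-ifd` console command exposes the same steps
(`generate`, `fit-fr`, `fit-growth`, `fit-rd`, `simulate`, `analyze`,
`pipeline`).

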