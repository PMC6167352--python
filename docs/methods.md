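# Methods

## Model and integration

The model couples a non-dimensional vegetation cover `v ∈ ~[−1, 1]` to a
rainfall index `R = a + bP + cF + dv + N`. Vegetation relaxes towards
`tanh(R)` on the timescale `τ_v`; the red-noise term `N` is an
Ornstein–Uhlenbeck-like process representing interannual soil-moisture
variability. The discrete scheme is the explicit forward map

    v_{k+1} = v_k + (Δt/τ_v)[tanh(a + bP_k + cF_k + dv_k + N_k) − v_k]
    N_{k+1} = N_k − N_k·Δt/τ_N + √Δt·σ·W_k/τ_N

with `Δt = 1 yr` and `W_k ~ N(0,1)`. The scheme itself is part of the
method: `N` is exactly an AR(1) process with lag-1 coefficient
`1 − Δt/τ_N` and stationary s.d. `√(σ²Δt/τ_N² / (1 − (1 − Δt/τ_N)²))`, and
the tests check the simulator against that closed form. A configuration
error is raised when `Δt > min(τ_v, τ_N)` (explicit-scheme stability); since
`|tanh| < 1`, the noiseless drift can never carry `v` outside `[−1, 1]`.

Noise placement is literal: `W_k` is drawn once per step and enters `N`
only, never `v` directly. The rainfall is additive in the CO₂ radiative
forcing `F = 5.35·ln(CO₂/278)` W m⁻² (278 ppm preindustrial), which maps a
doubling to +3.71 W m⁻².

### Parameters

| parameter | meaning | units | default sampling range |
|---|---|---|---|
| `a` | background-rainfall offset | – | [−2.0, 0.5] |
| `b` | precession coefficient | – | [−40, 0] |
| `c` | radiative-forcing coefficient | (W m⁻²)⁻¹ | [0, 1.0] |
| `d` | vegetation–rainfall feedback | – | [0.5, 1.5] |
| `τ_v` | vegetation timescale | yr | [5, 100] |
| `τ_N` | soil-moisture timescale | yr | [1, 20] |
| `σ` | noise scaling | – | [0.1, 2.0] |

The ranges are engineering defaults (overridable from YAML), chosen so that
precession minima and high CO₂ favour the green state (`b < 0`, `c > 0`),
the background rainfall is generally below zero but at times approaches it
(`a` mostly negative), and the feedback range brackets the 0.8–1.2 band of
earlier idealised models. They are deliberately broad: screening, not the
prior, is meant to carry the information.

### Initial conditions and spin-up

Runs start at the noiseless equilibrium for the first forcing value (found
by root-finding on `v = tanh(r + dv)`), `N₀ = 0`, followed by a 1,000-year
spin-up at constant first forcing whose output is discarded. This removes
transients of order `τ_v` without biasing the subsequent statistics. A run
can be continued from a stored `(v, N)` state on the *same* random-number
stream, which is how the Holocene extension avoids re-randomising member
noise; tests verify that a split-and-continue run is bitwise identical to a
single long run.

## Equilibrium potential and threshold times

The noiseless system has potential `U(v) = v²/2 − ln(cosh(r + dv))/d` with
`r = a + bP + cF`. `U` is exactly antisymmetric under `(v, r) → (−v, −r)`
because cosh is even, so the global minimiser always carries the sign of
`r`, and the threshold time — the global minimum changing side of `v = 0` —
is exactly a sign change of `r(t)`. The implementation exploits this: the
`r < 0` branch of `min_potential_state` is computed as the mirror image of
the `r > 0` branch, making the antisymmetry hold to the last bit. `sgn(0)`
is treated as positive (a documented convention; exact zeros of `r` are
vanishingly rare on floating-point forcing). `ln cosh` is computed as
`|x| + log1p(e^{−2|x|}) − ln 2` to avoid overflow.

The test-suite oracle for this equivalence minimises `U` by brute force on a
`10⁻³` v-grid at every timestep. The grid is symmetric about zero with the
zero point excluded: `U(v) − U(−v)` has the sign of `−r` exactly, so on such
a grid the argmin's side is unambiguous at the oracle's own resolution and
agreement with the sign rule can be demanded exactly.

### Collapse selection and binning

When `r(t)` wiggles across zero several times, a member's Holocene collapse
is dated to the first collapse-direction crossing after its most recent
onset (first crossing in the window if no onset occurs there); a member
with no such crossing has no collapse date. This per-member-single-date
convention mirrors the first-non-humid rule used to date proxy records;
counting every crossing instead is available via `selection="all"`.

Sensitivity bins are centuries labelled by their older edge and left-closed
there: `t*` belongs to bin `b` when `b ≥ t* > b − 100`. The 3-point running
mean averages over available neighbours at the edges (2 points), keeping
the series length.

## Screening

Members are run over 230–20 ka and retained ("not implausible") exactly
when the number of detected green episodes equals the observed count (six).
Exact equality, not ≥, is used: the observation is a count, and overshooting
it contradicts the record as much as undershooting. Green episodes are
detected on the simulated vegetation: boxcar-smooth `v` over 1,000 yr, mark
smoothed `v > 0`, merge green intervals separated by gaps under 2,000 yr,
drop events shorter than 2,000 yr. The three knobs treat humid episodes as
millennial features (sapropel-like) and suppress noise flicker; all are
exposed as configuration. Timing of the episodes is deliberately *not*
matched — only their number — since pre-Holocene dating errors are of order
millennia.

Member seeds are `base_seed + member_id`, one independent generator per
member, so screening is reproducible and order-invariant and the Holocene
extension continues each member's stream.

## Synthetic study conditions

The synthetic forcing uses two precession quasi-periods (23.7 and 22.4 kyr,
amplitudes 0.032 and 0.028) under a 100-kyr modulation of depth 0.5 peaking
at 11 ka BP, phased so both terms reach their minimum (wettest North
Africa) near 11 ka BP; CO₂ is a 100-kyr asymmetric sawtooth from 190 to
280 ppm whose deglacial rise spans 20–10 ka BP. This preserves what matters
for the method — discrete precession-paced humid windows, gated by
glacial–interglacial CO₂, with a deglaciation and a mid-Holocene drying —
without computing an orbital solution. It does not emulate the real beat
structure of the full precession series, millennial-scale climate events,
or proxy taphonomy; passing tests therefore demonstrate the machinery and
its internal consistency, not agreement with the real AHP chronology, whose
regeneration requires user-supplied orbital and ice-core tables.

The truth study tunes the offset `a` of a reference member
(`b=−12, c=0.35, d=1, τ_v=20, τ_N=5, σ=0.6`) by coarse scan plus bisection
on its (stepwise, not strictly monotone) green-episode count until the
screening window shows exactly six episodes; with the default geometry this
lands at `a ≈ 0.20` and a final threshold time of 4.3 ka BP. The proxy
trace is truth `v` sampled every 100 yr plus Gaussian noise (default s.d.
0.2, comparable to half the signal s.d. — the regime in which
correlation-based member recovery is still expected to succeed). The state
table classifies 1,000-yr-smoothed truth `v` at 500-yr bins as wet (> 0.3),
dry (< −0.3) or moderate.

On this geometry the present-day precession maximum drives the background
rainfall negative for every parameter vector capable of six episodes, so no
plausible member stays green to 0 ka and the never-leaves-green subset is
empty; the invariance of SS under dropping that subset is therefore
exercised both on the pipeline (where it holds trivially) and on an
engineered always-green member in the unit tests (where it does not).

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at 2,000 members
on annual-resolution 230-kyr forcing (the screening stage is a few
milliseconds per member via a compiled inner loop, with a pure-Python
fallback when numba is unavailable) and use 100-yr-resolution forcing for
threshold-time work, where the sign rule is resolution-independent down to
the crossings themselves (a consistency test compares event counts across
resolutions). Root finding uses Brent's method at `xtol = 10⁻¹⁴`;
interpolation of forcing tables is linear with no extrapolation, and time
units of input tables must be declared (`time_ka` vs `time_yrBP` header),
never guessed.

## Limitations

The model is a single scalar vegetation box: no spatial structure, no
separate regional sensitivities, no groundwater or dust feedbacks. The
plausibility filter conditions only on an event count, so the retained set
is a "not implausible" ensemble, not a posterior. Proxy-state tables are
consumed as already-classified wet/moderate/dry calls; the subjective
classification upstream is outside the package, as is computing transition
rates from escape theory (the analysis uses the noiseless potential
throughout).
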