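# Methods

## Model

The model tracks free PPDK subunit pools `x0, x1, x2` (states PPDK0, PPDK1,
PPDK2), the RP complexes `B1 = [PPDK1·RP]`, `B2 = [PPDK2·RP]`,
`T = [PPDK1·RP·PPDK2]`, and PPi, under mass-action kinetics:

* catalytic cycle — auto-phosphorylation `x0 → x1` at flux
  `F1 = delta1·satATP·x0` (producing PPi) and phospho-transfer `x1 → x0` at
  `F2 = V1·satPyr·x1` (producing PEP), with Michaelis saturation factors
  `satATP = atp/(Km_atp+atp)`, `satPyr = pyr/(Km_pyr+pyr)`;
* binding — RP binds a free PPDK1 (rate `kon1·x1·RPfree`, off `koff1`) or
  PPDK2 (`kon4`, `koff4`); a bound RP captures an adjacent second subunit at
  the fast intramolecular rates `kon2`, `kon3`, with mean-field neighbour
  probabilities `p1 = x2/PPDK_T`, `p2 = x1/PPDK_T`. A ternary event frees
  both subunits;
* catalysis by RP — the ternary complex fires at `Vk = Vk0·adp` (kinase,
  releasing two PPDK2) or `Vp = Vp0/(1+ppi/Ki_PPi)` (phosphatase, releasing
  two PPDK1). Binary complexes catalyse at `eps_binary·Vk` / `eps_binary·Vp`;
* PPi — `d ppi/dt = F1 − alpha·ppi`. The PPi released by the RP phosphatase
  itself is neglected relative to the auto-kinase flux (it is bounded by
  `Vp·RP_T`, two orders below F* at defaults), and AMP inhibition of the RP
  kinase is neglected entirely (its inhibition constant is far above cellular
  AMP). Pi is treated as high and buffered and never appears.

Conservation laws: `x0+x1+x2+B1+B2+2T = PPDK_T` and
`RPfree+B1+B2+T = RP_T` hold exactly along trajectories (tested to 1e-8
relative).

## Steady-state solver

At `eps_binary = 0` the kinase/phosphatase balance `Vk(T+εB1) = Vp(T+εB2)`
factorizes as `(Vk − Vp(ppi))·T = 0`, which splits the solution into explicit
branches, each a one-dimensional bracketed root problem (`scipy` brentq,
xtol 1e-13):

* **robust** — `Vp(ppi) = Vk` fixes `ppi* = Ki_PPi(Vp0/Vk − 1)`, hence
  `F2 = alpha·ppi*`, `x1 = F2/(V1·satPyr)`, `x0 = F2/(delta1·satATP)`; the
  remaining unknown `x2` is the root of PPDK conservation (monotone in `x2`).
  Exists when the conservation residual at `x2 = 0` is negative, i.e. enough
  enzyme/substrate to supply F*;
* **substrate-limited** — otherwise `x2 = T = B2 = 0` (all PPDK active) and
  `x1` solves conservation; `F2 = V1·satPyr·x1` is then linear in PPDK_T;
* **dark shutdown** — for `Vk ≥ Vp0` the kinase outruns the phosphatase at any
  PPi, so the ideal-avidity steady state is `x0 = x1 = 0`, `F2 = 0` (the
  basal dark rate is exactly zero in this limit; a small positive basal rate
  appears for `eps_binary > 0`).

With `eps_binary > 0` the branch solution seeds a bounded two-dimensional
least-squares solve in `(x1, x2)` of (relative flux balance, relative
conservation), tolerances 1e-15, which converges to ~1e-12 relative — tight
enough that finite-difference sensitivities down to 1e-5 are clean. Given
`(x1, x2)` the complex balance is linear in `(B1, B2, T)` after eliminating
free RP, and is solved directly (`complex_steady_state`).

Regime labels: `substrate_limited` when solved `x2 < 1e-6·PPDK_T`;
`dark_shutdown` when the PPDK2 fraction exceeds 95 % *and* `Vk ≥ 0.9·Vp0`
(the input actually drives the shutdown — a large PPDK2 buffer alone is the
normal robust state); `adp_limited` when the ADP pool is finite (see below)
and `PPDK_T > adp`; otherwise `robust`. Stability is checked from the
numerical Jacobian of the 7-state ODE (all eigenvalue real parts ≤ 0 up to
the conserved-direction zero mode).

### ADP as signal vs. pool

The main analysis treats ADP as a clamped input (`adp_buffered = True`).
Robustness genuinely fails when total PPDK exceeds the ADP supply — there is
then too little ADP to keep the excess PPDK1 phosphorylated — and exposing
this requires ADP consumption: with `adp_buffered = False` the free ADP is
`adp − (Thr-phosphorylated subunits)`, since each PPDK2 holds one
ADP-derived phosphoryl group. In that mode F2 rises linearly with PPDK_T
again once `PPDK_T` approaches the pool size.

## Parameters (normalized units)

Time is measured in 1/koff1 and concentration in units of total RP, so the
printed avid parameter set is directly usable: `kon1 = kon4 = 0.01`
[koff1/RP_T], `kon2 = kon3 = 200` [koff1] (avidity ratio A = 200),
`koff1..4 = 1`, `PPDK_T/RP_T = 100`. Catalytic rates are slow relative to
off-rates, as for most enzymes (physically ~1–10 s⁻¹ against millisecond
unbinding): `Vk(adp=1) = 0.01`, `Vp0 = 0.02` — so the default input sits at
`Vk/Vp0 = 1/2`, mid-range between full activity and shutdown —
`delta1 = 0.015` and `V1 = delta2 = 0.01` (auto-phosphorylation 1.5× faster
than phospho-transfer, the measured ratio, which keeps the subunit pool
cycling between PPDK1/PPDK2 rather than accumulating PPDK0). `alpha = 1`,
`Ki_PPi = 0.05` set the output scale `F0 = alpha·Ki_PPi = 0.05`, well below
the catalytic capacity `V1·PPDK_T ≈ 1` so the robust window is wide; their
physical counterparts (α ≈ 100 s⁻¹, Ki,PPi = 160 µM, 20 µm³ chloroplast)
give the absolute scale `f0_magnitude() ≈ 1.9e8` reactions/s per
chloroplast. Substrates default to 10× their Michaelis constants
(`atp = pyruvate = 10`, `Km = 1`): saturated but not irrelevant, so the
sensitivity tests are meaningful.

`eps_binary` interpolates between the ideal avidity limit (0, default) and
the full mass-action scheme in which binary complexes catalyse at the same
specific rates as ternary ones (1). Robustness is exact at 0 and approximate
at small ε: non-input log-sensitivities grow linearly in ε (slope 0.99 over
ε ∈ [1e-3, 1e-1] at defaults).

## Configuration master equation

Subunits sit on a ring of n = 4 with full dihedral symmetry — the unique
adjacency reproducing 21 three-state classes — and classes are canonicalized
as the lexicographic minimum over the 2n symmetry operations. Events change
one subunit per firing: per-subunit binary flips S1↔S2 at rate μ, ternary
events on each adjacent (S1,S2) pair (S1→S2 at η1, S2→S1 at η2; η ≈ 1
because the long-lived ternary complex almost always reacts before
unbinding), and in the three-state model per-subunit S0→S1 at δ1 and S1→S0
at δ2. μ/η = (Vk/(koff1+Vk) + Vp/(koff4+Vp))/2 is the probability that a
short-lived binary complex reacts before dissociating; the displayed
distributions use Vk = Vp = 0.2·koff, i.e. μ = 1/6. Because single-site
events commute with the symmetry group, the class-level chain is an exact
lumping of the full 3ⁿ chain (verified brute-force at n = 4). The steady
state is the one-dimensional null space of the rate matrix (SVD with an
ergodicity check; μ > 0 is required — without binary events the all-S1 and
all-S2 states are absorbing). The Gillespie simulator is an exact SSA over
classes with time-weighted occupancies and per-kind event tallies, seeded
and bit-reproducible.

The boundary-chain reduction keeps only phase-separated configurations
labelled by their number of modified subunits; binary events act at the two
pure boundaries (rate n·ε), ternary events move the domain wall (rate 2η per
direction). For symmetric rates all interior states share occupancy
(n·ε/2η)·N(0); at n = 4 this reduces to N(0) = N(4) = η/(2(n−1)ε+2η),
N(i) = ε/((n−1)ε+η). The bulk-to-boundary ratio is O(ε/η) for any n, which
is why states with two or more domain walls (checkerboards) are O((ε/η)²)
and rarest.

The random-walk abstraction gives the ternary:binary reaction ratio of an
N-mer as the mean first-passage step count M(1) of a ±1 walk on 1..N−1 with
absorbing boundaries (tridiagonal linear solve; counting the absorbing
step). At p = 1/2, M(1) = N − 1 exactly. The Monte-Carlo estimator restarts
half its cycles from each boundary and reports mean ± standard error.

## Synthetic variability

Cell-to-cell fluctuations are log-normal and multiplicative with the base
value as median (σ² = ln(1+CV²)), the standard model for expression noise;
the paper states no magnitudes, so CV is a free experiment parameter with
default 0.3. Perturbable quantities: ppdk_total, rp_total, atp, pyruvate,
V1 (non-inputs) and adp (the input). Draws landing outside the robust regime
are solved anyway and counted in a regime census, never dropped. All
stochastic operations take explicit integer seeds recorded in outputs; CSV
floats are written with 12 significant digits so determinism audits can
compare bytes.

What the generator does *not* emulate: correlated fluctuations between
quantities, temporal noise within a cell, tissue-level averaging, or real
maize expression distributions — passing tests show the *model's*
input-output robustness under idealized noise, not agreement with plant
measurements.

## Numerical choices and problem sizes

brentq xtol 1e-13; least-squares tolerances 1e-15; steady-state residuals
checked against the full right-hand side at 1e-7·PPDK_T; ODE integration by
LSODA at rtol 1e-10/atol 1e-12 (the adaptation experiment runs to t = 5e4,
≈ 10 relaxation times of the PPDK2 buffer at default rates). Distribution
checks use 1e6 Gillespie events (total-variation ≈ 2e-3 against the
analytic solve) and 1e5 Monte-Carlo walk cycles; ensemble experiments use
200–1000 draws. Degenerate inputs: zero PPDK returns the all-free state;
`adp = 0` makes the robust rate undefined (the kinase is off and PPDK2
empties); μ = 0 raises a reducible-chain error; p ∈ {0,1} raises a
degenerate-walk error.

## Limitations

* The mean-field neighbour probabilities ignore spatial correlations within
  tetramers; the master-equation model captures them but is not fed back
  into the concentration-level solver (two-tier structure by design).
* Binary and ternary complexes are assumed to share specific catalytic rates
  (scaled by `eps_binary` for binaries).
* No RP diffusion, no inter-tetramer coupling, no explicit light→ADP
  mapping, and no fitting to measured maize data: parameters are normalized
  reference values, not estimates.
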