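# ppdkrp

Kinetic models of how C4 plants (maize, sugarcane, sorghum) keep the rate of
phosphoenolpyruvate (PEP) formation — a key step of the C4 carbon-fixation
cycle — precisely set by light while the concentrations of every enzyme and
substrate in the pathway fluctuate from cell to cell.

The enzyme pyruvate orthophosphate dikinase (PPDK) makes PEP in two steps:
auto-phosphorylation (PPDK0 → PPDK1, consuming ATP, releasing PPi and AMP)
and phospho-transfer to pyruvate (PPDK1 → PPDK0, releasing PEP at rate F2,
the system output). A bifunctional Regulatory Protein (RP) inactivates the
active form (PPDK1 → PPDK2, ADP-dependent kinase domain) and reactivates it
(PPDK2 → PPDK1, phosphatase domain, competitively inhibited by PPi). Light
is encoded by ADP: high ADP means darkness.

Two features of this biochemistry combine into a robustness mechanism:

1. **Avidity.** PPDK is a homotetramer and RP has two substrate-binding
   domains, so RP mostly acts from a *ternary complex* [PPDK1·RP·PPDK2]
   spanning two adjacent subunits. Steady state then requires the *specific*
   kinase and phosphatase rates to be equal, `Vk(ADP) = Vp(ADP, PPi)` —
   a condition on rates, not on concentrations.
2. **Product inhibition.** PPi, produced by the PPDK auto-kinase at the same
   flux as PEP formation (F1 = F2) and degraded at rate α, inhibits the RP
   phosphatase: `Vp = Vp0/(1 + PPi/Ki_PPi)`. The feedback loop settles at

   F2 = F\* = α·Ki_PPi·(Vp0/Vk(ADP) − 1),

   which depends only on the ADP input — not on PPDK, RP, ATP, pyruvate or
   the PPDK catalytic rate. The PPDK2 pool buffers excess enzyme.

The package implements this model in full: the mass-action complex balance
and its avidity bound, the feedback steady state with regime classification
(robust / substrate-limited / dark-shutdown / ADP-limited), adaptation
dynamics, log-sensitivity profiles, a master-equation model of subunit-state
configurations on the tetramer ring (bimodal: tetramers are mostly all-PPDK1
or all-PPDK2, checkerboard arrangements are rarest), the boundary-chain
closed forms, and the random-walk result that the ternary:binary reaction
ratio of an N-mer is M(1) = N − 1 at the symmetric point.

## Worked example

Units are normalized: time in 1/koff1, concentration in units of total RP.
The default parameter set (see `src/ppdkrp/data/default.yaml`) has
Vk = 0.01, Vp0 = 0.02, α·Ki_PPi = 0.05, PPDK_T/RP_T = 100, so
F\* = 0.05·(2 − 1) = 0.05.

```python
from ppdkrp import RateParameters, Environment, full_steady_state

params, env = RateParameters(), Environment()
res = full_steady_state(params, env)
print(res.F2, res.F_star, res.regime)   # 0.05 0.05 robust
```

Sweeping total PPDK 100-fold from the shell:

```bash
ppdkrp sweep --var ppdk_total --from 2 --to 200 --points 8 --log --out out/
```

```
 ppdk_total       F2  F_star            regime
   2.000000 0.010845    0.05 substrate_limited
   3.861395 0.020939    0.05 substrate_limited
   7.455187 0.040432    0.05 substrate_limited
  14.393713 0.050000    0.05            robust
  27.789910 0.050000    0.05            robust
  53.653916 0.050000    0.05            robust
 103.589494 0.050000    0.05            robust
 200.000000 0.050000    0.05            robust
```

Below ~10 there is not enough enzyme to supply F\* — all PPDK is active
(PPDK2 = 0) and F2 is linear in the total; above the threshold F2 locks onto
F\* = 0.05 regardless of enzyme level. An ensemble with 30 % cell-to-cell
variation on PPDK, RP, ATP, pyruvate and the catalytic rate leaves the
output unmoved:

```bash
ppdkrp robustness --cv 0.3 --n 300 --seed 7 --out out/
# output CV of F2: 1.49e-16
```

whereas the same variation on the ADP input propagates fully (output CV
≈ 0.6): the system rejects component noise but follows its signal. Other
subcommands: `steady-state`, `dynamics` (step adaptation, Figure-3-style),
`master` (tetramer configuration distribution, optionally with a Gillespie
simulation), `walk` (mean ternary steps per binary event).

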