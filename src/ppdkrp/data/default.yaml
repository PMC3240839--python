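# Default PPDK--RP parameter set, normalized units:
# time in 1/koff1, concentration in total RP.
# Binding follows the avid scheme kon2 = kon3 = 200 [koff1] >> kon1*PPDK_T.
kon1: 0.01
kon2: 200.0
kon3: 200.0
kon4: 0.01
koff1: 1.0
koff2: 1.0
koff3: 1.0
koff4: 1.0
Vk0: 0.01          # RP kinase rate per ADP unit; Vk(adp=1) = 0.01 [koff1]
Vp0: 0.02          # maximal (uninhibited) RP phosphatase rate
Ki_PPi: 0.05       # competitive PPi inhibition constant (physical ref 160 uM)
alpha: 1.0         # PPi degradation rate by pyrophosphatases
delta1: 0.015      # auto-phosphorylation rate scale (ATP-saturating)
delta2: 0.01       # phospho-transfer rate scale; delta1/delta2 = 1.5
V1: 0.01           # specific PEP formation rate (same step as delta2)
Km_atp: 1.0
Km_pyr: 1.0
eps_binary: 0.0    # binary-complex catalysis weight (0 = ideal avidity limit)

# Environment
adp: 1.0           # input signal; Vk/Vp0 = 1/2 here (mid-range light)
atp: 10.0
pi: 10.0
pyruvate: 10.0
ppdk_total: 100.0  # PPDK_T/RP_T = 100
rp_total: 1.0
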