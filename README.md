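# flpswitch

Mass-action modelling and parameter inference for a tyrosine-recombinase
(FlpO/FRT) inversion–excision switch controlling CAR expression in engineered
T cells.

## The problem

Engineered T cells expressing a chimeric antigen receptor (CAR) need ON/OFF
control that persists after the inducing drug is withdrawn. A
tyrosine-recombinase switch achieves this with a gated two-step design: a
reversible DNA **inversion** first creates a parallel pair of FRT sites, and a
quasi-stable **excision** then deletes the gating sequence and locks the
state. The inducer 4-hydroxytamoxifen (4-OHT) licenses nuclear entry of the
FlpO recombinase; leaky nuclear localisation gives basal switching without
drug. `flpswitch` is for modellers who want to simulate this circuit, fit its
rate constants to percent-CAR time courses, and ask which experimental knobs
(drug dose, promoter strength) shorten the switching response.

## Models

**Mechanistic network** (`flpswitch.mechanistic`): four recombination events
(two inversions `i1`, `i2`; two excisions `e1`, `e2`) resolved into cooperative
monomer-binding cascades (free → F1 → {F1,1 | F2,0} → F3 → F4 on the two FRT
sites), a ladder of five Holliday-junction intermediates per event, and
product dissociation; plus FlpO expression (α_a, α_b), 4-OHT-dependent
activation (K_a·V̄·[4OHT]·[Fa]), leaky import (K_b·V̄·[Fb]), degradation (β_p,
β_d) and dilution of the excised loop (δ). Binding cooperativity is imposed
through multipliers 0 < m1, m2 < 1 so that k1/k−1 < k2/k−2. The network has
63 DNA-containing species, 4 protein/drug species and 27 fitted rate
constants; its ODEs are pure mass action (stoichiometry matrix × flux).

**Reduced model** (`flpswitch.reduced`): each recombination event collapsed to
a single reversible reaction, giving nine ODEs — F, 4OHT, Fa, Fb and the five
DNA states D_S1, D_tS1, D_tS2, D_SX, D_S2 — with 12 fitted constants
(k1, k2 forward inversions, k3, k4 forward excisions, one shared reverse rate
k_r, plus the six protein/drug rates and δ). The cytoplasm-to-nucleus volume
quotient V̄ is fixed at 0.3 and the 4-OHT source rate α_d is the dose input,
so neither is fitted.

**Observables** (`flpswitch.observables`): percent CAR expression
(ON: 100·(D_tS1+D_tS2+D_S2)/genomic total; OFF construct: 100·D_S1/total) and
the 90% response time (time for the ON switch to reach 90% of its maximum
percent CAR, or for the OFF switch to achieve 90% of its total decrease).

**Inference**: all four time courses (ON/OFF × 0/1 µM) are fitted at once
with the distance

    d = (1/10) · Σ_{i=1..40} |x_i − y_i|

by a bounded genetic algorithm (`flpswitch.ga`) and by ABC-SMC with a
decreasing ε schedule and uniform [0,1] priors (`flpswitch.abc_smc`).
Post-fit scans (`flpswitch.sensitivity`) cover one-at-a-time parameter
sensitivity of response time, dose–response curves over 10⁻¹–10¹ µM,
FlpO-expression fold changes and the dose × expression trade-off grid.
Because the study's measured time courses are not machine-readable, the
package ships a synthetic ground truth (`flpswitch.synthetic`) with the same
statistical shape, so every stage is testable against known parameters.

## Worked example

```sh
python examples/01_simulate_switch.py
```

prints, for the shipped ground-truth parameters:

```
4-OHT dose 1 uM
  day        :     1      2      3      4      5      6      7      8      9     10
  ON  % CAR  :   1.9   12.7   28.8   45.4   60.5   72.8   81.7   87.3   90.4   91.8
  OFF % CAR  :  98.1   87.3   71.2   54.6   39.5   27.2   18.3   12.7    9.6    8.2
  response time: ON 7.14 d, OFF 7.14 d
```

Under induction the ON switch rises to a ~92% plateau and crosses 90% of that
maximum after 7.14 days; the mirrored OFF construct falls correspondingly. At
0 µM the same parameters give only a slow basal drift (30% by day 10) from
leaky nuclear localisation. The other examples generate noisy datasets and
re-fit them with the GA (`03`), run ABC-SMC and print the acceptance log and
posterior quantiles (`04`), and produce the dose–response curve, fold-change
responses and trade-off grid (`05`) — at the shipped truth, raising the dose
from 0.1 to 10 µM shortens the ON response from 9.2 to 5.5 days, and a
five-fold FlpO-expression increase shortens it to 4.7 days while raising
day-10 basal switching from 30% to 89%.

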