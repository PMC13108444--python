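# phagepass

Deterministic modelling of lytic bacteriophage populations under
serial-passage protocols, with estimators for the life-history traits that
drive their evolution.

## The problem

When a lytic phage such as ΦX174 is repeatedly diluted into fresh host
culture ("serial transfer"), the transfer schedule itself becomes a
selective force. Long co-culture intervals exhaust susceptible hosts early
and leave phage exposed to decay for hours, favouring fast adsorption and
high environmental persistence. Short intervals bottleneck the population
while most cells are already infected, so adsorption late in a transfer
mostly destroys phage on cells that cannot yield progeny — and, counter to
intuition, *slower* adsorption can win. `phagepass` is for experimental
evolutionists and phage ecologists who want to simulate these dynamics,
map the selective consequences of a transfer protocol before running it,
and estimate adsorption and decay rates from titre time courses.

## The model

Uninfected hosts $B$, infected hosts $B_I$ (cells/ml) and free phage of
each genotype $P_i$ (particles/ml) obey delay differential equations with a
fixed latent period $\tau_i$:

$$
\begin{aligned}
\dot B &= -\Big(\textstyle\sum_i \phi_i P_i\Big) B \\
\dot B_I &= \textstyle\sum_i \phi_i \big(B P_i - B_\tau P_{i,\tau}\big) \\
\dot P_i &= \phi_i \big(\beta_i\, B_\tau P_{i,\tau} - (B + B_I) P_i\big) - \delta_i P_i
\end{aligned}
$$

where $X_\tau \equiv X(t - \tau_i)$, $\phi_i$ is the adsorption constant
(ml⁻¹ min⁻¹), $\beta_i$ the burst size and $\delta_i$ the free-phage decay
rate (min⁻¹). Adsorption to an already infected cell removes the particle
without progeny; host growth within a transfer is neglected. Delayed
densities are zero before the start of a fresh culture, so no progeny
appear until one latent period has elapsed.

Two transfer protocols are built in: a chloroform-style reset (fresh hosts,
fixed total inoculum, infected cells discarded) and fractional carryover
(a fixed fraction of the whole co-culture — free phage *and* infected
cells, whose lysis schedule is preserved at diluted density — into fresh
hosts). On top of the integrator sit the in-silico experiments: adsorption
sweeps over 1:1 competitions, multi-genotype frequency trajectories, burst
detection in the settled within-transfer pattern, productive/unproductive
adsorption decomposition, and a transfer-time × dilution fitness landscape.

The estimators implement the standard assay analyses: the adsorption
constant as the negative slope of log titre versus time divided by host
density, and the decay rate from a log-linear fit of the post-peak decline
of a co-culture time course. A synthetic-data module generates both assay
types with Poisson plaque-count noise for pipeline validation.

## Worked example

```python
import numpy as np
from phagepass import ANCESTOR, RegimeConfig, run_regime
from phagepass.experiments import (
    detect_bursts, find_optimal_adsorption, single_transfer_competition,
)

config = RegimeConfig(
    transfer_duration=30.0, n_transfers=6, reset_mode="fractional_carryover",
    carryover_fraction=0.02, fresh_B=1e8, initial_P=(1e7,),
)
result = run_regime(config, [ANCESTOR])
print("end-of-transfer titres (PFU/ml):",
      np.array2string(result.end_titres[:, 0], precision=2))

bursts = detect_bursts(result.trajectories[-1], [ANCESTOR])
for b in bursts:
    print(f"burst at {b.time:5.2f} min, release flux {b.flux:.2e} PFU/ml/min")

sweep = single_transfer_competition()
opt = find_optimal_adsorption(sweep)
print(f"optimal adsorption constant: {opt.phi_opt:.2e} ml^-1 min^-1 "
      f"({opt.fold_reduction:.1f}-fold below ancestor)")
```

prints

```
end-of-transfer titres (PFU/ml): [5.37e+07 1.24e+10 8.16e+09 5.37e+09 4.36e+09 4.44e+09]
burst at  4.16 min, release flux 2.63e+08 PFU/ml/min
burst at 17.00 min, release flux 6.97e+09 PFU/ml/min
burst at 21.43 min, release flux 3.01e+09 PFU/ml/min
optimal adsorption constant: 7.68e-10 ml^-1 min^-1 (5.2-fold below ancestor)
```

The six 30-min transfers with 2% carryover settle into a repeating
within-transfer pattern with three lysis bursts: the carried-over infected
cells burst ~4 min in, phage that adsorbed at the transfer start burst at
the 17-min latent period (the dominant event), and their progeny's
reinfections burst ~21 min in. The competition sweep places the optimal
adsorption constant several-fold below the ancestral 4×10⁻⁹ ml⁻¹ min⁻¹ —
the quantitative form of the slow-adsorber advantage under short transfers.

A command-line interface mirrors the library
(`phagepass regime|sweep|pattern|decompose|landscape|simulate|frequency-course|synth|estimate-adsorption|estimate-decay`,
plus `phagepass run` to execute the scenario named in a YAML config; see
`phagepass write-config` for the default configuration).

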