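# qspreduce

Reduce-and-link toolkit for quantitative systems pharmacology (QSP).

QSP models couple whole-body pharmacokinetics — where a drug goes after a
dose — with cellular reaction networks describing what it does at its
target. Assembled naively, such models carry tens to hundreds of state
variables, which makes them slow to simulate, hard to fit to clinical
data, and difficult to interpret. `qspreduce` implements the alternative:
decompose the model into components, reduce each component with the
method suited to it while preserving its declared input–output behaviour,
and relink the reduced parts.

What's in the box:

* **PBPK model builder** — the 16-compartment whole-body
  physiologically-based pharmacokinetic model (13 tissues, venous and
  arterial blood, oral depot) as a linear state-space system
  `dx/dt = Ax + Bu`, `y = Cx`, fully parameterised for a 70 kg reference
  human and three packaged compounds (pindolol, midazolam, thiopental).
* **Balanced truncation** for stable linear components: Gramians from the
  Lyapunov equations `AP + PAᵀ + BBᵀ = 0`, `AᵀQ + QA + CᵀC = 0`,
  square-root balancing, Hankel singular values σ₁ ≥ … ≥ σₙ, truncation
  with the a-priori error bound 2·Σ_{i>k}σᵢ.
* **Proper lumping** for (possibly nonlinear) components: 0/1 partition
  operators `x̃ = Lx` with generalized-inverse reconstruction, and the
  greedy forward-selection search that merges the best pair of lumps at
  each step.
* **Conservation analysis** for reaction networks: left null space of the
  stoichiometry matrix via pivoted QR, and exact elimination of dependent
  species.
* **Model linkage**: wire outputs of one component to inputs of another
  (feedback allowed) into one monolithic ODE system, and the inverse
  linear/nonlinear decomposition.
* **Fidelity metric**: maximal relative error
  ε = ‖y − ȳ‖∞ / ‖y‖∞ per output channel.

SBML import (core constructs), a JSON model schema, and a `qsp-reduce`
command-line interface round out the tooling. See `docs/methods.md` for
the scientific detail and design decisions.

## Worked example

Reduce the midazolam PBPK model to 3 states by balanced truncation,
keeping the venous blood concentration accurate under a 500 mg oral dose:

```python
import numpy as np
from qspreduce import physiological_fixture, compound_fixture, pbpk_bt_reduction

phys = physiological_fixture()          # 70 kg reference human
mid = compound_fixture("midazolam")
res = pbpk_bt_reduction(phys, mid, k=3, outputs=("venous",), dose_mg=500.0)

print("Hankel singular values (leading 5):",
      np.round(res.detail.hankel_singular_values[:5], 5))
print("a-priori H-inf bound:", round(res.detail.error_bound, 5))
print(res.report)
```

prints

```
Hankel singular values (leading 5): [1.251e-02 1.300e-03 2.600e-04 1.200e-04 1.000e-05]
a-priori H-inf bound: 0.00026
eps = 1.84% (per output: venous: 1.84%)
```

Reading this: the Hankel spectrum collapses by an order of magnitude
after the third value, so three balanced states carry almost all of the
dose-to-venous-concentration behaviour. The reduced model (three balanced
distribution states plus the exact oral depot) reproduces the full
16-state venous concentration–time profile to within 1.84 % of its peak
over 48 h. `res.reduced` is an ordinary model — simulate it, serialize
it, or link it into a larger QSP system:

```python
from qspreduce import DoseRegimen, simulate
traj = simulate(res.reduced, DoseRegimen.single_oral_bolus(500.0))
traj.to_csv("venous_reduced.csv")
```

The same experiment from the shell:

```bash
qsp-reduce pbpk build --compound midazolam --out model.json
qsp-reduce bt model.json --dim 3 --dose oral:500mg@0 --out report.json
```

For nonlinear reaction networks, the pipeline is conservation analysis →
proper lumping → linkage; `scripts/erk_example.py` runs it end-to-end on
the 99-species ERK activation network from BioModels (requires network
access for the download).

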