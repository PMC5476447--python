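# attncov

Attention changes how populations of visual-cortex neurons fire together:
firing rates and stimulus sensitivity go up while trial-to-trial *noise
correlations* go down. `attncov` implements, as a tested Python library
plus a small analysis pipeline, the two computational pieces needed to
study this quantitatively:

1. **A rank-one model of covariance modulation.** If C_U and C_A are the
   spike-count covariance matrices of the same units in the unattended and
   attended states, the model posits per-neuron *covariance gains* g_i with

       C_A(i, j) = g_i · g_j · C_U(i, j)   (i ≠ j),

   i.e. attention modulates neurons, not pairs. The package fits g by
   least squares over the N(N−1)/2 off-diagonal equations, quantifies fit
   quality ρ against a structure-destroying **shuffle null** (ρ_shuf) and a
   finite-trial **upper bound** (ρ_ub, the same sampling noise applied to a
   perfectly decomposable covariance), cross-validates by leaving single
   equations out, and tests whether g_i is intrinsic to neuron i.

2. **An excitatory–inhibitory mean-field circuit.** Two population rates
   with LIF (first-passage-time) transfer functions, recurrent coupling,
   and a shared global noise source. Attention is a static depolarization
   of both populations. Linearizing around the fixed point gives closed
   forms for the population variance V_E, the stimulus-response gain G_E,
   and the linear Fisher information — showing how a single mechanism
   (stronger top-down drive to inhibition) simultaneously raises rates and
   gain, lowers shared variability, and improves an excitatory-only
   readout while leaving total information unchanged.

Since no recordings are distributed, a **synthetic-session generator**
(Gaussian-copula correlated Poisson counts with known rank-one ground
truth) stands in for the data; every estimator is validated against it.

Intended users: computational/systems neuroscientists studying noise
correlations and neuromodulation, and anyone needing a correlated-Poisson
sampler or 2×2 Ornstein–Uhlenbeck closed forms with receipts.

## Worked example

```python
import numpy as np
from attncov.session import make_session
from attncov.covstats import count_covariance
from attncov.rank1 import fit_rank1, shuffled_null, upper_bound

sess = make_session(n_units=30, n_trials=600, seed=100)   # known g_true
C_U = count_covariance(sess.unattended)
C_A = count_covariance(sess.attended)

sol = fit_rank1(C_U, C_A, n_restarts=2, seed=0)
rho_shuf = shuffled_null(C_U, C_A, n_shuffles=20, seed=1)
rho_ub = upper_bound(C_U, C_A, rates_A=sess.attended.mean_counts(),
                     n_trials=sess.attended.n_trials,
                     n_realizations=3, seed=2, solution=sol)

print(f"rho={sol.rho:.3f}  shuffle={np.mean(rho_shuf):.3f}  "
      f"upper bound={np.mean(rho_ub):.3f}")
print(f"gain recovery r={np.corrcoef(sol.g, sess.truth.g_true)[0,1]:.3f}")
```

prints

```
rho=0.887  shuffle=0.343  upper bound=0.917
gain recovery r=0.923
```

Read: the rank-one model explains the attended covariances nearly as well
as is possible at this trial count (ρ = 0.89 against a ceiling of 0.92),
far above what the fit extracts from shuffled matrices (0.34), and the
fitted per-neuron gains track the generative ones (r = 0.92).

On the circuit side:

```python
import numpy as np
from attncov.meanfield import REFERENCE, attention_sweep

df = attention_sweep(REFERENCE, np.linspace(0, 1, 21))
print(df[["A", "r_E_sps", "r_I_sps", "lambda1", "V_E", "G_E"]].iloc[[0, -1]])
```

shows the attended endpoint vs the unattended one: r_E 20.6 → 23.7 sp/s,
r_I 16.9 → 25.4 sp/s, leading eigenvalue −1.67 → −1.95 (better damping),
V_E down 29%, G_E up 4% — rate and gain up, shared variability down, from
one knob.

The numbered drivers under `analysis/` run the full story and write their
tables under `results/`:

```bash
python analysis/01_simulate_sessions.py    # sessions + covariance stats
python analysis/02_fit_rank1_model.py      # fits, nulls, cross-validation
python analysis/03_meanfield_attention.py  # sweep, input-plane and coupling maps
python analysis/04_fisher_information.py   # information along the path
```

There is also a CLI (`attncov run`, `attncov rank1-fit`, `attncov sweep-a`,
`attncov fisher`) for running the same steps from a shell or a YAML config.

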