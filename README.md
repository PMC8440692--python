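# qsat — Bayesian adaptive estimation of the speed–accuracy tradeoff function

Most psychophysical tasks measure both response time (RT) and accuracy, and
the two trade off: faster responses are less accurate.  The speed–accuracy
tradeoff (SAT) function captures the whole relationship by measuring
accuracy as a function of processing time under the *response-signal*
paradigm, in which the participant may respond only within a short window
following a signal presented at a controlled stimulus-onset asynchrony
(SOA).  Conventional SAT experiments are expensive — hundreds of trials per
SOA level are needed to estimate accuracy precisely at each of 5–10 levels.

`qsat` implements a trial-based Bayesian alternative and the adaptive design
built on it:

* **Model.**  Accuracy follows an exponential approach to an asymptote,

  ```
  pc(t) = chance + λ (1 − exp(−γ (t − δ)))   for t > δ,  else chance
  ```

  with λ the above-chance asymptote, γ the rate (1/s) and δ the intercept
  (s); `chance = 0.5` for 2AFC.

* **Trial-wise Bayesian estimation.**  Each trial's binary correctness at
  its *realized* RT contributes a Bernoulli likelihood; a posterior over a
  21×30×25 grid on (λ, γ, δ) is updated per trial.  Estimates are marginal
  means; precision is the half-width of the shortest 68.2% credible
  interval (HWCI).

* **Adaptive SOA selection ("multiple-step-ahead search").**  Because the
  response-signal paradigm changes SOA per block, the next block's SOA is
  chosen from 49 candidates on [0, 1.2] s to maximize the mutual information
  between the block's binomial correct-count (evaluated at the window
  midpoint RT) and the parameters.

* **Validation framework.**  Four virtual observers with ex-Gaussian RTs
  and four estimation procedures — (1) MLE on per-SOA averaged data,
  (2) trial-wise MLE, (3) trial-wise Bayesian, (4) Bayesian adaptive — are
  compared by parameter/function bias, replication SD and trials-to-precision.

## Worked example

```python
import numpy as np
from qsat import (STUDY_OBSERVERS, ProcedureConfig, VirtualObserver,
                  run_procedure4)

obs = VirtualObserver(STUDY_OBSERVERS[1])        # λ=0.47, γ=7.5, δ=0.28
cfg = ProcedureConfig(procedure_id=4, total_trials=2048,
                      checkpoints=(128, 512, 2048))
res = run_procedure4(obs, cfg, np.random.default_rng(7))
for i, cp in enumerate(res.checkpoints):
    lam, gam, dlt = res.estimates[i]
    print(f"after {cp:4d} trials: lam={lam:.3f} gam={gam:.2f} delta={dlt:.3f} "
          f"(lam HWCI {res.hwcis[i, 0]:.4f})")
```

prints

```
after  128 trials: lam=0.465 gam=20.01 delta=0.308 (lam HWCI 0.0225)
after  512 trials: lam=0.433 gam=9.44 delta=0.265 (lam HWCI 0.0225)
after 2048 trials: lam=0.465 gam=7.83 delta=0.274 (lam HWCI 0.0075)
```

i.e. a single run homes in on the generating parameters (0.470, 7.5, 0.28)
— γ is the hardest to pin down and still wanders at 512 trials — and the λ
credible interval shrinks threefold between 128 and 2048 trials.  `res.soa_history` shows the selections
concentrating in three SOA bands (≈0.2–0.3 s, ≈0.35–0.45 s, and 1.2 s) that
pin down δ, γ and λ respectively.

A command-line interface wraps the same machinery:

```
qsat simulate --observer 1 --procedure 4 --trials 2048 --reps 10 --seed 42 --out out/
qsat compare --config my_config.yaml
qsat fit --input trials.csv --method 3
qsat report --in out/ --out summary.csv
```

`qsat fit` estimates the SAT curve offline from recorded trials (CSV columns
`soa,rt,correct` in seconds / 0-1).

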