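# vascareless

Detecting and accounting for careless respondents in visual-analogue-scale
(VAS) questionnaire data with a Bayesian Beta mixture item response model.

## The problem

VAS (slider) items yield bounded continuous scores in (0, 1).  They are
sensitive instruments but also demanding ones, and some respondents answer
without processing item content — parking the slider at an end, hovering
around the midpoint, or clicking at random.  Such careless rows carry no
information about the measured trait and contaminate reliability, factor
structure, and substantive conclusions.  Classical screening tools built for
Likert data (long-string indices) or for unbounded data (normal factor
mixture models) fit bounded slider data poorly.

This package is for psychometricians and applied survey researchers who
want a model-based screen for VAS data: per-respondent attentiveness
probabilities, classification rules built on them, and attentive-model
parameter estimates that are already adjusted for the contamination.

## The model

An attentive response y_ij follows a Beta item response model whose shape
parameters are driven by the latent trait θ, item wording s_j ∈ {−1, +1},
difficulty b_j, and dispersion α_j:

    y_ij ~ Beta(a_ij, b_ij),   a_ij = exp[(s_j θ_i − b_j + α_j)/2],
                               b_ij = exp[−(s_j θ_i − b_j − α_j)/2]

so E[y_ij] = logistic(s_j θ_i − b_j) and α_j controls only the conditional
variance.  A careless response follows a single unstructured Beta(m, n)
common to all persons and items.  Each observed cell mixes the two with a
person-level attentiveness probability π_i:

    f(y_ij) = π_i Beta(y_ij; a_ij, b_ij) + (1 − π_i) Beta(y_ij; m, n)

π_i gets a hierarchical Dirichlet prior Beta(ωπ, ω(1−π)) around the
population attentive proportion π.  Estimation is MCMC (adaptive
Metropolis-within-Gibbs, vectorized over persons and items), convergence is
monitored with the Gelman–Rubin EPSR (< 1.1), and respondents are flagged
either by thresholding π_i at 0.5 or by ranking (flag the round(N(1−π̂))
least attentive).  A deliberately mis-specified normal mixture CFA baseline
is included to quantify what modeling the bounded Beta likelihood buys.
See `docs/methods.md` for the full prior stack and numerical choices.

## Worked example

Simulate a contaminated dataset (300 respondents, 10 items, 25% careless
respondents clicking at the scale extremes), fit the mixture, and screen:

```python
import numpy as np
from vascareless import (
    CarelessPattern, SimulationCondition, generate_dataset,
    ItemsMeta, McmcSpec, fit_mixture,
    classify_proportion, confusion_metrics,
)

cond = SimulationCondition(
    careless_pattern=CarelessPattern(kind="beta_extremes"),
    prop_careless=0.25, seed=42,
)
data = generate_dataset(cond)

meta = ItemsMeta(wording=np.array([it.wording for it in data.items]))
fit = fit_mixture(data.responses, meta,
                  spec=McmcSpec(chains=2, iterations=4000, seed=1, thin=2))

pi_hat = float(fit.point["attentive_prop"])
print(f"converged: {fit.converged} (max EPSR {fit.max_epsr:.3f})")
print(f"estimated careless proportion: {1 - pi_hat:.3f} (true 0.25)")
print(f"careless Beta shapes: m={float(fit.point['careless_m']):.2f}, "
      f"n={float(fit.point['careless_n']):.2f} (true 0.5, 0.5)")

labels = classify_proportion(fit.point["person_prob"], pi_hat)
report = confusion_metrics(data.membership, labels.labels)
print(f"flagged {labels.flagged_count} of 300 respondents")
print(f"accuracy {report.accuracy:.3f}, sensitivity {report.sensitivity:.3f}, "
      f"FPR {report.fpr:.3f}")
```

Output:

```
converged: True (max EPSR 1.094)
estimated careless proportion: 0.229 (true 0.25)
careless Beta shapes: m=0.52, n=0.54 (true 0.5, 0.5)
flagged 69 of 300 respondents
accuracy 0.973, sensitivity 0.996, FPR 0.093
```

The model recovers the contamination level (0.229 vs the generating 0.25)
and the careless response distribution (Beta(0.52, 0.54) vs the generating
Beta(0.5, 0.5)); the ranking rule flags 69 respondents, keeping 99.6% of the
attentive ones while letting 9.3% of the careless ones through.

The same workflows are available from the shell:

```
vascareless simulate --pattern beta_extremes --prop 0.25 --seed 42 --out data.csv
vascareless fit --model mixture --responses data.csv --items items.csv \
    --chains 2 --iters 4000 --seed 1 --out fit.json
vascareless classify --rule proportion --summary fit.json --out labels.csv
vascareless study --replications 5 --iters 4000 --seed 1 --out tables/
```

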