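# mixstock

Unconditional maximum-likelihood mixture models for **mixed-stock
analysis** from otolith chemistry, with a parametric-bootstrap framework
for quantifying how reliable the estimates are.

## The problem

Juvenile fish grow up in distinct nursery habitats (lagoons, estuaries)
whose water chemistry leaves a multivariate "fingerprint" in their
otoliths — here a panel of J = 7 element:Ca ratios (Li, B, Mg, Rb, Sr, Y,
Ba), standardized to mean 0 and sd 1. Adults sampled at sea are a *mixed
stock*: a finite mixture over the K nursery sources,

    f(x) = Σₖ pₖ · N(x; μₖ, Σₖ),   k = 1..K,

with three groups of parameters: the number of contributing sources K,
the baseline nursery signatures θₖ = (μₖ, Σₖ), and the mixing
proportions pₖ — the management-relevant quantity ("how much does each
nursery contribute to the stock?").

The classical *conditional* approach freezes θₖ at estimates from
juvenile (nursery-source) samples and estimates only pₖ; it fails when
some nurseries were never found or sampled. The **unconditional**
approach implemented here maximizes the *joint* likelihood of the
labeled nursery-source data and the unlabeled mixed-stock data by EM, so
signatures are refined by the mixed data and sources with no nursery
sample at all ("novel" components) can still be estimated. Starting
values come from a semi-supervised K-means step in which the Kₛ known
source means are *fixed* centroids and K − Kₛ *mobile* centroids seek the
unsampled sources. K itself can be selected by BIC over a ladder
K = max(1, Kₛ)..8.

Because all of this can go wrong when signatures overlap, the package
also ships the simulation framework that measures bias (BI) and
uncertainty (SE) of p̂, θ̂ and K̂ across *incomplete-sampling* scenarios
(Kₛ = 0..4 sources sampled) and *signature-separation* scenarios
(average squared centroid separation Δ² from 0.5 to 5.5 standardized
units), using parametric-bootstrap datasets of 25 fish per sampled
source and 100 mixed-stock fish at proportions {0.1, 0.2, 0.3, 0.4}.

## Worked example

Simulate a well-separated cohort, sample three of its four nurseries,
and fit the fourth as a novel component:

```python
from mixstock import write_observations
from mixstock.simulate import (observed_style_cohorts,
                               draw_nursery_dataset, draw_mixed_dataset)

base = observed_style_cohorts(seed=1)["2008"]          # Δ² = 3.29
lab = draw_nursery_dataset(base, base.source_ids[:3], 25, seed=42)
mix, truth = draw_mixed_dataset(base, (0.1, 0.2, 0.3, 0.4), 100, seed=43)
write_observations(lab, "nursery.csv")
write_observations(mix, "mixed.csv")
print(dict(sorted(truth.allocation.items())))
# {'S1': 0.2, 'S2': 0.3, 'S3': 0.1, 'S4': 0.4}
```

```sh
$ mixstock fit --nursery nursery.csv --mixed mixed.csv --k 4 --out fit-out --seed 7
K = 4, loglik = -1319.790, converged = True
  p[S1] = 0.2170
  p[S2] = 0.3304
  p[S3] = 0.1136
  p[novel-1] = 0.3390
```

The three sampled sources are recovered near their true contributions
(0.2, 0.3, 0.1) and the never-sampled source S4 (truth 0.4) is picked up
by the novel component at 0.34. Asking the model to also choose K shows
the method's known weakness:

```sh
$ mixstock fit --nursery nursery.csv --mixed mixed.csv --k auto --out sel-out --seed 7
K = 3, loglik = -1374.647, converged = True
  ...
selected K = 3 by BIC (delta = 272.13)
```

BIC prefers the 3-component model — the number of contributing sources
is systematically *under*-estimated whenever sampling is incomplete, so
K̂ should be read as a lower bound.

The full simulation grid is driven by a YAML config:

```sh
mixstock simulate --config experiment.yaml --seed 1 --out results/
```

which writes a long-format `summary.csv` of BI/SE metrics per scenario.

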