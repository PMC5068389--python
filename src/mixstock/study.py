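"""The benchmark experiments, packaged as reproducible functions.

Each function here rebuilds one of the benchmark computations from
scratch: synthetic stand-ins for the three observed cohorts (matching
their printed separation and per-source spread statistics), the
incomplete-sampling grid of proportion/signature bias, BIC selection of
the source count under complete sampling, the three-source separation
threshold, and the deterministic virtual-cohort rescaling check.

Everything is a pure function of the seed; replicate counts default to
desk-scale values (200 resampling runs for the bias grids, 100 for model
selection) that keep each experiment in the minutes range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baseline import average_separation
from .em import EMControls
from .pipeline import run_scenario
from .selection import K_MAX_DEFAULT
from .simulate import (ScenarioConfig, make_virtual_cohort,
                       observed_style_cohorts, random_baseline)

__all__ = [
    "sampling_grid",
    "k_selection_rate",
    "k_selection_median",
    "threshold_bi_p",
    "rescaled_separation",
]


def _child_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def sampling_grid(
    seed: int = 0,
    R: int = 200,
    K_S_values=range(5),
    controls: EMControls = EMControls(),
) -> pd.DataFrame:
    """Bias/uncertainty metrics over cohorts x sampling scenarios.

    Runs every (cohort, K_S) cell of the incomplete-sampling experiment
    on the three observed-style synthetic cohorts, R resampling runs per
    cell with the standard sample sizes (25 nursery fish per sampled
    source, 100 mixed-stock fish at proportions {0.1, 0.2, 0.3, 0.4}).
    Returns one row per cell with BI_p, SE_p, BI_theta, SE_theta.
    """
    cohorts = observed_style_cohorts(seed=_child_seed(seed, 0))
    rows = []
    for ci, (name, cohort) in enumerate(sorted(cohorts.items())):
        for K_S in K_S_values:
            sc = ScenarioConfig(cohort=cohort, K_S=int(K_S), R=R,
                                seed=_child_seed(seed, 1, ci, K_S),
                                label=f"{name}/KS{K_S}")
            s = run_scenario(sc, controls=controls)
            rows.append({"cohort": name, "K_S": int(K_S),
                         "separation": average_separation(
                             cohort, np.eye(cohort.panel.J)),
                         "BI_p": s.BI_p, "SE_p": s.SE_p,
                         "BI_theta": s.BI_theta, "SE_theta": s.SE_theta,
                         "R_effective": s.R_effective})
    return pd.DataFrame(rows)


def k_selection_rate(
    seed: int = 0,
    R: int = 100,
    K_S: int = 4,
    K_max: int = K_MAX_DEFAULT,
    controls: EMControls = EMControls(),
) -> float:
    """Percent of runs in which BIC selects the true K = 4.

    Uses the intermediate-separation cohort (the 2010-style baseline at
    average squared separation 2.78) and the complete-sampling scenario
    by default; the selection ladder spans K = max(1, K_S)..K_max.
    """
    cohorts = observed_style_cohorts(seed=_child_seed(seed, 0))
    sc = ScenarioConfig(cohort=cohorts["2010"], K_S=K_S, R=R,
                        seed=_child_seed(seed, 2, K_S))
    _, records = run_scenario(sc, controls=controls, select_k=True,
                              K_max=K_max, return_records=True)
    k_hats = np.array([r.K_hat for r in records])
    return float(100.0 * np.mean(k_hats == 4))


def k_selection_median(
    seed: int = 0,
    R: int = 30,
    K_S: int = 2,
    controls: EMControls = EMControls(),
) -> float:
    """Median selected K under an incomplete-sampling scenario."""
    cohorts = observed_style_cohorts(seed=_child_seed(seed, 0))
    sc = ScenarioConfig(cohort=cohorts["2010"], K_S=K_S, R=R,
                        seed=_child_seed(seed, 3, K_S))
    _, records = run_scenario(sc, controls=controls, select_k=True,
                              return_records=True)
    return float(np.median([r.K_hat for r in records]))


def threshold_bi_p(
    seed: int = 0,
    R: int = 200,
    separation: float = 1.5,
    K_S: int = 3,
    controls: EMControls = EMControls(),
) -> float:
    """BI_p at a virtual-cohort separation with K_S sources sampled.

    The virtual cohort keeps the intermediate cohort's covariances and
    rescales its centroids to the target separation, as in the virtual
    grid construction.
    """
    cohorts = observed_style_cohorts(seed=_child_seed(seed, 0))
    virt = make_virtual_cohort(cohorts["2010"], separation,
                               cohort_id=f"virtual-{separation:g}")
    sc = ScenarioConfig(cohort=virt, K_S=K_S, R=R,
                        seed=_child_seed(seed, 4, K_S))
    s = run_scenario(sc, controls=controls)
    return float(s.BI_p)


def rescaled_separation(seed: int = 0, target: float = 0.5) -> float:
    """Recomputed separation of a virtual cohort rescaled to ``target``.

    Deterministic construction check: generate a synthetic 4-source
    baseline, rescale its centroids to the smallest virtual-grid target,
    and recompute the average squared Mahalanobis separation from the
    rescaled means and unchanged covariances.
    """
    base = random_baseline(4, 7, target_sep=2.78,
                           seed=_child_seed(seed, 5))
    virt = make_virtual_cohort(base, target)
    return float(average_separation(virt, np.eye(virt.panel.J)))
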