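"""Selecting the number of contributing nursery sources.

Competing mixture models are fit over a ladder of component counts
K = max(1, K_S) .. K_max (the benchmark convention caps the ladder at
K_max = 8) and compared by an information criterion, BIC by default.
The selected K-hat is the argmin; ties break to the smallest K.  The
strength of the selection is summarized by delta_bic, the gap between
the median and the minimum criterion value across the ladder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline import ObservationTable
from .em import EMControls, MixtureFit, em_fit, initialize

__all__ = ["SelectionResult", "information_criterion", "estimate_k",
           "n_free_parameters", "K_MAX_DEFAULT"]

logger = logging.getLogger(__name__)

K_MAX_DEFAULT = 8


def n_free_parameters(K: int, J: int) -> int:
    """Free parameters of a K-component MVN mixture in J dimensions.

    K means (J each), K unrestricted covariances (J(J+1)/2 each) and
    K - 1 free mixing proportions.
    """
    return K * J + K * (J * (J + 1)) // 2 + (K - 1)


def information_criterion(fit: MixtureFit, n_obs: int,
                          which: str = "BIC") -> float:
    """BIC (default) or AIC of a fitted mixture.

    BIC = -2 loglik + q ln(n_obs); AIC = -2 loglik + 2 q, with q the
    free-parameter count of the K-component model.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if not math.isfinite(fit.loglik):
        raise ValueError("fit has non-finite log-likelihood")
    J = fit.mu_hat.shape[1]
    q = n_free_parameters(fit.K, J)
    if which.upper() == "BIC":
        return -2.0 * fit.loglik + q * math.log(n_obs)
    if which.upper() == "AIC":
        return -2.0 * fit.loglik + 2.0 * q
    raise ValueError(f"unknown criterion {which!r}")


@dataclass
class SelectionResult:
    """Outcome of the K-selection ladder."""

    K_hat: int
    criterion_values: dict[int, float]
    fits: dict[int, MixtureFit]
    delta_bic: float
    criterion: str = "BIC"
    failed: dict[int, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Selection table: K, loglik, q, BIC-or-AIC, converged, selected."""
        rows = []
        for K, fit in sorted(self.fits.items()):
            rows.append({
                "K": K,
                "loglik": fit.loglik,
                "q": n_free_parameters(K, fit.mu_hat.shape[1]),
                self.criterion: self.criterion_values[K],
                "converged": fit.converged,
                "selected": K == self.K_hat,
            })
        return pd.DataFrame(rows)


def estimate_k(
    labeled: ObservationTable | None,
    mixed: ObservationTable,
    K_S: int,
    K_max: int = K_MAX_DEFAULT,
    controls: EMControls = EMControls(),
    criterion: str = "BIC",
) -> SelectionResult:
    """Fit every K in [max(1, K_S), K_max] and select by the criterion.

    Each candidate runs the full initialization pipeline (known-source
    moments, seeded K-means, cluster moments, empirical proportions)
    followed by EM.  Candidates whose fit raises are recorded as failed
    and excluded; if every candidate fails, the error propagates.
    """
    if mixed is None or mixed.n == 0:
        raise ValueError("estimate_k needs a non-empty mixed-stock dataset")
    K_min = max(1, K_S)
    if K_max < K_min:
        raise ValueError(f"K_max={K_max} below K_min={K_min}")
    n_obs = mixed.n + (labeled.n if labeled is not None else 0)
    values: dict[int, float] = {}
    fits: dict[int, MixtureFit] = {}
    failed: dict[int, str] = {}
    for K in range(K_min, K_max + 1):
        try:
            init = initialize(labeled, mixed, K, controls)
            fit = em_fit(labeled, mixed, K, init=init, controls=controls)
            values[K] = information_criterion(fit, n_obs, criterion)
            fits[K] = fit
        except Exception as exc:  # noqa: BLE001 - per-candidate isolation
            failed[K] = f"{type(exc).__name__}: {exc}"
            logger.warning("model with K=%d failed: %s", K, failed[K])
    if not fits:
        raise RuntimeError(
            f"all candidate models failed: {failed}"
        )
    vals = np.array([values[K] for K in sorted(values)])
    K_hat = min(K for K, v in values.items()
                if v == min(values.values()))
    delta_bic = float(np.median(vals) - vals.min())
    return SelectionResult(K_hat=K_hat, criterion_values=values, fits=fits,
                           delta_bic=delta_bic, criterion=criterion.upper(),
                           failed=failed)
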