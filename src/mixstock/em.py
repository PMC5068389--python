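"""Unconditional maximum-likelihood mixture model, fit by EM.

The mixed stock is modelled as a K-component multivariate-normal finite
mixture f(x) = sum_k p_k N(x; mu_k, Sigma_k).  *Unconditional* means the
baseline signatures (mu_k, Sigma_k) are not frozen at their nursery-sample
estimates: EM maximizes the joint likelihood of the labeled nursery-source
data (each fish pinned to its own component) and the unlabeled mixed-stock
data (latent membership), so mixed-stock information updates the
signatures, and components with no nursery sample at all ("novel"
sources) can still be estimated.

Initialization follows a fixed pipeline:

1. ``init_known``      — sample mean/covariance per labeled source;
2. ``seeded_kmeans``   — semi-supervised K-means on the mixed data where
   the known means are *fixed* centroids and K_U *mobile* centroids are
   fitted for the unsampled sources;
3. ``init_unknown``    — sample moments of each mobile cluster;
4. ``init_proportions``— hard maximum-density assignment of the mixed
   rows, giving empirical starting proportions.

The M-step keeps every covariance positive definite via an eigenvalue
floor plus a determinant floor (``regularize_cov``).  Mixing proportions
are updated from the mixed-row responsibilities only: nursery sampling is
by design, so labeled counts carry no information about the mixture
weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import brentq
from scipy.special import logsumexp

from .baseline import ObservationTable

__all__ = [
    "EMControls",
    "MixtureFit",
    "ComponentInit",
    "mvn_logdensity",
    "joint_loglik",
    "init_known",
    "seeded_kmeans",
    "init_unknown",
    "init_proportions",
    "initialize",
    "em_fit",
    "regularize_cov",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class EMControls:
    """Numerical knobs of the EM fit.

    ``rel_tol`` is on the relative change in joint log-likelihood;
    ``eig_floor`` / ``cov_det_floor`` bound the covariance spectrum and
    determinant in every M-step; ``kmeans_restarts`` random starts are
    used for the mobile centroids; ``update_known`` chooses whether
    known-source signatures are re-estimated during EM (the unconditional
    default) or held at their nursery-sample values.
    """

    max_iter: int = 1000
    rel_tol: float = 1e-8
    cov_det_floor: float = 1e-9
    eig_floor: float = 1e-6
    kmeans_restarts: int = 10
    seed: int = 0
    update_known: bool = True

    def __post_init__(self) -> None:
        if min(self.max_iter, self.kmeans_restarts) < 1:
            raise ValueError("max_iter and kmeans_restarts must be >= 1")
        if not (0 < self.rel_tol < 1):
            raise ValueError("rel_tol must be in (0, 1)")
        if self.cov_det_floor <= 0 or self.eig_floor <= 0:
            raise ValueError("covariance floors must be positive")


@dataclass
class ComponentInit:
    """Starting parameters for the K components, in component order.

    ``provenance[k]`` is the known source id for components initialized
    from nursery data, or ``"novel-i"`` for mobile-centroid components.
    """

    mus: np.ndarray          # K x J
    covs: np.ndarray         # K x J x J
    p: np.ndarray            # K
    provenance: list[str]


@dataclass
class MixtureFit:
    """A fitted unconditional mixture model."""

    K: int
    p_hat: np.ndarray
    mu_hat: np.ndarray           # K x J
    cov_hat: np.ndarray          # K x J x J
    loglik: float
    n_iter: int
    converged: bool
    provenance: list[str]
    loglik_trace: list[float] = field(default_factory=list)
    p_estimated: bool = True     # False when there were no mixed rows

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "K": self.K,
            "p_hat": self.p_hat.tolist(),
            "mu_hat": self.mu_hat.tolist(),
            "cov_hat": self.cov_hat.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "provenance": self.provenance,
            "loglik_trace_len": len(self.loglik_trace),
            "p_estimated": self.p_estimated,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(text_or_path: str | Path) -> "MixtureFit":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return MixtureFit(
            K=d["K"], p_hat=np.array(d["p_hat"]),
            mu_hat=np.array(d["mu_hat"]), cov_hat=np.array(d["cov_hat"]),
            loglik=d["loglik"], n_iter=d["n_iter"],
            converged=d["converged"], provenance=list(d["provenance"]),
            p_estimated=d.get("p_estimated", True),
        )


# Densities ------------------------------------------------------------------


def _chol(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance is not positive definite") from exc


def _mvn_logpdf(X: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Row-wise log N(x; mu, cov) via a Cholesky factor (no explicit inverse)."""
    L = _chol(cov)
    J = mu.shape[0]
    w = solve_triangular(L, (np.atleast_2d(X) - mu).T, lower=True)
    maha = np.einsum("ij,ij->j", w, w)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (J * _LOG_2PI + logdet + maha)


def mvn_logdensity(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """Log multivariate-normal density of a single observation."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(_mvn_logpdf(x.reshape(1, -1), mu,
                             np.asarray(cov, dtype=float))[0])


def _component_logdens(X: np.ndarray, mus: np.ndarray,
                       covs: np.ndarray) -> np.ndarray:
    """n x K matrix of per-component log densities."""
    return np.column_stack([_mvn_logpdf(X, mus[k], covs[k])
                            for k in range(mus.shape[0])]) \
        if X.shape[0] else np.empty((0, mus.shape[0]))


def _labeled_blocks(labeled: ObservationTable,
                    provenance: list[str]) -> dict[int, np.ndarray]:
    """Map component index -> labeled rows of that source; error on orphans."""
    blocks: dict[int, np.ndarray] = {}
    if labeled is None or labeled.n == 0:
        return blocks
    by_source = {sid: k for k, sid in enumerate(provenance)}
    X = labeled.values()
    src = labeled.data["source"].to_numpy()
    for sid in pd_unique(src):
        if sid not in by_source:
            raise ValueError(
                f"labeled source {sid!r} has no matching model component"
            )
        blocks[by_source[sid]] = X[src == sid]
    return blocks


def pd_unique(arr) -> list:
    seen, out = set(), []
    for v in arr:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def joint_loglik(
    labeled: ObservationTable | None,
    mixed: ObservationTable | None,
    p: np.ndarray,
    mus: np.ndarray,
    covs: np.ndarray,
    provenance: list[str],
) -> float:
    """Joint log-likelihood of nursery-source and mixed-stock data.

    Labeled rows contribute the log density at their own component;
    mixed rows contribute log sum_k p_k N(y; mu_k, Sigma_k).
    """
    total = 0.0
    for k, Xk in _labeled_blocks(labeled, provenance).items():
        total += float(_mvn_logpdf(Xk, mus[k], covs[k]).sum())
    if mixed is not None and mixed.n:
        ld = _component_logdens(mixed.values(), mus, covs)
        with np.errstate(divide="ignore"):
            logp = np.log(np.asarray(p, dtype=float))
        total += float(logsumexp(ld + logp, axis=1).sum())
    return total


# Initialization -------------------------------------------------------------


def init_known(labeled: ObservationTable,
               eig_floor: float = 1e-6) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Sample mean and covariance per labeled nursery source.

    Sources with fewer than J + 2 rows (where the sample covariance is
    unreliable or singular) fall back to the pooled covariance of the
    whole labeled dataset, regularized to be positive definite.
    Returns (means, covariances, source ids) in first-appearance order;
    all empty for an empty table (the K_S = 0 scenario).
    """
    if labeled is None or labeled.n == 0:
        J = 0 if labeled is None else labeled.panel.J
        return (np.empty((0, J)), np.empty((0, J, J)), [])
    X = labeled.values()
    J = X.shape[1]
    src = labeled.data["source"].to_numpy()
    ids = pd_unique(src)
    grand = np.cov(X, rowvar=False, ddof=1) if X.shape[0] > 1 \
        else np.eye(J)
    grand = regularize_cov(np.atleast_2d(grand), eig_floor=eig_floor)
    mus, covs = [], []
    for sid in ids:
        Xk = X[src == sid]
        mus.append(Xk.mean(axis=0))
        if Xk.shape[0] >= J + 2:
            C = np.cov(Xk, rowvar=False, ddof=1)
            C = regularize_cov(np.atleast_2d(C), eig_floor=eig_floor)
        else:
            C = grand
        covs.append(C)
    return np.array(mus), np.array(covs), list(ids)


def seeded_kmeans(
    mixed: ObservationTable | np.ndarray,
    fixed_centroids: np.ndarray,
    K_U: int,
    restarts: int = 10,
    seed: int | np.random.SeedSequence = 0,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Semi-supervised K-means with fixed and mobile centroids.

    Lloyd iterations on the mixed-stock data in which each point is
    assigned to its nearest centroid — fixed (the known-source means) or
    mobile — but only the K_U mobile centroids are re-estimated.  The best
    of ``restarts`` random initializations by total within-cluster sum of
    squares is returned as ``(mobile_centroids, assignments)``;
    assignments index the stacked [fixed, mobile] centroid list.
    """
    X = mixed.values() if isinstance(mixed, ObservationTable) else np.asarray(mixed, float)
    n = X.shape[0]
    if n == 0:
        raise ValueError("seeded_kmeans needs a non-empty mixed dataset")
    if K_U < 1:
        raise ValueError("K_U must be >= 1")
    if K_U > n:
        raise ValueError(f"K_U={K_U} exceeds the number of mixed rows ({n})")
    fixed = np.atleast_2d(np.asarray(fixed_centroids, dtype=float)) \
        if np.size(fixed_centroids) else np.empty((0, X.shape[1]))
    n_fixed = fixed.shape[0]
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(restarts):
        mobile = X[rng.choice(n, size=K_U, replace=False)].copy()
        assign = np.full(n, -1)
        for _it in range(max_iter):
            cents = np.vstack([fixed, mobile])
            d2 = ((X[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
            new_assign = d2.argmin(axis=1)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for u in range(K_U):
                rows = X[assign == n_fixed + u]
                if rows.shape[0]:
                    mobile[u] = rows.mean(axis=0)
                # empty mobile cluster: centroid kept as-is
        wcss = float(d2[np.arange(n), assign].sum())
        if best is None or wcss < best[0] - 1e-12:
            best = (wcss, mobile.copy(), assign.copy())
    assert best is not None
    return best[1], best[2]


def init_unknown(
    mixed: ObservationTable,
    assignments: np.ndarray,
    mobile_centroids: np.ndarray,
    n_fixed: int,
    eig_floor: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Starting moments of the K_U novel components from their clusters.

    Clusters with fewer than J + 2 members (including empty ones, whose
    kept centroid still defines the mean) use the pooled covariance of
    the whole mixed dataset.
    """
    X = mixed.values()
    J = X.shape[1]
    K_U = mobile_centroids.shape[0]
    pooled = np.cov(X, rowvar=False, ddof=1) if X.shape[0] > 1 else np.eye(J)
    pooled = regularize_cov(np.atleast_2d(pooled), eig_floor=eig_floor)
    mus, covs = [], []
    for u in range(K_U):
        rows = X[assignments == n_fixed + u]
        if rows.shape[0]:
            mus.append(rows.mean(axis=0))
        else:
            mus.append(mobile_centroids[u])
        if rows.shape[0] >= J + 2:
            C = regularize_cov(np.atleast_2d(np.cov(rows, rowvar=False, ddof=1)),
                               eig_floor=eig_floor)
        else:
            C = pooled
        covs.append(C)
    tags = [f"novel-{u + 1}" for u in range(K_U)]
    return np.array(mus), np.array(covs), tags


def init_proportions(mixed: ObservationTable, mus: np.ndarray,
                     covs: np.ndarray) -> np.ndarray:
    """Empirical starting proportions by hard maximum-density assignment.

    Each mixed row goes to the component with the highest density (equal
    priors); p_k = count_k / n.  Components that capture no rows are
    floored at 1/(2n) and the vector renormalized, so EM never starts on
    the simplex boundary.
    """
    K = mus.shape[0]
    n = mixed.n
    if n == 0:
        return np.full(K, 1.0 / K)
    ld = _component_logdens(mixed.values(), mus, covs)
    hard = ld.argmax(axis=1)
    counts = np.bincount(hard, minlength=K).astype(float)
    p = counts / n
    floor = 1.0 / (2 * n)
    p = np.maximum(p, floor)
    return p / p.sum()


def initialize(
    labeled: ObservationTable | None,
    mixed: ObservationTable,
    K: int,
    controls: EMControls = EMControls(),
) -> ComponentInit:
    """Full starting-parameter pipeline for a K-component fit."""
    mus_k, covs_k, known_ids = init_known(
        labeled, eig_floor=controls.eig_floor)
    K_S = len(known_ids)
    if K < max(1, K_S):
        raise ValueError(f"K={K} is below the number of labeled sources ({K_S})")
    J = mixed.panel.J
    if K_S and mus_k.shape[1] != J:
        raise ValueError("labeled and mixed tables disagree on the panel")
    K_U = K - K_S
    if K_U > 0:
        mobile, assign = seeded_kmeans(
            mixed, mus_k if K_S else np.empty((0, J)), K_U,
            restarts=controls.kmeans_restarts, seed=controls.seed)
        mus_u, covs_u, novel_ids = init_unknown(
            mixed, assign, mobile, n_fixed=K_S, eig_floor=controls.eig_floor)
        mus = np.vstack([mus_k.reshape(K_S, J), mus_u])
        covs = np.concatenate([covs_k.reshape(K_S, J, J), covs_u])
        provenance = list(known_ids) + novel_ids
    else:
        mus, covs, provenance = mus_k, covs_k, list(known_ids)
    p = init_proportions(mixed, mus, covs)
    return ComponentInit(mus=mus, covs=covs, p=p, provenance=provenance)


# Covariance constraint ------------------------------------------------------


def regularize_cov(cov: np.ndarray, eig_floor: float = 1e-6,
                   det_floor: float = 1e-9) -> np.ndarray:
    """Repair a covariance to be positive definite with det >= det_floor.

    Eigenvalues are floored at ``eig_floor``; if the determinant is still
    below ``det_floor``, the smallest ridge tau * I achieving the floor is
    added (tau solved on the eigenvalues, so the output stays symmetric
    PD with the same eigenvectors).
    """
    cov = np.asarray(cov, dtype=float)
    cov = 0.5 * (cov + cov.T)
    lam, V = np.linalg.eigh(cov)
    lam = np.maximum(lam, eig_floor)
    logdet = np.sum(np.log(lam))
    if logdet < np.log(det_floor):
        J = lam.shape[0]
        def f(tau: float) -> float:
            return float(np.sum(np.log(lam + tau)) - np.log(det_floor))
        hi = det_floor ** (1.0 / J)  # prod(lam + hi) >= hi^J = det_floor
        tau = 0.0 if f(0.0) >= 0 else brentq(f, 0.0, hi + 1e-30)
        lam = lam + tau
    return (V * lam) @ V.T


# EM -------------------------------------------------------------------------


def em_fit(
    labeled: ObservationTable | None,
    mixed: ObservationTable | None,
    K: int,
    init: ComponentInit | None = None,
    controls: EMControls = EMControls(),
) -> MixtureFit:
    """Fit the K-component unconditional mixture by EM.

    E-step: responsibilities z_jk for mixed rows; labeled rows keep unit
    membership in their own component.  M-step: p from mixed-row
    responsibilities only; each component's mean and (ML, 1/n-weighted)
    covariance from its labeled rows plus responsibility-weighted mixed
    rows, regularized each iteration.  Stops when the relative joint
    log-likelihood change drops below ``controls.rel_tol``.
    """
    has_mixed = mixed is not None and mixed.n > 0
    if not has_mixed:
        if labeled is None or labeled.n == 0:
            raise ValueError("em_fit needs at least one observation")
        mus, covs, ids = init_known(labeled, eig_floor=controls.eig_floor)
        if K < len(ids):
            raise ValueError(f"K={K} below number of labeled sources ({len(ids)})")
        ll = joint_loglik(labeled, None, np.full(len(ids), 1 / max(len(ids), 1)),
                          mus, covs, ids)
        return MixtureFit(K=len(ids), p_hat=np.full(len(ids), 1 / len(ids)),
                          mu_hat=mus, cov_hat=covs, loglik=ll, n_iter=0,
                          converged=True, provenance=ids,
                          loglik_trace=[ll], p_estimated=False)

    if init is None:
        init = initialize(labeled, mixed, K, controls)
    provenance = list(init.provenance)
    if K != len(provenance):
        raise ValueError("init has wrong number of components")
    n_known = sum(not t.startswith("novel-") for t in provenance)
    mus = init.mus.copy()
    covs = init.covs.copy()
    p = init.p.copy()
    Y = mixed.values()
    n_mix, J = Y.shape
    blocks = _labeled_blocks(labeled, provenance)
    lab_n = {k: b.shape[0] for k, b in blocks.items()}
    lab_sum = {k: b.sum(axis=0) for k, b in blocks.items()}

    trace: list[float] = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, controls.max_iter + 1):
        # E-step (mixed rows only)
        ld = _component_logdens(Y, mus, covs)
        with np.errstate(divide="ignore"):
            logw = ld + np.log(p)
        norm = logsumexp(logw, axis=1)
        z = np.exp(logw - norm[:, None])          # n_mix x K
        ll = float(norm.sum())
        for k, Xk in blocks.items():
            ll += float(_mvn_logpdf(Xk, mus[k], covs[k]).sum())
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite joint log-likelihood at EM iteration {it}")
        trace.append(ll)
        if it > 1 and abs(ll - ll_old) <= controls.rel_tol * (1.0 + abs(ll_old)):
            converged = True
            break
        ll_old = ll

        # M-step
        Zk = z.sum(axis=0)                        # responsibility mass
        p = Zk / n_mix
        for k in range(K):
            if k < n_known and not controls.update_known:
                continue
            w_tot = Zk[k] + lab_n.get(k, 0)
            if w_tot <= 1e-12:
                continue  # keep previous parameters for a dead component
            s1 = z[:, k] @ Y + lab_sum.get(k, 0.0)
            mu_new = s1 / w_tot
            dev = Y - mu_new
            S = (z[:, k, None] * dev).T @ dev
            if k in blocks:
                devl = blocks[k] - mu_new
                S = S + devl.T @ devl
            mus[k] = mu_new
            covs[k] = regularize_cov(S / w_tot, eig_floor=controls.eig_floor,
                                     det_floor=controls.cov_det_floor)

    return MixtureFit(K=K, p_hat=p, mu_hat=mus, cov_hat=covs,
                      loglik=trace[-1], n_iter=it, converged=converged,
                      provenance=provenance, loglik_trace=trace,
                      p_estimated=True)
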