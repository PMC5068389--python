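"""Baseline nursery-signature statistics and geometry.

A *nursery signature* is the multivariate-normal baseline of otolith
chemistry for juveniles from one nursery habitat in one cohort: a mean
vector ``mu`` over J standardized element:Ca ratios and a J x J covariance
``cov``.  This module holds the container types and the descriptive /
geometric computations on sets of signatures:

* per-variable z-score standardization of observation tables,
* squared Mahalanobis distance and the average among-centroid separation,
* the effective standard deviation det(cov)^(1/2J), a scalar spread index,
* deterministic rescaling of centroids to a target average separation
  (the construction behind "virtual cohorts").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ElementPanel",
    "NurserySignature",
    "SignatureSet",
    "ObservationTable",
    "standardize",
    "sq_mahalanobis",
    "pooled_covariance",
    "average_separation",
    "effective_sd",
    "rescale_separation",
    "read_observations",
    "write_observations",
    "read_signature_set",
    "write_signature_set",
]

#: Element:Ca ratio labels of the seven most discriminant elements in the
#: sea-bream otolith panel, in fixed order.
DEFAULT_ELEMENTS = ("Li", "B", "Mg", "Rb", "Sr", "Y", "Ba")


@dataclass(frozen=True)
class ElementPanel:
    """Ordered panel of J element:Ca ratio variables.

    The order is fixed: every vector and matrix that references the panel
    uses this ordering.
    """

    names: tuple[str, ...] = DEFAULT_ELEMENTS

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) < 2:
            raise ValueError("an element panel needs at least 2 variables")
        if len(set(names)) != len(names):
            raise ValueError("element panel names must be unique")

    @property
    def J(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class NurserySignature:
    """Baseline parameters theta_k = (mu_k, Sigma_k) of one nursery source.

    Parameters
    ----------
    source_id, cohort_id
        Labels identifying the nursery habitat and the year class.
    mu
        Length-J mean vector on the standardized scale.
    cov
        J x J symmetric positive-definite covariance matrix.
    n
        Sample size the signature was computed from; 0 for purely
        synthetic signatures.
    """

    source_id: str
    cohort_id: str
    mu: np.ndarray
    cov: np.ndarray
    n: int = 0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "cov", cov)
        if mu.ndim != 1:
            raise ValueError("mu must be a vector")
        if not np.all(np.isfinite(mu)):
            raise ValueError("mu must be finite")
        J = mu.shape[0]
        if cov.shape != (J, J):
            raise ValueError(f"cov must be {J}x{J}, got {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("cov must be symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig[0] <= 0:
            raise ValueError(
                f"cov of source {self.source_id!r} is not positive definite "
                f"(min eigenvalue {eig[0]:.3e})"
            )
        if self.n < 0:
            raise ValueError("n must be >= 0")

    @property
    def J(self) -> int:
        return self.mu.shape[0]


@dataclass(frozen=True)
class SignatureSet:
    """The K nursery signatures of one cohort on a common panel."""

    cohort_id: str
    panel: ElementPanel
    signatures: tuple[NurserySignature, ...]

    def __post_init__(self) -> None:
        sigs = tuple(self.signatures)
        object.__setattr__(self, "signatures", sigs)
        J = self.panel.J
        ids = [s.source_id for s in sigs]
        if len(set(ids)) != len(ids):
            raise ValueError("source_ids must be unique within a SignatureSet")
        for s in sigs:
            if s.J != J:
                raise ValueError(
                    f"signature {s.source_id!r} has J={s.J}, panel has J={J}"
                )

    @property
    def K(self) -> int:
        return len(self.signatures)

    @property
    def source_ids(self) -> list[str]:
        return [s.source_id for s in self.signatures]

    def centroids(self) -> np.ndarray:
        """K x J matrix of signature means."""
        return np.array([s.mu for s in self.signatures])

    def __getitem__(self, source_id: str) -> NurserySignature:
        for s in self.signatures:
            if s.source_id == source_id:
                return s
        raise KeyError(source_id)


# Observation tables ---------------------------------------------------------

ID_COLUMNS = ("specimen_id", "cohort", "source")


@dataclass(frozen=True)
class ObservationTable:
    """One row per fish: identifiers plus J element:Ca ratio columns.

    ``source`` may be missing (NaN/empty) for mixed-stock fish of unknown
    origin; nursery-source (labeled) tables carry it for every row.
    """

    data: pd.DataFrame
    panel: ElementPanel = field(default_factory=ElementPanel)

    def __post_init__(self) -> None:
        missing = [c for c in (*ID_COLUMNS, *self.panel.names)
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")

    @property
    def n(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        """n x J float matrix of the ratio columns, panel order."""
        return self.data.loc[:, list(self.panel.names)].to_numpy(dtype=float)

    def is_labeled(self) -> pd.Series:
        src = self.data["source"]
        return src.notna() & (src.astype(str) != "")

    @staticmethod
    def from_arrays(
        x: np.ndarray,
        panel: ElementPanel,
        cohort: str | Sequence[str],
        source: Sequence[str | None] | None = None,
        specimen_ids: Sequence[str] | None = None,
    ) -> "ObservationTable":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        if x.shape[1] != panel.J:
            raise ValueError(f"expected {panel.J} columns, got {x.shape[1]}")
        df = pd.DataFrame(x, columns=list(panel.names))
        df.insert(0, "specimen_id",
                  list(specimen_ids) if specimen_ids is not None
                  else [f"obs{i}" for i in range(n)])
        df.insert(1, "cohort", cohort)
        df.insert(2, "source",
                  pd.array(list(source), dtype=object) if source is not None
                  else pd.array([None] * n, dtype=object))
        return ObservationTable(df, panel)

    @staticmethod
    def empty(panel: ElementPanel, cohort: str | None = None) -> "ObservationTable":
        df = pd.DataFrame(columns=[*ID_COLUMNS, *panel.names])
        if cohort is not None:
            df["cohort"] = df["cohort"].astype(object)
        return ObservationTable(df, panel)


def standardize(
    table: ObservationTable,
    params: pd.DataFrame | None = None,
) -> tuple[ObservationTable, pd.DataFrame]:
    """Z-score each ratio column to mean 0, sd 1 (sd with denominator n-1).

    Returns the transformed table and a parameter frame (index = variable,
    columns ``mean``/``sd``) so that new data can be mapped onto the same
    scale by passing ``params`` back in.

    Raises
    ------
    ValueError
        If any variable has zero variance across the table.
    """
    x = table.values()
    if params is None:
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        zero = [name for name, s in zip(table.panel.names, sd)
                if not s > 0]
        if zero:
            raise ValueError(
                f"cannot standardize zero-variance variable(s): {zero}"
            )
        params = pd.DataFrame(
            {"mean": mean, "sd": sd}, index=list(table.panel.names)
        )
    else:
        params = params.loc[list(table.panel.names)]
        mean = params["mean"].to_numpy()
        sd = params["sd"].to_numpy()
    z = (x - mean) / sd
    df = table.data.copy()
    df.loc[:, list(table.panel.names)] = z
    return ObservationTable(df, table.panel), params


# Separation geometry --------------------------------------------------------


def sq_mahalanobis(mu_a: np.ndarray, mu_b: np.ndarray, S: np.ndarray) -> float:
    """Squared Mahalanobis distance (mu_a - mu_b)' S^-1 (mu_a - mu_b)."""
    d = np.asarray(mu_a, dtype=float) - np.asarray(mu_b, dtype=float)
    S = np.asarray(S, dtype=float)
    try:
        c = np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "reference covariance is singular or not positive definite "
            f"(condition number ~{np.linalg.cond(S):.2e})"
        ) from exc
    w = np.linalg.solve(c, d)
    return float(w @ w)


def pooled_covariance(sigset: SignatureSet) -> np.ndarray:
    """Sample-size-weighted average of the source covariances.

    Uses equal weights when sample sizes are unavailable (all zero).
    """
    ns = np.array([s.n for s in sigset.signatures], dtype=float)
    if ns.sum() <= 0:
        ns = np.ones_like(ns)
    w = ns / ns.sum()
    return np.einsum("k,kij->ij", w, np.array([s.cov for s in sigset.signatures]))


def _reference_cov(sigset: SignatureSet, reference_cov) -> np.ndarray:
    if isinstance(reference_cov, str):
        if reference_cov != "pooled":
            raise ValueError(f"unknown reference covariance {reference_cov!r}")
        return pooled_covariance(sigset)
    return np.asarray(reference_cov, dtype=float)


def average_separation(sigset: SignatureSet, reference_cov="pooled") -> float:
    """Average squared Mahalanobis distance among the K centroids.

    Unweighted mean over all K(K-1)/2 unordered centroid pairs, with a
    single reference covariance: by default the pooled source covariance,
    or an explicit J x J matrix.
    """
    if sigset.K < 2:
        raise ValueError("average_separation needs at least 2 signatures")
    S = _reference_cov(sigset, reference_cov)
    mus = sigset.centroids()
    total = 0.0
    npairs = 0
    for a in range(sigset.K):
        for b in range(a + 1, sigset.K):
            total += sq_mahalanobis(mus[a], mus[b], S)
            npairs += 1
    return total / npairs


def effective_sd(cov: np.ndarray, J: int | None = None) -> float:
    """Effective standard deviation det(cov)^(1/2J) of a covariance matrix.

    A scalar index of multivariate spread: the geometric mean of the
    per-axis standard deviations along the principal axes.
    """
    cov = np.asarray(cov, dtype=float)
    if J is None:
        J = cov.shape[0]
    lam = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    tol = max(abs(lam[-1]), 1.0) * 1e-10
    if lam[0] < -tol:
        raise ValueError(
            f"covariance has a negative eigenvalue ({lam[0]:.3e}) beyond "
            "numerical tolerance")
    lam = np.clip(lam, 0.0, None)
    if lam[0] == 0.0:
        return 0.0
    return float(np.exp(np.sum(np.log(lam)) / (2 * J)))


def rescale_separation(
    sigset: SignatureSet, target: float, reference_cov="pooled"
) -> SignatureSet:
    """Shrink/expand centroids about their grand mean to a target separation.

    Centroids move along mu_k <- mu_bar + c (mu_k - mu_bar) with
    c = sqrt(target / current); covariances are untouched, so every
    pairwise squared Mahalanobis distance scales by exactly target/current.
    """
    if target <= 0:
        raise ValueError("target separation must be > 0")
    current = average_separation(sigset, reference_cov)
    if current <= 0:
        raise ValueError("cannot rescale coincident centroids (current separation 0)")
    c = float(np.sqrt(target / current))
    mu_bar = sigset.centroids().mean(axis=0)
    new_sigs = tuple(
        replace(s, mu=mu_bar + c * (s.mu - mu_bar)) for s in sigset.signatures
    )
    return replace(sigset, signatures=new_sigs)


# Plain-text I/O -------------------------------------------------------------


def read_observations(path: str | Path, panel: ElementPanel | None = None,
                      sep: str | None = None) -> ObservationTable:
    """Read an observation CSV/TSV (header: specimen_id, cohort, source, ratios)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip",
                     dtype={"specimen_id": str, "cohort": str,
                            "source": str})
    if panel is None:
        ratio_cols = [c for c in df.columns if c not in ID_COLUMNS]
        panel = ElementPanel(tuple(ratio_cols))
    return ObservationTable(df, panel)


def write_observations(table: ObservationTable, path: str | Path) -> None:
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    table.data.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_signature_set(sigset: SignatureSet, means_path: str | Path,
                        covs_path: str | Path) -> None:
    """Write signatures as a means CSV plus a flattened-covariance CSV.

    The means file has columns source_id, cohort_id, n, mu_1..mu_J; the
    companion file stores each covariance row-major under headers cov_i_j.
    Full double precision is kept so the round trip is lossless.
    """
    J = sigset.panel.J
    mu_rows, cov_rows = [], []
    for s in sigset.signatures:
        mu_rows.append({"source_id": s.source_id, "cohort_id": s.cohort_id,
                        "n": s.n,
                        **{f"mu_{j + 1}": s.mu[j] for j in range(J)}})
        cov_rows.append({"source_id": s.source_id, "cohort_id": s.cohort_id,
                         **{f"cov_{i + 1}_{j + 1}": s.cov[i, j]
                            for i in range(J) for j in range(J)}})
    pd.DataFrame(mu_rows).to_csv(means_path, index=False, float_format="%.17g")
    pd.DataFrame(cov_rows).to_csv(covs_path, index=False, float_format="%.17g")


def read_signature_set(means_path: str | Path, covs_path: str | Path,
                       panel: ElementPanel | None = None) -> SignatureSet:
    mus = pd.read_csv(means_path, float_precision="round_trip",
                      dtype={"source_id": str, "cohort_id": str})
    covs = pd.read_csv(covs_path, float_precision="round_trip",
                       dtype={"source_id": str, "cohort_id": str})
    J = sum(c.startswith("mu_") for c in mus.columns)
    if panel is None:
        panel = ElementPanel(tuple(f"v{j + 1}" for j in range(J))) \
            if J != len(DEFAULT_ELEMENTS) else ElementPanel()
    sigs = []
    covs = covs.set_index("source_id")
    for _, row in mus.iterrows():
        mu = row[[f"mu_{j + 1}" for j in range(J)]].to_numpy(dtype=float)
        crow = covs.loc[row["source_id"]]
        cov = np.array([[crow[f"cov_{i + 1}_{j + 1}"] for j in range(J)]
                        for i in range(J)], dtype=float)
        sigs.append(NurserySignature(row["source_id"], row["cohort_id"],
                                     mu, cov, int(row["n"])))
    return SignatureSet(mus["cohort_id"].iloc[0], panel, tuple(sigs))
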