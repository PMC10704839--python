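"""Non-coding background model.

Each gene's raw background is its non-coding mutation count and coverage
summed over patients and categories.  Covariate-nearest neighbors whose
non-coding rate is compatible with the target's (beta-binomial
predictive check) are pooled into a "bagel"; cohort-level marginal
relative rates per patient and per category then scale the pooled
background into per-(gene, category, patient) effective counts, from
which the probabilities of observing 0/1/2+ target-zone mutations are
computed with a beta-binomial predictive distribution.

The marginal-rate and bagel-qualification conventions (ratio-of-rates
marginals; +1-pseudocount predictive; greedy nearest-first
qualification with stop-at-first-failure) follow the MutSigCV-style
design and are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.special import betaln, gammaln, logsumexp

from synsig.tensors import NONCODING, TOTAL, CountTensor, CoverageTensor

log = logging.getLogger(__name__)

DEFAULT_QUALIFICATION_THRESHOLD = 0.05
DEFAULT_MAX_NEIGHBORS = 50


@dataclass
class GeneBackground:
    """Raw and bagel-aggregated non-coding background for one gene."""

    gene: str
    n_bkgd: float
    N_bkgd: float
    bagel: list[str] = field(default_factory=list)
    x: float = 0.0
    X: float = 0.0


@dataclass
class CohortMarginals:
    """Relative rate factors per category (1..7) and per patient."""

    rho_c: np.ndarray  # shape (7,)
    rho_p: np.ndarray  # shape (n_patients,)
    patients: list[str]


def apply_synonyms(covariates: pd.DataFrame, synonyms: dict[str, str]) -> pd.DataFrame:
    """Rename covariate rows via an old_name -> new_name mapping."""
    renamed = covariates.rename(index=synonyms)
    return renamed[~renamed.index.duplicated(keep="first")]


def covariate_distance_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances on per-covariate standardized values.

    Missing values are imputed to the covariate mean (flagged in the
    log).  Raises if a covariate column is entirely missing.
    """
    if len(covariates) < 2:
        raise ValueError("need at least 2 genes for a distance matrix")
    values = covariates.astype(float).copy()
    for col in values.columns:
        if values[col].isna().all():
            raise ValueError(f"covariate column {col!r} is entirely missing")
        n_missing = int(values[col].isna().sum())
        if n_missing:
            log.info("covariate %s: imputed %d missing values to the mean", col, n_missing)
            values[col] = values[col].fillna(values[col].mean())
        sd = values[col].std(ddof=0)
        values[col] = (values[col] - values[col].mean()) / (sd if sd > 0 else 1.0)
    dist = squareform(pdist(values.to_numpy(), metric="euclidean"))
    return pd.DataFrame(dist, index=covariates.index, columns=covariates.index)


def raw_background(
    counts: CountTensor, coverage: CoverageTensor, gene: str
) -> tuple[float, float]:
    """(n_bkgd, N_bkgd): total-slot non-coding count/coverage over patients."""
    if gene not in counts.gene_index or gene not in coverage.gene_index:
        raise KeyError(f"gene {gene!r} absent from tensors")
    n = float(counts.gene(gene)[TOTAL, :, NONCODING].sum())
    N = float(coverage.gene(gene)[TOTAL, :, NONCODING].sum())
    return n, N


def beta_binomial_logpmf(k, N, x, X):
    """log H(k, N, x, X) with +1 pseudocounts, fully vectorized.

    H(k,N,x,X) = C(N,k) * B(k+x+1, N-k+X-x+1) / B(x+1, X-x+1), the
    predictive probability of k events in N sites when x events were
    seen in X background sites.
    """
    k = np.asarray(k, dtype=float)
    N = np.asarray(N, dtype=float)
    x = np.asarray(x, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(k < 0) or np.any(N < 0) or np.any(x < 0) or np.any(X < x):
        raise ValueError("negative inputs (or x > X) to beta-binomial pmf")
    return (
        gammaln(N + 1)
        - gammaln(k + 1)
        - gammaln(N - k + 1)
        + betaln(k + x + 1, N - k + X - x + 1)
        - betaln(x + 1, X - x + 1)
    )


def beta_binomial_pmf(k, N, x, X):
    """H(k, N, x, X); see :func:`beta_binomial_logpmf`."""
    return np.exp(beta_binomial_logpmf(k, N, x, X))


def _beta_binomial_logcdf(k: int, N: int, x: float, X: float) -> float:
    """log P(K <= k) by direct summation (k is assumed modest)."""
    if k >= N:
        return 0.0
    ks = np.arange(0, k + 1, dtype=float)
    return float(logsumexp(beta_binomial_logpmf(ks, float(N), x, X)))


def qualify_neighbor(
    target: tuple[float, float],
    neighbor: tuple[float, float],
    threshold: float = DEFAULT_QUALIFICATION_THRESHOLD,
) -> bool:
    """Beta-binomial compatibility check between two (n, N) backgrounds.

    The neighbor's count is referred to the predictive distribution
    BetaBinomial(N_neighbor; n_target+1, N_target-n_target+1); it
    qualifies iff the two-sided predictive tail probability is at least
    ``threshold``.  A neighbor with no coverage never qualifies.
    """
    n_t, N_t = target
    n_i, N_i = neighbor
    if N_i <= 0 or N_t <= 0:
        return False
    N_int = int(round(N_i))
    k = int(round(n_i))
    k = min(k, N_int)
    lo = np.exp(_beta_binomial_logcdf(k, N_int, n_t, N_t))
    hi = 1.0 if k == 0 else 1.0 - np.exp(_beta_binomial_logcdf(k - 1, N_int, n_t, N_t))
    tail = 2.0 * min(lo, hi)
    return min(tail, 1.0) >= threshold


def _qualify_batch(
    target: tuple[float, float],
    neighbors: np.ndarray,
    threshold: float,
) -> np.ndarray:
    """Vectorized :func:`qualify_neighbor` over an (m, 2) array of (n, N)."""
    n_t, N_t = target
    m = len(neighbors)
    out = np.zeros(m, dtype=bool)
    if N_t <= 0 or m == 0:
        return out
    N_i = np.round(neighbors[:, 1]).astype(np.int64)
    k_i = np.minimum(np.round(neighbors[:, 0]).astype(np.int64), np.maximum(N_i, 0))
    valid = N_i > 0
    if not valid.any():
        return out
    kmax = int(k_i[valid].max())
    grid = np.arange(kmax + 1, dtype=float)
    # log pmf over the k grid for each neighbor's trial count
    logpmf = beta_binomial_logpmf(
        grid[None, :], N_i[:, None].astype(float), n_t, N_t
    )
    logpmf[grid[None, :] > N_i[:, None]] = -np.inf
    with np.errstate(divide="ignore"):
        logcdf = np.logaddexp.accumulate(logpmf, axis=1)
    rows = np.arange(m)
    lo = np.exp(logcdf[rows, np.clip(k_i, 0, kmax)])
    below = np.where(k_i > 0, np.exp(logcdf[rows, np.clip(k_i - 1, 0, kmax)]), 0.0)
    hi = 1.0 - below
    tail = np.minimum(2.0 * np.minimum(lo, hi), 1.0)
    out[valid] = tail[valid] >= threshold
    return out


def build_bagel(
    gene: str,
    distances: pd.DataFrame,
    backgrounds: dict[str, tuple[float, float]],
    qualification_threshold: float = DEFAULT_QUALIFICATION_THRESHOLD,
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
    max_coverage: float | None = None,
) -> GeneBackground:
    """Greedy nearest-first bagel construction for one gene.

    Neighbors are visited in increasing covariate distance; each
    qualifying neighbor is pooled until the first disqualification, the
    neighbor cap, or (optionally) a pooled-coverage cap.
    """
    n_g, N_g = backgrounds[gene]
    bg = GeneBackground(gene=gene, n_bkgd=n_g, N_bkgd=N_g, x=n_g, X=N_g)
    if gene not in distances.index:
        return bg
    order = distances.loc[gene].drop(labels=[gene], errors="ignore").sort_values(kind="stable")
    candidates = [nb for nb in order.index if nb in backgrounds]
    # the walk stops at the first failure, so only the nearest cap+1 matter
    candidates = candidates[: max_neighbors + 1]
    nN = np.array([backgrounds[nb] for nb in candidates], dtype=float).reshape(-1, 2)
    qualified = _qualify_batch((n_g, N_g), nN, qualification_threshold)
    for neighbor, ok, (n_i, N_i) in zip(candidates, qualified, nN):
        if len(bg.bagel) >= max_neighbors:
            break
        if max_coverage is not None and bg.X >= max_coverage:
            break
        if not ok:
            break
        bg.bagel.append(neighbor)
        bg.x += n_i
        bg.X += N_i
    return bg


def build_all_backgrounds(
    counts: CountTensor,
    coverage: CoverageTensor,
    covariates: pd.DataFrame,
    qualification_threshold: float = DEFAULT_QUALIFICATION_THRESHOLD,
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
    max_coverage: float | None = None,
) -> dict[str, GeneBackground]:
    """Raw backgrounds, distance matrix, and bagels for every gene."""
    genes = counts.genes
    raw = {g: raw_background(counts, coverage, g) for g in genes}
    cov = covariates.reindex(genes)
    distances = covariate_distance_matrix(cov)
    return {
        g: build_bagel(
            g,
            distances,
            raw,
            qualification_threshold=qualification_threshold,
            max_neighbors=max_neighbors,
            max_coverage=max_coverage,
        )
        for g in genes
    }


def compute_marginals(counts: CountTensor, coverage: CoverageTensor) -> CohortMarginals:
    """Ratio-of-rates marginal factors within one histology cohort.

    rho_c = (mutations in category c / coverage in category c) divided
    by the cohort's overall rate; rho_p analogously per patient.  All
    mutations (synonymous, non-synonymous, non-coding) and all zones'
    coverage contribute.  Category slots 1..7 are used on both axes
    (the category-7 coverage being the whole-gene coverage).
    """
    mut = counts.values[:, :7].astype(float)  # (G, 7, P, 3)
    cov6 = coverage.values[:, :6]  # substitution-category coverage only
    mut_c = mut.sum(axis=(0, 2, 3))
    cov_c = np.empty(7)
    cov_c[:6] = cov6.sum(axis=(0, 2, 3))
    cov_c[6] = cov_c[:6].sum()  # whole-gene coverage backs the indel category
    mut_p = mut.sum(axis=(0, 1, 3))
    cov_p = cov6.sum(axis=(0, 1, 3))
    C = cov_c[:6].sum()
    if C <= 0:
        raise ValueError("zero total coverage; marginals undefined")
    # the category-7 slot repeats the categories-1..6 territory, so overall
    # rates are referred to the substitution coverage to avoid double counting
    overall_c = mut_c[:6].sum() / C
    overall_p = mut_c.sum() / C
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_c = np.where(cov_c > 0, mut_c / np.where(cov_c > 0, cov_c, 1.0), 0.0)
        rho_p = np.where(cov_p > 0, mut_p / np.where(cov_p > 0, cov_p, 1.0), 0.0)
    rho_c = rho_c / overall_c if overall_c > 0 else np.ones_like(rho_c)
    rho_p = rho_p / overall_p if overall_p > 0 else np.ones_like(rho_p)
    return CohortMarginals(rho_c=rho_c, rho_p=rho_p, patients=list(counts.patients))


@dataclass
class GcpBackground:
    """Effective background count/coverage per (category, patient) for one gene."""

    gene: str
    x: np.ndarray  # (7, n_patients)
    X: float


def gcp_background(bg: GeneBackground, marginals: CohortMarginals) -> GcpBackground:
    """Scale the bagel background by the marginal rate factors.

    x_gcp = x_g * rho_c * rho_p, clamped into [0, X_g]; the coverage
    denominator stays the bagel coverage X_g.
    """
    x = bg.x * np.outer(marginals.rho_c, marginals.rho_p)
    x = np.clip(x, 0.0, bg.X if bg.X > 0 else 0.0)
    return GcpBackground(gene=bg.gene, x=x, X=bg.X)


def naive_gcp_background(
    bg: GeneBackground, global_rate: float, n_patients: int
) -> GcpBackground:
    """Deliberately naive background: one constant rate, no bagel, no marginals."""
    x = np.full((7, n_patients), global_rate * bg.N_bkgd)
    x = np.clip(x, 0.0, bg.N_bkgd if bg.N_bkgd > 0 else 0.0)
    return GcpBackground(gene=bg.gene, x=x, X=bg.N_bkgd)


def site_probabilities(
    gcp: GcpBackground, target_coverage: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P0, P1, P2+) of observing 0 / 1 / >=2 target-zone mutations.

    ``target_coverage`` is the per-(category, patient) coverage of the
    target zone (synonymous in the main mode); it is rounded to the
    nearest integer for the pmf support.  P2+ = 1 - P0 - P1, floored
    at 0.  With zero coverage the triplet is (1, 0, 0).
    """
    N = np.round(np.asarray(target_coverage, dtype=float))
    N = np.maximum(N, 0.0)
    x = np.minimum(gcp.x, gcp.X)
    X = max(gcp.X, 0.0)
    if X <= 0:
        P0 = np.ones_like(N)
        return P0, np.zeros_like(N), np.zeros_like(N)
    P0 = beta_binomial_pmf(np.zeros_like(N), N, x, X)
    P1 = np.where(N >= 1, beta_binomial_pmf(np.ones_like(N), np.maximum(N, 1.0), x, X), 0.0)
    P0 = np.where(N == 0, 1.0, P0)
    P1 = np.where(N == 0, 0.0, P1)
    P2 = 1.0 - P0 - P1
    # flooring roundoff-negative P2 must not break the sum-to-one identity
    neg = P2 < 0.0
    if np.any(neg):
        scale = np.where(neg, P0 + P1, 1.0)
        P0 = np.where(neg, P0 / scale, P0)
        P1 = np.where(neg, P1 / scale, P1)
        P2 = np.where(neg, 0.0, P2)
    return P0, P1, np.clip(P2, 0.0, 1.0)
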