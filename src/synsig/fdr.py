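"""Empirical-Bayes local FDR and Benjamini-Hochberg candidate calling.

The local FDR of a gene with p-value s is p0 * F0(s) / F(s), where F0
is a kernel-smoothed CDF of p-values from a null gene set (non-expressed
genes, FPKM < 1 in every cohort) and F is the kernel-smoothed mixture
CDF over all tested genes.  Fdr is evaluated only for genes with
p-value < 0.05.  The non-synonymous QC mode uses Benjamini-Hochberg
q-values instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from synsig.significance import GeneResult

log = logging.getLogger(__name__)

DEFAULT_P0 = 0.99
DEFAULT_P_CUTOFF = 0.05
DEFAULT_FDR_THRESHOLD = 1e-2
DEFAULT_MIN_SAMPLES = 30
#: floor (in -log10 units) for the smoothing bandwidth used in FDR fitting
DEFAULT_LOG_BANDWIDTH_FLOOR = 1.0
P_FLOOR = 1e-16


def select_null_genes(expression: pd.DataFrame, gene_set: Iterable[str]) -> list[str]:
    """Genes non-expressed (FPKM < 1) in *every* cohort, within the gene set.

    ``expression`` is a gene x cohort FPKM table.  Raises if the null
    set comes out empty (the FDR cannot be calibrated without it).
    """
    gene_set = set(gene_set)
    in_table = expression.loc[expression.index.isin(gene_set)]
    null_genes = sorted(in_table.index[(in_table < 1.0).all(axis=1)])
    if not null_genes:
        raise ValueError("no non-expressed genes available to build the FDR null set")
    log.info("null gene set: %d genes with FPKM < 1 in all cohorts", len(null_genes))
    return null_genes


def _plugin_bandwidth(values: np.ndarray, floor: float = 0.0) -> float:
    """Normal-reference plug-in bandwidth at the CDF-smoothing n^(-1/3) rate."""
    n = len(values)
    sd = float(np.std(values, ddof=0))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * scale * n ** (-1.0 / 3.0)
    return max(h, floor, 1e-12)


def kernel_cdf(
    samples: Sequence[float],
    min_samples: int = DEFAULT_MIN_SAMPLES,
    bandwidth: float | None = None,
    log_scale: bool = False,
    bandwidth_floor: float = 0.0,
    p_floor: float = P_FLOOR,
) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth Gaussian-kernel estimate of the CDF of p-values.

    The estimator is monotone non-decreasing by construction and
    evaluable at any s in [0, 1].  With ``log_scale`` the smoothing is
    applied to t = -log10(p) with reflection at t = 0, which resolves
    the extreme lower tail where candidate genes live; the raw scale is
    a plain Nadaraya-style smoothed ECDF.
    """
    values = np.asarray(list(samples), dtype=float)
    if len(values) < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {len(values)}")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("p-values must lie in [0, 1]")

    if log_scale:
        t = -np.log10(np.clip(values, p_floor, 1.0))
        h = bandwidth if bandwidth is not None else _plugin_bandwidth(t, bandwidth_floor)

        def estimator(s):
            s_arr = np.atleast_1d(np.asarray(s, dtype=float))
            ts = -np.log10(np.clip(s_arr, p_floor, 1.0))
            # P(p <= s) = P(T >= t(s)), reflected at t = 0
            surv = norm.cdf((t[None, :] - ts[:, None]) / h)
            refl = norm.cdf((-t[None, :] - ts[:, None]) / h)
            out = np.clip((surv + refl).mean(axis=1), 0.0, 1.0)
            return out if np.ndim(s) else float(out[0])

    else:
        h = bandwidth if bandwidth is not None else _plugin_bandwidth(values, bandwidth_floor)

        def estimator(s):
            s_arr = np.atleast_1d(np.asarray(s, dtype=float))
            out = norm.cdf((s_arr[:, None] - values[None, :]) / h).mean(axis=1)
            return out if np.ndim(s) else float(out[0])

    return estimator


@dataclass
class FdrModel:
    """Fitted empirical-Bayes FDR components."""

    p0: float
    null_pvalues: np.ndarray
    mixture_pvalues: np.ndarray
    F0_hat: Callable = field(repr=False, default=None)
    F_hat: Callable = field(repr=False, default=None)


def fit_fdr_model(
    mixture_pvalues: Sequence[float],
    null_pvalues: Sequence[float],
    p0: float = DEFAULT_P0,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    bandwidth_floor: float = DEFAULT_LOG_BANDWIDTH_FLOOR,
) -> FdrModel:
    """Fit F (all tested genes) and F0 (null gene set) kernel CDFs.

    Both CDFs are smoothed on the -log10 p scale with a bandwidth floor
    (default one decade) so that the estimate discriminates decades of
    significance rather than absolute p differences.
    """
    if not 0 < p0 <= 1:
        raise ValueError("p0 must be in (0, 1]")
    F_hat = kernel_cdf(
        mixture_pvalues, min_samples, log_scale=True, bandwidth_floor=bandwidth_floor
    )
    F0_hat = kernel_cdf(
        null_pvalues, min_samples, log_scale=True, bandwidth_floor=bandwidth_floor
    )
    return FdrModel(
        p0=p0,
        null_pvalues=np.asarray(list(null_pvalues), dtype=float),
        mixture_pvalues=np.asarray(list(mixture_pvalues), dtype=float),
        F0_hat=F0_hat,
        F_hat=F_hat,
    )


def bayes_fdr(
    results: Sequence[GeneResult],
    F0_hat: Callable,
    F_hat: Callable,
    p0: float = DEFAULT_P0,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> list[GeneResult]:
    """Local FDR = p0 * F0(s_i) / F(s_i) for genes with p-value < cutoff.

    Genes at or above the cutoff keep fdr = None (not evaluated).
    Values are clipped into [0, 1]; a vanishing mixture CDF yields
    fdr = 1 with a warning (no evidence either way).
    """
    for r in results:
        if r.p_value >= p_cutoff:
            r.fdr = None
            continue
        denom = float(F_hat(r.p_value))
        if denom <= 0.0:
            log.warning("gene %s: mixture CDF is 0 at p=%.3g; Fdr set to 1", r.gene, r.p_value)
            r.fdr = 1.0
            continue
        r.fdr = float(np.clip(p0 * float(F0_hat(r.p_value)) / denom, 0.0, 1.0))
    return list(results)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Standard step-up q-values (monotone-enforced)."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_candidates(
    results: Sequence[GeneResult],
    threshold: float = DEFAULT_FDR_THRESHOLD,
    exclusion: Iterable[str] = (),
    method: str = "bayes",
) -> list[GeneResult]:
    """Genes below the FDR threshold, minus the overlap-exclusion list.

    ``method='bayes'`` reads the fitted local Fdr from each result;
    ``method='bh'`` recomputes Benjamini-Hochberg q-values over the
    supplied results.  Excluded genes are dropped with a logged reason.
    """
    exclusion = set(exclusion)
    if method == "bh":
        qs = benjamini_hochberg([r.p_value for r in results])
        scored = [(r, q) for r, q in zip(results, qs)]
    elif method == "bayes":
        scored = [(r, r.fdr) for r in results]
    else:
        raise ValueError(f"unknown FDR method {method!r}")

    candidates = []
    for r, q in scored:
        if q is None or q >= threshold:
            continue
        if r.gene in exclusion:
            log.info("candidate %s dropped: on the overlap-exclusion list", r.gene)
            continue
        if method == "bh":
            r.fdr = float(q)
        candidates.append(r)
    return candidates
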