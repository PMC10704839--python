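"""Projection-convolution significance engine.

Per patient, the per-category probabilities of 0/1/2+ target-zone
mutations are projected onto 2-D outcomes (d1, d2): the priority-ranked
categories of the two most extreme mutations (0 = no mutation).  Each
outcome is scored -log10(probability) (the no-mutation outcome scores
0); the per-patient score distributions are convolved across patients
into a null score distribution, and a gene's p-value is the null mass
at scores at least as extreme as the observed summed score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

DEFAULT_BIN_WIDTH = 0.1
DEFAULT_SCORE_CAP = 250.0
DEFAULT_MAX_TOTAL_BINS = 20_000


@dataclass
class PatientProjection:
    """Projected outcome space for one patient.

    ``probs`` maps (d1, d2) -> probability, with category labels in
    cohort numbering and 0 meaning "no mutation"; ``scores`` maps the
    same outcomes to their -log10 scores ((0,0) scores exactly 0).
    """

    probs: dict[tuple[int, int], float]
    scores: dict[tuple[int, int], float]


@dataclass
class GeneResult:
    gene: str
    n_target: int
    observed_score: float
    p_value: float
    fdr: float | None = None
    cohort: str = ""


def rank_categories(P0: np.ndarray, P1: np.ndarray, P2: np.ndarray) -> np.ndarray:
    """Priority order (indices into the category axis) for one patient.

    Categories are sorted by mutation-proneness P1 + P2+ descending;
    ties break toward the lower category index.  Deterministic.
    """
    prone = np.asarray(P1) + np.asarray(P2)
    return np.lexsort((np.arange(len(prone)), -prone))


def project_2d(
    P0: np.ndarray,
    P1: np.ndarray,
    P2: np.ndarray,
    order: np.ndarray,
    labels: Sequence[int] | None = None,
    score_cap: float = DEFAULT_SCORE_CAP,
) -> PatientProjection:
    """Project independent per-category (P0, P1, P2+) onto 2-D outcomes.

    Walking categories in priority order, the first category carrying a
    mutation is d1; a 2+ event gives (d1, d1) with lower-priority
    categories marginalized, a single event gives (d1, d2) where d2 is
    the next category carrying a mutation (or 0).  Outcome probabilities
    sum to 1.  The null score boost is 0: no outcome gets an additive
    bonus.
    """
    K = len(order)
    labels = list(labels) if labels is not None else list(range(1, K + 1))
    probs: dict[tuple[int, int], float] = {}

    def add(key: tuple[int, int], value: float) -> None:
        if value > 0.0:
            probs[key] = probs.get(key, 0.0) + value

    prefix = 1.0  # P(no mutation in all higher-priority categories)
    for i in range(K):
        c = int(order[i])
        lc = labels[c]
        add((lc, lc), prefix * P2[c])
        single = prefix * P1[c]
        if single > 0.0:
            between = 1.0
            for j in range(i + 1, K):
                m = int(order[j])
                add((lc, labels[m]), single * between * (1.0 - P0[m]))
                between *= P0[m]
            add((lc, 0), single * between)
        prefix *= P0[c]
    add((0, 0), prefix)

    scores = {
        key: 0.0 if key == (0, 0) else min(-np.log10(p), score_cap)
        for key, p in probs.items()
    }
    return PatientProjection(probs=probs, scores=scores)


def observed_outcome(
    counts: np.ndarray, order: np.ndarray, labels: Sequence[int] | None = None
) -> tuple[int, int]:
    """Collapse a patient's observed per-category counts to a 2-D outcome.

    Multiplicity above 2 in the leading category collapses to the 2+
    outcome; the projection keeps only the two most extreme mutations.
    """
    labels = list(labels) if labels is not None else list(range(1, len(order) + 1))
    mutated = [int(c) for c in order if counts[int(c)] >= 1]
    if not mutated:
        return (0, 0)
    d1 = mutated[0]
    if counts[d1] >= 2:
        return (labels[d1], labels[d1])
    if len(mutated) > 1:
        return (labels[d1], labels[mutated[1]])
    return (labels[d1], 0)


def _binned(
    projection: PatientProjection, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """(bin indices, probabilities) for one patient's score distribution."""
    items = list(projection.probs.items())
    scores = np.fromiter((projection.scores[k] for k, _ in items), dtype=float, count=len(items))
    bins = np.rint(scores / bin_width).astype(np.int64)
    ps = np.fromiter((p for _, p in items), dtype=float, count=len(items))
    # merge duplicate bins
    uniq, inv = np.unique(bins, return_inverse=True)
    mass = np.zeros(len(uniq))
    np.add.at(mass, inv, ps)
    return uniq, mass


def convolve_null(
    projections: Sequence[PatientProjection],
    bin_width: float = DEFAULT_BIN_WIDTH,
    score_cap: float = DEFAULT_SCORE_CAP,
    max_total_bins: int = DEFAULT_MAX_TOTAL_BINS,
    tail_eps: float = 0.0,
) -> np.ndarray:
    """Discrete convolution of per-patient binned score distributions.

    Returns the null probability mass per score bin (bin i covers score
    i * bin_width).  Mass beyond ``max_total_bins`` is lumped into the
    final bin so total mass is conserved and tail p-values stay
    conservative.  With ``tail_eps`` > 0, support whose survival mass is
    below ``tail_eps`` is lumped into the last retained bin after each
    convolution step (p-values beyond that point collapse to ~0).
    """
    if not projections:
        raise ValueError("need at least one patient distribution")
    per_patient = []
    for proj in projections:
        per_patient.append(_binned(proj, bin_width))
    return _convolve_binned(per_patient, bin_width, score_cap, max_total_bins, tail_eps)


def _convolve_binned(
    per_patient: Sequence[tuple[np.ndarray, np.ndarray]],
    bin_width: float,
    score_cap: float,
    max_total_bins: int,
    tail_eps: float,
) -> np.ndarray:
    null = np.array([1.0])
    cap_bin = int(round(score_cap / bin_width))
    for bins, mass in per_patient:
        bins = np.minimum(bins, cap_bin)
        grown = len(null) + int(bins.max())
        if grown <= max_total_bins + 1:
            out = np.zeros(grown)
            for b, m in zip(bins, mass):
                out[b : b + len(null)] += m * null
        else:
            new_len = max_total_bins + 1
            out = np.zeros(new_len)
            for b, m in zip(bins, mass):
                end = min(len(null), new_len - b)
                if end > 0:
                    out[b : b + end] += m * null[:end]
                overflow = m * null[end:].sum()
                if overflow > 0:
                    out[-1] += overflow
        if tail_eps > 0.0 and len(out) > 1:
            sf = np.cumsum(out[::-1])[::-1]
            keep = int(np.searchsorted(-sf, -tail_eps))  # first bin with sf <= eps
            if 0 < keep < len(out):
                out[keep - 1] += sf[keep]
                out = out[:keep]
        null = out
    return null


def gene_pvalue(observed_bin: int, null: np.ndarray) -> float:
    """Null mass at bins >= the observed bin (inclusive)."""
    if observed_bin <= 0:
        return float(null.sum())
    if observed_bin >= len(null):
        return 0.0
    return float(null[observed_bin:].sum())


def score_gene(
    gene: str,
    observed_counts: np.ndarray,
    P0: np.ndarray,
    P1: np.ndarray,
    P2: np.ndarray,
    labels: Sequence[int] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    score_cap: float = DEFAULT_SCORE_CAP,
    max_total_bins: int = DEFAULT_MAX_TOTAL_BINS,
    tail_eps: float = 0.0,
    cohort: str = "",
) -> GeneResult:
    """Full per-gene significance computation.

    Parameters
    ----------
    observed_counts : (n_categories, n_patients) int array
        Observed target-zone mutation counts.
    P0, P1, P2 : (n_categories, n_patients) arrays
        Per-category/patient prior probabilities of 0 / 1 / 2+ events.
    labels : category labels for reporting (default 1..K).
    """
    K, P = observed_counts.shape
    cap_bin = int(round(score_cap / bin_width))

    orders = np.stack(
        [rank_categories(P0[:, p], P1[:, p], P2[:, p]) for p in range(P)], axis=1
    )  # (K, P), sorted-category index -> original index
    cols = np.arange(P)
    P0s = P0[orders, cols]
    P1s = P1[orders, cols]
    P2s = P2[orders, cols]
    prefix0 = np.vstack([np.ones(P), np.cumprod(P0s, axis=0)])  # (K+1, P)

    # outcome probabilities in sorted-category space
    p_null = prefix0[K]  # (P,)
    p_two = prefix0[:K] * P2s  # (K, P): 2+ event in sorted category i
    base = prefix0[:K] * P1s  # single event in i, nothing above
    p_pair = np.zeros((K, K, P))  # single in i, next mutated is j > i
    p_single = np.zeros((K, P))  # single in i, nothing else anywhere
    for i in range(K):
        between = np.ones(P)
        for j in range(i + 1, K):
            p_pair[i, j] = base[i] * between * (1.0 - P0s[j])
            between = between * P0s[j]
        p_single[i] = base[i] * between

    def to_score(prob: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            s = np.where(prob > 0.0, -np.log10(np.maximum(prob, 1e-300)), score_cap)
        return np.minimum(s, score_cap)

    s_two = to_score(p_two)
    s_single = to_score(p_single)
    s_pair = to_score(p_pair)

    # per-patient binned score distributions for the convolution
    per_patient = []
    prob_rows = [p_null[None, :], p_two, p_single]
    score_rows = [np.zeros((1, P)), s_two, s_single]
    iu = np.triu_indices(K, k=1)
    prob_rows.append(p_pair[iu[0], iu[1], :])
    score_rows.append(s_pair[iu[0], iu[1], :])
    prob_matrix = np.concatenate(prob_rows, axis=0)
    score_matrix = np.concatenate(score_rows, axis=0)
    bin_matrix = np.rint(score_matrix / bin_width).astype(np.int64)
    for p in range(P):
        live = prob_matrix[:, p] > 0.0
        per_patient.append((bin_matrix[live, p], prob_matrix[live, p]))

    # observed outcomes
    obs_total_bin = 0
    obs_score = 0.0
    counts_sorted = observed_counts[orders, cols]
    for p in range(P):
        nz = np.nonzero(counts_sorted[:, p])[0]
        if len(nz) == 0:
            continue
        i = int(nz[0])
        if counts_sorted[i, p] >= 2:
            score = float(s_two[i, p]) if p_two[i, p] > 0 else score_cap
        elif len(nz) > 1:
            j = int(nz[1])
            score = float(s_pair[i, j, p]) if p_pair[i, j, p] > 0 else score_cap
        else:
            score = float(s_single[i, p]) if p_single[i, p] > 0 else score_cap
        obs_score += score
        obs_total_bin += min(int(round(score / bin_width)), cap_bin)

    null = _convolve_binned(per_patient, bin_width, score_cap, max_total_bins, tail_eps)
    p_value = gene_pvalue(min(obs_total_bin, max_total_bins), null)
    return GeneResult(
        gene=gene,
        n_target=int(observed_counts.sum()),
        observed_score=obs_score,
        p_value=min(p_value, 1.0),
        cohort=cohort,
    )
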