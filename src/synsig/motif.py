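"""Permutation test for mutation clustering inside protein motifs.

Mutations are placed uniformly and independently (with replacement)
over the gene's coding positions; the p-value is the fraction of
permutations whose in-motif count strictly exceeds the observed count,
with no pseudocount.  Note the printed formula can legitimately return
p = 0 when the observed count is at the top of the permuted range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MotifAnnotation:
    """Motif intervals in 0-based half-open CDS nucleotide coordinates."""

    gene: str
    motif: str
    intervals: list[tuple[int, int]]

    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def validate(self, cds_length: int) -> None:
        for s, e in self.intervals:
            if not (0 <= s < e <= cds_length):
                raise ValueError(
                    f"motif {self.motif} interval [{s}, {e}) outside CDS of length {cds_length}"
                )


@dataclass
class PermResult:
    observed: int
    permuted_counts: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def motif_permutation_test(
    n_mutations: int,
    cds_length: int,
    motif: MotifAnnotation,
    observed_count: int,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermResult:
    """Randomization test of in-motif mutation enrichment.

    p = #{permutations with in-motif count > observed} / n_perm.
    Deterministic for a fixed seed.
    """
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    motif.validate(cds_length)

    in_motif = np.zeros(cds_length, dtype=bool)
    for s, e in motif.intervals:
        in_motif[s:e] = True

    rng = np.random.default_rng(seed)
    placements = rng.integers(0, cds_length, size=(n_perm, n_mutations))
    counts = in_motif[placements].sum(axis=1)
    p_value = float(np.count_nonzero(counts > observed_count)) / n_perm
    return PermResult(
        observed=observed_count,
        permuted_counts=counts,
        p_value=p_value,
        n_perm=n_perm,
        seed=seed,
    )


def read_motif_annotations(stream) -> list[MotifAnnotation]:
    """Read a motif TSV: gene, motif, start, end (0-based half-open CDS nt)."""
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("gene\t"):
            continue
        gene, motif, start, end = line.split("\t")[:4]
        grouped.setdefault((gene, motif), []).append((int(start), int(end)))
    return [
        MotifAnnotation(gene=g, motif=m, intervals=sorted(ivals))
        for (g, m), ivals in sorted(grouped.items())
    ]
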