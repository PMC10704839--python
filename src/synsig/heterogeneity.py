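"""Cohort heterogeneity descriptives.

Per-patient synonymous mutation rates (per Mbp of covered synonymous
site), category composition fractions, and sliding-window chromosome
mutation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from synsig.tensors import SYN, CoverageTensor

#: substitute rate (per Mbp) for patients with zero synonymous mutations
ZERO_COUNT_RATE = 0.01

MBP = 1_000_000


@dataclass
class PatientRate:
    patient: str
    count: int
    mbp: float
    rate: float
    fractions: np.ndarray | None  # categories 1..6; None when count == 0


def synonymous_sites_mbp(coverage: CoverageTensor) -> dict[str, float]:
    """Covered synonymous site megabases per patient.

    Every (position, alt) synonymous entry contributes 1/3 bp; summing
    the synonymous-zone total slot over genes gives the per-patient
    synonymous territory in bp, divided by 1e6.
    """
    per_patient = coverage.values[:, 7, :, SYN].sum(axis=0) / MBP
    return dict(zip(coverage.patients, per_patient))


def patient_synonymous_rate(count: int, mbp: float) -> float:
    """Synonymous mutations per Mbp; zero-count patients get 0.01/Mbp."""
    if mbp <= 0:
        raise ValueError("undefined rate: no covered synonymous sites")
    if count == 0:
        return ZERO_COUNT_RATE
    return count / mbp


def category_fractions(category_counts: np.ndarray) -> np.ndarray | None:
    """Counts over categories 1..6 scaled to fractions (None if empty)."""
    counts = np.asarray(category_counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def patient_rates(counts, coverage: CoverageTensor) -> list[PatientRate]:
    """Fig-1-style per-patient rate table from cohort tensors."""
    mbps = synonymous_sites_mbp(coverage)
    out = []
    for pi, patient in enumerate(counts.patients):
        per_cat = counts.values[:, :6, pi, SYN].sum(axis=0)
        n = int(per_cat.sum())
        out.append(
            PatientRate(
                patient=patient,
                count=n,
                mbp=mbps[patient],
                rate=patient_synonymous_rate(n, mbps[patient]),
                fractions=category_fractions(per_cat),
            )
        )
    return out


def sliding_window_profile(
    positions: np.ndarray,
    chrom_length: int,
    n_patients: int,
    window: int = MBP,
) -> np.ndarray:
    """Cohort-average mutation count in a window sliding over each base.

    The value at offset ``s`` is the number of mutations in the
    half-open window [s, s + window) divided by the cohort size,
    computed with prefix sums (linear in chromosome length plus
    mutation count).
    """
    if n_patients <= 0:
        raise ValueError("cohort must contain at least one patient")
    per_base = np.bincount(
        np.asarray(positions, dtype=np.int64), minlength=chrom_length
    ).astype(float)
    prefix = np.concatenate(([0.0], np.cumsum(per_base)))
    starts = np.arange(chrom_length)
    ends = np.minimum(starts + window, chrom_length)
    return (prefix[ends] - prefix[starts]) / n_patients


def write_bedgraph(profile: np.ndarray, chrom: str, stream) -> None:
    """Run-length-compressed bedGraph export of a windowed profile."""
    if len(profile) == 0:
        return
    change = np.nonzero(np.diff(profile))[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(profile)]))
    for s, e in zip(starts, ends):
        value = profile[s]
        if value != 0:
            stream.write(f"{chrom}\t{s}\t{e}\t{value:.6g}\n")
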