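"""Shared count/coverage cube structures.

Both mutation counts and site coverage are stored as dense 4-D cubes
indexed by (gene, category slot, patient, zone).  Category slots 0..6
hold categories 1..7; slot 7 is the cross-category total.  For mutation
counts the total is the sum over categories 1..7; for coverage both the
category-7 slot (indels cover the whole gene) and the total slot equal
the sum over categories 1..6.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

#: zone axis order
ZONE_NAMES = ("synonymous", "nonsynonymous", "noncoding")
SYN, NONSYN, NONCODING = 0, 1, 2

N_CATEGORIES = 7
#: index of the cross-category total slot on the category axis
TOTAL = 7
N_CATEGORY_SLOTS = 8


class _Cube:
    """Dense (gene, category slot, patient, zone) array with name lookups."""

    def __init__(self, genes: Sequence[str], patients: Sequence[str], dtype) -> None:
        self.genes = list(genes)
        self.patients = list(patients)
        self.gene_index = {g: i for i, g in enumerate(self.genes)}
        self.patient_index = {p: i for i, p in enumerate(self.patients)}
        if len(self.gene_index) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(self.patient_index) != len(self.patients):
            raise ValueError("duplicate patient identifiers")
        self.values = np.zeros(
            (len(self.genes), N_CATEGORY_SLOTS, len(self.patients), 3), dtype=dtype
        )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def gene(self, name: str) -> np.ndarray:
        """Slice for one gene: shape (category slots, patients, zones)."""
        return self.values[self.gene_index[name]]

    def subset_patients(self, keep: Iterable[str]) -> "_Cube":
        """New cube restricted to ``keep`` (order preserved)."""
        keep = [p for p in keep if p in self.patient_index]
        out = type(self)(self.genes, keep)
        idx = [self.patient_index[p] for p in keep]
        out.values = self.values[:, :, idx, :].copy()
        return out


class CountTensor(_Cube):
    """Integer mutation counts per (gene, category, patient, zone)."""

    def __init__(self, genes: Sequence[str], patients: Sequence[str]) -> None:
        super().__init__(genes, patients, np.int64)

    def finalize(self) -> "CountTensor":
        """Populate the total slot as the sum over categories 1..7."""
        self.values[:, TOTAL] = self.values[:, :N_CATEGORIES].sum(axis=1)
        return self


class CoverageTensor(_Cube):
    """Fractional site coverage (thirds) per (gene, category, patient, zone)."""

    def __init__(self, genes: Sequence[str], patients: Sequence[str]) -> None:
        super().__init__(genes, patients, np.float64)

    def finalize(self) -> "CoverageTensor":
        """Set the category-7 and total slots to the sum of categories 1..6."""
        six = self.values[:, : N_CATEGORIES - 1].sum(axis=1)
        self.values[:, N_CATEGORIES - 1] = six
        self.values[:, TOTAL] = six
        return self
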