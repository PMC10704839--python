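"""WIG coverage masks and the 21-bin per-gene coverage structure.

Each covered genomic position counts as one site split into thirds, one
third per alternate allele, credited to the (zone, category) bin of that
allele's consequence.  A gene therefore has 3 zones x 6 substitution
categories = 18 base bins plus the 3 category-7 (whole-gene) bins.
Positions not reported in a WIG file are treated as fully covered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from synsig.genome import SiteEffectTable, normalize_chrom
from synsig.tensors import N_CATEGORIES, CoverageTensor

log = logging.getLogger(__name__)


class WigParseError(ValueError):
    """Malformed WIG step header, reported with the line number."""


@dataclass
class CoverageMask:
    """Positions *known uncovered* per chromosome, as sorted intervals.

    The mask is stored as the complement of coverage because unreported
    positions count as covered: only positions whose reported value
    fails the covered-threshold are recorded.
    """

    uncovered: dict[str, np.ndarray] = field(default_factory=dict)
    # each value: (n, 2) int64 array of disjoint sorted [start, end) intervals

    def is_covered(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean coverage for an array of positions (vectorized)."""
        ivals = self.uncovered.get(normalize_chrom(chrom))
        if ivals is None or len(ivals) == 0:
            return np.ones(len(positions), dtype=bool)
        idx = np.searchsorted(ivals[:, 0], positions, side="right") - 1
        inside = idx >= 0
        inside[inside] &= positions[inside] < ivals[idx[inside], 1]
        return ~inside


def _runs_to_intervals(positions: np.ndarray) -> np.ndarray:
    """Collapse a sorted unique position array into [start, end) runs."""
    if len(positions) == 0:
        return np.empty((0, 2), dtype=np.int64)
    breaks = np.nonzero(np.diff(positions) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(positions) - 1]))
    return np.stack([positions[starts], positions[ends] + 1], axis=1)


def parse_wig(stream: Iterable[str] | TextIO, covered_threshold: float = 0.0) -> CoverageMask:
    """Parse fixedStep/variableStep WIG into a :class:`CoverageMask`.

    Positions with value > ``covered_threshold`` are covered.  WIG
    coordinates are 1-based and converted to 0-based internally.  Only
    reported-but-failing positions enter the mask; everything else is
    covered by default.
    """
    uncovered: dict[str, list[int]] = {}
    mode = None
    chrom = ""
    pos = 0  # next 0-based position (fixedStep)
    step = 1
    span = 1

    def header_params(fields: list[str], lineno: int) -> dict[str, str]:
        params = {}
        for f in fields[1:]:
            if "=" not in f:
                raise WigParseError(f"line {lineno}: malformed parameter {f!r}")
            k, _, v = f.partition("=")
            params[k] = v
        return params

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if fields[0] == "fixedStep":
            params = header_params(fields, lineno)
            try:
                chrom = normalize_chrom(params["chrom"])
                pos = int(params["start"]) - 1
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
            except (KeyError, ValueError) as exc:
                raise WigParseError(f"line {lineno}: bad fixedStep header") from exc
            mode = "fixed"
        elif fields[0] == "variableStep":
            params = header_params(fields, lineno)
            try:
                chrom = normalize_chrom(params["chrom"])
                span = int(params.get("span", 1))
            except (KeyError, ValueError) as exc:
                raise WigParseError(f"line {lineno}: bad variableStep header") from exc
            mode = "variable"
        elif mode == "fixed":
            try:
                value = float(fields[0])
            except ValueError as exc:
                raise WigParseError(f"line {lineno}: expected a numeric value") from exc
            if not value > covered_threshold:
                uncovered.setdefault(chrom, []).extend(range(pos, pos + span))
            pos += step
        elif mode == "variable":
            if len(fields) != 2:
                raise WigParseError(f"line {lineno}: variableStep rows need 2 fields")
            try:
                p = int(fields[0]) - 1
                value = float(fields[1])
            except ValueError as exc:
                raise WigParseError(f"line {lineno}: bad variableStep row") from exc
            if not value > covered_threshold:
                uncovered.setdefault(chrom, []).extend(range(p, p + span))
        else:
            raise WigParseError(f"line {lineno}: data before any step header")

    mask = CoverageMask()
    for c, plist in uncovered.items():
        mask.uncovered[c] = _runs_to_intervals(np.unique(np.asarray(plist, dtype=np.int64)))
    return mask


def compute_patient_coverage(
    masks: Mapping[str, CoverageMask | None],
    site_effects: SiteEffectTable,
    patients: Sequence[str] | None = None,
) -> CoverageTensor:
    """Fold per-patient coverage masks over the site effect table.

    ``masks`` maps patient -> CoverageMask (or None: no WIG file at all,
    treated as fully covered with a warning).  Each covered entry adds
    1/3 to its (gene, category, zone) bin; the category-7 and total
    slots are the sums over categories 1..6.
    """
    patients = list(patients) if patients is not None else sorted(masks)
    genes = site_effects.gene_ids()
    tensor = CoverageTensor(genes, patients)
    third = 1.0 / 3.0
    for pi, patient in enumerate(patients):
        mask = masks.get(patient)
        if mask is None:
            log.warning("patient %s has no coverage file; assuming full coverage", patient)
        for gid in genes:
            gs = site_effects[gid]
            gi = tensor.gene_index[gid]
            if mask is None:
                covered = np.ones(len(gs.positions), dtype=bool)
            else:
                covered = mask.is_covered(gs.chrom, gs.positions)
            if not covered.any():
                continue
            zones = gs.zones[covered]
            cats = gs.categories[covered].astype(np.int64)
            flat = (cats - 1) * 3 + zones
            binned = np.bincount(flat, minlength=(N_CATEGORIES - 1) * 3).astype(np.float64)
            tensor.values[gi, : N_CATEGORIES - 1, pi, :] += (
                binned.reshape(N_CATEGORIES - 1, 3) * third
            )
    return tensor.finalize()
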