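"""MAF-style variant ingestion, category/zone assignment, and filters.

Seven mutation categories: 1..6 for single-base substitutions by
(CpG status, C:G vs A:T pair, transition vs transversion) and 7 for
indel/null mutations.  Zones: synonymous, nonsynonymous, noncoding
(intron/UTR), or excluded (not transcribed).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from synsig.genome import BASES, SiteEffectTable, categorize_snv, normalize_chrom
from synsig.tensors import NONCODING, NONSYN, SYN, CountTensor

log = logging.getLogger(__name__)

ZONE_EXCLUDED = -1
CATEGORY_INDEL = 7

#: Variant_Classification values treated as null-type (category 7)
NULL_CLASSIFICATIONS = {
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Splice_Site",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
}

DEFAULT_HYPERMUTATOR_THRESHOLD = 50_000


@dataclass
class MafDialect:
    """Column-name configuration with PCAWG/TCGA defaults.

    Positions in the file are 1-based; they are converted to the
    internal 0-based convention on read.
    """

    gene: str = "Hugo_Symbol"
    chrom: str = "Chromosome"
    position: str = "Start_position"
    ref: str = "Reference_Allele"
    alt: str = "Tumor_Seq_Allele2"
    patient: str = "Tumor_Sample_Barcode"
    classification: str = "Variant_Classification"

    def required(self) -> list[str]:
        return [self.gene, self.chrom, self.position, self.ref, self.alt, self.patient]


class MafConfigError(ValueError):
    """A mandatory column is missing from the MAF header."""


@dataclass
class MutationRecord:
    patient_id: str
    gene_id: str
    chrom: str
    position: int  # 0-based
    ref: str
    alt: str
    classification: str = ""
    zone: int | None = None  # SYN / NONSYN / NONCODING / ZONE_EXCLUDED
    category: int | None = None  # 1..7
    unmapped: bool = False

    @property
    def is_indel(self) -> bool:
        return (
            self.ref == "-"
            or self.alt == "-"
            or len(self.ref) != 1
            or len(self.alt) != 1
            or self.ref.upper() not in BASES
            or self.alt.upper() not in BASES
        )


def read_maf(
    stream: Iterable[str] | TextIO,
    dialect: MafDialect | None = None,
    known_genes: set[str] | None = None,
) -> list[MutationRecord]:
    """Parse a tab-delimited MAF-style file into records.

    Rows whose gene is not in ``known_genes`` (when given) are retained
    but flagged ``unmapped``; multi-allelic alt fields (comma-separated)
    are split into one record per alternate allele.
    """
    dialect = dialect or MafDialect()
    reader = csv.DictReader(stream, delimiter="\t")
    if reader.fieldnames is None:
        return []
    missing = [c for c in dialect.required() if c not in reader.fieldnames]
    if missing:
        raise MafConfigError(f"MAF is missing mandatory columns: {missing}")
    has_class = dialect.classification in reader.fieldnames

    records: list[MutationRecord] = []
    for row in reader:
        gene = row[dialect.gene]
        alts = [a for a in row[dialect.alt].split(",") if a]
        for alt in alts:
            rec = MutationRecord(
                patient_id=row[dialect.patient],
                gene_id=gene,
                chrom=normalize_chrom(row[dialect.chrom]),
                position=int(row[dialect.position]) - 1,
                ref=row[dialect.ref].upper(),
                alt=alt.upper(),
                classification=row[dialect.classification] if has_class else "",
            )
            rec.unmapped = known_genes is not None and gene not in known_genes
            records.append(rec)
    return records


def categorize_mutation(ref: str, alt: str, context: str = "", classification: str = "") -> int:
    """Category 1..6 for SNVs, 7 for indels and null-type mutations."""
    if classification in NULL_CLASSIFICATIONS:
        return CATEGORY_INDEL
    if (
        ref == "-"
        or alt == "-"
        or len(ref) != 1
        or len(alt) != 1
        or ref.upper() not in BASES
        or alt.upper() not in BASES
    ):
        return CATEGORY_INDEL
    return categorize_snv(ref, alt, context)


def annotate_mutations(
    records: Sequence[MutationRecord],
    site_effects: SiteEffectTable,
) -> list[MutationRecord]:
    """Assign zone and category to each record in place.

    SNV zone/category come from the site effect table of the record's
    gene.  Indel/null records get category 7 and a position-level zone.
    Records outside their gene's transcript span (or with unknown genes)
    are marked excluded.
    """
    out = []
    for rec in records:
        if rec.unmapped or rec.gene_id not in site_effects:
            rec.zone = ZONE_EXCLUDED
            out.append(rec)
            continue
        gs = site_effects[rec.gene_id]
        if rec.is_indel or rec.classification in NULL_CLASSIFICATIONS:
            rec.category = CATEGORY_INDEL
            zone = gs.position_zone(rec.position)
            rec.zone = NONCODING if zone == NONCODING else (
                NONSYN if zone is not None else ZONE_EXCLUDED
            )
        else:
            hit = gs.lookup(rec.position, rec.alt)
            if hit is None:
                rec.zone = ZONE_EXCLUDED
            else:
                rec.zone, rec.category = hit
        out.append(rec)
    return out


def filter_hypermutators(
    patients: Sequence[str],
    mutations: Sequence[MutationRecord],
    threshold: int = DEFAULT_HYPERMUTATOR_THRESHOLD,
) -> tuple[list[str], list[tuple[str, int]]]:
    """Drop patients with total mutation count strictly above ``threshold``.

    All mutation rows are counted, regardless of type or zone (logged
    choice; the threshold's basis is not further specified).

    Returns (retained patients, [(excluded patient, count), ...]).
    """
    counts: dict[str, int] = {p: 0 for p in patients}
    for rec in mutations:
        if rec.patient_id in counts:
            counts[rec.patient_id] += 1
    excluded = [(p, c) for p, c in counts.items() if c > threshold]
    retained = [p for p in patients if counts[p] <= threshold]
    for p, c in excluded:
        log.info("patient %s excluded as hypermutator (%d mutations)", p, c)
    return retained, excluded


def filter_nontranscribed(
    mutations: Sequence[MutationRecord], site_effects: SiteEffectTable
) -> list[MutationRecord]:
    """Keep only mutations inside an analyzed gene's transcript span.

    Intergenic / promoter / up- and downstream mutations have no
    transcribed-zone assignment and are dropped (their records keep
    zone=excluded for audit).
    """
    kept = []
    for rec in mutations:
        if rec.zone in (SYN, NONSYN, NONCODING):
            kept.append(rec)
    n_dropped = len(mutations) - len(kept)
    if n_dropped:
        log.info("dropped %d mutations outside transcribed regions", n_dropped)
    return kept


def build_count_tensor(
    mutations: Sequence[MutationRecord],
    genes: Sequence[str],
    patients: Sequence[str],
) -> CountTensor:
    """Aggregate annotated mutations into the (gene, category, patient, zone) cube."""
    tensor = CountTensor(genes, patients)
    for rec in mutations:
        if rec.zone not in (SYN, NONSYN, NONCODING) or rec.category is None:
            continue
        gi = tensor.gene_index.get(rec.gene_id)
        pi = tensor.patient_index.get(rec.patient_id)
        if gi is None or pi is None:
            continue
        tensor.values[gi, rec.category - 1, pi, rec.zone] += 1
    return tensor.finalize()
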