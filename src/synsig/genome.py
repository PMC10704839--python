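"""Gene models and the per-site effect table.

Builds the analyzable gene set from a Gencode-v19-dialect GTF (KNOWN,
protein_coding genes; principal transcript if supplied, else longest)
and enumerates, for every genomic position of every gene and every
alternate allele, the effect zone (synonymous / nonsynonymous /
noncoding) and mutation category (1..6).  Each (position, alt) entry
carries weight 1/3 site.

All internal coordinates are 0-based half-open; GTF input is converted
from 1-based inclusive on read.  Chromosome names are normalized by
stripping a leading ``chr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from Bio.Data import CodonTable

from synsig.tensors import SYN, NONSYN, NONCODING

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table.get(codon, "X")


def normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq))


class GtfParseError(ValueError):
    """Malformed GTF input, reported with the offending line number."""


@dataclass
class GeneModel:
    """One gene reduced to a single analyzed transcript.

    Interval lists are 0-based half-open genomic coordinates, sorted,
    and mutually disjoint across the three zones.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcript_id: str
    coding_intervals: list[tuple[int, int]]
    intron_intervals: list[tuple[int, int]]
    utr_intervals: list[tuple[int, int]]

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.coding_intervals)

    @property
    def span(self) -> tuple[int, int]:
        ivals = self.coding_intervals + self.intron_intervals + self.utr_intervals
        return min(s for s, _ in ivals), max(e for _, e in ivals)

    def territory(self) -> int:
        """Total analyzed length (coding + intron + UTR)."""
        return sum(
            e - s
            for s, e in self.coding_intervals + self.intron_intervals + self.utr_intervals
        )


def _parse_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_gtf_records(stream: Iterable[str]):
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        chrom, _source, feature, start, end, _score, strand, frame, attrs = fields
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
        if strand not in "+-":
            raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
        yield {
            "chrom": normalize_chrom(chrom),
            "feature": feature,
            "start": start_i - 1,  # to 0-based half-open
            "end": end_i,
            "strand": strand,
            "frame": frame,
            "attrs": _parse_attributes(attrs),
        }


def _merge_sorted(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _subtract(outer: list[tuple[int, int]], inner: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set-difference of sorted disjoint interval lists."""
    result = []
    inner = sorted(inner)
    for s, e in sorted(outer):
        cur = s
        for is_, ie in inner:
            if ie <= cur or is_ >= e:
                continue
            if is_ > cur:
                result.append((cur, min(is_, e)))
            cur = max(cur, ie)
            if cur >= e:
                break
        if cur < e:
            result.append((cur, e))
    return result


def load_gene_models(
    annotation: Iterable[str] | TextIO,
    principal_transcripts: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Build one :class:`GeneModel` per KNOWN protein-coding gene.

    Parameters
    ----------
    annotation : iterable of str
        GTF lines (Gencode v19 dialect: ``gene_type``/``transcript_type``
        and ``gene_status`` attributes).
    principal_transcripts : mapping, optional
        gene_id -> transcript_id of the principal transcript.  When a
        gene's principal transcript is present in the annotation it is
        used; otherwise the longest transcript (by summed exon length)
        is chosen.

    Returns
    -------
    list of GeneModel, sorted by gene_id.  Genes without any valid
    protein-coding transcript are excluded (with a logged reason).
    """
    principal_transcripts = principal_transcripts or {}
    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}

    for rec in _read_gtf_records(annotation):
        attrs = rec["attrs"]
        feature = rec["feature"]
        if feature == "gene":
            genes[attrs["gene_id"]] = {
                "gene_name": attrs.get("gene_name", attrs["gene_id"]),
                "gene_type": attrs.get("gene_type", ""),
                "gene_status": attrs.get("gene_status", ""),
                "chrom": rec["chrom"],
                "strand": rec["strand"],
            }
        elif feature == "transcript":
            transcripts[attrs["transcript_id"]] = {
                "gene_id": attrs["gene_id"],
                "transcript_type": attrs.get("transcript_type", ""),
                "chrom": rec["chrom"],
                "strand": rec["strand"],
                "exons": [],
                "cds": [],
                "utr": [],
            }
        elif feature in ("exon", "CDS", "UTR"):
            tid = attrs.get("transcript_id")
            if tid is None:
                continue  # feature not attributable to a transcript
            if tid not in transcripts:
                # tolerate exon lines arriving before their transcript line
                transcripts[tid] = {
                    "gene_id": attrs.get("gene_id", ""),
                    "transcript_type": attrs.get("transcript_type", ""),
                    "chrom": rec["chrom"],
                    "strand": rec["strand"],
                    "exons": [],
                    "cds": [],
                    "utr": [],
                }
            slot = {"exon": "exons", "CDS": "cds", "UTR": "utr"}[feature]
            transcripts[tid][slot].append((rec["start"], rec["end"]))

    by_gene: dict[str, list[tuple[str, dict]]] = {}
    for tid, t in transcripts.items():
        by_gene.setdefault(t["gene_id"], []).append((tid, t))

    models: list[GeneModel] = []
    for gene_id, info in genes.items():
        if info["gene_status"] != "KNOWN" or info["gene_type"] != "protein_coding":
            log.debug("gene %s excluded: status/type filter", gene_id)
            continue
        candidates = [
            (tid, t)
            for tid, t in by_gene.get(gene_id, [])
            if t["transcript_type"] == "protein_coding" and t["cds"]
        ]
        if not candidates:
            log.info("gene %s excluded: no valid protein-coding transcript", gene_id)
            continue
        principal = principal_transcripts.get(gene_id)
        chosen = None
        if principal is not None:
            for tid, t in candidates:
                if tid == principal:
                    chosen = (tid, t)
                    break
        if chosen is None:
            chosen = max(
                candidates, key=lambda item: sum(e - s for s, e in item[1]["exons"])
            )
        tid, t = chosen
        cds = _merge_sorted(t["cds"])
        exons = _merge_sorted(t["exons"]) or cds
        utr = _merge_sorted(t["utr"])
        if not utr:
            utr = _subtract(exons, cds)
        span = (min(s for s, _ in exons), max(e for _, e in exons))
        introns = _subtract([span], exons)
        models.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=info["gene_name"],
                chrom=info["chrom"],
                strand=info["strand"],
                transcript_id=tid,
                coding_intervals=cds,
                intron_intervals=introns,
                utr_intervals=utr,
            )
        )
    models.sort(key=lambda m: m.gene_id)
    return models


class GenomeAccessor:
    """Uniform 0-based half-open fetch over pyfaidx.Fasta or a dict of strings."""

    def __init__(self, source) -> None:
        self._source = source
        self._keymap: dict[str, str] = {}
        keys = source.keys() if hasattr(source, "keys") else []
        for k in keys:
            self._keymap[normalize_chrom(str(k))] = str(k)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        key = self._keymap.get(normalize_chrom(chrom), chrom)
        seq = self._source[key][max(start, 0):end]
        text = seq if isinstance(seq, str) else str(seq)
        if start < 0:
            text = "N" * (-start) + text
        if len(text) < end - max(start, 0):
            text = text + "N" * (end - max(start, 0) - len(text))
        return text.upper()


def categorize_snv(ref: str, alt: str, context: str) -> int:
    """Mutation category 1..6 from ref/alt and the reference triplet.

    ``context`` is the genome forward-strand triplet centred on the
    mutated base.  Categories are defined on base-pair identity (C:G vs
    A:T) and are therefore strand-symmetric:

    1. transition at a CpG dinucleotide
    2. transversion at a CpG dinucleotide
    3. transition at C:G not in CpG
    4. transversion at C:G not in CpG
    5. transition at A:T
    6. transversion at A:T
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if context[1] != ref:
        raise ValueError(f"context {context} is not centred on ref {ref}")
    transition = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    is_ts = (ref, alt) in transition
    if ref in "CG":
        cpg = (ref == "C" and context[2] == "G") or (ref == "G" and context[0] == "C")
        if cpg:
            return 1 if is_ts else 2
        return 3 if is_ts else 4
    return 5 if is_ts else 6


@dataclass
class GeneSites:
    """All (position, alternate allele) effect entries for one gene.

    Arrays are parallel with 3 entries per analyzed position; each entry
    carries weight 1/3 site.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    positions: np.ndarray  # int64, genomic 0-based
    alts: np.ndarray  # uint8 codes into BASES (genome forward strand)
    zones: np.ndarray  # int8: SYN / NONSYN / NONCODING
    categories: np.ndarray  # int8, 1..6
    skipped_positions: list[int] = field(default_factory=list)
    span: tuple[int, int] = (0, 0)

    _lookup: dict | None = field(default=None, repr=False)

    def entry_weight(self) -> float:
        return 1.0 / 3.0

    def lookup(self, position: int, alt: str) -> tuple[int, int] | None:
        """(zone, category) for one genomic position / forward-strand alt."""
        if self._lookup is None:
            self._lookup = {
                (int(p), int(a)): (int(z), int(c))
                for p, a, z, c in zip(self.positions, self.alts, self.zones, self.categories)
            }
        code = _BASE_CODE.get(alt.upper())
        if code is None:
            return None
        return self._lookup.get((int(position), code))

    def position_zone(self, position: int) -> int | None:
        """Position-level zone: coding positions collapse to NONSYN unless
        purely looked up per-allele; noncoding positions map to NONCODING."""
        hits = [self.lookup(position, b) for b in BASES]
        hits = [h for h in hits if h is not None]
        if not hits:
            return None
        zones = {z for z, _ in hits}
        if zones == {NONCODING}:
            return NONCODING
        return SYN if zones == {SYN} else NONSYN


class SiteEffectTable:
    """Per-gene site effect entries plus a transcript-span index."""

    def __init__(self, genes: dict[str, GeneSites]) -> None:
        self.genes = genes
        self._span_index: dict[str, list[tuple[int, int, str]]] = {}
        for gid, gs in genes.items():
            self._span_index.setdefault(gs.chrom, []).append((gs.span[0], gs.span[1], gid))
        for chrom in self._span_index:
            self._span_index[chrom].sort()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneSites:
        return self.genes[gene_id]

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def genes_at(self, chrom: str, position: int) -> list[str]:
        """Genes whose transcript span contains ``position``."""
        out = []
        for start, end, gid in self._span_index.get(normalize_chrom(chrom), []):
            if start <= position < end:
                out.append(gid)
            elif start > position:
                break
        return out


def _cds_sequence(gene: GeneModel, genome: GenomeAccessor) -> tuple[str, np.ndarray]:
    """CDS-strand sequence and a parallel genomic-position array."""
    parts, pos_parts = [], []
    for s, e in gene.coding_intervals:
        parts.append(genome.fetch(gene.chrom, s, e))
        pos_parts.append(np.arange(s, e, dtype=np.int64))
    seq = "".join(parts)
    positions = np.concatenate(pos_parts) if pos_parts else np.array([], dtype=np.int64)
    if gene.strand == "-":
        seq = revcomp(seq)
        positions = positions[::-1]
    return seq, positions


def enumerate_site_effects(
    genes: Sequence[GeneModel], genome
) -> SiteEffectTable:
    """Classify every possible single-nucleotide change in every gene.

    Coding positions: each of the three alternate codons is translated
    and the change is synonymous iff the amino acid is preserved.
    Intron/UTR positions are noncoding.  The mutation category is
    evaluated on the genome forward strand (pair-symmetric).  Positions
    whose reference base is not A/C/G/T are skipped and logged.
    """
    accessor = genome if isinstance(genome, GenomeAccessor) else GenomeAccessor(genome)
    table: dict[str, GeneSites] = {}
    for gene in genes:
        positions_out: list[int] = []
        alts_out: list[int] = []
        zones_out: list[int] = []
        cats_out: list[int] = []
        skipped: list[int] = []

        def classify_position(pos: int, zone_for_alt) -> None:
            ctx = accessor.fetch(gene.chrom, pos - 1, pos + 2)
            ref = ctx[1]
            if ref not in BASES:
                skipped.append(pos)
                return
            for alt in BASES:
                if alt == ref:
                    continue
                cat = categorize_snv(ref, alt, ctx)
                positions_out.append(pos)
                alts_out.append(_BASE_CODE[alt])
                zones_out.append(zone_for_alt(pos, ref, alt))
                cats_out.append(cat)

        # coding positions: zone depends on the codon change
        cds_seq, cds_positions = _cds_sequence(gene, accessor)
        if len(cds_seq) % 3 != 0:
            log.warning(
                "gene %s: CDS length %d not a multiple of 3; trailing bases ignored",
                gene.gene_id,
                len(cds_seq),
            )
            usable = 3 * (len(cds_seq) // 3)
            cds_seq, cds_positions = cds_seq[:usable], cds_positions[:usable]
        cds_index_of = {int(p): i for i, p in enumerate(cds_positions)}

        def coding_zone(pos: int, ref: str, alt: str) -> int:
            i = cds_index_of[pos]
            # convert the forward-strand alt into CDS orientation
            alt_cds = alt if gene.strand == "+" else _COMPLEMENT[alt]
            codon_start = 3 * (i // 3)
            offset = i - codon_start
            codon = cds_seq[codon_start : codon_start + 3]
            mutated = codon[:offset] + alt_cds + codon[offset + 1 :]
            return SYN if _translate_codon(mutated) == _translate_codon(codon) else NONSYN

        for pos in cds_positions:
            classify_position(int(pos), coding_zone)
        for s, e in gene.intron_intervals + gene.utr_intervals:
            for pos in range(s, e):
                classify_position(pos, lambda *_: NONCODING)

        if skipped:
            log.info("gene %s: skipped %d positions with non-ACGT reference", gene.gene_id, len(skipped))

        table[gene.gene_id] = GeneSites(
            gene_id=gene.gene_id,
            gene_name=gene.gene_name,
            chrom=gene.chrom,
            strand=gene.strand,
            positions=np.asarray(positions_out, dtype=np.int64),
            alts=np.asarray(alts_out, dtype=np.uint8),
            zones=np.asarray(zones_out, dtype=np.int8),
            categories=np.asarray(cats_out, dtype=np.int8),
            skipped_positions=skipped,
            span=gene.span,
        )
    return SiteEffectTable(table)


def validate_gene_consistency(
    gene_sites: GeneSites,
    maf_zone_by_position: Mapping[int, int],
    coverage_zone_by_position: Mapping[int, int] | None = None,
) -> bool:
    """False iff any mutation's zone assignment disagrees between sources.

    ``maf_zone_by_position`` maps mutated genomic positions to the zone
    claimed by the variant file; the model's own position-level zone is
    the reference.  ``coverage_zone_by_position`` may supply a second
    independent zone map (e.g. from the coverage preparation); both must
    agree with the model wherever defined.
    """
    for source in (maf_zone_by_position, coverage_zone_by_position or {}):
        for pos, claimed in source.items():
            model_zone = gene_sites.position_zone(int(pos))
            if model_zone is None:
                return False
            coding_claim = claimed in (SYN, NONSYN)
            coding_model = model_zone in (SYN, NONSYN)
            if coding_claim != coding_model:
                return False
    return True
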