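"""Gene model loading and site effect enumeration."""

import numpy as np
import pytest
from Bio.Seq import Seq

from synsig.genome import (
    BASES,
    GeneModel,
    GenomeAccessor,
    GtfParseError,
    categorize_snv,
    enumerate_site_effects,
    load_gene_models,
    revcomp,
    validate_gene_consistency,
)
from synsig.tensors import NONCODING, NONSYN, SYN

ATTRS = (
    'gene_id "{g}"; transcript_id "{t}"; gene_name "{g}"; gene_type "{gt}"; '
    'gene_status "{status}"; transcript_type "{tt}";'
)


def gtf_line(feature, start, end, gene="G1", tid="T1", gt="protein_coding",
             tt="protein_coding", status="KNOWN", strand="+"):
    a = ATTRS.format(g=gene, t=tid, gt=gt, tt=tt, status=status)
    return f"chr1\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{a}"


class TestLoadGeneModels:
    def test_longest_transcript_chosen_when_no_principal(self):
        lines = [
            gtf_line("gene", 1, 3000),
            gtf_line("transcript", 1, 900, tid="T.short"),
            gtf_line("exon", 1, 900, tid="T.short"),
            gtf_line("CDS", 1, 900, tid="T.short"),
            gtf_line("transcript", 1, 1200, tid="T.long"),
            gtf_line("exon", 1, 1200, tid="T.long"),
            gtf_line("CDS", 1, 1200, tid="T.long"),
        ]
        models = load_gene_models(lines)
        assert len(models) == 1
        assert models[0].transcript_id == "T.long"

    def test_principal_transcript_wins_over_longest(self):
        lines = [
            gtf_line("gene", 1, 3000),
            gtf_line("transcript", 1, 900, tid="T.short"),
            gtf_line("exon", 1, 900, tid="T.short"),
            gtf_line("CDS", 1, 900, tid="T.short"),
            gtf_line("transcript", 1, 1200, tid="T.long"),
            gtf_line("exon", 1, 1200, tid="T.long"),
            gtf_line("CDS", 1, 1200, tid="T.long"),
        ]
        models = load_gene_models(lines, {"G1": "T.short"})
        assert models[0].transcript_id == "T.short"

    def test_pseudogene_excluded(self):
        lines = [
            gtf_line("gene", 1, 100, gt="pseudogene"),
            gtf_line("transcript", 1, 100, gt="pseudogene", tt="pseudogene"),
        ]
        assert load_gene_models(lines) == []

    def test_non_known_status_excluded(self):
        lines = [
            gtf_line("gene", 1, 100, status="NOVEL"),
            gtf_line("transcript", 1, 100, status="NOVEL"),
            gtf_line("CDS", 1, 99, status="NOVEL"),
        ]
        assert load_gene_models(lines) == []

    def test_empty_annotation(self):
        assert load_gene_models([]) == []

    def test_malformed_line_reports_lineno(self):
        with pytest.raises(GtfParseError, match="line 2"):
            load_gene_models([gtf_line("gene", 1, 100), "chr1\tonly\tthree"])

    def test_intron_and_utr_derived(self):
        lines = [
            gtf_line("gene", 1, 100),
            gtf_line("transcript", 1, 100),
            gtf_line("exon", 1, 40),
            gtf_line("exon", 61, 100),
            gtf_line("CDS", 11, 40),
            gtf_line("CDS", 61, 90),
        ]
        (model,) = load_gene_models(lines)
        assert model.intron_intervals == [(40, 60)]
        assert model.utr_intervals == [(0, 10), (90, 100)]
        assert model.coding_length == 60


class TestCategorizeSnv:
    def test_cpg_transition_is_category_1(self):
        assert categorize_snv("C", "T", "ACG") == 1

    def test_cpg_transversion_is_category_2(self):
        assert categorize_snv("C", "G", "ACG") == 2

    def test_non_cpg_cg_transition_is_category_3(self):
        assert categorize_snv("C", "T", "ACA") == 3

    def test_non_cpg_cg_transversion_is_category_4(self):
        assert categorize_snv("C", "A", "TCA") == 4

    def test_at_transition_is_category_5(self):
        assert categorize_snv("A", "G", "CAT") == 5

    def test_at_transversion_is_category_6(self):
        assert categorize_snv("T", "G", "CTT") == 6

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            categorize_snv("A", "A", "CAT")

    def test_pair_symmetry_all_192_changes(self):
        # complementing ref/alt/context must preserve the category
        for left in BASES:
            for ref in BASES:
                for right in BASES:
                    ctx = left + ref + right
                    for alt in BASES:
                        if alt == ref:
                            continue
                        flipped = categorize_snv(
                            revcomp(ref), revcomp(alt), revcomp(ctx)
                        )
                        assert categorize_snv(ref, alt, ctx) == flipped


def brute_force_synonymous_weight(model: GeneModel, genome: dict[str, str]) -> float:
    """Independent oracle: codon-table enumeration of synonymous (codon, alt) pairs."""
    seq = "".join(genome[model.chrom][s:e] for s, e in model.coding_intervals)
    if model.strand == "-":
        seq = revcomp(seq)
    total = 0
    for ci in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[ci : ci + 3]
        aa = str(Seq(codon).translate())
        for off in range(3):
            for alt in BASES:
                if alt == codon[off]:
                    continue
                mutated = codon[:off] + alt + codon[off + 1 :]
                if str(Seq(mutated).translate()) == aa:
                    total += 1
    return total / 3.0


class TestEnumerateSiteEffects:
    def test_three_entries_per_position_weight_one(self, toy_sites, toy_models):
        for model in toy_models:
            gs = toy_sites[model.gene_id]
            positions, counts = np.unique(gs.positions, return_counts=True)
            assert (counts == 3).all()
            assert len(positions) == model.territory() - len(gs.skipped_positions)

    def test_coding_positions_synonymous_plus_nonsynonymous(self, toy_sites, toy_models):
        for model in toy_models:
            gs = toy_sites[model.gene_id]
            coding = set()
            for s, e in model.coding_intervals:
                coding.update(range(s, e))
            for pos, zone in zip(gs.positions, gs.zones):
                if pos in coding:
                    assert zone in (SYN, NONSYN)
                else:
                    assert zone == NONCODING

    def test_synonymous_weight_matches_codon_oracle(self, toy_sites, toy_models, toy_genome):
        for model in toy_models:
            gs = toy_sites[model.gene_id]
            got = (gs.zones == SYN).sum() / 3.0
            assert got == pytest.approx(brute_force_synonymous_weight(model, toy_genome))

    def test_fourfold_degenerate_site(self):
        # CTG codon: all third-base changes are synonymous (Leu)
        genome = {"1": "AACTGAA"}
        model = GeneModel("G", "G", "1", "+", "T", [(2, 5)], [], [])
        gs = enumerate_site_effects([model], genome)["G"]
        third = gs.zones[gs.positions == 4]
        assert len(third) == 3 and (third == SYN).all()

    def test_atg_first_base_all_nonsynonymous(self):
        genome = {"1": "AATGCAA"}
        model = GeneModel("G", "G", "1", "+", "T", [(1, 4)], [], [])
        gs = enumerate_site_effects([model], genome)["G"]
        first = gs.zones[gs.positions == 1]
        assert len(first) == 3 and (first == NONSYN).all()

    def test_intronic_cpg_transition_category_1(self):
        genome = {"1": "AAACGAAATTTGGGCCCAAATTT"}
        model = GeneModel("G", "G", "1", "+", "T", [(8, 23)], [(3, 8)], [])
        gs = enumerate_site_effects([model], genome)["G"]
        hit = gs.lookup(3, "T")  # C at position 3 followed by G, alt T
        assert hit == (NONCODING, 1)

    def test_reference_n_skipped(self):
        genome = {"1": "AANTGCAAA"}
        model = GeneModel("G", "G", "1", "+", "T", [(2, 8)], [], [])
        gs = enumerate_site_effects([model], genome)["G"]
        assert 2 in gs.skipped_positions
        assert 2 not in set(gs.positions.tolist())

    def test_strand_flip_preserves_zones(self):
        """Reverse-complementing the genome and flipping the strand leaves
        zone classification invariant (positions mirror accordingly)."""
        L = 30
        genome = {"1": make_seq_for_strand_test(L)}
        fwd = GeneModel("G", "G", "1", "+", "T", [(6, 24)], [], [(0, 6), (24, 30)])
        rc_genome = {"1": revcomp(genome["1"])}
        rev = GeneModel("G", "G", "1", "-", "T", [(6, 24)], [], [(0, 6), (24, 30)])
        gs_fwd = enumerate_site_effects([fwd], genome)["G"]
        gs_rev = enumerate_site_effects([rev], rc_genome)["G"]
        for pos, alt_code, zone in zip(gs_fwd.positions, gs_fwd.alts, gs_fwd.zones):
            mirror_pos = L - 1 - int(pos)
            mirror_alt = revcomp(BASES[alt_code])
            hit = gs_rev.lookup(mirror_pos, mirror_alt)
            assert hit is not None and hit[0] == zone


def make_seq_for_strand_test(length: int) -> str:
    rng = np.random.default_rng(5)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


class TestValidateGeneConsistency:
    def test_identical_zone_maps_pass(self, toy_sites):
        gs = toy_sites["GA"]
        zones = {int(gs.positions[0]): int(gs.position_zone(int(gs.positions[0])))}
        assert validate_gene_consistency(gs, zones)

    def test_zone_mismatch_fails(self, toy_sites):
        gs = toy_sites["GA"]
        # position 35 is intronic in the model but claimed coding by the MAF
        assert validate_gene_consistency(gs, {35: SYN}) is False

    def test_zero_mutations_vacuously_pass(self, toy_sites):
        assert validate_gene_consistency(toy_sites["GA"], {})


class TestGenomeAccessor:
    def test_padding_beyond_contig(self):
        acc = GenomeAccessor({"1": "ACGT"})
        assert acc.fetch("1", -1, 2) == "NAC"
        assert acc.fetch("chr1", 3, 6) == "TNN"
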