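"""Shared fixtures: a tiny hand-built genome and simulated bundles."""

from __future__ import annotations

import numpy as np
import pytest

from synsig.genome import GeneModel, enumerate_site_effects


def make_sequence(length: int, seed: int = 42) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def toy_genome() -> dict[str, str]:
    return {"1": make_sequence(600)}


@pytest.fixture(scope="session")
def toy_models() -> list[GeneModel]:
    """Two plus-strand genes and one minus-strand gene on chromosome 1.

    Gene layout (0-based half-open):
      GA (+): UTR [10,16) CDS [16,31)+[40,55) intron [31,40) UTR [55,61)
      GB (-): UTR [100,106) CDS [106,121)+[130,145) intron [121,130) UTR [145,151)
      GC (+): UTR [200,203) CDS [203,233) UTR [233,236)   (single exon)
    """
    return [
        GeneModel(
            gene_id="GA",
            gene_name="GA",
            chrom="1",
            strand="+",
            transcript_id="GA.t1",
            coding_intervals=[(16, 31), (40, 55)],
            intron_intervals=[(31, 40)],
            utr_intervals=[(10, 16), (55, 61)],
        ),
        GeneModel(
            gene_id="GB",
            gene_name="GB",
            chrom="1",
            strand="-",
            transcript_id="GB.t1",
            coding_intervals=[(106, 121), (130, 145)],
            intron_intervals=[(121, 130)],
            utr_intervals=[(100, 106), (145, 151)],
        ),
        GeneModel(
            gene_id="GC",
            gene_name="GC",
            chrom="1",
            strand="+",
            transcript_id="GC.t1",
            coding_intervals=[(203, 233)],
            intron_intervals=[],
            utr_intervals=[(200, 203), (233, 236)],
        ),
    ]


@pytest.fixture(scope="session")
def toy_sites(toy_models, toy_genome):
    return enumerate_site_effects(toy_models, toy_genome)


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """A small simulated file bundle shared by the I/O tests."""
    from synsig.simulate import SimulationConfig, simulate_cohort

    config = SimulationConfig(
        n_genes=6,
        n_patients=4,
        seed=123,
        base_rate=3e-3,
        coverage_dropout=0.15,
        n_null_genes=2,
    )
    return simulate_cohort(config, tmp_path_factory.mktemp("bundle"))
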