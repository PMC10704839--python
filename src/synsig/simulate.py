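"""Synthetic cohort generation.

Two layers:

* :func:`simulate_tensors` draws mutation-count and coverage cubes
  directly (fast; used for calibration and power experiments at
  hundreds of genes x tens of patients).
* :func:`simulate_cohort` writes a complete toy file bundle -- genome
  FASTA, Gencode-dialect GTF, principal-transcript mapping, per-patient
  MAF rows and WIG coverage, covariate/synonym/expression tables, and a
  cohort manifest -- in exactly the dialects the readers accept, so the
  whole pipeline is testable without downloads.

Mutation counts are Poisson with mean = base rate x patient factor x
category factor x gene covariate factor x zone site count; spike-in
genes multiply the synonymous-zone mean only.  All randomness flows
from one seeded generator with spawned sub-streams per artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from synsig import genome as genome_mod
from synsig.genome import BASES, GeneModel, enumerate_site_effects
from synsig.tensors import (
    N_CATEGORIES,
    NONCODING,
    NONSYN,
    SYN,
    CountTensor,
    CoverageTensor,
)

#: default relative site composition over categories 1..6
DEFAULT_CATEGORY_SITES = np.array([0.04, 0.04, 0.26, 0.26, 0.20, 0.20])


@dataclass
class SimulationConfig:
    """Knobs for both simulator layers.

    Rates are per site unit (one covered position contributes one unit
    spread over its three alternate alleles).
    """

    n_genes: int = 100
    n_patients: int = 20
    cohort: str = "Toy-Cohort"
    seed: int = 0

    # gene geometry (bp); coding length is rounded to a multiple of 3
    coding_length: int = 900
    intron_length: int = 1500
    utr_length: int = 300
    length_jitter: float = 0.2  # +/- fractional spread on all lengths

    base_rate: float = 2e-3
    patient_rate_spread: float = 1.0  # max/min ratio of patient multipliers
    category_rates: np.ndarray = field(
        default_factory=lambda: np.ones(N_CATEGORIES - 1)
    )
    indel_rate_fraction: float = 0.05  # category-7 rate relative to base
    covariate_effect: float = 0.0  # log-scale slope of gene factor on covariate 1
    synonymous_fraction: float = 0.25  # fraction of coding sites that are synonymous

    spike_genes: dict[str, float] = field(default_factory=dict)
    coverage_dropout: float = 0.0
    n_null_genes: int = 0  # first genes flagged non-expressed (FPKM < 1)

    def __post_init__(self) -> None:
        self.category_rates = np.asarray(self.category_rates, dtype=float)
        if np.any(self.category_rates < 0) or self.base_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


def _patient_multipliers(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-uniform multipliers spanning the configured spread, mean-normalized."""
    if config.patient_rate_spread <= 1.0:
        return np.ones(config.n_patients)
    log_spread = np.log(config.patient_rate_spread)
    mult = np.exp(rng.uniform(0.0, log_spread, size=config.n_patients))
    return mult / mult.mean()


def _gene_tables(config: SimulationConfig, rng: np.random.Generator):
    """Covariates, per-gene rate factors, and jittered gene geometries."""
    genes = config.gene_names()
    cov = pd.DataFrame(
        {
            "expression": rng.normal(size=config.n_genes),
            "replication_timing": rng.normal(size=config.n_genes),
            "chromatin": rng.normal(size=config.n_genes),
        },
        index=pd.Index(genes, name="gene"),
    )
    factors = np.exp(config.covariate_effect * cov["expression"].to_numpy())
    jitter = 1.0 + config.length_jitter * rng.uniform(-1, 1, size=(config.n_genes, 3))
    coding = np.maximum(3 * np.round(config.coding_length * jitter[:, 0] / 3), 3).astype(int)
    intron = np.maximum(np.round(config.intron_length * jitter[:, 1]), 0).astype(int)
    utr = np.maximum(np.round(config.utr_length * jitter[:, 2]), 0).astype(int)
    return genes, cov, factors, coding, intron, utr


@dataclass
class SimulatedTensors:
    counts: CountTensor
    coverage: CoverageTensor
    covariates: pd.DataFrame
    expression: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Machine-readable ground truth for recovery scoring."""
    genes = config.gene_names()
    folds = [config.spike_genes.get(g, 1.0) for g in genes]
    return pd.DataFrame(
        {"gene": genes, "enriched": [f > 1.0 for f in folds], "fold": folds}
    ).set_index("gene")


def expression_table(config: SimulationConfig) -> pd.DataFrame:
    """FPKM table: the first ``n_null_genes`` genes are non-expressed."""
    genes = config.gene_names()
    fpkm = np.full(config.n_genes, 10.0)
    fpkm[: config.n_null_genes] = 0.1
    return pd.DataFrame({config.cohort: fpkm}, index=pd.Index(genes, name="gene"))


def simulate_tensors(config: SimulationConfig) -> SimulatedTensors:
    """Draw cohort count/coverage cubes without writing any files."""
    rng = np.random.default_rng(config.seed)
    genes, cov_table, gene_factors, coding, intron, utr = _gene_tables(config, rng)
    patients = [f"P{i:03d}" for i in range(config.n_patients)]
    rho_p = _patient_multipliers(config, rng)
    cat_sites = DEFAULT_CATEGORY_SITES / DEFAULT_CATEGORY_SITES.sum()

    coverage = CoverageTensor(genes, patients)
    # zone site totals per gene
    syn_sites = coding * config.synonymous_fraction
    nonsyn_sites = coding * (1.0 - config.synonymous_fraction)
    noncod_sites = (intron + utr).astype(float)
    zone_sites = np.stack([syn_sites, nonsyn_sites, noncod_sites], axis=1)  # (G, 3)
    base_cov = zone_sites[:, None, :] * cat_sites[:, None]  # (G, 6, 3)
    keep = 1.0 - config.coverage_dropout
    coverage.values[:, : N_CATEGORIES - 1, :, :] = (
        base_cov[:, :, None, :] * keep
    )
    coverage.finalize()

    counts = CountTensor(genes, patients)
    fold = np.array([config.spike_genes.get(g, 1.0) for g in genes])
    # substitution categories 1..6
    mean = (
        config.base_rate
        * gene_factors[:, None, None, None]
        * config.category_rates[None, :, None, None]
        * rho_p[None, None, :, None]
        * coverage.values[:, : N_CATEGORIES - 1, :, :]
    )
    mean[:, :, :, SYN] *= fold[:, None, None]
    counts.values[:, : N_CATEGORIES - 1] = rng.poisson(mean)
    # indel/null mutations (category 7) over the whole gene, noncoding zone split
    indel_mean = (
        config.base_rate
        * config.indel_rate_fraction
        * gene_factors[:, None]
        * rho_p[None, :]
        * zone_sites.sum(axis=1)[:, None]
    )
    indel = rng.poisson(indel_mean)
    counts.values[:, N_CATEGORIES - 1, :, NONCODING] = indel
    counts.finalize()

    return SimulatedTensors(
        counts=counts,
        coverage=coverage,
        covariates=cov_table,
        expression=expression_table(config),
        truth=truth_table(config),
        config=config,
    )


# ---------------------------------------------------------------------------
# file-bundle layer


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.asarray(list(BASES))[rng.integers(0, 4, size=length)])


@dataclass
class SimulatedBundle:
    """Paths of the written artifacts plus the simulator's internal draws."""

    root: Path
    gtf: Path
    fasta: Path
    maf: Path
    wigs: dict[str, Path]
    covariates: Path
    synonyms: Path
    expression: Path
    manifest: Path
    principal: Path
    truth: Path
    drawn_counts: dict  # (gene, patient) -> int mutation rows written
    config: SimulationConfig


def _build_gene_layout(config: SimulationConfig, rng: np.random.Generator):
    """Place genes with UTR-exon-intron-exon-UTR structure along chromosomes."""
    genes, cov_table, factors, coding, intron, utr = _gene_tables(config, rng)
    layout = []
    pos = 100
    chrom = "1"
    for i, name in enumerate(genes):
        strand = "+" if i % 2 == 0 else "-"
        u5 = max(int(utr[i] // 2), 1)
        u3 = max(int(utr[i] - u5), 1)
        half = int(3 * ((coding[i] // 2) // 3)) or 3
        rest = int(coding[i] - half)
        start = pos
        # genomic order: 5'UTR, CDS-a, intron, CDS-b, 3'UTR (flip roles on -)
        a = (start, start + u5)
        b = (a[1], a[1] + half)
        c = (b[1], b[1] + int(intron[i]))
        d = (c[1], c[1] + rest)
        e = (d[1], d[1] + u3)
        layout.append(
            {
                "gene": name,
                "chrom": chrom,
                "strand": strand,
                "utr5": a,
                "cds": [b, d],
                "intron": c,
                "utr3": e,
                "span": (start, e[1]),
            }
        )
        pos = e[1] + 200
    chrom_len = pos + 100
    return genes, cov_table, factors, layout, {chrom: chrom_len}


def _write_fasta(path: Path, sequences: dict[str, str]) -> None:
    with path.open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _gtf_attrs(gene: str, tid: str) -> str:
    return (
        f'gene_id "{gene}"; transcript_id "{tid}"; gene_name "{gene}"; '
        f'gene_type "protein_coding"; gene_status "KNOWN"; '
        f'transcript_type "protein_coding";'
    )


def _write_gtf(path: Path, layout: list[dict]) -> None:
    with path.open("w") as fh:
        fh.write("##description: synthetic toy annotation\n")
        for g in layout:
            chrom, strand = f"chr{g['chrom']}", g["strand"]
            tid = g["gene"] + ".t1"
            s, e = g["span"]

            def feat(kind: str, iv: tuple[int, int]) -> str:
                return (
                    f"{chrom}\tsim\t{kind}\t{iv[0] + 1}\t{iv[1]}\t.\t{strand}\t.\t"
                    + _gtf_attrs(g["gene"], tid)
                    + "\n"
                )

            fh.write(feat("gene", (s, e)))
            fh.write(feat("transcript", (s, e)))
            # exon 1 = utr5 + first CDS chunk, exon 2 = second chunk + utr3
            fh.write(feat("exon", (g["utr5"][0], g["cds"][0][1])))
            fh.write(feat("exon", (g["cds"][1][0], g["utr3"][1])))
            for iv in g["cds"]:
                fh.write(feat("CDS", iv))
            fh.write(feat("UTR", g["utr5"]))
            fh.write(feat("UTR", g["utr3"]))


MAF_HEADER = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
]


def simulate_cohort(config: SimulationConfig, outdir: str | Path) -> SimulatedBundle:
    """Write a complete toy dataset; byte-identical for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    rng_layout, rng_seq, rng_mut, rng_cov = master.spawn(4)

    genes, cov_table, factors, layout, chrom_lens = _build_gene_layout(config, rng_layout)
    sequences = {f"chr{c}": _random_sequence(rng_seq, ln) for c, ln in chrom_lens.items()}
    fasta = outdir / "genome.fa"
    _write_fasta(fasta, sequences)
    gtf = outdir / "annotation.gtf"
    _write_gtf(gtf, layout)

    models = [
        GeneModel(
            gene_id=g["gene"],
            gene_name=g["gene"],
            chrom=g["chrom"],
            strand=g["strand"],
            transcript_id=g["gene"] + ".t1",
            coding_intervals=list(g["cds"]),
            intron_intervals=[g["intron"]],
            utr_intervals=[g["utr5"], g["utr3"]],
        )
        for g in layout
    ]
    plain = {genome_mod.normalize_chrom(c): s for c, s in sequences.items()}
    site_effects = enumerate_site_effects(models, plain)

    patients = [f"P{i:03d}" for i in range(config.n_patients)]
    rho_p = _patient_multipliers(config, rng_mut)
    cat_rates = config.category_rates

    maf = outdir / "mutations.maf"
    drawn: dict[tuple[str, str], int] = {}
    rows: list[list[str]] = []
    for gi, g in enumerate(layout):
        gs = site_effects[g["gene"]]
        fold = config.spike_genes.get(g["gene"], 1.0)
        chrom_seq = plain[g["chrom"]]
        for zone in (SYN, NONSYN, NONCODING):
            for cat in range(1, N_CATEGORIES):
                sel = np.nonzero((gs.zones == zone) & (gs.categories == cat))[0]
                if len(sel) == 0:
                    continue
                site_units = len(sel) / 3.0
                for pi, patient in enumerate(patients):
                    mean = (
                        config.base_rate
                        * factors[gi]
                        * cat_rates[cat - 1]
                        * rho_p[pi]
                        * site_units
                    )
                    if zone == SYN:
                        mean *= fold
                    k = int(rng_mut.poisson(mean))
                    if k == 0:
                        continue
                    k = min(k, len(sel))
                    picks = rng_mut.choice(sel, size=k, replace=False)
                    for idx in picks:
                        pos = int(gs.positions[idx])
                        rows.append(
                            [
                                g["gene"],
                                "chr" + g["chrom"],
                                str(pos + 1),
                                chrom_seq[pos],
                                BASES[gs.alts[idx]],
                                "Silent" if zone == SYN else (
                                    "Missense_Mutation" if zone == NONSYN else "Intron"
                                ),
                                patient,
                            ]
                        )
                        drawn[(g["gene"], patient)] = drawn.get((g["gene"], patient), 0) + 1
    with maf.open("w") as fh:
        fh.write("\t".join(MAF_HEADER) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")

    wigs: dict[str, Path] = {}
    for patient in patients:
        wig = outdir / f"coverage_{patient}.wig"
        with wig.open("w") as fh:
            for g in layout:
                s, e = g["span"]
                values = np.ones(e - s, dtype=int)
                if config.coverage_dropout > 0:
                    drop = rng_cov.random(e - s) < config.coverage_dropout
                    values[drop] = 0
                fh.write(f"fixedStep chrom=chr{g['chrom']} start={s + 1} step=1\n")
                fh.write("\n".join(str(v) for v in values) + "\n")
        wigs[patient] = wig

    cov_path = outdir / "covariates.tsv"
    cov_table.to_csv(cov_path, sep="\t")
    syn_path = outdir / "synonyms.tsv"
    with syn_path.open("w") as fh:
        fh.write("old_name\tnew_name\n")
        for g in genes[: min(2, len(genes))]:
            fh.write(f"{g}_ALIAS\t{g}\n")
    expr_path = outdir / "expression.tsv"
    expression_table(config).to_csv(expr_path, sep="\t")
    manifest = outdir / "manifest.tsv"
    with manifest.open("w") as fh:
        fh.write("patient\tcohort\n")
        for p in patients:
            fh.write(f"{p}\t{config.cohort}\n")
    principal = outdir / "principal_transcripts.tsv"
    with principal.open("w") as fh:
        for g in genes[::2]:
            fh.write(f"{g}\t{g}.t1\n")
    truth_path = outdir / "truth.tsv"
    truth_table(config).to_csv(truth_path, sep="\t")
    (outdir / "config.json").write_text(
        json.dumps(
            {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in vars(config).items()
            },
            indent=2,
            sort_keys=True,
        )
    )

    return SimulatedBundle(
        root=outdir,
        gtf=gtf,
        fasta=fasta,
        maf=maf,
        wigs=wigs,
        covariates=cov_path,
        synonyms=syn_path,
        expression=expr_path,
        manifest=manifest,
        principal=principal,
        truth=truth_path,
        drawn_counts=drawn,
        config=config,
    )
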