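"""End-to-end cohort analysis.

``analyze_tensors`` is the statistical core shared by simulations and
the file-based driver: backgrounds -> marginals -> per-gene priors ->
projection/convolution -> p-values.  ``run_pipeline`` wires the file
readers around it and applies the FDR stage per cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import synsig
from synsig import background as bg_mod
from synsig import coverage as cov_mod
from synsig import fdr as fdr_mod
from synsig import maf as maf_mod
from synsig.genome import enumerate_site_effects, load_gene_models
from synsig.significance import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_MAX_TOTAL_BINS,
    DEFAULT_SCORE_CAP,
    GeneResult,
    score_gene,
)
from synsig.tensors import NONCODING, NONSYN, SYN, TOTAL, CountTensor, CoverageTensor

log = logging.getLogger(__name__)

TARGET_ZONES = {"synonymous": SYN, "nonsynonymous": NONSYN}


@dataclass
class AnalysisConfig:
    """Thresholds and knobs for one cohort analysis."""

    mode: str = "synonymous"
    fdr_method: str = "bayes"  # or "bh"
    hypermutator_threshold: int = maf_mod.DEFAULT_HYPERMUTATOR_THRESHOLD
    qualification_threshold: float = bg_mod.DEFAULT_QUALIFICATION_THRESHOLD
    max_neighbors: int = bg_mod.DEFAULT_MAX_NEIGHBORS
    max_bagel_coverage: float | None = None
    bin_width: float = DEFAULT_BIN_WIDTH
    score_cap: float = DEFAULT_SCORE_CAP
    max_total_bins: int = DEFAULT_MAX_TOTAL_BINS
    convolution_tail_eps: float = 1e-40
    p0: float = fdr_mod.DEFAULT_P0
    p_cutoff: float = fdr_mod.DEFAULT_P_CUTOFF
    fdr_threshold: float = fdr_mod.DEFAULT_FDR_THRESHOLD
    fdr_min_samples: int = fdr_mod.DEFAULT_MIN_SAMPLES
    exclusion_list: list[str] = field(default_factory=list)
    naive: bool = False  # constant-rate scorer: no bagels, no marginals

    def digest(self) -> str:
        blob = json.dumps(
            {k: v for k, v in vars(self).items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def analyze_tensors(
    counts: CountTensor,
    coverage: CoverageTensor,
    covariates: pd.DataFrame,
    config: AnalysisConfig | None = None,
    cohort: str = "",
    audit: dict | None = None,
) -> list[GeneResult]:
    """Score every gene in one cohort's count/coverage cubes.

    When a dict is passed as ``audit`` it receives the fitted
    backgrounds and marginals for inspection/export.
    """
    config = config or AnalysisConfig()
    zone = TARGET_ZONES[config.mode]
    genes = counts.genes

    if config.naive:
        total_nc_mut = float(counts.values[:, TOTAL, :, NONCODING].sum())
        total_nc_cov = float(coverage.values[:, TOTAL, :, NONCODING].sum())
        global_rate = total_nc_mut / total_nc_cov if total_nc_cov > 0 else 0.0
        backgrounds = {
            g: bg_mod.GeneBackground(g, *bg_mod.raw_background(counts, coverage, g))
            for g in genes
        }
        marginals = None
    else:
        backgrounds = bg_mod.build_all_backgrounds(
            counts,
            coverage,
            covariates,
            qualification_threshold=config.qualification_threshold,
            max_neighbors=config.max_neighbors,
            max_coverage=config.max_bagel_coverage,
        )
        marginals = bg_mod.compute_marginals(counts, coverage)

    if audit is not None:
        audit["backgrounds"] = backgrounds
        audit["marginals"] = marginals

    results = []
    for g in genes:
        if config.naive:
            gcp = bg_mod.naive_gcp_background(
                backgrounds[g], global_rate, counts.n_patients
            )
        else:
            gcp = bg_mod.gcp_background(backgrounds[g], marginals)
        target_cov = coverage.gene(g)[:6, :, zone]
        P0, P1, P2 = bg_mod.site_probabilities(
            bg_mod.GcpBackground(g, gcp.x[:6], gcp.X), target_cov
        )
        observed = counts.gene(g)[:6, :, zone]
        results.append(
            score_gene(
                g,
                observed,
                P0,
                P1,
                P2,
                labels=list(range(1, 7)),
                bin_width=config.bin_width,
                score_cap=config.score_cap,
                max_total_bins=config.max_total_bins,
                tail_eps=config.convolution_tail_eps,
                cohort=cohort,
            )
        )
    return results


def apply_fdr(
    results_by_cohort: dict[str, list[GeneResult]],
    expression: pd.DataFrame,
    config: AnalysisConfig,
) -> dict[str, list[GeneResult]]:
    """Attach FDR values and return candidate lists per cohort.

    Bayesian mode: the null CDF F0 is fitted on the pooled p-values of
    non-expressed genes across cohorts; the mixture CDF F per cohort.
    BH mode: q-values within each cohort.
    """
    candidates: dict[str, list[GeneResult]] = {}
    if config.fdr_method == "bh":
        for cohort, results in results_by_cohort.items():
            candidates[cohort] = fdr_mod.call_candidates(
                results,
                threshold=config.fdr_threshold,
                exclusion=config.exclusion_list,
                method="bh",
            )
        return candidates

    all_genes = {r.gene for rs in results_by_cohort.values() for r in rs}
    null_genes = set(fdr_mod.select_null_genes(expression, all_genes))
    null_pvalues = [
        r.p_value
        for rs in results_by_cohort.values()
        for r in rs
        if r.gene in null_genes
    ]
    for cohort, results in results_by_cohort.items():
        model = fdr_mod.fit_fdr_model(
            [r.p_value for r in results],
            null_pvalues,
            p0=config.p0,
            min_samples=config.fdr_min_samples,
        )
        fdr_mod.bayes_fdr(results, model.F0_hat, model.F_hat, config.p0, config.p_cutoff)
        candidates[cohort] = fdr_mod.call_candidates(
            results,
            threshold=config.fdr_threshold,
            exclusion=config.exclusion_list,
            method="bayes",
        )
    return candidates


@dataclass
class PipelineResult:
    results_by_cohort: dict[str, list[GeneResult]]
    candidates_by_cohort: dict[str, list[GeneResult]]
    excluded_patients: list[tuple[str, int]]


def _read_two_column_tsv(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            if a.lower() in ("old_name", "gene_id", "patient"):
                continue
            out[a] = b
    return out


def run_pipeline(
    gtf: str | Path,
    fasta: str | Path,
    maf: str | Path,
    wigs: dict[str, str | Path],
    covariates: str | Path,
    expression: str | Path,
    manifest: str | Path,
    synonyms: str | Path | None = None,
    principal: str | Path | None = None,
    config: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """File-based end-to-end run over every cohort in the manifest."""
    import pyfaidx

    config = config or AnalysisConfig()
    principal_map = _read_two_column_tsv(principal) if principal else {}
    with open(gtf) as fh:
        models = load_gene_models(fh, principal_map)
    genome = pyfaidx.Fasta(str(fasta))
    site_effects = enumerate_site_effects(models, genome)
    gene_ids = site_effects.gene_ids()

    with open(maf) as fh:
        records = maf_mod.read_maf(fh, known_genes=set(gene_ids))
    records = maf_mod.annotate_mutations(records, site_effects)

    manifest_df = pd.read_csv(manifest, sep="\t")
    cohort_of = dict(zip(manifest_df["patient"], manifest_df["cohort"]))
    patients = list(manifest_df["patient"])
    retained, excluded = maf_mod.filter_hypermutators(
        patients, records, config.hypermutator_threshold
    )
    records = [r for r in records if r.patient_id in set(retained)]
    records = maf_mod.filter_nontranscribed(records, site_effects)

    cov_df = pd.read_csv(covariates, sep="\t", index_col=0)
    if synonyms:
        cov_df = bg_mod.apply_synonyms(cov_df, _read_two_column_tsv(synonyms))
    expr_df = pd.read_csv(expression, sep="\t", index_col=0)

    masks = {}
    for patient in retained:
        path = wigs.get(patient)
        if path is None:
            masks[patient] = None
        else:
            with open(path) as fh:
                masks[patient] = cov_mod.parse_wig(fh)

    results_by_cohort: dict[str, list[GeneResult]] = {}
    audits: dict[str, dict] = {}
    for cohort in sorted(set(cohort_of[p] for p in retained)):
        cohort_patients = [p for p in retained if cohort_of[p] == cohort]
        cohort_records = [r for r in records if r.patient_id in set(cohort_patients)]
        counts = maf_mod.build_count_tensor(cohort_records, gene_ids, cohort_patients)
        coverage = cov_mod.compute_patient_coverage(
            {p: masks[p] for p in cohort_patients}, site_effects, cohort_patients
        )
        audits[cohort] = {}
        results_by_cohort[cohort] = analyze_tensors(
            counts, coverage, cov_df, config, cohort=cohort, audit=audits[cohort]
        )

    candidates = apply_fdr(results_by_cohort, expr_df, config)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_results(outdir / "gene_results.tsv", results_by_cohort, config)
        write_results(outdir / "candidates.tsv", candidates, config)
        write_background_audit(outdir / "backgrounds.tsv", audits)
        with open(outdir / "excluded_patients.tsv", "w") as fh:
            fh.write("patient\ttotal_mutations\treason\n")
            for patient, count in excluded:
                fh.write(f"{patient}\t{count}\thypermutator\n")
    return PipelineResult(results_by_cohort, candidates, excluded)


def write_background_audit(path: str | Path, audits: dict[str, dict]) -> None:
    """Per-gene background dump: raw counts, bagel size, pooled x/X."""
    with open(path, "w") as fh:
        fh.write("cohort\tgene\tn_bkgd\tN_bkgd\tbagel_size\tx\tX\n")
        for cohort, audit in sorted(audits.items()):
            for gene, bg in sorted(audit.get("backgrounds", {}).items()):
                fh.write(
                    f"{cohort}\t{gene}\t{bg.n_bkgd:.0f}\t{bg.N_bkgd:.3f}\t"
                    f"{len(bg.bagel)}\t{bg.x:.3f}\t{bg.X:.3f}\n"
                )


def write_results(
    path: str | Path,
    results_by_cohort: dict[str, list[GeneResult]],
    config: AnalysisConfig,
) -> None:
    """TSV export with a provenance header (config hash, version)."""
    with open(path, "w") as fh:
        fh.write(f"# synsig {synsig.__version__} config={config.digest()} mode={config.mode}\n")
        fh.write("cohort\tgene\tn_target\tobserved_score\tp_value\tfdr\n")
        for cohort, results in sorted(results_by_cohort.items()):
            for r in sorted(results, key=lambda r: (r.p_value, r.gene)):
                fdr_txt = "" if r.fdr is None else f"{r.fdr:.6g}"
                fh.write(
                    f"{cohort}\t{r.gene}\t{r.n_target}\t{r.observed_score:.4f}\t"
                    f"{r.p_value:.6g}\t{fdr_txt}\n"
                )
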