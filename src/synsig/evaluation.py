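"""Reference cohort configurations and replicate experiments.

Used by the acceptance tests and the acceptance report script so both
measure exactly the same quantities: type-I error and candidate counts
on heterogeneous null cohorts, spike-in recovery, and the effect of
disabling the heterogeneity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from synsig.pipeline import AnalysisConfig, analyze_tensors, apply_fdr
from synsig.simulate import SimulationConfig, simulate_tensors

#: skewed relative category rates (CpG transitions hot, A:T transversions cold)
SKEWED_CATEGORY_RATES = np.array([4.0, 1.0, 2.0, 1.0, 1.5, 0.5])


def null_cohort_config(
    seed: int, n_genes: int = 1000, n_patients: int = 50
) -> SimulationConfig:
    """Heterogeneous null: 10x patient-rate spread, skewed categories,
    covariate-linked gene-level rate variation, no enrichment."""
    return SimulationConfig(
        n_genes=n_genes,
        n_patients=n_patients,
        seed=seed,
        base_rate=1e-3,
        patient_rate_spread=10.0,
        covariate_effect=0.5,
        category_rates=SKEWED_CATEGORY_RATES.copy(),
        n_null_genes=max(30, n_genes // 5),
    )


def spike_cohort_config(
    seed: int,
    n_genes: int = 400,
    n_patients: int = 50,
    fold: float = 10.0,
    n_spikes: int = 5,
) -> tuple[SimulationConfig, list[str], list[str]]:
    """Heterogeneous cohort with synonymous spike-ins and matched controls.

    Spike genes get a ``fold`` multiplier on the synonymous-zone mean
    only; the control for each spike is the neighboring gene id (same
    geometry distribution, same non-coding background model).
    """
    config = null_cohort_config(seed, n_genes, n_patients)
    null_block = config.n_null_genes
    step = max((n_genes - null_block - 1) // n_spikes, 2)
    spike_ids = [f"G{null_block + i * step:04d}" for i in range(n_spikes)]
    control_ids = [f"G{null_block + i * step + 1:04d}" for i in range(n_spikes)]
    config.spike_genes = {g: fold for g in spike_ids}
    return config, spike_ids, control_ids


@dataclass
class NullReplicate:
    frac_p_below_05: float
    n_candidates: int
    min_p: float


def run_null_replicate(
    seed: int, n_genes: int = 1000, n_patients: int = 50
) -> NullReplicate:
    """One heterogeneous-null cohort through the full caller + FDR."""
    sim = simulate_tensors(null_cohort_config(seed, n_genes, n_patients))
    results = analyze_tensors(sim.counts, sim.coverage, sim.covariates)
    p = np.array([r.p_value for r in results])
    candidates = apply_fdr({"null": results}, sim.expression, AnalysisConfig())
    return NullReplicate(
        frac_p_below_05=float((p < 0.05).mean()),
        n_candidates=len(candidates["null"]),
        min_p=float(p.min()),
    )


@dataclass
class SpikeReplicate:
    spikes_called: int
    n_spikes: int
    controls_called: int
    n_controls: int


def run_spike_replicate(seed: int, n_genes: int = 400, n_patients: int = 50) -> SpikeReplicate:
    """One spike-in cohort: which spikes/controls pass Fdr < 1e-2."""
    config, spikes, controls = spike_cohort_config(seed, n_genes, n_patients)
    sim = simulate_tensors(config)
    results = analyze_tensors(sim.counts, sim.coverage, sim.covariates)
    candidates = apply_fdr({"spike": results}, sim.expression, AnalysisConfig())
    called = {r.gene for r in candidates["spike"]}
    return SpikeReplicate(
        spikes_called=sum(g in called for g in spikes),
        n_spikes=len(spikes),
        controls_called=sum(g in called for g in controls),
        n_controls=len(controls),
    )


def run_naive_replicate(seed: int, n_genes: int = 1000, n_patients: int = 50) -> float:
    """Fraction of genes at p < 0.05 under the deliberately naive scorer
    (constant rate, no marginals, no bagels) on the heterogeneous null."""
    sim = simulate_tensors(null_cohort_config(seed, n_genes, n_patients))
    results = analyze_tensors(
        sim.counts, sim.coverage, sim.covariates, AnalysisConfig(naive=True)
    )
    p = np.array([r.p_value for r in results])
    return float((p < 0.05).mean())
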