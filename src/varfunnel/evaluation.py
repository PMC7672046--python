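"""Simulation studies over the synthetic cohort: recovery and error control.

These helpers replicate the study design at configurable scale: repeated
synthetic cohorts with planted truth are pushed through the full funnel ->
association -> enrichment path, and recovery/error rates are measured
against the planted truth.  They are used by the validation suite and the
reproduction script, and are exposed for users who want to re-check
operating characteristics under their own simulation settings.
"""

from __future__ import annotations

import numpy as np

from .association import DIFFERENTIAL, NOVEL, associate_all, fisher_exact, build_contingency
from .enrichment import enrich
from .funnel import FunnelConfig, post_population_genes, run_funnel
from .io import PanelRecord
from .simulate import SimulationConfig, generate_dataset

__all__ = ["recovery_study", "null_fdr_study", "fisher_null_uniformity"]


def recovery_study(
    n_sims: int = 200,
    seed: int = 0,
    n_variants: int = 300,
    alpha: float = 0.05,
    **sim_overrides,
) -> dict:
    """Planted-truth recovery over repeated simulated cohorts.

    Each replicate generates a cohort with planted novel and differential
    variants (study-design defaults: 195 cases, panels CHS n=105 and EAS
    n=4327), runs the funnel and the burden tests, and scores recovery.
    Returns pooled sensitivities and the fraction of replicates in which
    the planted gene family ranks first in the enrichment table.
    """
    rng = np.random.default_rng(seed)
    novel_found = novel_total = 0
    diff_found = diff_total = 0
    family_first = 0
    for _ in range(n_sims):
        cfg = SimulationConfig(
            n_variants=n_variants, seed=int(rng.integers(2**31)), **sim_overrides
        )
        ds = generate_dataset(cfg)
        candidates, _ = run_funnel(ds.variants, ds.panels)
        results = associate_all(candidates, ds.panels, cfg.n_patients, alpha)
        found_novel = {str(r.key) for r in results if r.classification == NOVEL}
        found_diff = {str(r.key) for r in results if r.classification == DIFFERENTIAL}
        novel_found += len(ds.truth.planted_novel_ids & found_novel)
        novel_total += len(ds.truth.planted_novel_ids)
        diff_found += len(ds.truth.planted_differential_ids & found_diff)
        diff_total += len(ds.truth.planted_differential_ids)

        universe = post_population_genes(ds.variants, ds.panels) & set(
            ds.family_map.gene_to_families
        )
        genes = {
            r.gene for r in results if r.classification != "not_associated"
        } & universe
        if genes:
            ranked = enrich(genes, ds.family_map.family_to_genes, universe, alpha)
            if ranked and ranked[0].set_id == ds.truth.planted_family:
                family_first += 1
    return {
        "n_sims": n_sims,
        "novel_sensitivity": novel_found / novel_total if novel_total else float("nan"),
        "differential_sensitivity": diff_found / diff_total if diff_total else float("nan"),
        "planted_family_first_rate": family_first / n_sims,
    }


def null_fdr_study(
    n_sims: int = 200,
    seed: int = 0,
    n_variants: int = 400,
    alpha: float = 0.05,
    **sim_overrides,
) -> dict:
    """Empirical FDR among declared differential variants under the null.

    With no planted variants, every declared differential variant is a
    false discovery, so the per-replicate false-discovery proportion is 1
    when any variant is declared and 0 otherwise; its mean estimates the
    FDR that BH is meant to control at ``alpha``.  Also reports the mean
    number of null discoveries per replicate and the Monte-Carlo standard
    error of the FDR estimate.
    """
    rng = np.random.default_rng(seed)
    fdp = np.zeros(n_sims)
    n_disc = np.zeros(n_sims)
    for i in range(n_sims):
        cfg = SimulationConfig(
            n_variants=n_variants,
            n_planted_novel=0,
            n_planted_differential=0,
            seed=int(rng.integers(2**31)),
            **sim_overrides,
        )
        ds = generate_dataset(cfg)
        candidates, _ = run_funnel(ds.variants, ds.panels)
        results = associate_all(candidates, ds.panels, cfg.n_patients, alpha)
        discoveries = sum(1 for r in results if r.classification == DIFFERENTIAL)
        n_disc[i] = discoveries
        fdp[i] = 1.0 if discoveries else 0.0
    est = float(fdp.mean())
    return {
        "n_sims": n_sims,
        "empirical_fdr": est,
        "mc_se": float(np.sqrt(max(est * (1 - est), 1e-12) / n_sims)),
        "mean_null_discoveries": float(n_disc.mean()),
        "alpha": alpha,
    }


def fisher_null_uniformity(
    n_variants: int = 2000,
    seed: int = 0,
    n_cases: int = 195,
    panel_n: int = 4327,
    af_range: tuple[float, float] = (0.001, 0.05),
    alphas: tuple[float, ...] = (0.01, 0.05),
) -> dict:
    """Super-uniformity of the Fisher p-value under the allele-level null.

    For each variant a population frequency is drawn, case alternate
    alleles are binomial draws at that same frequency, and the 2x2 test is
    run against the panel's (rounded) allele counts.  Under this null
    P(p <= alpha) must not exceed alpha (the exact test is conservative).
    Returns per-alpha rejection rates and Monte-Carlo standard errors.
    """
    rng = np.random.default_rng(seed)
    afs = rng.uniform(*af_range, size=n_variants)
    ps = np.empty(n_variants)
    for i, af in enumerate(afs):
        case_alt = int(rng.binomial(2 * n_cases, af))
        carriers = min(case_alt, n_cases)
        hom = case_alt - carriers
        rec = PanelRecord("panel", panel_n, float(af))
        table = build_contingency(carriers, hom, n_cases, rec)
        ps[i] = fisher_exact(table)
    out = {"n_variants": n_variants}
    for alpha in alphas:
        rate = float((ps <= alpha).mean())
        out[f"rate_at_{alpha}"] = rate
        out[f"mc_se_at_{alpha}"] = float(np.sqrt(alpha * (1 - alpha) / n_variants))
    return out
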