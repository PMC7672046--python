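"""End-to-end orchestration: simulate (optional) -> funnel -> association ->
enrichment -> clinical screen, with a machine-readable run manifest.

The run is configured by a single declarative :class:`RunConfig` (loadable
from YAML, overridable from the CLI); all randomness flows through the one
seed it carries.  The manifest records the package version, seed, a hash
of the normalized config, per-stage funnel counts and warning counts, so
a rerun with the same config and seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from . import io as fio
from .association import associate_all, association_frame
from .clinical import (
    VENN_FEATURES,
    cohort_summary,
    feature_correlation,
    intersect_variant_sets,
    variant_feature_screen,
)
from .enrichment import enrich, enrichment_frame
from .funnel import FunnelConfig, post_population_genes, run_funnel
from .io import ValidationError
from .simulate import SimulationConfig, generate_dataset, write_dataset

logger = logging.getLogger("varfunnel")

__all__ = ["RunConfig", "run_all", "report"]

RESULT_TABLES = ["candidates", "associations", "enrichment", "funnel_report"]


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    out_dir: str = "results"
    vcf: str | None = None
    annotation: str | None = None
    panels: dict = field(default_factory=dict)  # panel id -> {"path": ..., "n_samples": ...}
    clinical: str | None = None
    family_map: str | None = None
    gmt: str | None = None
    funnel: FunnelConfig = field(default_factory=FunnelConfig)
    alpha: float = 0.05
    panel_sig_mode: str = "all"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict | None = None  # SimulationConfig overrides; triggers simulation

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "rt") as fh:
            raw = yaml.safe_load(fh) or {}
        funnel_kwargs = raw.pop("funnel", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.funnel = FunnelConfig(**funnel_kwargs)
        return cfg

    def normalized(self) -> dict:
        d = dataclasses.asdict(self)
        d["funnel"] = dataclasses.asdict(self.funnel)
        d["version"] = __version__
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.normalized(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(path: str | None, name: str) -> str:
    if path is None:
        raise ValidationError(f"missing input path: {name}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"input path does not exist: {name} = {path}")
    return path


def run_all(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns the manifest dictionary.

    When ``config.simulate`` is set, a synthetic dataset is generated
    (seeded from ``config.seed``) under ``out_dir/inputs`` and its files
    become the run inputs.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    os.makedirs(config.out_dir, exist_ok=True)
    warnings_count: dict[str, int] = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "complete": False,
    }

    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim = SimulationConfig(**sim_kwargs)
        logger.info("simulate: %d variants, %d patients", sim.n_variants, sim.n_patients)
        paths = write_dataset(generate_dataset(sim), os.path.join(config.out_dir, "inputs"))
        config.vcf = paths["vcf"]
        config.annotation = paths["annotation"]
        config.clinical = paths["clinical"]
        config.family_map = paths["family_map"]
        config.panels = {
            pid: {"path": paths[f"panel_{pid}"], "n_samples": n}
            for pid, n in sim.panel_sizes.items()
        }

    # --- read inputs -------------------------------------------------------
    variants, vcf_warnings = fio.read_cohort_vcf(_require(config.vcf, "vcf"))
    warnings_count["vcf"] = len(vcf_warnings)
    annotations = fio.read_annotation_tsv(_require(config.annotation, "annotation"))
    ann_warnings = fio.attach_annotations(variants, annotations)
    warnings_count["annotation"] = len(ann_warnings)
    panels = {
        pid: fio.read_panel_tsv(_require(spec["path"], f"panel {pid}"), pid, spec["n_samples"])
        for pid, spec in config.panels.items()
    }
    clinical_records = fio.read_clinical_csv(_require(config.clinical, "clinical"))
    clinical = fio.clinical_to_frame(clinical_records)
    n_cases = len(clinical)

    if config.family_map:
        fam = fio.read_family_map(_require(config.family_map, "family_map"))
        set_map, set_names = fam.family_to_genes, fam.family_names
    elif config.gmt:
        set_map = fio.read_gmt(_require(config.gmt, "gmt"))
        set_names = {k: k for k in set_map}
    else:
        raise ValidationError("missing input path: family_map or gmt")

    # --- funnel ------------------------------------------------------------
    logger.info("funnel: %d input variants", len(variants))
    candidates, funnel_report = run_funnel(variants, panels, config.funnel)
    funnel_report.warnings = vcf_warnings + ann_warnings + funnel_report.warnings
    logger.info("funnel: %d candidates (%s)", len(candidates), funnel_report.counts)

    # --- association -------------------------------------------------------
    results = associate_all(
        candidates, panels, n_cases, config.alpha,
        config.funnel.min_carriers, config.panel_sig_mode,
    )
    assoc = association_frame(results)
    class_counts = (
        assoc.drop_duplicates(["chrom", "pos", "ref", "alt"])["class"].value_counts().to_dict()
    )
    logger.info("association: %s", class_counts)

    # --- enrichment --------------------------------------------------------
    universe = post_population_genes(variants, panels, config.funnel) & set(
        g for genes in set_map.values() for g in genes
    )
    associated_genes = {
        r.gene for r in results if r.classification != "not_associated" and r.gene in universe
    }
    if universe and associated_genes:
        enr = enrichment_frame(
            enrich(associated_genes, set_map, universe, config.alpha, set_names)
        )
    else:
        enr = enrichment_frame([])

    # --- clinical ----------------------------------------------------------
    assoc_keys = {r.key for r in results if r.classification != "not_associated"}
    screened = [v for v in candidates if v.key in assoc_keys]
    screen, significant, screen_warnings = variant_feature_screen(
        screened, clinical, alpha=config.alpha
    )
    warnings_count["clinical_screen"] = len(screen_warnings)
    venn = intersect_variant_sets({f: significant[f] for f in VENN_FEATURES})
    venn = {k: ({str(kk): vv for kk, vv in v.items()} if isinstance(v, dict) else v)
            for k, v in venn.items()}
    corr_p, corr_tests = feature_correlation(clinical)

    # --- write outputs -----------------------------------------------------
    candidate_rows = [
        {
            "chrom": v.key.chrom, "pos": v.key.pos, "ref": v.key.ref, "alt": v.key.alt,
            "gene": v.gene, "consequence": v.consequence,
            "carriers": v.carriers,
            "hom_carriers": sum(1 for c in v.calls if c.genotype_class == "hom"),
            "carrier_ids": ",".join(c.sample_id for c in v.calls),
        }
        for v in candidates
    ]
    import pandas as pd

    tables = {
        "candidates": pd.DataFrame(
            candidate_rows,
            columns=["chrom", "pos", "ref", "alt", "gene", "consequence",
                     "carriers", "hom_carriers", "carrier_ids"],
        ),
        "associations": assoc,
        "enrichment": enr,
        "clinical_screen": screen,
        "feature_correlation": corr_p.reset_index().rename(columns={"index": "feature"}),
        "funnel_report": funnel_report.to_dict(),
        "venn": venn,
        "cohort_summary": {
            k: ({str(kk): vv for kk, vv in v.items()} if isinstance(v, dict) else v)
            for k, v in cohort_summary(clinical).items()
        },
    }
    fio.write_results(tables, config.out_dir)
    with open(os.path.join(config.out_dir, "universe_genes.txt"), "wt") as fh:
        fh.write("\n".join(sorted(universe)) + "\n")

    manifest.update(
        {
            "complete": True,
            "stage_counts": {s["stage"]: s["survived"] for s in funnel_report.stages},
            "funnel_counts": funnel_report.counts,
            "n_candidates": len(candidates),
            "class_counts": class_counts,
            "n_enriched_sets": int(len(enr)),
            "venn_shared_by_all": venn["shared_by_all"],
            "warnings": warnings_count,
        }
    )
    with open(os.path.join(config.out_dir, "manifest.json"), "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report(results_dir: str) -> str:
    """Assemble a human-readable summary from a completed run directory."""
    import pandas as pd

    needed = {
        "manifest": "manifest.json",
        "funnel_report": "funnel_report.json",
        "associations": "associations.tsv",
        "enrichment": "enrichment.tsv",
        "venn": "venn.json",
    }
    missing = [f for f in needed.values() if not os.path.exists(os.path.join(results_dir, f))]
    if missing:
        raise ValidationError(f"incomplete run in {results_dir}: missing {missing}")

    with open(os.path.join(results_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    with open(os.path.join(results_dir, "funnel_report.json")) as fh:
        funnel_rep = json.load(fh)
    with open(os.path.join(results_dir, "venn.json")) as fh:
        venn = json.load(fh)
    assoc = pd.read_csv(os.path.join(results_dir, "associations.tsv"), sep="\t")
    enr = pd.read_csv(os.path.join(results_dir, "enrichment.tsv"), sep="\t")

    lines = [
        f"varfunnel {manifest.get('version')} run {manifest.get('config_hash')} "
        f"(seed {manifest.get('seed')})",
        "",
        "Funnel:",
    ]
    for s in funnel_rep["stages"]:
        lines.append(f"  {s['stage']:<24} {s['input']:>8} -> {s['survived']:>8}")
    lines.append("")
    if not assoc.empty:
        per_variant = assoc.drop_duplicates(["chrom", "pos", "ref", "alt"])
        lines.append("Classification counts: " + json.dumps(per_variant["class"].value_counts().to_dict()))
        top = per_variant.nsmallest(5, "q", keep="first")
        lines.append("Top associations (by q):")
        for row in top.to_dict("records"):
            lines.append(
                f"  {row['chrom']}:{row['pos']}:{row['ref']}:{row['alt']}  gene={row['gene']} "
                f"carriers={row['carriers']} class={row['class']}"
            )
    if not enr.empty:
        lines.append("Top enriched gene sets:")
        for row in enr.head(5).itertuples(index=False):
            lines.append(
                f"  {row.set_id:<14} k/K={row.k}/{row.K}  -log10(q)={row.neg_log10_q:.2f}"
            )
    lines.append(
        f"Venn: union={venn['union']} shared_by_all={venn['shared_by_all']} "
        f"({venn['shared_by_all_pct']:.1f}% of union)"
    )
    return "\n".join(lines)
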