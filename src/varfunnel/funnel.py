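"""High-confidence QC and prioritization filters for case-only cohorts.

The funnel applies, in order:

1. **QC** — per-call genotype classification from sequencing depth and
   read-level alternate-allele fraction: depth >= 30 and 0.4 < AF < 0.6
   (heterozygous) or AF > 0.9 (homozygous); everything else fails.  A
   variant survives iff at least one call passes.
2. **Recurrence** — keep variants carried by >= 2 patients.
3. **Population frequency** — remove variants whose allele frequency
   exceeds 5% in *both* reference panels (absence counts as frequency 0).
4. **Deleteriousness consensus** — keep variants called deleterious by
   >= 2 of the five in-silico predictors.

Every stage returns a subset of its input; the :class:`FunnelReport`
records survivor/dropped counts per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io import CohortVariant, PanelRecord, ValidationError, VariantKey

__all__ = [
    "FunnelConfig",
    "FunnelReport",
    "classify_genotype",
    "qc_high_confidence",
    "recurrence_filter",
    "population_frequency_filter",
    "deleterious_consensus",
    "run_funnel",
]

HET = "het"
HOM = "hom"
FAIL = "fail"


@dataclass(frozen=True)
class FunnelConfig:
    """Thresholds for the four funnel stages.

    Window boundaries are strict: alt fraction exactly 0.4, 0.6 or 0.9
    fails QC.  ``panel_af_mode`` selects whether the population filter
    removes variants common in *both* panels (the default) or in *any*
    panel.
    """

    min_depth: int = 30
    het_low: float = 0.4
    het_high: float = 0.6
    hom_threshold: float = 0.9
    min_carriers: int = 2
    panel_af_cutoff: float = 0.05
    min_deleterious_votes: int = 2
    panel_af_mode: str = "both"

    def __post_init__(self) -> None:
        if not (0 < self.het_low < self.het_high <= self.hom_threshold < 1):
            raise ValidationError(
                "require 0 < het_low < het_high <= hom_threshold < 1, got "
                f"({self.het_low}, {self.het_high}, {self.hom_threshold})"
            )
        if self.min_carriers < 1:
            raise ValidationError(f"min_carriers must be >= 1, got {self.min_carriers}")
        if not 0 < self.panel_af_cutoff < 1:
            raise ValidationError(
                f"panel_af_cutoff must be in (0,1), got {self.panel_af_cutoff}"
            )
        if self.min_deleterious_votes < 0:
            raise ValidationError("min_deleterious_votes must be >= 0")
        if self.panel_af_mode not in ("both", "any"):
            raise ValidationError(f"panel_af_mode must be 'both' or 'any', got {self.panel_af_mode!r}")


@dataclass
class FunnelReport:
    """Per-stage survivor and dropped counts (non-increasing by stage)."""

    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValidationError(f"stage {name}: survivors {n_out} exceed input {n_in}")
        self.stages.append({"stage": name, "input": n_in, "survived": n_out, "dropped": n_in - n_out})

    @property
    def counts(self) -> list[int]:
        """Input size followed by each stage's survivor count."""
        if not self.stages:
            return []
        return [self.stages[0]["input"]] + [s["survived"] for s in self.stages]

    def to_dict(self) -> dict:
        return {"stages": self.stages, "warnings": self.warnings}


def classify_genotype(depth: int, alt_fraction: float, config: FunnelConfig | None = None) -> str:
    """Classify one call as het, hom or fail.

    Fails whenever depth is below the minimum, regardless of the alt
    fraction; the het window and hom threshold are open (strict)
    inequalities.
    """
    config = config or FunnelConfig()
    if depth < config.min_depth:
        return FAIL
    if config.het_low < alt_fraction < config.het_high:
        return HET
    if alt_fraction > config.hom_threshold:
        return HOM
    return FAIL


def qc_high_confidence(
    variants: list[CohortVariant], config: FunnelConfig | None = None
) -> list[CohortVariant]:
    """Keep variants with >= 1 het/hom call; drop failing calls from carriers.

    Returns new variant objects whose calls carry ``genotype_class``.
    """
    config = config or FunnelConfig()
    out = []
    for v in variants:
        kept = []
        for call in v.calls:
            cls = classify_genotype(call.depth, call.alt_fraction, config)
            if cls != FAIL:
                kept.append(replace(call, genotype_class=cls))
        if kept:
            out.append(
                CohortVariant(v.key, kept, v.gene, v.consequence, dict(v.predictor_verdicts))
            )
    return out


def recurrence_filter(
    variants: list[CohortVariant], config: FunnelConfig | None = None
) -> list[CohortVariant]:
    """Keep variants carried by at least ``min_carriers`` patients."""
    config = config or FunnelConfig()
    return [v for v in variants if v.carriers >= config.min_carriers]


def population_frequency_filter(
    variants: list[CohortVariant],
    panels: dict[str, dict[VariantKey, PanelRecord]],
    config: FunnelConfig | None = None,
    report: FunnelReport | None = None,
) -> list[CohortVariant]:
    """Remove variants common in the reference panels.

    In ``both`` mode (default) a variant is removed only when its frequency
    exceeds the cutoff in every panel; absence from a panel counts as
    frequency 0, so a variant common in a single panel is kept (flagged in
    the report warnings, since many pipelines would drop it).
    """
    config = config or FunnelConfig()
    out = []
    n_single_panel_common = 0
    for v in variants:
        afs = {
            pid: (panel[v.key].af if v.key in panel else 0.0)
            for pid, panel in panels.items()
        }
        over = [af > config.panel_af_cutoff for af in afs.values()]
        if config.panel_af_mode == "both":
            remove = bool(over) and all(over)
            if any(over) and not remove:
                n_single_panel_common += 1
        else:
            remove = any(over)
        if not remove:
            out.append(v)
    if report is not None and n_single_panel_common:
        report.warnings.append(
            f"kept {n_single_panel_common} variant(s) above the AF cutoff in one panel only"
        )
    return out


def deleterious_consensus(
    predictor_verdicts: dict[str, str], config: FunnelConfig | None = None
) -> bool:
    """True iff >= ``min_deleterious_votes`` predictors call the variant deleterious.

    Verdicts must already be normalized to {deleterious, tolerated,
    missing}; missing counts as non-deleterious.
    """
    config = config or FunnelConfig()
    allowed = {"deleterious", "tolerated", "missing"}
    bad = {v for v in predictor_verdicts.values() if v not in allowed}
    if bad:
        raise ValidationError(f"unnormalized verdict labels: {sorted(bad)}")
    votes = sum(1 for v in predictor_verdicts.values() if v == "deleterious")
    return votes >= config.min_deleterious_votes


def run_funnel(
    variants: list[CohortVariant],
    panels: dict[str, dict[VariantKey, PanelRecord]],
    config: FunnelConfig | None = None,
) -> tuple[list[CohortVariant], FunnelReport]:
    """Run QC -> recurrence -> population frequency -> deleterious consensus."""
    config = config or FunnelConfig()
    report = FunnelReport()

    stage0 = variants
    stage1 = qc_high_confidence(stage0, config)
    report.add_stage("qc_high_confidence", len(stage0), len(stage1))

    stage2 = recurrence_filter(stage1, config)
    report.add_stage("recurrence", len(stage1), len(stage2))

    stage3 = population_frequency_filter(stage2, panels, config, report)
    report.add_stage("population_frequency", len(stage2), len(stage3))

    stage4 = [v for v in stage3 if deleterious_consensus(v.predictor_verdicts, config)]
    report.add_stage("deleterious_consensus", len(stage3), len(stage4))

    return stage4, report


def post_population_genes(
    variants: list[CohortVariant],
    panels: dict[str, dict[VariantKey, PanelRecord]],
    config: FunnelConfig | None = None,
) -> set[str]:
    """Genes carrying >= 1 variant surviving QC, recurrence and the population
    filter — the enrichment universe before the deleteriousness stage."""
    config = config or FunnelConfig()
    stage = qc_high_confidence(variants, config)
    stage = recurrence_filter(stage, config)
    stage = population_frequency_filter(stage, panels, config)
    return {v.gene for v in stage if v.gene is not None}
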