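"""Synthetic cohort generator with planted, known truth.

Emulates the study design the pipeline targets: a case-only exome cohort
(default 195 patients) screened against two reference panels of Southern
Han / East Asian ancestry (defaults: CHS, 105 diploid samples; EAS,
4,327).  Each simulated variant gets carrier calls (depth and read-level
alt fraction), native-label deleteriousness verdicts from five predictors,
per-panel allele frequencies, a gene and a gene-family assignment; the
cohort gets a clinical table with the categories used for subgroup
analysis.

Planted truth:

* *novel* variants — >= 2 case carriers, absent from every panel, >= 2
  deleterious verdicts; they satisfy the novel-variant discovery rule by
  construction.
* *differential* variants — configured carrier excess in cases and a
  small nonzero panel frequency.  A panel reports a variant only when its
  rounded allele count is >= 1, so frequencies below a panel's resolution
  (1 / 2n) leave the variant absent from that panel, as in real
  frequency tables.
* one designated gene family holds all planted genes, making enrichment
  recovery testable; null genes scatter uniformly over the remaining
  families.

Null variants draw a latent population frequency from a point mass at
zero plus a scaled-Beta component on (0, 0.5]; case carrier counts are
binomial with the diploid carrier probability 1 - (1 - af)^2, and panel
frequencies are binomial resamples of the latent frequency, so case and
panel distributions agree under the null.

Everything is driven by one seeded generator: identical configs and seeds
give byte-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as fio
from .io import (
    CohortVariant,
    FamilyMap,
    ObservedCall,
    PanelRecord,
    ValidationError,
    VariantKey,
)

__all__ = [
    "BackgroundAF",
    "DepthModel",
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_clinical",
    "write_dataset",
    "DEFAULT_CLINICAL_PROPORTIONS",
]


class ConfigurationError(ValueError):
    """A simulation config field is invalid; the message names the field."""


@dataclass(frozen=True)
class BackgroundAF:
    """Null law for latent panel allele frequencies.

    A point mass at zero (variants absent from the panels) with
    probability ``p_absent``, plus a Beta(a, b) component scaled to
    (0, ``max_af``].  ``fixed_af`` overrides both with a single value for
    calibration runs.
    """

    p_absent: float = 0.25
    beta_a: float = 0.5
    beta_b: float = 8.0
    max_af: float = 0.5
    fixed_af: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_absent <= 1.0:
            raise ConfigurationError(f"background_panel_af_distribution.p_absent: {self.p_absent}")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ConfigurationError("background_panel_af_distribution: beta shape parameters must be > 0")
        if not 0 < self.max_af <= 0.5:
            raise ConfigurationError(f"background_panel_af_distribution.max_af: {self.max_af}")
        if self.fixed_af is not None and not 0.0 <= self.fixed_af <= 0.5:
            raise ConfigurationError(f"background_panel_af_distribution.fixed_af: {self.fixed_af}")


@dataclass(frozen=True)
class DepthModel:
    """Sequencing-depth law: Poisson(mean), support clipped to >= 1.

    The default mean (100) keeps essentially all uncorrupted calls above
    the depth-30 QC bar; ``corruption_rate`` (on the main config) controls
    how many calls are deliberately emitted below it or outside the
    het/hom windows.
    """

    mean: float = 100.0

    def __post_init__(self) -> None:
        if self.mean < 1:
            raise ConfigurationError(f"depth_distribution.mean: {self.mean} (must be >= 1)")


DEFAULT_CLINICAL_PROPORTIONS: dict[str, dict] = {
    "sex": {"F": 156 / 195, "M": 39 / 195},
    "shape": {"C": 131 / 195, "S": 64 / 195},
    "direction": {"L": 52 / 195, "R": 143 / 195},
    "apex_class": {1: 106 / 195, 2: 89 / 195},
    "lenke": {k: 1 / 6 for k in range(1, 7)},
}

#: Continuous clinical laws: cohort means and SDs for age at diagnosis
#: (years), Cobb angle (degrees, truncated > 10 per the AIS definition)
#: and tilted-vertebrae count (integer >= 2).
CLINICAL_CONTINUOUS = {
    "age": (14.93, 3.04),
    "cobb": (41.88, 18.35),
    "tilted_count": (13.00, 3.84),
}


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 195
    panel_sizes: dict = field(default_factory=lambda: {"CHS": 105, "EAS": 4327})
    n_variants: int = 2000
    background_panel_af_distribution: BackgroundAF = field(default_factory=BackgroundAF)
    n_planted_novel: int = 10
    n_planted_differential: int = 10
    planted_carrier_range: tuple[int, int] = (5, 10)
    planted_differential_af: float = 0.001
    planted_family: str = "FAM_PLANTED"
    n_families: int = 40
    deleterious_rate_null: float = 0.2
    depth_distribution: DepthModel = field(default_factory=DepthModel)
    corruption_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients: {self.n_patients} (must be >= 1)")
        for pid, n in self.panel_sizes.items():
            if n < 1:
                raise ConfigurationError(f"panel_sizes[{pid!r}]: {n} (must be >= 1)")
        if self.n_variants < 0:
            raise ConfigurationError(f"n_variants: {self.n_variants}")
        if self.n_planted_novel < 0 or self.n_planted_differential < 0:
            raise ConfigurationError("n_planted_novel / n_planted_differential must be >= 0")
        if self.n_planted_novel + self.n_planted_differential > self.n_variants:
            raise ConfigurationError(
                "n_planted_novel + n_planted_differential exceeds n_variants"
            )
        lo, hi = self.planted_carrier_range
        if lo < 2:
            raise ConfigurationError(
                f"planted_carrier_range: minimum {lo} < 2 (planted variants must survive the recurrence filter)"
            )
        if hi < lo or hi > self.n_patients:
            raise ConfigurationError(f"planted_carrier_range: ({lo}, {hi})")
        if not 0 < self.planted_differential_af <= 0.05:
            raise ConfigurationError(
                f"planted_differential_af: {self.planted_differential_af} (must be in (0, 0.05])"
            )
        if not 0.0 <= self.deleterious_rate_null <= 1.0:
            raise ConfigurationError(f"deleterious_rate_null: {self.deleterious_rate_null}")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ConfigurationError(f"corruption_rate: {self.corruption_rate}")
        if self.n_families < 1:
            raise ConfigurationError(f"n_families: {self.n_families}")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated dataset."""

    planted_novel_ids: set[str]
    planted_differential_ids: set[str]
    planted_family: str
    effects: dict[str, dict]

    def __post_init__(self) -> None:
        if self.planted_novel_ids & self.planted_differential_ids:
            raise ValidationError("planted novel/differential sets overlap")

    def to_dict(self) -> dict:
        return {
            "planted_novel_ids": sorted(self.planted_novel_ids),
            "planted_differential_ids": sorted(self.planted_differential_ids),
            "planted_family": self.planted_family,
            "effects": self.effects,
        }


@dataclass
class SyntheticDataset:
    variants: list[CohortVariant]
    panels: dict[str, dict[VariantKey, PanelRecord]]
    panel_sizes: dict[str, int]
    clinical: pd.DataFrame
    family_map: FamilyMap
    truth: SyntheticTruth
    sample_ids: list[str]
    annotation_rows: list[dict]


# Native predictor labels used when emitting annotation sidecars.
_DELETERIOUS_LABELS = {
    "sift": "D", "polyphen2": "probably_damaging", "lrt": "D",
    "fathmm": "D", "mutationtaster": "disease_causing",
}
_TOLERATED_LABELS = {
    "sift": "T", "polyphen2": "benign", "lrt": "N",
    "fathmm": "T", "mutationtaster": "polymorphism",
}


def _verdicts(rng: np.random.Generator, n_deleterious: int) -> dict[str, str]:
    """Native labels with exactly ``n_deleterious`` deleterious votes."""
    order = list(fio.PREDICTORS)
    dele = set(rng.choice(order, size=n_deleterious, replace=False)) if n_deleterious else set()
    out = {}
    for p in order:
        if p in dele:
            out[p] = _DELETERIOUS_LABELS[p]
        elif rng.random() < 0.05:
            out[p] = "."
        else:
            out[p] = _TOLERATED_LABELS[p]
    return out


def _panel_record(panel_id: str, n_samples: int, af: float) -> PanelRecord | None:
    """Emit a panel row only when the frequency is resolvable as >= 1 allele."""
    count = int(np.floor(af * 2 * n_samples + 0.5))
    if count < 1:
        return None
    return PanelRecord(panel_id, n_samples, count / (2 * n_samples), present=True)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset with planted truth.

    Deterministic given the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n_pat = config.n_patients
    sample_ids = [f"P{i:04d}" for i in range(1, n_pat + 1)]
    bg = config.background_panel_af_distribution
    n_novel, n_diff = config.n_planted_novel, config.n_planted_differential
    n_null = config.n_variants - n_novel - n_diff

    # Unique variant sites, ordered by genome coordinate.
    positions = rng.choice(50_000_000, size=config.n_variants, replace=False) + 1
    chroms = rng.integers(1, 23, size=config.n_variants)
    base_idx = rng.integers(0, 4, size=config.n_variants)
    alt_shift = rng.integers(1, 4, size=config.n_variants)
    bases = np.array(["A", "C", "G", "T"])
    roles = np.array(["novel"] * n_novel + ["differential"] * n_diff + ["null"] * n_null)
    rng.shuffle(roles)

    variants: list[CohortVariant] = []
    annotation_rows: list[dict] = []
    panels: dict[str, dict[VariantKey, PanelRecord]] = {pid: {} for pid in config.panel_sizes}
    truth_novel: set[str] = set()
    truth_diff: set[str] = set()
    effects: dict[str, dict] = {}
    planted_genes: list[str] = []
    null_genes: list[str] = []
    lo, hi = config.planted_carrier_range

    gene_counter = 0
    for i in range(config.n_variants):
        key = VariantKey(
            str(chroms[i]),
            int(positions[i]),
            bases[base_idx[i]],
            bases[(base_idx[i] + alt_shift[i]) % 4],
        )
        role = roles[i]
        gene_counter += 1
        gene = f"GENE{gene_counter:05d}"

        if role == "novel":
            carriers = int(rng.integers(lo, hi + 1))
            latent_af = 0.0
            verdicts = _verdicts(rng, int(rng.integers(2, 6)))
            planted_genes.append(gene)
            corruptible = False
        elif role == "differential":
            carriers = int(rng.integers(lo, hi + 1))
            latent_af = config.planted_differential_af
            for pid, n_samples in config.panel_sizes.items():
                rec = _panel_record(pid, n_samples, latent_af)
                if rec is not None:
                    panels[pid][key] = rec
            verdicts = _verdicts(rng, int(rng.integers(2, 6)))
            planted_genes.append(gene)
            corruptible = False
        else:
            if bg.fixed_af is not None:
                latent_af = bg.fixed_af
            elif rng.random() < bg.p_absent:
                latent_af = 0.0
            else:
                latent_af = float(rng.beta(bg.beta_a, bg.beta_b)) * bg.max_af
                latent_af = max(latent_af, 1e-6)
            for pid, n_samples in config.panel_sizes.items():
                if latent_af > 0:
                    count = int(rng.binomial(2 * n_samples, latent_af))
                    if count >= 1:
                        panels[pid][key] = PanelRecord(
                            pid, n_samples, count / (2 * n_samples), present=True
                        )
            p_carrier = 1.0 - (1.0 - latent_af) ** 2 if latent_af > 0 else 1.0 / (2 * n_pat)
            carriers = int(rng.binomial(n_pat, p_carrier))
            n_del = (
                int(rng.integers(2, 6))
                if rng.random() < config.deleterious_rate_null
                else int(rng.integers(0, 2))
            )
            verdicts = _verdicts(rng, n_del)
            null_genes.append(gene)
            corruptible = True

        carrier_idx = rng.choice(n_pat, size=min(carriers, n_pat), replace=False)
        calls = []
        for j in sorted(carrier_idx):
            depth = max(1, int(rng.poisson(config.depth_distribution.mean)))
            # Kept inside (0.42, 0.58) so read-count rounding on write/read
            # cannot push a passing call across the strict 0.4/0.6 bounds.
            alt_frac = float(rng.uniform(0.42, 0.58))
            if corruptible and rng.random() < config.corruption_rate:
                if rng.random() < 0.5:
                    depth = int(rng.integers(1, 30))        # low depth
                else:
                    alt_frac = float(rng.uniform(0.61, 0.89))  # off-window fraction
            calls.append(ObservedCall(sample_ids[j], depth, alt_frac))
        normalized = {p: fio.normalize_verdict(p, v) for p, v in verdicts.items()}
        variants.append(CohortVariant(key, calls, gene, "missense_variant", normalized))
        annotation_rows.append(
            {"chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt,
             "gene": gene, "consequence": "missense_variant", **verdicts}
        )

        if role in ("novel", "differential"):
            (truth_novel if role == "novel" else truth_diff).add(str(key))
            effects[str(key)] = {
                "role": role,
                "gene": gene,
                "carriers": len(calls),
                "panel_afs": {
                    pid: (panels[pid][key].af if key in panels[pid] else 0.0)
                    for pid in config.panel_sizes
                },
            }

    # Gene families: planted genes in one designated family, null genes
    # scattered uniformly over the rest.
    family_to_genes: dict[str, set[str]] = {config.planted_family: set(planted_genes)}
    family_ids = [f"FAM{i:03d}" for i in range(config.n_families)]
    for g in null_genes:
        fam = family_ids[int(rng.integers(0, config.n_families))]
        family_to_genes.setdefault(fam, set()).add(g)
    gene_to_families: dict[str, set[str]] = {}
    for fam, genes in family_to_genes.items():
        for g in genes:
            gene_to_families.setdefault(g, set()).add(fam)
    family_names = {fam: fam.replace("FAM", "family ") for fam in family_to_genes}
    family_names[config.planted_family] = "planted family"
    family_map = FamilyMap(gene_to_families, family_to_genes, family_names)

    clinical = generate_clinical(n_pat, rng=rng)
    truth = SyntheticTruth(truth_novel, truth_diff, config.planted_family, effects)
    return SyntheticDataset(
        variants=variants,
        panels=panels,
        panel_sizes=dict(config.panel_sizes),
        clinical=clinical,
        family_map=family_map,
        truth=truth,
        sample_ids=sample_ids,
        annotation_rows=annotation_rows,
    )


def _exact_counts(n: int, proportions: dict) -> dict:
    """Largest-remainder apportionment of n among categories."""
    items = list(proportions.items())
    raw = [n * p for _, p in items]
    counts = [int(np.floor(x)) for x in raw]
    short = n - sum(counts)
    order = np.argsort([c - x for x, c in zip(raw, counts)])  # most negative remainder first
    for idx in order[:short]:
        counts[idx] += 1
    return {label: c for (label, _), c in zip(items, counts)}


def generate_clinical(
    n_patients: int,
    seed: int | None = None,
    category_proportions: dict | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a clinical table with exact category counts.

    Category counts follow the given proportions via largest-remainder
    apportionment (defaults reproduce the study cohort's margins:
    156 F / 39 M, 131 C / 64 S, 52 L / 143 R, apex 106/89 at
    ``n_patients=195``); labels are then shuffled across patients.
    Continuous fields draw from the cohort laws: age ~ N(14.93, 3.04),
    Cobb ~ N(41.88, 18.35) truncated above 10 degrees, tilted count
    rounded from N(13.00, 3.84) and clipped to >= 2.
    """
    if n_patients < 1:
        raise ConfigurationError(f"n_patients: {n_patients} (must be >= 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    proportions = {**DEFAULT_CLINICAL_PROPORTIONS, **(category_proportions or {})}
    for field_name, props in proportions.items():
        vals = list(props.values())
        if any(not 0.0 <= v <= 1.0 for v in vals) or abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"category_proportions[{field_name!r}]: proportions must be in [0,1] and sum to 1"
            )

    data: dict[str, list] = {"patient_id": [f"P{i:04d}" for i in range(1, n_patients + 1)]}
    for field_name, props in proportions.items():
        counts = _exact_counts(n_patients, props)
        labels = [label for label, c in counts.items() for _ in range(c)]
        data[field_name] = list(rng.permutation(np.array(labels, dtype=object)))

    mean, sd = CLINICAL_CONTINUOUS["age"]
    data["age"] = np.clip(rng.normal(mean, sd, n_patients), 5.0, None).round(1)
    mean, sd = CLINICAL_CONTINUOUS["cobb"]
    cobb = rng.normal(mean, sd, n_patients)
    while (cobb <= 10).any():  # AIS inclusion requires Cobb > 10 degrees
        bad = cobb <= 10
        cobb[bad] = rng.normal(mean, sd, int(bad.sum()))
    data["cobb"] = cobb.round(1)
    mean, sd = CLINICAL_CONTINUOUS["tilted_count"]
    data["tilted_count"] = np.maximum(2, np.round(rng.normal(mean, sd, n_patients))).astype(int)

    frame = pd.DataFrame(data)[fio.CLINICAL_COLUMNS]
    frame["apex_class"] = frame["apex_class"].astype(int)
    frame["lenke"] = frame["lenke"].astype(int)
    return frame


def write_dataset(dataset: SyntheticDataset, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write every dataset table through the package's format writers.

    Returns a name -> path map: cohort VCF, annotation TSV, one panel TSV
    per panel, clinical CSV, family-map TSV, truth JSON.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "annotation": os.path.join(out_dir, "annotation.tsv"),
        "clinical": os.path.join(out_dir, "clinical.csv"),
        "family_map": os.path.join(out_dir, "families.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    fio.write_cohort_vcf(dataset.variants, paths["vcf"], dataset.sample_ids)
    fio.write_annotation_tsv(dataset.annotation_rows, paths["annotation"])
    for pid, panel in dataset.panels.items():
        paths[f"panel_{pid}"] = os.path.join(out_dir, f"panel_{pid}.tsv")
        fio.write_panel_tsv(panel, paths[f"panel_{pid}"])
    fio.write_clinical_csv(dataset.clinical, paths["clinical"])
    fio.write_family_map(dataset.family_map, paths["family_map"])
    with open(paths["truth"], "wt") as fh:
        json.dump(dataset.truth.to_dict(), fh, indent=2, sort_keys=True)
    return paths
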