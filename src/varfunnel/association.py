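"""Per-variant burden comparison between the case cohort and reference panels.

Each funnel-surviving variant is compared against each panel with a 2x2
test on alternate-allele counts: case alleles (het carriers + 2 x hom
carriers out of 2 x n_cases) versus panel alleles (frequency x 2 x panel
size, rounded).  Fisher's exact test (two-sided, probability-mass
definition) and the 1-df Pearson chi-squared test are both reported;
classification uses Fisher.  Benjamini-Hochberg FDR is applied per panel
over all panel-present variants.

Classification follows the case-only discovery rule: a variant carried by
multiple patients and absent from every panel is *novel*; a panel-present
variant significantly enriched in cases (q < alpha) is *differential*;
everything else is *not_associated*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CohortVariant, PanelRecord, ValidationError, VariantKey

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "build_contingency",
    "fisher_exact",
    "chi_squared",
    "bh_fdr",
    "classify_variant",
    "associate_all",
    "NOVEL",
    "DIFFERENTIAL",
    "NOT_ASSOCIATED",
]

NOVEL = "novel"
DIFFERENTIAL = "differential"
NOT_ASSOCIATED = "not_associated"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 allele-count table: cases vs one reference panel."""

    case_alt: int
    case_ref: int
    panel_alt: int
    panel_ref: int

    def __post_init__(self) -> None:
        cells = (self.case_alt, self.case_ref, self.panel_alt, self.panel_ref)
        if any(c < 0 for c in cells):
            raise ValidationError(f"negative contingency cell in {cells}")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.case_alt, self.case_ref], [self.panel_alt, self.panel_ref]])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_contingency(
    case_carriers: int,
    case_hom_carriers: int,
    n_cases: int,
    panel: PanelRecord,
) -> ContingencyTable:
    """Build the allele-count table for one variant against one panel.

    Case alternate alleles are het carriers + 2 x hom carriers out of
    2 x n_cases chromosomes; panel alternate alleles are the published
    frequency times 2 x panel size, rounded to the nearest integer (ties
    up) since panels publish frequencies, not counts.
    """
    if case_hom_carriers > case_carriers:
        raise ValidationError("hom carriers exceed total carriers")
    if case_carriers > n_cases:
        raise ValidationError("carriers exceed cohort size")
    case_alt = (case_carriers - case_hom_carriers) + 2 * case_hom_carriers
    case_ref = 2 * n_cases - case_alt
    panel_alt = _round_half_up(panel.af * 2 * panel.n_samples) if panel.present else 0
    panel_ref = 2 * panel.n_samples - panel_alt
    return ContingencyTable(case_alt, case_ref, panel_alt, panel_ref)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value on the allele-count table.

    Uses the probability-mass definition: the sum of hypergeometric
    probabilities of all margin-fixed tables no more probable than the
    observed one.  A zero margin makes the table degenerate; p = 1 by
    convention.
    """
    a = table.as_array
    if a.sum(axis=0).min() == 0 or a.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(a, alternative="two-sided").pvalue)


def chi_squared(table: ContingencyTable) -> tuple[float, float, bool]:
    """1-df Pearson chi-squared without continuity correction.

    Returns ``(statistic, p, low_expected)`` where ``low_expected`` flags
    any expected cell below 5.  A zero margin leaves the statistic
    undefined; p = 1 with the flag set.
    """
    a = table.as_array
    if a.sum(axis=0).min() == 0 or a.sum(axis=1).min() == 0:
        return float("nan"), 1.0, True
    stat, p, _, expected = stats.chi2_contingency(a, correction=False)
    return float(stat), float(p), bool((expected < 5).any())


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PanelStats:
    """One panel's test results for one variant."""

    panel_id: str
    present: bool
    panel_alt: int
    p_fisher: float
    p_chi2: float
    chi2_stat: float
    low_expected: bool
    q: float | None = None


@dataclass
class AssociationResult:
    key: VariantKey
    gene: str | None
    carriers: int
    hom_carriers: int
    panel_stats: dict[str, PanelStats]
    classification: str = NOT_ASSOCIATED

    @property
    def min_q(self) -> float:
        qs = [s.q for s in self.panel_stats.values() if s.q is not None]
        return min(qs) if qs else 1.0


def classify_variant(
    carrier_count: int,
    panel_records: dict[str, PanelRecord | None],
    q_values: dict[str, float | None],
    alpha: float = 0.05,
    min_carriers: int = 2,
    panel_sig_mode: str = "all",
) -> str:
    """Classify one variant as novel / differential / not_associated.

    *Novel*: carried by >= ``min_carriers`` patients and absent (zero
    frequency) from every panel.  *Differential*: present in >= 1 panel
    and q < alpha in every present panel (``panel_sig_mode='all'``) or in
    at least one (``'any'``).  The two labels are mutually exclusive.
    """
    if panel_sig_mode not in ("all", "any"):
        raise ValidationError(f"panel_sig_mode must be 'all' or 'any', got {panel_sig_mode!r}")
    present = [
        pid for pid, rec in panel_records.items()
        if rec is not None and rec.present and rec.af > 0
    ]
    if not present:
        return NOVEL if carrier_count >= min_carriers else NOT_ASSOCIATED
    sig = [q_values.get(pid) is not None and q_values[pid] < alpha for pid in present]
    combine = all if panel_sig_mode == "all" else any
    return DIFFERENTIAL if combine(sig) else NOT_ASSOCIATED


def associate_all(
    candidates: list[CohortVariant],
    panels: dict[str, dict[VariantKey, PanelRecord]],
    n_cases: int,
    alpha: float = 0.05,
    min_carriers: int = 2,
    panel_sig_mode: str = "all",
) -> list[AssociationResult]:
    """Test every funnel candidate against every panel and classify.

    BH correction is applied within each panel's family of tests over the
    panel-present candidates.  Results are sorted by minimum q, then key.
    """
    results: list[AssociationResult] = []
    for v in candidates:
        hom = sum(1 for c in v.calls if c.genotype_class == "hom")
        stats_by_panel: dict[str, PanelStats] = {}
        for pid, panel in panels.items():
            rec = panel.get(v.key)
            present = rec is not None and rec.present and rec.af > 0
            if rec is None:
                rec = PanelRecord(pid, _panel_size(panel), 0.0, present=False)
            table = build_contingency(v.carriers, hom, n_cases, rec)
            p_f = fisher_exact(table)
            chi_stat, p_c, low = chi_squared(table)
            stats_by_panel[pid] = PanelStats(pid, present, table.panel_alt, p_f, p_c, chi_stat, low)
        results.append(AssociationResult(v.key, v.gene, v.carriers, hom, stats_by_panel))

    # BH family: per panel, over the panel-present candidates.
    for pid in panels:
        tested = [r for r in results if r.panel_stats[pid].present]
        if tested:
            qs = bh_fdr([r.panel_stats[pid].p_fisher for r in tested])
            for r, q in zip(tested, qs):
                r.panel_stats[pid].q = float(q)

    for r in results:
        panel_records = {
            pid: (panels[pid].get(r.key)) for pid in panels
        }
        q_values = {pid: r.panel_stats[pid].q for pid in panels}
        r.classification = classify_variant(
            r.carriers, panel_records, q_values, alpha, min_carriers, panel_sig_mode
        )

    results.sort(key=lambda r: (r.min_q, r.key))
    return results


def _panel_size(panel: dict[VariantKey, PanelRecord]) -> int:
    for rec in panel.values():
        return rec.n_samples
    return 1


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Long-format table: one row per variant x panel."""
    rows = []
    for r in results:
        for pid, s in r.panel_stats.items():
            rows.append(
                {
                    "chrom": r.key.chrom,
                    "pos": r.key.pos,
                    "ref": r.key.ref,
                    "alt": r.key.alt,
                    "gene": r.gene,
                    "carriers": r.carriers,
                    "case_alt": (r.carriers - r.hom_carriers) + 2 * r.hom_carriers,
                    "panel": pid,
                    "panel_present": s.present,
                    "panel_alt": s.panel_alt,
                    "p_fisher": s.p_fisher,
                    "p_chi2": s.p_chi2,
                    "q": s.q if s.q is not None else float("nan"),
                    "class": r.classification,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "carriers", "case_alt",
            "panel", "panel_present", "panel_alt", "p_fisher", "p_chi2", "q", "class",
        ],
    )
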