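"""Clinical-feature encoding, subgroup screening and feature correlation.

The cohort's phenotype table carries sex, age, Cobb angle, curve shape
(C/S), main-curve direction (L/R), apical-vertebra class (1 = T1-T9,
2 = under T10), tilted-vertebrae count and Lenke type.  Continuous
features are dichotomized at the cohort mean (values exactly at the mean
go to "below"); categorical features pass their levels through.

Per-variant genotype-phenotype screening compares carriers against
non-carriers: Wilcoxon rank-sum for continuous/ordinal features, Fisher's
exact test on the 2x2 carrier-by-level table for binary features, with BH
correction within each feature.  Lenke type is recorded but not screened.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr, fisher_exact as _fisher_2x2, ContingencyTable
from .io import CohortVariant, ValidationError, VariantKey

__all__ = [
    "SubgroupDefinition",
    "ClinicalAssociationResult",
    "FEATURE_TYPES",
    "VENN_FEATURES",
    "SCREEN_FEATURES",
    "cohort_summary",
    "dichotomize",
    "wilcoxon_rank_sum",
    "variant_feature_screen",
    "feature_correlation",
    "intersect_variant_sets",
]

#: Statistical type of each clinical feature.
FEATURE_TYPES = {
    "age": "continuous",
    "cobb": "continuous",
    "tilted_count": "continuous",
    "sex": "binary",
    "shape": "binary",
    "direction": "binary",
    "apex_class": "binary",
    "lenke": "categorical",
}

#: Features screened per variant; sex and shape are screened but excluded
#: from the default four-set Venn intersection.
SCREEN_FEATURES = ("cobb", "tilted_count", "direction", "apex_class", "shape", "sex")
VENN_FEATURES = ("apex_class", "cobb", "direction", "tilted_count")

#: Exact Wilcoxon enumeration is used up to this combined sample size
#: (tie-free); beyond it, the tie-corrected normal approximation with
#: continuity correction takes over.
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class SubgroupDefinition:
    """How to split the cohort on one feature.

    ``rule`` is ``above_below_mean`` for continuous features or
    ``categorical`` for two-level factors; ``levels`` names the group
    labels (for mean splits, ("below", "above")).
    """

    feature: str
    rule: str
    levels: tuple = ("below", "above")

    def __post_init__(self) -> None:
        if self.rule not in ("above_below_mean", "categorical"):
            raise ValidationError(f"unknown subgroup rule {self.rule!r}")
        if len(self.levels) != 2:
            raise ValidationError("subgroup definitions must name exactly two levels")


@dataclass(frozen=True)
class ClinicalAssociationResult:
    key: VariantKey
    feature: str
    test: str
    statistic: float
    p: float
    q: float | None = None


def cohort_summary(clinical: pd.DataFrame) -> dict:
    """Cohort descriptives: means +/- sample SD, category counts, F:M ratio.

    SDs use the n-1 denominator and are reported as None on a single
    record; the female:male ratio is None when there are no males.
    """
    if clinical.empty:
        raise ValidationError("empty clinical table")
    n = len(clinical)

    def mean_sd(col):
        mean = float(clinical[col].mean())
        sd = float(clinical[col].std(ddof=1)) if n > 1 else None
        return {"mean": mean, "sd": sd}

    counts = {
        col: clinical[col].value_counts().to_dict()
        for col in ("sex", "shape", "direction", "apex_class", "lenke")
    }
    n_f = int((clinical["sex"] == "F").sum())
    n_m = int((clinical["sex"] == "M").sum())
    return {
        "n_patients": n,
        "age": mean_sd("age"),
        "cobb": mean_sd("cobb"),
        "tilted_count": mean_sd("tilted_count"),
        "counts": counts,
        "female_male_ratio": (n_f / n_m) if n_m else None,
    }


def dichotomize(clinical: pd.DataFrame, definition: SubgroupDefinition) -> pd.Series:
    """Per-patient group labels for one subgroup definition.

    Mean splits assign "above" to values strictly greater than the cohort
    mean and "below" otherwise (ties at the mean go below); a constant
    continuous feature cannot be split and is an error.
    """
    if definition.feature not in clinical.columns:
        raise ValidationError(f"feature {definition.feature!r} not in clinical table")
    col = clinical[definition.feature]
    if definition.rule == "above_below_mean":
        if col.nunique() < 2:
            raise ValidationError(f"feature {definition.feature!r} is constant; cannot mean-split")
        below, above = definition.levels
        return pd.Series(
            np.where(col > col.mean(), above, below), index=clinical.index, name=definition.feature
        )
    return col.astype(str) if col.dtype != object else col.copy()


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact p by enumeration of rank assignments for small tie-free samples
    (combined n <= 12); otherwise the normal approximation with
    tie-corrected variance and continuity correction.  Degenerate inputs
    (all values identical) give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("wilcoxon_rank_sum requires two non-empty groups")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return float(a.size * b.size / 2), 1.0
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def variant_feature_screen(
    variants: list[CohortVariant],
    clinical: pd.DataFrame,
    features=SCREEN_FEATURES,
    alpha: float = 0.05,
    binary_feature_test: str = "fisher",
) -> tuple[pd.DataFrame, dict[str, set[VariantKey]], list[str]]:
    """Screen every variant against every clinical feature.

    Continuous/ordinal features compare the feature values of carriers vs
    non-carriers by Wilcoxon rank-sum; binary features use Fisher's exact
    test on the carrier-by-level 2x2 table (or a rank-sum on 0/1 coding
    with ``binary_feature_test='wilcoxon'``).  BH runs within each
    feature.  Returns the result table, the per-feature significant
    variant sets at q < alpha, and warnings for skipped variants (zero
    carriers, or carriers spanning the whole cohort).
    """
    if binary_feature_test not in ("fisher", "wilcoxon"):
        raise ValidationError(f"binary_feature_test must be fisher|wilcoxon, got {binary_feature_test!r}")
    patient_ids = clinical["patient_id"].astype(str)
    warnings: list[str] = []
    rows: list[ClinicalAssociationResult] = []
    for v in variants:
        carrier_ids = {c.sample_id for c in v.calls}
        is_carrier = patient_ids.isin(carrier_ids).to_numpy()
        if not is_carrier.any():
            warnings.append(f"{v.key}: no carriers in the clinical table; skipped")
            continue
        if is_carrier.all():
            warnings.append(f"{v.key}: carried by every patient; no contrast; skipped")
            continue
        for feature in features:
            ftype = FEATURE_TYPES[feature]
            col = clinical[feature]
            if ftype == "continuous":
                stat, p = wilcoxon_rank_sum(col[is_carrier], col[~is_carrier])
                rows.append(ClinicalAssociationResult(v.key, feature, "wilcoxon", stat, p))
            elif ftype == "binary":
                levels = sorted(col.unique())
                if len(levels) < 2:
                    continue
                if binary_feature_test == "wilcoxon":
                    coded = (col == levels[1]).astype(int)
                    stat, p = wilcoxon_rank_sum(coded[is_carrier], coded[~is_carrier])
                    rows.append(ClinicalAssociationResult(v.key, feature, "wilcoxon", stat, p))
                else:
                    level1 = col == levels[1]
                    table = ContingencyTable(
                        int((is_carrier & level1).sum()),
                        int((is_carrier & ~level1).sum()),
                        int((~is_carrier & level1).sum()),
                        int((~is_carrier & ~level1).sum()),
                    )
                    p = _fisher_2x2(table)
                    rows.append(ClinicalAssociationResult(v.key, feature, "fisher", float("nan"), p))

    frame = pd.DataFrame(
        [
            {
                "chrom": r.key.chrom, "pos": r.key.pos, "ref": r.key.ref, "alt": r.key.alt,
                "feature": r.feature, "test": r.test, "statistic": r.statistic, "p": r.p,
            }
            for r in rows
        ],
        columns=["chrom", "pos", "ref", "alt", "feature", "test", "statistic", "p"],
    )
    frame["q"] = np.nan
    significant: dict[str, set[VariantKey]] = {f: set() for f in features}
    for feature in features:
        mask = frame["feature"] == feature
        if mask.any():
            frame.loc[mask, "q"] = bh_fdr(frame.loc[mask, "p"].to_numpy())
        for _, row in frame.loc[mask & (frame["q"] < alpha)].iterrows():
            significant[feature].add(
                VariantKey(str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
            )
    return frame, significant, warnings


def feature_correlation(
    clinical: pd.DataFrame, features=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise association p-values between clinical features.

    The test is chosen by feature type: Fisher exact (2x2) or chi-squared
    for categorical pairs, Wilcoxon/Kruskal-Wallis for categorical vs
    continuous, Spearman correlation for continuous pairs.  Returns a
    symmetric p-value matrix (diagonal 0: a feature is perfectly
    associated with itself) and a matching matrix of test names.
    """
    features = list(features) if features is not None else [
        f for f in FEATURE_TYPES if f in clinical.columns and f != "lenke"
    ]
    if len(features) < 2:
        raise ValidationError("feature_correlation needs >= 2 features")
    p = pd.DataFrame(np.zeros((len(features), len(features))), index=features, columns=features)
    tests = pd.DataFrame("self", index=features, columns=features)
    for fa, fb in itertools.combinations(features, 2):
        pij, test = _pair_association(clinical, fa, fb)
        p.loc[fa, fb] = p.loc[fb, fa] = pij
        tests.loc[fa, fb] = tests.loc[fb, fa] = test
    return p, tests


def _pair_association(clinical: pd.DataFrame, fa: str, fb: str) -> tuple[float, str]:
    ta, tb = FEATURE_TYPES[fa], FEATURE_TYPES[fb]
    a, b = clinical[fa], clinical[fb]
    cat = {"binary", "categorical"}
    if ta in cat and tb in cat:
        table = pd.crosstab(a, b).to_numpy()
        if table.shape == (2, 2):
            return float(stats.fisher_exact(table, alternative="two-sided").pvalue), "fisher"
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            return 1.0, "chi2"
        return float(stats.chi2_contingency(table, correction=False).pvalue), "chi2"
    if ta in cat or tb in cat:
        cat_col, num_col = (a, b) if ta in cat else (b, a)
        groups = [num_col[cat_col == lvl] for lvl in sorted(cat_col.unique(), key=str)]
        groups = [g for g in groups if len(g)]
        if len(groups) < 2:
            return 1.0, "degenerate"
        if len(groups) == 2:
            _, pij = wilcoxon_rank_sum(groups[0], groups[1])
            return pij, "wilcoxon"
        return float(stats.kruskal(*groups).pvalue), "kruskal"
    if a.nunique() < 2 or b.nunique() < 2:
        return 1.0, "degenerate"
    return float(stats.spearmanr(a, b).pvalue), "spearman"


def intersect_variant_sets(
    sets: dict[str, set[VariantKey]]
) -> dict:
    """Venn-region counts over k named variant sets.

    Returns counts for all 2^k - 1 non-empty membership regions (keyed by
    the sorted tuple of member set names joined with '&'), the union size,
    and the shared-by-all count with its percentage of the union.
    """
    names = sorted(sets)
    if len(names) < 2:
        raise ValidationError("intersect_variant_sets needs >= 2 sets")
    union: set[VariantKey] = set().union(*sets.values())
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set(union)
            for m in members:
                inside &= sets[m]
            for other in names:
                if other not in members:
                    inside -= sets[other]
            regions["&".join(members)] = len(inside)
    shared_all = regions["&".join(names)]
    return {
        "set_sizes": {n: len(sets[n]) for n in names},
        "regions": regions,
        "union": len(union),
        "shared_by_all": shared_all,
        "shared_by_all_pct": (100.0 * shared_all / len(union)) if union else 0.0,
    }
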