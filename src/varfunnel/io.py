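"""Readers and writers for every file the pipeline touches.

All on-disk formats are plain text: a VCF 4.2 subset for cohort genotypes
(FORMAT fields DP and AD), TSV sidecars for annotation and reference-panel
allele frequencies, CSV for the clinical table, TSV for the HGNC-style
gene-family map, and GMT for gene sets.  Readers validate strictly and
return warnings as data rather than printing them.

Coordinates are 1-based inclusive, as in VCF.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd
import pysam

__all__ = [
    "VariantKey",
    "ObservedCall",
    "CohortVariant",
    "PanelRecord",
    "ClinicalRecord",
    "FamilyMap",
    "ParseError",
    "ValidationError",
    "NormalizationError",
    "PREDICTORS",
    "normalize_verdict",
    "read_cohort_vcf",
    "write_cohort_vcf",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "attach_annotations",
    "read_panel_tsv",
    "write_panel_tsv",
    "read_clinical_csv",
    "write_clinical_csv",
    "read_family_map",
    "write_family_map",
    "read_gmt",
    "write_gmt",
    "write_results",
]

BASES = {"A", "C", "G", "T"}

#: The five deleteriousness predictors whose verdicts arrive as annotation.
PREDICTORS = ("sift", "polyphen2", "lrt", "fathmm", "mutationtaster")

#: Missing-verdict tokens accepted in the annotation sidecar.
_MISSING_TOKENS = {"", ".", "na", "nan", "none", "missing", "unknown", "u"}

#: Native predictor labels -> {deleterious, tolerated}.  "D" is deleterious
#: in SIFT/LRT/FATHMM, probably-damaging in PolyPhen2 and disease-causing in
#: MutationTaster; everything the tools call benign/neutral/tolerated maps to
#: tolerated.
_VERDICT_TABLE: dict[str, dict[str, str]] = {
    "sift": {"d": "deleterious", "deleterious": "deleterious",
             "t": "tolerated", "tolerated": "tolerated"},
    "polyphen2": {"d": "deleterious", "probably_damaging": "deleterious",
                  "p": "tolerated", "possibly_damaging": "tolerated",
                  "b": "tolerated", "benign": "tolerated"},
    "lrt": {"d": "deleterious", "deleterious": "deleterious",
            "n": "tolerated", "neutral": "tolerated"},
    "fathmm": {"d": "deleterious", "damaging": "deleterious",
               "t": "tolerated", "tolerated": "tolerated"},
    "mutationtaster": {"a": "deleterious", "disease_causing_automatic": "deleterious",
                       "d": "deleterious", "disease_causing": "deleterious",
                       "n": "tolerated", "polymorphism": "tolerated",
                       "p": "tolerated", "polymorphism_automatic": "tolerated"},
}


class ParseError(ValueError):
    """A file cannot be parsed as its declared format."""


class ValidationError(ValueError):
    """A parsed value violates a schema or domain invariant."""


class NormalizationError(ValidationError):
    """A predictor verdict label is not in the normalization table."""


def normalize_verdict(predictor: str, label: object) -> str:
    """Map a predictor's native verdict label to {deleterious, tolerated, missing}."""
    if predictor not in _VERDICT_TABLE:
        raise NormalizationError(f"unknown predictor {predictor!r}")
    if label is None or (isinstance(label, float) and pd.isna(label)):
        return "missing"
    text = str(label).strip().lower()
    if text in _MISSING_TOKENS:
        return "missing"
    try:
        return _VERDICT_TABLE[predictor][text]
    except KeyError:
        raise NormalizationError(
            f"unknown {predictor} verdict label {label!r}"
        ) from None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic SNV site: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(f"ref/alt must be single A/C/G/T bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, ref, alt = text.split(":")
        return cls(chrom, int(pos), ref, alt)


@dataclass(frozen=True)
class ObservedCall:
    """One sample's read-level observation of a variant.

    ``alt_fraction`` is the fraction of reads supporting the alternate
    allele; ``genotype_class`` (het/hom/fail) is assigned by the QC stage
    and is ``None`` on read.
    """

    sample_id: str
    depth: int
    alt_fraction: float
    genotype_class: str | None = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth}")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValidationError(f"alt_fraction must be in [0,1], got {self.alt_fraction}")


@dataclass
class CohortVariant:
    """A cohort SNV with its carrier calls, gene annotation and verdicts."""

    key: VariantKey
    calls: list[ObservedCall]
    gene: str | None = None
    consequence: str | None = None
    predictor_verdicts: dict[str, str] = field(
        default_factory=lambda: {p: "missing" for p in PREDICTORS}
    )

    def __post_init__(self) -> None:
        ids = [c.sample_id for c in self.calls]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate sample ids in calls for {self.key}")
        if set(self.predictor_verdicts) != set(PREDICTORS):
            raise ValidationError(
                f"predictor_verdicts must have exactly the keys {PREDICTORS}"
            )

    @property
    def carriers(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class PanelRecord:
    """A reference panel's allele frequency for one variant."""

    panel_id: str
    n_samples: int
    af: float
    present: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError(f"n_samples must be >= 1, got {self.n_samples}")
        if not 0.0 <= self.af <= 1.0:
            raise ValidationError(f"af must be in [0,1], got {self.af}")
        if not self.present and self.af != 0.0:
            raise ValidationError("absent panel record must have af 0")


SEX_LEVELS = ("F", "M")
SHAPE_LEVELS = ("C", "S")
DIRECTION_LEVELS = ("L", "R")
APEX_LEVELS = (1, 2)          # 1 = apex at T1-T9, 2 = under T10
LENKE_LEVELS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's phenotype fields used for subgroup dichotomization."""

    patient_id: str
    sex: str
    age: float
    cobb: float
    shape: str
    direction: str
    apex_class: int
    tilted_count: int
    lenke: int

    def __post_init__(self) -> None:
        checks = [
            ("sex", self.sex, SEX_LEVELS),
            ("shape", self.shape, SHAPE_LEVELS),
            ("direction", self.direction, DIRECTION_LEVELS),
            ("apex_class", self.apex_class, APEX_LEVELS),
            ("lenke", self.lenke, LENKE_LEVELS),
        ]
        for name, value, levels in checks:
            if value not in levels:
                raise ValidationError(
                    f"patient {self.patient_id}: field {name}={value!r} not in {levels}"
                )
        if self.cobb <= 0:
            raise ValidationError(f"patient {self.patient_id}: cobb must be > 0")
        if self.tilted_count < 2:
            raise ValidationError(f"patient {self.patient_id}: tilted_count must be >= 2")


@dataclass
class FamilyMap:
    """HGNC-style gene-family membership (many-to-many)."""

    gene_to_families: dict[str, set[str]]
    family_to_genes: dict[str, set[str]]
    family_names: dict[str, str]


# ---------------------------------------------------------------------------
# Cohort VCF
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "patient_id", "sex", "age", "cobb", "shape", "direction",
    "apex_class", "tilted_count", "lenke",
]

ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "consequence", *PREDICTORS]


def read_cohort_vcf(path: str | os.PathLike) -> tuple[list[CohortVariant], list[str]]:
    """Read a cohort VCF into :class:`CohortVariant` records.

    Multiallelic and non-SNV records are excluded and counted in the
    returned warning list.  ``alt_fraction`` is computed as alt AD over
    total AD; samples with zero alternate reads are not carriers and are
    dropped from the call list.  Gene annotation and predictor verdicts are
    attached separately from the annotation sidecar.
    """
    path = os.fspath(path)
    with open(path, "rt") as fh:
        first = fh.readline()
    if not first.startswith("##fileformat=VCFv4"):
        raise ParseError(f"{path}: missing ##fileformat=VCFv4 header line")

    warnings: list[str] = []
    n_multi = n_non_snv = 0
    variants: list[CohortVariant] = []
    seen: set[VariantKey] = set()
    with pysam.VariantFile(path) as vf:
        fmt_keys = set(vf.header.formats.keys())
        if "DP" not in fmt_keys or ("AD" not in fmt_keys and "AF" not in fmt_keys):
            raise ParseError(f"{path}: FORMAT must declare DP and AD (or AF)")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                n_non_snv += 1
                continue
            key = VariantKey(rec.chrom, rec.pos, ref, alt)
            if key in seen:
                raise ParseError(f"{path}: duplicate record for {key}")
            seen.add(key)
            calls = []
            for sample, data in rec.samples.items():
                depth = data.get("DP")
                ad = data.get("AD")
                if depth is None:
                    raise ParseError(f"{path}: record {key} sample {sample} lacks DP")
                if ad is not None and ad[0] is not None:
                    total = sum(ad)
                    if total == 0:
                        continue
                    alt_frac = ad[1] / total
                elif "AF" in data and data.get("AF") is not None:
                    af_val = data.get("AF")
                    alt_frac = float(af_val[0] if isinstance(af_val, tuple) else af_val)
                else:
                    raise ParseError(f"{path}: record {key} sample {sample} lacks AD and AF")
                if alt_frac > 0:
                    calls.append(ObservedCall(sample, int(depth), float(alt_frac)))
            variants.append(CohortVariant(key, calls))
    if n_multi:
        warnings.append(f"multiallelic excluded: {n_multi}")
    if n_non_snv:
        warnings.append(f"non-SNV excluded: {n_non_snv}")
    return variants, warnings


def write_cohort_vcf(
    variants: list[CohortVariant],
    path: str | os.PathLike,
    sample_ids: list[str],
) -> None:
    """Write carriers-only calls as a single-alt VCF with DP/AD per sample.

    Non-carrier samples are written as ``0/0:<depth>:<depth>,0`` with a
    nominal reference depth so that round-tripping recovers the same
    carrier set.
    """
    lines = ["##fileformat=VCFv4.2", "##source=varfunnel"]
    for chrom in sorted({v.key.chrom for v in variants}, key=_chrom_order):
        lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    ref_depth = 60
    for v in sorted(variants, key=lambda v: (_chrom_order(v.key.chrom), v.key.pos)):
        by_sample = {c.sample_id: c for c in v.calls}
        cells = []
        for sid in sample_ids:
            call = by_sample.get(sid)
            if call is None:
                cells.append(f"0/0:{ref_depth}:{ref_depth},0")
            else:
                alt_reads = round(call.alt_fraction * call.depth)
                gt = "1/1" if call.alt_fraction > 0.9 else "0/1"
                cells.append(f"{gt}:{call.depth}:{call.depth - alt_reads},{alt_reads}")
        lines.append(
            f"{v.key.chrom}\t{v.key.pos}\t.\t{v.key.ref}\t{v.key.alt}\t.\tPASS\t.\tGT:DP:AD\t"
            + "\t".join(cells)
        )
    with open(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


def _chrom_order(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (0, f"{int(c):03d}") if c.isdigit() else (1, c)


# ---------------------------------------------------------------------------
# Annotation sidecar
# ---------------------------------------------------------------------------

def read_annotation_tsv(path: str | os.PathLike) -> dict[VariantKey, dict]:
    """Read the annotation sidecar keyed by variant.

    Returns ``{key: {"gene": ..., "consequence": ..., "verdicts": {...}}}``
    with verdicts normalized to {deleterious, tolerated, missing}.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    out: dict[VariantKey, dict] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        if key in out:
            raise ValidationError(f"{path}: duplicate annotation for {key}")
        out[key] = {
            "gene": str(row.gene),
            "consequence": str(row.consequence),
            "verdicts": {p: normalize_verdict(p, getattr(row, p)) for p in PREDICTORS},
        }
    return out


def write_annotation_tsv(rows: list[dict], path: str | os.PathLike) -> None:
    """Write annotation rows; each row carries native predictor labels."""
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def attach_annotations(
    variants: list[CohortVariant],
    annotations: dict[VariantKey, dict],
) -> list[str]:
    """Attach gene/consequence/verdicts to variants in place.

    Returns warnings for variants without an annotation row (their verdicts
    stay all-missing, so the deleteriousness filter drops them).
    """
    warnings = []
    for v in variants:
        ann = annotations.get(v.key)
        if ann is None:
            warnings.append(f"no annotation for {v.key}; verdicts treated as missing")
            continue
        v.gene = ann["gene"]
        v.consequence = ann["consequence"]
        v.predictor_verdicts = dict(ann["verdicts"])
    return warnings


# ---------------------------------------------------------------------------
# Reference panel tables
# ---------------------------------------------------------------------------

def read_panel_tsv(
    path: str | os.PathLike, panel_id: str, n_samples: int
) -> dict[VariantKey, PanelRecord]:
    """Read one panel's variant frequencies (columns chrom,pos,ref,alt,af).

    Variants absent from the file are absent from the panel (af 0).
    Duplicate keys and out-of-range frequencies are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "ref", "alt", "af"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing panel columns {missing}")
    out: dict[VariantKey, PanelRecord] = {}
    for row in df.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        if key in out:
            raise ValidationError(f"{path}: duplicate panel row for {key}")
        af = float(row.af)
        if not 0.0 <= af <= 1.0:
            raise ValidationError(f"{path}: af {af} outside [0,1] for {key}")
        out[key] = PanelRecord(panel_id, n_samples, af, present=True)
    return out


def write_panel_tsv(
    panel: dict[VariantKey, PanelRecord], path: str | os.PathLike
) -> None:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "af": rec.af}
        for k, rec in sorted(panel.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

def read_clinical_csv(path: str | os.PathLike) -> list[ClinicalRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing clinical columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                ClinicalRecord(
                    patient_id=str(row.patient_id),
                    sex=str(row.sex),
                    age=float(row.age),
                    cobb=float(row.cobb),
                    shape=str(row.shape),
                    direction=str(row.direction),
                    apex_class=int(row.apex_class),
                    tilted_count=int(row.tilted_count),
                    lenke=int(row.lenke),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 1}: {exc}") from None
    return records


def write_clinical_csv(
    records: list[ClinicalRecord] | pd.DataFrame, path: str | os.PathLike
) -> None:
    if isinstance(records, pd.DataFrame):
        df = records[CLINICAL_COLUMNS]
    else:
        df = pd.DataFrame([vars(r) for r in records], columns=CLINICAL_COLUMNS)
    df.to_csv(path, index=False)


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=CLINICAL_COLUMNS)


# ---------------------------------------------------------------------------
# Gene-family map and GMT gene sets
# ---------------------------------------------------------------------------

def read_family_map(path: str | os.PathLike) -> FamilyMap:
    """Read gene,family_id,family_name TSV; many-to-many memberships kept."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene", "family_id", "family_name"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing family-map columns {missing}")
    gene_to_families: dict[str, set[str]] = {}
    family_to_genes: dict[str, set[str]] = {}
    family_names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gene_to_families.setdefault(row.gene, set()).add(row.family_id)
        family_to_genes.setdefault(row.family_id, set()).add(row.gene)
        family_names.setdefault(row.family_id, row.family_name)
    return FamilyMap(gene_to_families, family_to_genes, family_names)


def write_family_map(fam: FamilyMap, path: str | os.PathLike) -> None:
    rows = [
        {"gene": g, "family_id": f, "family_name": fam.family_names.get(f, f)}
        for f, genes in sorted(fam.family_to_genes.items())
        for g in sorted(genes)
    ]
    pd.DataFrame(rows, columns=["gene", "family_id", "family_name"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene [<tab> gene ...]."""
    sets: dict[str, set[str]] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT line needs >= 3 tab-fields")
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene set {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, name, *sorted(sets[name])]) + "\n")


# ---------------------------------------------------------------------------
# Result bundle
# ---------------------------------------------------------------------------

def write_results(tables: dict, out_dir: str | os.PathLike) -> list[str]:
    """Write result tables to ``out_dir``.

    DataFrame values go to ``<name>.tsv``; dict values (e.g. the funnel
    report) to ``<name>.json``.  Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, table in tables.items():
        if isinstance(table, pd.DataFrame):
            path = os.path.join(out_dir, f"{name}.tsv")
            table.to_csv(path, sep="\t", index=False)
        else:
            path = os.path.join(out_dir, f"{name}.json")
            with open(path, "wt") as fh:
                json.dump(table, fh, indent=2, sort_keys=True, default=str)
        written.append(path)
    return written
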