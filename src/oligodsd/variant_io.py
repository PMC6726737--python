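"""Read and write per-patient annotated variant tables.

Two tab-separated dialects are supported:

``simple_tsv``
    The package's own dialect: one header line with a fixed column set, missing
    values written as ``ND``.  Predictor information is carried either as
    pre-summarized consensus count columns (``cadd_phred``, ``n_func``,
    ``n_cons``, ``n_spl_db``, ``n_spl_alamut``) or as raw per-predictor columns
    prefixed ``pred_``; the reader auto-detects which form is present.

``annovar_tsv``
    A thin adapter for annotation-pipeline exports whose consequence vocabulary
    is mapped onto the internal enum through an editable YAML table.

Coordinates are 1-based inclusive on the hg19/GRCh37 build (carried as
metadata, no liftover).  ``ND`` and ``0`` are distinct in frequency columns:
``ND`` means the variant was never observed in the reference population, ``0``
means observed-absent (frequency 0.0).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .predictors import (
    ALL_PREDICTORS,
    ConsensusCounts,
    PredictorProfile,
    profile_from_columns,
)

GENOME_BUILD = "hg19/GRCh37"
MISSING = "ND"

VAR_TYPES = frozenset({"snv", "deletion", "insertion", "delins"})
CONSEQUENCES = frozenset(
    {
        "missense",
        "synonymous",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "splicing_intronic",
        "splicing_exonic",
        "intronic",
        "upstream",
        "regulatory",
        "intergenic",
    }
)
ZYGOSITIES = frozenset({"het", "hemi", "hom"})

SIMPLE_TSV_COLUMNS = [
    "patient_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "var_type",
    "consequence",
    "hgvs_c",
    "hgvs_p",
    "dbsnp_id",
    "maf_gnomad",
    "maf_cohort",
    "zygosity",
    "depth",
    "quality",
    "ad_ref",
    "ad_alt",
    "repeat_region",
    "high_variability",
    "confirmed",
]
CONSENSUS_COLUMNS = ["cadd_phred", "n_func", "n_cons", "n_spl_db", "n_spl_alamut"]
TRAILING_COLUMNS = ["acmg_codes", "hgmd_note", "clinvar_label"]


class VariantTableError(ValueError):
    """Raised for malformed variant tables."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One patient-variant with its annotations, QC fields and evidence."""

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    var_type: str
    consequence: str
    hgvs_c: str
    hgvs_p: str = ""
    dbsnp_id: str = ""
    maf_gnomad: float | None = None  # None = not observed
    maf_cohort: float | None = None
    zygosity: str = "het"
    depth: int = 0
    quality: float = 0.0
    ad_ref: int = 0
    ad_alt: int = 0
    repeat_region: bool = False
    high_variability: bool = False
    confirmed: bool = True
    predictor_profile: PredictorProfile | None = None
    consensus: ConsensusCounts | None = None
    acmg_codes: str = ""
    hgmd_note: str = ""
    clinvar_label: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantTableError(f"{self.key}: pos must be >= 1")
        if self.var_type not in VAR_TYPES:
            raise VariantTableError(f"{self.key}: unknown var_type {self.var_type!r}")
        if self.consequence not in CONSEQUENCES:
            raise VariantTableError(
                f"{self.key}: unknown consequence {self.consequence!r}"
            )
        if self.zygosity not in ZYGOSITIES:
            raise VariantTableError(f"{self.key}: unknown zygosity {self.zygosity!r}")
        if self.var_type == "snv" and self.ref == self.alt:
            raise VariantTableError(f"{self.key}: ref == alt for an snv")
        for maf in (self.maf_gnomad, self.maf_cohort):
            if maf is not None and not (0.0 <= maf <= 1.0):
                raise VariantTableError(f"{self.key}: MAF {maf} outside [0, 1]")
        if self.depth < 0 or self.ad_ref < 0 or self.ad_alt < 0:
            raise VariantTableError(f"{self.key}: negative depth or allelic depth")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.gene, self.hgvs_c)

    @property
    def variant_key(self) -> tuple[str, str]:
        """Cross-patient identity: (gene, HGVSc)."""
        return (self.gene, self.hgvs_c)


@dataclass
class PatientVariantSet:
    """All retained variants of one patient plus the index MAMLD1 variation."""

    patient_id: str
    karyotype: str = "46,XY"
    variants: list[AnnotatedVariant] = field(default_factory=list)
    mamld1_variant: str = ""

    def __post_init__(self) -> None:
        for v in self.variants:
            if v.patient_id != self.patient_id:
                raise VariantTableError(
                    f"variant {v.key} does not belong to patient {self.patient_id}"
                )

    def __len__(self) -> int:
        return len(self.variants)

    def genes(self) -> set[str]:
        return {v.gene for v in self.variants}


# ------------------------------------------------------------------ parsing


def _parse_maf(cell: str, where: str) -> float | None:
    cell = cell.strip()
    if cell in ("", MISSING, "-", "–"):
        return None
    try:
        value = float(cell)
    except ValueError as exc:
        raise VariantTableError(f"{where}: non-numeric MAF {cell!r}") from exc
    if not (0.0 <= value <= 1.0):
        raise VariantTableError(f"{where}: MAF {value} outside [0, 1]")
    return value


def _parse_float(cell: str) -> float | None:
    cell = cell.strip()
    if cell in ("", MISSING, "-", "–", "NA"):
        return None
    return float(cell)


def _parse_int_count(cell: str) -> int | None:
    value = _parse_float(cell)
    return None if value is None else int(value)


def _parse_bool(cell: str) -> bool:
    return cell.strip() in ("1", "true", "True")


def default_consequence_map() -> dict[str, str]:
    """The packaged annotation-token -> internal-consequence mapping."""
    text = (
        resources.files("oligodsd").joinpath("data/consequence_map.yaml").read_text()
    )
    return {str(k): str(v) for k, v in yaml.safe_load(text).items()}


def map_consequence(token: str, mapping: dict[str, str], where: str = "") -> str:
    token = token.strip()
    if token in mapping:
        mapped = mapping[token]
    elif token in CONSEQUENCES:
        mapped = token
    else:
        raise VariantTableError(
            f"{where}: unmappable consequence token {token!r}; extend the mapping table"
        )
    if mapped not in CONSEQUENCES:
        raise VariantTableError(
            f"{where}: mapping sends {token!r} to unknown consequence {mapped!r}"
        )
    return mapped


def _row_to_variant(
    row: dict[str, str],
    pred_columns: list[str],
    has_consensus: bool,
    where: str,
) -> AnnotatedVariant:
    profile = None
    consensus = None
    if pred_columns:
        profile = profile_from_columns(
            {c[len("pred_") :]: _parse_float(row[c]) for c in pred_columns},
            cadd_phred=_parse_float(row.get("cadd_phred", MISSING)),
        )
    elif has_consensus:
        consensus = ConsensusCounts(
            cadd_phred=_parse_float(row["cadd_phred"]),
            functional_deleterious=_parse_int_count(row["n_func"]),
            conservation_conserved=_parse_int_count(row["n_cons"]),
            splicing_db_altered=_parse_int_count(row["n_spl_db"]),
            splicing_alamut_altered=_parse_int_count(row["n_spl_alamut"]),
        )
    return AnnotatedVariant(
        patient_id=row["patient_id"].strip(),
        gene=row["gene"].strip().upper(),
        chrom=row["chrom"].strip(),
        pos=int(row["pos"]),
        ref=row["ref"].strip(),
        alt=row["alt"].strip(),
        var_type=row["var_type"].strip(),
        consequence=row["consequence"].strip(),
        hgvs_c=row["hgvs_c"].strip(),
        hgvs_p=row["hgvs_p"].strip(),
        dbsnp_id=row["dbsnp_id"].strip(),
        maf_gnomad=_parse_maf(row["maf_gnomad"], where),
        maf_cohort=_parse_maf(row["maf_cohort"], where),
        zygosity=row["zygosity"].strip(),
        depth=int(row["depth"]),
        quality=float(row["quality"]),
        ad_ref=int(row["ad_ref"]),
        ad_alt=int(row["ad_alt"]),
        repeat_region=_parse_bool(row["repeat_region"]),
        high_variability=_parse_bool(row["high_variability"]),
        confirmed=_parse_bool(row["confirmed"]),
        predictor_profile=profile,
        consensus=consensus,
        acmg_codes=row.get("acmg_codes", "").strip(),
        hgmd_note=row.get("hgmd_note", "").strip(),
        clinvar_label=row.get("clinvar_label", "").strip(),
    )


def read_variant_table(
    path: str | Path,
    dialect: str = "simple_tsv",
    patient_id: str | None = None,
    karyotype: str = "46,XY",
    mamld1_variant: str = "",
    consequence_map: dict[str, str] | None = None,
) -> PatientVariantSet:
    """Read one per-patient annotated variant table.

    ``simple_tsv`` requires the package's exact column set; ``annovar_tsv``
    maps an annotation-pipeline export (columns Chr, Start, Ref, Alt,
    Func_refGene, ExonicFunc_refGene, Gene_refGene, HGVSc, HGVSp, avsnp,
    gnomAD_AF, cohort_AF, DP, GQ, AD_ref, AD_alt) through the consequence
    mapping table.
    """
    path = Path(path)
    if dialect == "simple_tsv":
        return _read_simple_tsv(path, patient_id, karyotype, mamld1_variant)
    if dialect == "annovar_tsv":
        return _read_annovar_tsv(
            path, patient_id, karyotype, mamld1_variant,
            consequence_map or default_consequence_map(),
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_simple_rows(path: Path) -> list[AnnotatedVariant]:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise VariantTableError(f"{path}: empty file, header required")
    header = lines[0].split("\t")
    missing = [c for c in SIMPLE_TSV_COLUMNS if c not in header]
    if missing:
        raise VariantTableError(f"{path}: missing required columns {missing}")
    pred_columns = [c for c in header if c.startswith("pred_")]
    has_consensus = not pred_columns and all(c in header for c in CONSENSUS_COLUMNS)
    variants = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if len(cells) != len(header):
            raise VariantTableError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        row = dict(zip(header, cells))
        variants.append(
            _row_to_variant(row, pred_columns, has_consensus, f"{path}:{lineno}")
        )
    return variants


def read_cohort_table(path: str | Path, karyotype: str = "46,XY") -> list["PatientVariantSet"]:
    """Read a simple_tsv table holding several patients; one set per patient id."""
    by_patient: dict[str, list[AnnotatedVariant]] = {}
    for v in _read_simple_rows(Path(path)):
        by_patient.setdefault(v.patient_id, []).append(v)
    return [
        PatientVariantSet(patient_id=pid, karyotype=karyotype, variants=vs)
        for pid, vs in sorted(by_patient.items())
    ]


def _read_simple_tsv(
    path: Path, patient_id: str | None, karyotype: str, mamld1_variant: str
) -> PatientVariantSet:
    variants = _read_simple_rows(path)
    pid = patient_id or (variants[0].patient_id if variants else "unknown")
    variants = [v for v in variants if v.patient_id == pid]
    return PatientVariantSet(
        patient_id=pid, karyotype=karyotype, variants=variants,
        mamld1_variant=mamld1_variant,
    )


_ANNOVAR_REQUIRED = [
    "Chr", "Start", "Ref", "Alt", "Func_refGene", "ExonicFunc_refGene",
    "Gene_refGene",
]


def _read_annovar_tsv(
    path: Path,
    patient_id: str | None,
    karyotype: str,
    mamld1_variant: str,
    cmap: dict[str, str],
) -> PatientVariantSet:
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise VariantTableError(f"{path}: empty file, header required")
    header = lines[0].split("\t")
    missing = [c for c in _ANNOVAR_REQUIRED if c not in header]
    if missing:
        raise VariantTableError(f"{path}: missing required columns {missing}")
    pid = patient_id or path.stem
    variants = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        row = dict(zip(header, raw.split("\t")))
        where = f"{path}:{lineno}"
        ref, alt = row["Ref"].strip(), row["Alt"].strip()
        if ref in ("-", "") :
            var_type = "insertion"
        elif alt in ("-", ""):
            var_type = "deletion"
        elif len(ref) == 1 and len(alt) == 1:
            var_type = "snv"
        else:
            var_type = "delins"
        token = row["ExonicFunc_refGene"].strip() or row["Func_refGene"].strip()
        if token in (".", ""):
            token = row["Func_refGene"].strip()
        consequence = map_consequence(token, cmap, where)
        variants.append(
            AnnotatedVariant(
                patient_id=pid,
                gene=row["Gene_refGene"].strip().upper(),
                chrom=row["Chr"].strip().removeprefix("chr"),
                pos=int(row["Start"]),
                ref=ref or "-",
                alt=alt or "-",
                var_type=var_type,
                consequence=consequence,
                hgvs_c=row.get("HGVSc", "").strip(),
                hgvs_p=row.get("HGVSp", "").strip(),
                dbsnp_id=row.get("avsnp", "").strip().replace(".", ""),
                maf_gnomad=_parse_maf(row.get("gnomAD_AF", MISSING), where),
                maf_cohort=_parse_maf(row.get("cohort_AF", MISSING), where),
                zygosity=row.get("zygosity", "het").strip() or "het",
                depth=int(row.get("DP", "0") or 0),
                quality=float(row.get("GQ", "0") or 0.0),
                ad_ref=int(row.get("AD_ref", "0") or 0),
                ad_alt=int(row.get("AD_alt", "0") or 0),
            )
        )
    return PatientVariantSet(
        patient_id=pid, karyotype=karyotype, variants=variants,
        mamld1_variant=mamld1_variant,
    )


# ------------------------------------------------------------------ writing


def _format_maf(value: float | None) -> str:
    if value is None:
        return MISSING
    return repr(value)


def _format_count(value: int | None) -> str:
    return MISSING if value is None else str(value)


def _format_float(value: float | None) -> str:
    return MISSING if value is None else repr(value)


def write_candidates(records: list[AnnotatedVariant], path: str | Path) -> None:
    """Write records as simple_tsv with pre-summarized predictor columns.

    Round-trips: ``read_variant_table(write_candidates(x)) == x`` field-by-field
    for records carrying consensus counts (raw predictor profiles are written
    as their ``pred_`` columns instead and survive their own round-trip).
    """
    path = Path(path)
    any_profile = any(r.predictor_profile is not None for r in records)
    header = list(SIMPLE_TSV_COLUMNS)
    if any_profile:
        header += ["cadd_phred"] + [f"pred_{name}" for name in ALL_PREDICTORS]
    else:
        header += CONSENSUS_COLUMNS
    header += TRAILING_COLUMNS
    lines = ["\t".join(header)]
    for r in records:
        cells = [
            r.patient_id, r.gene, r.chrom, str(r.pos), r.ref, r.alt, r.var_type,
            r.consequence, r.hgvs_c, r.hgvs_p, r.dbsnp_id,
            _format_maf(r.maf_gnomad), _format_maf(r.maf_cohort), r.zygosity,
            str(r.depth), repr(r.quality), str(r.ad_ref), str(r.ad_alt),
            "1" if r.repeat_region else "0",
            "1" if r.high_variability else "0",
            "1" if r.confirmed else "0",
        ]
        if any_profile:
            prof = r.predictor_profile
            cells.append(_format_float(prof.cadd_phred if prof else None))
            scores = prof.all_scores() if prof else {}
            cells += [_format_float(scores.get(name)) for name in ALL_PREDICTORS]
        else:
            c = r.consensus
            cells += [
                _format_float(c.cadd_phred if c else None),
                _format_count(c.functional_deleterious if c else None),
                _format_count(c.conservation_conserved if c else None),
                _format_count(c.splicing_db_altered if c else None),
                _format_count(c.splicing_alamut_altered if c else None),
            ]
        cells += [r.acmg_codes, r.hgmd_note, r.clinvar_label]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ----------------------------------------------------------------- fixture


class FixtureIntegrityError(RuntimeError):
    """Packaged cohort fixture does not match its recorded checksum."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files("oligodsd").joinpath(f"data/{name}")))


def verify_fixture_checksums() -> None:
    sums = _data_path("checksums.sha256").read_text().splitlines()
    for line in sums:
        digest, fname = line.split()
        actual = hashlib.sha256(_data_path(fname).read_bytes()).hexdigest()
        if actual != digest:
            raise FixtureIntegrityError(
                f"packaged fixture {fname} checksum mismatch "
                f"(expected {digest[:12]}..., got {actual[:12]}...)"
            )


def load_cohort_fixture() -> list[PatientVariantSet]:
    """Load the packaged eight-patient MAMLD1-carrier cohort.

    Returns the eight patients in id order; per-patient record counts are
    9, 1, 2, 4, 6, 16, 5 and 14 (57 records, 55 unique variants after
    cross-patient deduplication).  The patient-6 MAML3 record carries
    ``confirmed=False`` (Sanger confirmation failed for that call).
    """
    verify_fixture_checksums()
    meta = {}
    lines = _data_path("cohort_patients.tsv").read_text(encoding="utf-8").splitlines()
    for raw in lines[1:]:
        pid, karyotype, mamld1 = raw.split("\t")
        meta[pid] = (karyotype, mamld1)
    rows = _read_simple_rows(_data_path("cohort_variants.tsv"))
    by_patient: dict[str, list[AnnotatedVariant]] = {pid: [] for pid in meta}
    for v in rows:
        by_patient[v.patient_id].append(v)
    return [
        PatientVariantSet(
            patient_id=pid,
            karyotype=meta[pid][0],
            variants=by_patient[pid],
            mamld1_variant=meta[pid][1],
        )
        for pid in sorted(meta, key=int)
    ]


def read_vcf(
    path: str | Path,
    patient_id: str | None = None,
    karyotype: str = "46,XY",
) -> PatientVariantSet:
    """Minimal VCF 4.x adapter (CHROM/POS/REF/ALT/QUAL + GT, DP, AD).

    Produces simple_tsv-equivalent records with empty annotation fields;
    functional annotation must be supplied upstream as columns.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    path = str(path)
    vcf = VCF(path)
    pid = patient_id or (vcf.samples[0] if vcf.samples else Path(path).stem)
    variants = []
    for rec in vcf:
        for alt in rec.ALT:
            if len(rec.REF) == 1 and len(alt) == 1:
                var_type = "snv"
            elif len(alt) < len(rec.REF):
                var_type = "deletion"
            elif len(alt) > len(rec.REF):
                var_type = "insertion"
            else:
                var_type = "delins"
            gts = rec.genotypes[0] if rec.genotypes else [0, 0, False]
            alleles = [a for a in gts[:-1] if a >= 0]
            if len(alleles) == 1:
                zygosity = "hemi"
            elif len(set(alleles)) == 1 and alleles[0] != 0:
                zygosity = "hom"
            else:
                zygosity = "het"
            ad = rec.format("AD")
            ad_ref, ad_alt = (int(ad[0][0]), int(ad[0][1])) if ad is not None else (0, 0)
            dp = rec.format("DP")
            variants.append(
                AnnotatedVariant(
                    patient_id=pid,
                    gene="",
                    chrom=str(rec.CHROM).removeprefix("chr"),
                    pos=int(rec.POS),
                    ref=rec.REF,
                    alt=alt,
                    var_type=var_type,
                    consequence="intergenic",
                    hgvs_c=f"g.{rec.POS}{rec.REF}>{alt}",
                    zygosity=zygosity,
                    depth=int(dp[0][0]) if dp is not None else 0,
                    quality=float(rec.QUAL or 0.0),
                    ad_ref=ad_ref,
                    ad_alt=ad_alt,
                )
            )
    return PatientVariantSet(patient_id=pid, karyotype=karyotype, variants=variants)


def with_fields(v: AnnotatedVariant, **changes) -> AnnotatedVariant:
    """Functional update helper for an (immutable) AnnotatedVariant."""
    return replace(v, **changes)
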