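"""The prioritization cascade: panel, frequency/consequence, and QC rules.

Each variant is evaluated against an ordered rule sequence and receives a
complete audit trace:

  A   gene on the disease-tailored panel
  B   rare in the reference population (MAF <= keep threshold, or never
      observed) and in a retained consequence/location class; synonymous
      changes are deliberately retained (they can affect splicing)
  D1  not recurrent in more than ``max_patient_recurrence`` patients
  D2  not in a repeat region
  D3  not in a gene/region of high variability
  D4  adequate coverage and call quality
  D5  plausible allelic balance for heterozygous calls (hemi/hom exempt)
  H   local-cohort frequency lookup (informational; feeds step I)
  I   final rejection when ANY observed frequency (reference population or
      local cohort) reaches the reject threshold

The first failing rule determines exclusion; candidates have all-pass traces.
Cross-patient recurrence is computed on identical variant keys (gene, HGVSc)
over the whole cohort before any per-variant rule runs, so results are
independent of patient and row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .panel import GenePanel, annotate_gene
from .variant_io import AnnotatedVariant, PatientVariantSet

STEP_ORDER = ("A", "B", "D1", "D2", "D3", "D4", "D5", "H", "I")

DEFAULT_KEPT_CONSEQUENCES = frozenset(
    {
        "missense",
        "synonymous",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "splicing_intronic",
        "splicing_exonic",
        "upstream",
        "regulatory",
        "intergenic",
    }
)


class CascadeConfigError(ValueError):
    """Invalid cascade configuration."""


@dataclass(frozen=True)
class CascadeConfig:
    """Tunable thresholds of the cascade.

    ``maf_keep_threshold`` is the retention bound applied to the reference
    population frequency at step B; ``maf_reject_threshold`` is the stricter
    final rejection bound applied at step I to every observed frequency
    source.  Depth/quality floors and the heterozygous allele-balance window
    implement the coverage/quality/allelic-depth criteria.
    """

    maf_keep_threshold: float = 0.015
    maf_reject_threshold: float = 0.01
    max_patient_recurrence: int = 2
    kept_consequences: frozenset[str] = DEFAULT_KEPT_CONSEQUENCES
    min_depth: int = 10
    min_quality: float = 20.0
    het_allele_balance: tuple[float, float] = (0.25, 0.75)

    def validate(self) -> None:
        if self.maf_reject_threshold > self.maf_keep_threshold:
            raise CascadeConfigError(
                f"maf_reject_threshold ({self.maf_reject_threshold}) must be <= "
                f"maf_keep_threshold ({self.maf_keep_threshold})"
            )
        lo, hi = self.het_allele_balance
        if not (0.0 < lo < hi < 1.0):
            raise CascadeConfigError(
                f"het_allele_balance {self.het_allele_balance} must satisfy "
                "0 < lower < upper < 1"
            )
        if self.max_patient_recurrence < 1:
            raise CascadeConfigError("max_patient_recurrence must be >= 1")
        if self.min_depth < 0 or self.min_quality < 0:
            raise CascadeConfigError("min_depth and min_quality must be >= 0")


@dataclass(frozen=True)
class StepOutcome:
    label: str
    rule: str
    outcome: str  # "pass" | "fail"
    detail: str = ""

    @property
    def passed(self) -> bool:
        return self.outcome == "pass"


@dataclass
class FilterTrace:
    """Ordered record of every rule applied to one variant."""

    key: tuple[str, str, str]  # (patient_id, gene, hgvs_c)
    steps: list[StepOutcome] = field(default_factory=list)

    @property
    def final(self) -> str:
        return "excluded" if any(not s.passed for s in self.steps) else "candidate"

    @property
    def first_failure(self) -> StepOutcome | None:
        for s in self.steps:
            if not s.passed:
                return s
        return None


def apply_gene_filter(v: AnnotatedVariant, panel: GenePanel) -> StepOutcome:
    """Step A: retain only variants in panel genes (alias-aware)."""
    entry = annotate_gene(v.gene, panel)
    if entry is None:
        return StepOutcome("A", "gene on disease panel", "fail",
                           f"{v.gene} not on panel {panel.name!r}")
    return StepOutcome("A", "gene on disease panel", "pass",
                       f"{v.gene} -> panel entry {entry.symbol}")


def apply_frequency_consequence_filter(
    v: AnnotatedVariant, cfg: CascadeConfig
) -> list[StepOutcome]:
    """Steps B, H and I: rarity, location class, and final frequency rejection."""
    outcomes = []
    # step B: reference-population rarity + consequence class
    if v.consequence not in cfg.kept_consequences:
        outcomes.append(
            StepOutcome("B", "rare and in retained consequence class", "fail",
                        f"consequence {v.consequence} not retained")
        )
    elif v.maf_gnomad is not None and v.maf_gnomad > cfg.maf_keep_threshold:
        outcomes.append(
            StepOutcome("B", "rare and in retained consequence class", "fail",
                        f"gnomAD MAF {v.maf_gnomad} > {cfg.maf_keep_threshold}")
        )
    else:
        maf_txt = "not observed" if v.maf_gnomad is None else f"MAF {v.maf_gnomad}"
        outcomes.append(
            StepOutcome("B", "rare and in retained consequence class", "pass",
                        f"gnomAD {maf_txt}; consequence {v.consequence}")
        )
    # step H: local-cohort frequency lookup (informational)
    cohort_txt = (
        "not observed in local control cohort"
        if v.maf_cohort is None
        else f"local control cohort MAF {v.maf_cohort}"
    )
    outcomes.append(StepOutcome("H", "local-cohort frequency lookup", "pass", cohort_txt))
    # step I: either-source rejection
    offending = [
        (src, maf)
        for src, maf in (("gnomAD", v.maf_gnomad), ("cohort", v.maf_cohort))
        if maf is not None and maf >= cfg.maf_reject_threshold
    ]
    if offending:
        src, maf = offending[0]
        outcomes.append(
            StepOutcome("I", "below final rejection frequency", "fail",
                        f"{src} MAF {maf} >= {cfg.maf_reject_threshold}")
        )
    else:
        outcomes.append(
            StepOutcome("I", "below final rejection frequency", "pass", "")
        )
    return outcomes


def apply_quality_exclusions(
    v: AnnotatedVariant, cfg: CascadeConfig, recurrence_count: int
) -> list[StepOutcome]:
    """Steps D1-D5: recurrence, repeat/variability regions, coverage, balance.

    ``recurrence_count`` is the number of cohort patients carrying the
    identical variant (gene, HGVSc), computed cohort-wide by run_cascade.
    When allelic depths sum to zero for a heterozygous call the balance is
    undefined: D4 fails instead and D5 is skipped.
    """
    outcomes = []
    if recurrence_count > cfg.max_patient_recurrence:
        outcomes.append(
            StepOutcome("D1", "not recurrent across patients", "fail",
                        f"identical variant in {recurrence_count} patients "
                        f"(> {cfg.max_patient_recurrence})")
        )
    else:
        outcomes.append(
            StepOutcome("D1", "not recurrent across patients", "pass",
                        f"present in {recurrence_count} patient(s)")
        )
    outcomes.append(
        StepOutcome("D2", "not in repeat region", "fail" if v.repeat_region else "pass")
    )
    outcomes.append(
        StepOutcome("D3", "not in high-variability region",
                    "fail" if v.high_variability else "pass")
    )
    ad_total = v.ad_ref + v.ad_alt
    balance_undefined = v.zygosity == "het" and ad_total == 0
    if v.depth < cfg.min_depth or v.quality < cfg.min_quality or balance_undefined:
        details = []
        if v.depth < cfg.min_depth:
            details.append(f"depth {v.depth} < {cfg.min_depth}")
        if v.quality < cfg.min_quality:
            details.append(f"quality {v.quality} < {cfg.min_quality}")
        if balance_undefined:
            details.append("allelic depths unavailable")
        outcomes.append(
            StepOutcome("D4", "adequate coverage and quality", "fail", "; ".join(details))
        )
    else:
        outcomes.append(StepOutcome("D4", "adequate coverage and quality", "pass"))
    if v.zygosity == "het" and not balance_undefined:
        lo, hi = cfg.het_allele_balance
        balance = v.ad_alt / ad_total
        if lo <= balance <= hi:
            outcomes.append(
                StepOutcome("D5", "balanced allelic depths", "pass",
                            f"alt fraction {balance:.3f}")
            )
        else:
            outcomes.append(
                StepOutcome("D5", "balanced allelic depths", "fail",
                            f"alt fraction {balance:.3f} outside [{lo}, {hi}]")
            )
    # hemi/hom calls and undefined-balance hets carry no D5 step
    return outcomes


def compute_recurrence(cohort: list[PatientVariantSet]) -> dict[tuple[str, str], set[str]]:
    """Patients carrying each identical variant key (gene, HGVSc)."""
    recurrence: dict[tuple[str, str], set[str]] = {}
    for patient in cohort:
        for v in patient.variants:
            recurrence.setdefault(v.variant_key, set()).add(patient.patient_id)
    return recurrence


@dataclass
class CascadeResult:
    candidates: dict[str, list[AnnotatedVariant]]
    traces: list[FilterTrace]

    @property
    def n_candidates(self) -> int:
        return sum(len(vs) for vs in self.candidates.values())

    @property
    def n_excluded(self) -> int:
        return sum(1 for t in self.traces if t.final == "excluded")

    def trace_for(self, key: tuple[str, str, str]) -> FilterTrace:
        for t in self.traces:
            if t.key == key:
                return t
        raise KeyError(key)


def evaluate_variant(
    v: AnnotatedVariant,
    panel: GenePanel,
    cfg: CascadeConfig,
    recurrence_count: int,
) -> FilterTrace:
    """Full trace for one variant (all rules evaluated, audit-complete)."""
    steps = [apply_gene_filter(v, panel)]
    freq = apply_frequency_consequence_filter(v, cfg)
    steps.extend(apply_quality_exclusions(v, cfg, recurrence_count))
    steps.extend(freq)
    order = {label: i for i, label in enumerate(STEP_ORDER)}
    steps.sort(key=lambda s: order[s.label])
    return FilterTrace(key=v.key, steps=steps)


def run_cascade(
    cohort: list[PatientVariantSet],
    panel: GenePanel,
    cfg: CascadeConfig | None = None,
) -> CascadeResult:
    """Apply the full cascade to a cohort.

    Deterministic for fixed input and configuration; every input variant
    receives exactly one trace, and permuting patients or rows changes
    neither candidate sets nor recurrence counts.
    """
    cfg = cfg or CascadeConfig()
    cfg.validate()
    recurrence = compute_recurrence(cohort)
    candidates: dict[str, list[AnnotatedVariant]] = {}
    traces: list[FilterTrace] = []
    for patient in cohort:
        kept: list[AnnotatedVariant] = []
        for v in patient.variants:
            trace = evaluate_variant(v, panel, cfg, len(recurrence[v.variant_key]))
            traces.append(trace)
            if trace.final == "candidate":
                kept.append(v)
        candidates[patient.patient_id] = kept
    return CascadeResult(candidates=candidates, traces=traces)
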