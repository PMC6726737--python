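"""Synthetic annotated-exome cohorts with known ground truth.

The generator emulates the statistical structure the prioritization cascade
operates on: a large disease-tailored panel (default 606 genes, always
containing the 41 cohort genes and the MAMLD1 anchor), per-patient variant
tables with a realistic allele-frequency mixture (a point mass of
never-observed variants, a rare component, and a common component), planted
true candidates with clean QC, planted cross-patient recurrent variants, and
planted QC artifacts each violating exactly one cascade rule.

Every variant receives a truth label (candidate, or excluded with the rule
expected to fail first) assigned at construction time from the designed
category — the cascade is never consulted, so recovery tests are a genuine
cross-check.  A fixed seed yields byte-identical output files.

It does not emulate read-level signal, linkage or haplotype structure, nor
genuinely ambiguous QC calls: every planted artifact is unambiguous by
design, so recovery tests demonstrate rule wiring, not robustness to noisy
real-world annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import write_edges, load_interaction_fixture
from .panel import (
    EVIDENCE_CATEGORIES,
    GenePanel,
    GenePanelEntry,
    INHERITANCE_MODES,
    PHENOTYPE_TAGS,
    load_panel,
    write_panel,
)
from .variant_io import AnnotatedVariant, PatientVariantSet, write_candidates
from .predictors import ConsensusCounts

COHORT_GENES_FIXTURE = "panel_41_cohort.tsv"
SYNTH_PREFIX = "SYNG"  # reserved prefix: no collision with real symbols
OFFPANEL_PREFIX = "OFFG"

ARTIFACT_RULES = ("repeat_region", "high_variability", "low_quality", "allele_imbalance")
_ARTIFACT_STEP = {
    "repeat_region": "D2",
    "high_variability": "D3",
    "low_quality": "D4",
    "allele_imbalance": "D5",
}


class SimConfigError(ValueError):
    """Infeasible or invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    ``maf_weights`` are the mixture weights (never-observed, rare on
    (0, 0.015], common on [0.01, 0.5]) of the background allele-frequency
    spectrum.  Planted candidates are on-panel, rare (MAF <= 0.005 or never
    observed), QC-clean and shared by at most two patients; each recurrent
    variant is identical across ``recurrence_multiplicity`` patients; each
    artifact violates exactly one QC rule and is otherwise candidate-like.
    """

    n_patients: int = 8
    n_variants_per_patient: int = 200
    panel_size: int = 606
    frac_on_panel: float = 0.15
    maf_weights: tuple[float, float, float] = (0.25, 0.35, 0.40)
    n_planted_candidates_per_patient: int = 3
    n_recurrent_variants: int = 1
    recurrence_multiplicity: int = 3
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {rule: 0.01 for rule in ARTIFACT_RULES}
    )
    predictor_damaging_prob_planted: float = 0.9
    predictor_damaging_prob_background: float = 0.2
    edge_density: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_variants_per_patient < 1:
            raise SimConfigError("need at least one patient and one variant")
        for name, frac in (
            ("frac_on_panel", self.frac_on_panel),
            ("predictor_damaging_prob_planted", self.predictor_damaging_prob_planted),
            ("predictor_damaging_prob_background", self.predictor_damaging_prob_background),
            *((f"maf_weights[{i}]", w) for i, w in enumerate(self.maf_weights)),
            *((f"artifact_rates[{k}]", v) for k, v in self.artifact_rates.items()),
        ):
            if not (0.0 <= frac <= 1.0):
                raise SimConfigError(f"{name}={frac} outside [0, 1]")
        if abs(sum(self.maf_weights) - 1.0) > 1e-9:
            raise SimConfigError(f"maf_weights {self.maf_weights} must sum to 1")
        unknown = set(self.artifact_rates) - set(ARTIFACT_RULES)
        if unknown:
            raise SimConfigError(f"unknown artifact rule(s) {sorted(unknown)}")
        if self.n_recurrent_variants > 0:
            if self.recurrence_multiplicity < 3:
                raise SimConfigError(
                    "recurrence_multiplicity must be >= 3 to exceed the "
                    "two-patient recurrence rule"
                )
            if self.recurrence_multiplicity > self.n_patients:
                raise SimConfigError(
                    f"recurrence_multiplicity {self.recurrence_multiplicity} "
                    f"exceeds n_patients {self.n_patients}"
                )
        if self.panel_size < 42:
            raise SimConfigError(
                "panel_size must be >= 42 (the guaranteed cohort genes + anchor)"
            )
        planted = (
            self.n_planted_candidates_per_patient
            + self.n_recurrent_variants
            + self.n_artifacts_per_patient
        )
        if planted > self.n_variants_per_patient:
            raise SimConfigError(
                f"planted candidates + recurrent + artifacts ({planted}) exceed "
                f"n_variants_per_patient ({self.n_variants_per_patient})"
            )

    @property
    def n_artifacts_per_patient(self) -> int:
        return sum(
            int(round(rate * self.n_variants_per_patient))
            for rate in self.artifact_rates.values()
        )


@dataclass
class TruthLabels:
    """Expected cascade outcome per generated variant, fixed at construction."""

    labels: dict[tuple[str, str, str], tuple[str, str | None]] = field(
        default_factory=dict
    )

    def add(self, key, status: str, first_fail: str | None) -> None:
        self.labels[key] = (status, first_fail)

    def __len__(self) -> int:
        return len(self.labels)

    def status(self, key) -> str:
        return self.labels[key][0]

    def first_fail(self, key) -> str | None:
        return self.labels[key][1]

    def candidates(self) -> set[tuple[str, str, str]]:
        return {k for k, (status, _) in self.labels.items() if status == "candidate"}

    def write(self, path: str | Path) -> None:
        lines = ["patient_id\tgene\thgvs_c\tstatus\tfirst_fail"]
        for (pid, gene, hgvs), (status, fail) in sorted(self.labels.items()):
            lines.append(f"{pid}\t{gene}\t{hgvs}\t{status}\t{fail or '-'}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _cohort_panel() -> GenePanel:
    from importlib import resources

    return load_panel(
        Path(str(resources.files("oligodsd").joinpath(f"data/{COHORT_GENES_FIXTURE}")))
    )


def generate_panel(cfg: SimConfig) -> GenePanel:
    """Synthetic disease panel: the 41 cohort genes + MAMLD1 + synthetic fill.

    Synthetic entries carry random tags and inheritance drawn from fixed
    frequencies; symbols use a reserved prefix so alias resolution can never
    collide with real gene symbols.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 101])
    entries = list(_cohort_panel().entries)
    entries.append(
        GenePanelEntry(
            symbol="MAMLD1",
            evidence_categories=frozenset({"XY_DSD_reported", "mamld1_related"}),
            phenotype_tags=frozenset({"hypospadias", "micropenis"}),
            inheritance="XL",
            diagnostic_panel_member=True,
            source_note="index gene of the cohort",
        )
    )
    tags = sorted(PHENOTYPE_TAGS)
    categories = sorted(EVIDENCE_CATEGORIES - {"mamld1_related"})
    modes = sorted(INHERITANCE_MODES)
    n_synth = cfg.panel_size - len(entries)
    for i in range(n_synth):
        n_tags = int(rng.integers(0, 3))
        entry_tags = frozenset(
            rng.choice(tags, size=n_tags, replace=False).tolist()
        ) if n_tags else frozenset()
        entries.append(
            GenePanelEntry(
                symbol=f"{SYNTH_PREFIX}{i + 1:04d}",
                evidence_categories=frozenset({str(rng.choice(categories))}),
                phenotype_tags=entry_tags,
                inheritance=str(rng.choice(modes)),
                diagnostic_panel_member=bool(rng.random() < 0.3),
                source_note="synthetic panel gene",
            )
        )
    return GenePanel(entries=entries, name="synthetic_panel", version="sim")


def generate_edges(cfg: SimConfig, panel: GenePanel | None = None):
    """Random interaction graph over panel genes; narrative edges preserved."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 202])
    graph = load_interaction_fixture()
    panel = panel or generate_panel(cfg)
    symbols = sorted(panel.symbols())
    n = len(symbols)
    if cfg.edge_density > 0:
        n_random = int(round(cfg.edge_density * n * (n - 1) / 2))
        for _ in range(n_random):
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            a, b = symbols[int(i)], symbols[int(j)]
            if not graph.has_edge(a, b):
                graph.add_edge(
                    a, b,
                    combined_score=round(float(rng.uniform(0.4, 1.0)), 3),
                    channels=frozenset({"textmining"}),
                )
    return graph


def _draw_background_maf(rng: np.random.Generator, weights) -> float | None:
    component = rng.choice(3, p=list(weights))
    if component == 0:
        return None
    if component == 1:
        return round(float(rng.uniform(1e-6, 0.015)), 6)
    return round(float(rng.uniform(0.01, 0.5)), 6)


def _counts(rng: np.random.Generator, damaging_prob: float) -> ConsensusCounts:
    return ConsensusCounts(
        cadd_phred=round(float(rng.uniform(0, 40)), 2),
        functional_deleterious=int(rng.binomial(15, damaging_prob)),
        conservation_conserved=int(rng.binomial(6, damaging_prob)),
        splicing_db_altered=int(rng.binomial(3, damaging_prob)),
        splicing_alamut_altered=int(rng.binomial(5, damaging_prob)),
    )


_KEPT_CONSEQUENCES = ("missense", "synonymous", "nonsense", "frameshift",
                      "inframe_indel", "splicing_intronic", "splicing_exonic")


def _clean_variant(
    pid: str, gene: str, serial: int, rng: np.random.Generator,
    maf: float | None, damaging_prob: float,
) -> AnnotatedVariant:
    """A candidate-like variant: on whatever gene, clean QC, retained class."""
    depth = int(rng.integers(30, 150))
    alt = int(round(depth * float(rng.uniform(0.4, 0.6))))
    return AnnotatedVariant(
        patient_id=pid,
        gene=gene,
        chrom=str(int(rng.integers(1, 23))),
        pos=int(rng.integers(10_000, 50_000_000)),
        ref="A",
        alt="G",
        var_type="snv",
        consequence=str(rng.choice(_KEPT_CONSEQUENCES)),
        hgvs_c=f"c.{serial}A>G",
        hgvs_p="",
        maf_gnomad=maf,
        maf_cohort=None,
        zygosity="het",
        depth=depth,
        quality=round(float(rng.uniform(30, 99)), 1),
        ad_ref=depth - alt,
        ad_alt=alt,
        consensus=_counts(rng, damaging_prob),
    )


def generate_cohort(
    cfg: SimConfig, panel: GenePanel | None = None
) -> tuple[list[PatientVariantSet], TruthLabels]:
    """Generate per-patient variant tables plus construction truth labels."""
    cfg.validate()
    panel = panel or generate_panel(cfg)
    on_panel_genes = sorted(panel.symbols() - {"MAMLD1"})
    truth = TruthLabels()
    serial = 0

    # recurrent variants are shared verbatim by the first `multiplicity` patients
    rec_rng = np.random.default_rng([cfg.seed, 303])
    recurrent_templates = []
    for _ in range(cfg.n_recurrent_variants):
        serial += 1
        gene = str(rec_rng.choice(on_panel_genes))
        recurrent_templates.append(
            _clean_variant("0", gene, serial, rec_rng, maf=None, damaging_prob=0.5)
        )

    cohort = []
    for p in range(cfg.n_patients):
        pid = str(p + 1)
        rng = np.random.default_rng([cfg.seed, 1000 + p])
        variants: list[AnnotatedVariant] = []

        for _ in range(cfg.n_planted_candidates_per_patient):
            serial += 1
            gene = str(rng.choice(on_panel_genes))
            maf = None if rng.random() < 0.5 else round(float(rng.uniform(1e-6, 0.005)), 6)
            v = _clean_variant(pid, gene, serial, rng,
                               maf, cfg.predictor_damaging_prob_planted)
            variants.append(v)
            truth.add(v.key, "candidate", None)

        if p < cfg.recurrence_multiplicity:
            for template in recurrent_templates:
                v = _replace(template, patient_id=pid)
                variants.append(v)
                truth.add(v.key, "excluded", "D1")

        for rule in ARTIFACT_RULES:
            n_rule = int(round(cfg.artifact_rates.get(rule, 0.0)
                               * cfg.n_variants_per_patient))
            for _ in range(n_rule):
                serial += 1
                gene = str(rng.choice(on_panel_genes))
                v = _clean_variant(pid, gene, serial, rng, None,
                                   cfg.predictor_damaging_prob_background)
                if rule == "repeat_region":
                    v = _replace(v, repeat_region=True)
                elif rule == "high_variability":
                    v = _replace(v, high_variability=True)
                elif rule == "low_quality":
                    v = _replace(v, depth=int(rng.integers(0, 10)))
                elif rule == "allele_imbalance":
                    v = _replace(v, ad_ref=95, ad_alt=5, depth=100)
                variants.append(v)
                truth.add(v.key, "excluded", _ARTIFACT_STEP[rule])

        n_background = cfg.n_variants_per_patient - len(variants)
        for _ in range(n_background):
            serial += 1
            if rng.random() < cfg.frac_on_panel:
                # on-panel background is common: excluded on frequency alone
                gene = str(rng.choice(on_panel_genes))
                maf = round(float(rng.uniform(0.01, 0.5)), 6)
                v = _clean_variant(pid, gene, serial, rng, maf,
                                   cfg.predictor_damaging_prob_background)
                first_fail = "B" if maf > 0.015 else "I"
            else:
                gene = f"{OFFPANEL_PREFIX}{int(rng.integers(1, 20_000)):05d}"
                maf = _draw_background_maf(rng, cfg.maf_weights)
                v = _clean_variant(pid, gene, serial, rng, maf,
                                   cfg.predictor_damaging_prob_background)
                first_fail = "A"
            variants.append(v)
            truth.add(v.key, "excluded", first_fail)

        cohort.append(
            PatientVariantSet(
                patient_id=pid,
                karyotype="46,XY",
                variants=variants,
                mamld1_variant=f"c.{1000 + p}C>T",
            )
        )
    return cohort, truth


def _replace(v: AnnotatedVariant, **changes) -> AnnotatedVariant:
    from dataclasses import replace

    return replace(v, **changes)


def write_simulation(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write cohort/, panel.tsv, edges.tsv and truth.tsv.

    Output is byte-identical for a fixed configuration (including seed).
    """
    outdir = Path(outdir)
    (outdir / "cohort").mkdir(parents=True, exist_ok=True)
    panel = generate_panel(cfg)
    cohort, truth = generate_cohort(cfg, panel)
    edges = generate_edges(cfg, panel)
    paths = {"panel": outdir / "panel.tsv", "edges": outdir / "edges.tsv",
             "truth": outdir / "truth.tsv"}
    write_panel(panel, paths["panel"])
    write_edges(edges, paths["edges"])
    truth.write(paths["truth"])
    for patient in cohort:
        p = outdir / "cohort" / f"patient_{patient.patient_id}.tsv"
        write_candidates(patient.variants, p)
        paths[f"patient_{patient.patient_id}"] = p
    return paths
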