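"""Cohort-level arithmetic: deduplication, recurrence, tallies, panel overlap.

Variant identity across patients is the (gene, HGVSc) pair; when genomic
coordinates are present, records sharing a key must agree on
(chrom, pos, ref, alt) — a mismatch indicates a transcription or annotation
error and raises.  Phenotype tallies are defined at the gene level: a gene
carried by several patients or with several distinct variants counts once
per phenotype tag.
"""

from __future__ import annotations

from dataclasses import dataclass

from .panel import GenePanel, PHENOTYPE_TAGS, annotate_gene
from .variant_io import PatientVariantSet

VariantKey = tuple[str, str]  # (gene, hgvs_c)


def deduplicate_cohort(
    cohort: list[PatientVariantSet],
) -> tuple[set[VariantKey], set[str]]:
    """Unique variant keys and unique genes across the cohort.

    Identical (gene, HGVSc) in multiple patients counts once.  Raises when
    two records with the same key disagree on genomic coordinates.
    """
    coords: dict[VariantKey, tuple] = {}
    for patient in cohort:
        for v in patient.variants:
            site = (v.chrom, v.pos, v.ref, v.alt)
            prev = coords.get(v.variant_key)
            if prev is not None and prev != site:
                raise ValueError(
                    f"variant key {v.variant_key} maps to conflicting sites "
                    f"{prev} and {site}"
                )
            coords[v.variant_key] = site
    unique_variants = set(coords)
    unique_genes = {gene for gene, _ in unique_variants}
    return unique_variants, unique_genes


def recurrence_map(
    cohort: list[PatientVariantSet],
) -> tuple[dict[str, set[str]], dict[VariantKey, set[str]]]:
    """Per-gene and per-identical-variant patient sets."""
    gene_recurrence: dict[str, set[str]] = {}
    variant_recurrence: dict[VariantKey, set[str]] = {}
    for patient in cohort:
        for v in patient.variants:
            gene_recurrence.setdefault(v.gene, set()).add(patient.patient_id)
            variant_recurrence.setdefault(v.variant_key, set()).add(patient.patient_id)
    return gene_recurrence, variant_recurrence


def genes_with_patient_count(
    gene_recurrence: dict[str, set[str]], k: int
) -> set[str]:
    """Genes with variants in exactly k patients."""
    return {gene for gene, pids in gene_recurrence.items() if len(pids) == k}


def phenotype_tally(
    genes: set[str], panel: GenePanel
) -> tuple[dict[str, int], set[str]]:
    """Unique-gene counts per phenotype tag, plus genes unresolvable on the panel.

    Unresolvable genes are reported separately and counted in no tag.
    """
    counts = {tag: 0 for tag in sorted(PHENOTYPE_TAGS)}
    unresolved: set[str] = set()
    for gene in genes:
        entry = annotate_gene(gene, panel)
        if entry is None:
            unresolved.add(gene)
            continue
        for tag in entry.phenotype_tags:
            counts[tag] += 1
    return counts, unresolved


def panel_overlap(genes: set[str], panel: GenePanel) -> tuple[set[str], set[str]]:
    """Partition genes into (known to diagnostic panels, newly implicated)."""
    known: set[str] = set()
    new: set[str] = set()
    for gene in genes:
        entry = annotate_gene(gene, panel)
        if entry is not None and entry.diagnostic_panel_member:
            known.add(gene)
        else:
            new.add(gene)
    return known, new


@dataclass
class CohortSummary:
    n_patients: int
    per_patient: dict[str, tuple[int, int]]  # pid -> (variant_count, gene_count)
    unique_variants: int
    unique_genes: int
    variant_recurrence: dict[VariantKey, set[str]]
    gene_recurrence: dict[str, set[str]]
    phenotype_tally: dict[str, int]
    unresolved_genes: set[str]
    panel_overlap: tuple[set[str], set[str]]  # (known, new)

    def to_dict(self) -> dict:
        known, new = self.panel_overlap
        return {
            "n_patients": self.n_patients,
            "per_patient": {
                pid: {"variants": nv, "genes": ng}
                for pid, (nv, ng) in sorted(self.per_patient.items())
            },
            "unique_variants": self.unique_variants,
            "unique_genes": self.unique_genes,
            "variant_recurrence": {
                f"{gene}|{hgvs}": sorted(pids)
                for (gene, hgvs), pids in sorted(self.variant_recurrence.items())
                if len(pids) > 1
            },
            "genes_in_multiple_patients": {
                gene: sorted(pids)
                for gene, pids in sorted(self.gene_recurrence.items())
                if len(pids) > 1
            },
            "phenotype_tally": self.phenotype_tally,
            "unresolved_genes": sorted(self.unresolved_genes),
            "known_panel_genes": sorted(known),
            "new_genes": sorted(new),
        }


def summarize(cohort: list[PatientVariantSet], panel: GenePanel) -> CohortSummary:
    """Assemble the full cohort summary."""
    unique_variants, unique_genes = deduplicate_cohort(cohort)
    gene_rec, variant_rec = recurrence_map(cohort)
    tally, unresolved = phenotype_tally(unique_genes, panel)
    return CohortSummary(
        n_patients=len(cohort),
        per_patient={
            p.patient_id: (len(p.variants), len(p.genes())) for p in cohort
        },
        unique_variants=len(unique_variants),
        unique_genes=len(unique_genes),
        variant_recurrence=variant_rec,
        gene_recurrence=gene_rec,
        phenotype_tally=tally,
        unresolved_genes=unresolved,
        panel_overlap=panel_overlap(unique_genes, panel),
    )


def render_report(summary: CohortSummary) -> str:
    """Human-readable cohort report."""
    known, new = summary.panel_overlap
    lines = [
        "# Cohort summary",
        "",
        f"Patients: {summary.n_patients}",
        f"Unique variants: {summary.unique_variants} in {summary.unique_genes} genes",
        "",
        "## Per patient",
    ]
    for pid, (nv, ng) in sorted(summary.per_patient.items()):
        lines.append(f"- patient {pid}: {nv} variant(s) in {ng} gene(s)")
    lines += ["", "## Genes with variants in multiple patients"]
    for gene, pids in sorted(summary.gene_recurrence.items()):
        if len(pids) > 1:
            lines.append(f"- {gene}: patients {', '.join(sorted(pids))}")
    lines += ["", "## Identical variants shared across patients"]
    for (gene, hgvs), pids in sorted(summary.variant_recurrence.items()):
        if len(pids) > 1:
            lines.append(f"- {gene} {hgvs}: patients {', '.join(sorted(pids))}")
    lines += ["", "## Phenotype tally (unique genes per tag)"]
    for tag, count in summary.phenotype_tally.items():
        lines.append(f"- {tag}: {count}")
    lines += [
        "",
        f"## Diagnostic-panel overlap",
        f"- known panel genes ({len(known)}): {', '.join(sorted(known))}",
        f"- newly implicated genes ({len(new)}): {', '.join(sorted(new))}",
    ]
    if summary.unresolved_genes:
        lines += [
            "",
            f"Unresolvable on panel: {', '.join(sorted(summary.unresolved_genes))}",
        ]
    return "\n".join(lines) + "\n"
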