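"""Disease-tailored gene-panel registry.

The prioritization cascade filters exome variants against a curated list of
genes implicated in disorders/differences of sex development (DSD) and in the
MAMLD1 pathway.  A panel entry records how a gene earned its place on the list
(evidence categories), which DSD phenotypes it has been reported with
(phenotype tags), its inheritance mode, and whether it already appears in
commercial/clinical DSD diagnostic panels.

Symbols are normalized to uppercase and resolved through aliases before any
comparison, because annotation pipelines and panel sources disagree on casing
and on secondary symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

EVIDENCE_CATEGORIES = frozenset(
    {
        "XY_DSD_reported",
        "XX_DSD_reported",
        "syndromic",
        "animal_model",
        "gonadal_expression",
        "mamld1_related",
    }
)

PHENOTYPE_TAGS = frozenset(
    {
        "hypospadias",
        "cryptorchidism",
        "micropenis",
        "female_gonadal",
        "other_dsd",
        "syndromic_genitourinary",
    }
)

INHERITANCE_MODES = frozenset({"AD", "AR", "AD_AR", "XL", "unknown"})

PANEL_COLUMNS = [
    "symbol",
    "aliases",
    "categories",
    "tags",
    "inheritance",
    "diagnostic_panel_member",
    "source_note",
]


class PanelValidationError(ValueError):
    """Raised when a panel file violates the panel contract."""


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol for alias-safe comparison."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GenePanelEntry:
    """One gene on the disease-tailored panel."""

    symbol: str
    aliases: tuple[str, ...] = ()
    evidence_categories: frozenset[str] = frozenset()
    phenotype_tags: frozenset[str] = frozenset()
    inheritance: str = "unknown"
    diagnostic_panel_member: bool = False
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise PanelValidationError("panel entry with empty symbol")
        if not self.evidence_categories:
            raise PanelValidationError(
                f"{self.symbol}: evidence_categories must be non-empty"
            )
        unknown = set(self.evidence_categories) - EVIDENCE_CATEGORIES
        if unknown:
            raise PanelValidationError(
                f"{self.symbol}: unknown evidence categories {sorted(unknown)}"
            )
        unknown = set(self.phenotype_tags) - PHENOTYPE_TAGS
        if unknown:
            raise PanelValidationError(
                f"{self.symbol}: unknown phenotype tags {sorted(unknown)}"
            )
        if self.inheritance not in INHERITANCE_MODES:
            raise PanelValidationError(
                f"{self.symbol}: inheritance {self.inheritance!r} not one of "
                f"{sorted(INHERITANCE_MODES)}"
            )


@dataclass
class GenePanel:
    """A validated gene panel with alias-aware lookup."""

    entries: list[GenePanelEntry]
    name: str = "panel"
    version: str = "0"
    _index: dict[str, GenePanelEntry] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        index: dict[str, GenePanelEntry] = {}
        for entry in self.entries:
            for key in (entry.symbol, *entry.aliases):
                key = normalize_symbol(key)
                if key in index:
                    raise PanelValidationError(
                        f"symbol or alias {key!r} appears in more than one entry"
                    )
                index[key] = entry
        self._index = index

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self._index

    def symbols(self) -> set[str]:
        return {e.symbol for e in self.entries}

    def get(self, symbol: str) -> GenePanelEntry | None:
        """Case-insensitive, alias-aware lookup; None when absent."""
        return self._index.get(normalize_symbol(symbol))


def annotate_gene(symbol: str, panel: GenePanel) -> GenePanelEntry | None:
    """Look a symbol up on the panel; absence is a value (None), not an error."""
    return panel.get(symbol)


def _split_multi(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell or cell == "-":
        return ()
    return tuple(tok.strip() for tok in cell.split("|") if tok.strip())


def load_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Load a tab-separated panel file.

    Expected header: symbol, aliases (|-separated), categories (|-separated),
    tags (|-separated), inheritance, diagnostic_panel_member (0/1), source_note.
    Malformed rows are reported with their 1-based line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise PanelValidationError(f"{path}: empty file, header required")
    header = lines[0].rstrip("\n").split("\t")
    if header != PANEL_COLUMNS:
        raise PanelValidationError(
            f"{path}: header {header} does not match required columns {PANEL_COLUMNS}"
        )
    entries: list[GenePanelEntry] = []
    seen: dict[str, int] = {}
    problems: list[str] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if len(cells) != len(PANEL_COLUMNS):
            problems.append(f"line {lineno}: expected {len(PANEL_COLUMNS)} columns, got {len(cells)}")
            continue
        row = dict(zip(PANEL_COLUMNS, cells))
        symbol = normalize_symbol(row["symbol"])
        try:
            entry = GenePanelEntry(
                symbol=symbol,
                aliases=tuple(normalize_symbol(a) for a in _split_multi(row["aliases"])),
                evidence_categories=frozenset(_split_multi(row["categories"])),
                phenotype_tags=frozenset(_split_multi(row["tags"])),
                inheritance=row["inheritance"].strip(),
                diagnostic_panel_member=row["diagnostic_panel_member"].strip() == "1",
                source_note=row["source_note"].strip(),
            )
        except PanelValidationError as exc:
            problems.append(f"line {lineno}: {exc}")
            continue
        for key in (entry.symbol, *entry.aliases):
            if key in seen:
                problems.append(
                    f"line {lineno}: duplicate symbol/alias {key!r} "
                    f"(first seen on line {seen[key]})"
                )
            else:
                seen[key] = lineno
        entries.append(entry)
    if problems:
        raise PanelValidationError(f"{path}: " + "; ".join(problems))
    return GenePanel(entries=entries, name=name or path.stem, version="1")


def write_panel(panel: GenePanel, path: str | Path) -> None:
    """Serialize a panel in the same tab-separated dialect load_panel reads."""
    path = Path(path)
    rows = ["\t".join(PANEL_COLUMNS)]
    for e in panel.entries:
        rows.append(
            "\t".join(
                [
                    e.symbol,
                    "|".join(e.aliases),
                    "|".join(sorted(e.evidence_categories)),
                    "|".join(sorted(e.phenotype_tags)),
                    e.inheritance,
                    "1" if e.diagnostic_panel_member else "0",
                    e.source_note,
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def panel_stats(panel: GenePanel) -> dict[str, int]:
    """Count unique genes per phenotype tag (a multi-tag gene counts once per tag)."""
    counts: dict[str, int] = {tag: 0 for tag in sorted(PHENOTYPE_TAGS)}
    for entry in panel.entries:
        for tag in entry.phenotype_tags:
            counts[tag] += 1
    return counts


def restrict(panel: GenePanel, genes: Iterable[str], name: str = "restricted") -> GenePanel:
    """Sub-panel containing only the given genes (alias-aware)."""
    keep = []
    seen = set()
    for g in genes:
        entry = panel.get(g)
        if entry is not None and entry.symbol not in seen:
            keep.append(entry)
            seen.add(entry.symbol)
    return GenePanel(entries=keep, name=name, version=panel.version)
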