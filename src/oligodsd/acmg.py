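"""ACMG/AMP evidence-code parsing and five-tier classification.

Evidence codes are inputs here (assigned upstream by interpretation tools and
curators); this module combines an evidence set into one of Pathogenic /
Likely_pathogenic / VUS / Likely_benign / Benign with the 2015 combining
rules.  Benign-side evidence that does not itself reach Likely_benign or
Benign does not veto a pathogenic-side classification; only full two-sided
satisfaction collapses to VUS (rationale ``conflict_VUS``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

PATHOGENIC_CODES = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
)
BENIGN_CODES = frozenset(
    {"BA1"} | {f"BS{i}" for i in range(1, 5)} | {f"BP{i}" for i in range(1, 8)}
)
CODE_INVENTORY = PATHOGENIC_CODES | BENIGN_CODES

CLASSES = ("Pathogenic", "Likely_pathogenic", "VUS", "Likely_benign", "Benign")

_CLASS_PREFIXES = {
    "pathogenic": "Pathogenic",
    "likely pathogenic": "Likely_pathogenic",
    "likely_pathogenic": "Likely_pathogenic",
    "vus": "VUS",
    "uncertain significance": "VUS",
    "likely benign": "Likely_benign",
    "likely_benign": "Likely_benign",
    "benign": "Benign",
}


class EvidenceParseError(ValueError):
    """A token in an evidence cell is not a recognized ACMG/AMP code."""


def strength(label: str) -> str:
    """Strength class of a code label (PVS, PS, PM, PP, BA, BS, BP)."""
    m = re.match(r"(PVS|PS|PM|PP|BA|BS|BP)\d+$", label)
    if not m:
        raise EvidenceParseError(f"{label!r} is not an ACMG/AMP code")
    return m.group(1)


@dataclass(frozen=True)
class EvidenceCode:
    label: str

    def __post_init__(self) -> None:
        if self.label not in CODE_INVENTORY:
            raise EvidenceParseError(f"{self.label!r} is not in the code inventory")

    @property
    def strength(self) -> str:
        return strength(self.label)


def split_class_prefix(text: str) -> tuple[str | None, str]:
    """Split a printed cell like ``"VUS: PM2, PP3"`` into (class, code text).

    The leading class is parsed for comparison only; it is never trusted as
    input to classification.  Returns (None, text) when no prefix is present.
    """
    if ":" in text:
        head, _, rest = text.partition(":")
        cls = _CLASS_PREFIXES.get(head.strip().lower())
        if cls is not None:
            return cls, rest
    return None, text


def parse_codes(text: str) -> frozenset[str]:
    """Parse an evidence cell into a set of code labels.

    Tolerant of comma or whitespace separation and a leading class prefix
    (parsed but not trusted); ``-``, en-dashes and empty cells give the empty
    set.  An unknown token raises, naming the token.
    """
    _, rest = split_class_prefix(text or "")
    rest = rest.strip()
    if rest in ("", "-", "–", "—"):
        return frozenset()
    labels = []
    for token in re.split(r"[,\s;]+", rest):
        token = token.strip()
        if not token or token in ("-", "–", "—"):
            continue
        if token not in CODE_INVENTORY:
            raise EvidenceParseError(
                f"token {token!r} is not an ACMG/AMP 2015 evidence code"
            )
        labels.append(token)
    return frozenset(labels)


@dataclass(frozen=True)
class ACMGClass:
    value: str
    rationale: str

    def __post_init__(self) -> None:
        if self.value not in CLASSES:
            raise ValueError(f"unknown class {self.value!r}")


def _counts(codes: Iterable[str]) -> dict[str, int]:
    n = {"PVS": 0, "PS": 0, "PM": 0, "PP": 0, "BA": 0, "BS": 0, "BP": 0}
    for label in codes:
        n[strength(label)] += 1
    return n


def _pathogenic_rule(n: dict[str, int]) -> str | None:
    if n["PVS"] >= 1 and (
        n["PS"] >= 1
        or n["PM"] >= 2
        or (n["PM"] == 1 and n["PP"] >= 1)
        or n["PP"] >= 2
    ):
        return "P.PVS1_combination"
    if n["PS"] >= 2:
        return "P.two_strong"
    if n["PS"] == 1 and (
        n["PM"] >= 3
        or (n["PM"] == 2 and n["PP"] >= 2)
        or (n["PM"] == 1 and n["PP"] >= 4)
    ):
        return "P.strong_combination"
    return None


def _likely_pathogenic_rule(n: dict[str, int]) -> str | None:
    if n["PVS"] >= 1 and n["PM"] >= 1:
        return "LP.PVS1_moderate"
    if n["PS"] == 1 and 1 <= n["PM"] <= 2:
        return "LP.strong_moderate"
    if n["PS"] == 1 and n["PP"] >= 2:
        return "LP.strong_supporting"
    if n["PM"] >= 3:
        return "LP.three_moderate"
    if n["PM"] == 2 and n["PP"] >= 2:
        return "LP.two_moderate_supporting"
    if n["PM"] == 1 and n["PP"] >= 4:
        return "LP.moderate_four_supporting"
    return None


def _benign_rule(n: dict[str, int]) -> str | None:
    if n["BA"] >= 1:
        return "B.standalone"
    if n["BS"] >= 2:
        return "B.two_strong"
    return None


def _likely_benign_rule(n: dict[str, int]) -> str | None:
    if n["BS"] >= 1 and n["BP"] >= 1:
        return "LB.strong_supporting"
    if n["BP"] >= 2:
        return "LB.two_supporting"
    return None


def classify(codes: frozenset[str] | set[str]) -> ACMGClass:
    """Combine an evidence set into exactly one five-tier class.

    Deterministic; rationale names the first satisfied combining rule, or
    ``default_VUS`` (no rule satisfied) / ``conflict_VUS`` (both a
    pathogenic-side and a benign-side class satisfied).
    """
    for label in codes:
        if label not in CODE_INVENTORY:
            raise EvidenceParseError(f"{label!r} is not in the code inventory")
    n = _counts(codes)
    path_rule = _pathogenic_rule(n)
    lp_rule = None if path_rule else _likely_pathogenic_rule(n)
    ben_rule = _benign_rule(n)
    lb_rule = None if ben_rule else _likely_benign_rule(n)

    pathogenic_side = path_rule or lp_rule
    benign_side = ben_rule or lb_rule
    if pathogenic_side and benign_side:
        return ACMGClass("VUS", "conflict_VUS")
    if path_rule:
        return ACMGClass("Pathogenic", path_rule)
    if lp_rule:
        return ACMGClass("Likely_pathogenic", lp_rule)
    if ben_rule:
        return ACMGClass("Benign", ben_rule)
    if lb_rule:
        return ACMGClass("Likely_benign", lb_rule)
    return ACMGClass("VUS", "default_VUS")


@dataclass
class FixtureAgreement:
    """Concordance between computed classes and printed class prefixes."""

    records: list[dict]
    n_parseable: int
    n_matches: int
    n_mismatches: int
    n_unparseable: int

    @property
    def mismatches(self) -> list[dict]:
        return [r for r in self.records if r["status"] == "mismatch"]


def classify_fixture(cohort) -> FixtureAgreement:
    """Compare computed classes against printed class prefixes for a cohort.

    Records whose evidence cell carries no printed class prefix (e.g. an
    empty dash) are skipped and counted as unparseable.
    """
    records = []
    n_match = n_mismatch = n_unparseable = 0
    for patient in cohort:
        for v in patient.variants:
            printed, _ = split_class_prefix(v.acmg_codes or "")
            if printed is None:
                n_unparseable += 1
                records.append(
                    {
                        "patient_id": v.patient_id,
                        "gene": v.gene,
                        "hgvs_c": v.hgvs_c,
                        "status": "unparseable",
                        "printed": None,
                        "computed": None,
                        "rationale": None,
                    }
                )
                continue
            codes = parse_codes(v.acmg_codes)
            result = classify(codes)
            status = "match" if result.value == printed else "mismatch"
            if status == "match":
                n_match += 1
            else:
                n_mismatch += 1
            records.append(
                {
                    "patient_id": v.patient_id,
                    "gene": v.gene,
                    "hgvs_c": v.hgvs_c,
                    "status": status,
                    "printed": printed,
                    "computed": result.value,
                    "rationale": result.rationale,
                }
            )
    return FixtureAgreement(
        records=records,
        n_parseable=n_match + n_mismatch,
        n_matches=n_match,
        n_mismatches=n_mismatch,
        n_unparseable=n_unparseable,
    )
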