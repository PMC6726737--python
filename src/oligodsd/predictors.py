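"""In-silico pathogenicity predictor consensus.

Thirty predictors are grouped into four batteries and binarized against
per-tool cutoffs, then summarized as grouped counts: how many functional
predictors call the substitution deleterious (0-15), how many conservation
metrics call the site conserved (0-6), and how many splicing predictors call
splicing altered (0-3 database tools, 0-5 assay-suite channels).  CADD is
reported as its raw PHRED-scaled score, not binarized.

Cutoffs default to each tool's published recommendation and are fully
configurable; categorical tools (class labels rather than scores) are
binarized by membership of the label in a damaging set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

FUNCTIONAL_PREDICTORS: tuple[str, ...] = (
    "SIFT",
    "PolyPhen2_HumDiv",
    "PolyPhen2_HumVar",
    "PROVEAN",
    "MutationAssessor",
    "MutationTaster",
    "LRT",
    "FATHMM",
    "FATHMM_MKL",
    "VEST3",
    "MetaSVM",
    "MetaLR",
    "MCAP",
    "DANN",
    "fitCons",
)
CONSERVATION_PREDICTORS: tuple[str, ...] = (
    "GERP++",
    "phyloP_vertebrate",
    "phyloP_mammalian",
    "phastCons_vertebrate",
    "phastCons_mammalian",
    "SiPhy",
)
SPLICING_DB_PREDICTORS: tuple[str, ...] = ("dbscSNV_ADA", "dbscSNV_RF", "SPIDEX_dpsi")
SPLICING_ALAMUT_PREDICTORS: tuple[str, ...] = (
    "SSF",
    "MaxEnt",
    "NNSPLICE",
    "GeneSplicer",
    "ExSkip",
)
ALL_PREDICTORS: tuple[str, ...] = (
    FUNCTIONAL_PREDICTORS
    + CONSERVATION_PREDICTORS
    + SPLICING_DB_PREDICTORS
    + SPLICING_ALAMUT_PREDICTORS
)

GROUPS: dict[str, tuple[str, ...]] = {
    "functional": FUNCTIONAL_PREDICTORS,
    "conservation": CONSERVATION_PREDICTORS,
    "splicing_db": SPLICING_DB_PREDICTORS,
    "splicing_alamut": SPLICING_ALAMUT_PREDICTORS,
}


class UnknownPredictorError(KeyError):
    """A score was supplied for a predictor outside the known battery."""


@dataclass(frozen=True)
class ThresholdRule:
    """Direction-aware cutoff: how a raw score becomes a damaging call.

    kind:
      ``le``      damaging when score <= cutoff (e.g. SIFT, PROVEAN, FATHMM)
      ``ge``      damaging when score >= cutoff (most tools)
      ``abs_ge``  damaging when |score| >= cutoff (signed splicing deltas)
      ``label_in`` damaging when the (string) label is in ``labels``
    """

    kind: str
    cutoff: float = 0.0
    labels: frozenset[str] = frozenset()

    def call(self, raw) -> bool:
        if self.kind == "le":
            return float(raw) <= self.cutoff
        if self.kind == "ge":
            return float(raw) >= self.cutoff
        if self.kind == "abs_ge":
            return abs(float(raw)) >= self.cutoff
        if self.kind == "label_in":
            return str(raw) in self.labels
        raise ValueError(f"unknown threshold kind {self.kind!r}")


DEFAULT_THRESHOLDS: dict[str, ThresholdRule] = {
    # functional battery: published recommended cutoffs
    "SIFT": ThresholdRule("le", 0.05),
    "PolyPhen2_HumDiv": ThresholdRule("ge", 0.446),
    "PolyPhen2_HumVar": ThresholdRule("ge", 0.446),
    "PROVEAN": ThresholdRule("le", -2.5),
    "MutationAssessor": ThresholdRule("ge", 1.935),
    "MutationTaster": ThresholdRule("label_in", labels=frozenset({"A", "D"})),
    "LRT": ThresholdRule("label_in", labels=frozenset({"D"})),
    "FATHMM": ThresholdRule("le", -1.5),
    "FATHMM_MKL": ThresholdRule("ge", 0.5),
    "VEST3": ThresholdRule("ge", 0.5),
    "MetaSVM": ThresholdRule("label_in", labels=frozenset({"D"})),
    "MetaLR": ThresholdRule("label_in", labels=frozenset({"D"})),
    "MCAP": ThresholdRule("ge", 0.025),
    "DANN": ThresholdRule("ge", 0.9),
    "fitCons": ThresholdRule("ge", 0.7),
    # conservation battery
    "GERP++": ThresholdRule("ge", 2.0),
    "phyloP_vertebrate": ThresholdRule("ge", 1.6),
    "phyloP_mammalian": ThresholdRule("ge", 1.6),
    "phastCons_vertebrate": ThresholdRule("ge", 0.8),
    "phastCons_mammalian": ThresholdRule("ge", 0.8),
    "SiPhy": ThresholdRule("ge", 12.17),
    # splicing: database tools
    "dbscSNV_ADA": ThresholdRule("ge", 0.6),
    "dbscSNV_RF": ThresholdRule("ge", 0.6),
    "SPIDEX_dpsi": ThresholdRule("abs_ge", 5.0),
    # splicing: assay-suite channels, expressed as relative ref-vs-variant change
    "SSF": ThresholdRule("abs_ge", 0.10),
    "MaxEnt": ThresholdRule("abs_ge", 0.10),
    "NNSPLICE": ThresholdRule("abs_ge", 0.10),
    "GeneSplicer": ThresholdRule("abs_ge", 0.10),
    "ExSkip": ThresholdRule("abs_ge", 0.10),
}


def binarize_predictor(
    name: str,
    raw,
    thresholds: Mapping[str, ThresholdRule] | None = None,
) -> str:
    """Classify one raw score as deleterious / tolerated / not_available."""
    if name not in ALL_PREDICTORS:
        raise UnknownPredictorError(f"unknown predictor {name!r}")
    if raw is None:
        return "not_available"
    rule = (thresholds or DEFAULT_THRESHOLDS)[name]
    return "deleterious" if rule.call(raw) else "tolerated"


def _validated(scores: Mapping[str, object], battery: tuple[str, ...], label: str):
    unknown = set(scores) - set(battery)
    if unknown:
        raise UnknownPredictorError(
            f"unknown {label} predictor(s) {sorted(unknown)}; known: {list(battery)}"
        )
    return dict(scores)


@dataclass(frozen=True)
class PredictorProfile:
    """Raw per-predictor scores of one variant; missing tools are simply absent."""

    cadd_phred: float | None = None
    functional_scores: Mapping[str, object] = field(default_factory=dict)
    conservation_scores: Mapping[str, object] = field(default_factory=dict)
    splicing_scores_db: Mapping[str, object] = field(default_factory=dict)
    splicing_scores_alamut: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "functional_scores",
            _validated(self.functional_scores, FUNCTIONAL_PREDICTORS, "functional"),
        )
        object.__setattr__(
            self, "conservation_scores",
            _validated(self.conservation_scores, CONSERVATION_PREDICTORS, "conservation"),
        )
        object.__setattr__(
            self, "splicing_scores_db",
            _validated(self.splicing_scores_db, SPLICING_DB_PREDICTORS, "splicing"),
        )
        object.__setattr__(
            self, "splicing_scores_alamut",
            _validated(self.splicing_scores_alamut, SPLICING_ALAMUT_PREDICTORS, "splicing"),
        )

    def all_scores(self) -> dict[str, object]:
        return {
            **self.functional_scores,
            **self.conservation_scores,
            **self.splicing_scores_db,
            **self.splicing_scores_alamut,
        }

    def group_scores(self, group: str) -> dict[str, object]:
        return {
            "functional": self.functional_scores,
            "conservation": self.conservation_scores,
            "splicing_db": self.splicing_scores_db,
            "splicing_alamut": self.splicing_scores_alamut,
        }[group]


def profile_from_columns(
    scores: Mapping[str, object], cadd_phred: float | None = None
) -> PredictorProfile:
    """Build a profile from flat per-predictor columns (None values dropped)."""
    groups: dict[str, dict[str, object]] = {g: {} for g in GROUPS}
    for name, value in scores.items():
        if value is None:
            continue
        for group, battery in GROUPS.items():
            if name in battery:
                groups[group][name] = value
                break
        else:
            raise UnknownPredictorError(f"unknown predictor column {name!r}")
    return PredictorProfile(
        cadd_phred=cadd_phred,
        functional_scores=groups["functional"],
        conservation_scores=groups["conservation"],
        splicing_scores_db=groups["splicing_db"],
        splicing_scores_alamut=groups["splicing_alamut"],
    )


@dataclass(frozen=True)
class ConsensusCounts:
    """Grouped damaging-call counts as printed in candidate tables.

    A group whose predictors are all unavailable reports None (printed "NA"),
    distinguishing "no tool could score this variant" from "all tools scored
    it benign" (0).
    """

    cadd_phred: float | None = None
    functional_deleterious: int | None = None
    conservation_conserved: int | None = None
    splicing_db_altered: int | None = None
    splicing_alamut_altered: int | None = None

    def __post_init__(self) -> None:
        limits = {
            "functional_deleterious": len(FUNCTIONAL_PREDICTORS),
            "conservation_conserved": len(CONSERVATION_PREDICTORS),
            "splicing_db_altered": len(SPLICING_DB_PREDICTORS),
            "splicing_alamut_altered": len(SPLICING_ALAMUT_PREDICTORS),
        }
        for attr, limit in limits.items():
            value = getattr(self, attr)
            if value is not None and not (0 <= value <= limit):
                raise ValueError(f"{attr}={value} outside [0, {limit}]")


def _group_count(
    scores: Mapping[str, object], thresholds: Mapping[str, ThresholdRule]
) -> int | None:
    calls = [
        binarize_predictor(name, raw, thresholds) for name, raw in scores.items()
    ]
    available = [c for c in calls if c != "not_available"]
    if not available:
        return None
    return sum(c == "deleterious" for c in available)


def summarize_profile(
    profile: PredictorProfile,
    thresholds: Mapping[str, ThresholdRule] | None = None,
) -> ConsensusCounts:
    """Collapse a raw profile into grouped consensus counts."""
    thresholds = thresholds or DEFAULT_THRESHOLDS
    return ConsensusCounts(
        cadd_phred=profile.cadd_phred,
        functional_deleterious=_group_count(profile.functional_scores, thresholds),
        conservation_conserved=_group_count(profile.conservation_scores, thresholds),
        splicing_db_altered=_group_count(profile.splicing_scores_db, thresholds),
        splicing_alamut_altered=_group_count(profile.splicing_scores_alamut, thresholds),
    )


def consensus_report(
    candidates: Iterable,
    thresholds: Mapping[str, ThresholdRule] | None = None,
):
    """Per-variant consensus table (annotation only; never excludes a variant).

    Accepts AnnotatedVariant records: records with a raw predictor profile are
    summarized, records carrying pre-summarized counts pass through verbatim.
    Returns a pandas DataFrame whose predictor columns follow the candidate
    table's printed order.
    """
    import pandas as pd

    rows = []
    for v in candidates:
        if v.predictor_profile is not None:
            counts = summarize_profile(v.predictor_profile, thresholds)
        elif v.consensus is not None:
            counts = v.consensus
        else:
            counts = ConsensusCounts()
        rows.append(
            {
                "patient_id": v.patient_id,
                "gene": v.gene,
                "hgvs_c": v.hgvs_c,
                "cadd_phred": counts.cadd_phred,
                "n_func": counts.functional_deleterious,
                "n_cons": counts.conservation_conserved,
                "n_spl_db": counts.splicing_db_altered,
                "n_spl_alamut": counts.splicing_alamut_altered,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "gene", "hgvs_c",
            "cadd_phred", "n_func", "n_cons", "n_spl_db", "n_spl_alamut",
        ],
    )
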