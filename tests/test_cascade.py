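"""Filter cascade: rule wiring, traces, oracle equivalence, monotonicity."""

import dataclasses

import pytest

from oligodsd.cascade import (
    CascadeConfig,
    CascadeConfigError,
    apply_frequency_consequence_filter,
    apply_gene_filter,
    apply_quality_exclusions,
    compute_recurrence,
    run_cascade,
)
from oligodsd.panel import GenePanel, GenePanelEntry
from oligodsd.simulate import SimConfig, generate_cohort, generate_panel
from oligodsd.variant_io import AnnotatedVariant, PatientVariantSet


def make_variant(**kw):
    defaults = dict(
        patient_id="1", gene="RET", chrom="10", pos=1000, ref="A", alt="G",
        var_type="snv", consequence="missense", hgvs_c="c.1A>G",
        maf_gnomad=0.001, zygosity="het", depth=100, quality=60.0,
        ad_ref=50, ad_alt=50,
    )
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


def tiny_panel(*symbols):
    return GenePanel(
        [
            GenePanelEntry(
                symbol=s, evidence_categories=frozenset({"XY_DSD_reported"})
            )
            for s in symbols
        ]
    )


# --------------------------------------------------------------- oracle
# Straight-line per-variant predicate, independent of the trace machinery.


def oracle_first_fail(v, on_panel, n_patients_with_variant, cfg):
    if not on_panel:
        return "A"
    if v.consequence not in cfg.kept_consequences:
        return "B"
    if v.maf_gnomad is not None and v.maf_gnomad > cfg.maf_keep_threshold:
        return "B"
    if n_patients_with_variant > cfg.max_patient_recurrence:
        return "D1"
    if v.repeat_region:
        return "D2"
    if v.high_variability:
        return "D3"
    undefined_balance = v.zygosity == "het" and v.ad_ref + v.ad_alt == 0
    if v.depth < cfg.min_depth or v.quality < cfg.min_quality or undefined_balance:
        return "D4"
    if v.zygosity == "het":
        balance = v.ad_alt / (v.ad_ref + v.ad_alt)
        lo, hi = cfg.het_allele_balance
        if not (lo <= balance <= hi):
            return "D5"
    for maf in (v.maf_gnomad, v.maf_cohort):
        if maf is not None and maf >= cfg.maf_reject_threshold:
            return "I"
    return None


def oracle_run(cohort, panel, cfg):
    carriers = {}
    for p in cohort:
        for v in p.variants:
            carriers.setdefault(v.variant_key, set()).add(p.patient_id)
    result = {}
    for p in cohort:
        for v in p.variants:
            result[v.key] = oracle_first_fail(
                v, v.gene in panel, len(carriers[v.variant_key]), cfg
            )
    return result


class TestGeneFilter:
    def test_panel_gene_passes(self, panel41):
        assert apply_gene_filter(make_variant(gene="RECQL4"), panel41).passed

    def test_off_panel_gene_fails(self, panel41):
        assert not apply_gene_filter(make_variant(gene="TTN"), panel41).passed

    def test_empty_panel_fails_everything(self):
        assert not apply_gene_filter(make_variant(), GenePanel([])).passed


class TestFrequencyConsequenceFilter:
    def run(self, v, cfg=None):
        return {s.label: s for s in
                apply_frequency_consequence_filter(v, cfg or CascadeConfig())}

    def test_rare_variant_passes(self):
        steps = self.run(make_variant(maf_gnomad=0.0088))
        assert steps["B"].passed and steps["I"].passed

    def test_borderline_frequency_fails_final_rejection_not_keep(self):
        steps = self.run(make_variant(maf_gnomad=0.012))
        assert steps["B"].passed          # 0.012 <= 0.015 keep-stage
        assert not steps["I"].passed      # 0.012 >= 0.01 reject-stage

    def test_never_observed_synonymous_passes(self):
        steps = self.run(make_variant(maf_gnomad=None, consequence="synonymous"))
        assert steps["B"].passed and steps["I"].passed

    def test_common_variant_fails_keep_stage(self):
        steps = self.run(make_variant(maf_gnomad=0.3))
        assert not steps["B"].passed

    def test_plain_intronic_location_not_retained(self):
        steps = self.run(make_variant(consequence="intronic"))
        assert not steps["B"].passed

    def test_local_cohort_frequency_triggers_rejection(self):
        steps = self.run(make_variant(maf_gnomad=None, maf_cohort=0.02))
        assert steps["B"].passed and not steps["I"].passed
        assert "cohort" in steps["I"].detail


class TestQualityExclusions:
    def run(self, v, recurrence=1, cfg=None):
        return {s.label: s for s in
                apply_quality_exclusions(v, cfg or CascadeConfig(), recurrence)}

    def test_two_patient_recurrence_allowed(self):
        assert self.run(make_variant(), recurrence=2)["D1"].passed

    def test_three_patient_recurrence_excluded(self):
        assert not self.run(make_variant(), recurrence=3)["D1"].passed

    def test_repeat_and_variability_flags(self):
        assert not self.run(make_variant(repeat_region=True))["D2"].passed
        assert not self.run(make_variant(high_variability=True))["D3"].passed

    def test_low_depth_or_quality_fails_coverage(self):
        assert not self.run(make_variant(depth=5))["D4"].passed
        assert not self.run(make_variant(quality=10.0))["D4"].passed

    def test_skewed_het_allelic_depths_fail_balance(self):
        steps = self.run(make_variant(ad_ref=30, ad_alt=2, depth=32))
        assert steps["D4"].passed and not steps["D5"].passed

    def test_hemizygous_exempt_from_balance(self):
        steps = self.run(make_variant(zygosity="hemi", ad_ref=0, ad_alt=100))
        assert "D5" not in steps

    def test_zero_allelic_depths_fail_coverage_and_skip_balance(self):
        steps = self.run(make_variant(ad_ref=0, ad_alt=0))
        assert not steps["D4"].passed and "D5" not in steps


class TestRunCascade:
    def test_cohort_fixture_rerun_excludes_nothing(self, cohort, panel41):
        result = run_cascade(cohort, panel41)
        assert result.n_excluded == 0
        assert result.n_candidates == 57
        assert all(t.final == "candidate" for t in result.traces)

    def test_planted_candidate_recovered_among_noise(self):
        cfg = SimConfig(
            n_patients=1, n_variants_per_patient=500, frac_on_panel=0.3,
            n_planted_candidates_per_patient=1, n_recurrent_variants=0,
            artifact_rates={}, seed=11,
        )
        panel = generate_panel(cfg)
        synth_cohort, truth = generate_cohort(cfg, panel)
        result = run_cascade(synth_cohort, panel)
        assert result.n_candidates == 1
        assert {v.key for v in result.candidates["1"]} == truth.candidates()

    def test_variant_in_three_patients_excluded_everywhere_at_recurrence(self):
        shared = dict(gene="RET", hgvs_c="c.5A>G", maf_gnomad=None)
        cohort = [
            PatientVariantSet(
                patient_id=pid, variants=[make_variant(patient_id=pid, **shared)]
            )
            for pid in ("1", "2", "3")
        ]
        result = run_cascade(cohort, tiny_panel("RET"))
        assert result.n_candidates == 0
        assert all(t.first_failure.label == "D1" for t in result.traces)

    def test_trace_conservation_and_first_fail_semantics(self, cohort, panel41):
        result = run_cascade(cohort, panel41)
        assert len(result.traces) == sum(len(p) for p in cohort)
        for trace in result.traces:
            labels = [s.label for s in trace.steps]
            assert len(labels) == len(set(labels))
            assert trace.final == (
                "excluded" if trace.first_failure is not None else "candidate"
            )

    def test_invalid_config_rejected_before_filtering(self, cohort, panel41):
        bad = CascadeConfig(maf_keep_threshold=0.001, maf_reject_threshold=0.01)
        with pytest.raises(CascadeConfigError):
            run_cascade(cohort, panel41, bad)
        with pytest.raises(CascadeConfigError):
            run_cascade(cohort, panel41, CascadeConfig(het_allele_balance=(0.9, 0.2)))

    def test_order_independence(self, panel41):
        cfg = SimConfig(n_patients=4, n_variants_per_patient=40, seed=3)
        panel = generate_panel(cfg)
        synth_cohort, _ = generate_cohort(cfg, panel)
        forward = run_cascade(synth_cohort, panel)
        shuffled = [
            PatientVariantSet(
                patient_id=p.patient_id,
                karyotype=p.karyotype,
                variants=list(reversed(p.variants)),
                mamld1_variant=p.mamld1_variant,
            )
            for p in reversed(synth_cohort)
        ]
        backward = run_cascade(shuffled, panel)
        as_sets = lambda res: {
            pid: {v.key for v in vs} for pid, vs in res.candidates.items()
        }
        assert as_sets(forward) == as_sets(backward)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_on_small_cohorts(self, seed):
        cfg = SimConfig(
            n_patients=2, n_variants_per_patient=25, seed=seed,
            n_planted_candidates_per_patient=2, n_recurrent_variants=0,
            artifact_rates={"repeat_region": 0.05, "low_quality": 0.05},
        )
        panel = generate_panel(cfg)
        synth_cohort, _ = generate_cohort(cfg, panel)
        assert sum(len(p) for p in synth_cohort) <= 50
        expected = oracle_run(synth_cohort, panel, CascadeConfig())
        result = run_cascade(synth_cohort, panel)
        for trace in result.traces:
            got = trace.first_failure.label if trace.first_failure else None
            assert got == expected[trace.key], trace.key


@pytest.fixture(scope="module")
def synth():
    cfg = SimConfig(n_patients=3, n_variants_per_patient=80, seed=19)
    panel = generate_panel(cfg)
    synth_cohort, _ = generate_cohort(cfg, panel)
    return synth_cohort, panel


class TestMonotonicity:
    def candidate_keys(self, cohort, panel, cfg):
        result = run_cascade(cohort, panel, cfg)
        return {v.key for vs in result.candidates.values() for v in vs}

    def test_raising_reject_threshold_never_shrinks_candidates(self, synth):
        synth_cohort, panel = synth
        keys = None
        for reject in (0.001, 0.005, 0.01, 0.015):
            cfg = CascadeConfig(maf_reject_threshold=reject)
            now = self.candidate_keys(synth_cohort, panel, cfg)
            if keys is not None:
                assert now >= keys
            keys = now

    def test_shrinking_panel_never_grows_candidates(self, synth):
        synth_cohort, panel = synth
        full = self.candidate_keys(synth_cohort, panel, CascadeConfig())
        half = GenePanel(panel.entries[: len(panel.entries) // 2])
        assert self.candidate_keys(synth_cohort, half, CascadeConfig()) <= full
        assert self.candidate_keys(synth_cohort, GenePanel([]), CascadeConfig()) == set()


def test_recurrence_counts_identical_keys_not_genes():
    # two different variants of one gene in two patients are not recurrence
    cohort = [
        PatientVariantSet(patient_id="1", variants=[make_variant(hgvs_c="c.1A>G")]),
        PatientVariantSet(
            patient_id="2",
            variants=[make_variant(patient_id="2", hgvs_c="c.2A>G", pos=1001)],
        ),
    ]
    recurrence = compute_recurrence(cohort)
    assert all(len(pids) == 1 for pids in recurrence.values())
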