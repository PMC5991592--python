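"""Generators: determinism, planted-site fidelity, cohort invariants,
proteome recovery, and the registry as a sufficient statistic."""

import numpy as np
import pytest

from rbcedit.errors import ContractError, GenerationError
from rbcedit.proteome import abundance_ratio
from rbcedit.screen import AttributionConfig, FlankedSite, run_screen, scan_window
from rbcedit.sequence import revcomp
from rbcedit.variants import Variant
from rbcedit.simulate import (
    CohortSummary,
    EditSpec,
    SiteSpec,
    implant_sites,
    make_reference,
    protospacer_hits,
    simulate_background,
    simulate_edits,
    simulate_screen_dataset,
    synth_cohort,
    synth_guides,
    synth_proteome,
    validate_cohort,
)


@pytest.fixture(scope="module")
def guides():
    return synth_guides(seed=9)


class TestMakeReference:
    def test_deterministic(self, guides):
        a = make_reference(guides, contig_len=5000, seed=7)
        b = make_reference(guides, contig_len=5000, seed=7)
        assert a == b

    def test_gc_extremes(self, guides):
        contigs = make_reference(guides, contig_len=1000, gc_fraction=1.0, seed=1)
        assert set(contigs["chr1"]) <= {"G", "C"}

    def test_no_near_copy_of_any_guide(self, guides):
        contigs = make_reference(guides, contig_len=20_000, seed=3)
        for g in guides:
            assert protospacer_hits(contigs["chr1"], g.protospacer, max_mm=1) == []


class TestImplantSites:
    def scan_at(self, contigs, site, guide, pad=30):
        cfg = AttributionConfig()
        lo = max(1, site.span_start - pad)
        hi = min(len(contigs["chr1"]), site.span_end + pad)
        window = contigs["chr1"][lo - 1 : hi]
        dummy = Variant("chr1", site.predicted_cut, "A", "C")
        fs = FlankedSite(dummy, lo, window, pad)
        return [
            m for m in scan_window(fs, guide, cfg)
            if m.mismatch_count <= len(site.spec.planted_mismatch_positions)
        ]

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("mismatches", [frozenset(), frozenset(range(1, 8))])
    def test_scan_reports_exactly_the_planted_profile(
        self, guides, strand, mismatches
    ):
        guide = guides[0]
        contigs = make_reference(guides, contig_len=5000, seed=5)
        spec = SiteSpec(
            guide=guide.name, contig="chr1", start=2000, strand=strand,
            planted_mismatch_positions=mismatches, planted_pam="AGG",
        )
        contigs, sites = implant_sites(contigs, {guide.name: guide}, [spec], seed=2)
        found = self.scan_at(contigs, sites[0], guide)
        assert len(found) == 1
        m = found[0]
        assert m.strand == strand
        assert m.mismatch_count == len(mismatches)
        assert m.pam_ok
        # mismatches at 1..7 are PAM-distal for a 20-mer: seed stays intact
        assert m.seed_ok
        assert m.predicted_cut == sites[0].predicted_cut

    def test_overlapping_specs_rejected(self, guides):
        guide = guides[0]
        contigs = make_reference(guides, contig_len=5000, seed=5)
        specs = [
            SiteSpec(guide.name, "chr1", 2000, "+"),
            SiteSpec(guide.name, "chr1", 2010, "+"),
        ]
        with pytest.raises(ContractError):
            implant_sites(contigs, {guide.name: guide}, specs, seed=0)


class TestSimulateEdits:
    def test_deletion_spans_the_cut_and_insertion_sits_in_it(self, guides):
        guide = guides[0]
        contigs = make_reference(guides, contig_len=5000, seed=6)
        spec = SiteSpec(guide.name, "chr1", 2000, "+", planted_pam="AGG",
                        is_target_locus=True)
        contigs, sites = implant_sites(contigs, {guide.name: guide}, [spec], seed=1)
        cut = sites[0].predicted_cut
        edits = [
            EditSpec(sites[0], "DEL", 4),
            EditSpec(sites[0], "INS", 1),
        ]
        out = simulate_edits(contigs, edits, seed=3)
        del_v = out[0][1]
        ins_v = out[1][1]
        assert del_v.vclass == "DEL" and del_v.indel_len == 4
        assert abs(del_v.anchor - cut) <= 3
        assert ins_v.vclass == "INS" and ins_v.indel_len == 1
        assert ins_v.pos == cut


class TestBackground:
    def test_shared_fraction_one_leaves_only_edits_somatic(self):
        ds = simulate_screen_dataset(
            contig_len=20_000, n_background=30, shared_fraction=1.0, seed=4
        )
        assert ds.edited_background == []
        somatic_keys = ds.edited.keys() - ds.control.keys()
        assert somatic_keys == {v.key for _, v in ds.edits}

    def test_shared_fraction_zero_counts(self):
        ds = simulate_screen_dataset(
            contig_len=20_000, n_background=30, shared_fraction=0.0, seed=4
        )
        assert ds.shared_background == []
        assert len(ds.edited.keys() - ds.control.keys()) == 30 + len(ds.edits)

    def test_background_avoids_site_neighbourhoods(self):
        ds = simulate_screen_dataset(contig_len=40_000, n_background=60, seed=8)
        pad = 123
        for v in ds.shared_background + ds.edited_background:
            for site in ds.sites:
                assert not (
                    site.span_start - pad <= v.pos <= site.span_end + pad
                )

    def test_rate_bounds(self, guides):
        contigs = make_reference(guides, contig_len=2000, seed=1)
        with pytest.raises(ContractError):
            simulate_background(contigs, [], snp_rate=0.5, shared_fraction=0.5)

    def test_pure_background_runs_never_attribute(self, cfg):
        # mirrors the null WGS finding across seeded replicates
        for seed in range(3):
            ds = simulate_screen_dataset(
                contig_len=20_000, n_background=25, seed=100 + seed
            )
            background_only_edited = type(ds.edited).from_variants(
                "5xKO", ds.shared_background + ds.edited_background, "synthetic"
            )
            report, _ = run_screen(
                background_only_edited, ds.control, ds.contigs, ds.guides, cfg,
                ds.target_loci,
            )
            assert len(report.off_target_attributed) == 0
            assert len(report.on_target) == 0


class TestDatasetDeterminism:
    def test_identical_seeds_identical_outputs(self):
        a = simulate_screen_dataset(contig_len=20_000, n_background=20, seed=12)
        b = simulate_screen_dataset(contig_len=20_000, n_background=20, seed=12)
        assert a.contigs == b.contigs
        assert a.edited.variants == b.edited.variants
        assert a.registry_dict() == b.registry_dict()

    def test_registry_predicts_screen_report(self, cfg):
        ds = simulate_screen_dataset(
            contig_len=30_000, n_background=40, adversarial=True, seed=21
        )
        report, _ = run_screen(
            ds.edited, ds.control, ds.contigs, ds.guides, cfg, ds.target_loci
        )
        assert {r.variant.key for r in report.on_target} == ds.expected_on_target
        assert {
            r.variant.key for r in report.off_target_attributed
        } == ds.expected_off_target
        assert report.unattributed == len(ds.edited_background) + len(
            ds.expected_unattributed_edits
        )


class TestCohortGenerator:
    def test_default_summary_invariants(self):
        cohort = synth_cohort(seed=13)
        validate_cohort(cohort, CohortSummary())  # raises on any violation
        counts = cohort.system_counts()
        assert [counts[s] for s in list(counts)[:5]] == [22, 19, 12, 10, 8]
        assert cohort.n_multi == 19

    def test_deterministic_per_seed(self):
        a = synth_cohort(seed=3)
        b = synth_cohort(seed=3)
        assert a == b

    def test_infeasible_summary_raises(self):
        bad = CohortSummary(n_multi=60)
        with pytest.raises(GenerationError):
            synth_cohort(summary=bad, seed=0)


class TestProteomeGenerator:
    def test_zero_noise_recovers_planted_ratios_exactly(self):
        planted = {"CD47": 0.61, "ICAM4": 0.07, "XK": 0.63, "RHD": 0.02}
        table = synth_proteome(n_proteins=50, planted=planted, noise_cv=0.0, seed=2)
        got = {q.accession: abundance_ratio(q) for q in table if q.accession in planted}
        for acc, ratio in planted.items():
            assert got[acc] == pytest.approx(ratio)

    def test_monte_carlo_recovery_at_small_cv(self):
        planted = {f"P{i}": 0.5 for i in range(50)}
        table = synth_proteome(
            n_proteins=1000, planted=planted, noise_cv=0.05, seed=7
        )
        ratios = np.array(
            [abundance_ratio(q) for q in table if q.accession in planted]
        )
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.5) < 2 * max(se, 1e-3)

    def test_deterministic(self):
        a = synth_proteome(n_proteins=30, seed=5)
        b = synth_proteome(n_proteins=30, seed=5)
        assert a == b
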