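"""Flank extraction, window scanning (vs a naive oracle), the attribution
criteria at their boundaries, and the screen's partition/monotonicity
properties."""

import numpy as np
import pytest

from rbcedit.errors import ContractError
from rbcedit.screen import (
    AttributionConfig,
    FlankedSite,
    attribute_variant,
    classify_on_target,
    extract_flanks,
    run_screen,
    scan_window,
)
from rbcedit.sequence import GuideRNA, SiteMatch
from rbcedit.variants import Callset, Variant

from conftest import random_seq

# ---------------------------------------------------------------------------
# independent naive scanner (the oracle): double loop, own complement table

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_IUPAC = {"N": "ACGT", "R": "AG", "G": "G"}


def naive_scan(window: str, proto: str, pam: str):
    """All (strand, offset0, mismatches, pam_ok, seed_ok) by direct loops."""
    out = []
    L, total = len(proto), len(proto) + 3
    for strand in "+-":
        seq = (
            window
            if strand == "+"
            else "".join(_COMP[b] for b in reversed(window))
        )
        for j in range(len(seq) - total + 1):
            site, p = seq[j : j + L], seq[j + L : j + total]
            mm = sum(1 for a, b in zip(site, proto) if a != b)
            pam_ok = all(
                b in _IUPAC[c] and b != "N" for b, c in zip(p, pam)
            )
            seed_ok = site[-10:] == proto[-10:]
            out.append((strand, j, mm, pam_ok, seed_ok))
    return out


def flat(matches):
    return [
        (m.strand, m.protospacer_start - 1, m.mismatch_count, m.pam_ok, m.seed_ok)
        for m in matches
    ]


def make_site(window: str, pos: int = 500, chrom: str = "chr1") -> FlankedSite:
    return FlankedSite(
        variant=Variant(chrom, pos, "A", "C"),
        window_start=pos - 100,
        window_seq=window,
        flank=100,
    )


class TestExtractFlanks:
    REF = {"chr1": random_seq(np.random.default_rng(7), 1000)}

    def test_interior_snv_window(self):
        site = extract_flanks(Variant("chr1", 150, self.REF["chr1"][149], "N"),
                              self.REF, flank=100)
        assert (site.window_start, site.window_end) == (50, 250)
        assert len(site.window_seq) == 201
        assert site.window_seq == self.REF["chr1"][49:250]
        assert not (site.truncated_left or site.truncated_right)

    def test_left_edge_truncation(self):
        site = extract_flanks(Variant("chr1", 30, self.REF["chr1"][29], "N"),
                              self.REF, flank=100)
        assert site.window_start == 1
        assert site.window_end == 130
        assert site.truncated_left and not site.truncated_right

    def test_deletion_span_widens_window(self):
        ref_allele = self.REF["chr1"][399:409]  # 10-base REF span
        v = Variant("chr1", 400, ref_allele, ref_allele[0] + "N")
        site = extract_flanks(v, self.REF, flank=100)
        assert len(site.window_seq) == 100 + 10 + 100


class TestScanWindow:
    def plant(self, guide, rng, strand="+", pam="AGG", mutate=()):
        """Window with the guide site planted at plus-offset 90."""
        window = random_seq(rng, 201)
        proto = list(guide.protospacer)
        for p in mutate:
            proto[p - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[proto[p - 1]]
        insert = "".join(proto) + pam
        if strand == "-":
            insert = "".join(_COMP[b] for b in reversed(insert))
        window = window[:90] + insert + window[90 + len(insert):]
        return window

    def test_planted_exact_site_found_once(self, guide, cfg, rng):
        window = self.plant(guide, rng)
        site = make_site(window)
        perfect = [
            m for m in scan_window(site, guide, cfg)
            if m.mismatch_count == 0 and m.pam_ok
        ]
        assert len(perfect) == 1
        m = perfect[0]
        assert (m.strand, m.protospacer_start, m.seed_ok) == ("+", 91, True)
        # planted at window offset 90 -> reference span starts at 400+90
        assert m.predicted_cut == (site.window_start + 90) + guide.length - 1 - 3

    def test_planted_minus_strand_site(self, guide, cfg, rng):
        window = self.plant(guide, rng, strand="-")
        site = make_site(window)
        perfect = [
            m for m in scan_window(site, guide, cfg)
            if m.mismatch_count == 0 and m.pam_ok
        ]
        assert len(perfect) == 1
        assert perfect[0].strand == "-"
        assert perfect[0].predicted_cut == (site.window_start + 90) + 3 + 3

    def test_short_window_empty(self, guide, cfg):
        site = FlankedSite(Variant("chr1", 5, "A", "C"), 1, "ACGTACGT", 100)
        assert scan_window(site, guide, cfg) == []

    def test_cut_inside_window_span(self, guide, cfg, rng):
        site = make_site(random_seq(rng, 201))
        for m in scan_window(site, guide, cfg):
            assert site.window_start <= m.predicted_cut <= site.window_end

    def test_matches_naive_oracle_on_random_windows(self, guide, cfg, rng):
        for _ in range(50):
            window = random_seq(rng, int(rng.integers(30, 240)))
            site = FlankedSite(Variant("chr1", 900, "A", "C"), 800, window, 100)
            got = flat(scan_window(site, guide, cfg))
            assert got == naive_scan(window, guide.protospacer, "NRG")


def match(guide, mm=0, seed_ok=True, pam_ok=True, cut=500, pam="AGG"):
    return SiteMatch(
        window_id="w", strand="+", protospacer_start=1,
        observed_protospacer=guide.protospacer, observed_pam=pam,
        mismatch_count=mm, pam_ok=pam_ok, seed_ok=seed_ok, predicted_cut=cut,
    )


def site_at(pos=500):
    return FlankedSite(Variant("chr1", pos, "A", "C"), pos - 100, "A" * 201, 100)


class TestAttribution:
    def test_perfect_on_target_case(self, guide, cfg):
        r = attribute_variant(site_at(), {"g1": [match(guide)]}, cfg)
        assert r.attributed and r.reason == "pam_proximal_low_mismatch"
        assert r.attributed_guides == ["g1"]

    def test_seed_rescues_seven_mismatches(self, guide, cfg):
        r = attribute_variant(
            site_at(), {"g1": [match(guide, mm=7, seed_ok=True)]}, cfg
        )
        assert r.attributed and r.reason == "pam_proximal_seed"

    def test_distal_cut_fails_criterion_one(self, guide, cfg):
        r = attribute_variant(
            site_at(), {"g1": [match(guide, mm=5, cut=560)]}, cfg
        )
        assert not r.attributed and r.reason == "none"

    def test_mismatch_boundary_five_vs_six(self, guide, cfg):
        ok = attribute_variant(
            site_at(), {"g1": [match(guide, mm=5, seed_ok=False)]}, cfg
        )
        bad = attribute_variant(
            site_at(), {"g1": [match(guide, mm=6, seed_ok=False)]}, cfg
        )
        assert ok.attributed and not bad.attributed

    def test_invalid_pam_never_attributes(self, guide, cfg):
        r = attribute_variant(
            site_at(), {"g1": [match(guide, mm=0, pam_ok=False, pam="ACG")]}, cfg
        )
        assert not r.attributed

    def test_monotone_in_tolerance_and_mismatch(self, guide):
        m = match(guide, mm=4, seed_ok=False, cut=504)
        loose = AttributionConfig(cut_proximity_tol=5, max_mismatch=5)
        tight_tol = AttributionConfig(cut_proximity_tol=3, max_mismatch=5)
        tight_mm = AttributionConfig(cut_proximity_tol=5, max_mismatch=3)
        assert attribute_variant(site_at(), {"g": [m]}, loose).attributed
        assert not attribute_variant(site_at(), {"g": [m]}, tight_tol).attributed
        assert not attribute_variant(site_at(), {"g": [m]}, tight_mm).attributed

    def test_ties_resolved_toward_lowest_mismatch(self, guide, cfg):
        r = attribute_variant(
            site_at(),
            {"a": [match(guide, mm=7, seed_ok=True)], "b": [match(guide, mm=2)]},
            cfg,
        )
        assert r.best[0] == "b"
        assert r.reason == "pam_proximal_low_mismatch"
        assert r.attributed_guides == ["a", "b"]


class TestClassifyOnTarget:
    def test_registered_perfect_cut_is_on_target(self, guide, cfg):
        r = attribute_variant(site_at(), {"g1": [match(guide)]}, cfg)
        r = classify_on_target(r, {"g1": guide}, {"g1": [("chr1", 490, 520)]})
        assert r.on_target

    def test_mismatched_site_stays_off_target(self, guide, cfg):
        r = attribute_variant(site_at(), {"g1": [match(guide, mm=3)]}, cfg)
        r = classify_on_target(r, {"g1": guide}, {"g1": [("chr1", 490, 520)]})
        assert r.attributed and not r.on_target

    def test_nrg_but_not_ngg_pam_stays_off_target(self, guide, cfg):
        r = attribute_variant(site_at(), {"g1": [match(guide, pam="TAG")]}, cfg)
        r = classify_on_target(r, {"g1": guide}, {"g1": [("chr1", 490, 520)]})
        assert r.attributed and not r.on_target

    def test_unknown_guide_label_contract(self, guide, cfg):
        r = attribute_variant(site_at(), {"g1": [match(guide)]}, cfg)
        with pytest.raises(ContractError):
            classify_on_target(r, {"other": guide}, {})


class TestRunScreen:
    def test_empty_difference_all_zero(self, guide, cfg, rng):
        ref = {"chr1": random_seq(rng, 2000)}
        shared = Callset.from_variants("e", [Variant("chr1", 50, ref["chr1"][49],
                                       "A" if ref["chr1"][49] != "A" else "T")])
        control = Callset.from_variants("c", shared.variants)
        report, _ = run_screen(shared, control, ref, [guide], cfg)
        assert report.n_somatic_unique == 0
        assert report.unattributed == 0
        assert not report.on_target and not report.off_target_attributed

    def test_partition_invariant(self, cfg):
        from rbcedit.simulate import simulate_screen_dataset

        ds = simulate_screen_dataset(contig_len=30_000, n_background=40, seed=11)
        report, results = run_screen(
            ds.edited, ds.control, ds.contigs, ds.guides, cfg, ds.target_loci
        )
        assert (
            len(report.on_target)
            + len(report.off_target_attributed)
            + report.unattributed
            == report.n_somatic_unique
            == len(results)
        )
        verdicts = [
            (r.on_target, r.attributed and not r.on_target, not r.attributed)
            for r in results
        ]
        assert all(sum(v) == 1 for v in verdicts)

    def test_duplicate_guide_names_rejected(self, guide, cfg):
        ref = {"chr1": "ACGT" * 1000}
        cs = Callset.from_variants("e", [])
        with pytest.raises(ContractError):
            run_screen(cs, cs, ref, [guide, guide], cfg)
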