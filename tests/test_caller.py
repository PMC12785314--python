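"""Genotype caller: peak matching, digestion gating, biallelic and STR calls."""

import dataclasses

import numpy as np
import pytest

from rflpmux.caller import (
    call_biallelic,
    call_sample,
    call_str,
    check_digestion,
    match_peak,
)
from rflpmux.peak_io import Peak, PeakTable
from rflpmux.simulator import MixtureSpec, SampleGenotype, SimParams, synthesize


def table(*peaks, sample_id="S1"):
    return PeakTable(sample_id, "R1", [Peak(d, s, h) for d, s, h in peaks])


# Control peaks that make both digests valid.
CONTROLS = [("black", 276.0, 8000)]


class TestMatchPeak:
    def test_within_tolerance(self):
        t = table(("red", 92.3, 5000))
        assert match_peak(t, "red", 92.0, 1.0).size == 92.3

    def test_outside_tolerance(self):
        t = table(("red", 94.0, 5000))
        assert match_peak(t, "red", 92.0, 1.0) is None

    def test_highest_peak_wins(self):
        t = table(("red", 91.8, 3000), ("red", 92.2, 9000))
        assert match_peak(t, "red", 92.0, 1.0).height == 9000

    def test_equal_height_tie_broken_by_smaller_size(self):
        t = table(("red", 91.6, 5000), ("red", 92.4, 5000))
        # equal |delta| = 0.4: deterministic pick by smaller size
        assert match_peak(t, "red", 92.0, 1.0).size == 91.6

    def test_dye_filter(self):
        t = table(("green", 92.0, 5000))
        assert match_peak(t, "red", 92.0, 1.0) is None

    def test_nonpositive_tol_rejected(self):
        with pytest.raises(ValueError):
            match_peak(table(("red", 92.0, 100)), "red", 92.0, 0.0)


class TestCheckDigestion:
    def test_undigested_sample_fails_both(self, cfg):
        # uncut 289 (MnlI) and uncut 339 (HindIII) both persist
        t = table(("red", 289.0, 7000), ("black", 339.0, 7000))
        assert check_digestion(t, cfg) == (False, False)

    def test_digested_sample_passes_both(self, cfg):
        t = table(("black", 276.0, 8000), ("red", 92.0, 9000))
        assert check_digestion(t, cfg) == (True, True)

    def test_empty_table_mnl_vacuous_hind_missing_control(self, cfg):
        # no uncut peaks, but the cut control product is also missing
        assert check_digestion(table(), cfg) == (True, False)

    def test_uncut_peak_below_call_threshold_ignored(self, cfg):
        t = table(("red", 289.0, 120), ("black", 276.0, 8000))
        assert check_digestion(t, cfg) == (True, True)


class TestCallBiallelic:
    def test_wt_only(self, cfg):
        call, flags = call_biallelic(table(("red", 92.0, 9000)), "F5", cfg)
        assert call.genotype == "wt/wt"
        assert call.ratio_var_over_wt is None
        assert not flags

    def test_het_with_nominal_ratio(self, cfg):
        call, flags = call_biallelic(
            table(("red", 92.0, 9000), ("red", 129.0, 5490)), "F5", cfg
        )
        assert call.genotype == "var/wt"
        assert call.ratio_var_over_wt == pytest.approx(0.61)
        assert not flags

    def test_low_ratio_flags_retest(self, cfg):
        call, flags = call_biallelic(
            table(("red", 92.0, 9000), ("red", 129.0, 4000)), "F5", cfg
        )
        assert call.genotype == "var/wt"
        assert call.ratio_var_over_wt == pytest.approx(4000 / 9000)
        assert flags == {"RATIO_LOW_F5"}

    def test_hom_variant(self, cfg):
        call, flags = call_biallelic(table(("red", 129.0, 9000)), "F5", cfg)
        assert call.genotype == "var/var"

    def test_f2_uses_its_own_sizes(self, cfg):
        call, _ = call_biallelic(
            table(("red", 246.0, 9000), ("red", 226.0, 6000)), "F2", cfg
        )
        assert call.genotype == "var/wt"
        assert call.ratio_var_over_wt == pytest.approx(6000 / 9000)

    def test_no_signal_is_no_call(self, cfg):
        call, flags = call_biallelic(table(), "F5", cfg)
        assert call.genotype == "no_call"
        assert flags == {"LOW_SIGNAL"}


class TestCallStr:
    def fga_table(self, *peaks):
        # FGA allele r sizes: 92 + 4*(r - 14)
        return table(*[("green", 92.0 + 4 * (r - 14), h) for r, h in peaks])

    def test_two_alleles_with_stutters(self, cfg):
        t = self.fga_table((20, 8000), (22, 8000), (19, 560), (21, 560))
        call, flags = call_str(t, cfg.str_locus("FGA"), cfg)
        assert call.alleles == ("20", "22")
        assert len(call.stutter_peaks) == 2
        assert all(abs(s.fraction_of_parent - 0.07) < 1e-9 for s in call.stutter_peaks)
        assert not call.extra_peaks and not flags

    def test_stutter_above_cap_is_suspected_contamination(self, cfg):
        t = self.fga_table((22, 8000), (21, 1200))  # 15% of parent
        call, flags = call_str(t, cfg.str_locus("FGA"), cfg)
        assert call.alleles == ("22",)
        assert not call.stutter_peaks
        assert [e.reason for e in call.extra_peaks] == ["stutter_excess"]
        assert flags == {"STUTTER_EXCESS"}

    def test_adjacent_repeat_heterozygote_not_mistaken_for_stutter(self, cfg):
        t = self.fga_table((22, 8000), (21, 6500))  # 81%: genuine sister allele
        call, flags = call_str(t, cfg.str_locus("FGA"), cfg)
        assert call.alleles == ("21", "22")
        assert not flags

    def test_third_allelic_peak_is_extra(self, cfg):
        t = self.fga_table((20, 8000), (22, 8000), (17, 5000))
        call, flags = call_str(t, cfg.str_locus("FGA"), cfg)
        assert call.alleles == ("20", "22")
        assert [e.reason for e in call.extra_peaks] == ["third_allele"]
        assert flags == {"EXTRA_STR_ALLELE"}

    def test_minor_second_peak_is_extra_not_sister_allele(self, cfg):
        # a lone 5%-height companion cannot be a heterozygote sister peak
        t = self.fga_table((22, 8000), (18, 400))
        call, flags = call_str(t, cfg.str_locus("FGA"), cfg)
        assert call.alleles == ("22",)
        assert [e.reason for e in call.extra_peaks] == ["imbalanced"]
        assert flags == {"EXTRA_STR_ALLELE"}

    def test_off_ladder_peak_flagged(self, cfg):
        t = table(("green", 250.0, 8000))  # beyond the FGA window
        call, flags = call_str(t, cfg.str_locus("FGA"), cfg)
        assert call.alleles == ()
        assert [e.reason for e in call.extra_peaks] == ["off_ladder"]
        assert "OFF_LADDER" in flags

    def test_stutter_of_smallest_ladder_allele_recognised(self, cfg):
        # stutter position of allele 14 lies one repeat below the window
        t = self.fga_table((14, 8000), (13, 600))
        call, flags = call_str(t, cfg.str_locus("FGA"), cfg)
        assert call.alleles == ("14",)
        assert len(call.stutter_peaks) == 1
        assert not flags


class TestCallSample:
    def clean_double_het(self):
        return table(
            ("red", 92.0, 9000), ("red", 129.0, 5490),
            ("red", 246.0, 9000), ("red", 226.0, 6030),
            ("black", 276.0, 8000),
            ("green", 116.0, 8000), ("green", 132.0, 8000),  # FGA 20/24
            ("green", 112.0, 600), ("green", 128.0, 600),
            ("blue", 329.0, 8000), ("blue", 375.0, 8000),    # SE33 17/28.2
            ("blue", 325.0, 600), ("blue", 371.0, 600),
        )

    def test_clean_double_het_passes(self, cfg):
        report = call_sample(self.clean_double_het(), cfg)
        assert report.f5.genotype == "var/wt" and report.f2.genotype == "var/wt"
        assert report.verdict == "PASS"
        assert not report.qc_flags
        assert report.genotype_string() == "F5:het F2:het FGA:20/24 SE33:17/28.2"

    def test_undigested_sample_fails_with_no_calls(self, cfg):
        t = table(("red", 289.0, 9000), ("black", 339.0, 9000),
                  ("red", 246.0, 9000))
        report = call_sample(t, cfg)
        assert report.verdict == "FAIL"
        assert report.f5.genotype == "no_call" and report.f2.genotype == "no_call"
        assert {"UNDIGESTED_MNL", "UNDIGESTED_HIND"} <= report.qc_flags

    def test_invalid_digest_never_yields_genotype(self, cfg):
        # wild-type-looking F2 peak but the HindIII control did not cut:
        # F2 wt/wt is indistinguishable from digestion failure
        t = table(("red", 92.0, 9000), ("red", 246.0, 9000),
                  ("black", 339.0, 9000))
        report = call_sample(t, cfg)
        assert report.f2.genotype == "no_call"
        assert report.f5.genotype == "wt/wt"  # MnlI digest was fine
        assert report.verdict == "FAIL"

    def test_ratio_low_gives_retest(self, cfg):
        t = table(("red", 92.0, 9000), ("red", 129.0, 4000),
                  ("red", 246.0, 9000), ("black", 276.0, 8000),
                  ("green", 116.0, 8000), ("blue", 329.0, 8000))
        report = call_sample(t, cfg)
        assert report.verdict == "RETEST"
        assert "RATIO_LOW_F5" in report.qc_flags


BIALLELIC_STATES = ("wt/wt", "var/wt", "var/var")


class TestCallerOnSimulatedData:
    def test_exhaustive_genotype_sweep_recovered(self, cfg, params, rng):
        """All 9 F5 x F2 genotype combinations are recovered exactly."""
        for f5 in BIALLELIC_STATES:
            for f2 in BIALLELIC_STATES:
                truth = SampleGenotype(f5=f5, f2=f2, fga=(20.0, 24.0), se33=(17.0, 28.2))
                t = synthesize(MixtureSpec(primary=truth), params, cfg, rng)
                report = call_sample(t, cfg)
                assert report.f5.genotype == f5
                assert report.f2.genotype == f2
                assert report.str_call("FGA").alleles == ("20", "24")
                assert report.str_call("SE33").alleles == ("17", "28.2")

    def test_calls_scale_invariant(self, cfg, params, rng):
        truth = SampleGenotype(f5="var/wt", f2="var/wt")
        t = synthesize(MixtureSpec(primary=truth), params, cfg, rng)
        scaled = PeakTable(t.sample_id, t.run_id,
                           [dataclasses.replace(p, height=p.height * 2) for p in t.peaks])
        a, b = call_sample(t, cfg), call_sample(scaled, cfg)
        assert (a.f5.genotype, a.f2.genotype) == (b.f5.genotype, b.f2.genotype)
        assert a.qc_flags == b.qc_flags and a.verdict == b.verdict
        assert [s.alleles for s in a.strs] == [s.alleles for s in b.strs]

    def test_raising_call_threshold_never_adds_alleles(self, cfg, params, rng):
        import dataclasses as dc
        strict = dc.replace(cfg, thresholds=dc.replace(cfg.thresholds, allele_call_rfu=450.0))
        for i in range(20):
            truth = SampleGenotype(f5="var/wt", f2="wt/wt")
            t = synthesize(MixtureSpec(primary=truth), params, cfg, rng)
            lax_report, strict_report = call_sample(t, cfg), call_sample(t, strict)
            for locus in ("FGA", "SE33"):
                assert set(strict_report.str_call(locus).alleles) <= set(
                    lax_report.str_call(locus).alleles
                )
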