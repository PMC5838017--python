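"""Discovery screen: overlap counting, filters, classification, composition."""

import numpy as np
import pytest

from conftest import make_track
from idmrscan.genome_data import AmrRecord, CgiRecord, GenomicInterval
from idmrscan.idmr_screen import (
    CandidateClass,
    ScreenParams,
    annotate_known,
    classify_candidate,
    count_overlapping_amrs,
    filter_by_record_count,
    intermediate_filter,
    run_screen,
)
from idmrscan.methylation_profiles import MethylationStatus


def brute_force_counts(cgis, amrs):
    """All-pairs overlap oracle."""
    out = {}
    for cgi in cgis:
        hits = [a for a in amrs if cgi.interval.overlaps(a.interval)]
        out[cgi.id] = (len(hits), len({a.source_methylome for a in hits}))
    return out


def random_instance(rng, n_cgis, n_amrs, n_methylomes=10, span=10_000):
    cgis = []
    for i in range(n_cgis):
        start = int(rng.integers(span))
        cgis.append(
            CgiRecord(
                f"c{i}",
                GenomicInterval(f"chr{rng.integers(3) + 1}", start,
                                start + int(rng.integers(1, 500))),
            )
        )
    amrs = []
    for _ in range(n_amrs):
        start = int(rng.integers(span))
        amrs.append(
            AmrRecord(
                GenomicInterval(f"chr{rng.integers(3) + 1}", start,
                                start + int(rng.integers(1, 500))),
                f"m{rng.integers(n_methylomes)}",
            )
        )
    return cgis, amrs


class TestCountOverlaps:
    def test_records_and_distinct_methylomes_counted(self):
        cgi = CgiRecord("c1", GenomicInterval("chr1", 100, 300))
        amrs = [
            AmrRecord(GenomicInterval("chr1", 250, 400), "m1"),
            AmrRecord(GenomicInterval("chr1", 0, 150), "m2"),
        ]
        assert count_overlapping_amrs([cgi], amrs) == {"c1": (2, 2)}

    def test_abutting_interval_is_not_overlap(self):
        cgi = CgiRecord("c1", GenomicInterval("chr1", 100, 300))
        amrs = [AmrRecord(GenomicInterval("chr1", 300, 400), "m1")]
        assert count_overlapping_amrs([cgi], amrs) == {"c1": (0, 0)}

    def test_duplicate_source_methylome_counted_once_in_methylome_count(self):
        cgi = CgiRecord("c1", GenomicInterval("chr1", 100, 300))
        amrs = [
            AmrRecord(GenomicInterval("chr1", 150, 200), "m1"),
            AmrRecord(GenomicInterval("chr1", 200, 280), "m1"),
        ]
        assert count_overlapping_amrs([cgi], amrs) == {"c1": (2, 1)}

    def test_empty_inputs_yield_zero_counts(self):
        cgi = CgiRecord("c1", GenomicInterval("chr1", 100, 300))
        assert count_overlapping_amrs([cgi], []) == {"c1": (0, 0)}
        assert count_overlapping_amrs([], []) == {}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cgis, amrs = random_instance(rng, 50, 200)
        assert count_overlapping_amrs(cgis, amrs) == brute_force_counts(cgis, amrs)


class TestRecordCountFilter:
    @pytest.mark.parametrize("count,kept", [(16, True), (15, False), (0, False)])
    def test_threshold_is_inclusive(self, count, kept):
        counts = {"c1": (count, count)}
        retained = filter_by_record_count(counts, ScreenParams(min_records=16))
        assert ("c1" in retained) is kept

    def test_raising_threshold_never_adds_candidates(self):
        rng = np.random.default_rng(0)
        cgis, amrs = random_instance(rng, 30, 300)
        counts = count_overlapping_amrs(cgis, amrs)
        previous = None
        for min_records in (1, 4, 8, 16, 32):
            kept = filter_by_record_count(counts, ScreenParams(min_records=min_records))
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestIntermediateFilter:
    def _cgi(self):
        return CgiRecord("c1", GenomicInterval("chr1", 100, 300))

    @pytest.mark.parametrize(
        "levels,expected",
        [
            ([0.40, 0.50, 0.60], True),
            ([0.40, 0.70], False),
            ([0.35, 0.65], True),  # bounds inclusive
        ],
    )
    def test_every_covered_site_must_be_in_band(self, levels, expected):
        ok, _ = intermediate_filter(self._cgi(), make_track(levels), ScreenParams())
        assert ok is expected

    def test_zero_covered_sites_not_evaluable(self):
        ok, note = intermediate_filter(
            self._cgi(), make_track([None, None]), ScreenParams()
        )
        assert ok is False and "not evaluable" in note

    def test_widening_band_never_removes_a_candidate(self):
        levels = [0.30, 0.45, 0.68]
        narrow = ScreenParams(intermediate_low=0.35, intermediate_high=0.65)
        wide = ScreenParams(intermediate_low=0.25, intermediate_high=0.75)
        ok_narrow, _ = intermediate_filter(self._cgi(), make_track(levels), narrow)
        ok_wide, _ = intermediate_filter(self._cgi(), make_track(levels), wide)
        assert ok_wide or not ok_narrow


class TestClassification:
    def _classify(self, oocyte_level, sperm_level):
        cgi = CgiRecord("c1", GenomicInterval("chr1", 100, 300))
        klass, gametes = classify_candidate(
            cgi,
            make_track([oocyte_level] * 3, sample_id="oocyte"),
            make_track([sperm_level] * 3, sample_id="sperm"),
            ScreenParams(),
        )
        return klass, gametes

    def test_oocyte_hyper_sperm_hypo_is_gametic_maternal(self):
        klass, gametes = self._classify(0.90, 0.05)
        assert klass is CandidateClass.GAMETIC_MATERNAL
        assert gametes.oocyte_status is MethylationStatus.HYPERMETHYLATED

    def test_mirror_asymmetry_is_gametic_paternal(self):
        klass, _ = self._classify(0.05, 0.90)
        assert klass is CandidateClass.GAMETIC_PATERNAL

    def test_both_gametes_hypomethylated_is_secondary(self):
        klass, _ = self._classify(0.05, 0.05)
        assert klass is CandidateClass.SECONDARY_CANDIDATE

    def test_unevaluable_gamete_defaults_to_secondary(self):
        cgi = CgiRecord("c1", GenomicInterval("chr1", 100, 300))
        klass, _ = classify_candidate(
            cgi,
            make_track([0.9], chrom="chr9", sample_id="oocyte"),  # no coverage here
            make_track([0.05] * 3, sample_id="sperm"),
            ScreenParams(),
        )
        assert klass is CandidateClass.SECONDARY_CANDIDATE

    def test_missing_gamete_track_is_an_error(self):
        cgi = CgiRecord("c1", GenomicInterval("chr1", 100, 300))
        with pytest.raises(ValueError):
            classify_candidate(cgi, None, make_track([0.05]), ScreenParams())


class TestAnnotateKnown:
    def _candidate(self, cgi_id="c1", start=100, end=300):
        from idmrscan.idmr_screen import CandidateIdmr

        return CandidateIdmr(
            cgi_id, "chr1", start, end, 20, 18, 0.9, 0.05,
            MethylationStatus.HYPERMETHYLATED, MethylationStatus.HYPOMETHYLATED,
            CandidateClass.GAMETIC_MATERNAL, True,
        )

    def test_id_match_clears_novel_flag(self):
        (c,) = annotate_known([self._candidate()], {"c1"})
        assert c.klass is CandidateClass.KNOWN and c.novel is False

    def test_empty_known_list_keeps_all_novel(self):
        (c,) = annotate_known([self._candidate()], set())
        assert c.novel is True

    def test_interval_overlap_match_when_enabled(self):
        known_iv = [GenomicInterval("chr1", 250, 500)]
        (c,) = annotate_known([self._candidate()], set(), known_iv)
        assert c.klass is CandidateClass.KNOWN
        # abutting known interval does not match
        (c2,) = annotate_known([self._candidate()], set(), [GenomicInterval("chr1", 300, 500)])
        assert c2.klass is CandidateClass.GAMETIC_MATERNAL


class TestRunScreen:
    def _inputs(self):
        cgis = [
            CgiRecord("mat", GenomicInterval("chr1", 1000, 2000)),
            CgiRecord("pat", GenomicInterval("chr1", 5000, 6000)),
            CgiRecord("sec", GenomicInterval("chr2", 1000, 2000)),
            CgiRecord("background", GenomicInterval("chr2", 5000, 6000)),
            CgiRecord("sexchrom", GenomicInterval("chrX", 1000, 2000)),
        ]
        amrs = [
            AmrRecord(cgi.interval, f"m{m}")
            for cgi in cgis
            if cgi.id != "background"
            for m in range(20)
        ]

        def track(sample, per_cgi):
            sites = []
            for cgi, level in per_cgi.items():
                iv = dict(mat=cgis[0], pat=cgis[1], sec=cgis[2],
                          background=cgis[3], sexchrom=cgis[4])[cgi].interval
                for k in range(3):
                    sites.append((iv.chrom, iv.start + k * 10, level))
            from idmrscan.genome_data import CpGSiteCall, MethylomeTrack

            return MethylomeTrack(
                sample_id=sample,
                sites=[CpGSiteCall(c, p, lv, 30) for c, p, lv in sites],
            )

        somatic = {c.id: 0.5 for c in cgis}
        reference = track("ref", somatic)
        oocyte = track("oocyte", {"mat": 0.95, "pat": 0.05, "sec": 0.05,
                                  "background": 0.05, "sexchrom": 0.95})
        sperm = track("sperm", {"mat": 0.05, "pat": 0.95, "sec": 0.05,
                                "background": 0.05, "sexchrom": 0.05})
        return cgis, amrs, reference, oocyte, sperm

    def test_truth_classes_recovered_at_zero_noise(self):
        cgis, amrs, ref, oo, sp = self._inputs()
        results = {
            c.cgi_id: c
            for c in run_screen(cgis, amrs, ref, oo, sp, ScreenParams())
        }
        assert results["mat"].klass is CandidateClass.GAMETIC_MATERNAL
        assert results["pat"].klass is CandidateClass.GAMETIC_PATERNAL
        assert results["sec"].klass is CandidateClass.SECONDARY_CANDIDATE
        assert results["background"].klass is CandidateClass.REJECTED
        assert "record_count" in results["background"].reject_reason

    def test_sex_chromosomes_excluded_by_default(self):
        cgis, amrs, ref, oo, sp = self._inputs()
        results = {c.cgi_id: c for c in run_screen(cgis, amrs, ref, oo, sp, ScreenParams())}
        assert results["sexchrom"].klass is CandidateClass.REJECTED
        assert "sex chromosome" in results["sexchrom"].reject_reason
        with_sex = {
            c.cgi_id: c
            for c in run_screen(cgis, amrs, ref, oo, sp,
                                ScreenParams(include_sex_chroms=True))
        }
        assert with_sex["sexchrom"].klass is CandidateClass.GAMETIC_MATERNAL

    def test_zero_amr_records_rejects_everything(self):
        cgis, _, ref, oo, sp = self._inputs()
        results = run_screen(cgis, [], ref, oo, sp, ScreenParams())
        assert all(c.klass is CandidateClass.REJECTED for c in results)

    def test_every_cgi_appears_once_and_partition_holds(self):
        cgis, amrs, ref, oo, sp = self._inputs()
        results = run_screen(cgis, amrs, ref, oo, sp, ScreenParams())
        assert sorted(c.cgi_id for c in results) == sorted(c.id for c in cgis)
        novel = [c for c in results if c.novel]
        by_class = [
            c for c in results
            if c.klass in (CandidateClass.GAMETIC_MATERNAL,
                           CandidateClass.GAMETIC_PATERNAL,
                           CandidateClass.SECONDARY_CANDIDATE)
        ]
        assert len(novel) == len(by_class)
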