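"""mean0 quantification, classification, association, context, profiles."""

import numpy as np
import pandas as pd
import pytest

from attenpipe.core import GenomicInterval, Peak, PeakSet, SignalTrack, TSSTable, ValidationError
from attenpipe.peaksignal import (
    annotate_context,
    associate_peaks_to_genes,
    chip_atac_correlation,
    classify_peaks,
    mean0,
    metaprofile,
    normalize_track,
)
from attenpipe.simulate import SimConfig, generate_peaks_and_tracks

from conftest import dense_expansion, random_track


class TestMean0:
    def test_uniform_coverage(self):
        track = SignalTrack({"chr1": [(0, 100, 2.0)]})
        assert mean0(track, GenomicInterval("chr1", 0, 100)) == 2.0

    def test_half_coverage_counts_zeros(self):
        track = SignalTrack({"chr1": [(0, 50, 4.0)]})
        assert mean0(track, GenomicInterval("chr1", 0, 100)) == 2.0

    def test_absent_chromosome_returns_zero(self, caplog):
        track = SignalTrack({"chr1": [(0, 10, 1.0)]})
        with caplog.at_level("WARNING"):
            assert mean0(track, GenomicInterval("chrX", 0, 10)) == 0.0
        assert "chrX" in caplog.text

    def test_matches_per_base_expansion_on_random_pairs(self, rng):
        for _ in range(100):
            track = random_track(rng, n_steps=40, chroms=("chr1",), max_pos=5000)
            starts, ends, values = track.steps("chr1")
            dense = dense_expansion(list(zip(starts, ends, values)), 8000)
            s = int(rng.integers(0, 7000))
            e = s + int(rng.integers(1, 900))
            iv = GenomicInterval("chr1", s, e)
            assert mean0(track, iv) == pytest.approx(dense[s:e].sum() / (e - s), rel=1e-9)

    def test_additivity(self, rng):
        """mean0 over [a,c) is the length-weighted mean of the two halves."""
        track = random_track(rng, n_steps=40, chroms=("chr1",))
        a, b, c = 100, 700, 1600
        m_ab = mean0(track, GenomicInterval("chr1", a, b))
        m_bc = mean0(track, GenomicInterval("chr1", b, c))
        m_ac = mean0(track, GenomicInterval("chr1", a, c))
        assert m_ac == pytest.approx((m_ab * (b - a) + m_bc * (c - b)) / (c - a))


class TestNormalizeTrack:
    def test_total_hits_target(self, rng):
        track = random_track(rng)
        norm = normalize_track(track)
        assert norm.total_signal() == pytest.approx(1e9, rel=1e-9)

    def test_depth_invariance(self, rng):
        track = random_track(rng)
        assert normalize_track(track.scaled(2.0)) == normalize_track(track) or np.allclose(
            [v for *_a, v in normalize_track(track.scaled(2.0)).iter_steps()],
            [v for *_a, v in normalize_track(track).iter_steps()],
        )

    def test_ratio_invariance(self, rng):
        """mean0 ratios between normalized tracks ignore original depths."""
        t1 = random_track(rng)
        t2 = random_track(rng)
        iv = GenomicInterval("chr1", 0, 2000)
        r_base = mean0(normalize_track(t1), iv) / mean0(normalize_track(t2), iv)
        r_scaled = mean0(normalize_track(t1.scaled(7.0)), iv) / mean0(
            normalize_track(t2.scaled(0.3)), iv
        )
        assert r_base == pytest.approx(r_scaled, rel=1e-9)

    def test_zero_track_rejected(self):
        with pytest.raises(ValidationError):
            normalize_track(SignalTrack({"chr1": [(0, 10, 0.0)]}))


def flat_peak_tracks(wt_level, ko_level, width=100):
    peaks = PeakSet("p", [Peak(GenomicInterval("chr1", 0, width), "p1")])
    wt = SignalTrack({"chr1": [(0, width, wt_level)]})
    ko = SignalTrack({"chr1": [(0, width, ko_level)]})
    return peaks, wt, ko


class TestClassifyPeaks:
    def test_down_call(self):
        peaks, wt, ko = flat_peak_tracks(10.0, 4.0)
        rec = classify_peaks(peaks, wt, ko, pseudocount_frac=0.0)[0]
        assert rec.fold == pytest.approx(2.5)
        assert rec.klass == "down"

    def test_unchanged_call(self):
        peaks, wt, ko = flat_peak_tracks(5.0, 5.0)
        assert classify_peaks(peaks, wt, ko, pseudocount_frac=0.0)[0].klass == "unchanged"

    def test_fold_exactly_two_is_down(self):
        """'At least twofold' is inclusive: fold == 2.0 classifies down."""
        peaks, wt, ko = flat_peak_tracks(4.0, 2.0)
        rec = classify_peaks(peaks, wt, ko, pseudocount_frac=0.0)[0]
        assert rec.fold == pytest.approx(2.0)
        assert rec.klass == "down"

    def test_fold_exactly_half_is_up(self):
        peaks, wt, ko = flat_peak_tracks(2.0, 4.0)
        assert classify_peaks(peaks, wt, ko, pseudocount_frac=0.0)[0].klass == "up"

    def test_invariant_to_joint_rescaling(self, rng):
        sim = SimConfig(seed=2, n_peaks=50, track_noise_sd=0.1)
        peaks, tracks, _ = generate_peaks_and_tracks(sim)
        r1 = classify_peaks(peaks, tracks["WT"], tracks["KO"])
        r2 = classify_peaks(peaks, tracks["WT"].scaled(3.0), tracks["KO"].scaled(3.0))
        assert [r.klass for r in r1] == [r.klass for r in r2]

    def test_planted_class_recovery(self):
        sim = SimConfig(seed=4, n_peaks=200, peak_fold=4.0, track_noise_sd=0.1)
        peaks, tracks, truth = generate_peaks_and_tracks(sim)
        recs = classify_peaks(
            peaks,
            normalize_track(tracks["WT"]),
            normalize_track(tracks["KO"]),
            genome_span=sum(l for _, l in sim.genome),
        )
        called = pd.Series({r.peak: r.klass for r in recs})
        agreement = (called == truth.peaks["class"].reindex(called.index)).mean()
        assert agreement >= 0.95


def tss_table(rows):
    return TSSTable(pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"]))


class TestAssociation:
    def test_boundary_inclusive_at_3000(self):
        peaks = PeakSet("p", [Peak(GenomicInterval("chr1", 1000, 2000), "p1")])
        tss = tss_table([("gA", "chr1", 5000, "+")])  # 3000 bp past peak end
        assert associate_peaks_to_genes(peaks, tss, window=3000) == [("p1", "gA")]

    def test_boundary_exclusive_at_3001(self):
        peaks = PeakSet("p", [Peak(GenomicInterval("chr1", 1000, 2000), "p1")])
        tss = tss_table([("gA", "chr1", 5001, "+")])
        assert associate_peaks_to_genes(peaks, tss, window=3000) == []

    def test_matches_brute_force_all_pairs(self, rng):
        peaks = []
        for i in range(100):
            s = int(rng.integers(0, 500_000))
            peaks.append(Peak(GenomicInterval("chr1", s, s + int(rng.integers(100, 1000))), f"p{i}"))
        ps = PeakSet("p", peaks)
        rows = [(f"g{j}", "chr1", int(rng.integers(0, 500_000)), "+") for j in range(50)]
        tss = tss_table(rows)
        got = set(associate_peaks_to_genes(ps, tss, window=3000))
        expected = set()
        for p in ps:
            for g, _c, t, _s in rows:
                d = max(p.interval.start - t, t - p.interval.end, 0)
                if d <= 3000:
                    expected.add((p.name, g))
        assert got == expected

    def test_reflection_symmetry(self, rng):
        """Mirroring every coordinate preserves the associated pairs."""
        L = 100_000
        peaks = []
        for i in range(40):
            s = int(rng.integers(0, L - 1000))
            peaks.append(Peak(GenomicInterval("chr1", s, s + 500), f"p{i}"))
        rows = [(f"g{j}", "chr1", int(rng.integers(0, L)), "+") for j in range(30)]
        fwd = set(associate_peaks_to_genes(PeakSet("p", peaks), tss_table(rows), 3000))
        mirrored_peaks = [
            Peak(GenomicInterval("chr1", L - p.interval.end, L - p.interval.start), p.name)
            for p in peaks
        ]
        mirrored_rows = [(g, c, L - t, s) for g, c, t, s in rows]
        rev = set(
            associate_peaks_to_genes(PeakSet("p", mirrored_peaks), tss_table(mirrored_rows), 3000)
        )
        assert fwd == rev


class TestContext:
    def test_center_on_tss(self):
        peaks = PeakSet("p", [Peak(GenomicInterval("chr1", 900, 1100), "p1")])
        tss = tss_table([("gA", "chr1", 1000, "+")])
        ann = annotate_context(peaks, tss, [])[0]
        assert ann.category == "TSS±1kb" and ann.tss_distance == 0

    def test_distal_intragenic(self):
        peaks = PeakSet("p", [Peak(GenomicInterval("chr1", 49_900, 50_100), "p1")])
        tss = tss_table([("gA", "chr1", 0, "+")])
        body = [GenomicInterval("chr1", 40_000, 60_000)]
        assert annotate_context(peaks, tss, body)[0].category == ">10kb intragenic"

    def test_distal_intergenic(self):
        peaks = PeakSet("p", [Peak(GenomicInterval("chr1", 49_900, 50_100), "p1")])
        tss = tss_table([("gA", "chr1", 0, "+")])
        assert annotate_context(peaks, tss, [])[0].category == ">10kb intergenic"

    def test_matches_brute_force_classifier(self, rng):
        peaks = []
        for i in range(150):
            s = int(rng.integers(0, 400_000))
            peaks.append(Peak(GenomicInterval("chr1", s, s + 300), f"p{i}"))
        ps = PeakSet("p", peaks)
        tss_rows = [(f"g{j}", "chr1", int(rng.integers(0, 400_000)), "+") for j in range(40)]
        bodies = []
        for _ in range(20):
            s = int(rng.integers(0, 380_000))
            bodies.append(GenomicInterval("chr1", s, s + int(rng.integers(5000, 20_000))))
        got = annotate_context(ps, tss_table(tss_rows), bodies)
        for ann, p in zip(got, ps):
            center = (p.interval.start + p.interval.end) // 2
            d = min(abs(t - center) for _g, _c, t, _s in tss_rows)
            if d <= 1000:
                want = "TSS±1kb"
            elif d <= 10_000:
                want = "1–10kb"
            elif any(b.start <= center < b.end for b in bodies):
                want = ">10kb intragenic"
            else:
                want = ">10kb intergenic"
            assert ann.category == want and ann.tss_distance == d

    def test_categories_partition(self, rng):
        sim = SimConfig(seed=8, n_peaks=100)
        peaks, _, _ = generate_peaks_and_tracks(sim)
        from attenpipe.simulate import generate_tss_table

        tss, bodies = generate_tss_table(sim)
        ann = annotate_context(peaks, tss, bodies)
        assert len(ann) == len(peaks)
        assert all(
            a.category in ("TSS±1kb", "1–10kb", ">10kb intragenic", ">10kb intergenic")
            for a in ann
        )


class TestMetaprofile:
    def test_constant_track(self):
        track = SignalTrack({"chr1": [(0, 100_000, 3.0)]})
        peaks = PeakSet(
            "p", [Peak(GenomicInterval("chr1", 10_000, 10_500), "p1"),
                  Peak(GenomicInterval("chr1", 50_000, 50_500), "p2")]
        )
        prof = metaprofile(track, peaks, half_window=2000, bin_size=50)
        assert np.allclose(prof.mean_signal, 3.0)
        assert len(prof.offsets) == 80

    def test_center_spike_symmetric_max(self):
        peaks = PeakSet("p", [Peak(GenomicInterval("chr1", 10_000, 10_100), "p1")])
        center = 10_050
        track = SignalTrack({"chr1": [(center - 25, center + 25, 10.0)]})
        prof = metaprofile(track, peaks, half_window=1000, bin_size=50)
        mid = len(prof.mean_signal) // 2
        assert prof.mean_signal.argmax() in (mid - 1, mid)
        assert np.allclose(prof.mean_signal, prof.mean_signal[::-1], atol=1e-12)

    def test_matches_naive_double_loop(self, rng):
        track = random_track(rng, n_steps=60, chroms=("chr1",))
        peaks = []
        for i in range(10):
            s = int(rng.integers(3000, 20_000))
            peaks.append(Peak(GenomicInterval("chr1", s, s + 200), f"p{i}"))
        ps = PeakSet("p", peaks)
        half, width = 1000, 100
        prof = metaprofile(track, ps, half_window=half, bin_size=width)
        starts, ends, values = track.steps("chr1")
        dense = dense_expansion(list(zip(starts, ends, values)), 40_000)
        expected = np.zeros(2 * half // width)
        for p in ps:
            c = (p.interval.start + p.interval.end) // 2
            for i in range(len(expected)):
                lo = c - half + i * width
                expected[i] += dense[lo : lo + width].sum() / width
        expected /= len(peaks)
        assert np.allclose(prof.mean_signal, expected, rtol=1e-9)

    def test_edge_peaks_dropped_and_counted(self):
        track = SignalTrack({"chr1": [(0, 5000, 1.0)]})
        peaks = PeakSet(
            "p", [Peak(GenomicInterval("chr1", 10, 100), "edge"),
                  Peak(GenomicInterval("chr1", 3000, 3100), "ok")]
        )
        prof = metaprofile(track, peaks, half_window=2000, bin_size=50)
        assert prof.n_peaks == 1 and prof.n_dropped == 1

    def test_no_usable_peaks_rejected(self):
        track = SignalTrack({"chr1": [(0, 5000, 1.0)]})
        peaks = PeakSet("p", [Peak(GenomicInterval("chr1", 10, 100), "edge")])
        with pytest.raises(ValidationError):
            metaprofile(track, peaks, half_window=2000, bin_size=50)


class TestChipAtacCorrelation:
    def test_identical_vectors(self, rng):
        s = pd.Series(rng.normal(size=40), index=[f"p{i}" for i in range(40)])
        rho, _ = chip_atac_correlation(s, s)
        assert rho == pytest.approx(1.0)

    def test_independent_vectors_mean_rho_near_zero(self, rng):
        rhos = []
        idx = [f"p{i}" for i in range(60)]
        for _ in range(200):
            a = pd.Series(rng.normal(size=60), index=idx)
            b = pd.Series(rng.normal(size=60), index=idx)
            rhos.append(chip_atac_correlation(a, b)[0])
        rhos = np.array(rhos)
        se = rhos.std(ddof=1) / np.sqrt(len(rhos))
        assert abs(rhos.mean()) <= 2 * se + 1e-9

    def test_too_few_peaks_rejected(self):
        s = pd.Series(np.arange(5.0), index=[f"p{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            chip_atac_correlation(s, s)
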