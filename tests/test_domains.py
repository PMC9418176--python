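"""Site construction, change flagging and uniform-change domain detection."""

import numpy as np
import pandas as pd
import pytest

from attenpipe.core import CountMatrix, GenomicInterval, Peak, PeakSet, SampleSheet, ValidationError
from attenpipe.domains import AtacSite, DomainCall, find_domains, flag_site_changes, merge_replicate_peaks
from attenpipe.simulate import SimConfig, generate_atac_sites


def peak(chrom, start, end, name, fdr=0.01):
    return Peak(GenomicInterval(chrom, start, end), name, 1.0, fdr)


class TestMergeReplicatePeaks:
    def test_identical_peak_in_both_replicates_significant(self):
        r1 = PeakSet("r1", [peak("chr1", 100, 300, "a")])
        r2 = PeakSet("r2", [peak("chr1", 100, 300, "b")])
        sites = merge_replicate_peaks([r1, r2])
        assert len(sites) == 1 and sites[0].significant

    def test_single_replicate_peak_not_significant(self):
        r1 = PeakSet("r1", [peak("chr1", 100, 300, "a")])
        r2 = PeakSet("r2", [])
        sites = merge_replicate_peaks([r1, r2])
        assert len(sites) == 1 and not sites[0].significant

    def test_high_fdr_peak_not_significant(self):
        r1 = PeakSet("r1", [peak("chr1", 100, 300, "a", fdr=0.01)])
        r2 = PeakSet("r2", [peak("chr1", 150, 350, "b", fdr=0.2)])
        sites = merge_replicate_peaks([r1, r2])
        assert len(sites) == 1 and not sites[0].significant

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValidationError):
            merge_replicate_peaks([PeakSet("r1", [])])

    def test_footprints_match_interval_union_oracle(self, rng):
        sets = []
        for r in range(3):
            peaks = []
            for i in range(60):
                s = int(rng.integers(0, 50_000))
                peaks.append(peak("chr1", s, s + int(rng.integers(50, 400)), f"r{r}_{i}"))
            sets.append(PeakSet(f"r{r}", peaks))
        sites = merge_replicate_peaks(sets)
        # oracle: per-base union then connected components
        covered = np.zeros(60_000, dtype=bool)
        for ps in sets:
            for p in ps:
                covered[p.interval.start : p.interval.end] = True
        expected = []
        i = 0
        while i < len(covered):
            if covered[i]:
                j = i
                while j < len(covered) and covered[j]:
                    j += 1
                expected.append((i, j))
                i = j
            else:
                i += 1
        got = [(s.interval.start, s.interval.end) for s in sites]
        assert got == expected


def site(chrom, start, end, sid, significant=True, changed=False):
    return AtacSite(
        site_id=sid,
        interval=GenomicInterval(chrom, start, end),
        rep_support=[True, True],
        rep_min_fdr=[0.01, 0.01],
        significant=significant,
        changed_in_both=changed,
    )


class TestFlagSiteChanges:
    def build_counts(self, wt, daxx, atrx, n_sites):
        """Constant per-condition counts with small per-replicate jitter."""
        ids = [f"s{i}" for i in range(n_sites)]
        cols, rows = {}, []
        for cond, level in (("WT", wt), ("DAXX_KO", daxx), ("ATRX_KO", atrx)):
            for r in (1, 2):
                name = f"{cond}_r{r}"
                cols[name] = [int(l * (1 + 0.01 * r)) for l in level]
                rows.append({"sample": name, "genotype": cond, "treatment": "etoposide", "replicate": r})
        return CountMatrix(pd.DataFrame(cols, index=ids)), SampleSheet(pd.DataFrame(rows))

    def test_planted_fourfold_loss_flagged(self):
        n = 30
        wt = [1000.0] * n
        daxx = [250.0] + [1000.0] * (n - 1)
        atrx = [250.0] + [1000.0] * (n - 1)
        counts, sheet = self.build_counts(wt, daxx, atrx, n)
        sites = [site("chr1", 1000 * i, 1000 * i + 300, f"s{i}") for i in range(n)]
        flagged = flag_site_changes(sites, counts, sheet)
        assert flagged[0].changed_in_both
        assert not any(s.changed_in_both for s in flagged[1:])

    def test_identical_conditions_not_flagged(self):
        n = 10
        counts, sheet = self.build_counts([500.0] * n, [500.0] * n, [500.0] * n, n)
        sites = [site("chr1", 1000 * i, 1000 * i + 300, f"s{i}") for i in range(n)]
        assert not any(s.changed_in_both for s in flag_site_changes(sites, counts, sheet))

    def test_fold_exactly_two_excluded(self):
        """'fold > 2' is strict: an exact twofold change does not count."""
        n = 20
        wt = [1000.0] * n
        ko = [500.0] + [1000.0] * (n - 1)  # exactly twofold down
        counts, sheet = self.build_counts(wt, ko, ko, n)
        # remove jitter so the fold is exactly 2.0 on the log scale
        df = counts.data.copy()
        for c in df.columns:
            cond = c.rsplit("_", 1)[0]
            df[c] = [1000] * n
            if cond != "WT":
                df.loc["s0", c] = 500
        # log2((500+1)/(1000+1)) is just under 1 in magnitude -> excluded
        counts = CountMatrix(df)
        flagged = flag_site_changes(sites=[site("chr1", 1000 * i, 1000 * i + 300, f"s{i}") for i in range(n)],
                                    counts=counts, sheet=sheet)
        assert not flagged[0].changed_in_both

    def test_missing_genotype_rejected(self):
        n = 4
        counts, sheet = self.build_counts([10.0] * n, [10.0] * n, [10.0] * n, n)
        sheet2 = SampleSheet(sheet.data[sheet.data["genotype"] != "ATRX_KO"].reset_index(drop=True))
        counts2 = CountMatrix(counts.data[[s for s in counts.samples if "ATRX" not in s]])
        sites = [site("chr1", 1000 * i, 1000 * i + 300, f"s{i}") for i in range(n)]
        with pytest.raises(ValidationError):
            flag_site_changes(sites, counts2, sheet2)


def brute_force_domains(sites, min_span=100_000, min_sites=5, min_frac=0.7):
    """All-(i, j) enumeration plus interval merge, written from the rule."""
    out = []
    by_chrom = {}
    for s in sites:
        if s.significant:
            by_chrom.setdefault(s.interval.chrom, []).append(s)
    for chrom in sorted(by_chrom):
        ss = sorted(by_chrom[chrom], key=lambda s: (s.interval.start, s.interval.end))
        qualifying = []
        for i in range(len(ss)):
            for j in range(i, len(ss)):
                window = ss[i : j + 1]
                start = window[0].interval.start
                end = max(w.interval.end for w in window)
                count = len(window)
                frac = sum(w.changed_in_both for w in window) / count
                if end - start > min_span and count >= min_sites and frac >= min_frac:
                    qualifying.append((start, end))
        qualifying.sort()
        merged = []
        for s0, e0 in qualifying:
            if merged and s0 <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e0))
            else:
                merged.append((s0, e0))
        for s0, e0 in merged:
            members = [w for w in ss if w.interval.start >= s0 and w.interval.end <= e0]
            changed = sum(w.changed_in_both for w in members)
            out.append((chrom, s0, e0, len(members), changed))
    return out


class TestFindDomains:
    def test_six_changed_sites_over_150kb(self):
        sites = [site("chr1", 30_000 * i, 30_000 * i + 300, f"s{i}", changed=True) for i in range(6)]
        calls = find_domains(sites)
        assert len(calls) == 1
        d = calls[0]
        assert d.n_sites == 6 and d.fraction == 1.0
        assert d.interval.length > 100_000

    def test_four_sites_never_enough(self):
        sites = [site("chr1", 70_000 * i, 70_000 * i + 300, f"s{i}", changed=True) for i in range(4)]
        assert find_domains(sites) == []

    def test_span_must_exceed_100kb_strictly(self):
        # 5 changed sites whose footprint is exactly 100,000 bp
        sites = [site("chr1", 24_925 * i, 24_925 * i + 300, f"s{i}", changed=True) for i in range(5)]
        span = sites[-1].interval.end - sites[0].interval.start
        assert span == 100_000
        assert find_domains(sites) == []

    def test_low_changed_fraction_excluded(self):
        sites = [
            site("chr1", 30_000 * i, 30_000 * i + 300, f"s{i}", changed=(i < 3))
            for i in range(6)
        ]
        assert find_domains(sites) == []

    def test_insignificant_sites_ignored(self):
        sites = [
            site("chr1", 30_000 * i, 30_000 * i + 300, f"s{i}", significant=False, changed=True)
            for i in range(6)
        ]
        assert find_domains(sites) == []

    def test_empty_input(self):
        assert find_domains([]) == []

    def test_matches_brute_force_on_random_configurations(self, rng):
        for _ in range(200):
            sites = []
            n = int(rng.integers(0, 25))
            for i in range(n):
                chrom = "chr1" if rng.random() < 0.7 else "chr2"
                start = int(rng.integers(0, 400_000))
                sites.append(
                    site(
                        chrom, start, start + 300, f"s{i}",
                        significant=rng.random() < 0.9,
                        changed=rng.random() < 0.5,
                    )
                )
            got = [
                (d.interval.chrom, d.interval.start, d.interval.end, d.n_sites, d.n_changed)
                for d in find_domains(sites)
            ]
            assert got == brute_force_domains(sites)

    def test_invariant_to_site_order(self, rng):
        sites = [
            site("chr1", int(p), int(p) + 300, f"s{i}", changed=rng.random() < 0.8)
            for i, p in enumerate(rng.choice(500_000, size=15, replace=False))
        ]
        ref = find_domains(sites)
        perm = list(sites)
        rng.shuffle(perm)
        got = find_domains(perm)
        assert [(d.interval.start, d.interval.end) for d in got] == [
            (d.interval.start, d.interval.end) for d in ref
        ]

    def test_reported_domains_disjoint_and_thresholded(self, rng):
        for _ in range(30):
            sites = [
                site("chr1", int(p), int(p) + 300, f"s{i}", changed=rng.random() < 0.7)
                for i, p in enumerate(sorted(rng.choice(600_000, size=20, replace=False)))
            ]
            calls = find_domains(sites)
            for a, b in zip(calls, calls[1:]):
                assert a.interval.end <= b.interval.start or a.interval.chrom != b.interval.chrom
            for d in calls:
                assert d.interval.length > 100_000
                assert d.n_sites >= 5


class TestPlantedDomainRecovery:
    def test_planted_domains_recovered_end_to_end(self):
        sim = SimConfig(seed=12)
        atac = generate_atac_sites(sim)
        sets = [ps for c in sorted(atac.rep_peaksets) for ps in atac.rep_peaksets[c]]
        sites = merge_replicate_peaks(sets)
        sites = flag_site_changes(sites, atac.counts, atac.sheet)
        calls = find_domains(sites)
        for planted in atac.truth.domains:
            assert any(d.interval.overlaps(planted) for d in calls)

    def test_no_planted_structure_yields_no_domains(self):
        sim = SimConfig(seed=13, n_planted_domains=0, background_change_rate=0.0)
        atac = generate_atac_sites(sim)
        sets = [ps for c in sorted(atac.rep_peaksets) for ps in atac.rep_peaksets[c]]
        sites = merge_replicate_peaks(sets)
        sites = flag_site_changes(sites, atac.counts, atac.sheet)
        assert find_domains(sites) == []
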