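import numpy as np
import pandas as pd
import pytest

import ttsakit as tk
from ttsakit.align import AlignmentRecord
from ttsakit.calling import _signed_dist3p, coverage_profile
from ttsakit.classify import QCSummary
from ttsakit.errors import UsageError

from conftest import refs_dict
from oracles import naive_call_ttsa


def classified(rid, chrom, start, end, strand, category="genome_unique"):
    aln = AlignmentRecord(read_id=rid, chrom=chrom, start=start, end=end, strand=strand)
    tr = tk.TrimmedRead(rid, "A" * (end - start), True, True)
    return tk.ClassifiedRead(tr, category, aln if category == "genome_unique" else None)


def site(sid, pos, strand="+", chrom="c"):
    return tk.PolyASite(sid, chrom, pos, strand)


def windows_for(sites):
    return tk.build_windows(sites)


class TestCallTTSa:
    def test_exact_end_has_dist_zero(self):
        s = [site("s1", 121)]
        recs = tk.call_ttsa([classified("r", "c", 100, 122, "+")], windows_for(s), s)
        assert len(recs) == 1 and recs[0].dist3p == 0 and recs[0].sense

    def test_single_nt_window_overlap_qualifies(self):
        # read [100,122) touches window [121,126) of site at 123 by exactly 1 nt
        s = [site("s1", 123)]
        recs = tk.call_ttsa([classified("r", "c", 100, 122, "+")], windows_for(s), s)
        assert len(recs) == 1 and recs[0].dist3p == -2

    def test_no_overlap_not_called(self):
        s = [site("s1", 124)]  # window [122,127), read ends at 121
        assert tk.call_ttsa([classified("r", "c", 100, 122, "+")],
                            windows_for(s), s) == []

    def test_antisense_read_excluded_by_default(self):
        s = [site("s1", 121)]
        read = classified("r", "c", 100, 122, "-")
        assert tk.call_ttsa([read], windows_for(s), s) == []
        recs = tk.call_ttsa([read], windows_for(s), s, sense_only=False)
        assert len(recs) == 1 and not recs[0].sense

    def test_minus_strand_dist_sign(self):
        # minus-strand site: downstream means decreasing coordinate
        s = [site("s1", 200, "-")]
        recs = tk.call_ttsa([classified("r", "c", 198, 220, "-")], windows_for(s), s)
        assert recs[0].dist3p == 2  # 3' end at 198, two nt downstream of 200

    def test_multi_window_tie_breaks_to_smaller_coordinate(self):
        ss = [site("a", 120), site("b", 124)]
        recs = tk.call_ttsa([classified("r", "c", 100, 123, "+")], windows_for(ss), ss)
        assert recs[0].site_id == "a"  # 3' end 122 equidistant from 120 and 124

    def test_size_filter(self):
        s = [site("s1", 121)]
        read = classified("r", "c", 94, 122, "+")  # 28 nt
        assert tk.call_ttsa([read], windows_for(s), s, size_range=(18, 26)) == []
        assert len(tk.call_ttsa([read], windows_for(s), s, size_range=(18, None))) == 1

    def test_inverted_size_range(self):
        with pytest.raises(UsageError):
            tk.call_ttsa([], [], [], size_range=(26, 18))

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(40):
            sites = []
            taken = set()
            for i in range(8):
                pos = int(rng.integers(50, 2000))
                if pos in taken:
                    continue
                taken.add(pos)
                sites.append(site(f"s{i}", pos, "+" if rng.random() < 0.5 else "-"))
            wins = windows_for(sites)
            reads, alns = [], []
            for j in range(50):
                L = int(rng.integers(18, 30))
                start = int(rng.integers(0, 2000))
                strand = "+" if rng.random() < 0.5 else "-"
                reads.append(classified(f"r{j}", "c", start, start + L, strand))
                alns.append((f"r{j}", "c", start, start + L, strand, L))
            got = sorted((r.read_id, r.site_id, r.dist3p, r.sense)
                         for r in tk.call_ttsa(reads, wins, sites))
            expected = naive_call_ttsa(
                alns, [(w.site_id, w.chrom, w.start, w.end, w.strand) for w in wins],
                {s.site_id: (s.position, s.strand) for s in sites})
            assert got == expected

    def test_records_overlap_their_window(self, bundle):
        res = bundle["result"]
        wins = {w.site_id: w for w in res.windows}
        for r in res.ttsa_records:
            w = wins[r.site_id]
            assert min(r.alignment.end, w.end) - max(r.alignment.start, w.start) >= 1


class TestQuantify:
    def qc(self, denom):
        q = QCSummary()
        q.aligned_denominator = denom
        return q

    def test_rpm_arithmetic(self):
        s = [site("s1", 121)]
        recs = tk.call_ttsa([classified(f"r{i}", "c", 100, 122, "+")
                             for i in range(50)], windows_for(s), s)
        quant = tk.quantify(recs, self.qc(500_000))
        assert quant.rpm == pytest.approx(100.0)
        assert quant.per_site.loc["s1", "count"] == 50

    def test_rpm_linearity(self):
        s = [site("s1", 121)]
        mk = lambda n: tk.call_ttsa([classified(f"r{i}", "c", 100, 122, "+")
                                     for i in range(n)], windows_for(s), s)
        assert tk.quantify(mk(40), self.qc(1000)).rpm == \
            pytest.approx(2 * tk.quantify(mk(20), self.qc(1000)).rpm)

    def test_zero_records(self):
        quant = tk.quantify([], self.qc(1000))
        assert quant.rpm == 0 and quant.per_site.empty

    def test_zero_denominator_rejected(self):
        with pytest.raises(UsageError):
            tk.quantify([], self.qc(0))

    def test_per_site_and_gene_counts_match_truth(self):
        """A background-free library: called records reproduce truth exactly."""
        cfg = tk.SyntheticConfig(
            seed=23, reads_per_library=4000,
            class_mixture={"ttsa": 0.7, "mirna": 0.3, "trna_rrna": 0.0,
                           "background": 0.0, "antisense_noise": 0.0},
        )
        refs = tk.make_reference(cfg)
        reads, truth = tk.simulate_library(cfg, refs)
        res = tk.run_sample(reads, refs_dict(refs), refs.annotation())
        t = truth[truth.true_class == "ttsa"]
        assert {r.read_id for r in res.ttsa_records} == set(t.read_id)
        got_by_site = pd.Series([r.site_id for r in res.ttsa_records]).value_counts()
        exp_by_site = t.site_id.value_counts()
        assert got_by_site.sort_index().equals(exp_by_site.sort_index())
        # every record carries the dist3p the generator drew
        dist = {r.read_id: r.dist3p for r in res.ttsa_records}
        assert all(dist[row.read_id] == row.dist3p for row in t.itertuples())
        # per-gene counts equal per-site counts via the site->gene link
        site2gene = {s.site_id: s.gene_id for s in refs.polya_sites}
        exp_by_gene = t.site_id.map(site2gene).value_counts()
        got = res.quant.per_gene["count"]
        assert got.sort_index().equals(exp_by_gene.sort_index().astype(got.dtype))


class TestProximityStats:
    def rec(self, d, length=22, sense=True):
        return tk.TTSaRecord("r", AlignmentRecord("r", "c", 0, length, "+"),
                             "s", sense, d, length)

    def test_all_zero(self):
        st = tk.proximity_stats([self.rec(0)] * 4)
        assert st["fraction_within"] == 1.0

    def test_counting(self):
        st = tk.proximity_stats([self.rec(0), self.rec(-2), self.rec(3)])
        assert st["fraction_within"] == pytest.approx(2 / 3)
        assert st["dist3p_hist"].loc[3] == 1

    def test_empty_undefined(self):
        st = tk.proximity_stats([])
        assert st["fraction_within"] is None and st["n"] == 0


class TestCoverage:
    def test_single_sense_read_ending_at_site(self):
        sites = [site("s1", 121)]
        prof = coverage_profile([AlignmentRecord("r", "c", 100, 122, "+")], sites)
        assert prof.total_mass == 22
        covered = prof.offsets[prof.sense > 0]
        assert covered.min() == -21 and covered.max() == 0
        assert prof.antisense.sum() == 0

    def test_antisense_split(self):
        sites = [site("s1", 121)]
        prof = coverage_profile([AlignmentRecord("r", "c", 100, 122, "-")], sites)
        assert prof.sense.sum() == 0 and prof.antisense.sum() == 22

    def test_equidistant_read_goes_to_smaller_coordinate(self):
        sites = [site("a", 110), site("b", 130)]
        # read [110,131): midpoint 120 is exactly 10 nt from both sites
        prof = coverage_profile([AlignmentRecord("r", "c", 110, 131, "+")], sites)
        covered = prof.offsets[prof.sense > 0]
        assert covered.min() == 0 and covered.max() == 20  # relative to site a

    def test_minus_strand_site_orientation(self):
        sites = [site("s", 200, "-")]
        prof = coverage_profile([AlignmentRecord("r", "c", 198, 220, "-")], sites)
        covered = prof.offsets[prof.sense > 0]
        # read 3' end at 198 is 2 nt downstream (offset +2) of the site
        assert covered.min() == -19 and covered.max() == 2

    def test_excluded_sites_do_not_attract_reads(self):
        sites = [site("a", 100), site("b", 400)]
        reads = [AlignmentRecord("r", "c", 90, 112, "+")]
        prof = coverage_profile(reads, sites, exclude=["a"])
        # nearest remaining site is b at 400; the read lies outside its window
        assert prof.total_mass == 22  # offsets -310..-289 are inside +-500
        prof2 = coverage_profile(reads, sites, exclude=["a", ("c", 400)])
        assert prof2.total_mass == 0

    def test_mass_conservation_on_bundle(self, bundle):
        res = bundle["result"]
        reads = [c for c in res.classified if c.category == "genome_unique"][:3000]
        sites, _ = tk.filter_polya_sites(bundle["refs"].annotation())
        prof = coverage_profile(reads, sites)
        positions = {}
        for s in sorted(sites, key=lambda s: s.position):
            positions.setdefault(s.chrom, []).append(s.position)
        expected = 0
        for c in reads:
            a = c.alignment
            pos = positions[a.chrom]
            mid = (a.start + a.end - 1) / 2
            i = int(np.argmin([abs(p - mid) for p in pos]))
            p = pos[i]
            expected += max(0, min(a.end, p + 500) - max(a.start, p - 500))
        assert prof.total_mass == expected

    def test_parclip_mode_requires_single_mismatch(self):
        sites = [site("s1", 121)]
        clean = AlignmentRecord("r0", "c", 100, 122, "+", mismatches=0)
        cross = AlignmentRecord("r1", "c", 100, 122, "+", mismatches=1,
                                mismatch_positions=[(10, "T", "C")])
        double = AlignmentRecord("r2", "c", 100, 122, "+", mismatches=2)
        prof = coverage_profile([clean, double], sites, parclip_mode=True)
        assert prof.total_mass == 0
        prof = coverage_profile([clean, cross, double], sites, parclip_mode=True)
        assert prof.total_mass == 22 and prof.mismatch_spectrum == {"T>C": 1}
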