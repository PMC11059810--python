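"""SV parsing, summaries, reciprocal-overlap matching and the candidate filter."""

import itertools

import numpy as np
import pytest

from discordia import sv_tools as sv
from discordia import synthetic_data as sd


def _rec(start, end, genome="g1", type="deletion", ref="chr1", size=None):
    return sv.SvRecord(
        reference=ref, start=start, end=end, type=type,
        size=size if size is not None else end - start, genome=genome,
    )


class TestReadWrite:
    def test_toy_file_round_trip(self, tmp_path):
        records = [
            _rec(100, 300), _rec(500, 501, type="insertion", size=250),
            _rec(900, 1000, type="inversion"),
        ]
        path = tmp_path / "svs.bed"
        sv.write_assemblytics(records, path)
        back = sv.read_assemblytics(path, "g1")
        assert len(back) == 3
        assert [r.size for r in back] == [200, 250, 100]
        assert [r.type for r in back] == ["deletion", "insertion", "inversion"]

    def test_type_normalization(self, tmp_path):
        path = tmp_path / "svs.bed"
        path.write_text("chr1\t10\t60\tsv_0\t50\t+\tTandem_expansion\t50\t0\t.\tm\n")
        (rec,) = sv.read_assemblytics(path, "g1")
        assert rec.type == "tandem_expansion"

    def test_unknown_type_reports_line(self, tmp_path):
        path = tmp_path / "svs.bed"
        path.write_text("chr1\t10\t60\tsv_0\t50\t+\tweirdness\t50\t0\t.\tm\n")
        with pytest.raises(ValueError, match="1"):
            sv.read_assemblytics(path, "g1")

    def test_end_before_start_rejected(self, tmp_path):
        path = tmp_path / "svs.bed"
        path.write_text("chr1\t60\t10\tsv_0\t50\t+\tDeletion\t50\t0\t.\tm\n")
        with pytest.raises(ValueError):
            sv.read_assemblytics(path, "g1")


class TestSummarize:
    def test_fold_ratios(self):
        records = {"g1": [
            _rec(0, 100), _rec(200, 500),
            _rec(700, 701, type="insertion", size=50),
        ]}
        s = sv.summarize_svs(records)
        assert s.count_ratio["g1"] == pytest.approx(2.0)
        assert s.base_ratio["g1"] == pytest.approx(400 / 50)

    def test_mean_over_genomes(self):
        records = {
            "g1": [_rec(0, 100), _rec(200, 300),
                   _rec(400, 401, type="insertion", size=10)],
            "g2": [_rec(0, 100), _rec(200, 300), _rec(400, 500), _rec(600, 700),
                   _rec(800, 801, genome="g2", type="insertion", size=10)],
        }
        s = sv.summarize_svs(records)
        assert s.mean_count_ratio == pytest.approx((2.0 + 4.0) / 2)

    def test_empty_and_undefined_ratio(self):
        s = sv.summarize_svs({"g1": []})
        assert s.counts.to_numpy().sum() == 0
        assert np.isnan(s.count_ratio["g1"])

    def test_total_conservation(self):
        records = {"g1": [_rec(i * 100, i * 100 + 50, type=t)
                          for i, t in enumerate(sv.SV_TYPES)]}
        s = sv.summarize_svs(records)
        assert s.counts.loc["g1"].sum() == len(sv.SV_TYPES)


class TestMatch:
    def test_identical_intervals_at_full_overlap(self):
        assert sv.match_svs(_rec(0, 100), _rec(0, 100, "g2"), 1.0)

    def test_half_overlap_boundary(self):
        assert sv.match_svs(_rec(0, 100), _rec(50, 150, "g2"), 0.5)

    def test_disjoint(self):
        assert not sv.match_svs(_rec(0, 100), _rec(200, 300, "g2"), 0.5)

    def test_different_reference_or_type(self):
        assert not sv.match_svs(_rec(0, 100), _rec(0, 100, ref="chr2"))
        assert not sv.match_svs(_rec(0, 100), _rec(0, 100, type="inversion"))

    def test_insertion_breakpoint_rule(self):
        a = _rec(500, 501, type="insertion", size=200)
        b = _rec(560, 561, "g2", type="insertion", size=200)
        assert sv.match_svs(a, b, 0.5)       # 60 <= 100
        assert not sv.match_svs(a, b, 0.8)   # 60 > 40

    def test_symmetric(self):
        a, b = _rec(0, 100), _rec(30, 120, "g2")
        assert sv.match_svs(a, b, 0.5) == sv.match_svs(b, a, 0.5)


def _brute_force_candidates(tables, present, absent, r):
    """Independent all-pairs oracle: a present-group deletion qualifies iff it
    has a match in every present genome and none in any absent genome."""
    out = set()
    for g in present:
        for rec in tables[g]:
            if rec.type != "deletion":
                continue
            ok = all(
                any(sv.match_svs(rec, other, r)
                    for other in tables[h] if other.type == "deletion")
                for h in present
            )
            hit_absent = any(
                sv.match_svs(rec, other, r)
                for h in absent
                for other in tables[h] if other.type == "deletion"
            )
            if ok and not hit_absent:
                out.add((rec.reference, rec.start, rec.end))
    return out


class TestCandidateDeletions:
    def _tables(self, n_planted=5, seed=0):
        planted = tuple(
            ("chr1", 50_000 + i * 30_000, 50_000 + i * 30_000 + 400)
            for i in range(n_planted)
        )
        design = sd.PlantedSvDesign(
            genomes=("p1", "p2", "p3", "a1", "a2"),
            present_genomes=("p1", "p2", "p3"),
            reference_lengths={"chr1": 1_000_000},
            background_counts={g: {"deletion": 8, "insertion": 4}
                               for g in ("p1", "p2", "p3", "a1", "a2")},
            planted=planted,
        )
        return sd.generate_sv_tables(design, seed=seed), planted

    def test_planted_recovered_exactly(self):
        tables, planted = self._tables()
        cands = sv.candidate_deletions(tables, ["p1", "p2", "p3"], ["a1", "a2"], 1.0)
        got = {(c.reference, c.start, c.end) for c in cands}
        assert got == set(planted)

    def test_zero_planted_gives_empty(self):
        tables, _ = self._tables(n_planted=0, seed=1)
        cands = sv.candidate_deletions(tables, ["p1", "p2", "p3"], ["a1", "a2"], 1.0)
        assert cands == []

    def test_shared_by_all_excluded(self):
        shared = [_rec(1000, 1400, g) for g in ("p1", "p2", "a1")]
        tables = {g: [r] for g, r in zip(("p1", "p2", "a1"), shared)}
        assert sv.candidate_deletions(tables, ["p1", "p2"], ["a1"], 1.0) == []

    def test_partial_presence_excluded(self):
        tables = {
            "p1": [_rec(1000, 1400, "p1")],
            "p2": [_rec(1000, 1400, "p2")],
            "p3": [],
            "a1": [],
        }
        assert sv.candidate_deletions(tables, ["p1", "p2", "p3"], ["a1"], 1.0) == []

    def test_group_order_invariant(self):
        tables, _ = self._tables(seed=2)
        base = sv.candidate_deletions(tables, ["p1", "p2", "p3"], ["a1", "a2"], 1.0)
        for perm in itertools.permutations(["p1", "p2", "p3"]):
            other = sv.candidate_deletions(tables, list(perm), ["a2", "a1"], 1.0)
            assert [(c.start, c.end) for c in other] == [(c.start, c.end) for c in base]

    def test_matches_brute_force_with_jitter_and_overlap(self):
        design = sd.PlantedSvDesign(
            genomes=("p1", "p2", "a1"),
            present_genomes=("p1", "p2"),
            reference_lengths={"chr1": 500_000},
            background_counts={g: {"deletion": 6} for g in ("p1", "p2", "a1")},
            planted=(("chr1", 100_000, 100_400), ("chr1", 300_000, 300_400)),
            jitter=100,
        )
        tables = sd.generate_sv_tables(design, seed=3)
        cands = sv.candidate_deletions(tables, ["p1", "p2"], ["a1"], 0.5)
        oracle = _brute_force_candidates(tables, ["p1", "p2"], ["a1"], 0.5)
        # every qualifying record (oracle) lies inside some candidate's union
        # interval, and every candidate contains at least one such record
        for _, s, e in oracle:
            assert any(c.start <= s and e <= c.end for c in cands)
        for c in cands:
            assert any(c.start <= s and e <= c.end for _, s, e in oracle)
        # every planted deletion is recovered despite jitter <= (1-r) x size
        starts = sorted(c.start for c in cands)
        assert len(cands) == 2
        assert abs(starts[0] - 100_000) <= 100 and abs(starts[1] - 300_000) <= 100

    def test_overlapping_groups_rejected(self):
        tables, _ = self._tables()
        with pytest.raises(ValueError):
            sv.candidate_deletions(tables, ["p1"], ["p1", "a1"], 1.0)


GFF = """\
##gff-version 3
chr1\tsrc\tgene\t101\t500\t.\t+\t.\tID=gene_upstream
chr1\tsrc\tgene\t2001\t2600\t.\t-\t.\tID=gene_far
chr1\tsrc\tgene\t4900\t5600\t.\t+\t.\tID=gene_overlap
chr2\tsrc\tgene\t5000\t5200\t.\t+\t.\tID=gene_other_chrom
"""


class TestProximalGenes:
    @pytest.fixture
    def gff(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(GFF)
        return path

    def _cand(self, start, end):
        return sv.CandidateSv(
            reference="chr1", start=start, end=end,
            present_genomes=frozenset({"p1"}), absent_genomes=frozenset({"a1"}),
            records=(),
        )

    def test_distances_and_boundary(self, gff):
        # candidate at [2000, 2300): gene_upstream ends at 500 -> distance 1500
        (annotated,) = sv.annotate_proximal_genes([self._cand(2000, 2300)], gff, 2000)
        genes = dict(annotated.proximal_genes)
        assert genes["gene_upstream"] == 1500
        assert genes["gene_far"] == 0  # overlaps the candidate

        # 2001 bp away is excluded at the default threshold
        (far,) = sv.annotate_proximal_genes([self._cand(2501, 2600)], gff, 2000)
        assert "gene_upstream" not in dict(far.proximal_genes)

    def test_overlap_distance_zero(self, gff):
        (annotated,) = sv.annotate_proximal_genes([self._cand(5000, 5100)], gff)
        assert dict(annotated.proximal_genes)["gene_overlap"] == 0

    def test_other_chromosome_ignored(self, gff):
        (annotated,) = sv.annotate_proximal_genes([self._cand(4000, 6000)], gff)
        assert "gene_other_chrom" not in dict(annotated.proximal_genes)
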