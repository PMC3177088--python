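import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from cysmap.homology_map import (
    Hit,
    MappingResult,
    SearchParams,
    annotate_odd_case,
    global_realign,
    map_cysteines,
    proximity_hits,
    read_tabular_hits,
    search_homologs,
)
from cysmap.proteome_io import ProteinRecord
from cysmap.structure_db import StructureChain
from cysmap.synthetic_data import CysPlan, _sample_background, generate_structure
from oracle_utils import brute_force_hits, enumerate_alignment_score

AA = "ARNDCQEGHILKMFPSTWYV"


def _random_seq(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


def _points_mapping(points, cutoff=8.0):
    points = np.asarray(points, dtype=float)
    mapped = [(i, i, points[i]) for i in range(len(points))]
    distances = {
        (a, b): float(np.linalg.norm(points[a] - points[b]))
        for a in range(len(points))
        for b in range(a + 1, len(points))
    }
    return MappingResult(
        query_id="q",
        structure_id="s",
        chain_id="A",
        mapped_cys=mapped,
        unmapped_cys=[],
        pair_distances=distances,
        cutoff=cutoff,
    )


class TestGlobalRealign:
    def test_identical_sequences(self):
        aln = global_realign("MACDEF", "MACDEF")
        assert aln.pairs == tuple((i, i) for i in range(6))
        assert aln.identity == 1.0

    def test_single_deletion_skips_the_missing_column(self):
        aln = global_realign("ACDEFG", "ACDFG")
        assert aln.pairs == ((0, 0), (1, 1), (2, 2), (4, 3), (5, 4))
        assert aln.identity == 1.0

    def test_matches_exhaustive_enumeration_on_short_pairs(self, rng):
        for _ in range(30):
            q = _random_seq(rng, int(rng.integers(1, 8)))
            t = _random_seq(rng, int(rng.integers(1, 8)))
            assert global_realign(q, t).score == pytest.approx(
                enumerate_alignment_score(q, t)
            )

    def test_strict_global_matches_enumeration(self, rng):
        for _ in range(20):
            q = _random_seq(rng, int(rng.integers(1, 7)))
            t = _random_seq(rng, int(rng.integers(1, 7)))
            got = global_realign(q, t, semiglobal=False).score
            want = enumerate_alignment_score(q, t, semiglobal=False)
            assert got == pytest.approx(want)

    def test_score_agrees_with_biopython_semiglobal(self, rng):
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.mode = "global"
        aligner.open_gap_score = -12
        aligner.extend_gap_score = -1
        aligner.open_end_insertion_score = 0
        aligner.extend_end_insertion_score = 0
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
        for _ in range(10):
            q = _random_seq(rng, int(rng.integers(10, 40)))
            t = _random_seq(rng, int(rng.integers(10, 40)))
            assert global_realign(q, t).score == pytest.approx(aligner.score(q, t))

    def test_fragment_target_without_end_gap_penalty(self):
        # structure covers only an interior fragment of the query
        q = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        t = q[10:25]
        aln = global_realign(q, t)
        assert aln.identity == 1.0
        assert aln.pairs == tuple((10 + i, i) for i in range(15))

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            global_realign("", "MA")


class TestSearchHomologs:
    def test_self_hit_ranks_first(self, rng):
        lib = {f"S{i:03d}_A": _random_seq(rng, 200) for i in range(20)}
        target = lib["S007_A"]
        query = ProteinRecord(id="q", sequence=target)
        hits = search_homologs(query, lib)
        assert hits[0].target_id == "S007_A"

    def test_unrelated_query_yields_no_hits(self, rng):
        lib = {"S000_A": "W" * 50}
        query = ProteinRecord(id="q", sequence="P" * 50)
        assert search_homologs(query, lib) == []

    def test_evalue_increases_with_planted_divergence(self, rng):
        base = _sample_background(rng, 200)
        lib = {"S000_A": base}
        evalues = []
        for k, div in enumerate(np.linspace(0.0, 0.45, 10)):
            seq = list(base)
            n_mut = int(div * len(seq))
            for p in rng.choice(len(seq), size=n_mut, replace=False):
                new = seq[p]
                while new == seq[p]:
                    new = AA[rng.integers(0, 20)]
                seq[p] = new
            hits = search_homologs(
                ProteinRecord(id=f"q{k}", sequence="".join(seq)),
                lib,
                SearchParams(evalue_max=1e30),
            )
            evalues.append(hits[0].evalue)
        assert all(a <= b * (1 + 1e-12) for a, b in zip(evalues, evalues[1:]))

    def test_tabular_mode(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\tS000_A\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-30\t200\n"
            "q1\tS001_A\t40.0\t100\t60\t0\t1\t100\t1\t100\t0.5\t30\n"
        )
        hits = search_homologs(
            ProteinRecord(id="q1", sequence="MA"),
            {},
            SearchParams(hit_source="tabular"),
            tabular_path=path,
        )
        assert [h.target_id for h in hits] == ["S000_A"]  # 0.5 fails the gate

    def test_tabular_missing_file_is_an_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_tabular_hits(tmp_path / "absent.tsv")

    def test_tabular_wrong_column_count_is_an_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("q1\tS000_A\t95.0\n")
        with pytest.raises(ValueError, match="12 columns"):
            read_tabular_hits(p)

    def test_tie_break_ordering(self):
        hits = sorted(
            [Hit("B", 1e-9, 50.0), Hit("A", 1e-9, 50.0), Hit("C", 1e-10, 40.0)],
            key=lambda h: (h.evalue, -h.score, h.target_id),
        )
        assert [h.target_id for h in hits] == ["C", "A", "B"]


class TestProximity:
    def test_three_clique_counts_three_hits(self):
        pts = [[0, 0, 0], [5, 0, 0], [2.5, 4, 0]]  # mutual distances < 6
        mapping = _points_mapping(pts)
        n_hits, pairs = proximity_hits(mapping, 8.0)
        assert n_hits == 3
        assert len(pairs) == 3

    def test_strict_inequality_at_the_cutoff(self):
        mapping = _points_mapping([[0, 0, 0], [9, 0, 0]])
        assert proximity_hits(mapping, 8.0)[0] == 0
        exactly = _points_mapping([[0, 0, 0], [8.0, 0, 0]])
        assert proximity_hits(exactly, 8.0)[0] == 0

    def test_matches_brute_force_on_random_point_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 13))
            pts = rng.uniform(0, 25, size=(n, 3))
            mapping = _points_mapping(pts)
            n_hits, pairs = proximity_hits(mapping, 8.0)
            want_hits, want_pairs = brute_force_hits(pts, 8.0)
            assert n_hits == want_hits
            assert len(pairs) == want_pairs

    def test_permutation_invariance(self, rng):
        pts = rng.uniform(0, 20, size=(8, 3))
        base = proximity_hits(_points_mapping(pts), 8.0)[0]
        for _ in range(5):
            perm = rng.permutation(8)
            assert proximity_hits(_points_mapping(pts[perm]), 8.0)[0] == base

    def test_hit_count_monotone_in_cutoff(self, rng):
        pts = rng.uniform(0, 20, size=(10, 3))
        mapping = _points_mapping(pts)
        counts = [proximity_hits(mapping, c)[0] for c in (4, 6, 8, 12, 20, 40)]
        assert counts == sorted(counts)


class TestMapCysteines:
    def _chain_with_coords(self, seq, coords, sid="M001"):
        residues = [(i + 1, "", "CYS" if c == "C" else "ALA") for i, c in enumerate(seq)]
        return StructureChain(
            structure_id=sid,
            chain_id="A",
            residues=residues,
            ca_coords=[np.asarray(c, dtype=float) if c is not None else None
                       for c in coords],
        )

    def test_two_cysteines_at_known_distance(self):
        seq = "ACAAC"
        coords = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [1, 5.1, 0]]
        chain = self._chain_with_coords(seq, coords)
        aln = global_realign(seq, seq)
        mapping = map_cysteines(aln, chain, [1, 4])
        assert mapping.n_mapped == 2
        assert mapping.pair_distances[(1, 4)] == pytest.approx(5.1)
        assert mapping.hits == {1, 4}

    def test_cysteine_aligned_into_gap_is_unmapped(self):
        # target lacks the region containing the second cysteine
        q = "AAAACAAAAWWWWWWWWWWCAAAA"
        t = "AAAACAAAA"
        chain = self._chain_with_coords(t, [[i * 3.8, 0, 0] for i in range(len(t))])
        aln = global_realign(q, t)
        mapping = map_cysteines(aln, chain, [4, 19])
        assert 19 in mapping.unmapped_cys
        assert [p for p, _, _ in mapping.mapped_cys] == [4]

    def test_missing_ca_makes_cysteine_unmapped(self):
        seq = "ACAAC"
        coords = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], None]
        chain = self._chain_with_coords(seq, coords)
        aln = global_realign(seq, seq)
        mapping = map_cysteines(aln, chain, [1, 4])
        assert mapping.unmapped_cys == [4]

    def test_target_length_mismatch_is_an_error(self):
        seq = "ACAAC"
        chain = self._chain_with_coords("ACA", [[0, 0, 0]] * 3)
        aln = global_realign(seq, seq)
        with pytest.raises(ValueError, match="exceed"):
            map_cysteines(aln, chain, [1, 4])

    def test_self_mapping_matches_direct_coordinate_scan(self):
        plan = CysPlan(pairs=[(20, 35)], singles=[70])
        chain = generate_structure(100, plan, seed=21, structure_id="SM01")
        aln = global_realign(chain.sequence, chain.sequence)
        eligible = [i for i, aa in enumerate(chain.sequence) if aa == "C"]
        mapping = map_cysteines(aln, chain, eligible)
        n_hits, _ = proximity_hits(mapping, 8.0)
        pts = np.array([chain.ca_coords[i] for i in eligible])
        assert n_hits == brute_force_hits(pts, 8.0)[0]
        assert n_hits == 2  # the planted pair, never the distant single


class TestAnnotateOddCase:
    def test_metal_proximal_label(self):
        seq = "ACAAC"
        coords = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [30, 0, 0]]
        residues = [(i + 1, "", "CYS" if c == "C" else "ALA") for i, c in enumerate(seq)]
        chain = StructureChain(
            structure_id="Z001",
            chain_id="A",
            residues=residues,
            ca_coords=[np.asarray(c, dtype=float) for c in coords],
            metal_sites=[("ZN", np.array([5.0, 0.0, 0.0]))],
        )
        aln = global_realign(seq, seq)
        mapping = map_cysteines(aln, chain, [1, 4])
        labels = annotate_odd_case(mapping, chain)
        assert labels[1] == "metal-proximal"  # CA at 4 A from the Zn
        assert labels[4] == "surface-candidate"

    def test_chain_terminus_is_surface_candidate(self):
        plan = CysPlan(singles=[5, 95])
        chain = generate_structure(100, plan, seed=31, structure_id="SF01")
        aln = global_realign(chain.sequence, chain.sequence)
        mapping = map_cysteines(aln, chain, [5, 95])
        labels = annotate_odd_case(mapping, chain)
        # brute-force neighbour count for the terminal cysteine
        pts = np.array(chain.ca_coords)
        n_nb = int(np.sum(np.linalg.norm(pts - pts[95], axis=1) < 10.0)) - 1
        expected = "surface-candidate" if n_nb < 12 else "buried-unpaired"
        assert labels[95] == expected

    def test_dense_cluster_is_buried(self):
        # 5x5x5 A-spaced grid around a central cysteine: 20+ neighbours
        grid = [
            [x * 4.0, y * 4.0, z * 4.0]
            for x in range(3)
            for y in range(3)
            for z in range(3)
        ]
        seq = "A" * 13 + "C" + "A" * 13
        residues = [(i + 1, "", "CYS" if c == "C" else "ALA") for i, c in enumerate(seq)]
        chain = StructureChain(
            structure_id="B001",
            chain_id="A",
            residues=residues,
            ca_coords=[np.asarray(c, dtype=float) for c in grid],
        )
        aln = global_realign(seq, seq)
        mapping = map_cysteines(aln, chain, [13])
        assert annotate_odd_case(mapping, chain)[13] == "buried-unpaired"
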