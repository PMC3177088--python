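import numpy as np
import pytest

from cysmap.abundance import (
    DedupParams,
    ProteomeSummary,
    classify_abundance,
    compare_f_fprime,
    dedup_strains,
    protein_f,
    proteome_f,
)
from cysmap.homology_map import MappingResult


def _mapping(points, cutoff=8.0):
    points = [np.asarray(p, dtype=float) for p in points]
    distances = {
        (a, b): float(np.linalg.norm(points[a] - points[b]))
        for a in range(len(points))
        for b in range(a + 1, len(points))
    }
    return MappingResult(
        query_id="q",
        structure_id="s",
        chain_id="A",
        mapped_cys=[(i, i, p) for i, p in enumerate(points)],
        unmapped_cys=[],
        pair_distances=distances,
        cutoff=cutoff,
    )


class TestProteinF:
    def test_fully_paired_protein(self):
        hits, mapped, frac = protein_f(_mapping([[0, 0, 0], [5, 0, 0]]))
        assert (hits, mapped, frac) == (2, 2, 1.0)

    def test_nothing_mapped_is_undefined(self):
        hits, mapped, frac = protein_f(_mapping([]))
        assert (hits, mapped) == (0, 0) and frac is None

    def test_single_mapped_cysteine_forces_zero_hits(self):
        hits, mapped, frac = protein_f(_mapping([[0, 0, 0]]))
        assert (hits, mapped, frac) == (0, 1, 0.0)


class TestProteomeF:
    def test_viral_scale_examples(self):
        # m=4 with every cysteine hit -> f = 1
        assert proteome_f([(2, 2), (2, 2)]).f == 1.0
        # m=35, 20 hits -> f = 0.571
        s = proteome_f([(20, 35)])
        assert s.f == pytest.approx(0.5714, abs=1e-4)

    def test_pooled_ratio_not_mean_of_fractions(self):
        # per-protein fractions 1.0 and 0.0 but pooled 2/12
        s = proteome_f([(2, 2), (0, 10)])
        assert s.f == pytest.approx(2 / 12)

    def test_batching_invariance(self, rng):
        tallies = [
            (int(h), int(m))
            for m, h in (
                (m, rng.integers(0, m + 1)) for m in rng.integers(1, 9, size=50)
            )
        ]
        pooled = proteome_f(tallies).f
        assert pooled == pytest.approx(
            sum(h for h, _ in tallies) / sum(m for _, m in tallies)
        )
        # arbitrary re-batching: pool two halves then re-pool the sums
        half1, half2 = tallies[:25], tallies[25:]
        s1, s2 = proteome_f(half1), proteome_f(half2)
        repooled = (s1.n_hits + s2.n_hits) / (s1.m + s2.m)
        assert repooled == pytest.approx(pooled)

    def test_no_mapped_cysteines_is_an_error(self):
        with pytest.raises(ValueError, match="no mapped"):
            proteome_f([(0, 0)])


class TestClassify:
    @pytest.mark.parametrize(
        "f,tier",
        [
            (0.0, "background"),
            (0.15, "background"),  # strict >
            (0.16, "significant"),
            (0.25, "significant"),
            (0.26, "high"),
            (0.35, "high"),
            (0.36, "very_high"),
            (1.0, "very_high"),
        ],
    )
    def test_thresholds(self, f, tier):
        assert classify_abundance(f) == tier

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            classify_abundance(1.5)


def _summary(label, n_mapped):
    return ProteomeSummary(label=label, n_proteins_mapped=n_mapped, m=10, n_hits=5)


class TestDedupStrains:
    def test_similar_strain_is_removed(self):
        summaries = [_summary("parent", 1000), _summary("strainA", 1050)]
        key = {"parent": "sp1", "strainA": "sp1"}
        kept = dedup_strains(summaries, key)
        assert [s.label for s in kept] == ["parent"]

    def test_dissimilar_strain_is_retained(self):
        summaries = [_summary("parent", 1000), _summary("strainB", 1200)]
        key = {"parent": "sp1", "strainB": "sp1"}
        kept = dedup_strains(summaries, key)
        assert [s.label for s in kept] == ["parent", "strainB"]

    def test_different_species_are_never_compared(self):
        summaries = [_summary("a", 1000), _summary("b", 1000)]
        key = {"a": "sp1", "b": "sp2"}
        assert len(dedup_strains(summaries, key)) == 2

    def test_matches_brute_force_on_random_strain_sets(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 12))
            summaries = [
                _summary(f"s{i}", int(rng.integers(100, 2000))) for i in range(n)
            ]
            key = {f"s{i}": f"sp{int(rng.integers(0, 3))}" for i in range(n)}
            kept = {s.label for s in dedup_strains(summaries, key)}
            # brute force: first of each species is parent
            parents = {}
            expect = set()
            for s in summaries:
                sp = key[s.label]
                if sp not in parents:
                    parents[sp] = s
                    expect.add(s.label)
                elif (
                    abs(s.n_proteins_mapped - parents[sp].n_proteins_mapped)
                    > 0.10 * parents[sp].n_proteins_mapped
                ):
                    expect.add(s.label)
            assert kept == expect

    def test_tolerance_validation(self):
        with pytest.raises(ValueError):
            DedupParams(tolerance=1.0)


class TestCompare:
    def test_identical_vectors_give_r_one(self):
        assert compare_f_fprime([(0.1, 0.1), (0.2, 0.2), (0.3, 0.3)]) == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        r = compare_f_fprime([(0.1, 0.5), (0.5, 0.1), (0.3, 0.3)])
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        pairs = [(float(a), float(b)) for a, b in rng.uniform(0, 1, size=(20, 2))]
        x = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        want = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert compare_f_fprime(pairs) == pytest.approx(float(want))

    def test_too_few_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            compare_f_fprime([(0.1, 0.2), (0.3, 0.4)])
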