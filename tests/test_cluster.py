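import numpy as np
import pytest

from ferroscan.cluster import (
    classify_cluster,
    greedy_cluster,
    pangenome_bins,
    similarity_edges,
)
from ferroscan.records import ProteinRecord, RefEntry, ReferenceCatalog

RNG = np.random.default_rng(11)
AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(n, rng=RNG):
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


def prot(pid, seq, genome="g1"):
    return ProteinRecord(pid, genome, pid, "c1", 0, "+", seq)


class TestSimilarityEdges:
    def test_identical_pair_connected(self):
        s = random_protein(80)
        edges = similarity_edges([prot("a", s), prot("b", s)])
        assert edges == [("a", "b")]

    def test_length_mismatch_blocks_bidirectional_coverage(self):
        block = random_protein(50)
        long = block + random_protein(150)
        edges = similarity_edges([prot("a", block), prot("b", long)])
        assert edges == []

    def test_random_pairs_unconnected(self):
        rng = np.random.default_rng(3)
        prots = [prot(f"p{i}", random_protein(100, rng)) for i in range(30)]
        assert similarity_edges(prots) == []

    def test_prefilter_does_not_change_family_edges(self):
        rng = np.random.default_rng(9)
        base = random_protein(90, rng)
        fam = [prot(f"p{i}", _mutate(base, 0.1, rng)) for i in range(5)]
        with_pf = similarity_edges(fam, prefilter=True)
        without = similarity_edges(fam, prefilter=False)
        assert sorted(with_pf) == sorted(without)


def _mutate(seq, p, rng):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < p:
            out[i] = AA[rng.integers(0, 20)]
    return "".join(out)


class TestGreedyCluster:
    def test_triangle_single_cluster(self):
        prots = [prot(p, "A" * 50) for p in "abc"]
        clusters = greedy_cluster(prots, [("a", "b"), ("b", "c"), ("a", "c")])
        assert len(clusters) == 1
        assert clusters[0].members == {"a", "b", "c"}

    def test_path_centroid_is_middle_node(self):
        prots = [prot(p, "A" * 50) for p in "abc"]
        clusters = greedy_cluster(prots, [("a", "b"), ("b", "c")])
        assert len(clusters) == 1
        assert clusters[0].centroid_id == "b"

    def test_no_edges_all_singletons(self):
        prots = [prot(p, "A" * 20) for p in "abcd"]
        clusters = greedy_cluster(prots, [])
        assert len(clusters) == 4
        assert all(len(c.members) == 1 for c in clusters)

    def test_partition_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n = int(rng.integers(2, 25))
            ids = [f"p{i}" for i in range(n)]
            prots = [prot(i, "A" * int(rng.integers(10, 60))) for i in ids]
            edges = [
                (ids[i], ids[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.2
            ]
            clusters = greedy_cluster(prots, edges)
            seen = [m for c in clusters for m in c.members]
            assert sorted(seen) == sorted(ids)  # partition: no dup, no loss
            assert all(c.centroid_id in c.members for c in clusters)

    def test_deterministic(self):
        prots = [prot(f"p{i}", "A" * (10 + i)) for i in range(8)]
        edges = [("p0", "p1"), ("p1", "p2"), ("p3", "p4"), ("p4", "p5")]
        one = greedy_cluster(prots, edges)
        two = greedy_cluster(list(reversed(prots)), list(reversed(edges)))
        assert [(c.centroid_id, sorted(c.members)) for c in one] == [
            (c.centroid_id, sorted(c.members)) for c in two
        ]


def _catalog():
    rng = np.random.default_rng(8)
    return ReferenceCatalog(
        [
            RefEntry("iso_cyc2", "Cyc2", random_protein(120, rng)),
            RefEntry("ref_mtoA", "MtoA", random_protein(150, rng)),
            RefEntry("ref_mtrC", "MtrC", random_protein(150, rng)),
        ]
    )


class TestClassify:
    def test_isolate_representative_wins(self):
        catalog = _catalog()
        from ferroscan.cluster import ClusterAssignment

        cluster = ClusterAssignment(0, "iso_cyc2", {"iso_cyc2", "m1"})
        out = classify_cluster(cluster, {"m1": "MKL" * 20}, catalog)
        assert out.label == "Cyc2"
        assert out.label_source == "isolate-representative"

    def test_consensus_majority(self):
        catalog = _catalog()
        rng = np.random.default_rng(12)
        mto = catalog.for_role("MtoA")[0].sequence
        mtr = catalog.for_role("MtrC")[0].sequence
        seqs = {
            "a": _mutate(mto, 0.05, rng),
            "b": _mutate(mto, 0.05, rng),
            "c": _mutate(mto, 0.05, rng),
            "d": _mutate(mtr, 0.05, rng),
            "e": _mutate(mtr, 0.05, rng),
        }
        from ferroscan.cluster import ClusterAssignment

        cluster = ClusterAssignment(0, "a", set(seqs))
        out = classify_cluster(cluster, seqs, catalog)
        assert out.label == "MtoA"
        assert out.label_source == "consensus"

    def test_no_hits_unclassified(self):
        catalog = _catalog()
        rng = np.random.default_rng(13)
        from ferroscan.cluster import ClusterAssignment

        seqs = {"a": random_protein(100, rng), "b": random_protein(100, rng)}
        cluster = ClusterAssignment(0, "a", set(seqs))
        out = classify_cluster(cluster, seqs, catalog)
        assert out.label == "unclassified"
        assert out.label_source == "none"

    def test_empty_catalog_error(self):
        from ferroscan.cluster import ClusterAssignment

        with pytest.raises(ValueError, match="empty"):
            classify_cluster(
                ClusterAssignment(0, "a", {"a"}), {"a": "MKL"},
                ReferenceCatalog([]),
            )


class TestPangenomeBins:
    @pytest.mark.parametrize(
        "genomes,expected",
        [
            ([f"g{i}" for i in range(9)], "near-core"),       # 9/10 > 0.85
            (["g0"], "strain-specific"),
            ([f"g{i}" for i in range(5)], "accessory"),       # 5/10
        ],
    )
    def test_binning(self, genomes, expected):
        from ferroscan.cluster import ClusterAssignment

        members = {f"p_{g}" for g in genomes}
        genome_of = {f"p_{g}": g for g in genomes}
        cluster = ClusterAssignment(0, sorted(members)[0], members)
        (bin_,) = pangenome_bins([cluster], genome_of, 10)
        assert bin_.bin == expected
        assert bin_.prevalence == pytest.approx(len(genomes) / 10)

    def test_requires_two_genomes(self):
        with pytest.raises(ValueError):
            pangenome_bins([], {}, 1)


def test_threshold_monotonicity_on_families(medium_cohort):
    """Raising coverage/identity thresholds only splits planted-family
    clusters, never merges previously separate ones."""
    from ferroscan.hemes import scan_protein

    prots = [
        p
        for g in medium_cohort.genomes[:6]
        for p in g.proteins
        if scan_protein(p.sequence)
    ]
    loose = greedy_cluster(prots, similarity_edges(prots, 0.8, 30.0))
    strict = greedy_cluster(prots, similarity_edges(prots, 0.9, 60.0))

    def cluster_of(clusters):
        return {m: c.cluster_id for c in clusters for m in c.members}

    lo, hi = cluster_of(loose), cluster_of(strict)
    ids = [p.protein_id for p in prots]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if lo[a] != lo[b]:
                assert hi[a] != hi[b]
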