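import numpy as np
import pytest
from skbio import DistanceMatrix

from ferroscan.phylo import (
    MaskedAlignment,
    PhyloTree,
    _tree_bipartitions,
    align_marker,
    mask_and_concat,
    nj_from_distance_matrix,
    nj_tree,
    pairwise_distances,
)
from ferroscan.simulate import make_fixture

AA = "ACDEFGHIKLMNPQRSTVWY"


def _seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


class TestAlignMarker:
    def test_identical_sequences_no_gaps(self):
        s = _seq(60, 1)
        aligned = align_marker({"a": s, "b": s, "c": s})
        assert all(row == s for row in aligned.values())

    def test_single_sequence_unchanged(self):
        assert align_marker({"a": "MKL"}) == {"a": "MKL"}

    def test_single_internal_deletion_one_gap_column(self):
        s = _seq(80, 2)
        deleted = s[:40] + s[41:]
        aligned = align_marker({"full": s, "del": deleted})
        assert len(aligned["full"]) == len(aligned["del"])
        assert aligned["full"].count("-") == 0
        assert aligned["del"].count("-") == 1
        # agrees with an independent global pairwise aligner
        from Bio import Align
        from Bio.Align import substitution_matrices

        ref = Align.PairwiseAligner()
        ref.mode = "global"
        ref.substitution_matrix = substitution_matrices.load("BLOSUM62")
        ref.open_gap_score = -11
        ref.extend_gap_score = -1
        gap_pos = aligned["del"].index("-")
        qb, _tb = ref.align(s, deleted)[0].aligned
        # the independent aligner also places a single 1-column gap
        assert len(qb) == 2
        assert qb[0][1] == gap_pos

    def test_input_order_invariance(self):
        seqs = {f"s{i}": _seq(50, 10 + i) for i in range(5)}
        seqs["s0"] = seqs["s1"][:20] + seqs["s1"][25:]  # make two related
        fwd = align_marker(dict(seqs))
        rev = align_marker(dict(reversed(list(seqs.items()))))
        assert fwd == rev


def _block(rows):
    return {f"g{i}": r for i, r in enumerate(rows)}


class TestMasking:
    def test_boundary_column_retained(self):
        # interior column 1: 7 gaps of 10 rows (0.7, retained by strict >);
        # interior column 2: 8 of 10 (0.8, removed); flanks gap-free
        rows = [
            "A" + ("-" if i < 7 else "A") + ("-" if i < 8 else "A") + "A"
            for i in range(10)
        ]
        block = _block(rows)
        masked = mask_and_concat({"m": block}, list(block))
        assert masked.length == 3
        assert [c for _m, c in masked.column_map] == [0, 1, 3]

    def test_concat_length_is_sum_of_retained(self):
        b1 = _block(["AAA", "AAA", "A-A"])
        b2 = _block(["CCCC", "CC-C", "CCCC"])
        masked = mask_and_concat({"m1": b1, "m2": b2}, ["g0", "g1", "g2"])
        assert masked.length == 7
        assert all(len(r) == 7 for r in masked.matrix.values())

    def test_absent_marker_padded_with_gaps(self):
        b1 = _block(["AAA", "AAA"])
        masked = mask_and_concat({"m1": b1}, ["g0", "g1", "g9"])
        assert masked.matrix["g9"] == "---"

    def test_masking_idempotent(self):
        rng = np.random.default_rng(4)
        rows = {}
        for i in range(6):
            rows[f"g{i}"] = "".join(
                "-" if rng.random() < 0.3 else AA[rng.integers(0, 20)]
                for _ in range(40)
            )
        once = mask_and_concat({"m": rows}, list(rows))
        twice = mask_and_concat({"m": once.matrix}, list(rows))
        assert twice.matrix == once.matrix

    def test_fully_gapped_block_dropped(self):
        bad = _block(["---", "---", "AAA", "---"])
        masked = mask_and_concat({"m": bad}, ["g0", "g1", "g2", "g3"])
        assert masked.length == 0


class TestDistancesAndNJ:
    def test_nj_exact_on_additive_matrix(self):
        fx = make_fixture("nj-additive")
        tree = nj_from_distance_matrix(fx["distance_matrix"])
        # topology: the single non-trivial bipartition is AB|CD
        bips = _tree_bipartitions(tree)
        assert bips == {frozenset({"C", "D"})}
        for tip in tree.tips():
            assert tip.length == pytest.approx(
                fx["pendant_lengths"][tip.name], abs=1e-9
            )
        internal = [
            n.length for n in tree.non_tips(include_self=False) if n.length
        ]
        assert internal == [pytest.approx(fx["internal_length"], abs=1e-9)]

    def test_duplicate_rows_zero_length_pair(self):
        aln = MaskedAlignment(
            genome_ids=["a", "b", "c", "d"],
            matrix={
                "a": "AAAAAAAAAA", "b": "AAAAAAAAAA",
                "c": "CCCCCCCCCC", "d": "CCCCCGGGGG",
            },
            column_map=[("m", i) for i in range(10)],
        )
        dm = pairwise_distances(aln)
        assert dm["a", "b"] == 0.0

    def test_saturated_pair_capped(self):
        aln = MaskedAlignment(
            genome_ids=["a", "b", "c", "d"],
            matrix={"a": "AAAA", "b": "CCCC", "c": "AAAA", "d": "AAAC"},
            column_map=[("m", i) for i in range(4)],
        )
        dm = pairwise_distances(aln, model="poisson")
        assert dm["a", "b"] == pytest.approx(10.0)

    def test_bootstrap_deterministic_and_order_invariant(self):
        rng = np.random.default_rng(8)
        base = {g: _seq(60, 100) for g in "abcd"}
        # diverge pairs (a,b) vs (c,d)
        mat = {}
        for g in "abcd":
            s = list(base[g])
            extra = 0.05 if g in "ab" else 0.25
            for i in range(len(s)):
                if rng.random() < extra:
                    s[i] = AA[rng.integers(0, 20)]
            mat[g] = "".join(s)
        aln1 = MaskedAlignment(["a", "b", "c", "d"], mat,
                               [("m", i) for i in range(60)])
        aln2 = MaskedAlignment(["d", "c", "b", "a"], mat,
                               [("m", i) for i in range(60)])
        t1 = nj_tree(aln1, bootstraps=50, seed=3)
        t2 = nj_tree(aln2, bootstraps=50, seed=3)
        assert t1.supports == t2.supports

    def test_too_few_genomes_rejected(self):
        aln = MaskedAlignment(["a", "b"], {"a": "AA", "b": "AA"},
                              [("m", 0), ("m", 1)])
        with pytest.raises(ValueError):
            nj_tree(aln, bootstraps=1, seed=0)


def test_progressive_aligner_agrees_with_mafft():
    """Cross-check against an independent MSA tool: pairwise identities
    induced by our progressive alignment match mafft's within 3 points."""
    import shutil
    import subprocess
    import tempfile

    if shutil.which("mafft") is None:
        pytest.skip("mafft not on PATH")
    rng = np.random.default_rng(55)
    base = _seq(120, 900)
    seqs = {}
    for i in range(6):
        s = list(base)
        for j in range(len(s)):
            if rng.random() < 0.12:
                s[j] = AA[rng.integers(0, 20)]
        if i % 2:
            del s[40:43]  # small indel in half the sequences
        seqs[f"s{i}"] = "".join(s)
    ours = align_marker(seqs)

    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        for k, v in seqs.items():
            fh.write(f">{k}\n{v}\n")
        path = fh.name
    out = subprocess.run(
        ["mafft", "--quiet", path], capture_output=True, text=True, check=True
    ).stdout
    theirs = {}
    name = None
    for line in out.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            theirs[name] = ""
        else:
            theirs[name] += line.strip().upper()

    def pid(aln, a, b):
        pairs = [
            (x, y) for x, y in zip(aln[a], aln[b]) if x != "-" and y != "-"
        ]
        return 100.0 * sum(x == y for x, y in pairs) / len(pairs)

    for a in seqs:
        for b in seqs:
            if a < b:
                assert abs(pid(ours, a, b) - pid(theirs, a, b)) <= 3.0
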