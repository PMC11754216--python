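import numpy as np
import pytest

from oracles import (best_topology_by_least_squares, tree_distance_matrix,
                     _all_topologies, topology_bipartitions)
from vdjloci.phylo import (DistanceMatrix, bootstrap, nj, p_distance,
                           read_newick, write_newick)
from vdjloci.seq_core import SeqRecord

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _aa_records(rows):
    return [SeqRecord(id=name, seq=seq, moltype="aa") for name, seq in rows]


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        dm = p_distance(_aa_records([("a", "MKV"), ("b", "MKV")]))
        assert dm.values[0, 1] == 0.0

    def test_half_mismatch(self):
        dm = p_distance(_aa_records([("a", "AC"), ("b", "AD")]))
        assert dm.values[0, 1] == 0.5

    def test_pairwise_deletion_ignores_gap_columns(self):
        dm = p_distance(_aa_records([("a", "A-CD"), ("b", "AAC-")]))
        assert dm.values[0, 1] == 0.0  # only columns 1 and 4 are dropped

    def test_gap_only_overlap_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance(_aa_records([("a", "A--"), ("b", "-AA")]))

    def test_poisson_correction_exceeds_p(self):
        dm_p = p_distance(_aa_records([("a", "AAAA"), ("b", "AAAD")]))
        dm_c = p_distance(_aa_records([("a", "AAAA"), ("b", "AAAD")]), "poisson")
        assert dm_c.values[0, 1] > dm_p.values[0, 1]


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = nj(DistanceMatrix(["A", "B", "C"], d)).tree
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["B"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["C"] == pytest.approx((6 + 8 - 4) / 2)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # hand-built tree ((A:2,B:3):1,C:4,D:5)
        ids = list("ABCD")
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float)
        tree = nj(DistanceMatrix(ids, d)).tree
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 2, "B": 3, "C": 4, "D": 5})
        # AB form a cherry
        parents = {t.name: id(t.parent) for t in tree.tips()}
        assert parents["A"] == parents["B"]
        # tree distances reproduce the input exactly
        for i, x in enumerate(ids):
            for y in ids[i + 1 :]:
                ta = tree.find(x)
                assert ta.distance(tree.find(y)) == pytest.approx(d[ids.index(x), ids.index(y)])

    def test_matches_skbio_reference_implementation(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(3)
        n = 6
        raw = rng.uniform(0.1, 1.0, size=(n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"t{i}" for i in range(n)]
        ours = nj(DistanceMatrix(ids, d)).tree
        theirs = sknj(SkDM(d, ids))
        assert ours.compare_rfd(theirs) == 0.0

    def test_tie_case_is_deterministic(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        ids = list("ABCD")
        t1 = nj(DistanceMatrix(ids, d)).tree
        t2 = nj(DistanceMatrix(ids, d)).tree
        assert str(t1) == str(t2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float))

    @pytest.mark.parametrize("n_taxa,seed", [(5, 0), (5, 1), (6, 2), (6, 3)])
    def test_additive_recovery_verified_by_exhaustive_search(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        edges = _all_topologies(n_taxa)[int(rng.integers(len(_all_topologies(n_taxa))))]
        lengths = {e: float(rng.uniform(0.5, 3.0)) for e in range(len(edges))}
        d = tree_distance_matrix(edges, lengths, n_taxa)
        ids = [f"t{i}" for i in range(n_taxa)]
        # exhaustive least-squares over every topology: truth fits perfectly
        best_edges, sse, best_bps = best_topology_by_least_squares(d)
        assert sse == pytest.approx(0.0, abs=1e-18)
        tree = nj(DistanceMatrix(ids, d)).tree
        names = frozenset(ids)
        got = set()
        for node in tree.non_tips(include_self=False):
            side = frozenset(int(t.name[1:]) for t in node.tips())
            other = frozenset(range(n_taxa)) - side
            if len(side) >= 2 and len(other) >= 2:
                got.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        assert got == best_bps


class TestBootstrap:
    def _clade_msa(self, seed, n_per=3, diverge=60, wobble=2, length=120):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(AA, length))
        other = list(base)
        for p in rng.choice(length, diverge, replace=False):
            other[p] = rng.choice(AA)
        rows = []
        for tag, ancestor in (("a", base), ("b", "".join(other))):
            for i in range(n_per):
                s = list(ancestor)
                for p in rng.choice(length, wobble, replace=False):
                    s[p] = rng.choice(AA)
                rows.append((f"{tag}{i}", "".join(s)))
        return _aa_records(rows)

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_separated_clades_get_high_support(self, seed):
        msa = self._clade_msa(seed)
        tree = bootstrap(msa, n_reps=200, seed=seed)
        clade = frozenset({"a0", "a1", "a2"})
        comp = frozenset({"b0", "b1", "b2"})
        support = tree.supports.get(clade, tree.supports.get(comp))
        assert support is not None and support >= 95.0

    def test_same_seed_reproduces_supports(self):
        msa = self._clade_msa(11)
        t1 = bootstrap(msa, n_reps=50, seed=5)
        t2 = bootstrap(msa, n_reps=50, seed=5)
        assert t1.supports == t2.supports

    def test_supports_lie_in_0_100(self):
        msa = self._clade_msa(12, wobble=10)
        tree = bootstrap(msa, n_reps=50, seed=1)
        assert all(0.0 <= v <= 100.0 for v in tree.supports.values())

    def test_identical_sequences_degenerate_but_complete(self):
        msa = _aa_records([(f"t{i}", "MKVLAAGG" * 6) for i in range(4)])
        tree = bootstrap(msa, n_reps=20, seed=0)
        assert {t.name for t in tree.tree.tips()} == {f"t{i}" for i in range(4)}


class TestNewick:
    def test_three_taxon_star_pattern(self, tmp_path):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = nj(DistanceMatrix(["A", "B", "C"], d))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        text = path.read_text().strip()
        assert text.startswith("(") and text.endswith(";")
        assert all(name in text for name in "ABC")

    @pytest.mark.parametrize("seed", range(1, 6))
    def test_roundtrip_preserves_topology_and_lengths(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n = 6
        raw = rng.uniform(0.1, 1.0, size=(n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"t{i}" for i in range(n)]
        tree = nj(DistanceMatrix(ids, d))
        path = tmp_path / "rt.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert back.tree.compare_rfd(tree.tree) == 0.0
        for tip in tree.tree.tips():
            assert back.tree.find(tip.name).length == pytest.approx(tip.length, abs=1e-9)

    def test_labels_with_spaces_survive_roundtrip(self, tmp_path):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = nj(DistanceMatrix(["taxon one", "taxon two", "C"], d))
        path = tmp_path / "q.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert {t.name for t in back.tree.tips()} == {"taxon one", "taxon two", "C"}
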