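import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from camfam import build_distance_tree, cut_groups
from camfam.grouping import identity_distance_matrix
from camfam.synthetic import mutate_background, reference_cam

from .oracles import bipartitions


def random_additive_tree(n_leaves: int, rng: np.random.Generator) -> TreeNode:
    """Random binary tree with positive branch lengths (leaves L1..Ln)."""
    nodes = [TreeNode(name=f"L{i + 1}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.uniform(0.5, 5.0))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.5, 5.0))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return root


class TestNeighborJoining:
    def test_three_equidistant_sequences(self, rng):
        # three variants mutated at disjoint position sets are pairwise
        # equidistant; NJ resolves them as a star with equal branches
        from camfam import ProteinRecord

        ref = reference_cam(rng)
        # scattered, disjoint position sets and a distinct replacement letter
        # per variant, so every pair differs at exactly 8 positions and no
        # gapped alignment can recover extra matches
        sets = {"W": [8, 35, 61, 71], "Y": [81, 105, 131, 141], "H": [9, 36, 62, 72]}
        records = []
        for i, (letter, posset) in enumerate(sets.items()):
            seq = list(ref.seq)
            for p in posset:
                seq[p] = letter if seq[p] != letter else "F"
            records.append(ProteinRecord(f"s{i}", "".join(seq)))
        dtree = build_distance_tree(records)
        lengths = {t.name: t.length for t in dtree.tree.tips()}
        vals = list(lengths.values())
        assert max(vals) - min(vals) < 1e-6

    def test_additive_four_taxon_recovery(self, rng):
        # additive matrix from ((a,b),(c,d)): NJ recovers the {a,b}|{c,d} split
        dm = DistanceMatrix(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 5],
                [10, 11, 5, 0],
            ],
            ["a", "b", "c", "d"],
        )
        tree = nj(dm)
        assert bipartitions(tree, "a") == {frozenset({"c", "d"})}

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8])
    def test_nj_recovers_random_additive_topologies(self, n_leaves):
        rng = np.random.default_rng(n_leaves * 100)
        for _ in range(10):
            truth = random_additive_tree(n_leaves, rng)
            names = sorted(t.name for t in truth.tips())
            mat = np.zeros((n_leaves, n_leaves))
            for i in range(n_leaves):
                for j in range(i + 1, n_leaves):
                    d = truth.find(names[i]).distance(truth.find(names[j]))
                    mat[i, j] = mat[j, i] = d
            dm = DistanceMatrix(mat, names)
            recovered = nj(dm)
            assert bipartitions(recovered, "L1") == bipartitions(truth, "L1")

    def test_fewer_than_three_records_rejected(self, rng):
        ref = reference_cam(rng)
        with pytest.raises(ValueError):
            build_distance_tree([ref, mutate_background(ref, 3, rng, "v")])

    def test_distance_matrix_properties(self, rng):
        ref = reference_cam(rng)
        records = [ref] + [mutate_background(ref, k, rng, f"v{k}") for k in (5, 40)]
        dm = identity_distance_matrix(records)
        arr = dm.data
        assert np.allclose(arr, arr.T) and np.allclose(np.diag(arr), 0)
        assert arr[0, 1] == pytest.approx(100 - round(100 * 144 / 149, 2), abs=0.01)


class TestCutGroups:
    def test_k1_single_group(self, cohort):
        records, truth = cohort
        fam = [r for r in records if truth[r.id]["family"] != "excluded"][:8]
        dtree = build_distance_tree(fam)
        assert cut_groups(dtree, k=1) == [set(r.id for r in fam)]

    def test_k2_separates_cams_from_cmls(self, cohort):
        records, truth = cohort
        fam = [r for r in records if truth[r.id]["family"] != "excluded"]
        dtree = build_distance_tree(fam)
        groups = {frozenset(g) for g in cut_groups(dtree, k=2)}
        cams = frozenset(r.id for r in fam if truth[r.id]["family"] == "CaM")
        cmls = frozenset(r.id for r in fam if truth[r.id]["family"] == "CML")
        assert groups == {cams, cmls}

    def test_k_equal_leaves_gives_singletons(self, cohort):
        records, truth = cohort
        fam = [r for r in records if truth[r.id]["family"] != "excluded"][:6]
        dtree = build_distance_tree(fam)
        groups = cut_groups(dtree, k=6)
        assert sorted(map(len, groups)) == [1] * 6

    def test_increasing_k_refines_partition(self, cohort):
        records, truth = cohort
        fam = [r for r in records if truth[r.id]["family"] != "excluded"][:10]
        dtree = build_distance_tree(fam)
        prev = cut_groups(dtree, k=1)
        for k in range(2, 8):
            cur = cut_groups(dtree, k=k)
            for group in cur:
                assert any(group <= old for old in prev)
            prev = cur

    def test_k_out_of_range_rejected(self, cohort):
        records, truth = cohort
        fam = [r for r in records if truth[r.id]["family"] != "excluded"][:5]
        dtree = build_distance_tree(fam)
        with pytest.raises(ValueError):
            cut_groups(dtree, k=6)
        with pytest.raises(ValueError):
            cut_groups(dtree, k=2, threshold=10.0)
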