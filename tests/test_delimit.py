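import itertools
import random

import numpy as np
import pytest

from arenosae.delimit import (
    Partition,
    SimilarityMatrix,
    TreeSampleSet,
    UltrametricTree,
    apply_burnin,
    cluster_frequency_table,
    collapse_partition,
    ladderized_tip_order,
    plot_heatmap,
    read_matrix,
    read_trees,
    similarity_matrix,
    sort_by_tree,
    write_matrix,
)
from arenosae.errors import ArenosaeError, NotUltrametricError, TreeFormatError

from conftest import random_ultrametric

NEXUS = """#NEXUS
Begin taxa;
 Dimensions ntax=3;
 Taxlabels a b c;
End;
Begin trees;
 Translate
  1 a,
  2 b,
  3 c;
 tree STATE_0 = [&R] ((1:0.00005,2:0.00005):0.99995,3:1.0);
 tree STATE_1 = [&R] ((1:0.2,3:0.2):0.8,2:1.0);
End;
"""

ANNOTATED = """#NEXUS
Begin trees;
 Translate
  1 a,
  2 b,
  3 c;
 tree S0 = [&R] ((1[&rate=1.2]:0.00005,2[&rate=0.8]:0.00005)[&posterior=0.9]:0.99995,3:1.0)[&height=1.0];
End;
"""


def brute_force_partition(tree: UltrametricTree, eps: float) -> Partition:
    """All-pairs MRCA-height thresholding, merged by transitivity."""
    tips = list(tree.tips)
    parent = {t: t for t in tips}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for a, b in itertools.combinations(tips, 2):
        if tree.mrca_height(a, b) < eps:
            parent[find(a)] = find(b)
    groups = {}
    for t in tips:
        groups.setdefault(find(t), set()).add(t)
    return Partition(frozenset(frozenset(g) for g in groups.values()))


# -- reading --------------------------------------------------------------


def test_nexus_translate_table_honored(tmp_path):
    path = tmp_path / "post.trees"
    path.write_text(NEXUS)
    samples = read_trees(path, format="nexus")
    assert len(samples) == 2
    assert samples.tips == ("a", "b", "c")


def test_newick_mrca_height():
    tree = UltrametricTree.from_newick("((a:0.00005,b:0.00005):0.99995,c:1.0);")
    assert tree.mrca_height("a", "b") == pytest.approx(5e-5)
    assert tree.mrca_height("a", "c") == pytest.approx(1.0, rel=1e-3)


def test_annotations_stripped_to_same_heights(tmp_path):
    plain = tmp_path / "plain.trees"
    noisy = tmp_path / "annotated.trees"
    plain.write_text(NEXUS.replace(
        " tree STATE_1 = [&R] ((1:0.2,3:0.2):0.8,2:1.0);\n", ""))
    noisy.write_text(ANNOTATED)
    a = read_trees(plain, format="nexus").trees[0]
    b = read_trees(noisy, format="nexus").trees[0]
    for x, y in itertools.combinations("abc", 2):
        assert a.mrca_height(x, y) == pytest.approx(b.mrca_height(x, y))


def test_inconsistent_tip_sets_rejected(tmp_path):
    path = tmp_path / "bad.nwk"
    path.write_text("((a:0.1,b:0.1):0.9,c:1.0);\n((a:0.1,b:0.1):0.9,d:1.0);\n")
    with pytest.raises(TreeFormatError):
        read_trees(path, format="newick")


def test_non_ultrametric_tree_names_offending_tip():
    with pytest.raises(NotUltrametricError, match="b"):
        UltrametricTree.from_newick("((a:1.0,b:0.4):0.5,c:1.5);")


# -- burn-in --------------------------------------------------------------


@pytest.mark.parametrize("n, fraction, kept", [
    (100, 0.10, 90),
    (10, 0.0, 10),
    (7, 0.10, 7),   # floor(0.7) = 0 removed
])
def test_burnin_removes_floor_fraction(n, fraction, kept):
    rng = random.Random(5)
    samples = TreeSampleSet([random_ultrametric(rng, 4) for _ in range(n)])
    assert len(apply_burnin(samples, fraction)) == kept


# -- collapse partitions --------------------------------------------------


def test_collapse_threshold_example():
    tree = UltrametricTree.from_newick("((a:0.00005,b:0.00005):0.99995,c:1.0);")
    part = collapse_partition(tree, 1e-4)
    assert part.classes == frozenset({frozenset({"a", "b"}),
                                      frozenset({"c"})})


def test_collapse_above_root_yields_single_class():
    tree = UltrametricTree.from_newick("((a:0.1,b:0.1):0.9,c:1.0);")
    part = collapse_partition(tree, 10.0)
    assert part.classes == frozenset({frozenset({"a", "b", "c"})})


def test_collapse_matches_brute_force_on_random_trees():
    rng = random.Random(42)
    for _ in range(50):
        tree = random_ultrametric(rng, rng.randint(3, 20))
        eps = rng.uniform(0.0, 1.2)
        assert collapse_partition(tree, eps) == \
            brute_force_partition(tree, eps)


def test_collapse_defines_equivalence_relation():
    rng = random.Random(7)
    for _ in range(20):
        tree = random_ultrametric(rng, 12)
        part = collapse_partition(tree, rng.uniform(0.1, 0.9))
        tips = list(tree.tips)
        for a, b, c in itertools.combinations(tips, 3):
            if part.together(a, b) and part.together(b, c):
                assert part.together(a, c)


# -- similarity matrices --------------------------------------------------


def test_identical_samples_give_zero_one_entries():
    tree = UltrametricTree.from_newick("((a:0.00005,b:0.00005):0.99995,c:1.0);")
    m = similarity_matrix([tree] * 5, 1e-4)
    assert set(np.unique(m.matrix)) <= {0.0, 1.0}
    assert m.value("a", "b") == 1.0 and m.value("a", "c") == 0.0


def test_pair_coclustered_in_one_of_two_samples_is_half():
    t1 = UltrametricTree.from_newick("((a:0.00005,b:0.00005):0.99995,c:1.0);")
    t2 = UltrametricTree.from_newick("((a:0.2,b:0.2):0.8,c:1.0);")
    m = similarity_matrix([t1, t2], 1e-4)
    assert m.value("a", "b") == 0.5


def test_matrix_invariants_and_order_invariance():
    rng = random.Random(3)
    trees = [random_ultrametric(rng, 8, max_height=1.0) for _ in range(30)]
    m = similarity_matrix(trees, 0.3)
    assert np.allclose(m.matrix, m.matrix.T)
    assert np.allclose(np.diag(m.matrix), 1.0)
    assert m.matrix.min() >= 0 and m.matrix.max() <= 1
    shuffled = trees[::-1]
    assert np.array_equal(similarity_matrix(shuffled, 0.3).matrix, m.matrix)


def test_empty_sample_set_is_an_error():
    with pytest.raises(ArenosaeError):
        similarity_matrix([], 1e-4)


def test_cluster_frequency_table_counts():
    t1 = UltrametricTree.from_newick("((a:0.00005,b:0.00005):0.99995,c:1.0);")
    t2 = UltrametricTree.from_newick("((a:0.2,b:0.2):0.8,c:1.0);")
    rows = cluster_frequency_table([t1, t1, t1, t2, t2], 1e-4)
    assert [round(f, 6) for _, f in rows] == [0.6, 0.4]
    assert sum(f for _, f in rows) == pytest.approx(1.0)
    single = cluster_frequency_table([t1] * 4, 1e-4)
    assert len(single) == 1 and single[0][1] == 1.0


def test_cluster_frequencies_match_brute_force_counts():
    rng = random.Random(9)
    trees = [random_ultrametric(rng, 6) for _ in range(40)]
    eps = 0.4
    rows = cluster_frequency_table(trees, eps)
    from collections import Counter
    counted = Counter(collapse_partition(t, eps) for t in trees)
    assert {p: round(f * 40) for p, f in rows} == dict(counted)


# -- sorting and IO -------------------------------------------------------


def test_sort_by_caterpillar_summary_tree():
    summary = UltrametricTree.from_newick(
        "((a:0.5,b:0.5):0.5,c:1.0);")
    assert ladderized_tip_order(summary) == ["c", "a", "b"]
    m = similarity_matrix([summary], 0.6)
    sorted_m = sort_by_tree(m, summary)
    assert sorted_m.labels == ("c", "a", "b")


def test_sort_is_identity_when_already_ladderized():
    summary = UltrametricTree.from_newick("((a:0.5,b:0.5):0.5,c:1.0);")
    m = similarity_matrix([summary], 0.6).reorder(["c", "a", "b"])
    assert sort_by_tree(m, summary).labels == m.labels


def test_sort_invariant_to_input_permutation():
    rng = random.Random(11)
    trees = [random_ultrametric(rng, 7) for _ in range(10)]
    summary = random_ultrametric(rng, 7)
    m = similarity_matrix(trees, 0.4)
    for _ in range(5):
        perm = list(m.labels)
        rng.shuffle(perm)
        permuted = m.reorder(perm)
        assert sort_by_tree(permuted, summary).labels == \
            sort_by_tree(m, summary).labels
        assert np.array_equal(sort_by_tree(permuted, summary).matrix,
                              sort_by_tree(m, summary).matrix)


def test_matrix_write_read_round_trip(tmp_path):
    tree = UltrametricTree.from_newick("((a:0.00005,b:0.00005):0.99995,c:1.0);")
    m = similarity_matrix([tree], 1e-4)
    path = tmp_path / "m.csv"
    write_matrix(m, path)
    assert len(path.read_text().strip().splitlines()) == 4  # header + 3 rows
    again = read_matrix(path)
    assert again.labels == m.labels
    assert np.allclose(again.matrix, m.matrix)


def test_heatmap_file_written(tmp_path):
    tree = UltrametricTree.from_newick("((a:0.1,b:0.1):0.9,c:1.0);")
    m = similarity_matrix([tree], 0.5)
    path = tmp_path / "heat.png"
    plot_heatmap(m, path)
    assert path.exists() and path.stat().st_size > 0
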