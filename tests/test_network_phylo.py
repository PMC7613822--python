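"""Similarity networks, clustering, NJ trees, and bootstrap supports."""

import numpy as np
import pandas as pd
import pytest

from hydromine.network_phylo import (
    all_vs_all,
    bootstrap_support,
    build_network,
    components,
    nj_tree,
    p_distance_matrix,
    select_cocluster,
)
from hydromine.sequence_core import align_pair
from hydromine.synthetic_data import MetagenomeConfig, gen_metagenome

from conftest import make_record


@pytest.fixture(scope="module")
def planted():
    cfg = MetagenomeConfig(n_families=3, members_per_family=4, n_decoys=0)
    records, refs, manifest = gen_metagenome(cfg, seed=7)
    return records, refs, manifest


class TestAllVsAll:
    def test_identical_pair_and_symmetry(self, blosum):
        a, b = make_record("MKVLHEWACD", "a"), make_record("MKVLHEWACD", "b")
        c = make_record("WYWYWYWYWY", "c")
        w = all_vs_all([a, b, c], metric="identity", matrix=blosum)
        assert w.loc["a", "b"] == 1.0
        assert np.allclose(w.values, w.values.T)
        assert all(w.loc[i, i] == 1.0 for i in "abc")

    def test_matches_independent_pairwise_calls(self, blosum):
        seqs = [
            make_record("MKVLHEWACDEF", "a"),
            make_record("MKVLHEWACDEG", "b"),
            make_record("GHIKLMNPQRST", "c"),
        ]
        w = all_vs_all(seqs, metric="score_per_column", matrix=blosum)
        for i in range(3):
            for j in range(i + 1, 3):
                aln = align_pair(seqs[i], seqs[j], blosum)
                assert w.iloc[i, j] == pytest.approx(aln.score / len(aln))

    def test_duplicate_ids_rejected(self, blosum):
        with pytest.raises(ValueError):
            all_vs_all([make_record("ACD", "a"), make_record("ACD", "a")], matrix=blosum)


class TestNetworkAndClusters:
    def test_threshold_extremes(self):
        w = pd.DataFrame(
            [[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        empty = build_network(w, threshold=0.9)
        assert len(empty.edges) == 0
        assert components(empty).n_clusters == 3
        full = build_network(w, threshold=0.1)
        assert len(full.edges) == 3
        assert components(full).n_clusters == 1

    def test_planted_families_recovered_as_components(self, planted, blosum):
        records, refs, manifest = planted
        pool = records + [r for r, _, _ in refs.values()]
        w = all_vs_all(pool, metric="identity", matrix=blosum)
        net = build_network(w, threshold=0.45, metric="identity")
        assign = components(net)
        for fam in ("fam0", "fam1", "fam2"):
            members = manifest.family_members(fam)
            labels = {assign.labels[m] for m in members}
            assert len(labels) == 1  # family is one component
        # distinct families never merge
        all_labels = [assign.labels[m] for fam in ("fam0", "fam1", "fam2") for m in [manifest.family_members(fam)[0]]]
        assert len(set(all_labels)) == 3

    def test_component_count_monotone_in_threshold(self, planted, blosum):
        records, refs, _ = planted
        pool = records + [r for r, _, _ in refs.values()]
        w = all_vs_all(pool, metric="identity", matrix=blosum)
        counts = [
            components(build_network(w, threshold=t)).n_clusters
            for t in (0.0, 0.3, 0.45, 0.7, 0.95, 1.01)
        ]
        assert counts == sorted(counts)

    def test_canonical_labels_stable_under_permutation(self):
        w = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=list("bca"),
            columns=list("bca"),
        )
        assign = components(build_network(w, 0.5))
        perm = w.loc[list("acb"), list("acb")]
        assign2 = components(build_network(perm, 0.5))
        assert assign.labels == assign2.labels

    def test_select_cocluster(self, planted, blosum):
        records, refs, manifest = planted
        ref_id = sorted(refs)[0]
        pool = records + [r for r, _, _ in refs.values()]
        w = all_vs_all(pool, metric="identity", matrix=blosum)
        assign = components(build_network(w, threshold=0.45))
        picked = select_cocluster(assign, [ref_id])
        assert picked == manifest.family_members("fam0")
        with pytest.raises(ValueError):
            select_cocluster(assign, ["nope"])

    def test_singleton_references_select_nothing(self):
        w = pd.DataFrame(np.eye(3), index=list("abr"), columns=list("abr"))
        assign = components(build_network(w, threshold=0.5))
        assert select_cocluster(assign, ["r"]) == []


class TestNjTree:
    def test_two_taxa_split_halves_distance(self):
        dm = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["a", "b"], columns=["a", "b"])
        tree = nj_tree(dm)
        tips = {t.name: t.length for t in tree.tree.tips()}
        assert tips == {"a": pytest.approx(0.2), "b": pytest.approx(0.2)}

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # classic additive matrix from tree ((a:2,b:3):3,(c:4,d:4)) with
        # internal edge 3 (wiki NJ worked example)
        ids = list("abcd")
        mat = pd.DataFrame(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
            index=ids, columns=ids, dtype=float,
        )
        tree = nj_tree(mat)
        patristic = tree.tree.tip_tip_distances()
        for i in ids:
            for j in ids:
                if i != j:
                    assert patristic[i, j] == pytest.approx(mat.loc[i, j])
        assert frozenset({"c", "d"}) in tree.bipartitions() or frozenset({"b", "a"}) in tree.bipartitions()

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        # distances generated from ((a:1,b:2):1.5,(c:0.5,d:1):2,e:3)
        import itertools

        paths = {
            ("a", "b"): 3.0,
            ("a", "c"): 5.0, ("a", "d"): 5.5, ("a", "e"): 5.5,
            ("b", "c"): 6.0, ("b", "d"): 6.5, ("b", "e"): 6.5,
            ("c", "d"): 1.5, ("c", "e"): 5.5, ("d", "e"): 6.0,
        }
        ids = list("abcde")
        mat = pd.DataFrame(0.0, index=ids, columns=ids)
        for (i, j), d in paths.items():
            mat.loc[i, j] = mat.loc[j, i] = d
        tree = nj_tree(mat)
        patristic = tree.tree.tip_tip_distances()
        for i, j in itertools.combinations(ids, 2):
            assert patristic[i, j] == pytest.approx(mat.loc[i, j])
        assert frozenset({"c", "d"}) in tree.bipartitions()

    def test_topology_invariant_to_taxon_order(self):
        ids = list("abcd")
        mat = pd.DataFrame(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
            index=ids, columns=ids, dtype=float,
        )
        perm = list("dbca")
        t1 = nj_tree(mat)
        t2 = nj_tree(mat.loc[perm, perm])
        assert t1.bipartitions() == t2.bipartitions()

    def test_negative_distance_rejected(self):
        mat = pd.DataFrame([[0, -1], [-1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(mat)


class TestBootstrap:
    @staticmethod
    def _block_alignment():
        # two clean blocks: (a,b) vs (c,d) — every column supports ab|cd
        return {
            "a": "AAAAAAAAAACCCCCCCCCC",
            "b": "AAAAAAAAAACCCCCCCCCG",
            "c": "GGGGGGGGGGTTTTTTTTTT",
            "d": "GGGGGGGGGGTTTTTTTTTA",
        }

    def test_congruent_signal_gives_full_support(self):
        tree = bootstrap_support(self._block_alignment(), n_replicates=50, seed=5)
        assert tree.supports  # exactly one internal bipartition on 4 taxa
        assert all(s == 100.0 for s in tree.supports.values())

    def test_fixed_seed_reproducible(self):
        aligned = self._block_alignment()
        t1 = bootstrap_support(aligned, n_replicates=30, seed=9)
        t2 = bootstrap_support(aligned, n_replicates=30, seed=9)
        assert t1.supports == t2.supports
        assert t1.newick() == t2.newick()

    def test_identical_sequences_flagged_as_star(self):
        aligned = {k: "ACDACDACD" for k in "abc"}
        with pytest.warns(UserWarning, match="star"):
            tree = bootstrap_support(aligned, n_replicates=5, seed=1)
        assert tree.star

    def test_conflicting_columns_match_multinomial_oracle(self):
        # 90% of columns support ab|cd, 10% support ac|bd
        n_major, n_minor = 18, 2
        aligned = {
            "a": "A" * n_major + "A" * n_minor,
            "b": "A" * n_major + "C" * n_minor,
            "c": "C" * n_major + "A" * n_minor,
            "d": "C" * n_major + "C" * n_minor,
        }
        tree = bootstrap_support(aligned, n_replicates=1000, seed=13)
        support = max(tree.supports.values())
        assert 50 < support <= 100
        # independent oracle: resample column classes multinomially; the
        # ab|cd split wins a replicate iff more major than minor columns drawn
        rng = np.random.default_rng(99)
        L = n_major + n_minor
        draws = rng.multinomial(L, [n_major / L, n_minor / L], size=20000)
        oracle = 100.0 * np.mean(draws[:, 0] > draws[:, 1])
        assert support == pytest.approx(oracle, abs=4.0)


class TestPDistance:
    def test_counts_only_ungapped_columns(self):
        d = p_distance_matrix({"a": "AC-D", "b": "AA-D"})
        assert d.loc["a", "b"] == pytest.approx(1 / 3)

    def test_poisson_correction(self):
        d = p_distance_matrix({"a": "AAAA", "b": "AAAC"}, poisson=True)
        assert d.loc["a", "b"] == pytest.approx(-np.log(1 - 0.25))
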