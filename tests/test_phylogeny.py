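"""Exhaustive parsimony search, topology classification and the ML check,
validated against a brute-force small-parsimony oracle."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from lesionevo.phylogeny import (
    BinaryCharacterMatrix,
    build_matrix,
    classify_topology,
    cna_event_tree,
    enumerate_topologies,
    fitch_score,
    ml_cross_check,
    parsimony_tree,
    shared_vaf_comparison,
)
from lesionevo.records import TopologyType

from .conftest import make_variants


def brute_force_min_score(matrix: BinaryCharacterMatrix) -> int:
    """Independent oracle: for every topology, minimize changes over all
    internal-node state assignments by direct enumeration."""

    def tree_edges(topology):
        edges = []
        nodes = {}
        counter = [0]

        def walk(node):
            nid = counter[0]
            counter[0] += 1
            nodes[nid] = node if isinstance(node, str) else None
            if isinstance(node, tuple):
                for ch in node:
                    cid = walk(ch)
                    edges.append((nid, cid))
            return nid

        walk(topology)
        return edges, nodes

    best = None
    for topo in enumerate_topologies(matrix.taxa):
        edges, nodes = tree_edges(topo)
        internal = [n for n, lab in nodes.items() if lab is None]
        total = 0
        for j in range(len(matrix.characters)):
            leaf_state = {
                lab: int(matrix.matrix[matrix.taxa.index(lab), j])
                for lab in nodes.values()
                if lab is not None
            }
            char_best = None
            for assignment in product([0, 1], repeat=len(internal)):
                state = {n: s for n, s in zip(internal, assignment)}
                for n, lab in nodes.items():
                    if lab is not None:
                        state[n] = leaf_state[lab]
                changes = sum(state[a] != state[b] for a, b in edges)
                char_best = changes if char_best is None else min(char_best, changes)
            total += char_best
        best = total if best is None else min(best, total)
    return best


def random_matrix(rng, n_taxa, n_chars):
    taxa = tuple(f"t{i}" for i in range(n_taxa))
    mat = rng.integers(0, 2, size=(n_taxa, n_chars))
    return BinaryCharacterMatrix(taxa, tuple(f"c{j}" for j in range(n_chars)), mat)


class TestEnumerateTopologies:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 3), (5, 15), (6, 105)])
    def test_topology_counts(self, n, count):
        assert len(enumerate_topologies([f"t{i}" for i in range(n)])) == count

    def test_too_many_taxa_rejected(self):
        with pytest.raises(ValueError):
            enumerate_topologies([f"t{i}" for i in range(7)])


class TestBuildMatrix:
    def test_presence_pattern(self):
        by_sample = {
            "N": make_variants([], role="N"),
            "L": make_variants([{"pos": 7}], role="L"),
            "G": make_variants([{"pos": 7}], role="G"),
        }
        m = build_matrix(by_sample)
        assert m.taxa == ("Nm", "N", "L", "G")
        assert m.matrix[:, 0].tolist() == [0, 0, 1, 1]

    def test_duplicate_keys_collapse(self):
        by_sample = {
            "L": make_variants([{"pos": 7}, {"pos": 7}], role="L"),
            "G": make_variants([{"pos": 7}], role="G"),
        }
        m = build_matrix(by_sample)
        assert len(m.characters) == 1

    def test_empty_gives_empty_matrix(self):
        m = build_matrix({"L": make_variants([]), "G": make_variants([])})
        assert m.matrix.shape == (3, 0)

    def test_type1_pattern_counts_match_ledger(self, sim_case):
        from lesionevo.filtering import subtract_germline

        bundle, truth = sim_case
        nm = bundle.variants[bundle.variants["role"] == "Nm"]
        somatic = subtract_germline(bundle.variants[bundle.variants["role"] != "Nm"], nm)
        by_role = {r: g for r, g in somatic.groupby("role") if r != "Nm"}
        m = build_matrix({r: by_role[r] for r in ("N", "L", "G")})
        idx = {t: i for i, t in enumerate(m.taxa)}
        pattern_lg = int(
            np.sum(
                (m.matrix[idx["L"]] == 1)
                & (m.matrix[idx["G"]] == 1)
                & (m.matrix[idx["N"]] == 0)
            )
        )
        truth_shared = truth.variants[truth.variants["branch"] == "shared"]
        # every ledger-shared variant distinct key appears as an {L,G} pattern
        assert pattern_lg >= truth_shared[["chrom", "pos"]].drop_duplicates().shape[0] - 1


class TestParsimonyTree:
    def test_dominant_shared_signal(self):
        taxa = ("Nm", "N", "L", "G")
        chars = []
        mat = []
        for _ in range(50):
            mat.append([0, 0, 1, 1])
        for row in ([0, 0, 1, 0], [0, 0, 0, 1], [0, 1, 0, 0]):
            for _ in range(5):
                mat.append(list(row))
        m = BinaryCharacterMatrix(taxa, tuple(f"c{i}" for i in range(len(mat))), np.array(mat).T)
        tree = parsimony_tree(m)
        assert not tree.unresolved
        assert classify_topology(tree) is TopologyType.TYPE1
        assert tree.branch_counts[frozenset({"L", "G"})] == 50

    def test_single_character_is_tie(self):
        m = BinaryCharacterMatrix(
            ("Nm", "N", "L", "G"), ("c0",), np.array([[0], [0], [1], [1]]).reshape(4, 1)
        )
        tree = parsimony_tree(m)
        assert tree.score == 1
        # an {L,G} character does discriminate: only one topology needs 1 change
        assert classify_topology(tree) is TopologyType.TYPE1

    def test_uninformative_character_ties_all_topologies(self):
        m = BinaryCharacterMatrix(
            ("Nm", "N", "L", "G"), ("c0",), np.array([0, 0, 0, 1]).reshape(4, 1)
        )
        tree = parsimony_tree(m)
        assert len(tree.tied_topologies) == 3
        assert classify_topology(tree) is TopologyType.UNRESOLVED

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_min_score_matches_brute_force(self, n_taxa, rng):
        for _ in range(10):
            m = random_matrix(rng, n_taxa, int(rng.integers(1, 25)))
            assert parsimony_tree(m).score == brute_force_min_score(m)

    def test_taxon_order_invariance(self, rng):
        m = random_matrix(rng, 4, 30)
        tree_a = parsimony_tree(m)
        perm = [2, 0, 3, 1]
        m2 = BinaryCharacterMatrix(
            tuple(m.taxa[i] for i in perm), m.characters, m.matrix[perm]
        )
        tree_b = parsimony_tree(m2)
        assert tree_a.score == tree_b.score

    def test_branch_counts_sum_to_score(self, rng):
        m = random_matrix(rng, 5, 40)
        tree = parsimony_tree(m)
        assert sum(tree.branch_counts.values()) == tree.score

    def test_empty_matrix(self):
        m = BinaryCharacterMatrix(("Nm", "N", "L", "G"), (), np.zeros((4, 0)))
        tree = parsimony_tree(m)
        assert tree.topology is None and tree.score == 0

    def test_newick_rooted_at_nm(self):
        m = BinaryCharacterMatrix(
            ("Nm", "N", "L", "G"),
            tuple(f"c{i}" for i in range(10)),
            np.tile([0, 0, 1, 1], (10, 1)).T,
        )
        nwk = parsimony_tree(m).newick
        assert nwk.startswith("(Nm:") and nwk.endswith(";")
        assert "L:0" in nwk and "G:0" in nwk


class TestClassifyTopology:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ([0, 0, 1, 1], TopologyType.TYPE1),  # {L,G} branch
            ([0, 1, 1, 0], TopologyType.TYPE2),  # {N,L} branch
            ([0, 1, 0, 1], TopologyType.TYPE3),  # {N,G} branch
        ],
    )
    def test_types_from_dominant_branch(self, pattern, expected):
        m = BinaryCharacterMatrix(
            ("Nm", "N", "L", "G"),
            tuple(f"c{i}" for i in range(20)),
            np.tile(pattern, (20, 1)).T,
        )
        assert classify_topology(parsimony_tree(m)) is expected

    def test_missing_normal_gland_unresolved(self):
        m = BinaryCharacterMatrix(
            ("Nm", "L", "G"), ("c0",), np.array([0, 1, 1]).reshape(3, 1)
        )
        assert classify_topology(parsimony_tree(m)) is TopologyType.UNRESOLVED

    def test_simulated_cohort_recovery(self, gene_table):
        from lesionevo.filtering import subtract_germline
        from lesionevo.synthetic_data import SimConfig, simulate_case

        for ttype in ("TYPE1", "TYPE2", "TYPE3"):
            cfg = SimConfig(seed=31, topology_types=ttype, n_cases=3)
            for i in range(3):
                bundle, _ = simulate_case(cfg, i, gene_table)
                nm = bundle.variants[bundle.variants["role"] == "Nm"]
                somatic = subtract_germline(
                    bundle.variants[bundle.variants["role"] != "Nm"], nm
                )
                by_role = {r: g for r, g in somatic.groupby("role")}
                tree = parsimony_tree(build_matrix({r: by_role[r] for r in ("N", "L", "G")}))
                assert classify_topology(tree) is TopologyType(ttype)


class TestCnaEventTree:
    def events(self, sample, rows):
        base = {
            "case_id": "case1", "sample_id": sample, "chrom": "chr1",
            "start": 1, "end": 1_000_000, "event_type": "GAIN",
            "affected_haplotype": pd.NA,
        }
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_shared_gain_private_losses_type1(self):
        ev = {
            "N": self.events("N", []),
            "L": self.events("L", [{}]),
            "G": self.events(
                "G",
                [{}, {"chrom": "chr2", "event_type": "LOSS"}, {"chrom": "chr3", "event_type": "LOSS"}],
            ),
        }
        tree = cna_event_tree(ev)
        assert classify_topology(tree) is TopologyType.TYPE1

    def test_no_events_empty_unresolved(self):
        ev = {r: self.events(r, []) for r in ("N", "L", "G")}
        tree = cna_event_tree(ev)
        assert tree.topology is None
        assert classify_topology(tree) is TopologyType.UNRESOLVED

    def test_same_interval_different_type_not_clustered(self):
        ev = {
            "L": self.events("L", [{"event_type": "GAIN"}]),
            "G": self.events("G", [{"event_type": "LOSS"}]),
        }
        tree = cna_event_tree(ev)
        assert len(tree.branch_counts) >= 1 and tree.score == 2


class TestSharedVafComparison:
    def test_identical_vectors(self):
        out = shared_vaf_comparison([0.2] * 10, [0.2] * 10)
        assert out["mean_difference"] == 0.0
        assert out["p_value"] == pytest.approx(1.0)

    def test_separated_vectors(self):
        out = shared_vaf_comparison([0.2] * 20, [0.4] * 20)
        assert out["mean_G"] > out["mean_L"]
        assert out["p_value"] < 1e-6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shared_vaf_comparison([], [0.2])


class TestMlCrossCheck:
    def test_concordant_on_strong_signal(self):
        m = BinaryCharacterMatrix(
            ("Nm", "N", "L", "G"),
            tuple(f"c{i}" for i in range(30)),
            np.tile([0, 0, 1, 1], (30, 1)).T,
        )
        out = ml_cross_check(m)
        assert out["concordant"]
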