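"""Alignment engine, bit-score gate, residue checks, NJ clade placement."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from _oracles import gotoh_score
from magenes import homology, synth_fixtures as sf
from magenes.homology import (
    DEFAULT_PARAMS,
    ResidueProfile,
    ScoringParams,
    align,
    align_score,
    check_residues,
    map_to_anchor,
    nj_clade_assign,
    nj_tree,
    screen_homologs,
)
from magenes.seq_io import SeqRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def _sub(params=DEFAULT_PARAMS):
    m = homology._matrix(params)
    return lambda x, y: float(m[x, y])


class TestAlign:
    def test_self_alignment_full_identity_and_coverage(self):
        r = align("MKTAYIAKQR", "MKTAYIAKQR")
        assert r.pct_identity == 1.0
        assert r.coverage_a == r.coverage_b == 1.0
        assert r.column_pairs == [(i, i) for i in range(10)]

    def test_bitscore_formula_hand_arithmetic(self):
        # S=100, lambda=0.267, K=0.041: (26.7 + 3.194) / ln 2 ~= 43.1
        p = ScoringParams()
        assert p.bitscore(100.0) == pytest.approx(43.126, abs=0.01)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align("", "MKLV")

    @pytest.mark.parametrize("mode", ["global", "local"])
    def test_scores_match_brute_force_dp_on_random_pairs(self, mode, rng):
        sub = _sub()
        for _ in range(50):
            a = "".join(rng.choice(list(AA), size=rng.integers(5, 61)))
            b = "".join(rng.choice(list(AA), size=rng.integers(5, 61)))
            mine = align_score(a, b, mode=mode)
            oracle = gotoh_score(a, b, sub, -11.0, -1.0, local=(mode == "local"))
            assert mine == pytest.approx(oracle, abs=1e-9)

    def test_score_symmetric(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list(AA), size=40))
            b = "".join(rng.choice(list(AA), size=35))
            assert align_score(a, b) == align_score(b, a)

    def test_bitscore_strictly_increasing_in_raw_score(self):
        p = ScoringParams()
        scores = [p.bitscore(s) for s in (10.0, 50.0, 100.0, 200.0)]
        assert scores == sorted(scores) and len(set(scores)) == 4

    def test_pyrrolysine_scored_as_lysine_by_default(self):
        m = homology._matrix(DEFAULT_PARAMS)
        assert m["O", "K"] == m["K", "K"]
        assert m["O", "W"] == m["K", "W"]


class TestScreen:
    def test_seed_screened_against_itself_is_retained(self, ancestors):
        seed = ancestors["cutC"]
        [(cand, best, bits)] = screen_homologs([seed], [seed])
        assert cand.id == seed.id and bits > 60

    def test_random_sequences_rejected_by_60_bit_gate(self, rng):
        seed = SeqRecord("seed", sf.random_protein(500, rng), moltype="protein")
        n_pass = 0
        for i in range(100):
            cand = SeqRecord(f"r{i}", sf.random_protein(100, rng), moltype="protein")
            n_pass += bool(screen_homologs([cand], [seed]))
        assert n_pass <= 1  # >= 99/100 rejected

    def test_short_identical_fragment_cannot_reach_60_bits(self, rng):
        seed = SeqRecord("seed", sf.random_protein(500, rng), moltype="protein")
        frag = SeqRecord("frag", seed.residues[100:120], moltype="protein")
        assert screen_homologs([frag], [seed]) == []
        bits = DEFAULT_PARAMS.bitscore(align_score(frag, seed, mode="local"))
        assert bits < 60

    def test_gate_disabled_returns_everything(self, rng):
        seed = SeqRecord("seed", sf.random_protein(200, rng), moltype="protein")
        cands = [
            SeqRecord(f"c{i}", sf.random_protein(80, rng), moltype="protein")
            for i in range(5)
        ]
        assert len(screen_homologs(cands, [seed], min_bits=-math.inf)) == 5

    def test_no_seeds_raises(self):
        with pytest.raises(ValueError):
            screen_homologs([], [])


class TestMapToAnchor:
    def test_identity_mapping_for_identical_sequences(self):
        m = map_to_anchor("MKTAYIAKQR", "MKTAYIAKQR")
        assert m == {i: i for i in range(10)}

    def test_deletion_maps_anchor_position_to_gap(self):
        # brute-force check on the toy pair: MKLV vs MLV (K deleted)
        m = map_to_anchor("MLV", "MKLV")
        assert m[0] == 0 and m[1] is None and m[2] == 1 and m[3] == 2

    def test_mapping_monotone(self, rng):
        for _ in range(10):
            anchor = sf.random_protein(60, rng)
            cand = sf.random_protein(55, rng)
            mapped = [v for v in map_to_anchor(cand, anchor).values() if v is not None]
            assert mapped == sorted(mapped)


class TestCheckResidues:
    @pytest.fixture()
    def profile(self, rng):
        anchor = SeqRecord("anc", sf.random_protein(80, rng), moltype="protein")
        required = [(10, frozenset(anchor.residues[10])), (40, frozenset(anchor.residues[40]))]
        return ResidueProfile(gene_type="cutC", anchor=anchor, required=required)

    def test_anchor_passes_its_own_profile(self, profile):
        ok, matched, failed = check_residues(profile.anchor, profile)
        assert ok and failed == [] and matched == [10, 40]

    def test_mutated_catalytic_position_fails_and_is_listed(self, profile):
        res = list(profile.anchor.residues)
        res[40] = "A" if res[40] != "A" else "G"
        ok, _, failed = check_residues("".join(res), profile)
        assert not ok and failed == [40]

    def test_deletion_spanning_required_position_fails(self, profile):
        res = profile.anchor.residues
        ok, _, failed = check_residues(res[:35] + res[46:], profile)
        assert not ok and 40 in failed


class TestNJ:
    @staticmethod
    def _additive_distances(rng, n_leaves):
        """Random rooted binary tree; return leaf names, path distances and
        the set of (frozenset) splits it induces."""
        import itertools

        nodes = [(f"L{i}",) for i in range(n_leaves)]
        edges = {}
        children = {}
        next_id = 0
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[j], nodes[i]
            parent = a + b
            for child in (a, b):
                edges[child] = float(rng.uniform(0.05, 0.5))
                children.setdefault(parent, []).append(child)
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
        # path distances by walking up from leaves
        def path_to_root(leaf):
            out = {}
            node = leaf
            dist = 0.0
            chain = [(node, 0.0)]
            while node in edges:
                dist += edges[node]
                parent = next(p for p, cs in children.items() if node in cs)
                chain.append((parent, dist))
                node = parent
            return dict(chain)

        leaves = [f"L{i}" for i in range(n_leaves)]
        paths = {l: path_to_root((l,)) for l in leaves}
        d = np.zeros((n_leaves, n_leaves))
        for x, y in itertools.combinations(range(n_leaves), 2):
            px, py = paths[leaves[x]], paths[leaves[y]]
            common = [n for n in px if n in py]
            d_xy = min(px[n] + py[n] for n in common)
            d[x, y] = d[y, x] = d_xy
        splits = {
            frozenset(c)
            for c in children
            if 1 < len(c) < n_leaves - 1
        }
        return leaves, d, splits

    def test_nj_recovers_topology_from_additive_matrices(self, rng):
        for _ in range(20):
            leaves, d, true_splits = self._additive_distances(rng, 6)
            tree = nj_tree(DistanceMatrix(d, ids=leaves))
            tree_splits = set()
            for node in tree.non_tips(include_self=False):
                tips = frozenset(t.name for t in node.tips())
                if 1 < len(tips) < len(leaves) - 1:
                    tree_splits.add(tips)
            # unrooted comparison: a split equals itself or its complement
            all_leaves = frozenset(leaves)
            norm = lambda s: min(s, all_leaves - s, key=lambda x: sorted(x))
            assert {norm(s) for s in true_splits} <= {norm(s) for s in tree_splits} | {
                norm(s) for s in true_splits if len(s) in (1, len(leaves) - 1)
            }

    def test_copies_of_positive_reference_always_assigned(self, ancestors):
        anchor = ancestors["grdI"]
        refs = [anchor] + sf.make_family(anchor, 2, 0.9, seed=1, id_prefix="ref")
        copies = [
            SeqRecord(f"copy{i}", anchor.residues, moltype="protein") for i in range(2)
        ]
        assigned = nj_clade_assign(copies, refs)
        assert {c.id for c in copies} <= assigned

    def test_distant_candidate_excluded(self, rng):
        anc = sf.random_protein(200, rng)
        refs = [SeqRecord("anc", anc, moltype="protein")] + sf.make_family(
            anc, 3, 0.85, seed=2, id_prefix="ref"
        )
        inliers = sf.make_family(anc, 2, 0.92, seed=3, id_prefix="in")
        outlier = SeqRecord("out", sf.random_protein(200, rng), moltype="protein")
        assigned = nj_clade_assign(inliers + [outlier], refs)
        assert "out" not in assigned
        assert {"in_0", "in_1"} <= assigned

    def test_negative_reference_bounds_the_clade(self, rng):
        anc = sf.random_protein(150, rng)
        other = sf.random_protein(150, rng)
        pos = [SeqRecord("p_anc", anc, moltype="protein")] + sf.make_family(
            anc, 2, 0.9, seed=4, id_prefix="pos"
        )
        neg = [SeqRecord("n_anc", other, moltype="protein")]
        near_pos = sf.make_family(anc, 2, 0.95, seed=5, id_prefix="cand")
        near_neg = sf.make_family(other, 1, 0.95, seed=6, id_prefix="decoy")
        assigned = nj_clade_assign(near_pos + near_neg, pos, neg)
        assert {"cand_0", "cand_1"} <= assigned
        assert "decoy_0" not in assigned

    def test_fewer_than_four_sequences_raises(self, rng):
        a = SeqRecord("a", sf.random_protein(50, rng), moltype="protein")
        b = SeqRecord("b", sf.random_protein(50, rng), moltype="protein")
        with pytest.raises(ValueError, match="4"):
            nj_clade_assign([a], [b])
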