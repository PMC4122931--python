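"""Signed orders, synteny clusters, breakpoint distances and flank tallies."""

from itertools import permutations, product

import numpy as np
import pytest

from endoerode.core_io import GeneFeature
from endoerode.rearrangement import (
    SignedGeneOrder,
    breakpoint_distance,
    cluster_spans,
    flanking_element_tally,
    greedy_reversal_count,
    pairwise_distance_matrix,
    shared_signed_orders,
    synteny_clusters,
)
from endoerode.synthetic import SimulationConfig, apply_inversions, generate_genome


def _feat(fid, start, strand="+", klass="CDS", group=None, scaffold="c1"):
    return GeneFeature(fid, scaffold, start, start + 50, strand, klass,
                       ortho_group=group or fid)


# ---------------------------------------------------------------- signed orders

def test_identical_genomes_give_identity():
    feats = [_feat(f"g{i}", i * 100) for i in range(5)]
    oa, ob, dup = shared_signed_orders(feats, feats)
    assert ob.order == [1, 2, 3, 4, 5] and dup == 0


def test_inverted_block_gives_hand_permutation():
    a = [_feat(f"g{i}", i * 100) for i in range(4)]
    # genome B: genes 2..3 (0-based 1..2) inverted in place and strand-flipped
    b = [
        _feat("g0", 0),
        _feat("g2", 100, strand="-"),
        _feat("g1", 200, strand="-"),
        _feat("g3", 300),
    ]
    _, ob, _ = shared_signed_orders(a, b)
    assert ob.order == [1, -3, -2, 4]


def test_private_and_duplicated_genes_excluded():
    a = [_feat("g0", 0), _feat("g1", 100), _feat("gA", 200), _feat("d", 300, group="dup")]
    b = [_feat("g0", 0), _feat("g1", 100), _feat("d1", 200, group="dup"),
         _feat("d2", 300, group="dup")]
    oa, ob, dup = shared_signed_orders(a, b)
    groups = set(oa.index_to_group.values())
    assert groups == {"g0", "g1"} and dup == 1


def test_mobile_features_excluded_before_indexing():
    a = [_feat("g0", 0), _feat("is1", 100, klass="IS"), _feat("g1", 200)]
    b = [_feat("g0", 0), _feat("g1", 100), _feat("is1", 200, klass="IS")]
    oa, _, _ = shared_signed_orders(a, b)
    assert set(oa.index_to_group.values()) == {"g0", "g1"}


# ---------------------------------------------------------------- clusters

def _order(entries, strain="B"):
    return SignedGeneOrder(strain, list(entries),
                           {i: str(i) for i in range(1, len(entries) + 1)})


def _brute_force_clusters(b):
    """Maximal colinear runs of identity-order A inside signed order b."""
    n = len(b)
    pos = {abs(x): i for i, x in enumerate(b)}

    def colinear(i, j):  # genes i..j (1-based, inclusive)
        genes = list(range(i, j + 1))
        ps = [pos[g] for g in genes]
        fwd = ps == list(range(ps[0], ps[0] + len(genes))) and all(
            b[pos[g]] == g for g in genes
        )
        rev = ps == list(range(ps[0], ps[0] - len(genes), -1)) and all(
            b[pos[g]] == -g for g in genes
        )
        return fwd or rev or len(genes) == 1

    runs = []
    i = 1
    while i <= n:
        j = i
        while j + 1 <= n and colinear(i, j + 1):
            j += 1
        runs.append(list(range(i, j + 1)))
        i = j + 1
    return runs


def test_cluster_identity_and_hand_examples():
    assert [c.indices for c in synteny_clusters(_order([1, 2, 3], "A"), _order([1, 2, 3]))] == [[1, 2, 3]]
    a5 = _order([1, 2, 3, 4, 5], "A")
    got = [c.indices for c in synteny_clusters(a5, _order([1, 2, 3, -5, -4]))]
    assert got == [[1, 2, 3], [4, 5]]
    cl = synteny_clusters(a5, _order([1, 2, 3, -5, -4]))
    assert cl[0].orientation == "same" and cl[1].orientation == "reversed"


def test_clusters_equal_bruteforce_for_all_signed_permutations_upto_n6():
    for n in range(1, 7):
        a = _order(list(range(1, n + 1)), "A")
        for perm in permutations(range(1, n + 1)):
            for signs in product((1, -1), repeat=n):
                b = [p * s for p, s in zip(perm, signs)]
                got = [c.indices for c in synteny_clusters(a, _order(b))]
                assert got == _brute_force_clusters(b), b


def test_clusters_partition_and_reconstitute_order(small_genome):
    genome, features = small_genome
    _, dfeats, truth = apply_inversions(genome, features, 6, seed=41)
    oa, ob, _ = shared_signed_orders(features, dfeats)
    clusters = synteny_clusters(oa, ob)
    concat = [i for c in clusters for i in c.indices]
    assert concat == [abs(x) for x in oa.order]


# ---------------------------------------------------------------- distances

@pytest.mark.parametrize(
    "perm,expected",
    [
        ([1, 2, 3, 4], 0),
        ([1, -3, -2, 4], 2),
        ([-4, -3, -2, -1], 2),  # whole-genome reversal: only frame edges break
        ([2, 1], 3),
    ],
)
def test_breakpoint_distance_hand_counts(perm, expected):
    assert breakpoint_distance(perm) == expected


def test_every_single_inversion_breaks_exactly_two_adjacencies():
    """Brute force over all single inversions of the identity, n <= 8.

    A signed inversion of genes i..j replaces the adjacencies at its two
    ends with (i-1, -j) and (-i, j+1), neither of which can satisfy
    b - a = 1 for positive i, j — so the framed breakpoint distance of a
    single inversion is always exactly 2, frame edges included.
    """
    for n in range(2, 9):
        for i in range(n):
            for j in range(i, n):
                perm = list(range(1, n + 1))
                perm[i : j + 1] = [-x for x in reversed(perm[i : j + 1])]
                assert breakpoint_distance(perm) == 2, (perm, i, j)


def test_whole_reversal_preserves_internal_adjacencies():
    """Negate-reversal maps adjacency (a, b) to (-b, -a), preserving
    conservation; only the two frame adjacencies of a linear framing can
    change, so the distances differ by at most 2 — and circular framing,
    which has no distinguished ends, is exactly invariant."""
    rng = np.random.default_rng(43)
    for _ in range(30):
        n = int(rng.integers(2, 12))
        perm = [int(s) * p for s, p in zip(rng.choice([-1, 1], n),
                                           rng.permutation(np.arange(1, n + 1)))]
        rev = [-x for x in reversed(perm)]
        assert abs(breakpoint_distance(perm) - breakpoint_distance(rev)) <= 2
        assert breakpoint_distance(perm, circular=True) == breakpoint_distance(
            rev, circular=True
        )


def test_circular_framing_ignores_rotation_and_reflection():
    assert breakpoint_distance([2, 3, 1], circular=True) == 0
    assert breakpoint_distance([-3, -2, -1], circular=True) == 0
    assert breakpoint_distance([1, 2, 3], circular=True) == 0
    assert breakpoint_distance([1, 3, 2], circular=True) == 3


def test_planted_inversion_lower_bound_and_monotonic_trend():
    """d/2 never exceeds the planted count; distance tracks inversion load."""
    from scipy.stats import spearmanr

    counts, dists = [], []
    cfg = SimulationConfig(seed=47, genome_length=120_000, n_genes=100)
    genome, features, _ = generate_genome(cfg)
    for rep in range(20):
        n_inv = rep % 10 + 1
        _, _, truth = apply_inversions(genome, features, n_inv, seed=100 + rep)
        d = breakpoint_distance(truth.signed_order)
        assert n_inv >= d / 2
        counts.append(n_inv)
        dists.append(d)
    rho = spearmanr(counts, dists).statistic
    assert rho > 0.9


def test_pairwise_matrix_symmetric_zero_diagonal(small_genome):
    genome, features = small_genome
    orders = {"A": list(range(1, len(features) + 1))}
    for name, seed in (("B", 51), ("C", 52)):
        _, _, truth = apply_inversions(genome, features, 4, seed=seed)
        orders[name] = truth.signed_order
    names, mat = pairwise_distance_matrix(orders)
    assert (mat == mat.T).all() and (np.diag(mat) == 0).all()
    assert mat[names.index("A")][names.index("B")] > 0


def test_greedy_reversal_count_is_upper_bound_reaching_identity():
    rng = np.random.default_rng(53)
    for _ in range(30):
        n = int(rng.integers(2, 10))
        perm = [int(s) * p for s, p in zip(rng.choice([-1, 1], n),
                                           rng.permutation(np.arange(1, n + 1)))]
        ub = greedy_reversal_count(perm)
        assert ub >= breakpoint_distance(perm) / 2


# ---------------------------------------------------------------- flanks

def test_flanking_tally_rules():
    feats = [
        _feat("g1", 1_000, group="og1"),
        _feat("g2", 2_000, group="og2"),
        _feat("is1", 3_550, klass="IS"),  # 1.5 kb past the right boundary
        _feat("far", 20_000, klass="phage"),
    ]
    cl = synteny_clusters(
        _order([1, 2], "A"), _order([1, 2])
    )
    cl[0].members = ["og1", "og2"]
    cluster = cluster_spans(cl, {"S": feats})[0]
    assert cluster.spans["S"] == ("c1", 1_000, 2_050)
    tally = flanking_element_tally([cluster], feats, "S", window=3_000)
    assert tally["IS"] == 1 and tally["phage"] == 0 and tally["none"] == 0
    # nothing within 3 kb -> none
    tally2 = flanking_element_tally([cluster], [feats[0], feats[1], feats[3]],
                                    "S", window=3_000)
    assert tally2["none"] == 1


def test_breakpoint_is_planting_flanks_internal_clusters(small_genome):
    genome, features = small_genome
    _, dfeats, truth = apply_inversions(genome, features, 5, seed=57, plant_is=True)
    oa, ob, _ = shared_signed_orders(features, dfeats)
    clusters = synteny_clusters(oa, ob)
    cluster_spans(clusters, {"B": dfeats})
    tally = flanking_element_tally(clusters, dfeats, "B", window=3_000)
    # every non-terminal cluster boundary is an inversion breakpoint with an IS
    assert tally["IS"] >= len(clusters) - 2
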