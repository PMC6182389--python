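"""Positional/depth filter semantics, checked against quadratic oracles."""
import random

import pytest

from wildvar.filtering import (
    FilterConfig,
    apply_all_filters,
    filter_depth,
    filter_indel_clusters,
    filter_snp_clusters,
    filter_snps_near_indels,
)
from wildvar.model import Variant, Zygosity, sort_variants

CFG = FilterConfig()


# ---------------------------------------------------------------------------
# independent quadratic oracles
# ---------------------------------------------------------------------------

def oracle_cluster(variants, window_bp):
    """All-pairs: remove both members of any pair fitting in a window_bp span."""
    bad = set()
    for i, a in enumerate(variants):
        for j, b in enumerate(variants):
            if i != j and a.chrom == b.chrom and abs(a.pos - b.pos) <= window_bp - 1:
                bad.add(i)
                bad.add(j)
    return ([v for i, v in enumerate(variants) if i not in bad],
            [v for i, v in enumerate(variants) if i in bad])


def oracle_near_indels(snps, indels, dist):
    kept, removed = [], []
    for s in snps:
        hit = False
        for ind in indels:
            lo, hi = ind.span
            if ind.chrom == s.chrom and max(lo - s.pos, s.pos - hi, 0) <= dist:
                hit = True
        (removed if hit else kept).append(s)
    return kept, removed


def rand_variants(rng, n, chroms=("Chr1", "Chr2"), span=100_000, kinds="snp"):
    out = []
    for _ in range(n):
        chrom = rng.choice(chroms)
        pos = rng.randint(1, span)
        kind = rng.choice(kinds.split(","))
        if kind == "snp":
            out.append(Variant(chrom, pos, "A", "G", Zygosity.HOM,
                               rng.randint(0, 150)))
        elif kind == "ins":
            out.append(Variant(chrom, pos, "A", "A" + "T" * rng.randint(1, 10),
                               Zygosity.HOM, rng.randint(0, 150)))
        else:
            out.append(Variant(chrom, pos, "A" + "T" * rng.randint(1, 10), "A",
                               Zygosity.HOM, rng.randint(0, 150)))
    return sort_variants(out)


# ---------------------------------------------------------------------------
# depth filter
# ---------------------------------------------------------------------------

class TestDepth:
    def test_inclusive_bounds(self, mk):
        vs = [mk.snp("Chr1", 10 * i, depth=d)
              for i, d in enumerate([5, 11, 50, 100, 101], start=1)]
        kept, removed = filter_depth(vs, CFG)
        assert [v.depth for v in kept] == [11, 50, 100]
        assert [v.depth for v in removed] == [5, 101]

    def test_all_zero_depth_removed(self, mk):
        vs = [mk.snp("Chr1", 10 * i, depth=0) for i in range(1, 6)]
        kept, removed = filter_depth(vs, CFG)
        assert kept == [] and len(removed) == 5

    def test_matches_brute_force(self):
        rng = random.Random(11)
        vs = rand_variants(rng, 1000)
        kept, removed = filter_depth(vs, CFG)
        assert kept == [v for v in vs if 11 <= v.depth <= 100]
        assert removed == [v for v in vs if not 11 <= v.depth <= 100]


# ---------------------------------------------------------------------------
# SNP cluster filter
# ---------------------------------------------------------------------------

class TestSnpClusters:
    def test_pair_within_window_both_removed(self, mk):
        vs = [mk.snp("Chr1", p) for p in (100, 103, 500)]
        kept, removed = filter_snp_clusters(vs, CFG)
        assert [v.pos for v in kept] == [500]
        assert [v.pos for v in removed] == [100, 103]

    def test_boundary_five_bp_span(self, mk):
        # positions 100 and 105 span 6 bases: they do NOT share a 5-bp window
        vs = [mk.snp("Chr1", 100), mk.snp("Chr1", 105)]
        kept, removed = filter_snp_clusters(vs, CFG)
        assert len(kept) == 2 and removed == []
        vs = [mk.snp("Chr1", 100), mk.snp("Chr1", 104)]
        kept, removed = filter_snp_clusters(vs, CFG)
        assert kept == [] and len(removed) == 2

    def test_chromosomes_independent(self, mk):
        vs = sort_variants([mk.snp("Chr1", 100), mk.snp("Chr2", 101)])
        kept, _ = filter_snp_clusters(vs, CFG)
        assert len(kept) == 2

    def test_rejects_indels(self, mk):
        with pytest.raises(ValueError, match="non-SNP"):
            filter_snp_clusters([mk.deletion("Chr1", 10)], CFG)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = random.Random(seed)
        vs = rand_variants(rng, 200, span=2_000)
        assert filter_snp_clusters(vs, CFG) == oracle_cluster(vs, 5)


# ---------------------------------------------------------------------------
# SNP-near-InDel filter
# ---------------------------------------------------------------------------

class TestSnpsNearIndels:
    def test_distance_to_affected_span(self, mk):
        # DEL at 104 with ref ATT affects 104..106; SNP at 100 is 4 bp away
        snp = mk.snp("Chr1", 100)
        dele = mk.deletion("Chr1", 104, n=2)
        kept, removed = filter_snps_near_indels([snp], [dele], CFG)
        assert kept == [] and removed == [snp]

    def test_insertion_anchor_boundary(self, mk):
        # INS anchored at 106 affects only base 106; distance 6 > 5 -> kept
        snp = mk.snp("Chr1", 100)
        ins = mk.insertion("Chr1", 106, n=3)
        kept, removed = filter_snps_near_indels([snp], [ins], CFG)
        assert kept == [snp] and removed == []

    def test_indels_never_removed(self, mk):
        snps = [mk.snp("Chr1", 100)]
        indels = [mk.insertion("Chr1", 101)]
        kept, removed = filter_snps_near_indels(snps, indels, CFG)
        assert kept == [] and removed == snps  # only SNPs partitioned

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, seed):
        rng = random.Random(100 + seed)
        snps = rand_variants(rng, 100, span=3_000)
        indels = rand_variants(rng, 20, span=3_000, kinds="ins,del")
        got = filter_snps_near_indels(snps, indels, CFG)
        assert got == oracle_near_indels(snps, indels, 5)


# ---------------------------------------------------------------------------
# InDel cluster filter
# ---------------------------------------------------------------------------

class TestIndelClusters:
    def test_pair_within_ten_bp(self, mk):
        vs = [mk.insertion("Chr1", 100), mk.deletion("Chr1", 108)]
        kept, removed = filter_indel_clusters(vs, CFG)
        assert kept == [] and len(removed) == 2

    def test_boundary_ten_bp_span(self, mk):
        vs = [mk.insertion("Chr1", 100), mk.deletion("Chr1", 110)]
        kept, removed = filter_indel_clusters(vs, CFG)
        assert len(kept) == 2 and removed == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = random.Random(200 + seed)
        vs = rand_variants(rng, 150, span=3_000, kinds="ins,del")
        assert filter_indel_clusters(vs, CFG) == oracle_cluster(vs, 10)


# ---------------------------------------------------------------------------
# combined pipeline & properties
# ---------------------------------------------------------------------------

class TestApplyAll:
    def test_empty_input(self):
        rep = apply_all_filters([], CFG)
        assert rep.kept == [] and all(n == 0 for n in rep.removed_by_stage.values())

    def test_hand_placed_fixture(self, mk):
        vs = sort_variants([
            mk.snp("Chr1", 100),              # clustered with 103 -> removed
            mk.snp("Chr1", 103),              # removed
            mk.snp("Chr1", 500),              # kept
            mk.snp("Chr1", 1000, depth=5),    # survives positional, fails depth
            mk.snp("Chr1", 2000),             # near indel at 2003 -> removed
            mk.deletion("Chr1", 2003),        # kept (no indel neighbour)
            mk.insertion("Chr1", 3000),       # clustered with 3008 -> removed
            mk.deletion("Chr1", 3008),        # removed
            mk.snp("Chr2", 100),              # kept
            mk.snp("Chr2", 104),              # clustered with 100 -> removed
            mk.snp("Chr2", 103),              # clustered -> removed
            mk.insertion("Chr2", 5000, depth=101),  # fails depth
        ])
        rep = apply_all_filters(vs, CFG)
        assert {(v.chrom, v.pos) for v in rep.kept} == {
            ("Chr1", 500), ("Chr1", 2003)}
        assert rep.removed_by_stage == {
            "snp_cluster": 5, "snp_near_indel": 1, "indel_cluster": 2,
            "depth": 2}
        assert rep.n_input == len(vs)

    def test_depth_failing_variant_still_disqualifies_neighbours(self, mk):
        # default order: the depth-5 SNP at 103 still kills the SNP at 100
        vs = [mk.snp("Chr1", 100), mk.snp("Chr1", 103, depth=5)]
        rep = apply_all_filters(vs, CFG)
        assert rep.kept == []
        rep2 = apply_all_filters(vs, CFG, depth_first=True)
        assert [v.pos for v in rep2.kept] == [100]

    def test_survivor_depths_in_bounds(self):
        rng = random.Random(3)
        vs = rand_variants(rng, 500, kinds="snp,ins,del")
        rep = apply_all_filters(vs, CFG)
        assert all(11 <= v.depth <= 100 for v in rep.kept)

    def test_partition_exact(self):
        rng = random.Random(4)
        vs = rand_variants(rng, 400, kinds="snp,ins,del")
        rep = apply_all_filters(vs, CFG)
        assert len(rep.kept) + sum(rep.removed_by_stage.values()) == len(vs)

    def test_idempotent(self):
        rng = random.Random(5)
        vs = rand_variants(rng, 400, kinds="snp,ins,del")
        once = apply_all_filters(vs, CFG).kept
        twice = apply_all_filters(once, CFG).kept
        assert once == twice

    def test_order_insensitive_after_sorting(self):
        rng = random.Random(6)
        vs = rand_variants(rng, 300, kinds="snp,ins,del")
        shuffled = vs[:]
        rng.shuffle(shuffled)
        assert apply_all_filters(sort_variants(shuffled), CFG).kept == \
            apply_all_filters(vs, CFG).kept
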