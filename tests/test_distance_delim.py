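"""Barcode-gap partitioning and single-linkage MOTU clustering."""

import itertools

import numpy as np
import pytest

from barcodescope.distance_delim import (
    ABGDConfig,
    GapError,
    Partition,
    abgd_grid,
    abgd_partition,
    abgd_theta_and_limit,
    bp_differences,
    detect_barcode_gap,
    motu_cluster,
    motu_sweep,
)
from barcodescope.distances import distance_matrix
from barcodescope.seqio import AlignedSeqSet
from barcodescope.synthetic_data import make_gap_dataset


class TestThetaAndLimit:
    def test_mean_below_prior(self):
        theta, limit = abgd_theta_and_limit([0.001, 0.002, 0.003, 0.2, 0.3], 0.01)
        assert theta == pytest.approx(0.002)
        assert limit == pytest.approx(0.005991, abs=1e-6)

    def test_all_above_prior_errors(self):
        with pytest.raises(GapError, match="theta"):
            abgd_theta_and_limit([0.02, 0.03], 0.01)

    def test_empty_errors(self):
        with pytest.raises(GapError):
            abgd_theta_and_limit([], 0.01)


class TestGapDetection:
    def test_planted_bimodal_gap_found(self):
        d = np.concatenate([np.linspace(0.0005, 0.005, 50), np.linspace(0.10, 0.13, 50)])
        theta, limit = abgd_theta_and_limit(d, 0.01)
        scan = detect_barcode_gap(d, theta, limit, 1.5)
        assert scan.gap_position is not None
        assert 0.005 < scan.gap_position < 0.10

    def test_uniform_distances_no_gap(self):
        d = np.linspace(0.0, 0.05, 100)
        theta, limit = abgd_theta_and_limit(d, 0.01)
        scan = detect_barcode_gap(d, theta, limit, 1.5)
        assert scan.gap_position is None

    def test_gap_below_limit_ignored(self):
        # jump from 0.001 to 0.004 sits entirely below L ~ 3 * theta
        d = np.concatenate([np.full(30, 0.001), np.full(30, 0.004), np.full(5, 0.0045)])
        theta, limit = abgd_theta_and_limit(d, 0.01)
        assert limit > 0.0045
        scan = detect_barcode_gap(d, theta, limit, 1.5)
        assert scan.gap_position is None


class TestABGDPartition:
    def test_planted_three_species(self):
        aln, truth = make_gap_dataset(
            n_species=3, intra_max=0.005, inter_min=0.10, n_per=5, seed=2
        )
        dm = distance_matrix(aln, model="jc69")
        initial, recursive = abgd_partition(dm, ABGDConfig(prior=0.01))
        assert len(initial) == 3
        assert initial.same_blocks(recursive)
        truth_blocks = {frozenset(m) for m in truth.partition.values()}
        assert set(initial.blocks()) == truth_blocks

    def test_degenerate_prior_single_group(self):
        aln, _ = make_gap_dataset(n_species=2, n_per=4, seed=1)
        dm = distance_matrix(aln, model="jc69")
        initial, recursive = abgd_partition(dm, ABGDConfig(prior=0.9))
        assert len(initial) == 1

    def test_recursive_at_least_initial(self, rng):
        for seed in range(5):
            aln, _ = make_gap_dataset(
                n_species=3, intra_max=0.008, inter_min=0.08, n_per=4, seed=seed
            )
            dm = distance_matrix(aln, model="jc69")
            initial, recursive = abgd_partition(
                dm, ABGDConfig(prior=float(rng.uniform(0.005, 0.05)))
            )
            assert len(recursive) >= len(initial)
            assert recursive.refines(initial)

    def test_grid_shape_and_counts(self):
        aln, _ = make_gap_dataset(n_species=3, n_per=4, seed=3)
        grid = abgd_grid(
            aln, priors=[0.005, 0.01], gap_widths=[1.0, 1.5],
            models=[("jc69", None), ("k80", 2.0)],
        )
        assert len(grid) == 2 * 2 * 2
        ok = grid.dropna()
        assert (ok["recursive"] >= ok["initial"]).all()


class TestMOTU:
    def test_identical_sequences_one_motu(self):
        aln = AlignedSeqSet(ids=("a", "b", "c"), seqs=("ACGT" * 200,) * 3)
        assert len(motu_cluster(aln, cutoff_bp=4)) == 1

    def test_chain_linkage(self):
        # diffs a-b = 3, b-c = 3, a-c = 6; cutoff 4 links all through b
        base = list("A" * 600)
        sa = base.copy()
        sb = base.copy()
        sc = base.copy()
        for i in range(3):
            sb[i] = "C"
        for i in range(6):
            sc[i] = "C"
        aln = AlignedSeqSet(ids=("a", "b", "c"), seqs=("".join(sa), "".join(sb), "".join(sc)))
        assert len(motu_cluster(aln, cutoff_bp=4)) == 1
        assert len(motu_cluster(aln, cutoff_bp=2)) == 3

    def test_all_pairs_distant_all_singletons(self, rng):
        seqs = []
        base = rng.choice(list("ACGT"), size=600)
        for k in range(4):
            s = base.copy()
            s[k * 10 : k * 10 + 8] = [{"A": "C", "C": "G", "G": "T", "T": "A"}[c]
                                      for c in s[k * 10 : k * 10 + 8]]
            seqs.append("".join(s))
        aln = AlignedSeqSet(ids=tuple("abcd"), seqs=tuple(seqs))
        assert len(motu_cluster(aln, cutoff_bp=4)) == 4

    def test_short_sequences_excluded(self):
        aln = AlignedSeqSet(
            ids=("long", "short"),
            seqs=("ACGT" * 200, "ACGT" * 50 + "-" * 600),
        )
        part = motu_cluster(aln, cutoff_bp=4, min_len=500)
        assert part.n_members == 1

    def test_matches_bruteforce_connected_components(self, rng):
        """Single-linkage clusters equal connected components computed by an
        exhaustive reachability oracle on random instances with n <= 12."""
        for trial in range(20):
            local = np.random.default_rng(trial)
            n = int(local.integers(4, 13))
            length = 550
            base = local.choice(list("ACGT"), size=length)
            seqs = []
            for _ in range(n):
                s = base.copy()
                k = int(local.integers(0, 15))
                pos = local.choice(length, size=k, replace=False)
                for p in pos:
                    s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
                seqs.append("".join(s))
            ids = tuple(f"t{i}" for i in range(n))
            aln = AlignedSeqSet(ids=ids, seqs=tuple(seqs))
            cutoff = int(local.integers(1, 12))
            part = motu_cluster(aln, cutoff_bp=cutoff)

            # oracle: boolean adjacency + transitive closure by powers
            adj = np.eye(n, dtype=bool)
            for i, j in itertools.combinations(range(n), 2):
                diff, _ = bp_differences(seqs[i], seqs[j])
                if diff <= cutoff:
                    adj[i, j] = adj[j, i] = True
            reach = adj.copy()
            for _ in range(n):
                reach = reach | (reach @ adj)
            oracle_blocks = {
                frozenset(ids[j] for j in np.flatnonzero(reach[i])) for i in range(n)
            }
            assert set(part.blocks()) == oracle_blocks

    def test_sweep_monotone_and_nested(self):
        aln, _ = make_gap_dataset(n_species=3, intra_max=0.01, inter_min=0.08,
                                  n_per=4, seed=4)
        sweep = motu_sweep(aln, cutoffs=range(3, 24))
        assert (np.diff(sweep["motus"]) <= 0).all()
        p_small = motu_cluster(aln, cutoff_bp=5)
        p_large = motu_cluster(aln, cutoff_bp=15)
        assert p_small.refines(p_large)

    def test_gap_cutoff_recovers_planted_species(self):
        aln, truth = make_gap_dataset(
            n_species=4, intra_max=0.005, inter_min=0.10, n_per=4,
            length_bp=658, seed=6,
        )
        # cutoff between the bp-equivalents of intra_max and inter_min
        part = motu_cluster(aln, cutoff_bp=20)
        assert set(part.blocks()) == {frozenset(m) for m in truth.partition.values()}


class TestPartition:
    def test_blocks_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            Partition(units={"u1": ("a", "b"), "u2": ("b",)})

    def test_refinement(self):
        fine = Partition(units={"u1": ("a",), "u2": ("b",), "u3": ("c", "d")})
        coarse = Partition(units={"v1": ("a", "b"), "v2": ("c", "d")})
        assert fine.refines(coarse)
        assert not coarse.refines(fine)
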