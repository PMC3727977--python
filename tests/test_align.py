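"""Dynamic-programming Rmap alignment against an exhaustive oracle,
plus recall/specificity behavior on simulated molecules."""

import itertools

import numpy as np
import pytest

from rmapforge.align import (
    AlignmentParams,
    align_batch,
    align_rmap,
    block_cost,
)
from rmapforge.core_maps import FragmentMap, Rmap


def brute_force_best(qfrags, rfrags, params):
    """Enumerate every monotone block matching; return the minimal total
    cost.  Terminal query fragments are unscored, mirroring the DP."""
    Q, R = len(qfrags), len(rfrags)
    qcum = np.concatenate([[0.0], np.cumsum(qfrags)])
    rcum = np.concatenate([[0.0], np.cumsum(rfrags)])
    best = np.inf
    n_interior = Q - 1  # query boundaries 1..Q-1 to place

    def cost(i0, i1, j0, j1):
        q = qcum[j1] - qcum[j0]
        r = rcum[i1] - rcum[i0]
        return block_cost(q, r, params, q_frags=j1 - j0, r_frags=i1 - i0)

    def rec(i, j, acc):
        nonlocal best
        if acc >= best:
            return
        if j == Q - 1:
            best = min(best, acc)
            return
        for b in range(1, min(params.max_block, Q - 1 - j) + 1):
            for a in range(1, params.max_block + 1):
                if i + a > R:
                    break
                rec(i + a, j + b, acc + cost(i, i + a, j, j + b))

    if Q < 3:
        return 0.0
    for start in range(0, R + 1):
        rec(start, 1, 0.0)
    return best


class TestBlockCost:
    def test_equal_masses_cost_zero(self):
        assert block_cost(10.0, 10.0, AlignmentParams()) == 0.0

    def test_worked_example(self):
        p = AlignmentParams(sizing_cv=0.05)
        assert block_cost(45.0, 50.0, p) == pytest.approx(4.0)

    def test_monotone_in_deviation(self):
        p = AlignmentParams()
        costs = [block_cost(50.0 + d, 50.0, p) for d in (0, 1, 2, 5, 10)]
        assert all(b > a for a, b in zip(costs, costs[1:]))

    def test_cut_penalties_added(self):
        p = AlignmentParams()
        base = block_cost(30.0, 30.0, p)
        assert block_cost(30.0, 30.0, p, q_frags=2) == base + p.extra_penalty
        assert block_cost(30.0, 30.0, p, r_frags=3) == base + 2 * p.miss_penalty

    def test_nonpositive_mass_errors(self):
        with pytest.raises(ValueError):
            block_cost(0.0, 10.0, AlignmentParams())


class TestOracleEquivalence:
    def test_dp_matches_exhaustive_enumeration(self):
        """DP optimum equals brute force on 200 seeded small instances."""
        rng = np.random.default_rng(2024)
        params = AlignmentParams(
            max_block=2, accept_threshold=np.inf, min_second_gap=0.0,
            min_aligned_frags=3,
        )
        from rmapforge.align import _align_oriented

        for case in range(200):
            Q = int(rng.integers(3, 9))
            R = int(rng.integers(3, 9))
            qfrags = rng.uniform(2.0, 40.0, Q)
            rfrags = rng.uniform(2.0, 40.0, R)
            ref = FragmentMap(f"r{case}", rfrags, chrom="c")
            res = _align_oriented(qfrags, ref, params)
            mean_costs, _, _ = res
            dp_total = float(np.min(mean_costs)) * Q
            brute = brute_force_best(qfrags, rfrags, params)
            assert dp_total == pytest.approx(brute, abs=1e-9), case


class TestAlignRmap:
    def test_exact_slice_aligns_at_zero_cost(self, two_chrom_genome):
        _, genome = two_chrom_genome
        ref = genome.maps["chr1"]
        q = ref.fragments[20:32].copy()
        aln = align_rmap(Rmap("m", q), genome)
        assert aln.orientation == "+"
        assert aln.total_cost == pytest.approx(0.0, abs=1e-9)
        assert aln.blocks[0][0] == 21

    def test_reversed_slice_aligns_reverse_at_same_place(self, two_chrom_genome):
        _, genome = two_chrom_genome
        ref = genome.maps["chr1"]
        q = ref.fragments[20:32][::-1].copy()
        aln = align_rmap(Rmap("m", q), genome)
        assert aln.orientation == "-"
        assert aln.blocks[0][0] == 21

    def test_self_alignment_of_reference_window_recovers_identity(
        self, two_chrom_genome
    ):
        _, genome = two_chrom_genome
        ref = genome.maps["chr2"]
        q = ref.fragments[40:55].copy()
        aln = align_rmap(Rmap("m", q), genome)
        assert aln.chrom == "chr2"
        assert all(ri1 - ri0 == 1 and qi1 - qi0 == 1
                   for ri0, ri1, qi0, qi1 in aln.blocks)

    def test_short_molecule_rejected_with_reason(self, two_chrom_genome):
        _, genome = two_chrom_genome
        assert align_rmap(Rmap("m", np.array([5.0, 6.0])), genome) == "rejected_short"


class TestAlignBatch:
    def test_noise_free_molecules_align_to_true_origin(self, small_genome):
        from rmapforge.simulate import Desorption, SimulationConfig, simulate_rmaps

        _, genome = small_genome
        cfg = SimulationConfig(
            seed=21, coverage=10, digest_efficiency=1.0, false_cut_rate_per_mb=0.0,
            sizing_cv=0.0, desorption=Desorption(drop_prob=0.0),
        )
        rmaps = [r for r in simulate_rmaps({"s1": genome}, cfg) if r.n_fragments >= 8]
        table, alignments = align_batch(rmaps, genome)
        assert len(alignments) / len(rmaps) >= 0.99
        ok = 0
        for r in rmaps:
            if r.molecule_id not in alignments:
                continue
            a = alignments[r.molecule_id]
            ok += abs(a.ref_start_bp - r.truth["true_start_bp"]) < 70_000
        assert ok / len(alignments) >= 0.99

    def test_recall_and_orientation_on_default_noise(self, noisy_rmaps,
                                                     two_chrom_genome):
        _, genome = two_chrom_genome
        eligible = [r for r in noisy_rmaps if r.n_fragments >= 8]
        table, alignments = align_batch(eligible, genome)
        correct = oriented = 0
        for r in eligible:
            a = alignments.get(r.molecule_id)
            if a is None:
                continue
            t = r.truth
            overlap = min(a.ref_end_bp, t["true_end_bp"]) - max(
                a.ref_start_bp, t["true_start_bp"]
            )
            correct += overlap > 0.5 * (t["true_end_bp"] - t["true_start_bp"])
            oriented += a.orientation == t["true_orientation"]
        recall = len(alignments) / len(eligible)
        assert recall >= 0.90
        assert oriented / len(alignments) >= 0.99
        assert correct / len(alignments) >= 0.99

    def test_random_rmaps_are_rejected(self, two_chrom_genome):
        _, genome = two_chrom_genome
        rng = np.random.default_rng(77)
        mean = float(np.mean(np.concatenate(
            [m.fragments for m in genome.maps.values()]
        )))
        rand = [
            Rmap(f"r{i}", rng.exponential(mean, int(rng.integers(12, 35))).clip(0.5))
            for i in range(150)
        ]
        table, _ = align_batch(rand, genome)
        assert (table["status"] != "aligned").mean() >= 0.95

    def test_order_independence(self, noisy_rmaps, two_chrom_genome):
        _, genome = two_chrom_genome
        subset = noisy_rmaps[:40]
        t1, _ = align_batch(subset, genome)
        rng = np.random.default_rng(1)
        shuffled = list(subset)
        rng.shuffle(shuffled)
        t2, _ = align_batch(shuffled, genome)
        key = ["molecule_id"]
        a = t1.sort_values(key).reset_index(drop=True)
        b = t2.sort_values(key).reset_index(drop=True)
        assert a.equals(b)

    def test_empty_input_gives_empty_table(self, two_chrom_genome):
        _, genome = two_chrom_genome
        table, alignments = align_batch([], genome)
        assert len(table) == 0 and alignments == {}
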