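"""Coverage intervals, negative-binomial HMM fitting and decoding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rmapforge.cnv import (
    CnvModel,
    build_intervals,
    count_in_intervals,
    fit_model,
    midpoints,
    per_slice_cnv,
    viterbi_decode,
)


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=["molecule_id", "chrom", "start", "end", "orientation",
                 "n_blocks", "cost", "midpoint", "status", "source_label"],
    )


class TestMidpoints:
    def test_midpoint_is_span_center(self):
        t = make_table([("m1", "c", 100000, 300000, "+", 5, 1.0, 200000, "aligned", "s")])
        assert list(midpoints(t)["c"]) == [200000]

    def test_rejected_molecules_excluded_and_sorted(self):
        t = make_table([
            ("m1", "c", 0, 10, "+", 5, 1.0, 500, "aligned", "s"),
            ("m2", ".", -1, -1, ".", 0, np.nan, -1, "rejected_short", "s"),
            ("m3", "c", 0, 10, "+", 5, 1.0, 100, "aligned", "s"),
        ])
        assert list(midpoints(t)["c"]) == [100, 500]

    def test_empty_table(self):
        assert midpoints(make_table([])) == {}


class TestBuildIntervals:
    def test_uniform_midpoints_give_equal_counts(self):
        mids = {"c": np.arange(50, 100_000, 1000)}  # 100 midpoints
        ivs = build_intervals(mids, {"c": 100_000}, m=10)
        assert len(ivs) == 10
        assert all(iv.normal_count == 10 for iv in ivs)
        assert ivs[0].start_bp == 0 and ivs[-1].end_bp == 100_000

    def test_dense_regions_get_narrower_intervals(self):
        rng = np.random.default_rng(3)
        left = rng.uniform(0, 30_000, 300)  # 10x denser on the left
        right = rng.uniform(30_000, 100_000, 100)
        mids = {"c": np.sort(np.concatenate([left, right]))}
        ivs = build_intervals(mids, {"c": 100_000}, m=10)
        widths_left = [iv.end_bp - iv.start_bp for iv in ivs if iv.end_bp <= 30_000]
        widths_right = [iv.end_bp - iv.start_bp for iv in ivs if iv.start_bp >= 30_000]
        assert np.mean(widths_left) < np.mean(widths_right)

    def test_too_few_midpoints_gives_whole_chromosome(self):
        with pytest.warns(UserWarning):
            ivs = build_intervals({"c": np.array([5.0])}, {"c": 1000}, m=10)
        assert len(ivs) == 1 and (ivs[0].start_bp, ivs[0].end_bp) == (0, 1000)

    def test_m_below_two_errors(self):
        with pytest.raises(ValueError):
            build_intervals({"c": np.arange(100)}, {"c": 1000}, m=1)


class TestFitModel:
    def test_constant_counts_fit_their_value(self):
        model = fit_model(np.full(50, 17.0))
        assert model.baseline_rate == 17.0

    def test_poisson_counts_fit_near_zero_dispersion(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(25, size=500)
        model = fit_model(counts)
        assert model.dispersion < 0.01

    def test_overdispersed_counts_are_detected(self):
        rng = np.random.default_rng(5)
        lam = rng.gamma(10, 2.5, size=800)  # NB with phi = 0.1
        counts = rng.poisson(lam)
        model = fit_model(counts)
        assert 0.02 < model.dispersion < 0.3  # truncated MoM understates phi, but clearly non-Poisson

    def test_majority_aberrant_genome_triggers_bimodality_warning(self):
        rng = np.random.default_rng(6)
        counts = np.concatenate([rng.poisson(12, 250), rng.poisson(24, 250)])
        with pytest.warns(UserWarning, match="bimodal"):
            fit_model(counts)

    def test_too_few_intervals_error(self):
        with pytest.raises(ValueError):
            fit_model(np.arange(10))


class TestViterbi:
    def _intervals(self, n, L=10_000_000):
        mids = {"c": np.linspace(0, L, n * 10, endpoint=False) + 17}
        return build_intervals(mids, {"c": L}, m=10)

    def test_emission_matches_scipy_nbinom(self):
        model = CnvModel(baseline_rate=20.0, dispersion=0.05)
        counts = np.arange(0, 60)
        E = model.emission_logpmf(counts)
        r = 1 / 0.05
        for j, k in enumerate(model.states):
            m = model.state_mean(k)
            assert np.allclose(E[:, j], stats.nbinom.logpmf(counts, r, r / (r + m)))

    def test_flat_counts_decode_as_single_diploid_segment(self):
        ivs = self._intervals(40)
        model = CnvModel(baseline_rate=20.0, dispersion=0.01)
        path, segs = viterbi_decode(ivs, np.full(len(ivs), 20), model)
        assert len(segs) == 1
        assert segs[0].state == 2

    def test_half_rate_region_decodes_as_copy_one(self):
        rng = np.random.default_rng(7)
        ivs = self._intervals(40)
        mu = 24
        counts = np.array([
            rng.poisson(mu // 2 if (iv.start_bp + iv.end_bp) / 2 < 5_000_000 else mu)
            for iv in ivs
        ])
        model = CnvModel(baseline_rate=mu, dispersion=1e-6)
        path, segs = viterbi_decode(ivs, counts, model)
        states = np.array([model.states[p] for p in path])
        truth = np.array([
            1 if (iv.start_bp + iv.end_bp) / 2 < 5_000_000 else 2 for iv in ivs
        ])
        assert (states == truth).mean() > 0.95

    def test_segments_tile_decoded_intervals(self):
        rng = np.random.default_rng(8)
        ivs = self._intervals(30)
        counts = rng.poisson(20, len(ivs))
        model = CnvModel(baseline_rate=20.0, dispersion=0.01)
        _, segs = viterbi_decode(ivs, counts, model)
        assert segs[0].start_bp == ivs[0].start_bp
        assert segs[-1].end_bp == ivs[-1].end_bp
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom:
                assert a.end_bp == b.start_bp

    def test_rescaling_counts_and_baseline_together_is_invariant(self):
        rng = np.random.default_rng(9)
        ivs = self._intervals(30)
        counts = rng.poisson([12] * 15 + [24] * (len(ivs) - 15))
        m1 = CnvModel(baseline_rate=24.0, dispersion=1e-6)
        m2 = CnvModel(baseline_rate=72.0, dispersion=1e-6)
        p1, _ = viterbi_decode(ivs, counts, m1)
        p2, _ = viterbi_decode(ivs, counts * 3, m2)
        assert np.array_equal(p1, p2)

    def test_negative_counts_error(self):
        ivs = self._intervals(30)
        model = CnvModel()
        with pytest.raises(ValueError):
            viterbi_decode(ivs, np.full(len(ivs), -1), model)


class TestPerSlice:
    def _table(self, rng, label, chrom_rates, n=3000):
        rows = []
        for chrom, (L, rate) in chrom_rates.items():
            k = rng.poisson(int(n * rate))
            for i in range(k):
                mid = int(rng.uniform(0, L))
                rows.append((f"{label}{chrom}{i}", chrom, mid - 1000, mid + 1000,
                             "+", 5, 1.0, mid, "aligned", label))
        return make_table(rows)

    def test_identical_slices_have_no_discordance(self):
        rng = np.random.default_rng(10)
        lens = {"c1": 5_000_000, "c2": 5_000_000}
        rates = {"c1": (5_000_000, 1.0), "c2": (5_000_000, 1.0)}
        t = pd.concat([
            self._table(rng, "a", rates), self._table(rng, "b", rates)
        ])
        normal = {c: np.sort(rng.uniform(0, L, 2000)).astype(int)
                  for c, L in lens.items()}
        res = per_slice_cnv(t, normal, lens, m=25)
        assert len(res.discordant) == 0

    def test_slice_specific_chromosome_loss_is_localized(self):
        # c1 is ~17% of the genome, the regime where the median-as-diploid
        # anchor is safe (arm-scale losses in a mostly diploid genome)
        rng = np.random.default_rng(11)
        lens = {"c1": 2_000_000, "c2": 10_000_000}
        t = pd.concat([
            self._table(rng, "a", {"c1": (2_000_000, 0.2), "c2": (10_000_000, 1.0)}),
            self._table(rng, "b", {"c1": (2_000_000, 0.1), "c2": (10_000_000, 1.0)}),
        ])
        normal = {c: np.sort(rng.uniform(0, L, int(L / 2500))).astype(int)
                  for c, L in lens.items()}
        res = per_slice_cnv(t, normal, lens, m=25)
        assert len(res.discordant) > 0
        assert set(res.discordant["chrom"]) == {"c1"}
        assert (res.discordant["state_a"] == 2).all()
        assert (res.discordant["state_b"] == 1).all()

    def test_label_missing_data_is_skipped_with_warning(self):
        rng = np.random.default_rng(12)
        lens = {"c1": 5_000_000}
        t = self._table(rng, "a", {"c1": (5_000_000, 1.0)}, n=5)
        normal = {"c1": np.sort(rng.uniform(0, 5_000_000, 100)).astype(int)}
        with pytest.warns(UserWarning):
            res = per_slice_cnv(t, normal, lens, m=60)
        assert res.per_label == {}
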