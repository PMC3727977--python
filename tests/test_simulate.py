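"""Synthetic genome, variant implantation, and the Rmap error model."""

import numpy as np
import pytest

from rmapforge.core_maps import SWAI_SITE, GenomeMaps, in_silico_digest
from rmapforge.simulate import (
    Desorption,
    SimulationConfig,
    Subclone,
    VariantSpec,
    implant_variants,
    simulate_reference,
    simulate_rmaps,
)


class TestSimulateReference:
    def test_deterministic_under_seed(self):
        s1, _ = simulate_reference({"chr1": 50_000}, seed=9)
        s2, _ = simulate_reference({"chr1": 50_000}, seed=9)
        assert s1 == s2

    def test_mean_fragment_size_matches_site_probability(self):
        # at GC 0.5 every base is uniform, so the mean inter-site distance
        # is 4^8 bp = 65.5 kb
        _, genome = simulate_reference({"chr1": 10_000_000}, gc_fraction=0.5, seed=2)
        fm = genome.maps["chr1"]
        mean_kb = fm.total_mass_kb / fm.n_fragments
        assert mean_kb == pytest.approx(65.5, rel=0.15)

    def test_at_rich_genome_is_cut_denser(self):
        _, g40 = simulate_reference({"chr1": 5_000_000}, gc_fraction=0.4, seed=3)
        _, g50 = simulate_reference({"chr1": 5_000_000}, gc_fraction=0.5, seed=3)
        assert g40.maps["chr1"].n_fragments > g50.maps["chr1"].n_fragments

    def test_zero_length_chromosome_errors(self):
        with pytest.raises(ValueError):
            simulate_reference({"chr1": 0}, seed=1)


class TestImplantVariants:
    def test_deletion_conserves_length(self, small_genome):
        sequences, _ = small_genome
        out, truth = implant_variants(
            sequences, [VariantSpec("DEL", "chr1", 1_000_000, 10_000)]
        )
        assert len(out["chr1"]) == len(sequences["chr1"]) - 10_000
        assert truth.iloc[0]["size_bp"] == -10_000

    def test_insertion_adds_site_free_sequence(self, small_genome):
        sequences, genome = small_genome
        out, _ = implant_variants(
            sequences, [VariantSpec("INS", "chr1", 1_000_000, 20_000)]
        )
        assert len(out["chr1"]) == len(sequences["chr1"]) + 20_000
        # insertion is site-free: cut count unchanged
        assert (
            in_silico_digest(out["chr1"]).cut_coords.size
            == genome.maps["chr1"].cut_coords.size
        )

    def test_inversion_reverses_interior_spacings(self, small_genome):
        sequences, genome = small_genome
        cuts = genome.maps["chr1"].cut_coords
        a, b = int(cuts[10]) - 1234, int(cuts[20]) + 2345
        out, _ = implant_variants(
            sequences, [VariantSpec("INV", "chr1", a, b - a)]
        )
        new = in_silico_digest(out["chr1"])
        assert new.total_mass_kb == pytest.approx(
            genome.maps["chr1"].total_mass_kb
        )
        inner_old = cuts[(cuts > a) & (cuts < b)]
        inner_new = new.cut_coords[(new.cut_coords > a) & (new.cut_coords < b)]
        # interior inter-cut spacings appear in reversed order
        assert np.allclose(np.diff(inner_new), np.diff(inner_old)[::-1])

    def test_site_gain_adds_exactly_one_cut(self, small_genome):
        sequences, genome = small_genome
        from rmapforge.simulate import find_site_gain_positions

        w, _, _ = find_site_gain_positions(sequences["chr1"][100_000:200_000], 1)[0]
        out, _ = implant_variants(
            sequences, [VariantSpec("SITE_GAIN", "chr1", 100_000 + w, 0)]
        )
        assert (
            in_silico_digest(out["chr1"]).cut_coords.size
            == genome.maps["chr1"].cut_coords.size + 1
        )

    def test_site_loss_requires_a_site(self, small_genome):
        sequences, genome = small_genome
        cut = int(genome.maps["chr1"].cut_coords[5])
        out, _ = implant_variants(
            sequences, [VariantSpec("SITE_LOSS", "chr1", cut - 4, 0)]
        )
        assert (
            in_silico_digest(out["chr1"]).cut_coords.size
            == genome.maps["chr1"].cut_coords.size - 1
        )
        with pytest.raises(ValueError, match="no site"):
            implant_variants(sequences, [VariantSpec("SITE_LOSS", "chr1", 1234, 0)])

    def test_overlapping_specs_error(self, small_genome):
        sequences, _ = small_genome
        with pytest.raises(ValueError, match="overlap"):
            implant_variants(
                sequences,
                [
                    VariantSpec("DEL", "chr1", 1_000_000, 10_000),
                    VariantSpec("DEL", "chr1", 1_005_000, 10_000),
                ],
            )

    def test_truth_coordinates_round_trip(self, tumor_scenario):
        # digesting the altered sequence reproduces the altered maps exactly
        redigested = GenomeMaps.from_sequences(tumor_scenario["tumor_sequences"])
        for chrom, fm in tumor_scenario["tumor_genome"].maps.items():
            assert np.array_equal(redigested.maps[chrom].cut_coords, fm.cut_coords)


class TestSimulateRmaps:
    def test_noise_free_molecules_are_exact_digest_slices(self, small_genome):
        _, genome = small_genome
        cfg = SimulationConfig(
            seed=4, coverage=3, digest_efficiency=1.0, false_cut_rate_per_mb=0.0,
            sizing_cv=0.0, desorption=Desorption(drop_prob=0.0),
        )
        rmaps = simulate_rmaps({"s1": genome}, cfg)
        fm = genome.maps["chr1"]
        boundaries = np.concatenate([[0], fm.cut_coords, [fm.span_bp]])
        for r in rmaps[:40]:
            t = r.truth
            frags = r.fragments if t["true_orientation"] == "+" else r.fragments[::-1]
            lo = np.searchsorted(boundaries, t["true_start_bp"], side="right")
            hi = np.searchsorted(boundaries, t["true_end_bp"], side="left")
            inner = np.diff(boundaries[lo - 1 : hi + 1]) / 1000.0
            inner[0] = (boundaries[lo] - t["true_start_bp"]) / 1000.0
            inner[-1] = (t["true_end_bp"] - boundaries[hi - 1]) / 1000.0
            inner = inner[inner > 1e-9]
            assert np.allclose(frags, inner, atol=0.001), r.molecule_id

    def test_total_mass_matches_configured_coverage(self, small_genome):
        _, genome = small_genome
        cfg = SimulationConfig(seed=5, coverage=30)
        rmaps = simulate_rmaps({"s1": genome}, cfg)
        total = sum(r.total_mass_kb for r in rmaps) * 1000
        assert total / genome.total_length_bp == pytest.approx(30, rel=0.05)

    def test_interior_site_observation_rate_matches_digest_efficiency(
        self, small_genome
    ):
        _, genome = small_genome
        cfg = SimulationConfig(
            seed=6, coverage=30, false_cut_rate_per_mb=0.0, sizing_cv=0.0,
            desorption=Desorption(drop_prob=0.0),
        )
        rmaps = simulate_rmaps({"s1": genome}, cfg)
        cuts = genome.maps["chr1"].cut_coords
        shown = total = 0
        for r in rmaps:
            t = r.truth
            inside = cuts[(cuts > t["true_start_bp"]) & (cuts < t["true_end_bp"])]
            total += inside.size
            shown += r.n_fragments - 1
        assert shown / total == pytest.approx(0.80, abs=0.02)

    def test_determinism_under_config(self, small_genome):
        _, genome = small_genome
        cfg = SimulationConfig(seed=8, coverage=2)
        a = simulate_rmaps({"s1": genome}, cfg)
        b = simulate_rmaps({"s1": genome}, cfg)
        assert len(a) == len(b)
        assert all(np.array_equal(x.fragments, y.fragments) for x, y in zip(a, b))

    def test_subclone_copy_profile_shapes_coverage(self, small_genome):
        # a slice-specific loss halves that slice's coverage of the region
        _, genome = small_genome
        cfg = SimulationConfig(
            seed=9, coverage=40,
            subclones=[
                Subclone("a", 0.5),
                Subclone("b", 0.5, copy_profile=[("chr1", 0, 1_500_000, 1)]),
            ],
        )
        rmaps = simulate_rmaps({"a": genome, "b": genome}, cfg)
        mass = {"a": [0.0, 0.0], "b": [0.0, 0.0]}
        for r in rmaps:
            region = 0 if r.truth["true_start_bp"] < 1_500_000 else 1
            mass[r.source_label][region] += r.total_mass_kb
        ratio_b = mass["b"][0] / mass["b"][1]
        ratio_a = mass["a"][0] / mass["a"][1]
        assert ratio_b / ratio_a == pytest.approx(0.5, rel=0.25)

    def test_invalid_configs_error(self):
        with pytest.raises(ValueError):
            SimulationConfig(coverage=0)
        with pytest.raises(ValueError):
            SimulationConfig(subclones=[])
        with pytest.raises(ValueError):
            SimulationConfig(subclones=[Subclone("a", 0.5)])
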