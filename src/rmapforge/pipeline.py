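"""End-to-end orchestration: simulate (optionally), align, assemble,
call structural alterations and copy number, and filter candidates.

All stage parameters live in :class:`PipelineConfig`; every source of
randomness derives from the single configured seed, so a run is fully
reproducible from its configuration file.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod
from .align import AlignmentParams, align_batch
from .assemble import AssemblyParams, iterate_assembly
from .compare import IntersectionRules, annotate_genes, filter_somatic
from .core_maps import (
    GenomeMaps,
    read_bed,
    read_fasta,
    read_maps,
    write_bed,
    write_fasta,
    write_maps,
)
from .simulate import (
    SimulationConfig,
    Subclone,
    implant_variants,
    place_default_truth_set,
    simulate_reference,
    simulate_rmaps,
)
from .svcall import CallThresholds, ErrorModelParams, call_genome

log = logging.getLogger("rmapforge")


@dataclass
class PipelineConfig:
    out_dir: str = "rmapforge_out"
    seed: int = 0
    reference_fasta: str | None = None  # simulate when absent
    rmaps_path: str | None = None
    # simulation scenario (used when no rmaps are supplied)
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    gc_fraction: float = 0.41
    coverage: float = 30.0
    implant_variants: bool = True
    subclone_fractions: dict[str, float] = field(
        default_factory=lambda: {"slice1": 0.55, "slice2": 0.45}
    )
    arm_loss: tuple[str, int, int] | None = None  # slice2-only loss region
    # stage parameters (defaults carry the published values where they exist)
    align: AlignmentParams = field(default_factory=AlignmentParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    error_model: ErrorModelParams = field(default_factory=ErrorModelParams)
    rules: IntersectionRules = field(default_factory=IntersectionRules)
    n_rounds: int = 8
    window_bp: int = 1_000_000
    overlap_bp: int = 500_000
    cnv_m: int = 20
    panels: dict[str, str] = field(default_factory=dict)  # name -> BED path
    genes_bed: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if hasattr(current, "__dataclass_fields__") and isinstance(value, dict):
                for k, v in value.items():
                    if not hasattr(current, k):
                        raise ValueError(f"unknown config key {key}.{k}")
                    setattr(current, k, v)
            else:
                setattr(cfg, key, value)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (also written
    as JSON into the output directory)."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    if config.reference_fasta and not Path(config.reference_fasta).exists():
        raise FileNotFoundError(f"reference not found: {config.reference_fasta}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"seed": config.seed}

    # ---- stage 1: reference and molecules ---------------------------------
    truth = None
    if config.reference_fasta:
        log.info("reading reference %s", config.reference_fasta)
        sequences = read_fasta(config.reference_fasta)
        reference = GenomeMaps.from_sequences(sequences)
    else:
        log.info("simulating reference genome (seed %d)", config.seed)
        sequences, reference = simulate_reference(
            config.chrom_lengths, config.gc_fraction, seed=config.seed
        )
        write_fasta(sequences, out / "reference.fa")
    if config.rmaps_path:
        log.info("reading Rmaps from %s", config.rmaps_path)
        rmaps = [r for r in read_maps(config.rmaps_path)]
    else:
        log.info("simulating tumor Rmaps at %.0fx", config.coverage)
        specs = (
            place_default_truth_set(sequences, reference, rng)
            if config.implant_variants else []
        )
        tumor_seqs, truth = implant_variants(
            sequences, specs, seed=int(rng.integers(2**31))
        ) if specs else (sequences, pd.DataFrame())
        tumor_ref = GenomeMaps.from_sequences(tumor_seqs)
        subclones = []
        genomes = {}
        for i, (label, frac) in enumerate(sorted(config.subclone_fractions.items())):
            profile = []
            if config.arm_loss and i == len(config.subclone_fractions) - 1:
                profile = [(*config.arm_loss, 1)]
            subclones.append(Subclone(label, frac, copy_profile=profile))
            genomes[label] = tumor_ref
        sim = SimulationConfig(
            seed=int(rng.integers(2**31)),
            coverage=config.coverage,
            digest_efficiency=config.error_model.digest_efficiency,
            false_cut_rate_per_mb=config.error_model.false_cut_rate_per_mb,
            sizing_cv=config.error_model.sizing_cv,
            subclones=subclones,
        )
        rmaps = simulate_rmaps(genomes, sim, reference_length_bp=reference.total_length_bp)
        write_maps(rmaps, out / "rmaps.tsv")
        if truth is not None and len(truth):
            truth.to_json(out / "truth_variants.json", orient="records", indent=1)
    report["n_molecules"] = len(rmaps)

    # ---- stage 2: alignment ------------------------------------------------
    merged_ref = reference.merged(config.thresholds.merge_min_kb)
    log.info("aligning %d molecules", len(rmaps))
    aln_table, alignments = align_batch(rmaps, merged_ref, config.align)
    aln_table.to_csv(out / "alignments.tsv", sep="\t", index=False)
    aligned_mass = sum(
        r.total_mass_kb for r in rmaps if r.molecule_id in alignments
    )
    fold = aligned_mass * 1000.0 / reference.total_length_bp
    report["n_aligned"] = len(alignments)
    report["fold_coverage"] = round(fold, 2)
    log.info("%d aligned; %.2f fold coverage", len(alignments), fold)

    # ---- stage 3: iterative assembly --------------------------------------
    log.info("iterative assembly (%d rounds)", config.n_rounds)
    asm = iterate_assembly(
        rmaps, reference, config.assembly, n_rounds=config.n_rounds,
        window_bp=config.window_bp, overlap_bp=config.overlap_bp,
        merge_min_kb=config.thresholds.merge_min_kb,
    )
    report["aligned_per_round"] = asm.aligned_per_round
    consensus_maps = [cm.as_fragment_map() for cm in asm.consensus.values()]
    support_notes = {
        cm.window_id: "support=" + ",".join(
            f"{sp}:{co}" for sp, co in cm.cut_support
        )
        for cm in asm.consensus.values()
    }
    write_maps(consensus_maps, out / "consensus.tsv", annotations=support_notes)

    # ---- stage 4: structural alteration calls -----------------------------
    log.info("calling structural alterations")
    osa_table, class_counts = call_genome(
        asm.consensus, reference, config.thresholds, config.error_model, config.align
    )
    report["osa_counts"] = class_counts
    bed = osa_table[["chrom", "start", "end", "class"]]
    write_bed(bed, out / "osa.bed")
    osa_table.to_csv(out / "osa.tsv", sep="\t", index=False)

    # ---- stage 5: copy number (whole and per label) ------------------------
    log.info("coverage / copy-number analysis")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normal_sim = SimulationConfig(
            seed=int(rng.integers(2**31)), coverage=config.coverage,
            subclones=[Subclone("normal", 1.0)],
        )
        normal_rmaps = simulate_rmaps({"normal": reference}, normal_sim)
        normal_table, _ = align_batch(normal_rmaps, merged_ref, config.align)
        normal_mids = cnv_mod.midpoints(normal_table)
        chrom_lengths = {c: m.span_bp for c, m in reference.maps.items()}
        slice_res = cnv_mod.per_slice_cnv(
            aln_table, normal_mids, chrom_lengths, m=config.cnv_m
        )
        mids_all = cnv_mod.midpoints(aln_table)
        counts_all = cnv_mod.count_in_intervals(slice_res.intervals, mids_all)
        try:
            model = cnv_mod.fit_model(counts_all)
            _, segments = cnv_mod.viterbi_decode(slice_res.intervals, counts_all, model)
        except ValueError as exc:
            log.warning("whole-tumor CNV skipped: %s", exc)
            segments = []
    report["segments"] = [
        {"chrom": s.chrom, "start": s.start_bp, "end": s.end_bp, "state": s.state,
         "n_intervals": s.n_intervals}
        for s in segments
    ]
    report["n_discordant_intervals"] = int(len(slice_res.discordant))
    if len(slice_res.discordant):
        slice_res.discordant.to_csv(out / "slice_discordance.tsv", sep="\t", index=False)
    if segments:
        write_bed(
            pd.DataFrame([
                {"chrom": s.chrom, "start": s.start_bp, "end": s.end_bp,
                 "name": f"cn{s.state}"}
                for s in segments
            ]),
            out / "segments.bed",
        )

    # ---- stage 6: panels, genes, somatic filtering -------------------------
    if config.panels:
        panels = {
            name: (read_bed(path), "om") for name, path in config.panels.items()
        }
        candidates, removed, tallies = filter_somatic(osa_table, panels, config.rules)
        report["somatic_candidates"] = int(len(candidates))
        report["panel_tallies"] = tallies
        candidates.to_csv(out / "somatic_candidates.tsv", sep="\t", index=False)
    if config.genes_bed:
        genes = read_bed(config.genes_bed)
        annotated = annotate_genes(osa_table, genes)
        annotated.to_csv(out / "osa_annotated.tsv", sep="\t", index=False)

    # ---- truth comparison ---------------------------------------------------
    if truth is not None and len(truth):
        report["truth_metrics"] = _truth_metrics(osa_table, truth, reference)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    log.info("report written to %s", out / "report.json")
    return report


_TRUTH_TO_CLASS = {"INS": "INS", "DEL": "DEL", "SITE_GAIN": "EC", "SITE_LOSS": "MC"}


def _truth_metrics(osa_table: pd.DataFrame, truth: pd.DataFrame,
                   reference: GenomeMaps) -> dict:
    """Recall and precision of the calls against implanted truth.

    A truth record is recovered when a call of the expected class lies
    within one reference fragment of its (reference-coordinate)
    position.
    """
    tp = 0
    matched_calls: set[int] = set()
    for rec in truth.to_dict("records"):
        want = _TRUTH_TO_CLASS.get(rec["type"])
        if want is None:
            continue
        ref = reference.maps[rec["chrom"]]
        pos = int(rec["ref_pos"])
        cuts = ref.cut_coords
        i = int(np.searchsorted(cuts, pos))
        lo = int(cuts[max(0, i - 2)]) if cuts.size else 0
        hi = int(cuts[min(cuts.size - 1, i + 1)]) if cuts.size else ref.span_bp
        found = False
        for j, row in osa_table.iterrows():
            if j in matched_calls or row["class"] != want or row["chrom"] != rec["chrom"]:
                continue
            if row["end"] >= lo and row["start"] <= hi:
                matched_calls.add(j)
                found = True
                break
        tp += found
    n_truth = int((truth["type"].isin(_TRUTH_TO_CLASS)).sum())
    n_calls = int(len(osa_table))
    return {
        "recall": round(tp / n_truth, 3) if n_truth else None,
        "precision": round(len(matched_calls) / n_calls, 3) if n_calls else None,
        "n_truth": n_truth,
        "n_calls": n_calls,
    }
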