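"""End-to-end orchestration: simulate -> preprocess -> annotate -> profile ->
compare -> segregate -> guide-RNA scan, with reproducible on-disk outputs.

All stage parameters live in a single :class:`PipelineConfig`; a fixed
config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .annotation import AnnotationIndex, ReferenceSet, annotate_sample, category_profile
from .differential import comparing_set, results_frame, significant_species
from .preprocess import (AdapterConfig, DEFAULT_BARCODES, SampleLibrary,
                         preprocess_reads, read_fasta_or_fastq)
from .profiling import find_peaks, length_profile, species_frequency_table
from .segregation import Bipartition, segregation_test
from .structure import scan_candidates
from .synthetic import SyntheticSpec, make_reference_set, simulate_libraries, write_truth_tsv

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "srnaprof_out"
    seed: int = 0
    # inputs; when reads_path is None the synthetic generator runs first
    reads_path: Optional[str] = None
    reference_fasta: Optional[str] = None
    reference_tsv: Optional[str] = None
    sample_sheet: dict[str, dict[str, str]] = field(default_factory=dict)
    # synthetic stage
    simulate: bool = True
    n_samples: int = 6
    reads_per_sample: int = 2000
    n_planted_differential: int = 4
    differential_fold_change: float = 20.0
    artifact_fraction: float = 0.05
    # preprocessing
    barcode_table: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BARCODES))
    max_bc_mismatch: int = 0
    seed_mismatch: int = 1
    artifact_min_match_len: int = 10
    artifact_mismatch: int = 1
    apply_artifact_filter: bool = True
    length_lo: int = 5
    length_hi: int = 40
    # annotation
    annotation_max_mm: int = 2
    rdna_max_mm: int = 2
    profile_mode: str = "fractional"
    # differential + segregation
    top_n: int = 5
    alpha: float = 0.05
    run_segregation: bool = True
    case_group: str = "B"
    # structure scan
    min_acceptor_bp: int = 7
    window_upstream: int = 30

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        try:
            return cls(**raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def adapter_config(self) -> AdapterConfig:
        try:
            return AdapterConfig(
                barcode_table=dict(self.barcode_table),
                seed_mismatch=self.seed_mismatch,
                max_bc_mismatch=self.max_bc_mismatch,
                artifact_min_match_len=self.artifact_min_match_len,
                artifact_mismatch=self.artifact_mismatch,
                length_lo=self.length_lo, length_hi=self.length_hi,
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns a summary dict.

    Writes, under ``out_dir``: run_log.json, reference FASTA/TSV (when
    simulated), raw reads FASTQ (when simulated), truth TSV, accounting TSV,
    per-sample length profiles and category profiles, the comparison table,
    segregation report JSON, and the guide-candidate table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # --- reference + reads -------------------------------------------------
    if config.simulate:
        try:
            spec = SyntheticSpec(
                seed=config.seed,
                n_samples=config.n_samples,
                reads_per_sample=config.reads_per_sample,
                n_planted_differential=config.n_planted_differential,
                differential_fold_change=config.differential_fold_change,
                artifact_fraction=config.artifact_fraction,
                barcode_table=dict(config.barcode_table),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        refs = make_reference_set(spec)
        run = simulate_libraries(spec, refs)
        refs.write(out / "reference.fasta", out / "reference_categories.tsv")
        run.write_fastq(out / "reads.fastq")
        write_truth_tsv(run.truth, out / "truth.tsv")
        records = run.reads
        sample_sheet = {sid: {"group": spec.group(sid), "source": "synthetic"}
                        for sid in spec.sample_ids}
    else:
        if not (config.reads_path and config.reference_fasta
                and config.reference_tsv):
            raise ConfigError("reads_path, reference_fasta and reference_tsv "
                              "are required when simulate is off")
        for p in (config.reads_path, config.reference_fasta,
                  config.reference_tsv):
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        refs = ReferenceSet.read(config.reference_fasta, config.reference_tsv)
        records = list(read_fasta_or_fastq(config.reads_path))
        sample_sheet = config.sample_sheet

    # --- preprocess --------------------------------------------------------
    try:
        libraries, accounting = preprocess_reads(
            records, config.adapter_config(), sample_sheet,
            config.apply_artifact_filter)
    except ConfigError:
        raise
    except Exception as exc:       # pragma: no cover - defensive
        raise StageError("preprocess", str(exc)) from exc
    accounting.to_csv(out / "accounting.tsv", sep="\t")
    if int(accounting["total"].sum()) != len(records):
        raise StageError("preprocess", "read accounting does not conserve totals")
    summary["reads_total"] = len(records)
    summary["reads_kept"] = int(accounting["kept"].sum())

    samples = [libraries[sid] for sid in sorted(libraries)]

    # --- profile -----------------------------------------------------------
    prof_rows = []
    peaks = {}
    for s in samples:
        lp = length_profile(s, config.length_lo, config.length_hi)
        peaks[s.sample_id] = find_peaks(lp)
        for length in sorted(lp.counts):
            prof_rows.append((s.sample_id, length, lp.counts[length]))
    pd.DataFrame(prof_rows, columns=["sample", "length", "reads"]).to_csv(
        out / "length_profiles.tsv", sep="\t", index=False)
    summary["peaks"] = peaks

    # --- annotate ----------------------------------------------------------
    index = AnnotationIndex(refs)
    cat_rows = []
    for s in samples:
        ann = annotate_sample(s.counts, refs, index, config.annotation_max_mm,
                              config.rdna_max_mm)
        prof = category_profile(s.counts, ann, config.profile_mode)
        for cat, pct in sorted(prof.percentages.items()):
            cat_rows.append((s.sample_id, cat, pct, prof.annotated_reads,
                             prof.unannotated_reads))
    pd.DataFrame(cat_rows, columns=["sample", "category", "percent",
                                    "annotated_reads", "unannotated_reads"]
                 ).to_csv(out / "category_profiles.tsv", sep="\t", index=False)

    # --- compare -----------------------------------------------------------
    groups = {sid: sample_sheet.get(sid, {}).get("group", "") for sid in libraries}
    case_ids = sorted(sid for sid, g in groups.items() if g == config.case_group)
    control_ids = sorted(sid for sid, g in groups.items()
                         if g and g != config.case_group)
    seqs = comparing_set(samples, config.top_n, config.length_lo,
                         config.length_hi)
    table = species_frequency_table(samples, seqs)
    results = []
    if case_ids and control_ids:
        results = significant_species(table, (case_ids, control_ids),
                                      config.alpha)
        results_frame(results).to_csv(out / "comparisons.tsv", sep="\t",
                                      index=False)
    summary["comparing_sequences"] = len(seqs)
    summary["significant"] = sum(r.significant for r in results)

    # --- segregate ---------------------------------------------------------
    if config.run_segregation and case_ids and control_ids:
        if len(case_ids) != len(control_ids) or len(libraries) % 2:
            raise StageError(
                "segregation_stat",
                f"balanced bipartitions need an even sample count with equal "
                f"groups; got {len(case_ids)} vs {len(control_ids)}")
        seg = segregation_test(table, Bipartition.of(case_ids, control_ids),
                               config.alpha)
        with open(out / "segregation.json", "w") as fh:
            json.dump(seg.to_dict(), fh, indent=2)
        summary["segregation"] = seg.to_dict()

    # --- guide-RNA scan ----------------------------------------------------
    significant_seqs = [r.sequence for r in results if r.significant] or seqs
    candidates = scan_candidates(sorted(set(significant_seqs),
                                        key=lambda s: (len(s), s)))
    with open(out / "sgrna_candidates.tsv", "w") as fh:
        fh.write("sequence\tlength\tclasses\tacceptor_arm\n")
        for c in candidates:
            arm = c.fold.acceptor_arm if c.fold else ""
            fh.write(f"{c.sequence}\t{len(c.sequence)}\t"
                     f"{','.join(sorted(c.classes))}\t{arm}\n")
    summary["sgrna_candidates"] = len(candidates)

    with open(out / "run_log.json", "w") as fh:
        json.dump({"config": asdict(config), "summary_keys": sorted(summary)},
                  fh, indent=2, default=str)
    return summary
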