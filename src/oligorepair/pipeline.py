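"""Pipeline configuration and the end-to-end driver.

Stage order is fixed: demultiplex (optional) -> quality filter -> trim ->
dereplicate -> constraint filter/sort (optional) -> cluster (optional) ->
repair (optional).  Repair operates on clusters, so requesting it without
clustering is a configuration error, reported before any I/O.

The configuration is a YAML file whose keys are validated strictly (unknown
keys rejected); every default is materialised and the resolved config is
echoed to the output directory, so a run is reproducible from its outputs
alone.
"""

from __future__ import annotations

import csv
import logging
import time
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import clustering, filtering, io, repair, synthetic
from .constraints import ConstraintSet

log = logging.getLogger("oligorepair")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConstraintConfig(_StrictModel):
    gc_min: float = 0.40
    gc_max: float = 0.60
    window_size: int = 15
    gc_window_min: Optional[float] = None
    gc_window_max: Optional[float] = None
    max_homopolymer: int = 3
    blacklist: list[str] = Field(default_factory=list)
    kmer_k: Optional[int] = None
    kmer_max_occurrences: int = 1
    target_length: Optional[Union[int, tuple[int, int]]] = None
    rule_weights: dict[str, float] = Field(default_factory=dict)

    def build(self) -> ConstraintSet:
        return ConstraintSet(**self.model_dump())


class FilterConfig(_StrictModel):
    min_mean_q: float = 10.0
    mode: Literal["filter", "sort"] = "filter"
    quality_weight: float = 1.0
    primer_mismatches: int = 0


class ClusterConfig(_StrictModel):
    threshold: float = clustering.DEFAULT_SIMILARITY_THRESHOLD
    order: Literal["abundance", "quality"] = "abundance"

    def build(self) -> clustering.ClusterParams:
        return clustering.ClusterParams(threshold=self.threshold, order=self.order)


class RepairConfig(_StrictModel):
    max_changes: int = repair.DEFAULT_MAX_CHANGES
    keep_original: bool = False
    exhaustive: bool = True


class ChannelConfig(_StrictModel):
    n_refs: int = 50
    ref_length: int = 60
    coverage: float = 20.0
    abundance_dispersion: float = 0.5
    sub_rate: float = 0.01
    ins_rate: float = 0.005
    del_rate: float = 0.005
    q_correct: float = 35.0
    q_error: float = 12.0

    def build(self, seed: int) -> synthetic.ChannelParams:
        return synthetic.ChannelParams(seed=seed, **self.model_dump())


class StagesConfig(_StrictModel):
    demultiplex: bool = False
    constraint_handling: Literal["off", "filter", "sort"] = "off"
    cluster: bool = False
    repair: bool = False


class PipelineConfig(_StrictModel):
    """Full run description; see module docstring for the stage order."""

    inputs: list[str] = Field(default_factory=list)
    primer_table: Optional[str] = None
    output_dir: str = "oligorepair_out"
    seed: int = 0
    stages: StagesConfig = Field(default_factory=StagesConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    constraints: ConstraintConfig = Field(default_factory=ConstraintConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    repair: RepairConfig = Field(default_factory=RepairConfig)
    synthetic: ChannelConfig = Field(default_factory=ChannelConfig)

    def validate_consistency(self) -> None:
        if self.stages.repair and not self.stages.cluster:
            raise ConfigError("repair requires prior similarity clustering; "
                              "enable stages.cluster or disable stages.repair")
        if self.stages.demultiplex and self.primer_table is None:
            raise ConfigError("demultiplexing requires a primer_table")
        if not self.inputs:
            raise ConfigError("no input files configured")


class ConfigError(ValueError):
    """Inconsistent or invalid pipeline configuration."""


def load_config(path: Union[str, Path]) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:  # pydantic validation -> uniform error type
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def _read_any(path: Path) -> list[io.SequenceRecord]:
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        return list(io.read_fasta(path))
    return list(io.read_fastq(path))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages over every input file.

    Writes per run: ``representatives.fasta`` (dereplication dialect),
    ``report.json`` (when repair ran), ``counts.tsv`` with per-stage read
    accounting, and ``resolved_config.yaml``.
    """
    config.validate_consistency()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    with (outdir / "resolved_config.yaml").open("w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)

    cs = config.constraints.build()
    table = io.read_primer_table(config.primer_table) if config.primer_table else None
    counts: list[tuple[str, str, str, int, int, int]] = []  # file, sample, stage, in, kept, removed
    report: dict[str, list[dict]] = {}
    representatives: list[io.SequenceRecord] = []

    for input_path in config.inputs:
        input_path = Path(input_path)
        records = _read_any(input_path)
        log.info("%s: %d reads", input_path.name, len(records))

        if config.stages.demultiplex:
            bins = filtering.demultiplex(records, table)
            n_assigned = sum(len(v) for s, v in bins.items() if s != filtering.UNDETERMINED)
            counts.append((input_path.name, "*", "demultiplex", len(records),
                           n_assigned, len(bins[filtering.UNDETERMINED])))
        else:
            bins = {"all": records}

        for sample, sample_records in bins.items():
            if config.stages.demultiplex and sample == filtering.UNDETERMINED:
                continue
            reps, entries = _process_sample(
                input_path.name, sample, sample_records, config, cs, table, counts
            )
            representatives.extend(reps)
            if entries is not None:
                report.setdefault(input_path.name, []).extend(entries)

    io.write_fasta_derep(representatives, outdir / "representatives.fasta")
    if config.stages.repair:
        io.write_report(report, outdir / "report.json")
    with (outdir / "counts.tsv").open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["file", "sample", "stage", "n_in", "n_kept", "n_removed"])
        writer.writerows(counts)
    return outdir


def _process_sample(fname, sample, records, config, cs, table, counts):
    t0 = time.monotonic()

    if records and records[0].quals is not None:
        kept, removed = filtering.quality_filter(records, config.filter.min_mean_q)
        counts.append((fname, sample, "quality_filter", len(records), len(kept), len(removed)))
        records = kept

    if table is not None and sample in table.rows:
        trimmed, rejected = filtering.trim_all(
            records, table[sample], config.filter.primer_mismatches
        )
        counts.append((fname, sample, "trim", len(records), len(trimmed), len(rejected)))
        records = trimmed

    derep = clustering.dereplicate(records)
    counts.append((fname, sample, "dereplicate", len(records), len(derep), 0))
    records = derep

    if config.stages.constraint_handling == "filter":
        kept, removed = filtering.constraint_filter(records, cs)
        counts.append((fname, sample, "constraint_filter", len(records), len(kept), len(removed)))
        records = kept
    elif config.stages.constraint_handling == "sort":
        records = filtering.constraint_sort(records, cs, config.filter.quality_weight)
        counts.append((fname, sample, "constraint_sort", len(records), len(records), 0))

    if not config.stages.cluster:
        log.info("%s/%s done in %.2fs", fname, sample, time.monotonic() - t0)
        return records, None

    clusters = clustering.greedy_cluster(records, config.cluster.build())
    counts.append((fname, sample, "cluster", len(records), len(clusters), 0))

    if not config.stages.repair:
        log.info("%s/%s done in %.2fs", fname, sample, time.monotonic() - t0)
        return [cl.centroid for cl in clusters], None

    reps: list[io.SequenceRecord] = []
    entries: list[dict] = []
    n_recovered = 0
    for cl in clusters:
        done = repair.repair_cluster(
            cl, cs,
            max_changes=config.repair.max_changes,
            exhaustive=config.repair.exhaustive,
        )
        entries.append(repair.report_entry(done))
        emitted = list(repair.keep_original_option(done, config.repair.keep_original))
        reps.extend(emitted)
        if emitted:
            n_recovered += 1
    counts.append((fname, sample, "repair", len(clusters), n_recovered,
                   len(clusters) - n_recovered))
    log.info("%s/%s done in %.2fs", fname, sample, time.monotonic() - t0)
    return reps, entries
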