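"""End-to-end orchestration: build-ref -> trim/align -> profile -> call.

One :class:`RunConfig` drives every stage over a set of age-labelled
libraries; ``run_all`` writes each stage's tables plus a manifest (versions,
parameters, input checksums) into the output directory and is idempotent
given the same inputs, config and seed.  ``demo`` wires the synthetic
generator in front of the same pipeline for a one-command smoke run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .aligner import (ReadRecord, ReferenceSet, read_fastq, sequential_align,
                      trim_adapter, write_read_report, write_sam, REJECTED)
from .homology_analysis import (cluster_homology, correlate_groups_per_age,
                                percent_identity_matrix, select_cluster_number,
                                write_correlations, write_groups)
from .mod_caller import call_modifications, compare_across_ages, write_modification_table
from .profiler import pileup, write_profiles
from .reference_builder import (deduplicate, parse_gene_set, summarize_gene_set,
                                write_reference_fasta, write_reference_index)
from .trf_caller import call_trfs, write_trf_table

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    annotation: str
    genome: str
    libraries: dict[str, str]        # age label -> FASTQ path
    days: dict[str, float]           # age label -> numeric day
    outdir: str
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    max_error_rate: float = 0.1
    max_mismatches: int = 2
    theta: float = 0.5
    pct: float = 1.0
    min_gap: int = 3
    min_region_length: int = 10
    d5: int = 3
    d3: int = 3
    trend_r: float = 0.8
    mod_min_depth: float = 20
    mod_min_fraction: float = 0.1
    k_range: Sequence[int] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.libraries) != set(self.days):
            raise ValueError("libraries and days must have the same age labels")
        days = [self.days[a] for a in sorted(self.days, key=self.days.get)]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("age day labels must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_inputs(self) -> None:
        missing = [p for p in [self.annotation, self.genome, *self.libraries.values()]
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the result bundle with in-memory objects."""
    config.validate_inputs()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timers: dict[str, float] = {}
    bundle: dict = {}

    def stage(name):
        log.info("stage %s", name)
        timers[name] = time.perf_counter()

    def done(name):
        timers[name] = time.perf_counter() - timers[name]
        log.info("stage %s done in %.2fs", name, timers[name])

    stage("build-ref")
    try:
        genes = parse_gene_set(config.annotation, config.genome)
        references = deduplicate(genes)
        if not references:
            raise ValueError("reference set is empty after pseudogene removal")
        write_reference_fasta(references, out / "mature_refs.fa")
        write_reference_index(references, out / "mature_refs.tsv")
        summary = summarize_gene_set(genes)
        pd.Series(summary).to_csv(out / "gene_set_summary.tsv", sep="\t", header=False)
        bundle["references"], bundle["gene_set_summary"] = references, summary
    except Exception as err:
        raise RuntimeError(f"stage build-ref failed on {config.annotation}: {err}") from err
    done("build-ref")

    refset = ReferenceSet(references)
    ages = sorted(config.libraries, key=lambda a: config.days[a])
    alignments_by_age: dict[str, list] = {}
    profiles_by_age: dict[str, dict] = {}
    library_totals: dict[str, int] = {}
    for age in ages:
        stage(f"align-{age}")
        try:
            raw = read_fastq(config.libraries[age])
            kept: list[ReadRecord] = []
            for r in raw:
                t = trim_adapter(r, config.adapter, config.max_error_rate)
                if t is not REJECTED:
                    kept.append(t)
            library_totals[age] = len(kept)
            alignments, unaligned = sequential_align(kept, refset, config.max_mismatches)
            write_sam(alignments, refset, out / f"{age}.sam")
            write_read_report(alignments, out / f"{age}.reads.tsv")
            alignments_by_age[age] = alignments
        except Exception as err:
            raise RuntimeError(
                f"stage align-{age} failed on {config.libraries[age]}: {err}") from err
        done(f"align-{age}")

        stage(f"profile-{age}")
        profiles_by_age[age] = pileup(alignments_by_age[age], references)
        write_profiles(profiles_by_age[age], out / f"{age}.profile.tsv")
        done(f"profile-{age}")
    bundle["alignments_by_age"] = alignments_by_age
    bundle["profiles_by_age"] = profiles_by_age

    stage("call-trfs")
    trfs = call_trfs(
        profiles_by_age, references, alignments_by_age, config.days,
        theta=config.theta, pct=config.pct, min_gap=config.min_gap,
        min_length=config.min_region_length, d5=config.d5, d3=config.d3,
        r_threshold=config.trend_r, library_totals=library_totals,
    )
    write_trf_table(trfs, ages, out / "trfs.tsv")
    bundle["trfs"] = trfs
    done("call-trfs")

    stage("call-mods")
    mods = call_modifications(
        profiles_by_age, references,
        min_depth=config.mod_min_depth, min_fraction=config.mod_min_fraction)
    write_modification_table(mods, ages, out / "modifications.tsv")
    compare_across_ages(mods, ages).to_csv(
        out / "modification_stability.tsv", sep="\t", index=False)
    bundle["modifications"] = mods
    done("call-mods")

    stage("cluster-correlate")
    identity = percent_identity_matrix(references)
    identity.to_csv(out / "identity_matrix.tsv", sep="\t")
    abundance = pd.DataFrame(
        {age: pd.Series(
            pd.Index([a.ref_id for a in alignments_by_age[age]]).value_counts(),
            dtype=float)
         for age in ages}
    ).reindex([r.ref_id for r in references]).fillna(0.0)
    k_range = [k for k in config.k_range if 2 <= k <= len(references)] \
        or list(range(2, len(references) + 1))
    cluster_cfg = select_cluster_number(identity, references, abundance, k_range)
    groups = cluster_homology(identity, references, cluster_cfg.k)
    correlations = correlate_groups_per_age(groups, abundance)
    write_groups(groups, out / "homology_groups.tsv")
    write_correlations(correlations, out / "copy_number_correlation.tsv")
    cluster_cfg.k_table.to_csv(out / "cluster_scan.tsv", sep="\t", index=False)
    bundle.update(groups=groups, correlations=correlations, cluster_config=cluster_cfg)
    done("cluster-correlate")

    manifest = {
        "trfage_version": __version__,
        "parameters": {k: v for k, v in vars(config).items()
                       if isinstance(v, (int, float, str, list, tuple))},
        "inputs": {p: _sha256(p) for p in
                   [config.annotation, config.genome, *config.libraries.values()]},
        "stage_seconds": {k: round(v, 3) for k, v in timers.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    bundle["manifest"] = manifest
    return bundle


def demo(seed: int, outdir: str | Path, n_families: int = 8) -> dict:
    """Simulate an age series and run the full pipeline on it."""
    from .reference_builder import write_gene_set
    from .synthetic_data import SimulationConfig, simulate_gene_set, simulate_reads, \
        save_config, write_fastq

    out = Path(outdir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(n_families=n_families)
    genes, genome = simulate_gene_set(sim, seed)
    write_gene_set(genes, genome, out / "inputs" / "genes.tsv", out / "inputs" / "genome.fa")
    save_config(sim, out / "inputs" / "sim_config.txt")
    libraries, days = {}, {}
    for i, day in enumerate(sim.age_points):
        reads, truth = simulate_reads(sim, genes, i, seed)
        label = f"day{day:g}"
        write_fastq(reads, out / "inputs" / f"{label}.fastq")
        truth.per_read.to_csv(out / "inputs" / f"{label}.truth.tsv", sep="\t", index=False)
        libraries[label] = str(out / "inputs" / f"{label}.fastq")
        days[label] = float(day)
    config = RunConfig(
        annotation=str(out / "inputs" / "genes.tsv"),
        genome=str(out / "inputs" / "genome.fa"),
        libraries=libraries,
        days=days,
        outdir=str(out),
        adapter=sim.adapter,
        pct=60.0,  # small synthetic runs call few regions; keep most of them
        k_range=list(range(2, 2 * n_families + 1)),
        seed=seed,
    )
    return run_all(config)
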