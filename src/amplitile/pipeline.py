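"""Pipeline orchestration, run configuration, and output files.

Executes the four stages in order — target-region selection, unique oligo
design, priming-specificity evaluation, primer-pair selection — from a single
declarative configuration, and writes the primary output files: a run
summary, a primer order file, the pair/amplicon feature table, the minimum
tiling set with multiplex groups, and BED files of primers and amplicons
(0-based half-open, strand column set). Output is deterministic for fixed
inputs and configuration: rows are ordered by coordinate, then id.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import design, pairing, scan, specificity, thermo
from .genome import (
    ReferenceGenome,
    TargetRegion,
    VariantMask,
    convert_variants,
    extract_masked_region,
    load_genome,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All module settings in one document; a run is fully reproducible from
    (inputs, RunConfig)."""

    fasta: list[str] = field(default_factory=list)
    vcf: str | None = None
    chrom: str = ""
    start: int = 0
    stop: int = 0
    mask_enabled: bool = True
    gap_min: int = 100
    uod: design.UODSettings = field(default_factory=design.UODSettings)
    scan: scan.ScanParams = field(default_factory=scan.ScanParams)
    specificity_threshold: float = 10.0
    pps: pairing.PPSSettings = field(default_factory=pairing.PPSSettings)
    conditions: thermo.ReactionConditions = field(
        default_factory=thermo.ReactionConditions
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        kwargs = dict(doc)
        for key, sub in (
            ("uod", design.UODSettings),
            ("scan", scan.ScanParams),
            ("pps", pairing.PPSSettings),
            ("conditions", thermo.ReactionConditions),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass
class PipelineResult:
    config: RunConfig
    region: TargetRegion
    mask: VariantMask | None
    uod: design.UODResult
    hits: dict[str, list[scan.LocalHit]]
    thermoalignments: dict[str, list[specificity.ThermoAlignment]]
    profiles: dict[str, specificity.MisprimeProfile]
    specific: list[design.CandidateOligo]
    pairs: list[pairing.AmpliconPair]
    tiling: pairing.TilingResult | None
    timings: dict[str, float]

    @property
    def candidate_lookup(self) -> dict[str, design.CandidateOligo]:
        return {o.id: o for o in self.uod.candidates}


def run_pipeline(
    config: RunConfig, genome: ReferenceGenome | None = None
) -> PipelineResult:
    """TRS -> UOD -> PSE -> PPS on the configured target region.

    ``genome`` may be supplied directly (already loaded / synthetic);
    otherwise it is read from ``config.fasta``.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if genome is None:
        genome = load_genome([Path(p) for p in config.fasta])
    mask = convert_variants(config.vcf, genome) if config.vcf else None
    region = extract_masked_region(
        genome, config.chrom, config.start, config.stop,
        mask=mask, mask_enabled=config.mask_enabled, gap_min=config.gap_min,
    )
    timings["trs"] = time.perf_counter() - t0
    logger.info(
        "TRS: %s:%d-%d gc=%.1f%% snps=%d indels=%d gaps=%d",
        region.chrom, region.start, region.stop, region.summary.gc_pct,
        region.summary.n_snps, region.summary.n_indels, len(region.summary.gap_runs),
    )

    t0 = time.perf_counter()
    table = thermo.default_table()
    uod = design.run_uod(region, genome, config.uod, config.conditions, table)
    timings["uod"] = time.perf_counter() - t0
    logger.info("UOD: %d enumerated, %d candidates", uod.accounting["enumerated"],
                uod.accounting["pass_all"])

    t0 = time.perf_counter()
    index = scan.KmerIndex(genome, config.scan.word_size)
    hits: dict[str, list[scan.LocalHit]] = {}
    tas: dict[str, list[specificity.ThermoAlignment]] = {}
    profiles: dict[str, specificity.MisprimeProfile] = {}
    specific: list[design.CandidateOligo] = []
    for oligo in uod.passing:
        ohits = scan.find_local_hits(oligo, genome, config.scan, index)
        hits[oligo.id] = ohits
        otas = []
        for h in ohits:
            ta = specificity.build_thermoalignment(h, oligo, genome)
            if ta is not None:
                specificity.misprime_tm(ta, config.conditions, table)
                otas.append(ta)
        tas[oligo.id] = otas
        prof = specificity.misprime_profile(
            oligo, otas, config.conditions, table
        )
        specificity.specificity_filter(prof, config.specificity_threshold)
        profiles[oligo.id] = prof
        if prof.pass_specificity:
            specific.append(oligo)
    timings["pse"] = time.perf_counter() - t0
    logger.info("PSE: %d of %d primers pass specificity",
                len(specific), len(uod.passing))

    t0 = time.perf_counter()
    pairs = pairing.enumerate_pairs(
        specific, profiles, region, config.pps, config.conditions, table
    )
    tiling = None
    if pairs:
        tg = pairing.build_tiling_graph(pairs)
        tiling = pairing.minimum_tiling_path(
            tg, region_interval=(region.start, region.stop)
        )
        pairing.split_multiplex_groups(tiling)
    timings["pps"] = time.perf_counter() - t0
    logger.info("PPS: %d pairs, coverage %.1f%%", len(pairs),
                100 * (tiling.coverage_fraction if tiling else 0.0))
    return PipelineResult(
        config=config, region=region, mask=mask, uod=uod, hits=hits,
        thermoalignments=tas, profiles=profiles, specific=specific,
        pairs=pairs, tiling=tiling, timings=timings,
    )


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, float):
        if math.isinf(x):
            return "-inf" if x < 0 else "inf"
        return f"{x:.3f}"
    return str(x)


def _bed_row(chrom: str, interval: tuple[int, int], name: str, strand: str) -> str:
    lo, hi = interval
    return f"{chrom}\t{lo - 1}\t{hi}\t{name}\t0\t{strand}\n"


def write_outputs(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write the primary output files; returns name -> path.

    Files: summary.txt, primer_order.tsv, candidates.tsv, misprime_report.tsv,
    pairs.tsv, minimum_set.tsv, primers.bed, amplicons.bed, multiplx.tsv.
    Empty stages still produce files with header rows only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise OSError(f"unwritable output directory: {outdir}")
    paths: dict[str, Path] = {}
    region = result.region
    lookup = result.candidate_lookup

    p = paths["summary"] = outdir / "summary.txt"
    with open(p, "w") as fh:
        fh.write("# pipeline run summary\n")
        fh.write(f"target\t{region.chrom}:{region.start}-{region.stop}\n")
        fh.write(f"region_gc_pct\t{region.summary.gc_pct:.2f}\n")
        fh.write(f"n_snps\t{region.summary.n_snps}\n")
        fh.write(f"n_indels\t{region.summary.n_indels}\n")
        fh.write(f"n_assembly_gaps\t{len(region.summary.gap_runs)}\n")
        for key, val in result.uod.accounting.items():
            fh.write(f"uod_{key}\t{val}\n")
        fh.write(f"pse_pass_specificity\t{len(result.specific)}\n")
        fh.write(f"pps_n_pairs\t{len(result.pairs)}\n")
        if result.tiling:
            fh.write(f"tiling_n_subgraphs\t{len(result.tiling.paths)}\n")
            fh.write(
                f"tiling_n_pairs\t{sum(len(p) for p in result.tiling.paths)}\n"
            )
            fh.write(
                f"tiling_coverage_fraction\t{result.tiling.coverage_fraction:.4f}\n"
            )
        for stage, secs in result.timings.items():
            fh.write(f"time_{stage}_s\t{secs:.2f}\n")

    p = paths["candidates"] = outdir / "candidates.tsv"
    with open(p, "w") as fh:
        fh.write("id\tsequence\tstrand\tfive_prime_pos\tlength\tgc_pct\t"
                 "tm_on_target\thairpin_tm\thomodimer_tm\tflags\tpass\n")
        for o in sorted(result.uod.candidates,
                        key=lambda o: (o.genomic_interval, o.id)):
            if not o.passed and "non_acgt" in o.filter_flags:
                continue  # keep the table tractable: masked windows excluded
            fh.write("\t".join([
                o.id, o.sequence, o.strand, str(o.five_prime_pos), str(o.length),
                f"{o.gc_pct:.1f}",
                _fmt(o.tm_on_target) if o.tm_on_target is not None else "NA",
                _fmt(o.hairpin_tm) if o.hairpin_tm is not None else "NA",
                _fmt(o.homodimer_tm) if o.homodimer_tm is not None else "NA",
                ",".join(sorted(o.filter_flags)) or ".",
                str(o.passed),
            ]) + "\n")

    p = paths["primer_order"] = outdir / "primer_order.tsv"
    with open(p, "w") as fh:
        fh.write("id\tsequence\n")
        for o in sorted(result.specific, key=lambda o: (o.genomic_interval, o.id)):
            fh.write(f"{o.id}\t{o.sequence}\n")

    p = paths["misprime_report"] = outdir / "misprime_report.tsv"
    with open(p, "w") as fh:
        fh.write("id\ttm_on_target\ttm_offtarget_max\ttm_offtarget_p90\t"
                 "n_hits_scored\tfrac_hits_with_last5_mismatch\tpass\n")
        for oid in sorted(result.profiles):
            pr = result.profiles[oid]
            fh.write("\t".join([
                oid, _fmt(pr.tm_on_target), _fmt(pr.tm_offtarget_max),
                _fmt(pr.tm_offtarget_p90), str(pr.n_hits_scored),
                f"{pr.frac_hits_with_last5_mismatch:.3f}",
                str(pr.pass_specificity),
            ]) + "\n")

    p = paths["pairs"] = outdir / "pairs.tsv"
    with open(p, "w") as fh:
        fh.write("fwd_id\trev_id\tamplicon_start\tamplicon_stop\tamplicon_length\t"
                 "tm_min_of_pair\ttm_diff\tpair_max_misprime\theterodimer_dg\t"
                 "contains_assembly_gap\tcontains_indel\tamplicon_gc_pct\n")
        for pr in result.pairs:
            fh.write("\t".join([
                pr.fwd_id, pr.rev_id, str(pr.amplicon_start), str(pr.amplicon_stop),
                str(pr.amplicon_length), _fmt(pr.tm_min_of_pair), _fmt(pr.tm_diff),
                _fmt(pr.pair_max_misprime), _fmt(pr.heterodimer_dg),
                str(pr.contains_assembly_gap), str(pr.contains_indel),
                f"{pr.amplicon_gc_pct:.1f}",
            ]) + "\n")

    p = paths["minimum_set"] = outdir / "minimum_set.tsv"
    with open(p, "w") as fh:
        fh.write("subgraph\tposition_in_path\tfwd_id\trev_id\tamplicon_start\t"
                 "amplicon_stop\tamplicon_length\tmultiplex_group\n")
        if result.tiling:
            group_of = {
                pid: g
                for g, pids in result.tiling.multiplex_groups.items()
                for pid in pids
            }
            for si, path in enumerate(result.tiling.paths, start=1):
                for pi, pid in enumerate(path, start=1):
                    pr = result.tiling.pairs[pid]
                    fh.write("\t".join([
                        str(si), str(pi), pr.fwd_id, pr.rev_id,
                        str(pr.amplicon_start), str(pr.amplicon_stop),
                        str(pr.amplicon_length), group_of.get(pid, "."),
                    ]) + "\n")

    p = paths["primers_bed"] = outdir / "primers.bed"
    with open(p, "w") as fh:
        for o in sorted(result.specific, key=lambda o: (o.genomic_interval, o.id)):
            strand = "+" if o.strand == "F" else "-"
            fh.write(_bed_row(o.chrom, o.genomic_interval, o.id, strand))

    p = paths["amplicons_bed"] = outdir / "amplicons.bed"
    with open(p, "w") as fh:
        if result.tiling:
            for path in result.tiling.paths:
                for pid in path:
                    pr = result.tiling.pairs[pid]
                    fh.write(_bed_row(region.chrom, pr.interval, pr.pair_id, "+"))

    # export for external multiplex-compatibility grouping: name, fwd seq,
    # rev seq, expected product size (documented input layout of that tool)
    p = paths["multiplx"] = outdir / "multiplx.tsv"
    with open(p, "w") as fh:
        if result.tiling:
            for path in result.tiling.paths:
                for pid in path:
                    pr = result.tiling.pairs[pid]
                    fh.write("\t".join([
                        pid, lookup[pr.fwd_id].sequence, lookup[pr.rev_id].sequence,
                        str(pr.amplicon_length),
                    ]) + "\n")
    return paths
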