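"""Deterministic synthetic genomes, variants and truth tables for testing.

The generator emulates the features of a repeat-rich plant-style reference
that drive every branch of the pipeline: a multi-chromosome genome with
tunable GC, planted families of divergent repeat copies (off-target priming
sites with recorded coordinates and divergence), assembly-gap N runs of the
conventional 100/1000-nt lengths, and a VCF of SNP/indel positions using the
single-position indel encoding. Output is byte-identical for a fixed seed:
one RNG stream, no iteration-order dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._dna import revcomp
from .genome import ReferenceGenome

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RepeatFamily:
    """One divergent repeat family: n_copies of a consensus planted genome-wide.

    divergence is the per-base substitution probability applied independently
    to every copy; indel_rate the per-copy probability of one single-nt indel.
    The first copy is planted inside the target interval so primers designed
    there face real off-target sites.
    """

    n_copies: int = 4
    length: int = 600
    divergence: float = 0.04
    indel_rate: float = 0.2


@dataclass(frozen=True)
class FixtureSpec:
    """Defaults emulate a repeat-rich, variant-dense target in a 50 kb
    two-chromosome genome at 46% GC: four repeat families whose first copies
    tile ~80% of a 3 kb target region (divergent off-target copies
    elsewhere), variant sites at roughly one per 20 bp inside the target,
    and one 100-nt assembly-gap run outside it."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 25_000
    gc_fraction: float = 0.46
    repeat_families: tuple[RepeatFamily, ...] = (
        RepeatFamily(), RepeatFamily(), RepeatFamily(), RepeatFamily(),
    )
    gap_runs: tuple[tuple[str, int, int], ...] = (("chr1", 2_000, 100),)
    n_snps: int = 140
    n_indels: int = 12
    target_chrom: str = "chr1"
    target_start: int = 10_001
    target_stop: int = 13_000

    @property
    def target_interval(self) -> tuple[str, int, int]:
        return (self.target_chrom, self.target_start, self.target_stop)


@dataclass
class PlantedCopy:
    family: int
    copy: int
    chrom: str
    start: int  # 1-based inclusive
    stop: int
    strand: str
    identity_pct: float  # vs the family consensus, ungapped columns
    n_substitutions: int
    n_indels: int


@dataclass
class TruthTable:
    copies: list[PlantedCopy] = field(default_factory=list)
    snp_positions: list[int] = field(default_factory=list)  # on target chrom
    indel_positions: list[int] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "family\tcopy\tchrom\tstart\tstop\tstrand\tidentity_pct\t"
                "n_substitutions\tn_indels\n"
            )
            for c in self.copies:
                fh.write(
                    f"{c.family}\t{c.copy}\t{c.chrom}\t{c.start}\t{c.stop}\t"
                    f"{c.strand}\t{c.identity_pct:.2f}\t{c.n_substitutions}\t"
                    f"{c.n_indels}\n"
                )


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _mutate(
    rng: np.random.Generator, consensus: str, divergence: float, indel_rate: float
) -> tuple[str, int, int]:
    seq = list(consensus)
    subs = 0
    for i in range(len(seq)):
        if rng.random() < divergence:
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]
            subs += 1
    indels = 0
    if rng.random() < indel_rate:
        pos = int(rng.integers(5, len(seq) - 5))
        if rng.random() < 0.5:
            del seq[pos]
        else:
            seq.insert(pos, str(_BASES[rng.integers(4)]))
        indels = 1
    return "".join(seq), subs, indels


def generate_genome(spec: FixtureSpec) -> tuple[ReferenceGenome, TruthTable]:
    """Build the genome with planted repeat copies, gaps, and a truth table.

    Planted features never overlap each other, the target-interval copy is
    fully inside the target, and infeasible packing raises an error.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    chroms = {name: list(_random_seq(rng, spec.chrom_length, spec.gc_fraction))
              for name in chrom_names}
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in chrom_names}
    for chrom, start, length in spec.gap_runs:
        if start + length - 1 > spec.chrom_length:
            raise ValueError(f"gap run off the end of {chrom}")
        chroms[chrom][start - 1 : start - 1 + length] = ["N"] * length
        occupied[chrom].append((start, start + length - 1))
    tchrom, tstart, tstop = spec.target_interval

    def place(chrom: str, length: int, lo: int, hi: int) -> int:
        """Non-overlapping placement of a feature of `length` with 1-based
        start in [lo, hi]; raises after bounded retries (infeasible packing)."""
        for _ in range(200):
            start = int(rng.integers(lo, hi - length + 2))
            iv = (start, start + length - 1)
            if all(
                iv[1] < a or iv[0] > b for a, b in occupied[chrom]
            ):
                occupied[chrom].append(iv)
                return start
        raise ValueError(f"infeasible packing on {chrom}: no room for {length} nt")

    truth = TruthTable()
    n_fams = len(spec.repeat_families)
    # first copies tile the target evenly (with jitter) so random packing
    # cannot fail at high repeat coverage; later copies go anywhere outside
    # the target interval
    slot = (tstop - tstart + 1) // max(1, n_fams)
    if any(f.length + 2 > slot for f in spec.repeat_families if f.n_copies):
        raise ValueError("in-target repeat copies do not fit the target interval")
    occupied[tchrom].append((tstart, tstop))
    for fi, fam in enumerate(spec.repeat_families):
        consensus = _random_seq(rng, fam.length, spec.gc_fraction)
        for ci in range(fam.n_copies):
            seq, subs, indels = _mutate(rng, consensus, fam.divergence, fam.indel_rate)
            if ci == 0:
                chrom = tchrom
                slot_lo = tstart + fi * slot
                jitter_max = max(1, slot - len(seq) - 1)
                start = slot_lo + int(rng.integers(0, jitter_max))
                if start + len(seq) - 1 > tstop:
                    start = tstop - len(seq) + 1
                occupied[chrom].append((start, start + len(seq) - 1))
                strand = "+"
            else:
                chrom = chrom_names[int(rng.integers(spec.n_chroms))]
                start = place(chrom, len(seq), 1, spec.chrom_length)
                strand = "+" if rng.random() < 0.7 else "-"
            planted = seq if strand == "+" else revcomp(seq)
            chroms[chrom][start - 1 : start - 1 + len(seq)] = list(planted)
            n_cols = min(len(seq), len(consensus))
            ident = 100.0 * sum(
                a == b for a, b in zip(seq, consensus)
            ) / n_cols
            truth.copies.append(
                PlantedCopy(fi, ci, chrom, start, start + len(seq) - 1,
                            strand, ident, subs, indels)
            )
    genome = ReferenceGenome({n: "".join(chroms[n]) for n in chrom_names})
    return genome, truth


def generate_variants(
    spec: FixtureSpec, genome: ReferenceGenome, truth: TruthTable
) -> list[tuple[str, int, str, str, str]]:
    """Draw SNP and indel records inside the target interval.

    Returns (chrom, pos, ref, alt, class) tuples; indels carry a multi-base
    REF at a single POS (deletion encoding). Position collisions are resolved
    by re-draw; positions never fall on an N."""
    rng = np.random.default_rng(spec.seed + 1)
    tchrom, tstart, tstop = spec.target_interval
    text = genome.sequences[tchrom]
    used: set[int] = set()

    def draw(need_next_base: bool) -> int:
        for _ in range(1000):
            pos = int(rng.integers(tstart, tstop + 1))
            if pos in used or (need_next_base and pos + 1 in used):
                continue
            if text[pos - 1] == "N":
                continue
            if need_next_base and (pos + 1 > len(text) or text[pos] == "N"):
                continue
            return pos
        raise ValueError("could not place variants without collisions")

    records: list[tuple[str, int, str, str, str]] = []
    for _ in range(spec.n_snps):
        pos = draw(False)
        used.add(pos)
        ref = text[pos - 1]
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
        records.append((tchrom, pos, ref, alt, "snp"))
        truth.snp_positions.append(pos)
    for _ in range(spec.n_indels):
        pos = draw(True)
        used.add(pos)
        used.add(pos + 1)
        ref = text[pos - 1 : pos + 1]  # 2-base REF, 1-base ALT: deletion
        records.append((tchrom, pos, ref, ref[0], "indel"))
        truth.indel_positions.append(pos)
    truth.snp_positions.sort()
    truth.indel_positions.sort()
    records.sort(key=lambda r: (r[0], r[1]))
    return records


def write_vcf(
    records: list[tuple[str, int, str, str, str]],
    genome: ReferenceGenome,
    path: str | Path,
) -> None:
    """Write variant records as an uncompressed, site-only VCF v4.1."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        for name, seq in genome.sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, _cls in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def generate_fixture_set(spec: FixtureSpec, outdir: str | Path):
    """Genome FASTA + VCF + truth tables on disk; returns the in-memory trio."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(spec)
    records = generate_variants(spec, genome, truth)
    genome.write_fasta(outdir / "genome.fasta")
    write_vcf(records, genome, outdir / "variants.vcf")
    truth.to_tsv(outdir / "repeat_truth.tsv")
    return genome, truth, records
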