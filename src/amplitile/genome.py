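"""Reference genome and variant I/O, target-region extraction, masking.

Coordinates are 1-based inclusive throughout the library (BED emission
converts to 0-based half-open). Known variant sites are masked in the target
sequence as ``n`` (SNP) or ``N`` (indel) so the downstream base-composition
filter removes oligos overlapping them; assembly gaps are pre-existing runs
of ``N`` of at least ``gap_min`` characters in the reference itself.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import pysam
from Bio import SeqIO

from ._dna import gc_percent

logger = logging.getLogger(__name__)

_ALLOWED = frozenset("ACGTNacgtn")


class GenomeLoadError(ValueError):
    pass


@dataclass
class ReferenceGenome:
    """Named pseudomolecule sequences with 1-based random access."""

    sequences: dict[str, str]

    def __post_init__(self):
        for name, seq in self.sequences.items():
            if not seq:
                raise GenomeLoadError(f"empty record: {name}")

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def slice(self, name: str, start: int, stop: int) -> str:
        """Subsequence at 1-based inclusive [start, stop]."""
        if name not in self.sequences:
            raise KeyError(f"unknown sequence: {name}")
        seq = self.sequences[name]
        if not (1 <= start <= stop <= len(seq)):
            raise ValueError(
                f"coordinates {start}..{stop} out of range for {name} (1..{len(seq)})"
            )
        return seq[start - 1 : stop]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def load_genome(fasta_paths: str | Path | list[str | Path]) -> ReferenceGenome:
    """Load one or more FASTA files into an in-memory indexed genome.

    Lower-case soft-masking is uppercased (repeat masking plays no role in
    the algorithm); duplicate names, empty records and characters outside
    A/C/G/T/N are load errors listing the offenders.
    """
    if isinstance(fasta_paths, (str, Path)):
        fasta_paths = [fasta_paths]
    sequences: dict[str, str] = {}
    offenders: list[str] = []
    n_soft = 0
    for path in fasta_paths:
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in sequences:
                offenders.append(f"duplicate name {record.id!r} in {path}")
                continue
            seq = str(record.seq)
            if not seq:
                offenders.append(f"empty record {record.id!r} in {path}")
                continue
            bad = set(seq) - _ALLOWED
            if bad:
                offenders.append(
                    f"illegal characters {sorted(bad)} in record {record.id!r}"
                )
                continue
            n_soft += sum(1 for c in seq if c.islower())
            sequences[record.id] = seq.upper()
    if offenders:
        raise GenomeLoadError("; ".join(offenders))
    if not sequences:
        raise GenomeLoadError(f"no records found in {list(map(str, fasta_paths))}")
    if n_soft:
        logger.info("uppercased %d soft-masked positions on load", n_soft)
    return ReferenceGenome(sequences)


@dataclass
class VariantMask:
    """Sorted 1-based variant positions per sequence, classified snp/indel.

    A SNP and an indel recorded at the same position collapse to the indel
    (the stronger mask)."""

    snps: dict[str, list[int]] = field(default_factory=dict)
    indels: dict[str, list[int]] = field(default_factory=dict)
    n_skipped: int = 0

    def add(self, chrom: str, pos: int, kind: str) -> None:
        if kind == "indel":
            self.snps.setdefault(chrom, [])
            self.indels.setdefault(chrom, [])
            if pos in set(self._range(self.snps[chrom], pos, pos)):
                self.snps[chrom].remove(pos)
            if pos not in set(self._range(self.indels[chrom], pos, pos)):
                self._insert(self.indels[chrom], pos)
        else:
            self.indels.setdefault(chrom, [])
            self.snps.setdefault(chrom, [])
            if pos in set(self._range(self.indels[chrom], pos, pos)):
                return  # indel wins on collision
            if pos not in set(self._range(self.snps[chrom], pos, pos)):
                self._insert(self.snps[chrom], pos)

    @staticmethod
    def _insert(lst: list[int], pos: int) -> None:
        lst.insert(bisect_left(lst, pos), pos)

    @staticmethod
    def _range(lst: list[int], start: int, stop: int) -> list[int]:
        return lst[bisect_left(lst, start) : bisect_right(lst, stop)]

    def snps_in(self, chrom: str, start: int, stop: int) -> list[int]:
        return self._range(self.snps.get(chrom, []), start, stop)

    def indels_in(self, chrom: str, start: int, stop: int) -> list[int]:
        return self._range(self.indels.get(chrom, []), start, stop)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tclass\n")
            for chrom in sorted(set(self.snps) | set(self.indels)):
                merged = [(p, "snp") for p in self.snps.get(chrom, [])]
                merged += [(p, "indel") for p in self.indels.get(chrom, [])]
                for pos, kind in sorted(merged):
                    fh.write(f"{chrom}\t{pos}\t{kind}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantMask":
        mask = cls()
        with open(path) as fh:
            header = fh.readline()
            if header.strip() != "chrom\tpos\tclass":
                raise ValueError(f"unexpected variant table header: {header!r}")
            for line in fh:
                chrom, pos, kind = line.rstrip("\n").split("\t")
                mask.add(chrom, int(pos), kind)
        return mask


def convert_variants(
    vcf_path: str | Path, genome: ReferenceGenome | None = None
) -> VariantMask:
    """Convert a VCF (v4.0/4.1) into a compact position/class mask.

    SNP: REF and every ALT of length 1. Anything else (multi-base REF or ALT,
    symbolic alleles) is an indel recorded at its single POS, matching the
    single-position indel encoding of the variant resource the masking model
    expects. Malformed records are skipped with a logged count.
    """
    mask = VariantMask()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            try:
                chrom, pos = rec.chrom, rec.pos
                ref = rec.ref or ""
                alts = [a for a in (rec.alts or ()) if a is not None]
                if genome is not None:
                    if chrom not in genome.sequences:
                        raise ValueError(f"unknown sequence {chrom!r} in VCF")
                    if pos > genome.length(chrom):
                        raise ValueError(
                            f"VCF position {chrom}:{pos} past sequence end"
                        )
                if not ref or not alts:
                    mask.n_skipped += 1
                    continue
                simple = len(ref) == 1 and all(
                    len(a) == 1 and a.isalpha() for a in alts
                )
                mask.add(chrom, pos, "snp" if simple else "indel")
            except ValueError:
                raise
            except Exception:  # malformed record: skip, count
                mask.n_skipped += 1
    if mask.n_skipped:
        logger.warning("skipped %d malformed VCF records", mask.n_skipped)
    return mask


@dataclass(frozen=True)
class RegionSummary:
    gc_pct: float
    n_snps: int
    n_indels: int
    gap_runs: tuple[tuple[int, int], ...]  # genomic 1-based inclusive intervals


@dataclass(frozen=True)
class TargetRegion:
    chrom: str
    start: int
    stop: int
    raw_seq: str
    masked_seq: str
    summary: RegionSummary

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    def to_local(self, genomic_pos: int) -> int:
        """1-based position within the region for a genomic coordinate."""
        return genomic_pos - self.start + 1


def _gap_runs(raw_seq: str, start: int, gap_min: int) -> tuple[tuple[int, int], ...]:
    runs = []
    i = 0
    n = len(raw_seq)
    while i < n:
        if raw_seq[i] == "N":
            j = i
            while j < n and raw_seq[j] == "N":
                j += 1
            if j - i >= gap_min:
                runs.append((start + i, start + j - 1))
            i = j
        else:
            i += 1
    return tuple(runs)


def extract_masked_region(
    genome: ReferenceGenome,
    chrom: str,
    start: int,
    stop: int,
    mask: VariantMask | None = None,
    mask_enabled: bool = True,
    gap_min: int = 100,
) -> TargetRegion:
    """Extract [start, stop] and mask variant sites ('n' SNP, 'N' indel).

    Assembly N-runs of length >= gap_min in the raw sequence are reported as
    gap intervals; GC% is computed over unmasked A/C/G/T positions only.
    """
    raw = genome.slice(chrom, start, stop)
    masked = raw
    snps: list[int] = []
    indels: list[int] = []
    if mask is not None:
        snps = mask.snps_in(chrom, start, stop)
        indels = mask.indels_in(chrom, start, stop)
        if mask_enabled and (snps or indels):
            chars = list(raw)
            for p in snps:
                chars[p - start] = "n"
            for p in indels:
                chars[p - start] = "N"
            masked = "".join(chars)
    summary = RegionSummary(
        gc_pct=gc_percent(masked),
        n_snps=len(snps),
        n_indels=len(indels),
        gap_runs=_gap_runs(raw, start, gap_min),
    )
    return TargetRegion(chrom, start, stop, raw, masked, summary)
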