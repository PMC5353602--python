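"""Genome-wide discovery of imperfect off-target binding sites.

A low-stringency seed-and-extend scanner: every exact ``word_size`` match
(default 7, both strands) seeds a windowed local alignment of the primer
against the surrounding genomic sequence (match +1, mismatch -1, gap
open/extend -2), and local alignments with percent identity at or above the
floor (default 70) are reported as :class:`LocalHit` records. The primer's
own target site is excluded. Because every candidate locus sharing an exact
word with the primer is examined, the scanner is complete for sites with a
shared seed at fixture-genome scale; per-subject and subject-count caps are
available to emulate capped heuristic searches but default to off.

Hits can also be round-tripped through a BLASTN-like tabular format with
aligned-sequence columns, so an external search tool can stand in for the
internal scanner on large genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from ._dna import revcomp
from .design import CandidateOligo
from .genome import ReferenceGenome

logger = logging.getLogger(__name__)

TABULAR_COLUMNS = (
    "qseqid", "sseqid", "sstrand", "sstart", "send",
    "qstart", "qend", "qseq_aln", "sseq_aln", "pident",
)


@dataclass(frozen=True)
class ScanParams:
    word_size: int = 7
    min_identity: float = 70.0
    max_hits_per_subject: int | None = None
    max_subjects: int | None = None
    window_pad: int = 12  # extension slack around a seeded window


@dataclass(frozen=True)
class LocalHit:
    """One local alignment between a primer and an off-target locus.

    ``subject_start``/``subject_stop`` are 1-based on the + strand
    (start <= stop). ``aligned_primer``/``aligned_subject`` are the gapped
    alignment rows written in primer orientation, so equal characters are
    matches; for '-' strand hits ``aligned_subject`` is therefore the
    reverse complement of the + strand text.
    """

    primer_id: str
    subject_name: str
    subject_strand: str  # '+' or '-'
    subject_start: int
    subject_stop: int
    primer_aln_start: int  # 1-based within primer, 5'->3'
    primer_aln_stop: int
    aligned_primer: str
    aligned_subject: str
    percent_identity: float

    def __post_init__(self):
        if len(self.aligned_primer) != len(self.aligned_subject):
            raise ValueError("aligned rows differ in length")
        for a, b in zip(self.aligned_primer, self.aligned_subject):
            if a == "-" and b == "-":
                raise ValueError("gap aligned to gap")


def _aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
    )


class KmerIndex:
    """Exact k-mer positions (0-based) over the + strand of each sequence."""

    def __init__(self, genome: ReferenceGenome, k: int):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, text in genome.sequences.items():
            for i in range(len(text) - k + 1):
                kmer = text[i : i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((name, i))

    def positions(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for lo, hi in sorted(windows):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(w) for w in merged]


def _longest_match_run(qrow: str, srow: str) -> int:
    run = cur = 0
    for a, b in zip(qrow, srow):
        cur = cur + 1 if (a == b and a != "-") else 0
        run = max(run, cur)
    return run


def find_local_hits(
    primer: CandidateOligo,
    genome: ReferenceGenome,
    params: ScanParams = ScanParams(),
    index: KmerIndex | None = None,
) -> list[LocalHit]:
    """All off-target local-alignment hits for one primer.

    Every returned hit shares an exact ``word_size`` run with the subject,
    has identity >= ``min_identity`` over its local alignment, and does not
    overlap the primer's own target interval on the binding strand. Ordering
    is deterministic: (subject, + strand start, stop, strand).
    """
    if index is None:
        index = KmerIndex(genome, params.word_size)
    elif index.k != params.word_size:
        raise ValueError("index word size does not match params.word_size")
    L = primer.length
    pad = params.window_pad
    aligner = _aligner()
    own_lo, own_hi = primer.genomic_interval
    own_strand = "+" if primer.strand == "F" else "-"

    hits: dict[tuple, LocalHit] = {}
    for strand in ("+", "-"):
        query = primer.sequence if strand == "+" else revcomp(primer.sequence)
        # seed windows on the + strand text
        windows: dict[str, list[tuple[int, int]]] = {}
        for off in range(L - params.word_size + 1):
            for chrom, pos in index.positions(query[off : off + params.word_size]):
                lo = max(0, pos - off - pad)
                hi = min(genome.length(chrom), pos - off + L + pad)
                windows.setdefault(chrom, []).append((lo, hi))
        for chrom, wins in windows.items():
            text = genome.sequences[chrom]
            for lo, hi in _merge_windows(wins):
                sub = text[lo:hi]
                if strand == "-":
                    sub = revcomp(sub)
                alignments = aligner.align(sub, primer.sequence)
                if len(alignments) == 0 or alignments.score <= 0:
                    continue
                aln = alignments[0]
                srow, qrow = aln[0], aln[1]
                cols = len(srow)
                matches = sum(
                    a == b and a != "-" for a, b in zip(qrow, srow)
                )
                pident = 100.0 * matches / cols
                if pident < params.min_identity:
                    continue
                if _longest_match_run(qrow, srow) < params.word_size:
                    continue
                sblocks, qblocks = aln.aligned
                s0, s1 = sblocks[0][0], sblocks[-1][1]  # 0-based, half-open, in sub
                q0, q1 = qblocks[0][0], qblocks[-1][1]
                if strand == "+":
                    plus_start, plus_stop = lo + s0 + 1, lo + s1
                else:
                    # sub was reverse-complemented: flip local coords
                    plus_start = lo + (len(sub) - s1) + 1
                    plus_stop = lo + (len(sub) - s0)
                if (
                    chrom == primer.chrom
                    and strand == own_strand
                    and plus_start <= own_hi
                    and plus_stop >= own_lo
                ):
                    continue  # on-target
                key = (chrom, strand, plus_start, plus_stop)
                if key in hits:
                    continue
                hits[key] = LocalHit(
                    primer_id=primer.id,
                    subject_name=chrom,
                    subject_strand=strand,
                    subject_start=int(plus_start),
                    subject_stop=int(plus_stop),
                    primer_aln_start=int(q0) + 1,
                    primer_aln_stop=int(q1),
                    aligned_primer=qrow,
                    aligned_subject=srow,
                    # stored at the tabular format's precision so that
                    # export -> import is the identity
                    percent_identity=round(pident, 3),
                )

    out = sorted(
        hits.values(),
        key=lambda h: (h.subject_name, h.subject_start, h.subject_stop, h.subject_strand),
    )
    if params.max_hits_per_subject is not None:
        capped: list[LocalHit] = []
        per: dict[str, list[LocalHit]] = {}
        for h in out:
            per.setdefault(h.subject_name, []).append(h)
        for name in sorted(per):
            ranked = sorted(
                per[name], key=lambda h: (-h.percent_identity, h.subject_start)
            )
            capped.extend(ranked[: params.max_hits_per_subject])
        out = sorted(
            capped,
            key=lambda h: (h.subject_name, h.subject_start, h.subject_stop, h.subject_strand),
        )
    if params.max_subjects is not None:
        keep = sorted({h.subject_name for h in out})[: params.max_subjects]
        out = [h for h in out if h.subject_name in set(keep)]
    return out


def export_hits(hits: list[LocalHit], path) -> None:
    """Write hits in the BLASTN-like tabular format (documented column order)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TABULAR_COLUMNS) + "\n")
        for h in hits:
            # minus-strand convention on export: subject coordinates reversed
            sstart, send = (
                (h.subject_start, h.subject_stop)
                if h.subject_strand == "+"
                else (h.subject_stop, h.subject_start)
            )
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.primer_id, h.subject_name, "plus" if h.subject_strand == "+" else "minus",
                        sstart, send, h.primer_aln_start, h.primer_aln_stop,
                        h.aligned_primer, h.aligned_subject, f"{h.percent_identity:.3f}",
                    )
                )
                + "\n"
            )


def import_external_hits(
    tabular_path, primer_catalog: dict[str, CandidateOligo]
) -> list[LocalHit]:
    """Parse tabular hits produced by :func:`export_hits` or an external
    aligner. Rows with unknown primer ids or malformed fields are rejected
    and counted; reversed subject coordinates are normalized to + strand
    coordinates with the strand flag set."""
    hits: list[LocalHit] = []
    n_bad = 0
    with open(tabular_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TABULAR_COLUMNS:
            raise ValueError(f"unexpected hit-table header: {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            try:
                if len(fields) != len(TABULAR_COLUMNS):
                    raise ValueError("wrong column count")
                (qseqid, sseqid, sstrand, sstart, send,
                 qstart, qend, qaln, saln, pident) = fields
                if qseqid not in primer_catalog:
                    raise ValueError(f"unknown primer id {qseqid!r}")
                sstart, send = int(sstart), int(send)
                strand = "+"
                if sstrand in ("minus", "-") or sstart > send:
                    strand = "-"
                    if sstart > send:
                        sstart, send = send, sstart
                hits.append(
                    LocalHit(
                        primer_id=qseqid,
                        subject_name=sseqid,
                        subject_strand=strand,
                        subject_start=sstart,
                        subject_stop=send,
                        primer_aln_start=int(qstart),
                        primer_aln_stop=int(qend),
                        aligned_primer=qaln,
                        aligned_subject=saln,
                        percent_identity=float(pident),
                    )
                )
            except (ValueError, IndexError) as exc:
                n_bad += 1
                logger.warning("rejected hit row %d: %s", lineno, exc)
    if n_bad:
        logger.warning("rejected %d malformed hit rows", n_bad)
    return hits
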