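"""Unique oligonucleotide design (UOD).

Enumerates every oligo of every length in a target region on both strands
(1-bp sliding window per length) and applies the ordered filter cascade:

1. sequence features — base composition (non-ACGT, which also removes
   variant-masked oligos), GC range, A/T 3'-end, GC clamp, short repeats;
2. hybridization — on-target Tm range, hairpin and homodimer Tm within a
   margin of the on-target Tm;
3. genome-wide exact-match uniqueness (both strands, complete string search).

Each filter is a pure predicate producing category flags, so the final pass
set is independent of evaluation order; the cascade order only defines which
filters are evaluated for accounting and runtime.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field as dc_field

from . import thermo
from ._dna import BASES, gc_percent, revcomp
from .genome import ReferenceGenome, TargetRegion

logger = logging.getLogger(__name__)

SEQUENCE_FEATURE_FLAGS = ("non_acgt", "gc_range", "at_end", "gc_clamp", "repeats")
HYBRIDIZATION_FLAGS = ("tm_range", "hairpin", "homodimer")
EXACT_MATCH_FLAGS = ("off_target_exact",)


@dataclass(frozen=True)
class UODSettings:
    """Oligo enumeration and filter settings (study defaults)."""

    length_min: int = 18
    length_max: int = 27
    gc_min: float = 40.0
    gc_max: float = 60.0
    tm_min: float = 64.0
    tm_max: float = 74.0
    at_end_filter_enabled: bool = True
    gc_clamp_enabled: bool = True
    polymorphism_filter_enabled: bool = True
    repeat_unit_max: int = 4  # >= this many consecutive 1/2-nt units flags
    self_structure_margin: float = 20.0  # degC below on-target Tm
    flank_size: int | None = None
    flanking_mode: bool = False

    def __post_init__(self):
        if self.length_min < 2:
            raise ValueError("length_min must be >= 2")
        if self.length_max < self.length_min:
            raise ValueError("empty oligo length range")
        if self.gc_max < self.gc_min or self.tm_max < self.tm_min:
            raise ValueError("empty GC or Tm range")


@dataclass
class CandidateOligo:
    """One enumerated primer with position/strand and filter annotations.

    ``five_prime_pos``/``three_prime_pos`` are genomic (1-based); forward
    primers run 5'<3' in genome coordinates, reverse primers the opposite.
    """

    id: str
    sequence: str  # 5'->3'
    strand: str  # 'F' or 'R'
    five_prime_pos: int
    three_prime_pos: int
    chrom: str
    gc_pct: float = 0.0
    tm_on_target: float | None = None
    hairpin_tm: float | None = None
    homodimer_tm: float | None = None
    filter_flags: set[str] = dc_field(default_factory=set)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def passed(self) -> bool:
        return not self.filter_flags

    @property
    def genomic_interval(self) -> tuple[int, int]:
        lo, hi = sorted((self.five_prime_pos, self.three_prime_pos))
        return lo, hi


def oligo_id(chrom: str, five_prime_pos: int, length: int, strand: str) -> str:
    return f"TA_{chrom}_{five_prime_pos}_{length}_{strand}"


def enumerate_oligos(region: TargetRegion, settings: UODSettings):
    """Yield every oligo of every length on both strands (unfiltered).

    Enumeration reads the variant-masked sequence when the polymorphism
    filter is enabled (masked oligos then fail base composition), otherwise
    the raw reference sequence. In flanking mode only forward oligos whose
    3' end is at or before the locus start and reverse oligos whose 3' end is
    at or after the locus stop, within ``flank_size`` of the locus, are
    yielded.
    """
    text = region.masked_seq if settings.polymorphism_filter_enabled else region.raw_seq
    n = len(text)
    if n < settings.length_min:
        logger.warning(
            "region %s:%d-%d shorter than length_min=%d; no oligos",
            region.chrom, region.start, region.stop, settings.length_min,
        )
        return
    flanking = settings.flanking_mode
    if flanking and settings.flank_size is None:
        raise ValueError("flanking_mode requires flank_size")
    for L in range(settings.length_min, settings.length_max + 1):
        for off in range(0, n - L + 1):
            gstart = region.start + off          # genomic 5' of + strand window
            gstop = gstart + L - 1
            window = text[off : off + L]
            if flanking:
                lo = region.start + settings.flank_size
                hi = region.stop - settings.flank_size
                # locus = region minus the two flanks
                if gstop <= lo:  # forward primer 3' end at/left of locus start
                    yield _make(region.chrom, window, "F", gstart, gstop)
                if gstart >= hi:  # reverse primer 3' end at/right of locus stop
                    yield _make(region.chrom, revcomp(window), "R", gstop, gstart)
                continue
            yield _make(region.chrom, window, "F", gstart, gstop)
            yield _make(region.chrom, revcomp(window), "R", gstop, gstart)


def _make(chrom, seq, strand, five, three):
    return CandidateOligo(
        id=oligo_id(chrom, five, len(seq), strand),
        sequence=seq,
        strand=strand,
        five_prime_pos=five,
        three_prime_pos=three,
        chrom=chrom,
        gc_pct=gc_percent(seq),
    )


def _repeat_pattern(units: int) -> re.Pattern:
    mono = rf"([ACGT])\1{{{units - 1},}}"
    dinucs = "|".join(
        rf"(?:{x}{y}){{{units},}}"
        for x in "ACGT" for y in "ACGT" if x != y
    )
    return re.compile(f"{mono}|{dinucs}")


_REPEAT_CACHE: dict[int, re.Pattern] = {}


def sequence_feature_filter(oligo: CandidateOligo, settings: UODSettings) -> set[str]:
    """Flags from {non_acgt, gc_range, at_end, gc_clamp, repeats}.

    GC clamp: more than three G/C among the last five 3' bases. Repeats:
    ``repeat_unit_max`` or more consecutive copies of a 1-nt or 2-nt unit.
    A/T-end: 3'-terminal base is A or T. GC bounds are inclusive.
    """
    flags: set[str] = set()
    seq = oligo.sequence
    if not set(seq) <= BASES:
        flags.add("non_acgt")
        return flags  # feature rules below are defined on plain bases only
    if not settings.gc_min <= oligo.gc_pct <= settings.gc_max:
        flags.add("gc_range")
    if settings.at_end_filter_enabled and seq[-1] in "AT":
        flags.add("at_end")
    if settings.gc_clamp_enabled:
        tail = seq[-5:]
        if tail.count("G") + tail.count("C") > 3:
            flags.add("gc_clamp")
    pat = _REPEAT_CACHE.get(settings.repeat_unit_max)
    if pat is None:
        pat = _REPEAT_CACHE[settings.repeat_unit_max] = _repeat_pattern(
            settings.repeat_unit_max
        )
    if pat.search(seq):
        flags.add("repeats")
    return flags


def hybridization_filter(
    oligo: CandidateOligo,
    settings: UODSettings,
    conditions: thermo.ReactionConditions = thermo.DEFAULT_CONDITIONS,
    table: thermo.NNParameterTable | None = None,
    compute_structures: bool = True,
) -> set[str]:
    """Flags from {tm_range, hairpin, homodimer}; fills Tm annotations.

    The Tm range is inclusive at both ends. A structure flag is raised when
    the hairpin or homodimer Tm is above (on-target Tm − margin).
    """
    flags: set[str] = set()
    seq = oligo.sequence
    if not set(seq) <= BASES:
        # masked/ambiguous oligo: no physical on-target duplex exists; the
        # rule must stay a total predicate so cascade order cannot matter
        oligo.tm_on_target = thermo.NO_STRUCTURE_TM
        return {"tm_range"}
    oligo.tm_on_target = thermo.duplex_tm(seq, seq, conditions, table)
    if not settings.tm_min <= oligo.tm_on_target <= settings.tm_max:
        flags.add("tm_range")
        if not compute_structures:
            return flags
    threshold = oligo.tm_on_target - settings.self_structure_margin
    oligo.hairpin_tm = thermo.self_structure_tm(seq, "hairpin", conditions, table)
    if oligo.hairpin_tm > threshold:
        flags.add("hairpin")
    oligo.homodimer_tm = thermo.self_structure_tm(seq, "homodimer", conditions, table)
    if oligo.homodimer_tm > threshold:
        flags.add("homodimer")
    return flags


def genome_occurrences(genome: ReferenceGenome, seq: str):
    """All occurrences of ``seq`` or its reverse complement in the genome.

    Yields (chrom, start, stop, strand) with 1-based inclusive coordinates on
    the + strand; strand '+' for a direct match of ``seq``, '-' for a match
    of its reverse complement. A palindromic sequence yields one record per
    site (the two strand readings are the same physical locus).
    """
    rc = revcomp(seq)
    queries = [(seq, "+")] if seq == rc else [(seq, "+"), (rc, "-")]
    for chrom, text in genome.sequences.items():
        for query, strand in queries:
            i = text.find(query)
            while i != -1:
                yield (chrom, i + 1, i + len(query), strand)
                i = text.find(query, i + 1)


def exact_match_filter(
    oligo: CandidateOligo, genome: ReferenceGenome
) -> set[str]:
    """Flag {off_target_exact} iff the oligo (or its reverse complement)
    occurs anywhere in the genome outside its own target-site interval.

    Exhaustive string search over both strands: guaranteed-complete, unlike
    capped heuristic searches which only need to find one extra match.
    """
    lo, hi = oligo.genomic_interval
    for chrom, start, stop, _strand in genome_occurrences(genome, oligo.sequence):
        if chrom == oligo.chrom and start == lo and stop == hi:
            continue  # own site
        return {"off_target_exact"}
    return set()


@dataclass
class UODResult:
    candidates: list[CandidateOligo]  # every enumerated oligo, with flags
    accounting: dict[str, int]

    @property
    def passing(self) -> list[CandidateOligo]:
        return [o for o in self.candidates if o.passed]


def run_uod(
    region: TargetRegion,
    genome: ReferenceGenome,
    settings: UODSettings = UODSettings(),
    conditions: thermo.ReactionConditions = thermo.DEFAULT_CONDITIONS,
    table: thermo.NNParameterTable | None = None,
) -> UODResult:
    """Full UOD cascade with per-category accounting.

    Accounting is reported in the fixed order sequence features first, then
    interactions (Tm/structure), then exact match; later filters are only
    evaluated for oligos passing the earlier stages (the pass set itself is
    order-independent because every filter is a pure predicate).
    """
    table = table or thermo.default_table()
    oligos = list(enumerate_oligos(region, settings))
    acct: dict[str, int] = {"enumerated": len(oligos)}
    for f in SEQUENCE_FEATURE_FLAGS + HYBRIDIZATION_FLAGS + EXACT_MATCH_FLAGS:
        acct[f] = 0

    stage2: list[CandidateOligo] = []
    for o in oligos:
        flags = sequence_feature_filter(o, settings)
        o.filter_flags |= flags
        for f in flags:
            acct[f] += 1
        if not flags:
            stage2.append(o)
    acct["pass_sequence_features"] = len(stage2)

    stage3: list[CandidateOligo] = []
    for o in stage2:
        flags = hybridization_filter(o, settings, conditions, table)
        o.filter_flags |= flags
        for f in flags:
            acct[f] += 1
        if not flags:
            stage3.append(o)
    acct["pass_hybridization"] = len(stage3)

    n_pass = 0
    for o in stage3:
        flags = exact_match_filter(o, genome)
        o.filter_flags |= flags
        for f in flags:
            acct[f] += 1
        n_pass += not flags
    acct["pass_all"] = n_pass
    return UODResult(oligos, acct)
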