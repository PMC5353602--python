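"""Priming-specificity evaluation: thermoalignments and misprime Tm.

A *thermoalignment* is a full-length, ungapped pairing of a primer with a
contiguous genomic window, on which a physically meaningful Tm can be
computed. Local alignments are typically truncated and may contain gaps;
real primer-template annealing is full-length and gapless. The conversion
end-fills truncated alignments with the missing genomic bases and removes
gaps by shifting bases toward the primer's 3' end (primer gaps) or the
template's 5' end (template gaps), preserving strandedness. The net effect,
and the implemented contract: the template window is the contiguous genomic
window of exactly primer length that anchors the primer's 3'-most aligned
base at its hit-assigned template coordinate. Local alignments start and end
on matched columns, so that anchor is always a real base pairing.

Per primer, off-target thermoalignment Tms are aggregated into a misprime
profile (maximum and 90th-percentile Tm); alignments with a mismatch at the
3'-terminal nucleotide are excluded from aggregation because such sites do
not prime under standard conditions, and the fraction of alignments with any
mismatch in the last five 3' bases is recorded but never used for filtering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from . import thermo
from ._dna import revcomp
from .design import CandidateOligo
from .genome import ReferenceGenome
from .scan import LocalHit

logger = logging.getLogger(__name__)


@dataclass
class ThermoAlignment:
    """Full-length ungapped primer-vs-genomic-window pairing.

    ``template_primer_frame`` is the genomic window rewritten in primer
    orientation so column i pairs primer[i] and a match is equality;
    re-extracting the stored window from the genome reproduces it exactly.
    Mismatch positions are 1-based from the primer 5' end.
    """

    primer_id: str
    primer_seq: str
    template_primer_frame: str
    subject_name: str
    subject_strand: str
    template_window_start: int  # + strand, 1-based inclusive
    template_window_stop: int
    mismatch_positions: tuple[int, ...]
    has_3prime_terminal_mismatch: bool
    n_mismatches_last5: int
    tm_offtarget: float | None = None

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


@dataclass
class MisprimeProfile:
    """Per-primer aggregation of off-target thermoalignment Tms."""

    primer_id: str
    tm_on_target: float
    n_hits_scored: int
    tm_offtarget_max: float  # -inf when no scoreable hit exists
    tm_offtarget_p90: float
    frac_hits_with_last5_mismatch: float
    pass_specificity: bool = False


def build_thermoalignment(
    hit: LocalHit, primer: CandidateOligo, genome: ReferenceGenome
) -> ThermoAlignment | None:
    """Convert a local hit into a full-length ungapped thermoalignment.

    Returns None (with a logged reason) when the full-length window would
    run off the subject sequence; boundary sites cannot form a full-length
    template. The primer sequence itself is never altered.
    """
    L = primer.length
    qend = hit.primer_aln_stop
    # The 3'-most aligned primer base pairs the orientation-last subject base:
    # highest + coordinate for '+' hits, lowest for '-' hits.
    if hit.subject_strand == "+":
        anchor = hit.subject_stop
        win_start = anchor + 1 - qend
        win_stop = anchor + (L - qend)
    else:
        anchor = hit.subject_start
        win_start = anchor - (L - qend)
        win_stop = anchor + qend - 1
    chrom_len = genome.length(hit.subject_name)
    if win_start < 1 or win_stop > chrom_len:
        logger.info(
            "dropped hit %s @ %s:%d-%d: full-length window %d..%d off subject end",
            hit.primer_id, hit.subject_name, hit.subject_start, hit.subject_stop,
            win_start, win_stop,
        )
        return None
    window = genome.slice(hit.subject_name, win_start, win_stop)
    frame = window if hit.subject_strand == "+" else revcomp(window)
    p = primer.sequence
    mismatches = tuple(
        i + 1 for i, (a, b) in enumerate(zip(p, frame)) if a != b
    )
    return ThermoAlignment(
        primer_id=primer.id,
        primer_seq=p,
        template_primer_frame=frame,
        subject_name=hit.subject_name,
        subject_strand=hit.subject_strand,
        template_window_start=win_start,
        template_window_stop=win_stop,
        mismatch_positions=mismatches,
        has_3prime_terminal_mismatch=bool(mismatches) and mismatches[-1] == L,
        n_mismatches_last5=sum(1 for m in mismatches if m > L - 5),
    )


def misprime_tm(
    ta: ThermoAlignment,
    conditions: thermo.ReactionConditions = thermo.DEFAULT_CONDITIONS,
    table: thermo.NNParameterTable | None = None,
) -> float:
    """Tm of a thermoalignment with mismatch parameters at mismatch columns.

    Unparameterized steps (adjacent mismatches, ambiguous template bases)
    contribute a flagged zero pseudo-step; alignments too destabilized for a
    two-state melting solution report -inf, never NaN. The result is stored
    on the thermoalignment.
    """
    tm = thermo.duplex_tm(
        ta.primer_seq, ta.template_primer_frame, conditions, table, strict=False
    )
    if tm == thermo.NO_STRUCTURE_TM:
        tm = -math.inf
    ta.tm_offtarget = tm
    return tm


def nearest_rank_percentile(values: list[float], q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th order statistic."""
    if not values:
        raise ValueError("empty sample")
    ordered = sorted(values)
    rank = max(1, math.ceil(q * len(ordered)))
    return ordered[rank - 1]


def misprime_profile(
    primer: CandidateOligo,
    thermoalignments: list[ThermoAlignment],
    conditions: thermo.ReactionConditions = thermo.DEFAULT_CONDITIONS,
    table: thermo.NNParameterTable | None = None,
) -> MisprimeProfile:
    """Aggregate per-primer misprime statistics.

    Thermoalignments with a 3'-terminal mismatch are excluded from Tm
    aggregation; the last-5-mismatch fraction is computed over all
    alignments. With zero scored hits the max is -inf (trivially specific).
    """
    for ta in thermoalignments:
        if ta.primer_id != primer.id:
            raise ValueError(
                f"thermoalignment for {ta.primer_id} given to {primer.id}"
            )
        if ta.tm_offtarget is None:
            misprime_tm(ta, conditions, table)
    if primer.tm_on_target is None:
        primer.tm_on_target = thermo.duplex_tm(
            primer.sequence, primer.sequence, conditions, table
        )
    scored = [
        ta.tm_offtarget
        for ta in thermoalignments
        if not ta.has_3prime_terminal_mismatch
    ]
    n_all = len(thermoalignments)
    frac5 = (
        sum(1 for ta in thermoalignments if ta.n_mismatches_last5 > 0) / n_all
        if n_all
        else 0.0
    )
    if scored:
        tm_max = max(scored)
        tm_p90 = nearest_rank_percentile(scored, 0.9)
    else:
        tm_max = tm_p90 = -math.inf
    return MisprimeProfile(
        primer_id=primer.id,
        tm_on_target=primer.tm_on_target,
        n_hits_scored=len(scored),
        tm_offtarget_max=tm_max,
        tm_offtarget_p90=tm_p90,
        frac_hits_with_last5_mismatch=frac5,
    )


def specificity_filter(
    profile: MisprimeProfile, threshold_celsius: float = 10.0
) -> bool:
    """Pass iff on-target Tm >= max off-target Tm + threshold.

    Monotone in the threshold: relaxing it never shrinks the pass set.
    The result is stored on the profile.
    """
    ok = profile.tm_on_target >= profile.tm_offtarget_max + threshold_celsius
    profile.pass_specificity = ok
    return ok
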