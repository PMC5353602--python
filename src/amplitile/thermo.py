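"""Nearest-neighbor DNA hybridization thermodynamics.

Implements the two-state nearest-neighbor model for duplex stability:
total enthalpy/entropy as a sum over adjacent base-pair doublet steps plus
initiation terms, a sodium-equivalent salt adjustment of the entropy, and the
melting temperature

    Tm(K) = dH * 1000 / (dS_salt_adjusted + R * ln(C_T / x))

where C_T is total strand concentration and x is 4 for non-self-complementary
duplexes. Watson-Crick steps and single-internal-mismatch steps are read from
the packaged parameter table (unified WC set plus the G.T, G.A, A.C, C.T and
identical-base mismatch sets). Secondary structure (hairpin, homodimer,
heterodimer) is evaluated with a deliberately simple exhaustive engine:
stems of >= 3 bp with loops of 3-30 nt for hairpins, and every ungapped
offset alignment for dimers.

Sequence conventions
--------------------
A duplex is given as (primer, template_in_primer_frame): both 5'->3' strings
of equal length where column i of the template pairs column i of the primer
and a Watson-Crick match is *equality* (the frame is the genomic strand the
primer is identical to when perfectly matched; the physical bottom strand is
its complement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

from ._dna import BASES, complement, revcomp

GAS_CONSTANT_R = 1.9872  # cal/(K*mol)

#: Tm reported when no stable secondary structure exists; far below any
#: on-target Tm minus the structure margin, so it never trips a filter.
NO_STRUCTURE_TM = -273.15

#: dG reported when two sequences form no scoreable dimer at any offset.
NO_STRUCTURE_DG = 0.0


class UnparameterizedStepError(ValueError):
    """A doublet step with no tabulated parameters (e.g. adjacent mismatches)."""

    def __init__(self, step: str, position: int):
        self.step = step
        self.position = position
        super().__init__(
            f"unparameterized step {step!r} at primer position {position}"
        )


class NonPhysicalDuplexError(ValueError):
    """Tm denominator is non-negative: the two-state model has no solution."""


@dataclass(frozen=True)
class ReactionConditions:
    """PCR buffer and strand concentrations used for Tm prediction.

    Defaults are the study conditions: 50 mM monovalent cation, 1.5 mM Mg2+,
    0.8 mM total dNTPs, 0.25 uM total strand concentration, x = 4.
    """

    monovalent_mM: float = 50.0
    divalent_mg_mM: float = 1.5
    dntp_mM: float = 0.8
    total_strand_conc: float = 0.25e-6  # molar (C_T)
    symmetry_factor: int = 4  # x: 4 non-self-complementary, 1 self-complementary
    gas_constant: float = GAS_CONSTANT_R

    def __post_init__(self):
        for name in ("monovalent_mM", "divalent_mg_mM", "dntp_mM", "total_strand_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.symmetry_factor not in (1, 4):
            raise ValueError("symmetry_factor must be 1 or 4")


DEFAULT_CONDITIONS = ReactionConditions()


@dataclass(frozen=True)
class DuplexProfile:
    """Summed dH (kcal/mol) / dS (cal/K/mol) for one aligned duplex, pre-salt."""

    delta_h: float
    delta_s: float
    n_phosphates: int  # 2*(length-1) per duplex; dS salt term uses n/2
    unparameterized_positions: tuple[int, ...] = ()

    @property
    def flagged(self) -> bool:
        return bool(self.unparameterized_positions)


class NNParameterTable:
    """Doublet-step parameter table with strand-symmetric lookup.

    Keys are ``XY/WZ``: top strand 5'->3' and bottom strand 3'->5' as
    written left to right, so X pairs W and Y pairs Z. Reading the same step
    from the opposite strand gives ``ZW/YX``; the lookup tries both.
    """

    def __init__(self, entries: dict[str, tuple[float, float]], sources: dict[str, str]):
        self.entries = entries
        self.sources = sources

    @classmethod
    def load_default(cls) -> "NNParameterTable":
        path = resources.files("amplitile").joinpath("data/nn_params.tsv")
        entries: dict[str, tuple[float, float]] = {}
        sources: dict[str, str] = {}
        with path.open() as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("step\t"):
                    continue
                key, dh, ds, src = line.rstrip("\n").split("\t")
                entries[key] = (float(dh), float(ds))
                sources[key] = src
        return cls(entries, sources)

    def step(self, top2: str, bottom2: str) -> tuple[float, float] | None:
        """Parameters for one doublet: top strand 5'->3', bottom 3'->5'
        (actual bases). Returns None if the step is not tabulated."""
        key = top2 + "/" + bottom2
        hit = self.entries.get(key)
        if hit is None:
            hit = self.entries.get(key[::-1])
        return hit

    def initiation(self, which: str) -> tuple[float, float]:
        return self.entries[which]


_DEFAULT_TABLE: NNParameterTable | None = None


def default_table() -> NNParameterTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = NNParameterTable.load_default()
    return _DEFAULT_TABLE


def _terminal_initiation(table, primer_base: str, frame_base: str):
    """Initiation term for one duplex end.

    For a matched terminal pair this is the tabulated per-terminal A.T or G.C
    term. Terminal mismatches carry no published initiation parameters; the
    primer base class decides (5'-terminal mismatches are scored with internal
    tables upstream and 3'-terminal-mismatch alignments are excluded from any
    gating decision, so this convention never drives a filter).
    """
    base = primer_base if primer_base in BASES else frame_base
    which = "init_A/T" if base in "AT" else "init_G/C"
    return table.initiation(which)


def duplex_enthalpy_entropy(
    primer_seq: str,
    template_in_primer_frame: str,
    table: NNParameterTable | None = None,
    strict: bool = True,
) -> DuplexProfile:
    """Sum nearest-neighbor dH/dS over all doublet steps plus initiation.

    ``strict=True`` raises :class:`UnparameterizedStepError` for steps with no
    tabulated entry (adjacent mismatches, ambiguous bases). ``strict=False``
    scores such steps as a (0, 0) pseudo-step and records the position; such
    duplexes are always far below priming temperatures and must not crash
    genome-wide scans.
    """
    table = table or default_table()
    p, f = primer_seq.upper(), template_in_primer_frame.upper()
    if len(p) != len(f):
        raise ValueError("primer and template frame must have equal length")
    if len(p) < 2:
        raise ValueError("duplex must be at least 2 bp")
    if not set(p) <= BASES:
        raise ValueError(f"primer contains non-ACGT characters: {primer_seq!r}")
    if strict and not set(f) <= BASES:
        raise ValueError(f"template contains non-ACGT characters: {f!r}")

    # bottom strand (3'->5' as written) is the complement of the frame
    bottom = complement(f)

    dh, ds = table.initiation("init")
    for b_p, b_f in ((p[0], f[0]), (p[-1], f[-1])):
        idh, ids = _terminal_initiation(table, b_p, b_f)
        dh += idh
        ds += ids

    flagged: list[int] = []
    for i in range(len(p) - 1):
        top2 = p[i : i + 2]
        bot2 = bottom[i : i + 2]
        n_mm = (p[i] != f[i]) + (p[i + 1] != f[i + 1])
        entry = table.step(top2, bot2) if n_mm <= 1 else None
        if entry is None:
            if strict:
                raise UnparameterizedStepError(f"{top2}/{bot2}", i + 1)
            flagged.append(i + 1)
            continue
        dh += entry[0]
        ds += entry[1]

    if p == f and p == revcomp(p):  # perfect self-complementary duplex
        sdh, sds = table.initiation("sym")
        dh += sdh
        ds += sds

    return DuplexProfile(dh, ds, 2 * (len(p) - 1), tuple(flagged))


def sodium_equivalent(conditions: ReactionConditions) -> float:
    """Monovalent-equivalent cation concentration in mM.

    na_eq = monovalent + 120 * sqrt(Mg - dNTP) when free Mg2+ remains after
    dNTP chelation; otherwise the divalent term is dropped.
    """
    na = conditions.monovalent_mM
    if conditions.divalent_mg_mM > conditions.dntp_mM:
        na += 120.0 * math.sqrt(conditions.divalent_mg_mM - conditions.dntp_mM)
    return na


def melting_temperature(
    profile: DuplexProfile,
    conditions: ReactionConditions = DEFAULT_CONDITIONS,
) -> float:
    """Two-state Tm in Celsius with entropic salt adjustment.

    dS[Na+] = dS[1 M] + 0.368 * (n_phosphates / 2) * ln([Na+] molar);
    Tm(K) = dH*1000 / (dS[Na+] + R ln(C_T / x)).
    """
    na_eq_m = sodium_equivalent(conditions) / 1000.0
    if na_eq_m <= 0:
        raise ValueError("sodium equivalent must be positive")
    ds_adj = profile.delta_s + 0.368 * (profile.n_phosphates / 2.0) * math.log(na_eq_m)
    denom = ds_adj + conditions.gas_constant * math.log(
        conditions.total_strand_conc / conditions.symmetry_factor
    )
    if denom >= 0 or profile.delta_h >= 0:
        raise NonPhysicalDuplexError(
            f"no melting solution (dH={profile.delta_h}, adjusted dS denominator={denom})"
        )
    return profile.delta_h * 1000.0 / denom - 273.15


def duplex_tm(
    primer_seq: str,
    template_in_primer_frame: str | None = None,
    conditions: ReactionConditions = DEFAULT_CONDITIONS,
    table: NNParameterTable | None = None,
    strict: bool = True,
) -> float:
    """Convenience: dH/dS summation followed by Tm. Defaults to the perfect
    duplex of ``primer_seq`` with its own complement."""
    frame = template_in_primer_frame if template_in_primer_frame is not None else primer_seq
    profile = duplex_enthalpy_entropy(primer_seq, frame, table=table, strict=strict)
    try:
        return melting_temperature(profile, conditions)
    except NonPhysicalDuplexError:
        if strict:
            raise
        return NO_STRUCTURE_TM


# ---------------------------------------------------------------------------
# Secondary structure: simplified exhaustive engines
# ---------------------------------------------------------------------------

# Hairpin loop closure penalties dG37 (kcal/mol) by loop length; values between
# listed sizes are interpolated linearly, larger loops extrapolated on ln(n).
_LOOP_DG37 = {
    3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5, 10: 4.4,
    12: 4.7, 14: 5.0, 16: 5.1, 18: 5.2, 20: 5.3, 25: 5.6, 30: 5.9,
}
_LOOP_SIZES = sorted(_LOOP_DG37)
_T37 = 310.15


def _loop_dg37(n: int) -> float:
    if n in _LOOP_DG37:
        return _LOOP_DG37[n]
    for lo, hi in zip(_LOOP_SIZES, _LOOP_SIZES[1:]):
        if lo < n < hi:
            frac = (n - lo) / (hi - lo)
            return _LOOP_DG37[lo] + frac * (_LOOP_DG37[hi] - _LOOP_DG37[lo])
    last = _LOOP_SIZES[-1]
    return _LOOP_DG37[last] + 1.75 * GAS_CONSTANT_R / 1000.0 * _T37 * math.log(n / last)


def _wc(a: str, b: str) -> bool:
    return a + b in ("AT", "TA", "GC", "CG")


def hairpin_tm(
    seq: str,
    conditions: ReactionConditions = DEFAULT_CONDITIONS,
    table: NNParameterTable | None = None,
    min_stem: int = 3,
    min_loop: int = 3,
    max_loop: int = 30,
) -> float:
    """Tm of the most stable hairpin: exhaustive stems >= min_stem bp with
    loops of min_loop..max_loop nt. Unimolecular: Tm = dH*1000/dS, no strand
    concentration term. Stems must contain at least one G.C pair (A.T-only
    stems are weak nucleators and melt far below priming temperatures; treated
    as structureless). Returns NO_STRUCTURE_TM when no stem exists."""
    table = table or default_table()
    s = seq.upper()
    n = len(s)
    best = NO_STRUCTURE_TM
    for i in range(n):
        # outermost pair (i, j); extend the stem inward as far as it pairs
        for j in range(n - 1, i, -1):
            if not _wc(s[i], s[j]):
                continue
            # extend stem inward
            stem = 1
            while (
                i + stem < j - stem
                and _wc(s[i + stem], s[j - stem])
            ):
                stem += 1
            for use in range(min_stem, stem + 1):
                loop = j - i + 1 - 2 * use
                if loop < min_loop or loop > max_loop:
                    continue
                top = s[i : i + use]
                bottom = s[j - use + 1 : j + 1][::-1]  # 3'->5' under top
                if "G" not in top and "C" not in top:
                    continue
                dh = ds = 0.0
                for k in range(use - 1):
                    entry = table.step(top[k : k + 2], bottom[k : k + 2])
                    if entry is None:  # cannot happen for WC stems
                        break
                    dh += entry[0]
                    ds += entry[1]
                else:
                    ds += -1000.0 * _loop_dg37(loop) / _T37
                    if dh < 0 and ds < 0:
                        tm = dh * 1000.0 / ds - 273.15
                        best = max(best, tm)
    return best


def _dimer_alignments(a: str, b: str):
    """Yield (top_window, bottom_window) for every ungapped offset of a
    against b, with b written 3'->5' under a, trimmed to the first/last
    complementary column."""
    bottom_full = b[::-1]  # b read 3'->5' left to right
    la, lb = len(a), len(bottom_full)
    for offset in range(-(lb - 1), la):
        # column i of `a` pairs bottom_full[i - offset]
        lo = max(0, offset)
        hi = min(la, lb + offset)
        if hi - lo < 2:
            continue
        top = a[lo:hi]
        bot = bottom_full[lo - offset : hi - offset]
        # local maximal trimming: drop terminal non-complementary columns
        start, end = 0, len(top)
        while start < end and not _wc(top[start], bot[start]):
            start += 1
        while end > start and not _wc(top[end - 1], bot[end - 1]):
            end -= 1
        if end - start < 2:
            continue
        yield top[start:end], bot[start:end]


def _dimer_best(a: str, b: str, table: NNParameterTable, min_run: int = 3):
    """Best (most negative dG37) ungapped dimer. Returns (dh, ds, dg37, length)
    or None. Requires >= min_run consecutive complementary pairs."""
    best = None
    for top, bot in _dimer_alignments(a.upper(), b.upper()):
        run = cur = 0
        for x, y in zip(top, bot):
            cur = cur + 1 if _wc(x, y) else 0
            run = max(run, cur)
        if run < min_run:
            continue
        dh, ds = table.initiation("init")
        for b_t, b_b in ((top[0], bot[0]), (top[-1], bot[-1])):
            idh, ids = _terminal_initiation(table, b_t, complement(b_b))
            dh += idh
            ds += ids
        ok = True
        for k in range(len(top) - 1):
            entry = table.step(top[k : k + 2], bot[k : k + 2])
            if entry is None:
                continue  # adjacent mismatches: 0-contribution pseudo-step
            dh += entry[0]
            ds += entry[1]
        dg37 = dh * 1000.0 - _T37 * ds
        if best is None or dg37 < best[2]:
            best = (dh, ds, dg37, len(top))
    return best


def homodimer_tm(
    seq: str,
    conditions: ReactionConditions = DEFAULT_CONDITIONS,
    table: NNParameterTable | None = None,
) -> float:
    """Tm of the most stable self-dimer (two identical strands, x = 1)."""
    table = table or default_table()
    best_tm = NO_STRUCTURE_TM
    for top, bot in _dimer_alignments(seq.upper(), seq.upper()):
        run = cur = 0
        for x, y in zip(top, bot):
            cur = cur + 1 if _wc(x, y) else 0
            run = max(run, cur)
        if run < 3:
            continue
        dh, ds = table.initiation("init")
        for b_t, b_b in ((top[0], bot[0]), (top[-1], bot[-1])):
            idh, ids = _terminal_initiation(table, b_t, complement(b_b))
            dh += idh
            ds += ids
        for k in range(len(top) - 1):
            entry = table.step(top[k : k + 2], bot[k : k + 2])
            if entry is not None:
                dh += entry[0]
                ds += entry[1]
        profile = DuplexProfile(dh, ds, 2 * (len(top) - 1))
        cond = replace(conditions, symmetry_factor=1)
        try:
            tm = melting_temperature(profile, cond)
        except NonPhysicalDuplexError:
            continue
        best_tm = max(best_tm, tm)
    return best_tm


def self_structure_tm(
    seq: str,
    kind: str,
    conditions: ReactionConditions = DEFAULT_CONDITIONS,
    table: NNParameterTable | None = None,
) -> float:
    """Melting temperature of the most stable hairpin or homodimer."""
    if kind == "hairpin":
        return hairpin_tm(seq, conditions, table)
    if kind == "homodimer":
        return homodimer_tm(seq, conditions, table)
    raise ValueError(f"kind must be 'hairpin' or 'homodimer', got {kind!r}")


def heterodimer_dg(
    seq_a: str,
    seq_b: str,
    conditions: ReactionConditions = DEFAULT_CONDITIONS,
    table: NNParameterTable | None = None,
) -> float:
    """Most stable cross-dimer free energy at 37 C in cal/mol.

    Symmetric in its two arguments: the enumerated offset pairings of (a, b)
    and (b, a) are the same physical set and each pairing scores identically
    under the strand-symmetric table lookup.
    """
    table = table or default_table()
    best = _dimer_best(seq_a, seq_b, table)
    if best is None:
        return NO_STRUCTURE_DG
    return best[2]
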