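"""Genome-wide off-target scanning and thermoalignment scoring.

Plants a divergent copy of a primer's site elsewhere in a synthetic genome,
finds it with the seed-and-extend scanner, converts the local alignment into
a full-length ungapped thermoalignment and scores its misprime Tm.

Run:  python examples/02_offtarget_scan.py
"""

import random

from amplitile import genome as gmod, scan, specificity, thermo
from amplitile.design import CandidateOligo, oligo_id

rng = random.Random(7)
primer_seq = "".join(rng.choice("ACGT") for _ in range(24))

# off-target copy: three substitutions relative to the primer's target site
copy = list(primer_seq)
for i in (4, 12, 19):
    copy[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[i]]
background = "".join(rng.choice("ACGT") for _ in range(8000))
text = primer_seq + background[:5000] + "".join(copy) + background[5000:]
genome = gmod.ReferenceGenome({"chr1": text})

primer = CandidateOligo(
    id=oligo_id("chr1", 1, 24, "F"), sequence=primer_seq, strand="F",
    five_prime_pos=1, three_prime_pos=24, chrom="chr1", gc_pct=50.0,
)
primer.tm_on_target = thermo.duplex_tm(primer_seq, primer_seq)
print(f"primer {primer.id}: on-target Tm = {primer.tm_on_target:.2f} C")

hits = scan.find_local_hits(primer, genome)
print(f"off-target local hits (>=70% identity, shared 7-mer): {len(hits)}")
for h in hits:
    ta = specificity.build_thermoalignment(h, primer, genome)
    if ta is None:
        continue
    tm = specificity.misprime_tm(ta)
    print(
        f"  {h.subject_name}:{h.subject_start}-{h.subject_stop} ({h.subject_strand}) "
        f"identity {h.percent_identity:.1f}%  mismatches {ta.n_mismatches}  "
        f"misprime Tm {tm:.2f} C"
    )

profile = specificity.misprime_profile(primer, [
    ta for h in hits
    if (ta := specificity.build_thermoalignment(h, primer, genome)) is not None
])
ok = specificity.specificity_filter(profile, 10.0)
print(
    f"specific at the +10 C margin: {ok} "
    f"(on {profile.tm_on_target:.1f} C vs max off {profile.tm_offtarget_max:.1f} C)"
)
print("\nThe margin demands the primer bind its target at least 10 C more")
print("stably than anywhere else in the genome before it is accepted.")
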