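"""Nearest-neighbor melting temperatures: perfect duplexes, mismatches,
salt conditions and self-structures.

Run:  python examples/01_melting_temperature.py
"""

from amplitile import thermo
from amplitile._dna import revcomp

primer = "GCGATCGATTACGCGATCAG"
cond = thermo.ReactionConditions()  # 50 mM mono, 1.5 mM Mg, 0.8 mM dNTP, 0.25 uM

print(f"primer 5'->3': {primer}")
print(f"sodium equivalent: {thermo.sodium_equivalent(cond):.1f} mM")

profile = thermo.duplex_enthalpy_entropy(primer, primer)
print(f"perfect duplex: dH = {profile.delta_h:.1f} kcal/mol, "
      f"dS = {profile.delta_s:.1f} e.u.")
tm = thermo.melting_temperature(profile, cond)
print(f"perfect-duplex Tm = {tm:.2f} C")

# a single G.T wobble at position 11 (primer G over template T)
frame = primer[:10] + "T" + primer[11:]
tm_gt = thermo.duplex_tm(primer, frame, cond)
print(f"with one internal G.T mismatch: Tm = {tm_gt:.2f} C "
      f"({tm - tm_gt:.2f} C destabilization)")

# self-structures of a deliberately hairpin-prone oligo
stem = "GCGCATGC"
hairpinned = stem + "TTTT" + revcomp(stem)
print(f"\nhairpin-prone oligo: {hairpinned}")
print(f"  hairpin Tm   = {thermo.self_structure_tm(hairpinned, 'hairpin', cond):.1f} C")
print(f"  homodimer Tm = {thermo.self_structure_tm(hairpinned, 'homodimer', cond):.1f} C")
print(f"  heterodimer dG vs its own reverse complement = "
      f"{thermo.heterodimer_dg(hairpinned, revcomp(hairpinned), cond):.0f} cal/mol")
print("\nA primer is rejected when a self-structure melts within 20 C of its")
print("on-target Tm: such structures compete with template binding in PCR.")
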