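"""Exact-mass arithmetic for the pyroglutamyl hexapeptide.

Builds pGlu-Pro-Leu-Pro-Pro-Thr, prints its neutral formula, degrees of
unsaturation, and theoretical [M+H]+ — the numbers a high-resolution MS
run of the pure compound should reproduce within a few ppm.
"""
from prpkit import formula_of_peptide, mz, parse_peptide, ppm_error, rdbe

p = parse_peptide("pGlu-Pro-Leu-Pro-Pro-Thr")
f = formula_of_peptide(p)
theo = mz(p, 1)
print(f"peptide:            {p}")
print(f"neutral formula:    {f}  (RDBE = {rdbe(f):.0f})")
print(f"theoretical [M+H]+: {theo:.4f}")
print(f"vs measured 635.3392: {ppm_error(635.3392, theo):+.2f} ppm")
# The pGlu N-terminus is a cyclised Gln (-NH3); RDBE 11 = 6 C=O + 4 rings
# (3 Pro + pGlu) + 0 -> the formula alone pins the composition.
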