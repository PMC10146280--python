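"""Database-assisted sequencing against beta-casein.

Simulates a spectrum of the casein fragment Pro-Pro-Phe-Leu-Gln-Pro-Glu
and asks the sequencer to recover it from the parent protein alone:
every substring matching the precursor is scored against the fragment
ladder and ranked.
"""
from prpkit import SimulationConfig, beta_casein, parse_peptide, sequence_spectrum, simulate_spectrum
from prpkit.sequencing import ranking_table

p = parse_peptide("Pro-Pro-Phe-Leu-Gln-Pro-Glu")
s = simulate_spectrum(p, SimulationConfig(seed=3), charge=1, spectrum_id="pep")
ranked = sequence_spectrum(s, [beta_casein()], tol_ppm=30.0, top=3)
print(ranking_table("pep", ranked))
print("rank 1 should be span 100-106 of P02666 (precursor numbering); the "
      "score mixes b/y coverage and annotated intensity 50/50")
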