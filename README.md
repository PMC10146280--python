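# prpkit

Identification, molecular networking and antioxidant scoring of
**proline-rich peptides** (PRPs) from tandem mass spectrometry data.

Marine bacteria grown on tryptone-based media can proteolyse the bovine
β-casein in the medium into short, proline-rich oligopeptides — some
carrying an N-terminal pyroglutamate (pGlu, a cyclised Gln, −NH₃) and
several with documented bioactivity. Characterising such peptides from
LC-MS/MS data is a chain of small, exact computations that are usually
done by hand: exact-mass and molecular-formula arithmetic, theoretical
CID fragment ladders (b/y/a and internal ions), database-assisted
sequence inference against the parent protein, spectral similarity
networking, fragment-coordinate mapping, a ¹³C NMR rule for proline
peptide-bond conformation, and FRAP antioxidant scoring. `prpkit` makes
that chain reproducible, tested, importable Python, with a seeded
synthetic-data generator so the whole pipeline runs offline.

## The computations at the core

* **Mass arithmetic** — monoisotopic residue masses (IUPAC/CODATA,
  shipped as a versioned TSV); peptide neutral mass `M = Σ residues +
  H₂O (− NH₃ for Gln-derived pGlu)`; `m/z = (M + z·m_H⁺)/z`;
  RDBE `= C − H/2 + N/2 + 1`.
* **Fragment ladders** — `b_i = Σ₁..i + H⁺`, `a_i = b_i − CO`,
  `y_j = Σ_{n−j+1..n} + H₂O + H⁺`; b-type internal ions
  `= Σ span + H⁺`; greedy one-to-one peak annotation by |Δm/z|.
* **Sequencing** — every substring of the parent protein matching the
  precursor within a ppm tolerance (unspecific digestion, optional
  N-terminal Gln→pGlu) is scored
  `0.5·(matched b+y / theoretical b+y) + 0.5·(annotated intensity /
  total intensity)` and ranked; Leu/Ile are resolved by the protein.
* **Networking** — modified cosine on √-scaled intensities with
  precursor-shifted peak pairing (edges: cosine ≥ 0.7, ≥ 3 matched
  peaks, precursor Δ ≤ 300 Da; components pruned to ≤ 100 nodes).
* **Proline conformation** — Δδβγ = δCβ − δCγ; *trans* iff
  Δδβγ < 8 ppm and δCγ > 23 ppm; *cis* iff Δδβγ ≥ 8 ppm.
* **FRAP** — `[(A₁ − A₀)/(A_c − A₀)] × 2` at 593 nm against an
  ascorbic-acid control, with OLS calibration.

The bovine β-casein parent (UniProt **P02666**, precursor numbering)
ships as a FASTA fixture.

## Worked example

```python
from prpkit import parse_peptide, formula_of_peptide, mz, rdbe, ppm_error

p = parse_peptide("pGlu-Pro-Leu-Pro-Pro-Thr")
f = formula_of_peptide(p)
print(f, rdbe(f), round(mz(p, 1), 4), round(ppm_error(635.3392, mz(p, 1)), 2))
```

prints

```
C30H46N6O9 11.0 635.3399 -1.11
```

i.e. the hexapeptide's neutral formula has 11 degrees of unsaturation
and a theoretical [M+H]⁺ of 635.3399, −1.11 ppm from a measured
635.3392 — comfortably inside instrument accuracy, so the composition
is confirmed. Running `examples/03_sequence_inference.py` then shows
the sequencer recovering this family's relatives from β-casein alone:

```
spectrum  rank  peptide                          protein  start  end  score
pep       1     Pro-Pro-Phe-Leu/Ile-Gln-Pro-Glu  P02666   100    106  0.8239
```

rank 1 is the true casein fragment 100–106; `Leu/Ile` marks the
isobaric position resolved by the parent residue. The other
`examples/*.py` scripts demo annotation, networking, the proline rule
and FRAP, one capability each. A thin CLI mirrors the library:
`prpkit simulate | sequence | map | network | frap | run`.

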