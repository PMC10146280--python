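# Methods

This note documents the models, conventions and numerical choices
behind `prpkit`, and what the synthetic-data tests do and do not show
about real instrument data.

## Mass and formula arithmetic

Monoisotopic element masses (¹H 1.00782503207, ¹²C 12, ¹⁴N
14.0030740048, ¹⁶O 15.9949146196, ³²S 31.97207100 Da) and the twenty
residue formulas ship in `data/masses.tsv`; residue masses are derived
from the element table, and the loader cross-checks the stored values.
Constants: proton 1.00727646688 Da, electron 0.00054857990 Da. The
canonical in-memory species is the **neutral** molecule; protonation
(`[M+zH]z+`) adds z hydrogens and z charges and subtracts one electron
mass per charge only when an m/z or a cation formula is requested —
this avoids the classic double-counting of protons when cation
formulas are printed. N-terminal pyroglutamate is pure formula
arithmetic: −NH₃ (−17.026549 Da) from Gln, −H₂O from Glu. Leu/Ile are
isobaric; ambiguity is metadata and never enters arithmetic. RDBE is
defined for neutral CHNOS formulas as C − H/2 + N/2 + 1.

A 5 ppm window is used when calling agreement between a theoretical
m/z and a published measured value: Orbitrap data are usually within
~3 ppm, and at these masses 5 ppm does not admit an alternative
composition. Elements beyond CHNOS, average masses and isotope-pattern
simulation are out of scope.

## Fragment ladders and annotation

Singly protonated CID conventions: b_i = prefix sum + proton (the
N-terminal modification delta applies to a/b ions containing residue
1), a_i = b_i − CO, y_j = suffix sum + H₂O + proton (y ions are
unmodified — the modification is N-terminal). Internal fragments are
b-type (acylium, Σ span + proton) over spans excluding both termini;
a-type internals are not generated by default because the single
published internal ion is b-type. Neutral-loss generation defaults to
conservative: none on a/b, −H₂O on y only when the C-terminal residue
is S/T/E/D (hydroxyl- or carboxyl-bearing); broad combinatorial losses
inflate false matches at 0.02 Da tolerance. Annotation is a greedy
one-to-one assignment by ascending |Δm/z| (ties toward the lower peak
index), injective in both peaks and ions; the default fragment
tolerance is 0.02 Da, matching common high-resolution FBMN practice.

## Database-assisted sequencing

Candidates are **all** substrings of the parent protein (length ≤ 30)
whose m/z at the observed charge falls within the precursor tolerance,
with an extra −NH₃ variant when the substring starts with Gln.
Digestion is deliberately unspecific: the observed peptide termini
(e.g. Pro at P1′) are inconsistent with any single named protease, and
multiple sequential hydrolytic steps are the more plausible origin.
The score, 0.5·(b+y coverage) + 0.5·(annotated-intensity fraction), is
a repository-defined statistic formalising manual ion-series counting;
the equal weighting lets intensity evidence break coverage ties.
Consecutive-series coverage is not required. Ranking is total-ordered
(score desc, |precursor ppm| asc, span start asc, protein id), so
repeated substrings resolve deterministically. Pure de novo mode
(no parent protein) is out of scope; at these lengths the parent is
also what resolves Leu/Ile.

Default tolerances: precursor 10 ppm, fragments 0.02 Da. The
parameter-recovery experiments search at 3× the simulated precursor
jitter σ (30 ppm at the default σ = 10 ppm) — matching the search
window to the known noise scale, as one would on an instrument with a
characterised mass accuracy; a window equal to 1σ would discard ~32%
of true precursors before scoring.

## Molecular networking

Modified cosine: square-root intensity scaling (standard for spectral
dot products; it tames base-peak dominance), peak pairs allowed either
directly or offset by the precursor mass difference, greedy one-to-one
pairing by descending intensity product (ties toward smaller |Δm/z|),
normalised by the product of the √-intensity vector norms. Greedy
pairing is the ecosystem-standard choice; an exhaustive optimal
matcher exists in the tests as the small-instance oracle, and on
realistic (collision-free at 0.02 Da) peak lists the two coincide.

Network rules: edges require cosine ≥ 0.7 and ≥ 3 matched peaks; pairs
with precursor Δ > 300 Da are never linked (the analog cap is read as
bounding all linking); components larger than 100 nodes are reduced by
repeatedly deleting the weakest edge in the oversized component
(lowest cosine, then larger precursor Δ, then lexicographically
smaller node pair) — an explicit interpretation of the "maximum nodes
per cluster" rule. Nodes are never deleted. Upstream feature finding /
MS-Cluster merging is not replicated: nodes are the input spectra.

## Proline conformation rule

Δδβγ = δCβ − δCγ from ¹³C shifts; *trans* requires both Δδβγ < 8 ppm
and δCγ > 23 ppm (the conjunction is a documented choice — the two
criteria are stated together and used together); Δδβγ ≥ 8 ppm is
called *cis* (strict "below the threshold" reading, so exactly 8 ppm
is not trans); small Δδβγ with low δCγ is left indeterminate. The
NOE-absence criterion is not modelled (no NOE data model in scope).
The bundled CSV carries the three proline Cβ/Cγ pairs of the
pyroglutamyl hexapeptide (4.39, 3.54, 4.39 ppm differences — all
trans).

## FRAP

FRAP = (A₁ − A₀)/(A_c − A₀) × 2 at 593 nm; the ×2 encodes the assay's
control-concentration convention and is kept verbatim rather than
re-derived. Requested read times (default 4 and 16 min) use the
nearest acquired read, no interpolation. Sample replicates are
normalised against the replicate-mean control and blank at that read;
aggregation is mean ± sample (n−1) SD. Ascorbic-acid calibration is
ordinary least squares on blank-corrected absorbance vs concentration.
Published FRAP magnitudes (tens) imply a normalisation of the raw
ratio not derivable from the equation alone, so absolute published
FRAP values are treated as scale context, never as computable targets.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not an instrument: a parent protein with elevated Pro (0.15) and Gln
(0.10) frequencies; unspecific overlapping peptides of 5–12 residues
(20 per protein by default), N-terminal Gln cyclised with probability
0.5; spectra built from the theoretical charge-1 a/b/y + internal
ladder with 10% fragment dropout, Gaussian m/z jitter of σ = 10 ppm
(deliberately worse than a real Orbitrap's ~3 ppm, so recovery claims
are conservative), uniform intensities, and 20 uniform noise peaks in
[100, precursor]; precursors at z ∈ {1, 2} jittered with the same σ.
FRAP plates follow A(t) = A₀ + (A_max − A₀)(1 − e^(−kt)) plus Gaussian
read noise (σ = 0.005 AU), triplicate wells, reads at 0.5–16 min.

One integer seed drives a single numpy Generator stream; all outputs
are bit-reproducible per (seed, config). What passing tests show:
the arithmetic, matching, ranking and network logic are correct under
a noise model harsher than the instrument's. What they do not show:
robustness to co-isolation/chimeric spectra, isotope envelopes,
charge-state misassignment, retention-time structure or real
intensity models — none of which the generator emulates.

## Problem sizes and determinism

Default test and demonstration scales — 100 spectra for the rank-1
recovery rate, 100 random cases for the enumeration and pairing
oracles, 1000 random peptides for the complementarity invariant, a
101-spectrum chain for the component cap — were chosen as the smallest
sizes at which the statistical claims are meaningful. The
property-test seeds are fixed; the pipeline writes a manifest
(versions, parameters, seed, input checksums) and identical inputs
yield byte-identical outputs.

## Known limitations

Charge states above 3+ are rejected; fragment ions are generated at
charge 1 by default; no FDR model for sequencing (candidate spaces are
single proteins, not proteomes); the MGF reader trusts pyteomics'
dialect handling and reports malformed files as parse errors without
line numbers; BIOPEP-style bioactivity annotation is static metadata,
not a live lookup; the published node counts of service-built networks
depend on raw data and external services and are not reproduced.
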