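"""Annotate a simulated CID spectrum against its peptide.

Generates a noisy synthetic spectrum of the heptapeptide, then matches
peaks to the theoretical b/y/a + internal ladder; each line shows one
assigned peak and its mass error.
"""
from prpkit import SimulationConfig, annotate_spectrum, parse_peptide, simulate_spectrum
from prpkit.fragments import annotation_table

p = parse_peptide("Pro-Phe-Pro-Gly-Pro-Ile-Pro")
cfg = SimulationConfig(seed=7, mz_jitter_ppm_sigma=5.0, n_noise_peaks=5)
s = simulate_spectrum(p, cfg, charge=1, spectrum_id="demo")
ann = annotate_spectrum(s, p, tol=0.02)
print(annotation_table(s, ann))
print(f"{len(ann)}/{len(s)} peaks annotated; the internal[3-6] ion is the "
      "Pro-Gly-Pro-Ile fragment near m/z 365.22")
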