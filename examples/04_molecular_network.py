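"""Modified-cosine molecular networking of related peptides.

Three N-terminal truncations of one peptide share their y-ion series and
have precursor-shifted b ions, so the modified cosine links them; two
random-noise spectra stay unconnected.
"""
import numpy as np
from prpkit import SimulationConfig, Spectrum, build_network, parse_peptide, simulate_spectrum
from prpkit.networking import edges_table

cfg = SimulationConfig(seed=11, mz_jitter_ppm_sigma=3.0, n_noise_peaks=3,
                       fragment_dropout_rate=0.05)
rng = cfg.rng()
parent = "VVPPFLQPEV"
spectra = [simulate_spectrum(parse_peptide(parent[k:]), cfg, rng=rng,
                             charge=1, spectrum_id=f"trunc_{k}")
           for k in range(3)]
for k in range(2):
    spectra.append(Spectrum(f"noise_{k}", float(rng.uniform(400, 900)), 1,
                            np.sort(rng.uniform(100, 900, 25)),
                            rng.uniform(1, 100, 25)))
net = build_network(spectra, cosine_min=0.7, min_matched=3)
print(edges_table(net))
print(f"components: {[sorted(c) for c in net.components()]}")
print("edges carry cosine >= 0.7 with >= 3 matched peaks; the precursor "
      "delta equals the mass of the missing residues")
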