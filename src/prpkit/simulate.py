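"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates, without any instrument data: a proline/glutamine-rich parent
protein; overlapping unspecific proteolytic peptides (optionally with
N-terminal Gln cyclised to pyroglutamate); singly/doubly charged CID
spectra built from the theoretical b/y/a + internal ladders with
ppm-scale Gaussian m/z jitter, random fragment dropout and uniform
noise peaks; and saturating FRAP absorbance kinetics

    A(t) = A0 + (Amax - A0) * (1 - exp(-k t)) + read noise.

A single integer seed drives one numpy Generator stream; every output
is reproducible per (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import Peptide, mz as peptide_mz
from .fragments import theoretical_ions
from .frap import AbsorbanceSeries
from .mapping import ProteinRecord
from .spectra import Spectrum

__all__ = [
    "SimulationConfig",
    "simulate_protein",
    "simulate_digest",
    "simulate_spectrum",
    "simulate_frap_plate",
    "simulate_dataset",
]

# Residue frequencies of the simulated parent: proline and glutamine
# elevated (the proline-rich regime these peptides come from), the rest
# uniform over the remaining mass.
_ELEVATED = {"P": 0.15, "Q": 0.10}
_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    seed: int = 0
    protein_length: int = 300
    n_peptides: int = 20
    peptide_length_range: tuple[int, int] = (5, 12)
    pglu_probability: float = 0.5
    mz_jitter_ppm_sigma: float = 10.0
    fragment_dropout_rate: float = 0.1
    n_noise_peaks: int = 20
    intensity_model: str = "uniform"      # uniform | exponential
    charge_choices: tuple[int, ...] = (1, 2)
    # FRAP kinetics per sample: (A0, Amax, k[1/min])
    frap_kinetics: dict = field(default_factory=lambda: {
        "peptide_fast": (0.10, 0.90, 0.8),
        "peptide_slow": (0.10, 0.70, 0.15),
    })
    frap_control_absorbance: float = 0.50
    frap_read_noise_sd: float = 0.005
    frap_replicates: int = 3
    frap_times: tuple[float, ...] = (0.5, 1, 2, 4, 8, 12, 16)

    def __post_init__(self) -> None:
        for name, v in (("pglu_probability", self.pglu_probability),
                        ("fragment_dropout_rate", self.fragment_dropout_rate)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.intensity_model not in ("uniform", "exponential"):
            raise ValueError(f"unknown intensity model {self.intensity_model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _residue_probs() -> np.ndarray:
    rest = (1.0 - sum(_ELEVATED.values())) / (len(_ALPHABET) - len(_ELEVATED))
    return np.array([_ELEVATED.get(a, rest) for a in _ALPHABET])


def simulate_protein(cfg: SimulationConfig,
                     rng: np.random.Generator | None = None) -> ProteinRecord:
    """Random parent protein with elevated P/Q frequency."""
    rng = rng if rng is not None else cfg.rng()
    idx = rng.choice(len(_ALPHABET), size=cfg.protein_length, p=_residue_probs())
    seq = "".join(_ALPHABET[i] for i in idx)
    return ProteinRecord("SIM_PROT", "simulated proline-rich parent", seq)


def simulate_digest(
    prot: ProteinRecord,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[Peptide, tuple[int, int]]]:
    """Unspecific overlapping peptides with their true spans (1-based).

    N-terminal Gln is cyclised to pyroglutamate with ``pglu_probability``.
    """
    rng = rng if rng is not None else cfg.rng()
    lo, hi = cfg.peptide_length_range
    if len(prot.sequence) < lo:
        raise ValueError("protein shorter than the minimum peptide length")
    out = []
    for _ in range(cfg.n_peptides):
        length = int(rng.integers(lo, min(hi, len(prot.sequence)) + 1))
        start = int(rng.integers(0, len(prot.sequence) - length + 1))
        sub = prot.sequence[start:start + length]
        mod = "none"
        if sub[0] == "Q" and rng.random() < cfg.pglu_probability:
            mod = "pGlu_from_Q"
        out.append((Peptide(sub, mod), (start + 1, start + length)))
    return out


def simulate_spectrum(
    p: Peptide,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    charge: int | None = None,
    spectrum_id: str = "sim",
) -> Spectrum:
    """CID spectrum of one peptide under the configured noise model.

    The theoretical a/b/y + internal ladder (charge 1) is thinned by the
    dropout rate, jittered with Gaussian ppm noise, given intensities
    from the configured model, and topped up with uniform noise peaks in
    [100, precursor m/z]. The precursor m/z is jittered likewise.
    """
    rng = rng if rng is not None else cfg.rng()
    if charge is None:
        charge = int(rng.choice(cfg.charge_choices))
    ions = theoretical_ions(p, max_charge=1)
    mzs, intens = [], []
    for ion in ions:
        if rng.random() < cfg.fragment_dropout_rate:
            continue
        jitter = rng.normal(0.0, cfg.mz_jitter_ppm_sigma) * ion.mz / 1e6
        mzs.append(ion.mz + jitter)
        intens.append(_draw_intensity(cfg, rng))
    prec = peptide_mz(p, charge)
    prec_obs = prec * (1.0 + rng.normal(0.0, cfg.mz_jitter_ppm_sigma) / 1e6)
    for _ in range(cfg.n_noise_peaks):
        mzs.append(float(rng.uniform(100.0, max(prec_obs, 101.0))))
        intens.append(0.2 * _draw_intensity(cfg, rng))
    if not mzs:  # total dropout with zero noise peaks: keep the precursor
        mzs, intens = [prec_obs], [1.0]
    return Spectrum(
        id=spectrum_id,
        precursor_mz=float(prec_obs),
        precursor_charge=charge,
        mz=np.array(mzs),
        intensity=np.array(intens),
    )


def _draw_intensity(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    if cfg.intensity_model == "uniform":
        return float(rng.uniform(0.2, 1.0)) * 1000.0
    return float(rng.exponential(1.0)) * 1000.0


def simulate_frap_plate(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[AbsorbanceSeries]:
    """Saturating-kinetics FRAP plate: samples per ``frap_kinetics``,
    constant blank at A0, constant positive control."""
    rng = rng if rng is not None else cfg.rng()
    times = np.array(cfg.frap_times, dtype=float)
    plate: list[AbsorbanceSeries] = []

    def noisy(values: np.ndarray) -> np.ndarray:
        reps = np.tile(values, (cfg.frap_replicates, 1))
        reps = reps + rng.normal(0.0, cfg.frap_read_noise_sd, reps.shape)
        return np.clip(reps, 0.0, None)

    a0_ref = None
    for sid, (a0, amax, k) in cfg.frap_kinetics.items():
        a0_ref = a0 if a0_ref is None else a0_ref
        curve = a0 + (amax - a0) * (1.0 - np.exp(-k * times))
        plate.append(AbsorbanceSeries(sid, "sample", times, noisy(curve)))
    a0_ref = a0_ref if a0_ref is not None else 0.1
    plate.append(AbsorbanceSeries(
        "blank", "blank", times, noisy(np.full_like(times, a0_ref))))
    plate.append(AbsorbanceSeries(
        "ascorbic_acid", "positive_control", times,
        noisy(np.full_like(times, cfg.frap_control_absorbance))))
    return plate


def simulate_dataset(cfg: SimulationConfig):
    """Protein + digest + one spectrum per peptide, from one seeded stream.

    Returns (protein, truth, spectra) where truth is a list of
    (peptide, span) aligned with the spectra by index and id.
    """
    rng = cfg.rng()
    prot = simulate_protein(cfg, rng)
    truth = simulate_digest(prot, cfg, rng)
    spectra = [
        simulate_spectrum(p, cfg, rng, spectrum_id=f"sim_{i:03d}")
        for i, (p, _span) in enumerate(truth)
    ]
    return prot, truth, spectra
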