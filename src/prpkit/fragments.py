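"""Theoretical CID fragment ladders and spectrum annotation.

Generates singly/multiply protonated a/b/y series, b-type internal
fragments (two backbone cleavages, acylium form: residue sum + proton)
and optional H2O/NH3 neutral losses, then matches observed peak lists
against the ladder greedily by mass error. Conventions follow common
CID practice for protonated peptides:

    b_i = sum(residues 1..i) + z*proton          (N-terminal mods apply)
    a_i = b_i - CO
    y_j = sum(residues n-j+1..n) + H2O + z*proton
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .chem import (
    AMMONIA,
    CO,
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER,
    Peptide,
    peptide_mass,
)
from .spectra import Spectrum

__all__ = [
    "FragmentIon",
    "PeakAnnotation",
    "fragment_ladder",
    "internal_fragments",
    "theoretical_ions",
    "annotate_spectrum",
]

_LOSS_MASS = {"H2O": WATER.mass, "NH3": AMMONIA.mass}

# Residues whose side chain readily loses water from y ions when C-terminal.
_WATER_LOSS_CTERM = frozenset("STED")


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment: series, residue span (1-based, inclusive),
    charge, neutral losses, and its m/z."""

    series: str              # a | b | y | internal_by | precursor
    span: tuple[int, int]
    charge: int
    losses: tuple[str, ...]
    mz: float

    @property
    def label(self) -> str:
        i, j = self.span
        if self.series in ("a", "b"):
            base = f"{self.series}{j}"
        elif self.series == "y":
            base = f"y{j - i + 1}"
        elif self.series == "internal_by":
            base = f"internal[{i}-{j}]"
        else:
            base = self.series
        for loss in self.losses:
            base += f"-{loss}"
        if self.charge > 1:
            base += f"({self.charge}+)"
        return base


@dataclass(frozen=True)
class PeakAnnotation:
    peak_index: int
    ion: FragmentIon
    ppm: float


def _prefix_masses(p: Peptide) -> list[float]:
    """Cumulative residue-mass sums including the N-terminal mod delta."""
    out = [0.0]
    acc = p.nterm_delta_mass
    for r in p.residues:
        acc += RESIDUE_MASSES[r]
        out.append(acc)
    return out


def _with_losses(neutral: float, losses: Sequence[str]) -> float:
    return neutral - sum(_LOSS_MASS[l] for l in losses)


def fragment_ladder(
    p: Peptide,
    series: str,
    max_charge: int = 1,
    losses: Iterable[str] | None = None,
) -> list[FragmentIon]:
    """Full a/b/y ladder for one series.

    ``losses=None`` applies the default policy: no losses on a/b ions;
    a -H2O variant on y ions only when the C-terminal residue is S/T/E/D.
    Pass an explicit iterable (possibly empty) to override.
    """
    if series not in ("a", "b", "y"):
        raise ValueError(f"unknown ion series {series!r}")
    if len(p) < 2:
        raise ValueError("fragment ladders need at least 2 residues")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")

    n = len(p)
    prefix = _prefix_masses(p)
    total = prefix[n] + WATER.mass  # neutral peptide mass
    assert abs(total - peptide_mass(p)) < 1e-9

    if losses is None:
        if series == "y" and p.residues[-1] in _WATER_LOSS_CTERM:
            loss_sets: list[tuple[str, ...]] = [(), ("H2O",)]
        else:
            loss_sets = [()]
    else:
        loss_sets = [()] + [(l,) for l in losses]

    ions: list[FragmentIon] = []
    for k in range(1, n):  # fragment of k residues
        if series in ("a", "b"):
            neutral = prefix[k]  # b "neutral" = residue sum (+ mod delta)
            if series == "a":
                neutral -= CO.mass
            span = (1, k)
        else:
            # suffix residue sum + H2O; the N-terminal mod delta cancels
            # in the prefix difference, so y ions are unmodified.
            neutral = (prefix[n] - prefix[n - k]) + WATER.mass
            span = (n - k + 1, n)
        for ls in loss_sets:
            neutral_l = _with_losses(neutral, ls)
            for z in range(1, max_charge + 1):
                ion_mz = (neutral_l + z * PROTON_MASS) / z
                if ion_mz <= 0:
                    continue
                ions.append(FragmentIon(series, span, z, ls, ion_mz))
    return ions


def internal_fragments(
    p: Peptide, min_len: int = 2, max_len: int | None = None
) -> list[FragmentIon]:
    """b-type internal ions (acylium): every span excluding both termini,
    m/z = span residue sum + proton."""
    n = len(p)
    if n < 4:
        raise ValueError("internal fragments need at least 4 residues")
    if max_len is None:
        max_len = n - 2
    if not (2 <= min_len <= max_len <= n - 2):
        raise ValueError(
            f"invalid internal span bounds: 2 <= {min_len} <= {max_len} <= {n - 2}"
        )
    ions = []
    for start in range(2, n):          # 1-based start, excludes residue 1
        for end in range(start + min_len - 1, n):  # excludes residue n
            if end - start + 1 > max_len:
                break
            residue_sum = sum(RESIDUE_MASSES[r] for r in p.residues[start - 1:end])
            ions.append(
                FragmentIon("internal_by", (start, end), 1, (),
                            residue_sum + PROTON_MASS)
            )
    return ions


def theoretical_ions(
    p: Peptide,
    series: Iterable[str] = ("a", "b", "y"),
    max_charge: int = 1,
    include_internal: bool = True,
    internal_min_len: int = 2,
) -> list[FragmentIon]:
    """Combined ladder used for annotation and candidate scoring."""
    ions: list[FragmentIon] = []
    for s in series:
        ions.extend(fragment_ladder(p, s, max_charge=max_charge))
    if include_internal and len(p) >= 4:
        ions.extend(internal_fragments(p, min_len=internal_min_len))
    return ions


def annotate_spectrum(
    s: Spectrum,
    p: Peptide,
    tol: float = 0.02,
    mode: str = "da",
    ions: Sequence[FragmentIon] | None = None,
    max_charge: int = 1,
) -> list[PeakAnnotation]:
    """Match observed peaks to theoretical ions, one-to-one.

    Candidate (peak, ion) pairs within tolerance are accepted greedily by
    ascending |delta m/z|, ties broken toward the lower peak index; each
    peak and each ion is used at most once.

    ``mode`` selects a Da or ppm tolerance; ``tol`` must be positive.
    """
    if len(s) == 0:
        raise ValueError("cannot annotate an empty spectrum")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if mode not in ("da", "ppm"):
        raise ValueError(f"unknown tolerance mode {mode!r}")
    if ions is None:
        ions = theoretical_ions(p, max_charge=max_charge)

    candidates: list[tuple[float, int, int]] = []  # (|delta|, peak_idx, ion_idx)
    for ion_idx, ion in enumerate(ions):
        limit = tol if mode == "da" else tol * ion.mz / 1e6
        for peak_idx, mz_obs in enumerate(s.mz):
            delta = abs(mz_obs - ion.mz)
            if delta <= limit:
                candidates.append((delta, peak_idx, ion_idx))
    candidates.sort()

    used_peaks: set[int] = set()
    used_ions: set[int] = set()
    out: list[PeakAnnotation] = []
    for delta, peak_idx, ion_idx in candidates:
        if peak_idx in used_peaks or ion_idx in used_ions:
            continue
        used_peaks.add(peak_idx)
        used_ions.add(ion_idx)
        ion = ions[ion_idx]
        out.append(
            PeakAnnotation(
                peak_idx, ion, (s.mz[peak_idx] - ion.mz) / ion.mz * 1e6
            )
        )
    out.sort(key=lambda a: a.peak_index)
    return out


def annotation_table(s: Spectrum, annotations: Sequence[PeakAnnotation]) -> str:
    """TSV report: peak m/z, intensity, ion label, theoretical m/z, ppm."""
    lines = ["mz\tintensity\tion\ttheoretical_mz\tppm"]
    for a in annotations:
        lines.append(
            f"{s.mz[a.peak_index]:.4f}\t{s.intensity[a.peak_index]:.1f}\t"
            f"{a.ion.label}\t{a.ion.mz:.4f}\t{a.ppm:+.2f}"
        )
    return "\n".join(lines) + "\n"
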