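"""Database-assisted de novo sequencing of peptide MS/MS spectra.

Candidate sequences are every substring of a parent protein whose
[M+zH]z+ matches the observed precursor within a ppm tolerance —
digestion is deliberately unspecific (no protease cleavage rule), and
substrings starting with Gln are additionally tried with the N-terminus
cyclised to pyroglutamate (-NH3). Each candidate is scored against the
observed fragment ladder:

    score = 0.5 * (matched b+y ions / theoretical b+y ions)
          + 0.5 * (annotated intensity / total intensity)

with annotation over the a/b/y + internal-ion ladder. Ranking is by
score, then |precursor ppm|, then span start. Leu/Ile are isobaric; the
parent-protein residue resolves the ambiguity, and positions where an
L or I was read off the protein carry an ambiguity marker.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .chem import PROTON_MASS, RESIDUE_MASSES, WATER, Peptide, ppm_error
from .fragments import annotate_spectrum, fragment_ladder, theoretical_ions
from .mapping import ProteinRecord
from .spectra import Spectrum

__all__ = ["CandidateMatch", "candidate_peptides", "score_candidate",
           "sequence_spectrum"]

DEFAULT_PRECURSOR_TOL_PPM = 10.0
DEFAULT_FRAGMENT_TOL_DA = 0.02
DEFAULT_MAX_LEN = 30


@dataclass(frozen=True)
class CandidateMatch:
    peptide: Peptide
    protein_id: str
    span: tuple[int, int]           # 1-based inclusive in the parent
    precursor_ppm: float
    score: float = 0.0
    matched_ions: int = 0
    matched_intensity_fraction: float = 0.0


def _as_record(protein) -> ProteinRecord:
    if isinstance(protein, ProteinRecord):
        return protein
    return ProteinRecord("protein", "", str(protein))


def candidate_peptides(
    protein,
    precursor_mz: float,
    z: int,
    tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
    allow_pglu: bool = True,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[CandidateMatch]:
    """Unscored candidates: all protein substrings (length <= max_len)
    whose m/z at charge ``z`` lies within ``tol_ppm`` of the precursor,
    with and (for N-terminal Gln, if allowed) without NH3."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    prot = _as_record(protein)
    seq = prot.sequence
    n = len(seq)
    if n == 0:
        return []

    # Cumulative residue masses for O(1) substring masses.
    cum = np.zeros(n + 1)
    for i, r in enumerate(seq):
        cum[i + 1] = cum[i] + RESIDUE_MASSES[r]

    from .chem import AMMONIA
    nh3 = AMMONIA.mass
    water = WATER.mass
    tol_abs = tol_ppm * precursor_mz / 1e6

    out: list[CandidateMatch] = []
    for start in range(n):
        max_end = min(n, start + max_len)
        for end in range(start + 1, max_end + 1):
            neutral = cum[end] - cum[start] + water
            variants = [("none", 0.0)]
            if allow_pglu and seq[start] == "Q":
                variants.append(("pGlu_from_Q", -nh3))
            for mod, delta in variants:
                theo = (neutral + delta + z * PROTON_MASS) / z
                if abs(precursor_mz - theo) <= tol_abs:
                    sub = seq[start:end]
                    ambiguity = frozenset(
                        i for i, r in enumerate(sub) if r in "LI"
                    )
                    out.append(
                        CandidateMatch(
                            peptide=Peptide(sub, mod, ambiguity),
                            protein_id=prot.id,
                            span=(start + 1 + prot.numbering_offset,
                                  end + prot.numbering_offset),
                            precursor_ppm=ppm_error(precursor_mz, theo),
                        )
                    )
    return out


def score_candidate(
    s: Spectrum,
    c: CandidateMatch,
    tol_da: float = DEFAULT_FRAGMENT_TOL_DA,
    max_charge: int = 1,
) -> CandidateMatch:
    """Score by b/y ion-series coverage and annotated intensity (50/50)."""
    if len(s) == 0:
        raise ValueError("cannot score against an empty spectrum")
    p = c.peptide
    by_ions = (fragment_ladder(p, "b", max_charge=max_charge, losses=())
               + fragment_ladder(p, "y", max_charge=max_charge, losses=()))
    all_ions = list(by_ions) + fragment_ladder(p, "a", max_charge=max_charge,
                                               losses=())
    if len(p) >= 4:
        from .fragments import internal_fragments
        all_ions += internal_fragments(p)

    annotations = annotate_spectrum(s, p, tol=tol_da, mode="da", ions=all_ions)
    n_by = len(by_ions)
    matched_by = sum(1 for a in annotations if a.ion.series in ("b", "y"))
    total_intensity = float(s.intensity.sum())
    matched_intensity = float(
        sum(s.intensity[a.peak_index] for a in annotations)
    )
    frac_int = matched_intensity / total_intensity if total_intensity > 0 else 0.0
    score = 0.5 * (matched_by / n_by if n_by else 0.0) + 0.5 * frac_int
    return replace(
        c,
        score=score,
        matched_ions=len(annotations),
        matched_intensity_fraction=frac_int,
    )


def sequence_spectrum(
    s: Spectrum,
    proteins: Sequence,
    tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
    frag_tol_da: float = DEFAULT_FRAGMENT_TOL_DA,
    allow_pglu: bool = True,
    max_len: int = DEFAULT_MAX_LEN,
    top: int | None = None,
) -> list[CandidateMatch]:
    """Ranked candidates for one spectrum over one or more parent proteins.

    Sort order: score desc, |precursor ppm| asc, span start asc, then
    protein id (a deterministic total order)."""
    if not proteins:
        raise ValueError("at least one parent protein is required")
    candidates: list[CandidateMatch] = []
    for prot in proteins:
        candidates.extend(
            candidate_peptides(
                prot, s.precursor_mz, s.precursor_charge,
                tol_ppm=tol_ppm, allow_pglu=allow_pglu, max_len=max_len,
            )
        )
    if len(s) == 0:
        return []
    scored = [score_candidate(s, c, tol_da=frag_tol_da) for c in candidates]
    scored.sort(
        key=lambda c: (-c.score, abs(c.precursor_ppm), c.span[0], c.protein_id)
    )
    return scored[:top] if top is not None else scored


def ranking_table(spectrum_id: str, ranked: Sequence[CandidateMatch]) -> str:
    lines = ["spectrum\trank\tpeptide\tprotein\tstart\tend\tscore\t"
             "precursor_ppm\tmatched_ions"]
    for rank, c in enumerate(ranked, 1):
        lines.append(
            f"{spectrum_id}\t{rank}\t{c.peptide.to_dashed()}\t{c.protein_id}\t"
            f"{c.span[0]}\t{c.span[1]}\t{c.score:.4f}\t{c.precursor_ppm:+.2f}\t"
            f"{c.matched_ions}"
        )
    return "\n".join(lines) + "\n"
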