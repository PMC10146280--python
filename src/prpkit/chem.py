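"""Molecular-formula and peptide mass arithmetic.

Monoisotopic element and amino-acid residue masses are loaded from a
versioned plain-text table bundled with the package (``data/masses.tsv``,
IUPAC/CODATA values). Peptides are modelled as residue strings with an
optional N-terminal pyroglutamate modification: cyclisation of an
N-terminal Gln loses NH3 (-17.0265 Da), of an N-terminal Glu loses H2O.
The canonical in-memory form of a molecule is the *neutral* species;
protons are added only when an m/z is requested, so cation formulas such
as C30H47N6O9+ are derived, never stored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ELEMENT_MASSES",
    "RESIDUE_MASSES",
    "RESIDUE_FORMULAS",
    "MolecularFormula",
    "Peptide",
    "parse_peptide",
    "formula_of_peptide",
    "monoisotopic_mass",
    "peptide_mass",
    "mz",
    "rdbe",
    "ppm_error",
    "WATER",
    "AMMONIA",
    "CO",
]

PROTON_MASS = 1.00727646688  # Da
ELECTRON_MASS = 0.00054857990  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _load_mass_table() -> tuple[dict[str, float], dict[str, float], dict[str, str]]:
    elements: dict[str, float] = {}
    residues: dict[str, float] = {}
    residue_formulas: dict[str, str] = {}
    text = resources.files("prpkit.data").joinpath("masses.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, symbol, mass, formula = line.split("\t")
        if kind == "element":
            elements[symbol] = float(mass)
        elif kind == "residue":
            residues[symbol] = float(mass)
            residue_formulas[symbol] = formula
        else:  # pragma: no cover - guards table edits
            raise ValueError(f"unknown mass-table row kind: {kind!r}")
    return elements, residues, residue_formulas


ELEMENT_MASSES, RESIDUE_MASSES, RESIDUE_FORMULAS = _load_mass_table()

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

THREE_LETTER = {
    "Ala": "A", "Cys": "C", "Asp": "D", "Glu": "E", "Phe": "F",
    "Gly": "G", "His": "H", "Ile": "I", "Lys": "K", "Leu": "L",
    "Met": "M", "Asn": "N", "Pro": "P", "Gln": "Q", "Arg": "R",
    "Ser": "S", "Thr": "T", "Val": "V", "Trp": "W", "Tyr": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_LETTER.items()}


class InvalidResidueError(ValueError):
    """Raised for residue codes outside the 20 canonical amino acids."""


def _parse_formula_string(s: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(s):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {s!r} at position {pos}")
        pos = m.end()
        elem, n = m.group(1), int(m.group(2) or 1)
        if elem not in ELEMENT_MASSES:
            raise ValueError(f"unknown element {elem!r} in formula {s!r}")
        counts[elem] = counts.get(elem, 0) + n
    if pos != len(s):
        raise ValueError(f"cannot parse formula {s!r} at position {pos}")
    return counts


@dataclass(frozen=True)
class MolecularFormula:
    """Element->count map for a neutral molecule or a cation.

    ``charge`` counts positive charges; the monoisotopic mass of a cation
    subtracts one electron mass per charge. Arithmetic is elementwise and
    refuses to go negative.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for elem, n in self.counts.items():
            if elem not in ELEMENT_MASSES:
                raise ValueError(f"unknown element {elem!r}")
            if n < 0:
                raise ValueError(f"negative count for {elem}: {n}")
            if n > 0:
                clean[elem] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_string(cls, s: str, charge: int = 0) -> "MolecularFormula":
        return cls(_parse_formula_string(s), charge=charge)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for elem, n in other.counts.items():
            counts[elem] = counts.get(elem, 0) + n
        return MolecularFormula(counts, charge=self.charge + other.charge)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.counts)
        for elem, n in other.counts.items():
            new = counts.get(elem, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {elem} count ({new})"
                )
            counts[elem] = new
        return MolecularFormula(counts, charge=self.charge - other.charge)

    def protonated(self, z: int = 1) -> "MolecularFormula":
        """Cation formula [M+zH]z+ (adds z hydrogens and z charges)."""
        if z <= 0:
            raise ValueError("z must be positive")
        counts = dict(self.counts)
        counts["H"] = counts.get("H", 0) + z
        return MolecularFormula(counts, charge=self.charge + z)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (electron-corrected for cations)."""
        m = sum(ELEMENT_MASSES[e] * n for e, n in self.counts.items())
        return m - self.charge * ELECTRON_MASS

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = ["C", "H"] + sorted(e for e in self.counts if e not in ("C", "H"))
        body = "".join(
            f"{e}{self.counts[e] if self.counts[e] != 1 else ''}"
            for e in order
            if self.counts.get(e, 0)
        )
        if self.charge > 0:
            body += "+" if self.charge == 1 else f"{self.charge}+"
        return body or "(empty)"


WATER = MolecularFormula.from_string("H2O")
AMMONIA = MolecularFormula.from_string("NH3")
CO = MolecularFormula.from_string("CO")

NTERM_MODS = ("none", "pGlu_from_Q", "pGlu_from_E")


@dataclass(frozen=True)
class Peptide:
    """A linear peptide: residue string, N-terminal modification, ambiguity.

    ``ambiguity`` marks 0-based positions where Leu and Ile could not be
    distinguished (they are isobaric); it is metadata only and never
    affects mass arithmetic.
    """

    residues: str
    nterm_mod: str = "none"
    ambiguity: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide must have at least one residue")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise InvalidResidueError(f"invalid residue code(s): {sorted(bad)}")
        if self.nterm_mod not in NTERM_MODS:
            raise ValueError(f"unknown nterm_mod {self.nterm_mod!r}")
        if self.nterm_mod == "pGlu_from_Q" and self.residues[0] != "Q":
            raise ValueError("pGlu_from_Q requires an N-terminal Gln")
        if self.nterm_mod == "pGlu_from_E" and self.residues[0] != "E":
            raise ValueError("pGlu_from_E requires an N-terminal Glu")
        object.__setattr__(self, "ambiguity", frozenset(self.ambiguity))
        for i in self.ambiguity:
            if not (0 <= i < len(self.residues)):
                raise ValueError(f"ambiguity position {i} out of range")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def nterm_delta(self) -> MolecularFormula | None:
        """Formula removed by the N-terminal modification, if any."""
        if self.nterm_mod == "pGlu_from_Q":
            return AMMONIA
        if self.nterm_mod == "pGlu_from_E":
            return WATER
        return None

    @property
    def nterm_delta_mass(self) -> float:
        d = self.nterm_delta
        return -d.mass if d is not None else 0.0

    def to_dashed(self) -> str:
        """Dashed three-letter form, e.g. ``pGlu-Pro-Leu-Pro-Pro-Thr``."""
        parts = []
        for i, r in enumerate(self.residues):
            if i == 0 and self.nterm_mod != "none":
                parts.append("pGlu")
            elif i in self.ambiguity and r in "LI":
                parts.append("Leu/Ile" if r == "L" else "Ile/Leu")
            else:
                parts.append(ONE_TO_THREE[r])
        return "-".join(parts)

    def __str__(self) -> str:
        return self.to_dashed()


def parse_peptide(text: str) -> Peptide:
    """Parse a peptide from dashed three-letter or one-letter notation.

    Accepted forms::

        pGlu-Pro-Leu-Pro-Pro-Thr     (dashed; pGlu = cyclised Gln or Glu)
        Pro-Phe-Pro-Gly-Pro-Ile/Leu-Pro   (Leu/Ile ambiguity token)
        QPLPPT+pGlu                  (one-letter with modification suffix)
        PPFLQPE                      (plain one-letter)

    A leading ``pGlu`` is interpreted as cyclised glutamine (the common
    case for these peptides); use ``pGlu(E)-...`` for a glutamate origin.
    """
    text = text.strip()
    if "-" in text and any(t in THREE_LETTER or t.lower().startswith("pglu")
                           or "/" in t for t in text.split("-")):
        tokens = text.split("-")
        residues: list[str] = []
        ambiguity: set[int] = set()
        nterm_mod = "none"
        for i, tok in enumerate(tokens):
            tok = tok.strip()
            low = tok.lower()
            if low in ("pglu", "pglu(q)", "pglu(e)"):
                if i != 0:
                    raise ValueError("pGlu is only valid at the N-terminus")
                if low == "pglu(e)":
                    nterm_mod, residues = "pGlu_from_E", ["E"]
                else:
                    nterm_mod, residues = "pGlu_from_Q", ["Q"]
            elif "/" in tok:
                first = tok.split("/")[0].strip()
                if first not in ("Leu", "Ile"):
                    raise InvalidResidueError(f"unknown residue token {tok!r}")
                ambiguity.add(i)
                residues.append(THREE_LETTER[first])
            elif tok in THREE_LETTER:
                residues.append(THREE_LETTER[tok])
            else:
                raise InvalidResidueError(f"unknown residue token {tok!r}")
        return Peptide("".join(residues), nterm_mod, frozenset(ambiguity))

    nterm_mod = "none"
    if "+" in text:
        text, mod = text.split("+", 1)
        mod = mod.strip().lower()
        if mod not in ("pglu", "pglu(q)", "pglu(e)"):
            raise ValueError(f"unknown modification {mod!r}")
        text = text.strip()
        if mod == "pglu(e)":
            nterm_mod = "pGlu_from_E"
        elif mod == "pglu(q)":
            nterm_mod = "pGlu_from_Q"
        else:
            nterm_mod = {"Q": "pGlu_from_Q", "E": "pGlu_from_E"}.get(text[:1])
            if nterm_mod is None:
                raise ValueError("pGlu requires an N-terminal Q or E")
    return Peptide(text.upper(), nterm_mod)


def formula_of_peptide(p: Peptide) -> MolecularFormula:
    """Neutral molecular formula: residue formulas + H2O, minus the
    N-terminal cyclisation loss (NH3 for Gln-derived pGlu, H2O for Glu)."""
    total = WATER
    for r in p.residues:
        if r not in RESIDUE_FORMULAS:
            raise InvalidResidueError(f"invalid residue code {r!r}")
        total = total + MolecularFormula.from_string(RESIDUE_FORMULAS[r])
    delta = p.nterm_delta
    if delta is not None:
        total = total - delta
    return total


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass of a formula in Da."""
    return f.mass


def peptide_mass(p: Peptide) -> float:
    """Neutral monoisotopic peptide mass in Da (fast residue-sum path)."""
    try:
        m = sum(RESIDUE_MASSES[r] for r in p.residues)
    except KeyError as exc:
        raise InvalidResidueError(f"invalid residue code {exc.args[0]!r}") from exc
    return m + WATER.mass + p.nterm_delta_mass


def mz(p: Peptide, z: int) -> float:
    """m/z of [M+zH]z+ for z in {1, 2, 3}."""
    if z <= 0:
        raise ValueError("charge must be positive")
    if z > 3:
        raise ValueError("charge states above 3+ are not supported")
    return (peptide_mass(p) + z * PROTON_MASS) / z


def rdbe(f: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalents: C - H/2 + N/2 + 1.

    Defined here for neutral CHNOS formulas; may be half-integer for
    cations (odd-electron bookkeeping).
    """
    c = f.counts.get("C", 0)
    h = f.counts.get("H", 0)
    n = f.counts.get("N", 0)
    return c - h / 2 + n / 2 + 1


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6
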