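"""Locate peptides within parent proteins and report fragment coordinates.

Matching is exact sliding-window comparison with two equivalence rules:
an N-terminal pyroglutamate matches the Gln (or Glu, per its origin
flag) it cyclised from, and Leu/Ile-ambiguous positions match either
isobaric residue. At peptide lengths of 5-9 residues this is what a
protein-database alignment degenerates to, minus the scoring noise.

The bovine beta-casein parent (UniProt P02666) ships as a bundled FASTA
fixture in *precursor* numbering (signal peptide included), which is the
coordinate system the fragment spans are reported in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import AMINO_ACIDS, Peptide

__all__ = [
    "ProteinRecord",
    "FragmentHit",
    "read_fasta",
    "write_fasta",
    "map_peptide",
    "beta_casein",
]


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    description: str
    sequence: str
    numbering_offset: int = 0  # added to 1-based positions in reported spans

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein record {self.id!r} has an empty sequence")
        seq = self.sequence.upper().replace("*", "")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains invalid residues: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentHit:
    """One occurrence of a peptide in a parent protein (1-based, inclusive,
    after applying the protein's numbering offset)."""

    protein_id: str
    start: int
    end: int
    peptide: Peptide
    equivalences_used: frozenset[str] = frozenset()

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a (multi-)FASTA file; sequences are uppercased, '*' stripped."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, desc, seq))
    return records


def write_fasta(records, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
         for r in records],
        str(path),
        "fasta",
    )


def _position_matches(pep_res: str, is_first: bool, p: Peptide,
                      pos_in_pep: int, prot_res: str) -> str | None:
    """Return the equivalence label used ('' for exact) or None on mismatch."""
    if is_first and p.nterm_mod == "pGlu_from_Q":
        return "pGlu=Q" if prot_res == "Q" else None
    if is_first and p.nterm_mod == "pGlu_from_E":
        return "pGlu=E" if prot_res == "E" else None
    if pos_in_pep in p.ambiguity and pep_res in "LI":
        if prot_res in "LI":
            return "" if prot_res == pep_res else "L=I"
        return None
    return "" if prot_res == pep_res else None


def map_peptide(p: Peptide, prot: ProteinRecord) -> list[FragmentHit]:
    """All occurrences of ``p`` in ``prot`` (overlaps allowed), with the
    pGlu and Leu/Ile equivalence rules; empty list if absent."""
    hits: list[FragmentHit] = []
    n, m = len(prot.sequence), len(p)
    for start0 in range(n - m + 1):
        used: set[str] = set()
        ok = True
        for k in range(m):
            label = _position_matches(
                p.residues[k], k == 0, p, k, prot.sequence[start0 + k]
            )
            if label is None:
                ok = False
                break
            if label:
                used.add(label)
        if ok:
            hits.append(
                FragmentHit(
                    protein_id=prot.id,
                    start=start0 + 1 + prot.numbering_offset,
                    end=start0 + m + prot.numbering_offset,
                    peptide=p,
                    equivalences_used=frozenset(used),
                )
            )
    return hits


def beta_casein() -> ProteinRecord:
    """The bundled bovine beta-casein (P02666) precursor fixture.

    Precursor (UniProt) numbering: position 1 is the initiator Met of
    the signal peptide, so numbering_offset is 0.
    """
    with resources.as_file(
        resources.files("prpkit.data").joinpath("P02666.fasta")
    ) as path:
        rec = read_fasta(path)[0]
    return ProteinRecord(rec.id, rec.description, rec.sequence, numbering_offset=0)
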