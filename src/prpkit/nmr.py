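"""Proline peptide-bond conformation from 13C chemical shifts.

For X-Pro bonds the difference between the proline Cbeta and Cgamma
13C shifts (delta-delta-beta-gamma) discriminates the two peptide-bond
rotamers: trans prolines show a small difference (< ~8 ppm) together
with a Cgamma shift above ~23 ppm, while cis prolines show a large
difference. The rule is applied exactly as stated: trans requires both
criteria; a difference at or above the threshold is called cis; a small
difference with a low Cgamma shift is left indeterminate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "ProlineShifts",
    "ProlineCall",
    "classify_proline",
    "read_shifts_csv",
    "compound1_proline_shifts",
    "verdict_table",
]

DELTA_THRESHOLD_PPM = 8.0   # trans iff delta_bg strictly below this ...
GAMMA_MIN_PPM = 23.0        # ... and Cgamma strictly above this


@dataclass(frozen=True)
class ProlineShifts:
    residue_label: str
    delta_c_beta: float   # ppm
    delta_c_gamma: float  # ppm

    def __post_init__(self) -> None:
        for name, v in (("Cbeta", self.delta_c_beta),
                        ("Cgamma", self.delta_c_gamma)):
            if not (0.0 <= v <= 200.0):
                raise ValueError(f"{name} shift {v} ppm outside 0-200 ppm")


@dataclass(frozen=True)
class ProlineCall:
    residue_label: str
    delta_bg: float  # Cbeta - Cgamma, ppm
    conformation: str  # trans | cis | indeterminate


def classify_proline(
    ps: ProlineShifts,
    threshold: float = DELTA_THRESHOLD_PPM,
    gamma_min: float = GAMMA_MIN_PPM,
) -> ProlineCall:
    """Apply the delta-beta-gamma rule to one proline.

    trans: delta_bg < threshold and Cgamma > gamma_min;
    cis:   delta_bg >= threshold (strict "below threshold" reading);
    indeterminate otherwise.
    """
    delta_bg = ps.delta_c_beta - ps.delta_c_gamma
    if delta_bg >= threshold:
        conf = "cis"
    elif ps.delta_c_gamma > gamma_min:
        conf = "trans"
    else:
        conf = "indeterminate"
    return ProlineCall(ps.residue_label, delta_bg, conf)


def read_shifts_csv(path) -> list[ProlineShifts]:
    """CSV with columns residue, delta_c_beta, delta_c_gamma (header row)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ProlineShifts(
                    row.get("residue") or row.get("residue_label"),
                    float(row["delta_c_beta"]),
                    float(row["delta_c_gamma"]),
                )
            )
    return out


def compound1_proline_shifts() -> list[ProlineShifts]:
    """Bundled 13C Cbeta/Cgamma shifts of the three prolines of the
    pGlu-Pro-Leu-Pro-Pro-Thr hexapeptide (CD3OD, 175 MHz)."""
    with resources.as_file(
        resources.files("prpkit.data").joinpath("compound1_proline_shifts.csv")
    ) as path:
        return read_shifts_csv(path)


def verdict_table(calls) -> str:
    lines = ["residue\tdelta_bg_ppm\tconformation"]
    for c in calls:
        lines.append(f"{c.residue_label}\t{c.delta_bg:.2f}\t{c.conformation}")
    return "\n".join(lines) + "\n"
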