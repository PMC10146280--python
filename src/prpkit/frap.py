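"""Ferric-reducing antioxidant power (FRAP) from plate absorbance kinetics.

The assay reads the Fe3+-TPTZ -> Fe2+-TPTZ colour change at 593 nm.
A sample's FRAP value against an ascorbic-acid positive control is

    FRAP = (A1 - A0) / (Ac - A0) * 2

with A1 the sample absorbance, Ac the positive control and A0 the
blank, all at the same read time. The factor 2 encodes the assay's
control-concentration convention and is kept verbatim. The value is
affine-invariant in the absorbances (adding a constant to all three, or
rescaling all three, changes nothing), which is what makes it robust to
plate-reader offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbsorbanceSeries",
    "FrapResult",
    "frap_value",
    "frap_kinetics",
    "calibrate_ascorbic",
    "read_plate_csv",
]

ROLES = ("sample", "positive_control", "blank")


@dataclass
class AbsorbanceSeries:
    """A593 kinetics for one well group: times (min) x replicates."""

    sample_id: str
    role: str
    times: np.ndarray          # minutes, strictly increasing
    a593: np.ndarray           # shape (n_replicates, n_times)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a593 = np.atleast_2d(np.asarray(self.a593, dtype=float))
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.a593.shape[1] != len(self.times):
            raise ValueError("a593 columns must match times")
        if np.any(self.a593 < 0):
            raise ValueError("absorbances must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.a593.shape[0]


@dataclass(frozen=True)
class FrapResult:
    sample_id: str
    time_min: float
    mean: float
    sd: float
    n: int


def frap_value(a1: float, ac: float, a0: float) -> float:
    """FRAP = (A1 - A0)/(Ac - A0) * 2; errors if the control equals the blank."""
    if ac == a0:
        raise ValueError("degenerate control: positive control equals blank")
    return (a1 - a0) / (ac - a0) * 2.0


def _nearest_column(times: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(times - t)))


def frap_kinetics(
    plate: Sequence[AbsorbanceSeries],
    read_times: Iterable[float] = (4.0, 16.0),
) -> list[FrapResult]:
    """Per-sample FRAP at each requested read time, mean +/- sd (n-1).

    The nearest acquired read is used (no interpolation). Sample
    replicates are normalised against the replicate means of the
    positive control and blank at that read.
    """
    blanks = [s for s in plate if s.role == "blank"]
    controls = [s for s in plate if s.role == "positive_control"]
    samples = [s for s in plate if s.role == "sample"]
    if not blanks or not controls:
        raise ValueError("plate must contain a blank and a positive control")

    results: list[FrapResult] = []
    for t in read_times:
        a0 = float(np.mean([b.a593[:, _nearest_column(b.times, t)].mean()
                            for b in blanks]))
        ac = float(np.mean([c.a593[:, _nearest_column(c.times, t)].mean()
                            for c in controls]))
        for s in samples:
            col = _nearest_column(s.times, t)
            vals = np.array([frap_value(a1, ac, a0) for a1 in s.a593[:, col]])
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            results.append(
                FrapResult(s.sample_id, float(t), float(vals.mean()), sd, len(vals))
            )
    return results


def calibrate_ascorbic(
    standards: Sequence[tuple[float, float]], blank: float = 0.0
) -> tuple[float, float, float]:
    """OLS fit of blank-corrected absorbance vs concentration (uM).

    Returns (slope, intercept, r_squared). Needs >= 2 distinct
    concentrations.
    """
    conc = np.array([c for c, _ in standards], dtype=float)
    absorb = np.array([a for _, a in standards], dtype=float) - blank
    if len(conc) < 2 or np.allclose(conc, conc[0]):
        raise ValueError("need at least 2 distinct standard concentrations")
    fit = stats.linregress(conc, absorb)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def read_plate_csv(path) -> list[AbsorbanceSeries]:
    """Plate layout CSV: sample_id, role, time_min, a593, replicate."""
    df = pd.read_csv(path)
    required = {"sample_id", "role", "time_min", "a593", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    out = []
    for (sid, role), grp in df.groupby(["sample_id", "role"], sort=True):
        wide = grp.pivot_table(
            index="replicate", columns="time_min", values="a593"
        ).sort_index()
        if wide.isna().any().any():
            raise ValueError(f"incomplete time series for sample {sid!r}")
        out.append(
            AbsorbanceSeries(str(sid), str(role),
                             wide.columns.to_numpy(float), wide.to_numpy(float))
        )
    return out


def results_table(results: Sequence[FrapResult]) -> str:
    lines = ["sample_id\ttime_min\tfrap_mean\tfrap_sd\tn"]
    for r in results:
        lines.append(
            f"{r.sample_id}\t{r.time_min:g}\t{r.mean:.3f}\t{r.sd:.3f}\t{r.n}"
        )
    return "\n".join(lines) + "\n"
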