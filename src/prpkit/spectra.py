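"""Spectrum container, MGF reading/writing and peak-list preprocessing.

The MGF dialect is the GNPS/Mascot one: ``BEGIN IONS``/``END IONS``
blocks with ``PEPMASS`` (optionally carrying a precursor intensity as a
second token), ``CHARGE`` written as ``1+``, optional ``RTINSECONDS``
(stored internally in minutes) and ``TITLE``. Reading goes through
pyteomics; unknown headers are preserved across a round trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

__all__ = ["Spectrum", "MGFParseError", "read_mgf", "write_mgf", "preprocess"]


class MGFParseError(ValueError):
    """Raised when an MGF file cannot be parsed."""


@dataclass
class Spectrum:
    """An MS/MS record: precursor (m/z, charge), sorted peak list, metadata.

    Peaks are kept sorted ascending by m/z; intensities must be >= 0.
    """

    id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    rt_min: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0


def read_mgf(path) -> list[Spectrum]:
    """Read a GNPS-style MGF file into Spectrum objects.

    Records missing PEPMASS are skipped with a warning; a structurally
    malformed file raises :class:`MGFParseError`.
    """
    spectra: list[Spectrum] = []
    try:
        with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
            for i, rec in enumerate(reader):
                params = dict(rec.get("params", {}))
                pepmass = params.pop("pepmass", None)
                if pepmass is None or pepmass[0] is None:
                    warnings.warn(
                        f"MGF record {i} in {path} has no PEPMASS; skipped"
                    )
                    continue
                prec_mz = float(pepmass[0])
                charge_list = params.pop("charge", None)
                charge = int(charge_list[0]) if charge_list else 1
                rt = params.pop("rtinseconds", None)
                rt_min = float(rt) / 60.0 if rt is not None else None
                title = str(params.pop("title", f"scan_{i}"))
                if pepmass[1] is not None:
                    params["precursor_intensity"] = float(pepmass[1])
                spectra.append(
                    Spectrum(
                        id=title,
                        precursor_mz=prec_mz,
                        precursor_charge=charge,
                        mz=rec["m/z array"],
                        intensity=rec["intensity array"],
                        rt_min=rt_min,
                        params=params,
                    )
                )
    except MGFParseError:
        raise
    except Exception as exc:  # pyteomics raises various auxiliary errors
        raise MGFParseError(f"cannot parse MGF file {path}: {exc}") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra as GNPS-dialect MGF (CHARGE as ``1+``, RTINSECONDS)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            prec_int = s.params.get("precursor_intensity")
            if prec_int is not None:
                fh.write(f"PEPMASS={s.precursor_mz:.6f} {prec_int:.1f}\n")
            else:
                fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            if s.rt_min is not None:
                fh.write(f"RTINSECONDS={s.rt_min * 60.0:.3f}\n")
            for key, value in s.params.items():
                if key == "precursor_intensity":
                    continue
                fh.write(f"{key.upper()}={value}\n")
            for mz_val, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz_val:.6f} {inten:.4f}\n")
            fh.write("END IONS\n\n")


def preprocess(
    s: Spectrum,
    min_rel_intensity: float = 0.0,
    top_k_per_window: int | None = None,
    window: float = 50.0,
) -> Spectrum:
    """Noise-filter a peak list.

    Removes peaks below ``min_rel_intensity`` x base peak, then keeps a
    peak only if it ranks among the ``top_k_per_window`` most intense
    peaks within the +/- window/2 neighbourhood centred on it (intensity
    ties resolved toward lower m/z). Idempotent for fixed parameters;
    never reorders peaks.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mz = s.mz
    inten = s.intensity
    keep = np.ones(len(mz), dtype=bool)
    if len(mz) and min_rel_intensity > 0:
        keep &= inten >= min_rel_intensity * inten.max()
    mz, inten = mz[keep], inten[keep]

    if top_k_per_window is not None and len(mz):
        half = window / 2.0
        keep2 = np.zeros(len(mz), dtype=bool)
        for i in range(len(mz)):
            lo = np.searchsorted(mz, mz[i] - half, side="left")
            hi = np.searchsorted(mz, mz[i] + half, side="right")
            # rank of peak i inside its window: better = more intense,
            # ties broken toward lower m/z (lower index).
            rank = sum(
                1
                for j in range(lo, hi)
                if inten[j] > inten[i] or (inten[j] == inten[i] and j < i)
            )
            keep2[i] = rank < top_k_per_window
        mz, inten = mz[keep2], inten[keep2]

    return Spectrum(
        id=s.id,
        precursor_mz=s.precursor_mz,
        precursor_charge=s.precursor_charge,
        mz=mz,
        intensity=inten,
        rt_min=s.rt_min,
        params=dict(s.params),
    )
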