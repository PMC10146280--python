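"""Fragment-ladder arithmetic and annotation, checked against an
independent residue-mass summation oracle and brute-force matching."""

import itertools

import numpy as np
import pytest

from prpkit import (
    Peptide,
    annotate_spectrum,
    fragment_ladder,
    internal_fragments,
    parse_peptide,
    peptide_mass,
    ppm_error,
    theoretical_ions,
)
from prpkit.chem import PROTON_MASS, RESIDUE_MASSES, WATER
from prpkit.spectra import Spectrum

from conftest import random_peptide

CO_MASS = 27.994915


def spectrum_from_mz(mzs, intensities=None, precursor=1000.0, sid="t"):
    mzs = np.asarray(mzs, dtype=float)
    if intensities is None:
        intensities = np.ones_like(mzs)
    return Spectrum(sid, precursor, 1, mzs, np.asarray(intensities, float))


class TestLadders:
    def test_b5_of_pyroglutamyl_hexapeptide(self):
        """b5 = loss of the terminal Thr from pGlu-Pro-Leu-Pro-Pro-Thr."""
        p = parse_peptide("pGlu-Pro-Leu-Pro-Pro-Thr")
        b = {ion.span[1]: ion.mz for ion in fragment_ladder(p, "b")}
        # oracle: residue sum (Q-NH3, P, L, P, P) + proton
        oracle = (
            RESIDUE_MASSES["Q"] - 17.02654910
            + 3 * RESIDUE_MASSES["P"] + RESIDUE_MASSES["L"] + PROTON_MASS
        )
        assert b[5] == pytest.approx(oracle, abs=1e-6)
        assert b[5] == pytest.approx(516.2817, abs=0.005)

    def test_a_equals_b_minus_co(self, rng):
        for _ in range(20):
            p = random_peptide(rng, 2, 10)
            b = fragment_ladder(p, "b", losses=())
            a = fragment_ladder(p, "a", losses=())
            for bi, ai in zip(b, a):
                assert ai.mz == pytest.approx(bi.mz - CO_MASS, abs=1e-5)

    def test_y1_of_diglycine_is_protonated_glycine(self):
        y = fragment_ladder(Peptide("GG"), "y")
        assert y[0].mz == pytest.approx(76.0393, abs=1e-3)

    def test_ladder_monotonic(self, rng):
        for _ in range(20):
            p = random_peptide(rng, 3, 12)
            for series in ("b", "y"):
                mzs = [i.mz for i in fragment_ladder(p, series, losses=())]
                assert all(x < y for x, y in zip(mzs, mzs[1:]))

    def test_complementarity(self, rng):
        """b_i + y_(n-i) = M + 2*proton for singly charged ions."""
        for _ in range(100):
            p = random_peptide(rng, 2, 15)
            n = len(p)
            b = {i.span[1]: i.mz for i in fragment_ladder(p, "b", losses=())}
            y = {i.span[1] - i.span[0] + 1: i.mz
                 for i in fragment_ladder(p, "y", losses=())}
            total = peptide_mass(p) + 2 * PROTON_MASS
            for i in range(1, n):
                assert b[i] + y[n - i] == pytest.approx(total, abs=1e-6)

    def test_y_series_unaffected_by_pglu(self):
        plain = fragment_ladder(Peptide("QPLPPT"), "y", losses=())
        modded = fragment_ladder(Peptide("QPLPPT", "pGlu_from_Q"), "y", losses=())
        for a, b in zip(plain, modded):
            assert a.mz == pytest.approx(b.mz, abs=1e-9)

    def test_default_water_loss_policy(self):
        with_thr = fragment_ladder(parse_peptide("pGlu-Pro-Leu-Pro-Pro-Thr"), "y")
        assert any(ion.losses == ("H2O",) for ion in with_thr)
        with_pro = fragment_ladder(parse_peptide("PPFLQP"), "y")
        assert all(ion.losses == () for ion in with_pro)

    def test_bad_series_rejected(self):
        with pytest.raises(ValueError):
            fragment_ladder(Peptide("GG"), "c")

    def test_multiply_charged(self):
        p = parse_peptide("VVPPFLQPE")
        ions = fragment_ladder(p, "b", max_charge=2, losses=())
        singles = {i.span: i.mz for i in ions if i.charge == 1}
        doubles = {i.span: i.mz for i in ions if i.charge == 2}
        for span, m2 in doubles.items():
            neutral = singles[span] - PROTON_MASS
            assert m2 == pytest.approx((neutral + 2 * PROTON_MASS) / 2, abs=1e-9)


class TestInternalFragments:
    def test_pgpi_matches_published_value(self):
        p = parse_peptide("Pro-Phe-Pro-Gly-Pro-Ile-Pro")
        ions = {i.span: i.mz for i in internal_fragments(p)}
        assert abs(ppm_error(365.2179, ions[(3, 6)])) < 5.0

    def test_bounds_errors(self):
        p = parse_peptide("PFPGPIP")
        with pytest.raises(ValueError):
            internal_fragments(p, min_len=4, max_len=3)
        with pytest.raises(ValueError):
            internal_fragments(Peptide("PFP"))

    def test_spans_exclude_termini(self, rng):
        for _ in range(10):
            p = random_peptide(rng, 4, 10)
            for ion in internal_fragments(p):
                assert ion.span[0] >= 2 and ion.span[1] <= len(p) - 1

    def test_matches_summation_oracle(self, rng):
        for _ in range(10):
            p = random_peptide(rng, 4, 10)
            for ion in internal_fragments(p):
                i, j = ion.span
                oracle = sum(RESIDUE_MASSES[r]
                             for r in p.residues[i - 1:j]) + PROTON_MASS
                assert ion.mz == pytest.approx(oracle, abs=1e-9)


class TestAnnotation:
    def test_exact_ladder_fully_annotated(self):
        p = parse_peptide("pGlu-Pro-Leu-Pro-Pro")
        ions = theoretical_ions(p)
        s = spectrum_from_mz([i.mz for i in ions])
        ann = annotate_spectrum(s, p, tol=0.02)
        assert len(ann) == len(s)
        assert all(abs(a.ppm) < 1e-9 for a in ann)

    def test_shifted_peaks_never_match(self):
        p = parse_peptide("pGlu-Pro-Leu-Pro-Pro")
        ions = theoretical_ions(p)
        s = spectrum_from_mz([i.mz + 0.5 for i in ions])
        assert annotate_spectrum(s, p, tol=0.02) == []

    def test_injective_both_ways(self, rng):
        p = random_peptide(rng, 5, 10)
        noise = rng.uniform(100, 1000, 50)
        ion_mzs = [i.mz for i in theoretical_ions(p)]
        s = spectrum_from_mz(np.concatenate([ion_mzs, noise]))
        ann = annotate_spectrum(s, p, tol=0.02)
        peaks = [a.peak_index for a in ann]
        ions = [(a.ion.series, a.ion.span, a.ion.charge, a.ion.losses) for a in ann]
        assert len(peaks) == len(set(peaks))
        assert len(ions) == len(set(ions))

    def test_matches_bruteforce_minimum_delta_matching(self):
        """Toy near-tie: greedy assignment equals the exhaustive
        maximum-cardinality, minimum-total-|delta| matching."""
        ion_mzs = [100.0, 200.0, 300.0, 400.0, 500.0, 600.0]
        peak_mzs = [100.004, 199.995, 300.015, 400.019, 500.018]
        tol = 0.02
        from prpkit.fragments import FragmentIon

        ladder = [FragmentIon("b", (1, k + 1), 1, (), m)
                  for k, m in enumerate(ion_mzs)]
        s = spectrum_from_mz(peak_mzs)
        ann = annotate_spectrum(s, parse_peptide("GG"), tol=tol, ions=ladder)
        got = {(a.peak_index, a.ion.mz) for a in ann}

        # brute force over all injective peak->ion assignments
        best = None
        for perm in itertools.permutations(range(len(ion_mzs)), len(peak_mzs)):
            pairs = [
                (pi, ion_mzs[ii])
                for pi, ii in enumerate(perm)
                if abs(peak_mzs[pi] - ion_mzs[ii]) <= tol
            ]
            total = sum(abs(peak_mzs[pi] - m) for pi, m in pairs)
            key = (-len(pairs), total)
            if best is None or key < best[0]:
                best = (key, set(pairs))
        assert got == best[1]

    def test_tolerance_validation(self):
        s = spectrum_from_mz([100.0])
        with pytest.raises(ValueError):
            annotate_spectrum(s, Peptide("GG"), tol=0.0)
        with pytest.raises(ValueError):
            annotate_spectrum(s, Peptide("GG"), tol=0.02, mode="th")

    def test_empty_spectrum_rejected(self):
        s = Spectrum("e", 500.0, 1, np.array([]), np.array([]))
        with pytest.raises(ValueError):
            annotate_spectrum(s, Peptide("GG"))

    def test_ppm_mode(self):
        p = parse_peptide("PPFLQPE")
        ions = theoretical_ions(p)
        shift = [i.mz * (1 + 3e-6) for i in ions]  # +3 ppm
        s = spectrum_from_mz(shift)
        ann = annotate_spectrum(s, p, tol=5.0, mode="ppm")
        assert len(ann) == len(ions)
        assert annotate_spectrum(s, p, tol=1.0, mode="ppm") == []
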