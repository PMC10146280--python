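"""Modified cosine against brute force and matchms, and network topology
filtering."""

import itertools

import numpy as np
import pytest

from prpkit import (
    SimulationConfig,
    Spectrum,
    build_network,
    export_graphml,
    modified_cosine,
    parse_peptide,
    simulate_spectrum,
)
from prpkit.networking import read_graphml


def spec(sid, precursor, mzs, intens=None, charge=1):
    mzs = np.asarray(mzs, float)
    intens = np.ones_like(mzs) if intens is None else np.asarray(intens, float)
    return Spectrum(sid, precursor, charge, mzs, intens)


def brute_force_modified_cosine(s1, s2, frag_tol, allow_shift):
    """Exhaustive maximum over all one-to-one peak pairings."""
    w1, w2 = np.sqrt(s1.intensity), np.sqrt(s2.intensity)
    norm = np.linalg.norm(w1) * np.linalg.norm(w2)
    shift = s1.precursor_mz - s2.precursor_mz
    allowed = [
        (i, j)
        for i in range(len(s1))
        for j in range(len(s2))
        if abs(s1.mz[i] - s2.mz[j]) <= frag_tol
        or (allow_shift and abs(s1.mz[i] - s2.mz[j] - shift) <= frag_tol)
    ]
    best = (0.0, 0)
    idx2 = sorted({j for _, j in allowed})
    for r in range(len(idx2) + 1):
        for sub1 in itertools.permutations(range(len(s1)), r):
            for sub2 in itertools.permutations(idx2, r):
                pairs = list(zip(sub1, sub2))
                if all((i, j) in allowed for i, j in pairs):
                    total = sum(w1[i] * w2[j] for i, j in pairs)
                    best = max(best, (total / norm if norm else 0.0, len(pairs)))
    return best


class TestModifiedCosine:
    def test_identical_spectra(self, rng):
        s = spec("a", 500.0, np.sort(rng.uniform(100, 490, 12)),
                 rng.uniform(1, 100, 12))
        cos, matched = modified_cosine(s, s)
        assert cos == pytest.approx(1.0, abs=1e-9)
        assert matched == len(s)

    def test_disjoint_no_shift(self):
        s1 = spec("a", 500.0, [100.0, 200.0])
        s2 = spec("b", 500.0, [150.0, 250.0])
        cos, matched = modified_cosine(s1, s2, allow_shift=False)
        assert cos == 0.0 and matched == 0

    def test_three_peak_bruteforce(self, rng):
        for _ in range(30):
            p1 = float(rng.uniform(400, 600))
            p2 = p1 + float(rng.choice([0.0, rng.uniform(-50, 50)]))
            s1 = spec("a", p1, np.sort(rng.uniform(100, 390, 3)),
                      rng.uniform(1, 100, 3))
            s2 = spec("b", p2, np.sort(rng.uniform(100, 390, 3)),
                      rng.uniform(1, 100, 3))
            got_cos, got_n = modified_cosine(s1, s2, frag_tol=0.5)
            exp_cos, _ = brute_force_modified_cosine(s1, s2, 0.5, True)
            assert got_cos == pytest.approx(exp_cos, abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(10):
            s1 = spec("a", float(rng.uniform(400, 600)),
                      np.sort(rng.uniform(100, 390, 8)), rng.uniform(1, 100, 8))
            s2 = spec("b", float(rng.uniform(400, 600)),
                      np.sort(rng.uniform(100, 390, 8)), rng.uniform(1, 100, 8))
            ab = modified_cosine(s1, s2)
            ba = modified_cosine(s2, s1)
            assert ab[0] == pytest.approx(ba[0], abs=1e-9)
            assert ab[1] == ba[1]

    def test_bounded_by_one(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 10)), int(rng.integers(2, 10))
            s1 = spec("a", float(rng.uniform(400, 600)),
                      np.sort(rng.uniform(100, 390, n1)), rng.uniform(1, 100, n1))
            s2 = spec("b", float(rng.uniform(400, 600)),
                      np.sort(rng.uniform(100, 390, n2)), rng.uniform(1, 100, n2))
            cos, _ = modified_cosine(s1, s2, frag_tol=1.0)
            assert 0.0 <= cos <= 1.0

    def test_no_shift_same_precursor_equals_plain_cosine(self, rng):
        mzs = np.sort(rng.uniform(100, 450, 10))
        i1, i2 = rng.uniform(1, 100, 10), rng.uniform(1, 100, 10)
        s1, s2 = spec("a", 500.0, mzs, i1), spec("b", 500.0, mzs, i2)
        got, matched = modified_cosine(s1, s2, allow_shift=False)
        w1, w2 = np.sqrt(i1), np.sqrt(i2)
        plain = float(w1 @ w2 / (np.linalg.norm(w1) * np.linalg.norm(w2)))
        assert got == pytest.approx(plain, abs=1e-9)
        assert matched == 10

    def test_agrees_with_matchms(self, rng):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        for trial in range(5):
            base = np.sort(rng.uniform(100, 400, 10))
            s1 = spec("a", 450.0, base, rng.uniform(1, 100, 10))
            shift = float(rng.uniform(5, 40))
            s2 = spec("b", 450.0 + shift,
                      np.sort(np.concatenate([base[:5], base[5:] + shift])),
                      rng.uniform(1, 100, 10))
            m1 = matchms.Spectrum(mz=s1.mz, intensities=s1.intensity,
                                  metadata={"precursor_mz": s1.precursor_mz})
            m2 = matchms.Spectrum(mz=s2.mz, intensities=s2.intensity,
                                  metadata={"precursor_mz": s2.precursor_mz})
            ref = ModifiedCosine(tolerance=0.02).pair(m1, m2)
            # matchms scales intensities the same way (sqrt off by default:
            # it uses raw products), so compare our raw-product variant
            got, matched = modified_cosine(
                Spectrum("a", s1.precursor_mz, 1, s1.mz, s1.intensity**2),
                Spectrum("b", s2.precursor_mz, 1, s2.mz, s2.intensity**2),
            )
            assert got == pytest.approx(float(ref["score"]), abs=1e-6)
            assert matched == int(ref["matches"])

    def test_empty_spectrum_rejected(self):
        s1 = spec("a", 500.0, [100.0])
        s2 = Spectrum("b", 500.0, 1, np.array([]), np.array([]))
        with pytest.raises(ValueError):
            modified_cosine(s1, s2)


class TestBuildNetwork:
    def test_single_spectrum(self):
        net = build_network([spec("a", 500.0, [100.0, 200.0, 300.0])])
        assert net.nodes == ["a"] and net.edges == []

    def test_related_cluster_vs_noise_singletons(self, rng):
        """Spectra sharing a fragment ladder form one component; random
        noise spectra stay singletons."""
        cfg = SimulationConfig(seed=11, mz_jitter_ppm_sigma=3.0,
                               fragment_dropout_rate=0.05, n_noise_peaks=3)
        parent = parse_peptide("VVPPFLQPEV")
        related = [parse_peptide(parent.residues[k:]) for k in range(3)]
        r = np.random.default_rng(11)
        spectra = [simulate_spectrum(p, cfg, rng=r, charge=1,
                                     spectrum_id=f"rel_{k}")
                   for k, p in enumerate(related)]
        for k in range(3):
            mzs = np.sort(r.uniform(100, 900, 25))
            spectra.append(spec(f"noise_{k}", float(r.uniform(400, 900)), mzs,
                                r.uniform(1, 100, 25)))
        net = build_network(spectra, cosine_min=0.7, min_matched=3)
        comps = net.components()
        rel_comp = next(c for c in comps if "rel_0" in c)
        assert rel_comp == {"rel_0", "rel_1", "rel_2"}
        for k in range(3):
            assert {f"noise_{k}"} in comps

    def test_analog_cap_blocks_distant_precursors(self):
        mzs = [100.0, 200.0, 300.0, 400.0]
        s1 = spec("a", 500.0, mzs)
        s2 = spec("b", 900.0, mzs)
        assert build_network([s1, s2], analog_max_delta=300.0).edges == []
        assert len(build_network([s1, s2], analog_max_delta=500.0).edges) == 1

    def test_component_pruning_caps_size(self):
        # chain of near-identical spectra: unpruned it is one huge component
        base = np.array([100.0, 150.0, 200.0, 250.0, 300.0])
        spectra = [spec(f"s{i:03d}", 400.0 + 0.001 * i, base + 0.001 * i)
                   for i in range(30)]
        net = build_network(spectra, max_component=10)
        assert all(len(c) <= 10 for c in net.components())
        assert set(net.nodes) == {s.id for s in spectra}  # nodes never deleted

    def test_graphml_roundtrip(self, tmp_path, rng):
        s_list = [spec(f"s{i}", 400.0 + i, np.sort(rng.uniform(100, 390, 5)),
                       rng.uniform(1, 10, 5)) for i in range(4)]
        s_list.append(spec("dup", 400.0, s_list[0].mz, s_list[0].intensity))
        net = build_network(s_list, cosine_min=0.5, min_matched=3)
        path = tmp_path / "net.graphml"
        export_graphml(net, path)
        back = read_graphml(path)
        assert sorted(back.nodes) == sorted(net.nodes)
        assert len(back.edges) == len(net.edges)
        if net.edges:
            e = back.edges[0]
            assert 0.0 <= e.cosine <= 1.0 and e.matched_peaks >= 3

    def test_empty_edge_network_exports(self, tmp_path):
        net = build_network([spec("a", 500.0, [100.0])])
        path = tmp_path / "solo.graphml"
        export_graphml(net, path)
        assert read_graphml(path).nodes == ["a"]
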