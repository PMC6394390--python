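"""Isotope arithmetic, envelope prediction and matching.

The envelope predictor is checked against an independent brute-force
oracle that enumerates the full multinomial expansion of the per-element
isotope distributions for small compositions.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pmass

from pepquant.errors import ContractError, InputError
from pepquant.isotopes import (
    ENRICHED_VARIANTS,
    PROTON_MASS,
    ElementalComposition,
    apply_label,
    composition_from_peptide,
    dynamic_match_tolerance,
    load_scheme,
    load_scheme_catalogue,
    match_pattern,
    monoisotopic_mz,
    theoretical_pattern,
)
from pepquant.ms_io import Spectrum


def brute_force_pattern(counts, enrichment=None):
    """Oracle: full multinomial enumeration, aggregated by nominal offset.

    Returns offset -> (probability, abundance-weighted mean mass), offsets
    relative to the all-principal-isotope species.
    """

    def isotopes(sym):
        if sym in ENRICHED_VARIANTS:
            el, iso = ENRICHED_VARIANTS[sym]
            frac = (enrichment or {}).get(sym, 1.0)
            heavy = pmass.nist_mass[el][iso][0]
            light = min(
                m for k, (m, ab) in pmass.nist_mass[el].items() if k and ab > 0
            )
            out = [(0, heavy, frac)]
            if frac < 1:
                out.append((round(light - heavy), light, 1 - frac))
            return out
        table = pmass.nist_mass[sym]
        isos = sorted(
            (m, ab) for k, (m, ab) in table.items() if k and ab > 0
        )
        mono = isos[0][0]
        return [(round(m - mono), m, ab) for m, ab in isos]

    per_element = []
    for sym, n in counts.items():
        isos = isotopes(sym)
        combos = []
        # distribute n atoms over the isotopes (multinomial)
        for parts in itertools.product(range(n + 1), repeat=len(isos)):
            if sum(parts) != n:
                continue
            prob = float(math.factorial(n))
            m = 0.0
            off = 0
            for k, (o, mass_k, ab) in zip(parts, isos):
                prob = prob / math.factorial(k) * (ab**k)
                m += k * mass_k
                off += k * o
            combos.append((off, prob, m))
        per_element.append(combos)

    agg = {}
    for combo in itertools.product(*per_element):
        off = sum(c[0] for c in combo)
        p = math.prod(c[1] for c in combo)
        m = sum(c[2] for c in combo)
        if p < 1e-18:
            continue
        q, qm = agg.get(off, (0.0, 0.0))
        agg[off] = (q + p, qm + p * m)
    return {o: (p, pm / p) for o, (p, pm) in agg.items() if p > 0}


class TestComposition:
    def test_glycine_formula(self):
        comp = composition_from_peptide("G")
        assert comp.nonzero() == {"C": 2, "H": 5, "N": 1, "O": 2}

    def test_diglycine_formula(self):
        assert composition_from_peptide("GG").nonzero() == {
            "C": 4, "H": 8, "N": 2, "O": 3,
        }

    def test_unknown_residue_rejected(self):
        with pytest.raises(InputError):
            composition_from_peptide("GXG")

    def test_mass_only_modification_flagged(self):
        comp = composition_from_peptide("GK", [(2, 57.02146, "cam")])
        assert comp.mass_only_mods
        assert comp.extra_mass == pytest.approx(57.02146)

    def test_modification_with_formula_enters_counts(self):
        comp = composition_from_peptide(
            "GK", [(2, 57.02146, "cam")],
            modification_formulas={"cam": {"C": 2, "H": 3, "N": 1, "O": 1}},
        )
        assert not comp.mass_only_mods
        assert comp.counts["C"] == composition_from_peptide("GK").counts["C"] + 2


class TestMonoisotopicMz:
    def test_glycine_singly_charged(self):
        comp = composition_from_peptide("G")
        assert monoisotopic_mz(comp, 1) == pytest.approx(76.03930, abs=1e-4)

    def test_charge_two_identity(self):
        comp = composition_from_peptide("ALGVSEK")
        mz1 = monoisotopic_mz(comp, 1)
        assert monoisotopic_mz(comp, 2) == pytest.approx(
            (mz1 + PROTON_MASS) / 2, abs=1e-9
        )

    def test_empty_composition_is_proton(self):
        assert monoisotopic_mz(ElementalComposition({}), 1) == pytest.approx(
            PROTON_MASS
        )

    def test_zero_charge_rejected(self):
        with pytest.raises(ContractError):
            monoisotopic_mz(ElementalComposition({"C": 1}), 0)


class TestTheoreticalPattern:
    def test_single_carbon_ratio(self):
        p = theoretical_pattern(ElementalComposition({"C": 1}), 1, 2)
        assert p.rel_abundance[1] / p.rel_abundance[0] == pytest.approx(
            0.0107 / 0.9893, abs=1e-6
        )

    @pytest.mark.parametrize(
        "counts",
        [
            {"C": 6, "H": 12, "O": 6},
            {"C": 10, "N": 5, "S": 2},
            {"C": 2, "H": 5, "N": 1, "O": 2},
            {"S": 4},
        ],
    )
    def test_matches_brute_force_enumeration(self, counts):
        oracle = brute_force_pattern(counts)
        pmax = max(p for p, _ in oracle.values())
        pattern = theoretical_pattern(ElementalComposition(counts), 1, 5)
        for k in range(5):
            idx = pattern.monoisotopic_index + k
            want_p, want_m = oracle[k]
            assert pattern.rel_abundance[idx] == pytest.approx(
                want_p / pmax, abs=1e-9
            )
            assert pattern.mz[idx] == pytest.approx(
                want_m + PROTON_MASS, abs=1e-9
            )

    def test_enriched_composition_matches_brute_force(self):
        counts = {"C": 5, "N15": 4, "H": 8, "O": 2}
        enr = {"N15": 0.95}
        oracle = brute_force_pattern(counts, enr)
        pattern = theoretical_pattern(
            ElementalComposition(counts), 1, 4, enrichment=enr
        )
        pmax = max(p for p, _ in oracle.values())
        mono = pattern.monoisotopic_index
        for i in range(len(pattern)):
            off = i - mono
            want_p, _ = oracle[off]
            assert pattern.rel_abundance[i] == pytest.approx(want_p / pmax, abs=1e-9)

    def test_fully_enriched_is_mono_dominant(self):
        p = theoretical_pattern(
            ElementalComposition({"C13": 10, "N15": 3}), 1, 3
        )
        assert p.monoisotopic_index == 0
        assert p.rel_abundance[0] == 1.0

    def test_spacing_near_neutron_mass(self):
        comp = composition_from_peptide("ALGVSEK")
        for z in (1, 2, 3):
            p = theoretical_pattern(comp, z, 4)
            spacing = np.diff(p.mz)
            assert np.allclose(spacing, 1.003355 / z, atol=0.01 / z)

    def test_mass_only_extra_shifts_all_peaks(self):
        comp = composition_from_peptide("ALGVSEK")
        shifted = composition_from_peptide("ALGVSEK", [(1, 57.02146, "x")])
        p0 = theoretical_pattern(comp, 2, 3)
        p1 = theoretical_pattern(shifted, 2, 3)
        assert np.allclose(p1.mz - p0.mz, 57.02146 / 2, atol=1e-9)
        assert np.allclose(p1.rel_abundance, p0.rel_abundance)


class TestApplyLabel:
    def test_silac_heavy_shift_per_lysine(self):
        scheme = load_scheme("silac_k8r10")
        comp = composition_from_peptide("AKGLK")
        res = apply_label(comp, "AKGLK", scheme, 1)
        assert res.applicable
        assert res.mass_shift == pytest.approx(2 * 8.014199, abs=1e-4)
        assert res.composition.monoisotopic_mass() - comp.monoisotopic_mass() == \
            pytest.approx(2 * 8.014199, abs=1e-4)

    def test_full_15n_shift_counts_nitrogens(self):
        scheme = load_scheme("n15")
        comp = composition_from_peptide("ALGVSEK")  # 8 N
        n = comp.counts["N"]
        res = apply_label(comp, "ALGVSEK", scheme, 1)
        assert res.mass_shift == pytest.approx(n * 0.997035, abs=1e-4)
        assert res.composition.counts.get("N", 0) == 0
        assert res.composition.counts["N15"] == n

    def test_light_channel_is_identity(self):
        scheme = load_scheme("silac_k8r10")
        comp = composition_from_peptide("AKGLK")
        res = apply_label(comp, "AKGLK", scheme, 0)
        assert res.composition == comp
        assert res.mass_shift == 0.0

    def test_unlabelable_peptide_flagged(self):
        scheme = load_scheme("silac_k8r10")
        comp = composition_from_peptide("ALGVSE")
        res = apply_label(comp, "ALGVSE", scheme, 1)
        assert not res.applicable
        assert res.composition == comp

    def test_label_shifts_envelope_uniformly(self):
        scheme = load_scheme("silac_k8r10")
        comp = composition_from_peptide("ALGVSEK")
        res = apply_label(comp, "ALGVSEK", scheme, 1)
        p0 = theoretical_pattern(comp, 2, 3)
        p1 = theoretical_pattern(res.composition, 2, 3)
        assert np.allclose(p1.mz - p0.mz, res.mass_shift / 2, atol=2e-3)

    def test_catalogue_covers_documented_schemes(self):
        cat = load_scheme_catalogue()
        assert {"silac_k8r10", "silac_k4r6", "o18", "n15", "icat_c9",
                "icpl_4", "itraq4", "itraq8", "tmt6", "tmt10"} <= set(cat)
        assert cat["tmt10"].kind == "reporter"
        assert len(cat["tmt10"].reporter_mzs) == 10


class TestDynamicTolerance:
    def test_few_observations_keeps_initial(self):
        assert dynamic_match_tolerance([], 20.0) == 20.0
        assert dynamic_match_tolerance([0.1] * 19, 20.0) == 20.0

    def test_zero_errors_hits_lower_clamp(self):
        assert dynamic_match_tolerance([0.0] * 100, 20.0) == 1.0

    def test_gaussian_errors_shrink_to_about_four_sigma(self):
        rng = np.random.default_rng(7)
        errs = rng.normal(0.0, 2.0, 1000)
        tol = dynamic_match_tolerance(errs, 20.0)
        assert 7.0 <= tol <= 10.0

    @given(st.lists(st.floats(-50, 50), min_size=0, max_size=200),
           st.floats(0.5, 40.0))
    @settings(max_examples=50, deadline=None)
    def test_clamped_between_one_and_initial(self, errors, initial):
        tol = dynamic_match_tolerance(errors, initial)
        assert min(1.0, initial) <= tol <= initial


def _spectrum(mz, inten):
    mz = np.asarray(mz, dtype=float)
    inten = np.asarray(inten, dtype=float)
    order = np.argsort(mz)
    return Spectrum("s1", 1, 10.0, mz[order], inten[order])


class TestMatchPattern:
    def pattern(self):
        return theoretical_pattern(composition_from_peptide("ALGVSEK"), 2, 3)

    def test_self_match_scores_one(self):
        p = self.pattern()
        spec = _spectrum(p.mz, p.rel_abundance * 1e5)
        matches, score, errors = match_pattern(spec, p, 10.0)
        assert len(matches) == len(p)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(errors, 0.0)

    def test_missing_monoisotope_penalized(self):
        p = self.pattern()
        spec = _spectrum(p.mz[1:], p.rel_abundance[1:] * 1e5)
        matches, score, _ = match_pattern(spec, p, 10.0)
        assert 0 not in {i for i, _ in matches}
        assert score < 0.5 + 1e-9

    def test_noise_peaks_do_not_change_result(self):
        p = self.pattern()
        rng = np.random.default_rng(3)
        noise_mz = rng.uniform(150, 2000, 50)
        # keep noise far away from the envelope
        noise_mz = noise_mz[np.min(np.abs(noise_mz[:, None] - p.mz), axis=1) > 1.0]
        clean = _spectrum(p.mz, p.rel_abundance * 1e5)
        noisy = _spectrum(
            np.concatenate([p.mz, noise_mz]),
            np.concatenate([p.rel_abundance * 1e5, rng.uniform(10, 100, len(noise_mz))]),
        )
        m1, s1, _ = match_pattern(clean, p, 10.0)
        m2, s2, _ = match_pattern(noisy, p, 10.0)
        matched_mz_1 = sorted(clean.mz_array[j] for _, j in m1)
        matched_mz_2 = sorted(noisy.mz_array[j] for _, j in m2)
        assert np.allclose(matched_mz_1, matched_mz_2)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_score_invariant_to_intensity_scaling(self):
        p = self.pattern()
        spec1 = _spectrum(p.mz, p.rel_abundance * 123.0)
        spec2 = _spectrum(p.mz, p.rel_abundance * 1.7e7)
        _, s1, _ = match_pattern(spec1, p, 10.0)
        _, s2, _ = match_pattern(spec2, p, 10.0)
        assert s1 == pytest.approx(s2, abs=1e-12)
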