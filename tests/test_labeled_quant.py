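"""Channel quantification, envelope-overlap unmixing, peptide ratios."""

import numpy as np
import pytest

from conftest import gaussian_run, make_psm
from pepquant.config import QuantConfig
from pepquant.errors import ContractError
from pepquant.isotopes import (
    apply_label,
    composition_from_peptide,
    load_scheme,
    theoretical_pattern,
)
from pepquant.labeled_quant import (
    ChannelQuant,
    correct_overlap,
    peptide_ratio,
    quantify_channels,
)

SEQ = "ALGVSETDK"
SIGMA = 8.0


def silac_run(heavy_over_light=1.0, height=1000.0, scheme_name="silac_k8r10",
              scale=1.0, run_id="run1", enrichment=None):
    """Two co-eluting envelopes: light + labeled heavy at a known ratio."""
    scheme = load_scheme(scheme_name)
    comp = composition_from_peptide(SEQ)
    pairs = []
    for ch, mult in ((0, 1.0), (1, heavy_over_light)):
        lab = apply_label(comp, SEQ, scheme, ch)
        enr = dict(scheme.enrichment_map(ch))
        if enrichment is not None:
            enr = {k: enrichment for k in enr}
        pattern = theoretical_pattern(lab.composition, 2, 3,
                                      enrichment=enr or None)
        m0 = pattern.monoisotopic_index
        shares = pattern.rel_abundance[m0:m0 + 3]
        shares = shares / shares.sum()
        for mz, s in zip(pattern.mz[m0:m0 + 3], shares):
            if mult > 0:
                pairs.append((float(mz), scale * height * mult * float(s)))
    pairs.sort()
    light_pattern = theoretical_pattern(comp, 2, 3)
    run = gaussian_run(
        run_id=run_id, peptide_mzs=(tuple(pairs),), apexes=(300.0,),
        sigma=SIGMA, rt_max=600.0,
        ms2_at=[(300.4, float(light_pattern.mz[0]))],
    )
    ms2 = [s for s in run.spectra if s.ms_level == 2][0]
    psm = make_psm(run_id=run_id, scan_id=ms2.scan_id, sequence=SEQ,
                   charge=2, exp_mz=ms2.precursor_mz)
    return run, psm, scheme


class TestQuantifyChannels:
    def test_unit_ratio_gives_equal_areas(self):
        run, psm, scheme = silac_run(1.0)
        ch = quantify_channels(run, psm, scheme, QuantConfig())
        assert ch[1].area == pytest.approx(ch[0].area, rel=0.05)
        assert ch[1].shape_correlation > 0.99

    def test_ratio_two_recovered(self):
        run, psm, scheme = silac_run(2.0)
        ch = quantify_channels(run, psm, scheme, QuantConfig())
        assert ch[1].area / ch[0].area == pytest.approx(2.0, rel=0.10)

    def test_unlabelable_peptide_flagged_inapplicable(self):
        run, psm, scheme = silac_run(1.0)
        psm = make_psm(run_id=psm.run_id, scan_id=psm.scan_id,
                       sequence="ALGVSETDS", charge=2, exp_mz=psm.experimental_mz)
        ch = quantify_channels(run, psm, scheme, QuantConfig())
        assert "inapplicable" in ch[1].flags

    def test_ratio_invariant_to_run_scaling(self):
        cfg = QuantConfig()
        r1, p1, scheme = silac_run(3.0, scale=1.0)
        r2, p2, _ = silac_run(3.0, scale=57.0)
        ch1 = quantify_channels(r1, p1, scheme, cfg)
        ch2 = quantify_channels(r2, p2, scheme, cfg)
        assert ch1[1].area / ch1[0].area == pytest.approx(
            ch2[1].area / ch2[0].area, rel=1e-6
        )

    @pytest.mark.parametrize("true_ratio", [1.0, 2.0, 5.0, 10.0])
    def test_ratio_series_recovered(self, true_ratio):
        run, psm, scheme = silac_run(true_ratio)
        ch = quantify_channels(run, psm, scheme, QuantConfig())
        ratios = peptide_ratio(ch, QuantConfig())
        assert ratios[0].ratio == pytest.approx(true_ratio, rel=0.10)

    def test_15n_channel_shift_matches_nitrogen_count(self):
        comp = composition_from_peptide(SEQ)
        scheme = load_scheme("n15")
        lab = apply_label(comp, SEQ, scheme, 1)
        n_count = comp.counts["N"]
        for z in (1, 2):
            p_light = theoretical_pattern(comp, z, 1)
            p_heavy = theoretical_pattern(lab.composition, z, 1)
            got = p_heavy.monoisotopic_mz - p_light.monoisotopic_mz
            assert got == pytest.approx(n_count * 0.997035 / z, abs=1e-4)

    def test_o18_overlap_correction_engages(self):
        # 18O shift is ~4 Da: light +4 isotopologues overlap the heavy mono
        run, psm, scheme = silac_run(1.0, scheme_name="o18")
        ch = quantify_channels(run, psm, scheme, QuantConfig())
        assert ch[1].area == pytest.approx(ch[0].area, rel=0.10)


class TestCorrectOverlap:
    def make_channels(self, areas, masses):
        return [
            ChannelQuant(SEQ, (), 2, "r1", c, a, 1.0, 1.0, m)
            for c, (a, m) in enumerate(zip(areas, masses))
        ]

    def test_distant_channels_pass_through(self):
        comp = composition_from_peptide(SEQ)
        p0 = theoretical_pattern(comp, 2, 3)
        m = comp.monoisotopic_mass()
        chans = self.make_channels([100.0, 200.0], [m, m + 8.0])
        out = correct_overlap(chans, {0: p0, 1: p0})
        np.testing.assert_allclose(out, [100.0, 200.0], rtol=1e-9)

    def test_forward_simulated_mixture_recovered(self):
        # two channels 4 Da apart: envelope tail of ch0 bleeds into ch1
        comp = composition_from_peptide(SEQ)
        pattern = theoretical_pattern(comp, 2, 6)
        m = comp.monoisotopic_mass()
        true_x = np.array([300.0, 120.0])
        # build observed areas by forward projection
        ab = pattern.rel_abundance
        own = ab[:3].sum()
        a01 = ab[4:7].sum() / own if len(ab) >= 7 else ab[4:].sum() / own
        A = np.array([[1.0, 0.0], [a01, 1.0]])
        b = A @ true_x
        chans = self.make_channels(b, [m, m + 4.0 * 1.003355])
        p3 = theoretical_pattern(comp, 2, 3)
        out = correct_overlap(chans, {0: pattern, 1: p3})
        np.testing.assert_allclose(out, true_x, atol=1e-6)

    def test_zero_observed_stays_zero(self):
        comp = composition_from_peptide(SEQ)
        p = theoretical_pattern(comp, 2, 3)
        m = comp.monoisotopic_mass()
        chans = self.make_channels([0.0, 0.0], [m, m + 4.0])
        assert np.all(correct_overlap(chans, {0: p, 1: p}) == 0.0)

    def test_identical_channels_singular(self):
        comp = composition_from_peptide(SEQ)
        p = theoretical_pattern(comp, 2, 3)
        m = comp.monoisotopic_mass()
        chans = self.make_channels([10.0, 10.0], [m, m])
        with pytest.raises(ContractError):
            correct_overlap(chans, {0: p, 1: p})


class TestPeptideRatio:
    def chans(self, a0, a1):
        return [
            ChannelQuant(SEQ, (), 2, "r1", 0, a0, 1.0, 1.0, 1000.0),
            ChannelQuant(SEQ, (), 2, "r1", 1, a1, 1.0, 0.95, 1008.0),
        ]

    def test_equal_areas_unit_ratio(self):
        r = peptide_ratio(self.chans(100.0, 100.0))[0]
        assert r.ratio == pytest.approx(1.0)
        assert r.log2_ratio == pytest.approx(0.0)

    def test_three_to_one(self):
        assert peptide_ratio(self.chans(100.0, 300.0))[0].ratio == \
            pytest.approx(3.0)

    def test_missing_reference_flagged(self):
        r = peptide_ratio(self.chans(0.0, 300.0))[0]
        assert r.ratio is None
        assert "reference_missing" in r.flags

    def test_channel_swap_inverts_ratio(self):
        fwd = peptide_ratio(self.chans(100.0, 400.0))[0].ratio
        swapped = self.chans(400.0, 100.0)
        rev = peptide_ratio(swapped)[0].ratio
        assert fwd == pytest.approx(1.0 / rev, rel=1e-12)

    def test_low_quality_flagged(self):
        chans = self.chans(100.0, 100.0)
        chans[1].envelope_score = 0.1
        r = peptide_ratio(chans, QuantConfig())[0]
        assert "low_confidence" in r.flags
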