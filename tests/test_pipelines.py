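"""End-to-end pipelines on small simulated experiments."""

import numpy as np
import pandas as pd
import pytest

from pepquant.config import QuantConfig
from pepquant.identifications import IdentificationSet
from pepquant.isotopes import load_scheme
from pepquant.pipelines import (
    quantify_labeled,
    quantify_labelfree,
    quantify_reporter,
    replicate_cv_table,
)
from pepquant.synth_fixtures import (
    make_reporter_design,
    make_silac_design,
    make_ups2_like_design,
    simulate_run,
)


def simulate_all(design):
    runs, psms, truths = {}, [], []
    for i in range(len(design.runs)):
        run, ids, truth = simulate_run(design, i)
        runs[run.run_id] = run
        psms.extend(ids.psms)
        truths.append(truth)
    return runs, IdentificationSet(psms, "synthetic"), pd.concat(truths)


@pytest.fixture(scope="module")
def small_ups2():
    design = make_ups2_like_design(n_background=30, n_spike=8, seed=7)
    runs, ids, truth = simulate_all(design)
    result = quantify_labelfree(runs, ids, QuantConfig(normalize=False))
    return design, runs, ids, truth, result


class TestLabelFreePipeline:
    def test_stage_counts_consistent(self, small_ups2):
        _, _, ids, _, result = small_ups2
        log = result.log
        assert log["psms_retained"] <= log["psms_loaded"]
        assert log["features_quantified"] <= log["psms_retained"]

    def test_dilution_ratios_recovered(self, small_ups2):
        _, _, _, _, result = small_ups2
        pm = result.protein_matrix
        gm = pm.T.groupby(pd.Series({c: c[0] for c in pm.columns})).mean().T
        spike = gm[gm.index.str.startswith("SPK")]
        bg = gm[gm.index.str.startswith("BG")]
        assert (spike["A"] / spike["B"]).median() == pytest.approx(5.0, rel=0.2)
        assert (spike["A"] / spike["C"]).median() == pytest.approx(25.0, rel=0.2)
        assert (bg["A"] / bg["B"]).median() == pytest.approx(1.0, rel=0.05)

    def test_replicate_cvs_are_small(self, small_ups2):
        design, _, _, _, result = small_ups2
        groups = {r.run_id: r.group for r in design.runs}
        cv = replicate_cv_table(result.protein_matrix, groups)
        assert cv.median().median() < 0.1

    def test_spectral_counts_present(self, small_ups2):
        _, _, ids, _, result = small_ups2
        sc = result.spectral_counts
        assert sc.to_numpy().sum() == len(ids)

    def test_matrix_invariant_to_run_ordering(self, small_ups2):
        _, runs, ids, _, result = small_ups2
        reordered = dict(reversed(list(runs.items())))
        again = quantify_labelfree(reordered, ids, QuantConfig(normalize=False))
        pd.testing.assert_frame_equal(result.peptide_matrix, again.peptide_matrix)


class TestLabeledPipeline:
    @pytest.mark.parametrize("ratio", [1.0, 2.0])
    def test_silac_ratio_recovered(self, ratio):
        design = make_silac_design(ratio=ratio, n_peptides=40, n_runs=1, seed=9)
        runs, ids, _ = simulate_all(design)
        result = quantify_labeled(runs, ids, load_scheme("silac_k8r10"),
                                  QuantConfig(normalize=False))
        assert result.protein_ratios["ratio"].median() == \
            pytest.approx(ratio, rel=0.1)

    def test_n15_with_incomplete_enrichment(self):
        design = make_silac_design(ratio=1.0, n_peptides=40, n_runs=1,
                                   seed=9, scheme="n15", enrichment=0.98)
        runs, ids, _ = simulate_all(design)
        result = quantify_labeled(runs, ids, load_scheme("n15"),
                                  QuantConfig(normalize=False))
        assert result.protein_ratios["ratio"].median() == \
            pytest.approx(1.0, rel=0.1)

    def test_dynamic_tolerance_recorded_per_run(self):
        design = make_silac_design(ratio=1.0, n_peptides=30, n_runs=1, seed=2)
        runs, ids, _ = simulate_all(design)
        result = quantify_labeled(runs, ids, load_scheme("silac_k8r10"),
                                  QuantConfig(normalize=False))
        (tol,) = result.log["tolerance_ppm"].values()
        assert 1.0 <= tol <= 20.0
        # simulated m/z are exact, so the window should shrink hard
        assert tol < 5.0


class TestReporterPipeline:
    def test_channel_ratios_recovered(self):
        design = make_reporter_design((1.0, 2.0, 4.0, 1.0, 1.0, 1.0),
                                      n_psms=40, seed=5)
        runs, ids, _ = simulate_all(design)
        _, protein, _ = quantify_reporter(runs, ids, load_scheme("tmt6"),
                                          QuantConfig())
        med = protein.filter(like="ratio_").median()
        assert med["ratio_127_126"] == pytest.approx(2.0, rel=0.1)
        assert med["ratio_128_126"] == pytest.approx(4.0, rel=0.1)
        assert med["ratio_129_126"] == pytest.approx(1.0, rel=0.1)

    def test_impurity_matrix_round_trip(self):
        design = make_reporter_design((1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
                                      n_psms=10, seed=5)
        runs, ids, _ = simulate_all(design)
        M = np.eye(6)
        base, _, _ = quantify_reporter(runs, ids, load_scheme("tmt6"),
                                       QuantConfig(), impurity_matrix=M)
        names = [c.name for c in load_scheme("tmt6").channels]
        plain, _, _ = quantify_reporter(runs, ids, load_scheme("tmt6"),
                                        QuantConfig())
        np.testing.assert_allclose(base[names].to_numpy(),
                                   plain[names].to_numpy())


class TestTransfer:
    def test_holes_filled_and_accurate(self):
        design = make_silac_design(ratio=1.0, n_peptides=40, n_runs=2,
                                   seed=13, scheme=None)
        runs, psms, truths = {}, [], []
        dropped = []
        for i in range(2):
            run, ids, truth = simulate_run(design, i)
            runs[run.run_id] = run
            if i == 1:
                dropped = ids.psms[20:]
                psms.extend(ids.psms[:20])
            else:
                psms.extend(ids.psms)
            truths.append(truth)
        ids = IdentificationSet(psms, "synthetic")
        result = quantify_labelfree(
            runs, ids, QuantConfig(transfer=True, normalize=False)
        )
        m = result.peptide_matrix
        assert int(m.isna().sum().sum()) == 0
        truth = pd.concat(truths)
        t2 = truth[truth["run_id"] == "R2"].set_index("sequence")["true_area"]
        transferred = [f for f in result.features if f.source == "transferred"]
        assert len(transferred) == len(dropped)
        rel_err = np.array([
            abs(f.area - t2[f.sequence]) / t2[f.sequence] for f in transferred
        ])
        # >= 90% of transferred features land on their true apex
        assert (rel_err < 0.2).mean() >= 0.9

    def test_transfer_off_leaves_holes(self):
        design = make_silac_design(ratio=1.0, n_peptides=40, n_runs=2,
                                   seed=13, scheme=None)
        runs, psms = {}, []
        for i in range(2):
            run, ids, _ = simulate_run(design, i)
            runs[run.run_id] = run
            psms.extend(ids.psms if i == 0 else ids.psms[:20])
        result = quantify_labelfree(
            runs, IdentificationSet(psms, "s"),
            QuantConfig(transfer=False, normalize=False),
        )
        assert int(result.peptide_matrix.isna().sum().sum()) == 20
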