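"""End-to-end quantification pipelines shared by the CLI and the library.

Pipeline order: read -> confidence-filter -> quantify -> align/transfer ->
roll up -> write.  All functions operate on in-memory objects; the CLI is
a thin wrapper handling file I/O and logging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import labeled_quant, labelfree_quant, protein_rollup, reporter_quant
from .config import QuantConfig
from .errors import AlignmentInfeasibleError
from .identifications import IdentificationSet, filter_psms
from .isotopes import (
    LabelScheme,
    composition_from_peptide,
    dynamic_match_tolerance,
    match_pattern,
    theoretical_pattern,
)
from .ms_io import RunData
from .rt_alignment import collect_anchors, fit_alignment, invert_rt, map_rt
from .xic import RunIndex


@dataclass
class LabelFreeResult:
    peptide_matrix: pd.DataFrame
    protein_matrix: pd.DataFrame
    spectral_counts: pd.DataFrame
    normalization_factors: dict[str, float]
    features: list
    log: dict = field(default_factory=dict)


@dataclass
class LabeledResult:
    peptide_ratios: pd.DataFrame          # one row per peptide ratio per run
    protein_ratios: pd.DataFrame          # combined across runs
    protein_intensities: dict[int, pd.DataFrame]  # channel -> protein x run
    log: dict = field(default_factory=dict)


def _dedupe_psms(psms):
    """One PSM per peptide key: the highest-scoring (ties by psm_id)."""
    best = {}
    for p in psms:
        k = p.peptide_key
        if k not in best or (p.score, p.psm_id) > (best[k].score, best[k].psm_id):
            best[k] = p
    return [best[k] for k in sorted(best)]


def _unique_protein_map(ids: IdentificationSet) -> dict[str, str | None]:
    """sequence -> unique accession (None when shared between proteins)."""
    accs: dict[str, set[str]] = {}
    for p in ids.psms:
        accs.setdefault(p.peptide_sequence, set()).update(p.protein_accessions)
    return {
        seq: (next(iter(a)) if len(a) == 1 else None) for seq, a in accs.items()
    }


def quantify_labelfree(
    runs: dict[str, RunData],
    ids: IdentificationSet,
    config: QuantConfig | None = None,
) -> LabelFreeResult:
    """Label-free pipeline: spectral counts + XIC intensity matrix."""
    cfg = config or QuantConfig()
    retained = filter_psms(ids, cfg.q_threshold)
    log = {"psms_loaded": len(ids), "psms_retained": len(retained)}

    by_run = retained.by_run()
    indexes = {rid: RunIndex(run) for rid, run in runs.items()}
    scan_rt = {
        rid: {s.scan_id: s.rt_seconds for s in run.spectra}
        for rid, run in runs.items()
    }

    features = []
    deduped: dict[str, list] = {}
    for rid in sorted(runs):
        psms = _dedupe_psms(by_run.get(rid, []))
        deduped[rid] = psms
        for p in psms:
            features.append(labelfree_quant.quantify_feature(
                indexes[rid], p, cfg, anchor_rt=scan_rt[rid][p.scan_id]
            ))
    log["features_quantified"] = len(features)

    if cfg.transfer and len(runs) > 1:
        features += _transfer_missing(
            runs, indexes, scan_rt, deduped, features, cfg, log
        )

    matrix = labelfree_quant.build_intensity_matrix(features, transfer=cfg.transfer)
    factors = {rid: 1.0 for rid in runs}
    if cfg.normalize and matrix.shape[1] >= 2:
        matrix, factors = labelfree_quant.normalize_matrix(matrix)

    prot_map = _unique_protein_map(retained)
    protein_matrix = (
        protein_rollup.protein_intensity_table(matrix, prot_map)
        if not matrix.empty
        else pd.DataFrame()
    )
    sc = labelfree_quant.spectral_count_matrix(retained)
    return LabelFreeResult(matrix, protein_matrix, sc, factors, features, log)


def _transfer_missing(runs, indexes, scan_rt, deduped, features, cfg, log):
    """Fill peptide x run holes through the star-topology RT alignment."""
    ref = max(sorted(runs), key=lambda rid: len(deduped[rid]))
    models = {}
    for rid in sorted(runs):
        if rid == ref:
            continue
        try:
            anchors = collect_anchors(
                IdentificationSet(deduped[rid], "x"),
                IdentificationSet(deduped[ref], "x"),
                run_a=indexes[rid], run_b=indexes[ref],
                scan_rt_a=scan_rt[rid], scan_rt_b=scan_rt[ref],
                tol_ppm=cfg.tol_ppm,
            )
            models[rid] = fit_alignment(anchors)
        except AlignmentInfeasibleError:
            models[rid] = None
            log.setdefault("alignment_fallbacks", []).append(ref if rid == ref else rid)

    def to_ref(rid, t):
        return t if rid == ref or models[rid] is None else map_rt(models[rid], t)

    def from_ref(rid, t):
        return t if rid == ref or models[rid] is None else invert_rt(models[rid], t)

    seen = {(f.peptide_key, f.run_id) for f in features}
    best_source: dict[tuple, object] = {}
    for rid, psms in deduped.items():
        for p in psms:
            k = p.peptide_key
            if k not in best_source or p.score > best_source[k].score:
                best_source[k] = p
    transferred = []
    n = 0
    for key, psm in sorted(best_source.items()):
        src = psm.run_id
        src_rt = scan_rt[src][psm.scan_id]
        for rid in sorted(runs):
            if (key, rid) in seen:
                continue
            target_rt = from_ref(rid, to_ref(src, src_rt))
            fq = labelfree_quant.quantify_feature(
                indexes[rid], psm, cfg, anchor_rt=float(target_rt),
                source="transferred",
            )
            fq.run_id = rid
            transferred.append(fq)
            n += 1
    log["features_transferred"] = n
    return transferred


def _error_pool(index: RunIndex, psms, scan_rt, runs_spectra, cfg) -> list[float]:
    """First-pass matched-peak ppm errors feeding the dynamic tolerance."""
    errors: list[float] = []
    for p in psms:
        comp = composition_from_peptide(p.peptide_sequence, list(p.modifications))
        pattern = theoretical_pattern(comp, p.charge, n_peaks=cfg.n_isotopologues)
        rt = scan_rt[p.scan_id]
        # nearest MS1 scan to the identification
        s = int(np.searchsorted(index.scan_rt, rt))
        s = min(max(s, 0), len(index.scan_rt) - 1)
        spec = runs_spectra[s]
        _, _, errs = match_pattern(spec, pattern, cfg.initial_tol_ppm)
        errors.extend(errs)
    return errors


def quantify_labeled(
    runs: dict[str, RunData],
    ids: IdentificationSet,
    scheme: LabelScheme,
    config: QuantConfig | None = None,
) -> LabeledResult:
    """Precursor-label pipeline with per-run dynamic matching tolerance."""
    cfg = config or QuantConfig()
    retained = filter_psms(ids, cfg.q_threshold)
    log = {"psms_loaded": len(ids), "psms_retained": len(retained)}
    by_run = retained.by_run()
    prot_map = _unique_protein_map(retained)

    all_ratios = []
    per_run_protein = []
    channel_intensity: dict[int, dict[str, dict[str, float]]] = {}
    for rid in sorted(runs):
        run = runs[rid]
        index = RunIndex(run)
        scan_rt = {s.scan_id: s.rt_seconds for s in run.spectra}
        psms = _dedupe_psms(by_run.get(rid, []))

        tol = cfg.tol_ppm
        if cfg.dynamic_tolerance and psms:
            ms1 = run.ms1_spectra()
            pool = _error_pool(index, psms, scan_rt, ms1, cfg)
            tol = dynamic_match_tolerance(
                pool, cfg.initial_tol_ppm, cfg.min_tolerance_observations
            )
        log.setdefault("tolerance_ppm", {})[rid] = tol

        for p in psms:
            channels = labeled_quant.quantify_channels(
                index, p, scheme, cfg, anchor_rt=scan_rt[p.scan_id], tol_ppm=tol
            )
            ratios = labeled_quant.peptide_ratio(channels, cfg)
            all_ratios.extend(ratios)
            prot = prot_map.get(p.peptide_sequence)
            if prot is not None:
                for q in channels:
                    if "inapplicable" in q.flags:
                        continue
                    bucket = channel_intensity.setdefault(q.channel, {}).setdefault(
                        prot, {}
                    )
                    bucket[rid] = bucket.get(rid, 0.0) + q.area

        table = protein_rollup.protein_ratio_table(
            [r for r in all_ratios if r.run_id == rid], prot_map,
            min_peptides=cfg.min_peptides,
        )
        table["run_id"] = rid
        per_run_protein.append(table)

    combined = pd.concat(per_run_protein, ignore_index=True) if per_run_protein \
        else pd.DataFrame()
    if not combined.empty:
        protein = (
            combined.groupby(["protein", "channel"])
            .agg(log2_ratio=("log2_ratio", "median"),
                 n_peptides=("n_peptides", "sum"),
                 n_runs=("run_id", "nunique"))
            .reset_index()
        )
        protein["ratio"] = 2.0 ** protein["log2_ratio"]
        if cfg.normalize and len(protein) >= protein_rollup.MIN_PROTEINS_FOR_NORMALIZATION:
            protein, offset = protein_rollup.normalize_ratios(protein)
            log["normalization_offset_log2"] = offset
    else:
        protein = combined

    intensities = {
        ch: pd.DataFrame.from_dict(prot_runs, orient="index").sort_index()
        for ch, prot_runs in channel_intensity.items()
    }
    ratio_rows = pd.DataFrame([
        {
            "sequence": r.sequence, "charge": r.charge, "run_id": r.run_id,
            "channel": r.channel, "ratio": r.ratio, "log2_ratio": r.log2_ratio,
            "quality": r.quality, "flags": ";".join(sorted(r.flags)),
        }
        for r in all_ratios
    ])
    log["peptide_ratios"] = len(ratio_rows)
    return LabeledResult(ratio_rows, protein, intensities, log)


def quantify_reporter(
    runs: dict[str, RunData],
    ids: IdentificationSet,
    scheme: LabelScheme,
    config: QuantConfig | None = None,
    impurity_matrix=None,
):
    """Reporter-ion pipeline: PSM channel table + protein aggregation."""
    cfg = config or QuantConfig()
    retained = filter_psms(ids, cfg.q_threshold)
    psm_table = reporter_quant.psm_to_channel_table(
        retained, runs, scheme, cfg, impurity_matrix
    )
    protein = reporter_quant.aggregate_reporters(psm_table, scheme, "protein")
    log = {"psms_loaded": len(ids), "psms_retained": len(retained),
           "rows": len(psm_table)}
    return psm_table, protein, log


def replicate_cv_table(protein_matrix: pd.DataFrame, groups: dict[str, str]):
    """Per-protein CV within each replicate group of a protein x run matrix."""
    rows = {}
    for group in sorted(set(groups.values())):
        cols = [c for c in protein_matrix.columns if groups.get(c) == group]
        if len(cols) < 2:
            continue
        sub = protein_matrix[cols]
        ok = sub.notna().all(axis=1) & (sub > 0).all(axis=1)
        cv = sub[ok].std(axis=1, ddof=1) / sub[ok].mean(axis=1)
        rows[group] = cv
    return pd.DataFrame(rows)
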