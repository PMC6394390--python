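"""Label-free quantification: spectral counts and XIC intensities.

Each confident PSM anchors one feature: the theoretical envelope of its
peptide is predicted, XICs of the first isotopologues are extracted around
the MS2 scan's retention time, boundaries are detected on the smoothed
monoisotopic trace, and the raw traces are integrated over those shared
bounds.  Per-run features are assembled into a peptide x run matrix
(charge states quantified separately, summed per sequence+modifications),
optionally completed by cross-run transfer through the RT alignment, and
normalized by median log-intensity equalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QuantConfig
from .errors import ContractError
from .identifications import PSM, IdentificationSet
from .isotopes import composition_from_peptide, theoretical_pattern
from .ms_io import RunData
from .xic import (
    RunIndex,
    detect_boundaries,
    extract_xic,
    integrate_between,
    pearson_over,
    smooth_xic,
)


@dataclass
class FeatureQuant:
    """Integrated intensity of one peptide feature in one run."""

    sequence: str
    modifications: tuple
    charge: int
    run_id: str
    area: float
    apex_rt: float | None
    envelope_score: float
    source: str = "identified"  # or "transferred"
    flags: set[str] = field(default_factory=set)

    @property
    def peptide_key(self):
        return (self.sequence, self.modifications, self.charge)


def spectral_count(ids: IdentificationSet) -> dict[tuple[str, str], int]:
    """(protein, run) -> number of retained PSMs.

    Shared peptides increment every accession they map to (no razor
    assignment).
    """
    counts: dict[tuple[str, str], int] = {}
    for p in ids.psms:
        for acc in p.protein_accessions:
            key = (acc, p.run_id)
            counts[key] = counts.get(key, 0) + 1
    return counts


def spectral_count_matrix(ids: IdentificationSet) -> pd.DataFrame:
    """Protein x run spectral-count table (0 where never observed)."""
    counts = spectral_count(ids)
    if not counts:
        return pd.DataFrame()
    df = pd.Series(counts).unstack(fill_value=0)
    df.index.name = "protein"
    return df.sort_index()


def quantify_feature(
    run: RunData | RunIndex,
    psm: PSM,
    config: QuantConfig,
    anchor_rt: float | None = None,
    tol_ppm: float | None = None,
    source: str = "identified",
) -> FeatureQuant:
    """Quantify one peptide feature anchored at its MS2 scan.

    ``anchor_rt`` may be supplied directly (transferred features); otherwise
    the PSM's scan is looked up in the run.  ``tol_ppm`` overrides the
    config tolerance (dynamic-tolerance second pass).
    """
    if anchor_rt is None:
        if isinstance(run, RunIndex):
            raise ContractError("anchor_rt required when quantifying from a RunIndex")
        anchor_rt = run.spectrum_by_id(psm.scan_id).rt_seconds
    index = run if isinstance(run, RunIndex) else RunIndex(run)
    tol = config.tol_ppm if tol_ppm is None else tol_ppm

    comp = composition_from_peptide(psm.peptide_sequence, list(psm.modifications))
    pattern = theoretical_pattern(comp, psm.charge, n_peaks=config.n_isotopologues)
    mono = pattern.monoisotopic_index
    iso_mzs = pattern.mz[mono : mono + config.n_isotopologues]
    iso_abund = pattern.rel_abundance[mono : mono + config.n_isotopologues]

    apex_hw = (
        config.transfer_apex_halfwidth if source == "transferred"
        else config.apex_halfwidth
    )
    xics = [
        extract_xic(index, mz, tol, anchor_rt, config.rt_halfwidth) for mz in iso_mzs
    ]
    flags: set[str] = set()
    if comp.mass_only_mods:
        flags.add("mass_only_modification")

    if len(xics[0]) < 3:
        flags.add("not_detected")
        return FeatureQuant(psm.peptide_sequence, psm.modifications, psm.charge,
                            psm.run_id, 0.0, None, 0.0, source, flags)

    smoothed_mono = smooth_xic(xics[0], config.smooth_window)
    bounded = detect_boundaries(smoothed_mono, anchor_rt, apex_halfwidth=apex_hw)
    if bounded.apex_index is None:
        flags.add("not_detected")
        return FeatureQuant(psm.peptide_sequence, psm.modifications, psm.charge,
                            psm.run_id, 0.0, None, 0.0, source, flags)

    left, right = bounded.left_bound, bounded.right_bound
    areas = np.array([integrate_between(x, left, right) for x in xics])
    area = float(areas.sum())

    # isotope-envelope consistency filter: +1/+2 traces must co-elute with mono
    for k in range(1, len(xics)):
        if pearson_over(xics[0], xics[k], left, right) < config.envelope_min_corr:
            flags.add("low_quality_envelope")
            break

    denom = np.linalg.norm(iso_abund) * np.linalg.norm(areas)
    envelope_score = float(iso_abund @ areas / denom) if denom > 0 else 0.0
    if area == 0.0:
        flags.add("not_detected")

    return FeatureQuant(
        sequence=psm.peptide_sequence,
        modifications=psm.modifications,
        charge=psm.charge,
        run_id=psm.run_id,
        area=area,
        apex_rt=float(bounded.rt[bounded.apex_index]),
        envelope_score=envelope_score,
        source=source,
        flags=flags,
    )


def build_intensity_matrix(
    features: list[FeatureQuant], transfer: bool = False
) -> pd.DataFrame:
    """Assemble features into a peptide x run intensity matrix.

    Rows are keyed by (sequence, modifications string); charge states are
    summed.  Cells never observed stay NaN; transferred features fill their
    cells when ``transfer`` (they are marked by their ``source`` upstream).
    """
    rows: dict[tuple[str, str], dict[str, float]] = {}
    for f in features:
        if f.source == "transferred" and not transfer:
            continue
        key = (f.sequence, _mods_str(f.modifications))
        cell = rows.setdefault(key, {})
        cell[f.run_id] = cell.get(f.run_id, 0.0) + f.area
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["sequence", "mods"])
    return df.sort_index(axis=0).sort_index(axis=1)


def _mods_str(mods: tuple) -> str:
    return ";".join(f"{pos}:{delta:.5f}:{name}" for pos, delta, name in mods)


def normalize_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Equalize per-run median log2 intensity over fully observed peptides.

    Every run is scaled to the first run's median, so the first run's
    factor is 1.  Returns (scaled matrix, run -> multiplicative factor).
    Re-running on the output yields factors of 1 (idempotence), and the
    median cross-run log-ratio after scaling is 0.
    """
    if matrix.shape[1] < 2:
        raise ContractError("normalization needs at least 2 runs")
    complete = matrix.dropna()
    complete = complete[(complete > 0).all(axis=1)]
    if complete.empty:
        factors = {run: 1.0 for run in matrix.columns}
        return matrix.copy(), factors
    medians = np.log2(complete).median(axis=0)
    ref = medians.iloc[0]
    factors = {run: float(2.0 ** (ref - medians[run])) for run in matrix.columns}
    scaled = matrix.mul(pd.Series(factors), axis=1)
    return scaled, factors
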