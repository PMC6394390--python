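"""Precursor-ion labeled quantification (SILAC, ¹⁸O, ¹⁵N, ICAT, ICPL, ...).

An identification in any one channel fixes the peptide, charge and elution
window; the other channels' m/z values follow by label mass arithmetic.
Boundaries are detected once, on the identified channel's monoisotopic XIC,
and every channel is integrated over those same bounds (co-elution
assumption).  Channels whose envelopes overlap on the m/z axis — ¹⁸O's
4 Da spacing being the canonical case — are unmixed by a small non-negative
least-squares system built from the theoretical envelope abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .config import QuantConfig
from .errors import ContractError
from .identifications import PSM
from .isotopes import (
    PROTON_MASS,
    IsotopePattern,
    LabelScheme,
    apply_label,
    composition_from_peptide,
    theoretical_pattern,
)
from .ms_io import RunData
from .xic import (
    RunIndex,
    detect_boundaries,
    extract_xic,
    integrate_between,
    pearson_over,
    smooth_xic,
)

_ISOTOPOLOGUE_SPACING = 1.003355  # Da between adjacent isotopologues


@dataclass
class ChannelQuant:
    """Integrated area of one label channel of one peptide feature."""

    sequence: str
    modifications: tuple
    charge: int
    run_id: str
    channel: int
    area: float
    envelope_score: float
    shape_correlation: float  # Pearson vs the reference channel's mono trace
    mono_mass: float          # neutral monoisotopic mass of this channel
    flags: set[str] = field(default_factory=set)

    @property
    def peptide_key(self):
        return (self.sequence, self.modifications, self.charge)


@dataclass
class PeptideRatio:
    """channel_i / channel_0 abundance ratio of one peptide."""

    sequence: str
    modifications: tuple
    charge: int
    run_id: str
    channel: int
    ratio: float | None
    log2_ratio: float | None
    quality: float
    flags: set[str] = field(default_factory=set)

    @property
    def peptide_key(self):
        return (self.sequence, self.modifications, self.charge)


def quantify_channels(
    run: RunData | RunIndex,
    psm: PSM,
    scheme: LabelScheme,
    config: QuantConfig,
    anchor_rt: float | None = None,
    tol_ppm: float | None = None,
) -> list[ChannelQuant]:
    """Integrate every channel of a labeling scheme over shared RT bounds.

    The identified channel is inferred as the one whose monoisotopic m/z
    lies closest to the PSM's experimental m/z; its smoothed monoisotopic
    XIC supplies apex and bounds.  Channels without a labelable residue are
    returned with area 0 and an ``inapplicable`` flag.  Overlapping channel
    envelopes are unmixed afterwards (:func:`correct_overlap`), which is
    invoked automatically when channel spacing falls below the configured
    threshold.
    """
    if scheme.kind != "precursor":
        raise ContractError(f"{scheme.name} is not a precursor scheme")
    if anchor_rt is None:
        if isinstance(run, RunIndex):
            raise ContractError("anchor_rt required when quantifying from a RunIndex")
        anchor_rt = run.spectrum_by_id(psm.scan_id).rt_seconds
    index = run if isinstance(run, RunIndex) else RunIndex(run)
    tol = config.tol_ppm if tol_ppm is None else tol_ppm

    base = composition_from_peptide(psm.peptide_sequence, list(psm.modifications))
    labelled = [
        apply_label(base, psm.peptide_sequence, scheme, c)
        for c in range(scheme.n_channels)
    ]
    patterns: list[IsotopePattern | None] = []
    for c, lab in enumerate(labelled):
        if not lab.applicable:
            patterns.append(None)
            continue
        patterns.append(
            theoretical_pattern(
                lab.composition,
                psm.charge,
                n_peaks=config.n_isotopologues,
                enrichment=scheme.enrichment_map(c) or None,
            )
        )

    # identified channel = nearest mono m/z to the experimental precursor m/z
    cand = [
        (abs(p.monoisotopic_mz - psm.experimental_mz), c)
        for c, p in enumerate(patterns)
        if p is not None
    ]
    if not cand:
        raise ContractError(
            f"no channel of {scheme.name} applies to {psm.peptide_sequence!r}"
        )
    ident_channel = min(cand)[1]

    # per-channel isotopologue XICs
    xic_sets: list[list | None] = []
    for p in patterns:
        if p is None:
            xic_sets.append(None)
            continue
        m0 = p.monoisotopic_index
        mzs = p.mz[m0 : m0 + config.n_isotopologues]
        xic_sets.append(
            [extract_xic(index, mz, tol, anchor_rt, config.rt_halfwidth) for mz in mzs]
        )

    ident_xics = xic_sets[ident_channel]
    out: list[ChannelQuant] = []
    bounded = None
    if ident_xics and len(ident_xics[0]) >= 3:
        bounded = detect_boundaries(
            smooth_xic(ident_xics[0], config.smooth_window),
            anchor_rt,
            apex_halfwidth=config.apex_halfwidth,
        )
        if bounded.apex_index is None:
            bounded = None

    for c in range(scheme.n_channels):
        if patterns[c] is None:
            out.append(ChannelQuant(
                psm.peptide_sequence, psm.modifications, psm.charge, psm.run_id,
                c, 0.0, 0.0, 0.0, 0.0, flags={"inapplicable"},
            ))
            continue
        mono_mass = (patterns[c].monoisotopic_mz - PROTON_MASS) * psm.charge
        if bounded is None:
            out.append(ChannelQuant(
                psm.peptide_sequence, psm.modifications, psm.charge, psm.run_id,
                c, 0.0, 0.0, 0.0, mono_mass, flags={"not_detected"},
            ))
            continue
        left, right = bounded.left_bound, bounded.right_bound
        xics = xic_sets[c]
        areas = np.array([integrate_between(x, left, right) for x in xics])
        p = patterns[c]
        m0 = p.monoisotopic_index
        abund = p.rel_abundance[m0 : m0 + config.n_isotopologues]
        denom = np.linalg.norm(abund[: len(areas)]) * np.linalg.norm(areas)
        env = float(abund[: len(areas)] @ areas / denom) if denom > 0 else 0.0
        shape = (
            1.0
            if c == ident_channel
            else pearson_over(ident_xics[0], xics[0], left, right)
        )
        flags: set[str] = set()
        if areas.sum() == 0:
            flags.add("not_detected")
        out.append(ChannelQuant(
            psm.peptide_sequence, psm.modifications, psm.charge, psm.run_id,
            c, float(areas.sum()), env, shape, mono_mass, flags=flags,
        ))

    # unmix overlapping channel envelopes where spacing is tight
    applicable = [q for q in out if "inapplicable" not in q.flags]
    if len(applicable) > 1:
        masses = [q.mono_mass for q in applicable]
        min_gap = min(
            abs(b - a) for a, b in zip(sorted(masses), sorted(masses)[1:])
        )
        if min_gap < config.overlap_spacing_da * _ISOTOPOLOGUE_SPACING:
            pats = {q.channel: patterns[q.channel] for q in applicable}
            corrected = correct_overlap(applicable, pats, config.n_isotopologues)
            for q, a in zip(applicable, corrected):
                q.area = a
    return out


def correct_overlap(
    channels: list[ChannelQuant],
    patterns: dict[int, IsotopePattern],
    n_isotopologues: int = 3,
) -> np.ndarray:
    """Unmix channel areas whose theoretical envelopes overlap in m/z.

    Builds A[i, j] = fraction of channel j's envelope falling into the
    isotopologue positions integrated for channel i (diagonal 1), then
    solves A x = observed areas by non-negative least squares.  With
    channel spacing beyond the envelope width A is the identity and the
    observed areas pass through unchanged.
    """
    chans = list(channels)
    n = len(chans)
    if n < 1:
        return np.empty(0)

    # global integer isotopologue positions integrated for each channel
    def positions(q: ChannelQuant) -> np.ndarray:
        base = round(q.mono_mass / _ISOTOPOLOGUE_SPACING)
        return np.arange(base, base + n_isotopologues)

    # channel j's envelope abundance by global position
    def abundance_by_pos(q: ChannelQuant) -> dict[int, float]:
        p = patterns[q.channel]
        base = round(q.mono_mass / _ISOTOPOLOGUE_SPACING) - p.monoisotopic_index
        return {base + k: float(a) for k, a in enumerate(p.rel_abundance)}

    A = np.zeros((n, n))
    for j, qj in enumerate(chans):
        ab = abundance_by_pos(qj)
        own = sum(ab.get(int(p), 0.0) for p in positions(qj))
        if own <= 0:
            raise ContractError("channel envelope has no abundance in its window")
        for i, qi in enumerate(chans):
            A[i, j] = sum(ab.get(int(p), 0.0) for p in positions(qi)) / own
    if np.linalg.matrix_rank(A) < n:
        raise ContractError("singular channel design (identical channels?)")
    b = np.array([q.area for q in chans], dtype=float)
    if not b.any():
        return b
    x, _ = nnls(A, b)
    return x


def peptide_ratio(
    channels: list[ChannelQuant], config: QuantConfig | None = None
) -> list[PeptideRatio]:
    """Channel_i / channel_0 ratios with a [0, 1] quality score.

    quality = min(envelope scores) x max(0, shape correlation); ratios with
    quality below the configured floor are flagged low-confidence.  A zero
    reference area yields an absent ratio with a ``reference_missing`` flag.
    """
    cfg = config or QuantConfig()
    by_channel = {q.channel: q for q in channels}
    if 0 not in by_channel:
        raise ContractError("reference channel (0) missing")
    ref = by_channel[0]
    out: list[PeptideRatio] = []
    for c in sorted(by_channel):
        if c == 0:
            continue
        q = by_channel[c]
        flags = set(q.flags | ref.flags)
        quality = min(q.envelope_score, ref.envelope_score) * max(
            0.0, q.shape_correlation
        )
        if "inapplicable" in q.flags or "inapplicable" in ref.flags:
            out.append(PeptideRatio(q.sequence, q.modifications, q.charge, q.run_id,
                                    c, None, None, 0.0, flags))
            continue
        if ref.area <= 0:
            flags.add("reference_missing")
            out.append(PeptideRatio(q.sequence, q.modifications, q.charge, q.run_id,
                                    c, None, None, quality, flags))
            continue
        r = q.area / ref.area
        if quality < cfg.min_ratio_quality:
            flags.add("low_confidence")
        out.append(PeptideRatio(
            q.sequence, q.modifications, q.charge, q.run_id, c,
            float(r), float(np.log2(r)) if r > 0 else None, quality, flags,
        ))
    return out
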