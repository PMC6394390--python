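"""Peptide-to-protein aggregation, ratio normalization, replicate CVs.

Rollup uses unique peptides only (a peptide shared between accessions is
excluded rather than razor-assigned).  Protein log2 ratios are medians of
their peptides' log2 ratios — robust to a single outlying peptide from
three peptides up.  Ratio normalization subtracts the median protein log2
ratio, assuming most proteins are unchanged; spike-in designs violate that
assumption and disable it.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ContractError

MIN_PROTEINS_FOR_NORMALIZATION = 10


def unique_protein_of(accessions) -> str | None:
    """The single accession of a unique peptide, else None (shared)."""
    accs = list(dict.fromkeys(accessions))
    return accs[0] if len(accs) == 1 else None


def protein_ratio(
    peptide_log2_ratios, min_peptides: int = 1
) -> float | None:
    """Median of peptide log2 ratios; None below the peptide floor.

    Callers exclude shared and low-confidence peptides before this point.
    """
    vals = [v for v in peptide_log2_ratios if v is not None and math.isfinite(v)]
    if len(vals) < max(1, min_peptides):
        return None
    return float(np.median(vals))


def protein_ratio_table(
    peptide_ratios,
    protein_of_peptide: dict,
    min_peptides: int = 1,
    exclude_flag: str = "low_confidence",
) -> pd.DataFrame:
    """Aggregate :class:`~pepquant.labeled_quant.PeptideRatio` lists.

    ``protein_of_peptide`` maps peptide sequence -> unique accession (None
    for shared peptides, which are dropped).  Returns one row per
    (protein, channel) with the median log2 ratio, the linear ratio and the
    surviving peptide count.
    """
    buckets: dict[tuple[str, int], list[float]] = {}
    for r in peptide_ratios:
        if r.log2_ratio is None or exclude_flag in r.flags:
            continue
        prot = protein_of_peptide.get(r.sequence)
        if prot is None:
            continue
        buckets.setdefault((prot, r.channel), []).append(r.log2_ratio)
    rows = []
    for (prot, channel), vals in sorted(buckets.items()):
        med = protein_ratio(vals, min_peptides)
        if med is None:
            continue
        rows.append({
            "protein": prot,
            "channel": channel,
            "log2_ratio": med,
            "ratio": 2.0 ** med,
            "n_peptides": len(vals),
        })
    return pd.DataFrame(rows, columns=["protein", "channel", "log2_ratio",
                                       "ratio", "n_peptides"])


def normalize_ratios(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Median-center protein log2 ratios (most-proteins-unchanged assumption).

    Returns (centered table, subtracted offset).  Idempotent: a second pass
    subtracts 0.  Requires at least 10 protein ratios; spike-in designs
    should skip this step entirely.
    """
    if len(table) < MIN_PROTEINS_FOR_NORMALIZATION:
        raise ContractError(
            f"ratio normalization needs >= {MIN_PROTEINS_FOR_NORMALIZATION} proteins"
        )
    offset = float(table["log2_ratio"].median())
    out = table.copy()
    out["log2_ratio"] = out["log2_ratio"] - offset
    out["ratio"] = 2.0 ** out["log2_ratio"]
    return out, offset


def replicate_cv(values) -> float | None:
    """Coefficient of variation: sample SD / mean; None for zero mean."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ContractError("CV needs at least 2 replicate values")
    mean = vals.mean()
    if mean == 0:
        return None
    return float(vals.std(ddof=1) / mean)


def protein_intensity_table(
    peptide_matrix: pd.DataFrame, protein_of_peptide: dict
) -> pd.DataFrame:
    """Protein x run intensities: sum of unique peptides' areas per run.

    ``peptide_matrix`` is the (sequence, mods) x run matrix from
    label-free assembly; peptides without a unique protein are dropped.
    Missing cells propagate as NaN only when no peptide of the protein was
    observed in that run.
    """
    seqs = peptide_matrix.index.get_level_values("sequence")
    prot = pd.Series([protein_of_peptide.get(s) for s in seqs], index=peptide_matrix.index)
    kept = peptide_matrix[prot.notna().to_numpy()]
    groups = prot.dropna()
    summed = kept.groupby(groups.to_numpy()).sum(min_count=1)
    summed.index.name = "protein"
    return summed.sort_index()
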