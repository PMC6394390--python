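"""Loading and confidence-filtering of peptide-spectrum matches.

PSMs come either from mzIdentML 1.1/1.2 (the PSI standard emitted by
Mascot, MS-GF+, Comet, ...) or from a documented TSV dialect for tools
without mzIdentML export.  Filtering uses q-values as the single confidence
currency; PeptideProphet-style posterior probabilities in the TSV dialect
are converted to q-values by the standard running-mean transform when no
q-value column is present.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lxml import etree

from .errors import ContractError, FormatError, InputError

#: mandatory columns of the TSV PSM dialect (q_value may be replaced by
#: posterior_prob)
TSV_COLUMNS = (
    "psm_id", "run_id", "scan_id", "sequence", "mods",
    "charge", "exp_mz", "score", "q_value", "proteins",
)


@dataclass(frozen=True)
class PSM:
    """One identified peptide-spectrum match, the anchor of quantification."""

    psm_id: str
    run_id: str
    scan_id: str
    peptide_sequence: str
    modifications: tuple[tuple[int, float, str], ...]  # (position, delta Da, name)
    charge: int
    experimental_mz: float
    score: float
    q_value: float | None
    protein_accessions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ContractError(f"charge must be >= 1, got {self.charge}")
        for pos, _delta, _name in self.modifications:
            if pos < 0 or pos > len(self.peptide_sequence):
                raise ContractError(
                    f"modification position {pos} outside peptide "
                    f"{self.peptide_sequence!r}"
                )
        if not self.protein_accessions:
            raise ContractError("PSM must map to at least one protein")
        if self.q_value is not None and not 0.0 <= self.q_value <= 1.0:
            raise ContractError(f"q_value outside [0, 1]: {self.q_value}")

    @property
    def peptide_key(self) -> tuple[str, tuple, int]:
        """(sequence, modifications, charge) — the feature identity."""
        return (self.peptide_sequence, self.modifications, self.charge)


@dataclass
class IdentificationSet:
    psms: list[PSM] = field(default_factory=list)
    source_format: str = ""

    def __post_init__(self) -> None:
        ids = [p.psm_id for p in self.psms]
        if len(ids) != len(set(ids)):
            raise ContractError("duplicate psm_id in identification set")

    def __len__(self) -> int:
        return len(self.psms)

    def by_run(self) -> dict[str, list[PSM]]:
        out: dict[str, list[PSM]] = {}
        for p in self.psms:
            out.setdefault(p.run_id, []).append(p)
        return out


_QVALUE_NAMES = {
    "PSM-level q-value",
    "MS-GF:QValue",
    "Mascot:q-value",
    "q-value",
}


def _localname(element) -> str:
    tag = element.tag
    return tag.rsplit("}", 1)[-1] if "}" in tag else tag


def _children(element, name: str):
    return [c for c in element if _localname(c) == name]


def read_mzidentml(path) -> IdentificationSet:
    """Read rank-1 PSMs from an mzIdentML 1.1/1.2 file.

    One PSM per SpectrumIdentificationResult: its rank-1 item (ties broken
    by higher score, then lexicographic item id, for deterministic output).
    Modifications map to (position, monoisotopic delta, name); the q-value
    comes from the standard CV term when present, else stays absent;
    spectrum references resolve to scan_id, SpectraData to run_id.
    """
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        tree = etree.parse(str(path))
    except Exception as exc:
        raise FormatError(f"malformed mzIdentML {path}: {exc}") from exc
    root = tree.getroot()

    peptides: dict[str, tuple[str, tuple]] = {}
    evidences: dict[str, tuple[str, str]] = {}  # id -> (peptide_ref, dbseq_ref)
    accessions: dict[str, str] = {}
    spectra_data: dict[str, str] = {}
    results = []
    for el in root.iter():
        ln = _localname(el)
        if ln == "Peptide":
            seq = ""
            mods = []
            for c in el:
                cn = _localname(c)
                if cn == "PeptideSequence":
                    seq = (c.text or "").strip()
                elif cn == "Modification":
                    name = "unknown"
                    for cv in _children(c, "cvParam"):
                        name = cv.get("name", name)
                    mods.append((
                        int(c.get("location", 0)),
                        float(c.get("monoisotopicMassDelta", 0.0)),
                        name,
                    ))
            peptides[el.get("id")] = (seq, tuple(sorted(mods)))
        elif ln == "PeptideEvidence":
            evidences[el.get("id")] = (el.get("peptide_ref"),
                                       el.get("dBSequence_ref"))
        elif ln == "DBSequence":
            accessions[el.get("id")] = el.get("accession", el.get("id"))
        elif ln == "SpectraData":
            base = os.path.basename(el.get("location") or el.get("name") or "run")
            for suffix in (".gz", ".mzML", ".mzml", ".mzXML", ".mzxml"):
                if base.endswith(suffix):
                    base = base[: -len(suffix)]
            spectra_data[el.get("id")] = base
        elif ln == "SpectrumIdentificationResult":
            results.append(el)

    psms: list[PSM] = []
    for result in results:
        psm = _psm_from_result(result, peptides, evidences, accessions,
                               spectra_data)
        if psm is not None:
            psms.append(psm)
    return IdentificationSet(psms=psms, source_format="mzIdentML")


def _item_cv(item) -> dict[str, str]:
    return {
        cv.get("name", ""): cv.get("value", "")
        for cv in _children(item, "cvParam")
    }


def _item_score(cvs: dict[str, str]) -> float:
    for name, value in cvs.items():
        if "score" in name.lower():
            try:
                return float(value)
            except ValueError:
                continue
    return 0.0


def _psm_from_result(result, peptides, evidences, accessions, spectra_data):
    spectrum_id = result.get("spectrumID")
    if spectrum_id is None:
        raise FormatError(
            f"SpectrumIdentificationResult {result.get('id')!r} lacks a spectrumID"
        )
    items = _children(result, "SpectrumIdentificationItem")
    rank1 = [it for it in items if int(it.get("rank", 1)) == 1]
    if not rank1:
        return None
    rank1.sort(key=lambda it: (-_item_score(_item_cv(it)), it.get("id", "")))
    item = rank1[0]
    cvs = _item_cv(item)

    pep_ref = item.get("peptide_ref")
    if pep_ref not in peptides:
        raise FormatError(
            f"unresolvable peptide reference {pep_ref!r} for spectrum "
            f"{spectrum_id!r}"
        )
    sequence, mods = peptides[pep_ref]

    accs = []
    for ev in _children(item, "PeptideEvidenceRef"):
        ref = ev.get("peptideEvidence_ref")
        if ref not in evidences:
            raise FormatError(
                f"unresolvable PeptideEvidence reference {ref!r} in item "
                f"{item.get('id')!r}"
            )
        _pref, dbref = evidences[ref]
        accs.append(accessions.get(dbref, dbref or "unknown"))
    if not accs:
        raise FormatError(
            f"item {item.get('id')!r} has no resolvable protein accession"
        )

    q = None
    for name in _QVALUE_NAMES:
        if name in cvs:
            q = float(cvs[name])
            break
    sd_ref = result.get("spectraData_ref")
    return PSM(
        psm_id=str(item.get("id")),
        run_id=spectra_data.get(sd_ref, sd_ref or "run"),
        scan_id=str(spectrum_id),
        peptide_sequence=sequence,
        modifications=mods,
        charge=int(item.get("chargeState", 1)),
        experimental_mz=float(item.get("experimentalMassToCharge", 0.0)),
        score=_item_score(cvs),
        q_value=q,
        protein_accessions=tuple(dict.fromkeys(accs)),
    )


# ---------------------------------------------------------------------------
# TSV dialect


def read_psm_tsv(path) -> IdentificationSet:
    """Read PSMs from the documented TSV dialect.

    Columns: psm_id, run_id, scan_id, sequence, mods, charge, exp_mz, score,
    q_value (or posterior_prob), proteins.  ``mods`` cells are
    ``pos:delta:name`` triples joined by ";" (empty for none); ``proteins``
    is ";"-joined accessions.
    """
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    has_q = "q_value" in df.columns
    has_p = "posterior_prob" in df.columns
    for col in TSV_COLUMNS:
        if col == "q_value" and not has_q and has_p:
            continue
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")

    if not has_q and has_p:
        df = _posteriors_to_qvalues(df)

    psms = []
    for _, row in df.iterrows():
        mods = []
        if row["mods"]:
            for token in str(row["mods"]).split(";"):
                pos, delta, name = token.split(":")
                mods.append((int(pos), float(delta), name))
        qcell = str(row["q_value"]).strip() if "q_value" in row else ""
        psms.append(
            PSM(
                psm_id=str(row["psm_id"]),
                run_id=str(row["run_id"]),
                scan_id=str(row["scan_id"]),
                peptide_sequence=str(row["sequence"]),
                modifications=tuple(sorted(mods)),
                charge=int(row["charge"]),
                experimental_mz=float(row["exp_mz"]),
                score=float(row["score"]),
                q_value=float(qcell) if qcell not in ("", "NA") else None,
                protein_accessions=tuple(str(row["proteins"]).split(";")),
            )
        )
    return IdentificationSet(psms=psms, source_format="tsv")


def _posteriors_to_qvalues(df: pd.DataFrame) -> pd.DataFrame:
    """q(i) = mean of (1 - p) over the top-i PSMs sorted by p descending."""
    p = df["posterior_prob"].astype(float).to_numpy()
    order = np.argsort(-p, kind="stable")
    q_sorted = np.cumsum(1.0 - p[order]) / np.arange(1, len(p) + 1)
    # enforce monotone non-decreasing q along decreasing p
    q_sorted = np.maximum.accumulate(q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    df = df.copy()
    df["q_value"] = q
    return df


def write_psm_tsv(ids: IdentificationSet, path) -> None:
    """Write PSMs in the TSV dialect (inverse of :func:`read_psm_tsv`)."""
    rows = []
    for p in ids.psms:
        rows.append({
            "psm_id": p.psm_id,
            "run_id": p.run_id,
            "scan_id": p.scan_id,
            "sequence": p.peptide_sequence,
            "mods": ";".join(f"{pos}:{delta:.5f}:{name}"
                             for pos, delta, name in p.modifications),
            "charge": p.charge,
            "exp_mz": f"{p.experimental_mz:.6f}",
            "score": p.score,
            "q_value": "" if p.q_value is None else p.q_value,
            "proteins": ";".join(p.protein_accessions),
        })
    pd.DataFrame(rows, columns=list(TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


def filter_psms(ids: IdentificationSet, q_threshold: float) -> IdentificationSet:
    """Retain PSMs with q_value <= threshold, preserving order.

    Threshold 1 is a no-op and permits absent q-values; any stricter
    threshold requires q-values on every PSM.
    """
    if not 0.0 <= q_threshold <= 1.0:
        raise ContractError(f"q_threshold outside [0, 1]: {q_threshold}")
    if q_threshold >= 1.0:
        return IdentificationSet(list(ids.psms), ids.source_format)
    if any(p.q_value is None for p in ids.psms):
        raise ContractError(
            "q-values absent on some PSMs; filtering below 1 impossible"
        )
    kept = [p for p in ids.psms if p.q_value <= q_threshold]
    return IdentificationSet(kept, ids.source_format)
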