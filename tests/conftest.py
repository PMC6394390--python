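"""Shared fixtures: tiny synthetic runs and hand-built standard-format files."""

from __future__ import annotations

import base64
import struct
import zlib

import numpy as np
import pytest

from pepquant.identifications import PSM, IdentificationSet
from pepquant.ms_io import RunData, Spectrum


def gaussian_run(
    run_id: str = "run1",
    peptide_mzs=(((500.0, 1000.0),),),
    apexes=(300.0,),
    sigma: float = 8.0,
    rt_max: float = 600.0,
    cycle: float = 1.0,
    ms2_at=None,
):
    """A run with Gaussian elution profiles at given (mz, height) pairs.

    ``peptide_mzs`` is one tuple of (mz, apex height) pairs per peptide;
    ``ms2_at`` optionally adds MS2 scans: list of (rt, precursor_mz).
    """
    spectra = []
    n = 0
    for t in np.arange(0.0, rt_max + cycle / 2, cycle):
        mzs, ints = [], []
        for pairs, apex in zip(peptide_mzs, apexes):
            h = np.exp(-0.5 * ((t - apex) / sigma) ** 2)
            if h < 1e-6:
                continue
            for mz, height in pairs:
                mzs.append(mz)
                ints.append(height * h)
        order = np.argsort(mzs)
        n += 1
        spectra.append(Spectrum(
            f"scan={n}", 1, float(t),
            np.asarray(mzs, dtype=float)[order] if mzs else np.empty(0),
            np.asarray(ints, dtype=float)[order] if ints else np.empty(0),
        ))
    for rt, prec in (ms2_at or []):
        n += 1
        spectra.append(Spectrum(
            f"scan={n}", 2, float(rt),
            np.array([200.0, 300.0]), np.array([10.0, 20.0]),
            precursor_mz=prec, precursor_charge=2,
        ))
    spectra.sort(key=lambda s: s.rt_seconds)
    return RunData(run_id=run_id, spectra=spectra)


def make_psm(
    psm_id="p1", run_id="run1", scan_id="scan=1", sequence="ALGVSEK",
    charge=2, exp_mz=400.0, score=50.0, q=0.001, proteins=("P1",), mods=(),
):
    return PSM(
        psm_id=psm_id, run_id=run_id, scan_id=scan_id,
        peptide_sequence=sequence, modifications=tuple(mods), charge=charge,
        experimental_mz=exp_mz, score=score, q_value=q,
        protein_accessions=tuple(proteins),
    )


def ident_set(psms):
    return IdentificationSet(list(psms), source_format="test")


# ---------------------------------------------------------------------------
# hand-built standard-format documents


def mzxml_text(scans):
    """Minimal mzXML 3.2 text.

    ``scans``: list of dicts with num, level, rt_minutes (None to omit),
    mz, intensity, and optional precursor_mz.
    """
    body = []
    for s in scans:
        pairs = np.empty(2 * len(s["mz"]), dtype=">f4")
        pairs[0::2] = s["mz"]
        pairs[1::2] = s["intensity"]
        b64 = base64.b64encode(pairs.tobytes()).decode()
        rt = "" if s.get("rt_minutes") is None else \
            f' retentionTime="PT{s["rt_minutes"] * 60:.3f}S"'
        prec = (
            f'<precursorMz precursorCharge="2">{s["precursor_mz"]:.4f}</precursorMz>'
            if "precursor_mz" in s else ""
        )
        body.append(
            f'<scan num="{s["num"]}" msLevel="{s["level"]}" centroided="1" '
            f'peaksCount="{len(s["mz"])}"{rt}>{prec}'
            f'<peaks compressionType="none" compressedLen="0" precision="32" '
            f'byteOrder="network" contentType="m/z-int">{b64}</peaks></scan>'
        )
    return (
        '<?xml version="1.0" encoding="ISO-8859-1"?>\n'
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">'
        "<msRun scanCount=\"%d\">%s</msRun></mzXML>" % (len(scans), "".join(body))
    )


def mzid_text(items):
    """Minimal mzIdentML 1.1 with one SpectrumIdentificationResult per item.

    ``items``: dicts with id, spectrum_id, sequence, rank, charge, exp_mz,
    score, q (optional), protein, mods (list of (loc, delta, name)).
    """
    peptides, evidences, dbseqs, results = [], [], [], []
    seen_prot = {}
    for k, it in enumerate(items):
        pid = f"PEP_{k}"
        mods = "".join(
            f'<Modification location="{loc}" monoisotopicMassDelta="{delta}">'
            f'<cvParam cvRef="UNIMOD" accession="UNIMOD:0" name="{name}"/>'
            "</Modification>"
            for loc, delta, name in it.get("mods", [])
        )
        peptides.append(
            f'<Peptide id="{pid}"><PeptideSequence>{it["sequence"]}'
            f"</PeptideSequence>{mods}</Peptide>"
        )
        prot = it.get("protein", "P1")
        if prot not in seen_prot:
            seen_prot[prot] = f"DB_{prot}"
            dbseqs.append(
                f'<DBSequence id="DB_{prot}" accession="{prot}" '
                'searchDatabase_ref="SDB1"/>'
            )
        evidences.append(
            f'<PeptideEvidence id="PE_{k}" peptide_ref="{pid}" '
            f'dBSequence_ref="DB_{prot}" isDecoy="false"/>'
        )
        q = (
            f'<cvParam cvRef="PSI-MS" accession="MS:1002354" '
            f'name="PSM-level q-value" value="{it["q"]}"/>'
            if "q" in it else ""
        )
        results.append(
            f'<SpectrumIdentificationResult id="SIR_{k}" '
            f'spectrumID="{it["spectrum_id"]}" spectraData_ref="SD1">'
            f'<SpectrumIdentificationItem id="{it["id"]}" rank="{it["rank"]}" '
            f'chargeState="{it["charge"]}" '
            f'experimentalMassToCharge="{it["exp_mz"]}" '
            f'calculatedMassToCharge="{it["exp_mz"]}" '
            f'peptide_ref="{pid}" passThreshold="true">'
            f'<PeptideEvidenceRef peptideEvidence_ref="PE_{k}"/>'
            f'<cvParam cvRef="PSI-MS" accession="MS:1001330" '
            f'name="X!Tandem:expect score" value="{it["score"]}"/>'
            f"{q}</SpectrumIdentificationItem></SpectrumIdentificationResult>"
        )
    return f"""<?xml version="1.0" encoding="UTF-8"?>
<MzIdentML xmlns="http://psidev.info/psi/pi/mzIdentML/1.1" id="MZID"
           version="1.1.0" creationDate="2024-01-01T00:00:00">
<cvList>
  <cv id="PSI-MS" fullName="PSI-MS" uri="x"/>
  <cv id="UNIMOD" fullName="UNIMOD" uri="x"/>
</cvList>
<SequenceCollection>
{''.join(dbseqs)}
{''.join(peptides)}
{''.join(evidences)}
</SequenceCollection>
<DataCollection>
<Inputs>
  <SearchDatabase id="SDB1" location="db.fasta"/>
  <SpectraData id="SD1" location="file:///data/run1.mzML" name="run1.mzML">
    <FileFormat><cvParam cvRef="PSI-MS" accession="MS:1000584"
      name="mzML format"/></FileFormat>
    <SpectrumIDFormat><cvParam cvRef="PSI-MS" accession="MS:1000776"
      name="scan number only nativeID format"/></SpectrumIDFormat>
  </SpectraData>
</Inputs>
<AnalysisData>
<SpectrumIdentificationList id="SIL1">
{''.join(results)}
</SpectrumIdentificationList>
</AnalysisData>
</DataCollection>
</MzIdentML>
"""


@pytest.fixture
def simple_run():
    return gaussian_run()


def zlib_b64_doubles(values) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(zlib.compress(raw)).decode()
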