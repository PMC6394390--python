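# Built-in labeling scheme catalogue.
#
# Precursor schemes: ordered channels; channel 0 is the reference ("light").
# Residue deltas apply once per matching residue (nterm/cterm once per
# peptide); formulas are "Symbol:count" tokens, negative counts remove light
# atoms replaced by the enriched variants C13, H2 (deuterium), N15, O18.
# Masses are derived from the formulas at load time when omitted.
#
# Reporter schemes carry the published reporter-ion m/z list instead.
# User-defined schemes use this same format via --scheme-file.

[silac_k8r10]
kind = "precursor"

[[silac_k8r10.channels]]
name = "light"

[[silac_k8r10.channels]]
name = "heavy"
deltas.K.formula = "C:-6 C13:6 N:-2 N15:2"   # +8.014199 Da (Lys8)
deltas.R.formula = "C:-6 C13:6 N:-4 N15:4"   # +10.008269 Da (Arg10)

[silac_k4r6]
kind = "precursor"

[[silac_k4r6.channels]]
name = "light"

[[silac_k4r6.channels]]
name = "medium"
deltas.K.formula = "H:-4 H2:4"               # +4.025107 Da (Lys4)
deltas.R.formula = "C:-6 C13:6"              # +6.020129 Da (Arg6)

[o18]
kind = "precursor"

[[o18.channels]]
name = "light"

[[o18.channels]]
name = "heavy"
deltas.cterm.formula = "O:-2 O18:2"          # +4.008491 Da, enzymatic C-term exchange

[n15]
kind = "precursor"

[[n15.channels]]
name = "light"

[[n15.channels]]
name = "heavy"
replace.N = { variant = "N15", enrichment = 0.98 }

[icat_c9]
kind = "precursor"

[[icat_c9.channels]]
name = "light"
deltas.C.formula = "C:10 H:17 N:3 O:3"       # cleavable ICAT reagent, +227.126991 Da

[[icat_c9.channels]]
name = "heavy"
deltas.C.formula = "C:1 C13:9 H:17 N:3 O:3"  # 13C9 reagent, +236.157187 Da

[icpl_4]
kind = "precursor"

[[icpl_4.channels]]
name = "light"
deltas.K.formula = "C:6 H:3 N:1 O:1"         # nicotinoyl, +105.021464 Da
deltas.nterm.formula = "C:6 H:3 N:1 O:1"

[[icpl_4.channels]]
name = "heavy"
deltas.K.formula = "C:6 H:-1 H2:4 N:1 O:1"   # ring-d4 nicotinoyl, +109.046571 Da
deltas.nterm.formula = "C:6 H:-1 H2:4 N:1 O:1"

[itraq4]
kind = "reporter"
channel_names = ["114", "115", "116", "117"]
reporter_mzs = [114.110679, 115.107715, 116.111069, 117.114424]

[itraq8]
kind = "reporter"
channel_names = ["113", "114", "115", "116", "117", "118", "119", "121"]
reporter_mzs = [
    113.107325, 114.110679, 115.107715, 116.111069,
    117.114424, 118.111459, 119.114814, 121.121524,
]

[tmt6]
kind = "reporter"
channel_names = ["126", "127", "128", "129", "130", "131"]
reporter_mzs = [
    126.127726, 127.124761, 128.134436,
    129.131471, 130.141145, 131.138180,
]

[tmt10]
kind = "reporter"
channel_names = [
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131",
]
reporter_mzs = [
    126.127726, 127.124761, 127.131081, 128.128116, 128.134436,
    129.131471, 129.137790, 130.134825, 130.141145, 131.138180,
]
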