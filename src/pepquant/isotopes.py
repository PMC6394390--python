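"""Label-aware elemental composition arithmetic and isotope-envelope prediction.

The quantification engine anchors every peptide signal on its theoretical
isotope envelope.  This module provides:

* :class:`ElementalComposition` — integer element counts plus an optional
  mass-only remainder for modifications whose formula is unknown;
* :func:`composition_from_peptide` / :func:`monoisotopic_mz` — standard
  residue-formula arithmetic (residue formulas and isotope masses come from
  the NIST table shipped with :mod:`pyteomics`);
* :func:`theoretical_pattern` — aggregated-isotopologue envelope prediction
  by per-element convolution, including partially enriched label elements
  (e.g. 98 % ¹⁵N) modelled as two-point isotope distributions;
* :class:`LabelScheme` and :func:`apply_label` — built-in and user-defined
  precursor/reporter labeling schemes (SILAC, ¹⁸O, ¹⁵N, ICAT, ICPL,
  iTRAQ/TMT) loaded from a TOML catalogue;
* :func:`match_pattern` and :func:`dynamic_match_tolerance` — envelope
  matching against centroided spectra with a data-adaptive m/z window.

Conventions
-----------
Envelope peaks are aggregated per nominal isotopologue (one centroid per
~1.003355/z spacing), not fine structure.  For enriched label elements the
"monoisotopic" peak is the all-enriched-isotope species; residual-light
satellites appear *below* it, so ``monoisotopic_index`` may be positive.
"""

from __future__ import annotations

import importlib.resources
import tomllib
from dataclasses import dataclass, field, replace

import numpy as np
from pyteomics import mass as _pmass

from .errors import ContractError, InputError

PROTON_MASS = 1.00727646688  # mass of H+ in Da

#: enriched-variant symbol -> (base element, isotope number)
ENRICHED_VARIANTS = {
    "C13": ("C", 13),
    "H2": ("H", 2),
    "N15": ("N", 15),
    "O18": ("O", 18),
}

_CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

# abundance below which isotopologues are dropped from predicted envelopes,
# relative to the base peak
_REL_ABUNDANCE_FLOOR = 1e-4


def _natural_isotopes(element: str) -> list[tuple[float, float]]:
    """(mass, abundance) pairs with nonzero natural abundance, lightest first."""
    table = _pmass.nist_mass[element]
    isos = [(m, ab) for k, (m, ab) in table.items() if k != 0 and ab > 0.0]
    if not isos:
        raise InputError(f"no isotope data for element {element!r}")
    return sorted(isos)


def principal_isotope_mass(symbol: str) -> float:
    """Reference isotope mass of a symbol.

    Natural elements use their lightest naturally occurring isotope; enriched
    variants (C13, N15, O18, H2) use the enriched isotope itself.
    """
    if symbol in ENRICHED_VARIANTS:
        el, iso = ENRICHED_VARIANTS[symbol]
        return _pmass.nist_mass[el][iso][0]
    return _natural_isotopes(symbol)[0][0]


@dataclass(frozen=True)
class ElementalComposition:
    """Integer element counts, e.g. ``{"C": 2, "H": 5, "N": 1, "O": 2}``.

    ``extra_mass`` carries the summed mass of modifications without a known
    elemental formula: it shifts every envelope peak uniformly but does not
    enter the isotope convolution.  ``mass_only_mods`` flags that case.
    """

    counts: dict[str, int] = field(default_factory=dict)
    extra_mass: float = 0.0
    mass_only_mods: bool = False

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if n < 0:
                raise ContractError(f"negative count for {sym}: {n}")

    def nonzero(self) -> dict[str, int]:
        return {s: n for s, n in self.counts.items() if n != 0}

    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def with_delta(self, delta: dict[str, int]) -> "ElementalComposition":
        """Return a new composition with ``delta`` counts added.

        Delta values may be negative (label chemistry removes light atoms when
        adding heavy ones) but the result must stay non-negative.
        """
        new = dict(self.counts)
        for sym, d in delta.items():
            new[sym] = new.get(sym, 0) + d
        for sym, n in new.items():
            if n < 0:
                raise ContractError(
                    f"delta drives {sym} count negative ({n}); "
                    "label not applicable to this composition"
                )
        return replace(self, counts={s: n for s, n in new.items() if n != 0})

    def monoisotopic_mass(self) -> float:
        """Neutral mass with every atom at its principal isotope."""
        return (
            sum(n * principal_isotope_mass(s) for s, n in self.counts.items())
            + self.extra_mass
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        return (
            self.nonzero() == other.nonzero()
            and abs(self.extra_mass - other.extra_mass) < 1e-9
        )


@dataclass
class IsotopePattern:
    """Aggregated theoretical isotopologue envelope at a given charge.

    ``mz`` is ascending with ~1.003355/charge spacing; ``rel_abundance`` is
    scaled to max = 1; ``monoisotopic_index`` points at the all-principal-
    isotope peak (index > 0 only for enriched-label compositions with
    residual light satellites).
    """

    mz: np.ndarray
    rel_abundance: np.ndarray
    monoisotopic_index: int
    charge: int

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def monoisotopic_mz(self) -> float:
        return float(self.mz[self.monoisotopic_index])


_WATER = {"H": 2, "O": 1}


def composition_from_peptide(
    sequence: str,
    modifications: list[tuple[int, float, str]] | None = None,
    modification_formulas: dict[str, dict[str, int]] | None = None,
) -> ElementalComposition:
    """Elemental composition of a peptide: residue formulas + H2O + mods.

    ``modifications`` are ``(position, mass_delta_da, name)`` tuples
    (position 0 = N-terminus).  When a modification name has an entry in
    ``modification_formulas`` its elemental delta is applied; otherwise the
    delta contributes mass only and the composition is flagged.

    Protons for the charge state are handled at m/z computation, not here.
    """
    if not sequence:
        raise InputError("empty peptide sequence")
    bad = set(sequence) - _CANONICAL_RESIDUES
    if bad:
        raise InputError(f"unknown residue letter(s) {sorted(bad)} in {sequence!r}")

    counts: dict[str, int] = dict(_WATER)
    for res in sequence:
        for sym, n in _pmass.std_aa_comp[res].items():
            counts[sym] = counts.get(sym, 0) + n

    extra = 0.0
    mass_only = False
    comp = ElementalComposition(counts)
    for pos, delta, name in modifications or []:
        if pos < 0 or pos > len(sequence):
            raise InputError(
                f"modification position {pos} outside sequence of length {len(sequence)}"
            )
        formula = (modification_formulas or {}).get(name)
        if formula is not None:
            comp = comp.with_delta(formula)
        else:
            extra += delta
            mass_only = True
    return replace(comp, extra_mass=comp.extra_mass + extra, mass_only_mods=mass_only)


def monoisotopic_mz(composition: ElementalComposition, charge: int) -> float:
    """m/z of the all-principal-isotope species at the given positive charge."""
    if charge < 1:
        raise ContractError(f"charge must be >= 1, got {charge}")
    return (composition.monoisotopic_mass() + charge * PROTON_MASS) / charge


# ---------------------------------------------------------------------------
# envelope prediction


def _element_distribution(
    symbol: str, enrichment: dict[str, float] | None
) -> list[tuple[int, float, float]]:
    """Single-atom isotope distribution as (nominal offset, prob, mass).

    Offsets are nominal mass units relative to the principal isotope; for
    enriched variants the residual light isotope sits at a negative offset.
    """
    if symbol in ENRICHED_VARIANTS:
        el, iso = ENRICHED_VARIANTS[symbol]
        frac = 1.0 if enrichment is None else float(enrichment.get(symbol, 1.0))
        if not (0.0 < frac <= 1.0):
            raise ContractError(f"enrichment for {symbol} must be in (0, 1], got {frac}")
        heavy_mass = _pmass.nist_mass[el][iso][0]
        light_mass = _natural_isotopes(el)[0][0]
        dist = [(0, frac, heavy_mass)]
        if frac < 1.0:
            dist.append((round(light_mass - heavy_mass), 1.0 - frac, light_mass))
        return dist
    isos = _natural_isotopes(symbol)
    mono = isos[0][0]
    return [(round(m - mono), ab, m) for m, ab in isos]


def _convolve(a: dict[int, tuple[float, float]], b: dict[int, tuple[float, float]]):
    """Convolve two offset -> (prob, prob*mean_mass) distributions."""
    out: dict[int, tuple[float, float]] = {}
    for o1, (p1, pm1) in a.items():
        for o2, (p2, pm2) in b.items():
            p = p1 * p2
            if p < 1e-15:
                continue
            pm = p2 * pm1 + p1 * pm2
            o = o1 + o2
            if o in out:
                q, qm = out[o]
                out[o] = (q + p, qm + pm)
            else:
                out[o] = (p, pm)
    return out


def _power(dist: dict[int, tuple[float, float]], n: int):
    """n-fold self-convolution by binary exponentiation."""
    result = {0: (1.0, 0.0)}
    base = dist
    while n:
        if n & 1:
            result = _convolve(result, base)
        base = _convolve(base, base) if n > 1 else base
        n >>= 1
    return result


def theoretical_pattern(
    composition: ElementalComposition,
    charge: int,
    n_peaks: int = 3,
    enrichment: dict[str, float] | None = None,
) -> IsotopePattern:
    """Predict the aggregated isotope envelope of a composition.

    Returns the ``n_peaks`` isotopologues from the monoisotopic peak upward,
    plus any residual-light satellites below it whose relative abundance
    clears 1e-4 (these occur only with sub-unity enrichment).  Peak centroids
    are abundance-weighted mean masses per nominal isotopologue.
    """
    if n_peaks < 1:
        raise ContractError("n_peaks must be >= 1")
    if charge < 1:
        raise ContractError("charge must be >= 1")

    agg: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for sym, count in composition.nonzero().items():
        single = {o: (p, p * m) for o, p, m in _element_distribution(sym, enrichment)}
        agg = _convolve(agg, _power(single, count))

    if not agg:
        raise ContractError("empty envelope")
    pmax = max(p for p, _ in agg.values())
    keep = sorted(
        o
        for o, (p, _) in agg.items()
        if (0 <= o < n_peaks) or (o < 0 and p / pmax >= _REL_ABUNDANCE_FLOOR)
    )
    if 0 not in keep:
        keep = sorted(keep + [0])
    rel = np.array([agg[o][0] for o in keep])
    rel = rel / rel.max()
    masses = np.array(
        [agg[o][1] / agg[o][0] if agg[o][0] > 0 else 0.0 for o in keep]
    )
    mz = (masses + composition.extra_mass + charge * PROTON_MASS) / charge
    return IsotopePattern(
        mz=mz,
        rel_abundance=rel,
        monoisotopic_index=keep.index(0),
        charge=charge,
    )


# ---------------------------------------------------------------------------
# label schemes


@dataclass(frozen=True)
class ResidueDelta:
    """Mass and elemental change applied once per matching residue/terminus."""

    mass: float
    formula: dict[str, int] | None  # None -> mass-only delta


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    #: residue letter or "nterm"/"cterm" -> delta
    residue_deltas: dict[str, ResidueDelta] = field(default_factory=dict)
    #: element -> (enriched variant symbol, enrichment fraction)
    element_replacements: dict[str, tuple[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class LabelScheme:
    """A precursor- or reporter-ion labeling scheme.

    Channel 0 is the reference ("light").  Reporter schemes carry per-channel
    reporter m/z values instead of precursor deltas.
    """

    name: str
    kind: str  # "precursor" | "reporter"
    channels: tuple[ChannelSpec, ...]
    reporter_mzs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("precursor", "reporter"):
            raise InputError(f"unknown scheme kind {self.kind!r}")
        if not self.channels:
            raise InputError("scheme must define at least one channel")
        if self.kind == "reporter" and len(self.reporter_mzs) != len(self.channels):
            raise InputError("reporter scheme needs one reporter m/z per channel")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def enrichment_map(self, channel: int) -> dict[str, float]:
        """Variant symbol -> enrichment fraction for a channel."""
        return {
            variant: frac
            for variant, frac in self.channels[channel].element_replacements.values()
        }


@dataclass(frozen=True)
class LabelResult:
    """Outcome of applying one scheme channel to a peptide composition."""

    composition: ElementalComposition
    applicable: bool  # False if no labelable residue/element present
    mass_shift: float


def _parse_formula(text: str) -> dict[str, int]:
    """Parse 'C:-6 C13:6 N:-2 N15:2' into a delta dict."""
    out: dict[str, int] = {}
    for token in text.split():
        sym, _, n = token.partition(":")
        if not n:
            raise InputError(f"bad formula token {token!r}")
        out[sym] = out.get(sym, 0) + int(n)
    return out


def _formula_mass(formula: dict[str, int]) -> float:
    return sum(n * principal_isotope_mass(s) for s, n in formula.items())


def _channel_from_toml(raw: dict) -> ChannelSpec:
    deltas: dict[str, ResidueDelta] = {}
    for target, spec in raw.get("deltas", {}).items():
        formula = _parse_formula(spec["formula"]) if "formula" in spec else None
        mass_delta = spec.get("mass")
        if mass_delta is None:
            if formula is None:
                raise InputError(f"delta for {target!r} needs a mass or a formula")
            mass_delta = _formula_mass(formula)
        deltas[target] = ResidueDelta(mass=float(mass_delta), formula=formula)
    repl: dict[str, tuple[str, float]] = {}
    for element, spec in raw.get("replace", {}).items():
        repl[element] = (spec["variant"], float(spec.get("enrichment", 1.0)))
    return ChannelSpec(
        name=raw.get("name", ""), residue_deltas=deltas, element_replacements=repl
    )


def _scheme_from_toml(name: str, raw: dict) -> LabelScheme:
    kind = raw.get("kind", "precursor")
    if kind == "reporter":
        mzs = tuple(float(x) for x in raw["reporter_mzs"])
        names = raw.get("channel_names", [f"ch{i}" for i in range(len(mzs))])
        channels = tuple(ChannelSpec(name=n) for n in names)
        return LabelScheme(name=name, kind=kind, channels=channels, reporter_mzs=mzs)
    channels = tuple(_channel_from_toml(c) for c in raw["channels"])
    return LabelScheme(name=name, kind=kind, channels=channels)


def load_scheme_catalogue(path=None) -> dict[str, LabelScheme]:
    """Load all schemes from a TOML catalogue (built-in file by default)."""
    if path is None:
        ref = importlib.resources.files("pepquant.data") / "label_schemes.toml"
        data = tomllib.loads(ref.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return {name: _scheme_from_toml(name, raw) for name, raw in data.items()}


def load_scheme(name: str, path=None) -> LabelScheme:
    """Load one named scheme from the built-in or a user catalogue."""
    catalogue = load_scheme_catalogue(path)
    if name not in catalogue:
        raise InputError(
            f"unknown label scheme {name!r}; available: {sorted(catalogue)}"
        )
    return catalogue[name]


def apply_label(
    composition: ElementalComposition,
    sequence: str,
    scheme: LabelScheme,
    channel: int,
) -> LabelResult:
    """Apply one channel of a precursor labeling scheme to a peptide.

    Residue deltas apply once per matching residue (plus once per matching
    terminus); element replacements move the whole element count to the
    enriched variant (sub-unity enrichment is handled later, in
    :func:`theoretical_pattern`).  A channel whose deltas match nothing in
    the sequence returns the composition unchanged with ``applicable=False``.
    """
    if not 0 <= channel < scheme.n_channels:
        raise ContractError(f"channel {channel} out of range for {scheme.name}")
    if scheme.kind != "precursor":
        raise ContractError(f"{scheme.name} is not a precursor scheme")

    spec = scheme.channels[channel]
    comp = composition
    shift = 0.0
    n_applied = 0
    has_rules = bool(spec.residue_deltas) or bool(spec.element_replacements)

    for target, delta in spec.residue_deltas.items():
        if target == "nterm" or target == "cterm":
            n_sites = 1
        else:
            n_sites = sequence.count(target)
        if n_sites == 0:
            continue
        n_applied += n_sites
        shift += n_sites * delta.mass
        if delta.formula is not None:
            scaled = {s: n * n_sites for s, n in delta.formula.items()}
            comp = comp.with_delta(scaled)
        else:
            comp = replace(
                comp, extra_mass=comp.extra_mass + n_sites * delta.mass,
                mass_only_mods=True,
            )

    for element, (variant, _frac) in spec.element_replacements.items():
        n = comp.counts.get(element, 0)
        if n == 0:
            continue
        n_applied += n
        shift += n * (principal_isotope_mass(variant) - principal_isotope_mass(element))
        comp = comp.with_delta({element: -n, variant: n})

    if has_rules and n_applied == 0:
        return LabelResult(composition=composition, applicable=False, mass_shift=0.0)
    return LabelResult(composition=comp, applicable=True, mass_shift=shift)


# ---------------------------------------------------------------------------
# matching


def dynamic_match_tolerance(
    mass_errors_ppm, initial_tol_ppm: float, min_observations: int = 20
) -> float:
    """Data-adaptive m/z matching window.

    With at least ``min_observations`` observed matched-peak ppm errors the
    window shrinks to |median| + 4 robust standard deviations
    (MAD x 1.4826), clamped to [1 ppm, initial_tol_ppm]; with fewer it
    stays at ``initial_tol_ppm``.
    """
    if initial_tol_ppm <= 0:
        raise ContractError("initial_tol_ppm must be positive")
    e = np.asarray(list(mass_errors_ppm), dtype=float)
    if e.size < min_observations:
        return float(initial_tol_ppm)
    med = np.median(e)
    mad = np.median(np.abs(e - med))
    tol = abs(med) + 4.0 * mad * 1.4826
    return float(np.clip(tol, 1.0, initial_tol_ppm))


def match_pattern(
    spectrum, pattern: IsotopePattern, tol_ppm: float
) -> tuple[list[tuple[int, int]], float, list[float]]:
    """Match a theoretical envelope against a centroided spectrum.

    Greedy one-to-one assignment, closest ppm error first.  The score is the
    cosine similarity between theoretical and observed abundances over the
    matched positions, scaled by the matched fraction of total theoretical
    abundance, so missing envelope peaks cost score even when the matched
    subset correlates perfectly.

    Returns ``(matches, score, errors_ppm)`` where matches are
    ``(pattern index, spectrum peak index)`` pairs.
    """
    mzs = np.asarray(spectrum.mz_array, dtype=float)
    ints = np.asarray(spectrum.intensity_array, dtype=float)
    candidates = []
    for i, pmz in enumerate(pattern.mz):
        if mzs.size == 0:
            break
        lo = pmz * (1 - tol_ppm * 1e-6)
        hi = pmz * (1 + tol_ppm * 1e-6)
        j0, j1 = np.searchsorted(mzs, [lo, hi])
        for j in range(j0, j1):
            err = (mzs[j] - pmz) / pmz * 1e6
            candidates.append((abs(err), i, j, err))
    candidates.sort()

    used_pattern: set[int] = set()
    used_peak: set[int] = set()
    assigned: list[tuple[int, int, float]] = []
    for _aerr, i, j, err in candidates:
        if i in used_pattern or j in used_peak:
            continue
        used_pattern.add(i)
        used_peak.add(j)
        assigned.append((i, j, err))

    if not assigned:
        return [], 0.0, []
    assigned.sort()
    matches = [(i, j) for i, j, _ in assigned]
    errors = [err for _, _, err in assigned]
    theo = np.array([pattern.rel_abundance[i] for i, _ in matches])
    obs = np.array([ints[j] for _, j in matches])
    denom = np.linalg.norm(theo) * np.linalg.norm(obs)
    cosine = float(theo @ obs / denom) if denom > 0 else 0.0
    frac = float(theo.sum() / pattern.rel_abundance.sum())
    return matches, cosine * frac, errors
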