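"""Pipeline configuration: a flat TOML-backed parameter schema.

Every tunable of the quantification pipelines lives here with its default,
so a run is reproducible from the config file plus the seed alone.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, fields

from .errors import InputError


@dataclass
class QuantConfig:
    # identification filtering
    q_threshold: float = 0.01        # PSM-level q-value cutoff

    # XIC construction (filter stack)
    tol_ppm: float = 10.0            # m/z window half-width, ppm
    rt_halfwidth: float = 150.0      # XIC window half-width, s
    apex_halfwidth: float = 15.0     # apex search around the anchor, s
    transfer_apex_halfwidth: float = 30.0  # widened search for transferred features
    smooth_window: int = 3           # moving-average points (odd)
    n_isotopologues: int = 3         # envelope peaks integrated per channel
    envelope_min_corr: float = 0.6   # isotopologue-vs-mono Pearson floor

    # dynamic matching tolerance
    dynamic_tolerance: bool = True
    initial_tol_ppm: float = 20.0    # first-pass window feeding the error pool
    min_tolerance_observations: int = 20

    # labeled quantification
    scheme: str = "silac_k8r10"
    min_ratio_quality: float = 0.3   # below -> low-confidence flag
    overlap_spacing_da: float = 6.0  # channel spacing (in isotopologue widths)
                                     # under which overlap correction engages

    # reporter quantification
    reporter_tol_mz: float = 0.003   # Th; merges TMT10 N/C pairs by design

    # cross-run assembly
    transfer: bool = False           # match-between-runs off by default
    normalize: bool = True

    # protein rollup
    min_peptides: int = 1

    # simulation / CLI
    seed: int = 1

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise InputError("smooth_window must be a positive odd integer")
        if not 0.0 <= self.q_threshold <= 1.0:
            raise InputError("q_threshold must lie in [0, 1]")
        if self.tol_ppm <= 0 or self.initial_tol_ppm <= 0:
            raise InputError("ppm tolerances must be positive")
        if self.n_isotopologues < 1:
            raise InputError("n_isotopologues must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> QuantConfig:
    """Build a config from an optional TOML file plus keyword overrides.

    Unknown keys raise a startup error listing the valid ones.
    """
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            values.update(tomllib.load(fh))
    values.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(QuantConfig)}
    unknown = set(values) - valid
    if unknown:
        raise InputError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    return QuantConfig(**values)
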