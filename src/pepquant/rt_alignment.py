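"""Invertible monotone retention-time alignment between runs.

Chromatographic drift between runs is modelled as a strictly increasing
warp fitted to anchor pairs — peptides confidently identified in both runs.
The fit is robust LOWESS of the reference RT on the source RT, projected to
strict monotonicity (pool-adjacent-violators plus an epsilon separation)
and interpolated with a monotone piecewise-cubic (PCHIP) spline; beyond the
anchor range the warp continues linearly with the boundary slope.  Strict
monotonicity makes the mapping exactly invertible, which is what permits
transferring features in either direction between runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .errors import AlignmentInfeasibleError, ContractError
from .identifications import IdentificationSet
from .xic import RunIndex, detect_boundaries, extract_xic, smooth_xic

MIN_ANCHORS = 10
_EPS_SEP = 1e-6  # seconds; strictness margin between adjacent knots


@dataclass
class RTAlignmentModel:
    """A fitted strictly increasing warp rt_source -> rt_reference."""

    anchor_pairs: np.ndarray          # (n, 2) [rt_source, rt_reference]
    knots_x: np.ndarray               # strictly increasing source knots
    knots_y: np.ndarray               # strictly increasing reference knots
    valid_range: tuple[float, float]  # source-side range of the anchors

    def __post_init__(self) -> None:
        if np.any(np.diff(self.knots_x) <= 0) or np.any(np.diff(self.knots_y) <= 0):
            raise ContractError("alignment knots must be strictly increasing")
        self._spline = PchipInterpolator(self.knots_x, self.knots_y, extrapolate=False)
        d = self._spline.derivative()
        self._slope_lo = max(float(d(self.knots_x[0])), _EPS_SEP)
        self._slope_hi = max(float(d(self.knots_x[-1])), _EPS_SEP)


def collect_anchors(
    ids_a: IdentificationSet,
    ids_b: IdentificationSet,
    run_a=None,
    run_b=None,
    scan_rt_a: dict[str, float] | None = None,
    scan_rt_b: dict[str, float] | None = None,
    tol_ppm: float = 10.0,
    apex_halfwidth: float = 30.0,
) -> np.ndarray:
    """Anchor pairs (rt_a, rt_b) for peptides identified in both runs.

    One pair per (sequence, modifications, charge); duplicate
    identifications collapse to the highest-scoring PSM.  The RT of each
    anchor is the apex of the peptide's monoisotopic XIC near its MS2 scan
    when the run (and scan-RT lookup) is supplied, else the MS2 scan RT.
    """
    best_a = _best_by_key(ids_a)
    best_b = _best_by_key(ids_b)
    shared = sorted(set(best_a) & set(best_b))
    if len(shared) < MIN_ANCHORS:
        raise AlignmentInfeasibleError(
            f"only {len(shared)} shared peptides (< {MIN_ANCHORS}); "
            "falling back to identity alignment is the caller's decision"
        )
    pairs = []
    for key in shared:
        rt_a = _anchor_rt(best_a[key], run_a, scan_rt_a, tol_ppm, apex_halfwidth)
        rt_b = _anchor_rt(best_b[key], run_b, scan_rt_b, tol_ppm, apex_halfwidth)
        pairs.append((rt_a, rt_b))
    return np.array(sorted(pairs))


def _best_by_key(ids: IdentificationSet) -> dict:
    best = {}
    for p in ids.psms:
        key = p.peptide_key
        if key not in best or (p.score, p.psm_id) > (best[key].score, best[key].psm_id):
            best[key] = p
    return best


def _anchor_rt(psm, run, scan_rt, tol_ppm, apex_halfwidth) -> float:
    if scan_rt is None:
        if run is None:
            raise ContractError(
                "collect_anchors needs run data and/or a scan-RT lookup"
            )
        scan_rt = {s.scan_id: s.rt_seconds for s in run.spectra}
    rt0 = scan_rt[psm.scan_id]
    if run is None:
        return rt0
    index = run if isinstance(run, RunIndex) else RunIndex(run)
    x = extract_xic(index, psm.experimental_mz, tol_ppm, rt0, apex_halfwidth + 30.0)
    if len(x) < 3:
        return rt0
    x = detect_boundaries(smooth_xic(x, 3), rt0, apex_halfwidth=apex_halfwidth)
    if x.apex_index is None:
        return rt0
    return float(x.rt[x.apex_index])


def fit_alignment(
    anchors: np.ndarray, frac: float = 0.3, robust_iterations: int = 2
) -> RTAlignmentModel:
    """Fit the monotone warp from anchor pairs (rt_source, rt_reference)."""
    anchors = np.asarray(anchors, dtype=float)
    if anchors.ndim != 2 or anchors.shape[1] != 2 or len(anchors) < MIN_ANCHORS:
        raise ContractError(f"need >= {MIN_ANCHORS} anchor pairs")
    x, y = anchors[:, 0], anchors[:, 1]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]

    fitted = _lowess(y, x, frac=frac, it=robust_iterations, return_sorted=False)

    # collapse duplicate x (LOWESS is defined per unique x anyway)
    ux, inverse = np.unique(x, return_inverse=True)
    uy = np.zeros_like(ux)
    counts = np.bincount(inverse)
    np.add.at(uy, inverse, fitted)
    uy /= counts

    uy = _pava(uy)
    for i in range(1, len(uy)):  # epsilon separation -> strict monotonicity
        if uy[i] <= uy[i - 1]:
            uy[i] = uy[i - 1] + _EPS_SEP
    if len(ux) < 2:
        raise ContractError("need at least 2 distinct source RTs")
    return RTAlignmentModel(
        anchor_pairs=np.column_stack([x, y]),
        knots_x=ux,
        knots_y=uy,
        valid_range=(float(ux[0]), float(ux[-1])),
    )


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection to non-decreasing order."""
    y = y.astype(float).copy()
    n = len(y)
    weights = np.ones(n)
    values = y.copy()
    # classic stack-based PAVA
    vals: list[float] = []
    wts: list[float] = []
    sizes: list[int] = []
    for v, w in zip(values, weights):
        vals.append(v)
        wts.append(w)
        sizes.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2, s2 = vals.pop(), wts.pop(), sizes.pop()
            v1, w1, s1 = vals.pop(), wts.pop(), sizes.pop()
            vals.append((v1 * w1 + v2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
            sizes.append(s1 + s2)
    out = np.empty(n)
    i = 0
    for v, s in zip(vals, sizes):
        out[i : i + s] = v
        i += s
    return out


def map_rt(model: RTAlignmentModel, t) -> float | np.ndarray:
    """Map a source-run RT to the reference run's time axis."""
    t = np.asarray(t, dtype=float)
    lo, hi = model.valid_range
    out = np.empty(t.shape)
    below = t < lo
    above = t > hi
    inside = ~below & ~above
    out[inside] = model._spline(t[inside])
    out[below] = model.knots_y[0] + (t[below] - lo) * model._slope_lo
    out[above] = model.knots_y[-1] + (t[above] - hi) * model._slope_hi
    return float(out) if out.ndim == 0 else out


def invert_rt(model: RTAlignmentModel, t) -> float | np.ndarray:
    """Map a reference-run RT back to the source run (numeric inversion).

    Round-trips with :func:`map_rt` within 1e-3 s over the valid range.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    y_lo, y_hi = model.knots_y[0], model.knots_y[-1]
    out = np.empty(t_arr.shape)
    for i, yv in enumerate(t_arr):
        if yv <= y_lo:
            out[i] = model.valid_range[0] + (yv - y_lo) / model._slope_lo
        elif yv >= y_hi:
            out[i] = model.valid_range[1] + (yv - y_hi) / model._slope_hi
        else:
            out[i] = brentq(
                lambda x: model._spline(x) - yv,
                model.valid_range[0],
                model.valid_range[1],
                xtol=1e-9,
            )
    return float(out[0]) if np.ndim(t) == 0 else out


def transfer_feature(model: RTAlignmentModel, source_rt: float) -> float:
    """Predicted RT of a feature in the reference run.

    Downstream XIC extraction anchors at the prediction with a widened
    (+-30 s) apex search to absorb residual warp error.
    """
    return float(map_rt(model, source_rt))
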