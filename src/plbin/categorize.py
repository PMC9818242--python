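"""Categorization of raw multi-omics measurements into discrete states.

The implication-network machinery consumes discrete states; this module
implements the categorization conventions of the toolkit:

* **Ternary expression states** (down / normal / up) calibrated on
  housekeeping genes: the total fraction of up- plus down-regulated samples
  across the housekeeping panel is fixed (30% by default), the average
  standard deviation of the housekeeping normal ranges defines a single
  genome-wide half-width, and each gene's own center completes its normal
  range.
* **CNV states**: copy number < 2 is a deletion, 2 is diploid normal, > 2
  a duplication/amplification.
* **Single-cell binary states**: a feature count of 0 is "not expressed",
  any positive count is "expressed".
* **Drug-response categories** (sensitive / partial / resistant) from
  IC50/EC50 values via the tested dose range and a mean ± 0.5 SD band.
* **Proliferation essentiality flags** from normalized dependency scores
  (significant below −0.5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateModelError, IdentifierError, InputError
from .matrix import CategorizedMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalRangeModel",
    "fit_normal_range_model",
    "categorize_expression",
    "categorize_cnv",
    "binarize_single_cell",
    "categorize_drug_response",
    "flag_proliferation_effect",
]


@dataclass
class NormalRangeModel:
    """Housekeeping-calibrated normal-range model for ternary categorization.

    Attributes
    ----------
    hk_gene_ids
        Housekeeping genes the model was fitted on.
    target_outside_fraction
        Total up+down mass the calibration targets (default 0.30).
    per_hk_cutoffs
        Per-housekeeping-gene (lower, upper) quantile cutoffs that delimit
        its normal range.
    sigma_bar
        Arithmetic mean of the per-housekeeping normal-range sample SDs;
        the single genome-wide width unit.
    center_statistic
        Per-gene center used when applying the model: ``median`` (robust
        default) or ``mean``.
    width_multiplier
        Calibrated multiplier: the half-width of every gene's normal range
        is ``width_multiplier * sigma_bar``.
    """

    hk_gene_ids: list[str]
    target_outside_fraction: float
    per_hk_cutoffs: dict[str, tuple[float, float]]
    sigma_bar: float
    center_statistic: Literal["median", "mean"] = "median"
    width_multiplier: float = 1.0
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.sigma_bar < 0:
            raise InputError("sigma_bar must be non-negative")
        for g, (lo, hi) in self.per_hk_cutoffs.items():
            if lo > hi:
                raise InputError(f"lower cutoff exceeds upper for {g}")
        if self.width_multiplier <= 0:
            raise InputError("width_multiplier must be positive")

    @property
    def half_width(self) -> float:
        return self.width_multiplier * self.sigma_bar


def _center(values: np.ndarray, statistic: str) -> float:
    return float(np.nanmedian(values) if statistic == "median" else np.nanmean(values))


def _outside_fraction(
    expr: ExpressionMatrix,
    gene_ids: Sequence[str],
    half_width: float,
    center_statistic: str,
) -> float:
    """Average over genes of the fraction of samples outside center ± half_width."""
    fracs = []
    for g in gene_ids:
        v = expr.gene_values(g)
        v = v[~np.isnan(v)]
        c = _center(v, center_statistic)
        fracs.append(np.mean(np.abs(v - c) > half_width))
    return float(np.mean(fracs))


def fit_normal_range_model(
    expr: ExpressionMatrix,
    hk_ids: Sequence[str],
    target_outside: float = 0.30,
    center_statistic: Literal["median", "mean"] = "median",
    quantile_method: str = "linear",
    calibration_tol: float = 0.005,
) -> NormalRangeModel:
    """Fit the housekeeping normal-range model.

    For each housekeeping gene the (``target_outside/2``, ``1 −
    target_outside/2``) quantiles of its non-missing values delimit its
    normal range (the outside mass is split symmetrically); the sample SD
    (n−1 denominator) of the values strictly inside those cutoffs is its
    normal-range SD, and ``sigma_bar`` is the mean of these SDs.  The
    genome-wide half-width multiplier is then calibrated by bisection so
    that re-categorizing the housekeeping genes under the fitted model
    reproduces the target outside fraction to within ``calibration_tol``.

    Raises
    ------
    IdentifierError
        If a housekeeping id is absent from ``expr``.
    DegenerateModelError
        If every housekeeping gene is constant (sigma_bar would be 0).
    """
    if not 0 < target_outside < 1:
        raise InputError("target_outside must lie in (0, 1)")
    hk_ids = list(hk_ids)
    if not hk_ids:
        raise InputError("at least one housekeeping gene is required")
    missing = [g for g in hk_ids if g not in expr.gene_ids]
    if missing:
        raise IdentifierError(f"housekeeping id(s) not in matrix: {missing}")

    q_lo, q_hi = target_outside / 2.0, 1.0 - target_outside / 2.0
    cutoffs: dict[str, tuple[float, float]] = {}
    sds = []
    for g in hk_ids:
        v = expr.gene_values(g)
        v = v[~np.isnan(v)]
        if v.size < 4:
            raise InputError(f"housekeeping gene {g!r} has fewer than 4 values")
        lo = float(np.quantile(v, q_lo, method=quantile_method))
        hi = float(np.quantile(v, q_hi, method=quantile_method))
        cutoffs[g] = (lo, hi)
        inside = v[(v > lo) & (v < hi)]
        if inside.size < 2 or np.ptp(inside) == 0.0:
            warnings.warn(
                f"housekeeping gene {g!r} has a zero-variance normal range; "
                "its SD of 0 still enters the sigma_bar average",
                stacklevel=2,
            )
            sds.append(0.0)
        else:
            sds.append(float(np.std(inside, ddof=1)))
    sigma_bar = float(np.mean(sds))
    if sigma_bar == 0.0:
        raise DegenerateModelError(
            "all housekeeping genes are constant inside their normal range"
        )

    width_multiplier = _calibrate_width(
        expr, hk_ids, sigma_bar, target_outside, center_statistic, calibration_tol
    )
    return NormalRangeModel(
        hk_gene_ids=hk_ids,
        target_outside_fraction=target_outside,
        per_hk_cutoffs=cutoffs,
        sigma_bar=sigma_bar,
        center_statistic=center_statistic,
        width_multiplier=width_multiplier,
        quantile_method=quantile_method,
    )


def _calibrate_width(
    expr: ExpressionMatrix,
    hk_ids: Sequence[str],
    sigma_bar: float,
    target: float,
    center_statistic: str,
    tol: float,
    max_iter: int = 100,
) -> float:
    """Bisect the width multiplier until the housekeeping outside fraction hits target.

    The outside fraction is a non-increasing step function of the multiplier,
    so bisection converges to the jump nearest the target; the best multiplier
    seen (smallest |fraction − target|) is returned.
    """

    def frac(m: float) -> float:
        return _outside_fraction(expr, hk_ids, m * sigma_bar, center_statistic)

    lo, hi = 0.0, 1.0
    while frac(hi) > target and hi < 2**20:
        hi *= 2.0
    best_m, best_err = hi, abs(frac(hi) - target)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        err = abs(f - target)
        # prefer the larger multiplier on ties: conservative (wider normal range)
        if err < best_err:
            best_m, best_err = mid, err
        if err <= tol:
            best_m, best_err = mid, err
            break
        if f > target:
            lo = mid
        else:
            hi = mid
    if best_err > tol:
        warnings.warn(
            f"width calibration reached outside-fraction error {best_err:.4f} "
            f"(> {tol}); data may be too discrete for an exact {target:.0%} split",
            stacklevel=3,
        )
    return best_m


def categorize_expression(
    expr: ExpressionMatrix, model: NormalRangeModel
) -> CategorizedMatrix:
    """Ternary-categorize an expression matrix under a fitted normal-range model.

    Per gene, the center is the gene's own ``center_statistic`` over its
    non-missing values and the half-width is the genome-wide
    ``width_multiplier × sigma_bar``.  Values strictly above center + w map
    to +1, strictly below center − w to −1, everything else (boundaries
    included) to 0.  Missing values stay missing.
    """
    if model.sigma_bar == 0.0:
        raise DegenerateModelError("model has sigma_bar = 0; cannot categorize")
    w = model.half_width
    values = expr.values
    if model.center_statistic == "median":
        centers = np.nanmedian(values, axis=1, keepdims=True)
    else:
        centers = np.nanmean(values, axis=1, keepdims=True)
    states = np.zeros_like(values)
    with np.errstate(invalid="ignore"):
        states[values > centers + w] = 1.0
        states[values < centers - w] = -1.0
    states[np.isnan(values)] = np.nan
    return CategorizedMatrix(
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        states=states,
        arity=3,
        provenance=(
            f"normal-range model: center={model.center_statistic}, "
            f"half_width={w:.6g} (multiplier {model.width_multiplier:.6g} x "
            f"sigma_bar {model.sigma_bar:.6g}), "
            f"target_outside={model.target_outside_fraction}"
        ),
    )


def categorize_cnv(
    cn: ExpressionMatrix, tolerance: float | None = None
) -> CategorizedMatrix:
    """Map copy numbers to ternary states: CN < 2 deletion, CN = 2 normal, CN > 2 duplication.

    The rule is stated for integer copy-number states.  Continuous (segment
    mean derived) copy numbers require an explicit ``tolerance`` τ: normal
    iff \\|CN − 2\\| ≤ τ, deletion below, duplication above.
    """
    values = cn.values
    obs = values[~np.isnan(values)]
    if obs.size and (obs < 0).any():
        raise InputError("copy numbers must be non-negative")
    if tolerance is None:
        if obs.size and not np.equal(np.mod(obs, 1), 0).all():
            raise InputError(
                "non-integer copy numbers found; pass an explicit tolerance "
                "(normal iff |CN - 2| <= tolerance) to categorize continuous CN"
            )
        tolerance = 0.0
    elif tolerance < 0:
        raise InputError("tolerance must be non-negative")
    states = np.zeros_like(values)
    with np.errstate(invalid="ignore"):
        states[values < 2.0 - tolerance] = -1.0
        states[values > 2.0 + tolerance] = 1.0
    states[np.isnan(values)] = np.nan
    return CategorizedMatrix(
        gene_ids=list(cn.gene_ids),
        sample_ids=list(cn.sample_ids),
        states=states,
        arity=3,
        provenance=f"cnv rule: deletion CN<2, normal CN=2, duplication CN>2 (tolerance {tolerance})",
    )


def binarize_single_cell(counts: ExpressionMatrix) -> CategorizedMatrix:
    """Binarize single-cell feature counts: 0 → not expressed, > 0 → expressed.

    Dropout makes graded categorization of single-cell expression
    unreliable, so the binary expressed / not-expressed convention is used.
    """
    values = counts.values
    obs = values[~np.isnan(values)]
    if obs.size and (obs < 0).any():
        raise InputError("feature counts must be non-negative")
    states = (values > 0).astype(float)
    states[np.isnan(values)] = np.nan
    return CategorizedMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        states=states,
        arity=2,
        provenance="single-cell binarization: expressed iff feature count > 0",
    )


def categorize_drug_response(
    values: Sequence[float],
    min_dose: float,
    max_dose: float,
    log10_scale: bool = False,
) -> list[str]:
    """Label IC50/EC50 measurements sensitive / partial / resistant.

    Values above the maximum tested dose are resistant, below the minimum
    dose sensitive.  The remaining in-range values are split by their mean
    ± 0.5 sample SD: below the band sensitive, above it resistant, inside
    (boundaries included) partial response.  Set ``log10_scale`` to compute
    the band on log10-transformed values.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise InputError("no drug-sensitivity values given")
    if not min_dose < max_dose:
        raise InputError("min_dose must be less than max_dose")
    labels = np.empty(vals.shape, dtype=object)
    resistant = vals > max_dose
    sensitive = vals < min_dose
    labels[resistant] = "resistant"
    labels[sensitive] = "sensitive"
    in_range = ~(resistant | sensitive)
    x = vals[in_range]
    if x.size >= 2:
        t = np.log10(x) if log10_scale else x
        m, s = float(np.mean(t)), float(np.std(t, ddof=1))
        lo, hi = m - 0.5 * s, m + 0.5 * s
        band = np.full(t.shape, "partial", dtype=object)
        band[t < lo] = "sensitive"
        band[t > hi] = "resistant"
        labels[in_range] = band
    else:
        labels[in_range] = "partial"
    return labels.tolist()


def flag_proliferation_effect(dependency_scores: Sequence[float]) -> list[str]:
    """Flag normalized dependency scores with a significant proliferation effect.

    Scores are normalized so non-essential genes have median 0 and essential
    genes median −1; a score strictly below −0.5 is a significant effect.
    """
    scores = np.asarray(list(dependency_scores), dtype=float)
    return ["significant" if s < -0.5 else "not_significant" for s in scores]
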