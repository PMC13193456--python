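"""Model evaluation: AUC, partial ROC, and expert-range comparison.

Presence-background AUC is the rank probability that a presence
outscores a background point.  Partial ROC is the presence-only
alternative: the curve of (fraction of landscape predicted suitable,
1 - omission of test points) over descending thresholds, compared as an
area ratio against the same curve built from random points; a ratio
above 1 means the model concentrates test points into less area than
chance.  Expert-derived ranges (EDRs) give the classical confusion
summary — omission (EDR cells predicted unsuitable), commission
(suitable cells outside the EDR) and congruence (suitable cells inside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .grid import Grid
from .io import OccurrenceSet


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC: P(presence score > background score), ties count 1/2."""
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one score in each group")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


@dataclass
class PartialRocResult:
    ratios: np.ndarray
    mean_ratio: float
    p_value: float  # fraction of iterations with ratio <= 1 (one-sided vs chance)


def _omission_area_auc(scores: np.ndarray, grid_vals: np.ndarray, thresholds: np.ndarray) -> float:
    """Area under the (fractional predicted area, 1 - omission) curve."""
    # descending thresholds -> increasing area
    area = np.array([(grid_vals >= t).mean() for t in thresholds])
    sens = np.array([(scores >= t).mean() for t in thresholds])
    order = np.argsort(area)
    return float(np.trapezoid(sens[order], area[order]))


def partial_roc(
    suit: Grid,
    occs: OccurrenceSet,
    n_iter: int = 39,
    subsample_frac: float = 0.5,
    seed: int = 0,
) -> PartialRocResult:
    """Partial-ROC AUC ratio of subsampled occurrences vs random points.

    Each iteration draws ``subsample_frac`` of the occurrences and the
    same number of random landscape cells, builds both omission/area
    curves over thresholds at every 1% of predicted area, and records
    the ratio of the two curve areas.  The p-value is the fraction of
    iterations in which the model does no better than chance.
    """
    if len(occs) < 4:
        raise ValueError("need at least 4 occurrences for partial ROC")
    spec = suit.spec
    vals = suit.values[~np.isnan(suit.values)]
    if vals.size == 0 or vals.max() == vals.min():
        raise ValueError("suitability grid is constant; partial ROC undefined")
    i, j = spec.cell_of(occs.lon, occs.lat)
    ok = (i >= 0) & (i < spec.n_rows) & (j >= 0) & (j < spec.n_cols)
    occ_scores = suit.values[i[ok], j[ok]]
    occ_scores = occ_scores[~np.isnan(occ_scores)]
    if occ_scores.size < 4:
        raise ValueError("fewer than 4 occurrences fall on data cells")
    # thresholds at every 1% of predicted area
    thresholds = np.quantile(vals, np.linspace(0.0, 0.99, 100))
    rng = np.random.default_rng(seed)
    n_sub = max(1, int(round(subsample_frac * occ_scores.size)))
    ratios = np.empty(n_iter)
    for it in range(n_iter):
        sub = rng.choice(occ_scores, size=n_sub, replace=False)
        rand = rng.choice(vals, size=n_sub, replace=False)
        a_occ = _omission_area_auc(sub, vals, thresholds)
        a_rand = _omission_area_auc(rand, vals, thresholds)
        ratios[it] = a_occ / a_rand
    return PartialRocResult(
        ratios=ratios,
        mean_ratio=float(ratios.mean()),
        p_value=float(np.mean(ratios <= 1.0)),
    )


@dataclass
class EdrComparison:
    omission_pct: float     # EDR cells predicted unsuitable, % of EDR cells
    commission_pct: float   # suitable cells outside the EDR, % of suitable cells
    congruence_pct: float   # suitable cells inside the EDR, % of suitable cells


def rasterize_polygons(polygons, spec) -> np.ndarray:
    """Boolean mask of cells whose centre falls inside any polygon."""
    import shapely

    lon, lat = spec.center_lonlats()
    mask = np.zeros(spec.shape, dtype=bool)
    for poly in polygons:
        mask |= shapely.contains_xy(poly, lon, lat)
    return mask


def edr_compare(suit: Grid, edr_polygons) -> EdrComparison:
    """Confusion summary of a thresholded model against an expert range."""
    edr = rasterize_polygons(edr_polygons, suit.spec)
    if not edr.any():
        raise ValueError("EDR rasterizes to zero cells; omission undefined")
    suitable = np.nan_to_num(suit.values, nan=0.0) > 0
    n_suit = suitable.sum()
    if n_suit == 0:
        commission = congruence = 0.0
    else:
        congruence = 100.0 * (suitable & edr).sum() / n_suit
        commission = 100.0 * (suitable & ~edr).sum() / n_suit
    omission = 100.0 * (edr & ~suitable).sum() / edr.sum()
    return EdrComparison(float(omission), float(commission), float(congruence))
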