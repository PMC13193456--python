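"""Candidate-variable screening.

Two passes mirror common niche-modelling practice: a collinearity filter
on background-sample values drops one of each pair with |Pearson r|
above 0.8 (named pairs can be exempted, e.g. variables known to be
complementary despite collinearity), and a permutation-importance
reduction keeps the top five variables plus any variable that clears
both a 1% importance floor and a rank cap of one variable per 20
occurrence records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class VariableReport:
    names: list[str]
    correlations: pd.DataFrame
    importances: dict[str, float]
    retained: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.names:
            partners = [
                u
                for u in self.names
                if u != v and abs(self.correlations.loc[v, u]) > 0.8
            ]
            rows.append(
                {
                    "variable": v,
                    "r_partner": ";".join(partners),
                    "importance": self.importances.get(v, np.nan),
                    "retained": v in self.retained,
                }
            )
        return pd.DataFrame(rows)


def _normalize_overrides(keep_overrides) -> set[frozenset]:
    return {frozenset(p) for p in (keep_overrides or [])}


def collinearity_filter(
    samples: pd.DataFrame,
    r_max: float = 0.8,
    keep_overrides=None,
    priority: list[str] | None = None,
) -> list[str]:
    """Retain variables so no kept pair has |r| > ``r_max``.

    ``priority`` orders the variables by how much we want to keep them
    (default: column order); when a pair is collinear the lower-priority
    member is dropped.  Pairs listed in ``keep_overrides`` are both kept
    regardless.  Zero-variance columns are excluded with a warning.
    """
    if samples.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if samples.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    overrides = _normalize_overrides(keep_overrides)
    order = priority if priority is not None else list(samples.columns)
    usable = []
    for v in order:
        if samples[v].std() == 0:
            warnings.warn(f"variable {v!r} has zero variance; excluded")
            continue
        usable.append(v)
    corr = samples[usable].corr()
    kept: list[str] = []
    for v in usable:
        clash = any(
            abs(corr.loc[v, u]) > r_max and frozenset((v, u)) not in overrides
            for u in kept
        )
        if not clash:
            kept.append(v)
    # report in original column order
    return [c for c in samples.columns if c in kept]


def rank_importances(importances: dict[str, float]) -> list[str]:
    """Variables sorted by descending importance; ties broken by name."""
    return sorted(importances, key=lambda v: (-importances[v], v))


def reduce_variables(
    importances: dict[str, float],
    n_records: int,
    top_k: int = 5,
    min_importance: float = 1.0,
    rank_divisor: int = 20,
) -> list[str]:
    """Reduced-model variable set from permutation importances.

    The ``top_k`` best variables are always kept (guarding against
    oversimplified niches); beyond that a variable survives only if its
    importance is at least ``min_importance`` percent AND its rank does
    not exceed ``floor(n_records / rank_divisor)``, balancing predictor
    count against data volume.
    """
    names = rank_importances(importances)
    if len(names) < top_k + 1:
        return names
    rank_cap = int(np.floor(n_records / rank_divisor))
    kept = []
    for rank, v in enumerate(names, start=1):
        if rank <= top_k:
            kept.append(v)
        elif importances[v] >= min_importance and rank <= rank_cap:
            kept.append(v)
    return kept
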