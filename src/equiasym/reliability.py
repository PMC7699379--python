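"""Inter-observer reliability of pain-scale items via Kendall's W.

For each scale item, the scores that m observers gave the same n
assessments (horse x occasion x phase) are treated as m rankings of the n
assessments and their agreement is summarized by Kendall's coefficient of
concordance with the tie correction:

    W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j)

where ``S`` is the sum of squared deviations of the assessment rank sums
from their mean, ranks are mid-ranks within each observer, and
``T_j = sum (t^3 - t)`` over tie groups of observer j.  Significance uses
``chi2 = m (n - 1) W`` with ``n - 1`` degrees of freedom.  Agreement is
banded as very strong (W > 0.9), strong (0.7-0.9), moderate (0.5-0.7) or
weak (< 0.5).

Objectively measured (physiological) CPS items are excluded from the
reliability report: they are instrument readings, not observer judgements.
Items where every observer gives a constant score have an undefined W and
are flagged degenerate rather than assigned an arbitrary value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scales import ScaleItem, scale_index

__all__ = [
    "ReliabilityResult",
    "kendalls_w",
    "band",
    "reliability_report",
    "reliability_table",
]

BANDS = ("very_strong", "strong", "moderate", "weak")


@dataclass
class ReliabilityResult:
    """Tie-corrected Kendall's W for one scale item."""

    scale: str
    item: str
    n_used: int
    m_observers: int
    w: float            # NaN when degenerate
    chi2: float
    df: int
    p_value: float
    band: str | None
    degenerate: bool = False


def band(w: float) -> str:
    """Agreement band for a concordance coefficient.

    Boundary convention: 0.7 and 0.9 fall in 'strong', 0.5 in 'moderate'.
    """
    if not np.isfinite(w) or w < -1e-12 or w > 1 + 1e-12:
        raise ValueError(f"W must lie in [0, 1], got {w}")
    if w > 0.9:
        return "very_strong"
    if w >= 0.7:
        return "strong"
    if w >= 0.5:
        return "moderate"
    return "weak"


def kendalls_w(
    scores: np.ndarray,
    scale: str = "",
    item: str = "",
) -> ReliabilityResult:
    """Tie-corrected Kendall's coefficient of concordance.

    Parameters
    ----------
    scores : (n_assessments, m_observers) array
        Ordinal scores; each column is one observer's scores over the same
        assessments.

    Notes
    -----
    When every observer's column is completely tied the denominator is
    zero and W is undefined; the result is flagged ``degenerate`` with
    ``w = NaN`` and no band.
    """
    X = np.asarray(scores, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("scores must be a 2-D array with at least 2 observers")
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 assessments")
    ranks = np.column_stack([stats.rankdata(X[:, j]) for j in range(m)])
    R = ranks.sum(axis=1)
    S = float(np.sum((R - R.mean()) ** 2))
    T = 0.0
    for j in range(m):
        _, counts = np.unique(X[:, j], return_counts=True)
        T += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * T
    df = n - 1
    if denom <= 0:
        return ReliabilityResult(
            scale=scale, item=item, n_used=n, m_observers=m,
            w=float("nan"), chi2=float("nan"), df=df, p_value=float("nan"),
            band=None, degenerate=True,
        )
    w = 12.0 * S / denom
    w = min(max(w, 0.0), 1.0)
    chi2 = m * (n - 1) * w
    p = float(stats.chi2.sf(chi2, df))
    return ReliabilityResult(
        scale=scale, item=item, n_used=n, m_observers=m,
        w=float(w), chi2=float(chi2), df=df, p_value=p, band=band(w),
    )


def _observer_slots(scores: pd.DataFrame) -> tuple[pd.DataFrame, int, int]:
    """Pivot observers into per-assessment slot columns.

    The third observer rotated between horses in the emulated study, so
    rating matrices are formed by observer *slot* (sorted observer ids
    within each assessment).  Assessments with fewer observers than the
    modal count are dropped and counted.
    """
    key_cols = ["horse", "occasion", "phase"]
    obs_per = scores.groupby(key_cols)["observer"].nunique()
    m = int(obs_per.mode().iloc[0])
    complete_keys = obs_per[obs_per == m].index
    n_dropped = int(len(obs_per) - len(complete_keys))
    kept = scores.set_index(key_cols).loc[complete_keys].reset_index()
    slot = (
        kept[key_cols + ["observer"]]
        .drop_duplicates()
        .sort_values(key_cols + ["observer"])
    )
    slot["slot"] = slot.groupby(key_cols).cumcount()
    kept = kept.merge(slot, on=key_cols + ["observer"])
    return kept, m, n_dropped


def reliability_report(
    scores: pd.DataFrame,
    scales: list[ScaleItem],
) -> list[ReliabilityResult]:
    """Per-item reliability over a long-format score table.

    Assessments (horse x occasion x phase) are pooled into a single n per
    item; physiological items are excluded; only assessments scored by the
    full observer panel are used.
    """
    index = scale_index(scales)
    behavioral = scores[
        [
            not index[(s, i)].is_physiological
            for s, i in zip(scores["scale"], scores["item"])
        ]
    ]
    kept, m, _ = _observer_slots(behavioral)
    results = []
    for it in scales:
        if it.is_physiological:
            continue
        sub = kept[(kept["scale"] == it.scale_id) & (kept["item"] == it.item_id)]
        if sub.empty:
            continue
        mat = sub.pivot_table(
            index=["horse", "occasion", "phase"], columns="slot", values="score"
        ).dropna()
        results.append(kendalls_w(mat.to_numpy(), scale=it.scale_id, item=it.item_id))
    return results


def reliability_table(results: list[ReliabilityResult]) -> pd.DataFrame:
    """Flatten reliability results into a tidy table (one row per item)."""
    return pd.DataFrame(
        {
            "scale": [r.scale for r in results],
            "item": [r.item for r in results],
            "n": [r.n_used for r in results],
            "W": [r.w for r in results],
            "chi2": [r.chi2 for r in results],
            "df": [r.df for r in results],
            "p": [r.p_value for r in results],
            "band": [r.band if r.band is not None else "" for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
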