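"""Descriptive outputs: outlier summaries, rankings, modal profiles, bias check.

Everything here is emitted as data (DataFrames / plain dicts); plotting is
left to the caller so the numbers remain testable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import FeatureScheme
from .unusualness import FloorRule, floor_one_over_n_plus_one, state_frequencies

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopPercentSummary:
    n_songs: int
    n_societies: int
    songs: pd.DataFrame  # the selected score rows, most unusual first


def top_percent_summary(
    scores: pd.DataFrame, p: float, mode: str = "ceil", threshold: float | None = None
) -> TopPercentSummary:
    """The most unusual ``p`` fraction of songs and how many societies they span.

    ``mode='ceil'`` selects the ceil(p*N) smallest scores; ties at the
    cutoff are broken by ``unit_id`` for determinism. ``mode='threshold'``
    instead selects all songs at or below an absolute score ``threshold``
    (the distribution-tail reading of a top-percent line on a histogram).
    """
    if not (0 < p < 1):
        raise ValueError("p must lie in (0, 1)")
    ordered = scores.sort_values(["unusualness", "unit_id"]).reset_index(drop=True)
    if mode == "ceil":
        m = math.ceil(p * len(ordered))
        sel = ordered.head(m)
    elif mode == "threshold":
        if threshold is None:
            threshold = float(ordered["unusualness"].quantile(p))
        sel = ordered[ordered["unusualness"] <= threshold]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return TopPercentSummary(
        n_songs=len(sel), n_societies=sel["society_id"].nunique(), songs=sel
    )


def society_rankings(scores: pd.DataFrame, min_songs: int = 5) -> pd.DataFrame:
    """Societies with >= ``min_songs`` scored songs, ranked most-unusual first.

    Emits per-society boxplot statistics (Tukey convention: quartiles,
    median, whiskers at the most extreme points within 1.5 IQR).
    """
    g = scores.groupby("society_id")
    rows = []
    for society_id, df in g:
        if len(df) < min_songs:
            continue
        u = np.sort(df["unusualness"].to_numpy())
        q1, med, q3 = np.percentile(u, [25, 50, 75])
        iqr = q3 - q1
        lo = u[u >= q1 - 1.5 * iqr].min()
        hi = u[u <= q3 + 1.5 * iqr].max()
        rows.append(
            {
                "society_id": society_id,
                "region_id": df["region_id"].iloc[0],
                "n_songs": len(df),
                "mean_unusualness": float(df["unusualness"].mean()),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_low": float(lo),
                "whisker_high": float(hi),
            }
        )
    if not rows:
        logger.warning("society_rankings: no society reaches min_songs=%d", min_songs)
        return pd.DataFrame(
            columns=[
                "society_id", "region_id", "n_songs", "mean_unusualness",
                "median", "q1", "q3", "whisker_low", "whisker_high", "rank",
            ]
        )
    out = pd.DataFrame(rows).sort_values(
        ["mean_unusualness", "society_id"]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def modal_profile(
    codings: pd.DataFrame,
    scheme: FeatureScheme,
    society_id: str,
    floor_rule: FloorRule = floor_one_over_n_plus_one,
) -> pd.DataFrame:
    """Per-feature modal state of a society's songs, against regional frequencies.

    One row per (feature, permitted state) with the leave-that-society-out
    regional frequency (for symbol sizing), an ``is_modal`` flag (ties go to
    the lower state code), and the 13-point display position when the scheme
    defines one.
    """
    soc = codings[codings["society_id"] == society_id]
    if soc.empty:
        raise ValueError(f"unknown society {society_id!r}")
    region_id = soc["region_id"].iloc[0]
    freqs = state_frequencies(codings, scheme, str(region_id), str(society_id), floor_rule)
    rows = []
    for feat in scheme:
        col = soc[feat.feature_id].dropna()
        counts = col.value_counts()
        top = counts.max() if len(counts) else None
        modal = min(int(s) for s, c in counts.items() if c == top) if top else None
        for state in feat.states:
            rows.append(
                {
                    "feature_id": feat.feature_id,
                    "feature_name": feat.name,
                    "state": state,
                    "is_modal": state == modal,
                    "regional_freq": freqs.probs[feat.feature_id].get(state, 0.0),
                    "display_position": (
                        feat.display_scale[state] if feat.display_scale else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def sampling_bias_check(scores: pd.DataFrame) -> dict:
    """Pearson correlation of society mean unusualness with society song count.

    A near-zero correlation indicates unevenly sampled societies are not
    systematically scored as more (or less) unusual. Undefined (NaN, with
    ``defined=False``) when either variable has zero variance.
    """
    per_soc = scores.groupby("society_id")["unusualness"].agg(["mean", "count"])
    n = len(per_soc)
    if n < 3:
        raise ValueError("need at least 3 societies for the bias check")
    if per_soc["mean"].nunique() == 1 or per_soc["count"].nunique() == 1:
        logger.warning("sampling_bias_check: zero variance; correlation undefined")
        return {"pearson_r": float("nan"), "p_value": float("nan"), "n_societies": n, "defined": False}
    r, pval = stats.pearsonr(per_soc["mean"], per_soc["count"])
    return {"pearson_r": float(r), "p_value": float(pval), "n_societies": n, "defined": True}
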