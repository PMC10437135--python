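"""Leave-one-society-out (LOSO) unusualness scores.

The unusualness of a song is its log-likelihood under the categorical
state frequencies of its geographic region, estimated with every song of
the focal society held out. For a complete song with features
:math:`f = 1..F` coded in states :math:`s_f`,

.. math:: U = \\sum_f \\ln p_{r,-s}(f, s_f)

where :math:`p_{r,-s}` are the per-feature state proportions among the
region's songs excluding society :math:`s`. Smaller (more negative)
values are more unusual; :math:`U \\le 0` always, with equality exactly
when every state the song uses is universal among out-of-society songs.

Holding the focal society out removes self-similarity: a society cannot
look typical merely because its own songs dominate the regional sample.

Zero-count states are given a probability floor (default
``1/(support_n + 1)``, where ``support_n`` is the number of out-of-society
songs) so scores stay finite; the floor shrinks as regional support grows.

The same construction applies to categorical societal traits, where each
society contributes at most one state per trait; there the per-society
score averages (rather than sums) the log-probabilities over its
non-missing traits, so trait coverage does not masquerade as unusualness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .data_io import FeatureScheme

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["unit_id", "society_id", "region_id", "unusualness", "n_items_scored"]


def floor_one_over_n_plus_one(support_n: int) -> float:
    """Default probability floor for zero-count states: 1/(support_n + 1)."""
    return 1.0 / (support_n + 1)


FloorRule = Callable[[int], float]


class SupportError(ValueError):
    """A region has no out-of-society songs to estimate frequencies from."""


class ContaminationError(ValueError):
    """A song was scored against frequencies that did not exclude its society."""


@dataclass(frozen=True)
class StateFrequencyTable:
    """Per-feature state probabilities for one (region, excluded-society) context.

    ``probs[feature_id][state]`` holds the observed proportion for states seen
    among the out-of-society songs. States permitted by the scheme but unseen
    get the floor probability via :meth:`prob`.
    """

    region_id: str
    excluded_society_id: str
    probs: Mapping[str, Mapping[int, float]]
    support_n: int
    floor: float

    def prob(self, feature_id: str, state: int) -> float:
        p = self.probs[feature_id].get(state, 0.0)
        return p if p > 0.0 else self.floor


def state_frequencies(
    codings: pd.DataFrame,
    scheme: FeatureScheme,
    region_id: str,
    excluded_society_id: str,
    floor_rule: FloorRule = floor_one_over_n_plus_one,
) -> StateFrequencyTable:
    """Estimate per-feature state proportions in a region, holding one society out.

    For each feature, probability of a state = (count among the region's songs
    not from the excluded society) / (number of such songs with a non-missing
    state for the feature). Zero-count states receive ``floor_rule(support_n)``.

    Raises :class:`SupportError` when the region has no out-of-society songs.
    """
    mask = (codings["region_id"] == region_id) & (
        codings["society_id"] != excluded_society_id
    )
    pool = codings.loc[mask]
    support_n = len(pool)
    if support_n == 0:
        raise SupportError(
            f"insufficient regional support: region {region_id!r} has no songs "
            f"outside society {excluded_society_id!r}"
        )
    probs: dict[str, dict[int, float]] = {}
    for fid in scheme.feature_ids:
        col = pool[fid].dropna()
        counts = col.value_counts()
        total = int(counts.sum())
        probs[fid] = (
            {int(s): c / total for s, c in counts.items()} if total else {}
        )
    return StateFrequencyTable(
        region_id=region_id,
        excluded_society_id=excluded_society_id,
        probs=probs,
        support_n=support_n,
        floor=floor_rule(support_n),
    )


def song_unusualness(
    song: pd.Series,
    freqs: StateFrequencyTable,
    scheme: FeatureScheme,
    convention: str = "loglik",
) -> float:
    """Score one complete song against a LOSO frequency table.

    ``convention='loglik'`` (default) returns the sum of log state
    probabilities — the song's log-likelihood. ``'log_of_sum'`` returns the
    log of the summed probabilities, kept for sensitivity analysis.

    Raises :class:`ContaminationError` if the frequency table was not built
    with the song's society excluded.
    """
    if song["society_id"] != freqs.excluded_society_id:
        raise ContaminationError(
            f"song from society {song['society_id']!r} scored against "
            f"frequencies excluding {freqs.excluded_society_id!r}"
        )
    ps = [freqs.prob(fid, int(song[fid])) for fid in scheme.feature_ids]
    if convention == "loglik":
        return float(sum(math.log(p) for p in ps))
    if convention == "log_of_sum":
        return float(math.log(sum(ps)))
    raise ValueError(f"unknown score convention {convention!r}")


def all_song_unusualness(
    codings: pd.DataFrame,
    scheme: FeatureScheme,
    floor_rule: FloorRule = floor_one_over_n_plus_one,
    convention: str = "loglik",
) -> pd.DataFrame:
    """Score every song against its region's LOSO state frequencies.

    Iterates regions, then societies within each region; each society's songs
    are scored against frequencies excluding that society. Societies whose
    region offers no out-of-society songs are skipped with a log entry.

    Returns a score table (columns ``unit_id, society_id, region_id,
    unusualness, n_items_scored``) sorted by (region, society, unit) for
    reproducible output.
    """
    rows: list[tuple] = []
    for region_id, region_df in codings.groupby("region_id", sort=True):
        for society_id, soc_df in region_df.groupby("society_id", sort=True):
            try:
                freqs = state_frequencies(
                    codings, scheme, str(region_id), str(society_id), floor_rule
                )
            except SupportError:
                logger.info(
                    "skipping society %r: no out-of-society songs in region %r",
                    society_id,
                    region_id,
                )
                continue
            for _, song in soc_df.iterrows():
                u = song_unusualness(song, freqs, scheme, convention)
                rows.append(
                    (str(song["song_id"]), str(society_id), str(region_id), u, len(scheme))
                )
    out = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    return out.sort_values(["region_id", "society_id", "unit_id"]).reset_index(drop=True)


def society_trait_unusualness(
    traits: pd.DataFrame,
    societies: pd.DataFrame,
    theme: str = "general",
    floor_rule: FloorRule = floor_one_over_n_plus_one,
) -> pd.DataFrame:
    """LOSO unusualness of a society's categorical traits within its region.

    Each society contributes at most one state per trait, so the LOSO pool
    for a (region, society, trait) is the other societies in the region with
    a non-missing state for the trait. The score is the *mean* of
    ``ln p(trait, state)`` over the society's non-missing traits in the theme
    (``kinship``, ``economic``, or ``general`` = both), with zero-count
    states floored at ``floor_rule(pool size)``.

    Societies with no scorable trait, and regions with a single society,
    yield NaN scores (rows kept so downstream deletion is explicit).
    """
    if theme not in ("kinship", "economic", "general"):
        raise ValueError(f"theme must be kinship|economic|general, got {theme!r}")
    use = traits if theme == "general" else traits[traits["theme"] == theme]
    merged = use.merge(
        societies[["society_id", "region_id"]], on="society_id", how="inner"
    )
    rows: list[tuple] = []
    region_of = societies.set_index("society_id")["region_id"]
    for society_id in societies["society_id"]:
        region_id = region_of[society_id]
        own = merged[(merged["society_id"] == society_id) & merged["state"].notna()]
        logs: list[float] = []
        for _, row in own.iterrows():
            pool = merged[
                (merged["region_id"] == region_id)
                & (merged["society_id"] != society_id)
                & (merged["trait_id"] == row["trait_id"])
                & merged["state"].notna()
            ]
            n = len(pool)
            if n == 0:
                continue  # no regional support for this trait
            count = int((pool["state"] == row["state"]).sum())
            p = count / n if count else floor_rule(n)
            logs.append(math.log(p))
        score = float(np.mean(logs)) if logs else float("nan")
        rows.append((str(society_id), str(society_id), str(region_id), score, len(logs)))
    out = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    return out.sort_values(["region_id", "society_id", "unit_id"]).reset_index(drop=True)
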