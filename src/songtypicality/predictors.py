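"""Regression covariates: contact, isolation, trait unusualness, society style.

Builds the per-song predictor table for the multilevel models:

* ``neighbours`` — number of *other* sampled societies within a
  great-circle radius (default 500 km) of the society, a proxy for the
  frequency of inter-group contact;
* ``phylo_nn`` — patristic distance from the society's language to the
  nearest other sampled society's language on the phylogeny, a proxy for
  cultural isolation;
* ``kinship_u`` / ``economic_u`` — LOSO societal trait unusualness;
* ``society_mean_loo`` — the mean unusualness of the society's *other*
  songs, the operational measure of musical style;
* ``response`` — the song's own unusualness.

All covariates can be standardized to mean 0, sample sd 1. Missing
covariates are handled by listwise deletion with a logged report.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Haversine distance in km between points in decimal degrees (WGS84).

    Accepts scalars or broadcastable arrays. Raises for out-of-range
    coordinates.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180):
            raise ValueError("longitude outside [-180, 180]")
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def neighbour_counts(
    societies: pd.DataFrame,
    radius_km: float = 500.0,
    same_region_only: bool = False,
) -> pd.Series:
    """Count, per society, the other societies within ``radius_km`` (inclusive).

    Counting is global across the sample by default; ``same_region_only``
    restricts the count to societies sharing a region. Societies without
    coordinates get a missing count.
    """
    lat = societies["latitude"].to_numpy(dtype=float)
    lon = societies["longitude"].to_numpy(dtype=float)
    has = ~(np.isnan(lat) | np.isnan(lon))
    n = len(societies)
    counts = np.full(n, np.nan)
    idx = np.flatnonzero(has)
    if idx.size:
        d = great_circle_km(
            lat[idx][:, None], lon[idx][:, None], lat[idx][None, :], lon[idx][None, :]
        )
        within = (d <= radius_km)
        np.fill_diagonal(within, False)
        if same_region_only:
            regions = societies["region_id"].to_numpy()[idx]
            within &= regions[:, None] == regions[None, :]
        counts[idx] = within.sum(axis=1)
    return pd.Series(counts, index=societies["society_id"].to_numpy(), name="neighbours")


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """All-pairs patristic (branch-length) distances between tips."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    labels = [t.label for t in taxa]
    mat = np.zeros((len(taxa), len(taxa)))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if j > i:
                mat[i, j] = mat[j, i] = pdm.patristic_distance(ti, tj)
    return pd.DataFrame(mat, index=labels, columns=labels)


def phylo_nn_distance(tree: dendropy.Tree, societies: pd.DataFrame) -> pd.Series:
    """Patristic distance to the nearest *other sampled society's* language tip.

    Societies mapped (via ``language_id``) to the same tip are distance 0 to
    each other. Societies with no tip mapping get a missing distance (logged).
    """
    labels = {t.label for t in tree.taxon_namespace}
    lang = societies.set_index("society_id")["language_id"]
    mapped = lang.dropna()[lambda s: s.isin(labels)]
    unmapped = sorted(set(societies["society_id"]) - set(mapped.index))
    if unmapped:
        logger.info("%d societies lack a tree tip mapping: %s", len(unmapped), unmapped[:5])
    out = pd.Series(np.nan, index=societies["society_id"].to_numpy(), name="phylo_nn")
    if len(mapped) < 2:
        return out
    dist = patristic_matrix(tree)
    tip_counts = mapped.value_counts()
    used_tips = list(tip_counts.index)
    sub = dist.loc[used_tips, used_tips].to_numpy()
    for society_id, tip in mapped.items():
        i = used_tips.index(tip)
        if tip_counts[tip] > 1:  # another society shares this tip
            out[society_id] = 0.0
            continue
        others = np.delete(sub[i], i)
        out[society_id] = float(others.min()) if others.size else np.nan
    return out


def society_mean_loo(scores: pd.DataFrame) -> pd.Series:
    """Per song, the mean unusualness of the society's *other* songs.

    Missing for songs whose society has no other scored song. Indexed by
    ``unit_id`` (song id).
    """
    g = scores.groupby("society_id")["unusualness"]
    total = g.transform("sum")
    n = g.transform("count")
    loo = (total - scores["unusualness"]) / (n - 1)
    loo[n == 1] = np.nan
    return pd.Series(loo.to_numpy(), index=scores["unit_id"].to_numpy(), name="society_mean_loo")


def standardize(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """z-score columns using the sample sd (n-1) over non-missing rows.

    Missing entries are preserved. Raises on a constant column.
    """
    out = table.copy()
    for col in columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1, skipna=True)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero variance in column {col!r}; cannot standardize")
        out[col] = (x - x.mean(skipna=True)) / sd
    return out


PREDICTOR_COLUMNS = [
    "neighbours",
    "phylo_nn",
    "kinship_u",
    "economic_u",
    "society_mean_loo",
]


def assemble_predictors(
    scores: pd.DataFrame,
    kinship_scores: pd.DataFrame,
    economic_scores: pd.DataFrame,
    societies: pd.DataFrame,
    tree: dendropy.Tree | None,
    radius_km: float = 500.0,
    do_standardize: bool = True,
    same_region_only: bool = False,
    general_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join all covariates into one per-song predictor table.

    ``response`` is the song's unusualness. Rows with any missing required
    covariate are flagged ``complete=False`` and the listwise-deletion count
    is logged; standardization (optional) uses only non-missing rows.
    Passing ``general_scores`` adds the optional aggregate-trait covariate
    ``general_u`` (not part of the default models).
    """
    unknown = sorted(set(scores["society_id"]) - set(societies["society_id"]))
    if unknown:
        raise ValueError(f"scored societies absent from society table, e.g. {unknown[:5]}")

    df = scores.rename(columns={"unusualness": "response"})[
        ["unit_id", "society_id", "region_id", "response"]
    ].copy()

    nbrs = neighbour_counts(societies, radius_km, same_region_only)
    df["neighbours"] = df["society_id"].map(nbrs)
    if tree is not None:
        nn = phylo_nn_distance(tree, societies)
        df["phylo_nn"] = df["society_id"].map(nn)
    else:
        df["phylo_nn"] = np.nan
    df["kinship_u"] = df["society_id"].map(
        kinship_scores.set_index("society_id")["unusualness"]
    )
    df["economic_u"] = df["society_id"].map(
        economic_scores.set_index("society_id")["unusualness"]
    )
    if general_scores is not None:
        df["general_u"] = df["society_id"].map(
            general_scores.set_index("society_id")["unusualness"]
        )
    loo = society_mean_loo(scores)
    df["society_mean_loo"] = df["unit_id"].map(loo)

    required = ["response"] + PREDICTOR_COLUMNS
    df["complete"] = df[required].notna().all(axis=1)
    n_dropped = int((~df["complete"]).sum())
    if n_dropped:
        logger.info(
            "assemble_predictors: %d of %d songs flagged incomplete (listwise deletion)",
            n_dropped,
            len(df),
        )
    df.attrs["n_listwise_dropped"] = n_dropped
    if do_standardize:
        cols = [c for c in required + (["general_u"] if general_scores is not None else [])]
        ok = df["complete"]
        std = standardize(df.loc[ok, cols], cols)
        df.loc[ok, cols] = std
        df.loc[~ok, cols] = np.nan
    return df.reset_index(drop=True)
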