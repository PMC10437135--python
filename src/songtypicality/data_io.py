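"""Readers, writers and validation for the four pipeline inputs.

The pipeline works on four tabular/structured inputs:

* a **coding table** — one row per song, with identifier columns
  (``song_id``, ``society_id``, ``region_id``) and one column per
  categorical feature of the coding scheme;
* a **society table** — one row per society with its region, WGS84
  decimal-degree coordinates and an optional ``language_id`` matching a
  tip of the language phylogeny;
* a **trait table** — long-format categorical societal traits
  (``society_id``, ``trait_id``, ``state``) with each trait assigned to a
  theme (``kinship`` or ``economic``);
* a **language phylogeny** — a rooted Newick tree with non-negative
  branch lengths.

All tables are plain :class:`pandas.DataFrame` objects; the feature
scheme is the one structured object (:class:`FeatureScheme`), shipped as
data rather than code so alternative coding schemes can be dropped in.

Missing codings may appear in source CSVs as empty cells, ``NA``, or any
user-supplied sentinel; they are normalised to :data:`pandas.NA`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ID_COLUMNS = ("song_id", "society_id", "region_id")

DEFAULT_MISSING = ("", "NA")


class SchemeError(ValueError):
    """A feature scheme violates its structural invariants."""


class DataError(ValueError):
    """An input table violates a fatal validation rule."""


@dataclass(frozen=True)
class Feature:
    """One categorical feature (a 'line' of the coding scheme).

    ``states`` is the ordered tuple of permitted integer codes.
    ``display_scale`` optionally maps each code to a position on the
    13-point display line used for profile plots.
    """

    feature_id: str
    name: str
    states: tuple[int, ...]
    display_scale: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise SchemeError(f"feature {self.feature_id!r} has fewer than 2 states")
        if len(set(self.states)) != len(self.states):
            raise SchemeError(f"feature {self.feature_id!r} has duplicate state codes")
        if self.display_scale is not None:
            missing = set(self.states) - set(self.display_scale)
            if missing:
                raise SchemeError(
                    f"feature {self.feature_id!r}: display_scale lacks states {sorted(missing)}"
                )
            bad = [v for v in self.display_scale.values() if not (1 <= v <= 13)]
            if bad:
                raise SchemeError(
                    f"feature {self.feature_id!r}: display positions outside [1, 13]: {bad}"
                )


@dataclass(frozen=True)
class FeatureScheme:
    """An ordered collection of categorical features.

    The default scheme mirrors the 37 Cantometric coding lines; see
    :func:`default_scheme`.
    """

    features: tuple[Feature, ...]
    _by_id: Mapping[str, Feature] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_id = {f.feature_id: f for f in self.features}
        if len(by_id) != len(self.features):
            raise SchemeError("duplicate feature ids in scheme")
        object.__setattr__(self, "_by_id", by_id)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def permitted(self, feature_id: str, state: int) -> bool:
        return state in self._by_id[feature_id].states

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FeatureScheme":
        feats = []
        for entry in payload["features"]:
            scale = entry.get("display_scale")
            if scale is not None:
                scale = {int(k): float(v) for k, v in scale.items()}
            feats.append(
                Feature(
                    feature_id=str(entry["feature_id"]),
                    name=str(entry["name"]),
                    states=tuple(int(s) for s in entry["states"]),
                    display_scale=scale,
                )
            )
        return cls(features=tuple(feats))

    @classmethod
    def from_json(cls, path) -> "FeatureScheme":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        out = []
        for f in self.features:
            entry: dict = {
                "feature_id": f.feature_id,
                "name": f.name,
                "states": list(f.states),
            }
            if f.display_scale is not None:
                entry["display_scale"] = {str(k): v for k, v in f.display_scale.items()}
            out.append(entry)
        return {"features": out}


def default_scheme() -> FeatureScheme:
    """Load the packaged 37-feature default scheme.

    The shipped file is a synthetic stand-in: feature names follow the
    37 Cantometric coding lines, but per-line state inventories are
    schematic defaults. Analyses of a real release should load that
    release's own scheme definition with :meth:`FeatureScheme.from_json`.
    """
    ref = resources.files("songtypicality.data") / "cantometrics_scheme_synthetic.json"
    with ref.open(encoding="utf-8") as fh:
        return FeatureScheme.from_dict(json.load(fh))


def default_theme_map() -> dict[str, str]:
    """Load the packaged trait-id → theme map (approximate default)."""
    ref = resources.files("songtypicality.data") / "trait_theme_map_default.yaml"
    with ref.open(encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return {str(k): str(v) for k, v in payload["themes"].items()}


# ---------------------------------------------------------------------------
# coding table


def read_codings(
    path,
    scheme: FeatureScheme,
    missing_values: Sequence[str] = DEFAULT_MISSING,
) -> pd.DataFrame:
    """Read and validate a song-coding CSV.

    Expects the identifier columns plus one column per scheme feature.
    Cells that fail to parse as integers, or whose state is not permitted
    for the feature, are recorded as missing; a count is logged.

    Raises :class:`DataError` for missing identifier columns or
    duplicated ``song_id``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    return validate_codings(raw, scheme, missing_values=missing_values)


def validate_codings(
    raw: pd.DataFrame,
    scheme: FeatureScheme,
    missing_values: Sequence[str] = DEFAULT_MISSING,
) -> pd.DataFrame:
    missing_ids = [c for c in ID_COLUMNS if c not in raw.columns]
    if missing_ids:
        raise DataError(f"coding table lacks identifier columns: {missing_ids}")
    absent = [f for f in scheme.feature_ids if f not in raw.columns]
    if absent:
        raise DataError(f"coding table lacks feature columns: {absent}")
    if raw["song_id"].duplicated().any():
        dupes = raw.loc[raw["song_id"].duplicated(), "song_id"].head().tolist()
        raise DataError(f"duplicate song_id values, e.g. {dupes}")

    out = raw.loc[:, list(ID_COLUMNS)].astype(str).copy()
    sentinel = set(missing_values)
    n_invalid = 0
    for fid in scheme.feature_ids:
        col = raw[fid].astype(str).str.strip()
        parsed = pd.to_numeric(col.where(~col.isin(sentinel)), errors="coerce")
        permitted = parsed.isin(list(scheme[fid].states))
        bad = parsed.notna() & ~permitted
        n_invalid += int(bad.sum())
        out[fid] = parsed.where(permitted).astype("Int64")
    if n_invalid:
        logger.warning("codings: %d cells outside the scheme marked missing", n_invalid)

    # a society must live in exactly one region
    n_regions = out.groupby("society_id")["region_id"].nunique()
    multi = n_regions[n_regions > 1]
    if not multi.empty:
        raise DataError(f"societies mapped to multiple regions: {multi.index.tolist()}")
    return out.reset_index(drop=True)


def filter_complete(codings: pd.DataFrame, scheme: FeatureScheme) -> pd.DataFrame:
    """Keep only songs with a non-missing state for every scheme feature.

    Whole-song deletion: a single missing feature drops the song. Counts
    of dropped songs and societies are logged and recorded in
    ``.attrs['n_songs_dropped']`` / ``.attrs['n_societies_dropped']``.

    Raises :class:`DataError` if nothing survives.
    """
    feats = scheme.feature_ids
    keep = codings[feats].notna().all(axis=1)
    out = codings.loc[keep].reset_index(drop=True)
    if out.empty:
        raise DataError(
            "no complete songs remain after filtering; check the missing-value "
            "sentinels and that the scheme matches the data"
        )
    n_songs_dropped = int((~keep).sum())
    soc_before = codings["society_id"].nunique()
    soc_after = out["society_id"].nunique()
    out.attrs["n_songs_dropped"] = n_songs_dropped
    out.attrs["n_societies_dropped"] = soc_before - soc_after
    if n_songs_dropped:
        logger.info(
            "filter_complete: dropped %d songs (%d societies left with none)",
            n_songs_dropped,
            soc_before - soc_after,
        )
    return out


# ---------------------------------------------------------------------------
# society / trait tables and the tree


def read_societies(path) -> pd.DataFrame:
    """Read a society table CSV: society_id, region_id, latitude, longitude,
    optional language_id."""
    df = pd.read_csv(path, dtype={"society_id": str, "region_id": str, "language_id": str})
    return validate_societies(df)


def validate_societies(df: pd.DataFrame) -> pd.DataFrame:
    required = ["society_id", "region_id", "latitude", "longitude"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"society table lacks columns: {missing}")
    if df["society_id"].duplicated().any():
        raise DataError("duplicate society_id in society table")
    lat = pd.to_numeric(df["latitude"], errors="raise")
    lon = pd.to_numeric(df["longitude"], errors="raise")
    ok_lat = lat.isna() | ((lat >= -90) & (lat <= 90))
    ok_lon = lon.isna() | ((lon >= -180) & (lon <= 180))
    if not bool(ok_lat.all()) or not bool(ok_lon.all()):
        raise DataError("coordinates outside [-90, 90] x [-180, 180]")
    out = df.copy()
    out["latitude"] = lat
    out["longitude"] = lon
    if "language_id" not in out.columns:
        out["language_id"] = pd.NA
    out["society_id"] = out["society_id"].astype(str)
    out["region_id"] = out["region_id"].astype(str)
    return out.reset_index(drop=True)


def read_traits(path, theme_map: Mapping[str, str]) -> pd.DataFrame:
    """Read a long-format trait CSV (society_id, trait_id, state) and assign
    each trait a theme from ``theme_map``.

    Raises :class:`DataError` for a trait_id absent from the map or a theme
    outside {kinship, economic}, and for duplicate (society, trait) pairs.
    Missing states (blank/NA cells) are kept as explicit missing rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["society_id", "trait_id", "state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"trait table lacks columns: {missing}")
    unmapped = sorted(set(df["trait_id"]) - set(theme_map))
    if unmapped:
        raise DataError(f"unmapped trait theme for trait ids: {unmapped}")
    bad_theme = {t: theme_map[t] for t in set(df["trait_id"]) if theme_map[t] not in ("kinship", "economic")}
    if bad_theme:
        raise DataError(f"themes must be 'kinship' or 'economic', got: {bad_theme}")
    if df.duplicated(["society_id", "trait_id"]).any():
        raise DataError("duplicate (society_id, trait_id) rows in trait table")
    out = df.copy()
    out["state"] = pd.to_numeric(out["state"].replace({"": None, "NA": None}), errors="coerce").astype("Int64")
    out["theme"] = out["trait_id"].map(theme_map)
    return out.reset_index(drop=True)


def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick phylogeny; validates unique tip labels and
    non-negative branch lengths. Unspecified branch lengths become 0."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise DataError(f"malformed Newick file {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]
    if len(labels) != len(set(labels)):
        raise DataError("duplicate tip labels in phylogeny")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
        elif edge.length < 0:
            raise DataError(f"negative branch length {edge.length} in phylogeny")
    return tree


# ---------------------------------------------------------------------------
# writers (round-trip support) and config


def write_codings(codings: pd.DataFrame, path) -> None:
    codings.to_csv(path, index=False)


def write_societies(societies: pd.DataFrame, path) -> None:
    societies.to_csv(path, index=False)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.drop(columns=["theme"], errors="ignore").to_csv(path, index=False)


def load_config(path) -> dict:
    """Load the single YAML config file naming input paths and options."""
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def check_society_coverage(codings: pd.DataFrame, societies: pd.DataFrame) -> list[str]:
    """Societies present in the codings but absent from the society table.

    These are excluded from geography-dependent stages; a warning is logged.
    """
    missing = sorted(set(codings["society_id"]) - set(societies["society_id"]))
    if missing:
        logger.warning(
            "%d societies in codings lack a society-table row (excluded from "
            "geographic predictors): %s", len(missing), missing[:5],
        )
    return missing
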