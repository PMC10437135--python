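"""Synthetic worlds with the statistical structure the pipeline assumes.

The generator produces all four pipeline inputs — song codings, a society
table with clustered coordinates, categorical societal traits, and a
language phylogeny — from one seed, together with a ground-truth record
of every generating distribution. It emulates structure, not substance:
regions contain societies, societies sing songs, and each society's
feature distribution is a mixture

.. math:: \\pi_{s,f} = (1-\\lambda)\\,\\pi_{r,f} + \\lambda\\,\\delta_{s,f}

of a regional Dirichlet baseline :math:`\\pi_{r,f}` and a society-specific
Dirichlet draw :math:`\\delta_{s,f}`. The style-strength :math:`\\lambda`
is the single dial for within-society consistency: at 0 every society in a
region shares the baseline; at 1 each society has an idiosyncratic style
whose songs are mutually similar but regionally atypical. Traits mirror
the same mixture with a single draw per society; geography places
societies in per-region Gaussian clusters; the tree is a pure-birth
(Yule) tree over one language tip per society, scaled to unit depth.

All randomness flows from ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` spawns, so each component is independently
reproducible.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .data_io import Feature, FeatureScheme


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic world.

    Defaults give a mid-sized world: 4 regions x 10 societies x ~8 songs,
    10 features of 5 states, moderate style strength.
    """

    n_regions: int = 4
    societies_per_region: int = 10
    songs_per_society: tuple[int, int] = (4, 12)  # inclusive range; (k, k) fixes k
    n_features: int = 10
    states_per_feature: int = 5
    style_strength: float = 0.5  # lambda in [0, 1]
    regional_concentration: float = 1.0  # alpha_r > 0
    society_concentration: float = 0.3  # alpha_s > 0, small = spiky styles
    cluster_spread_km: float = 300.0
    tree_birth_rate: float = 1.0
    n_kinship: int = 5
    n_economic: int = 5
    trait_states: int = 4
    trait_missing_rate: float = 0.0
    true_beta: tuple[float, ...] = (0.5, 0.0, -0.3)
    group_sd: float = 1.0  # tau
    residual_sd: float = 1.0  # sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.style_strength <= 1):
            raise ValueError("style_strength must lie in [0, 1]")
        if self.regional_concentration <= 0 or self.society_concentration <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        for name in ("n_regions", "societies_per_region", "n_features",
                     "states_per_feature", "trait_states"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.songs_per_society
        if lo < 1 or hi < lo:
            raise ValueError("songs_per_society must be a valid positive range")


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *key]))


def scheme_for(config: SimConfig) -> FeatureScheme:
    """The synthetic feature scheme: f_01..f_K, states 1..S each."""
    feats = tuple(
        Feature(
            feature_id=f"f_{i + 1:02d}",
            name=f"synthetic feature {i + 1}",
            states=tuple(range(1, config.states_per_feature + 1)),
        )
        for i in range(config.n_features)
    )
    return FeatureScheme(features=feats)


def _society_ids(config: SimConfig):
    for r in range(config.n_regions):
        region = f"R{r + 1}"
        for s in range(config.societies_per_region):
            yield region, f"{region}_S{s + 1:02d}"


def simulate_repertoires(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw the coding table (and society skeleton) from the mixture model.

    Returns ``(codings, societies, truth)``; ``societies`` has coordinates
    and language ids filled by :func:`simulate_geography` /
    :func:`simulate_tree`. ``truth`` records every regional baseline and
    society mixture distribution, keyed by region/society and feature.
    """
    scheme = scheme_for(config)
    lam = config.style_strength
    n_states = config.states_per_feature

    truth: dict = {"regional": {}, "society": {}, "config_seed": config.seed}
    soc_rows, song_rows = [], []
    song_counter = 0
    for region, society in _society_ids(config):
        if region not in truth["regional"]:
            rng_r = _rng(config, 1, hash_region(region))
            truth["regional"][region] = {
                f.feature_id: rng_r.dirichlet([config.regional_concentration] * n_states)
                for f in scheme
            }
        rng_s = _rng(config, 2, hash_region(society))
        baseline = truth["regional"][region]
        mixture = {}
        for f in scheme:
            delta = rng_s.dirichlet([config.society_concentration] * n_states)
            mixture[f.feature_id] = (1 - lam) * baseline[f.feature_id] + lam * delta
        truth["society"][society] = mixture
        soc_rows.append({"society_id": society, "region_id": region})

        lo, hi = config.songs_per_society
        n_songs = int(rng_s.integers(lo, hi + 1))
        for _ in range(n_songs):
            song_counter += 1
            row = {
                "song_id": f"song_{song_counter:05d}",
                "society_id": society,
                "region_id": region,
            }
            for f in scheme:
                row[f.feature_id] = int(
                    rng_s.choice(np.arange(1, n_states + 1), p=mixture[f.feature_id])
                )
            song_rows.append(row)

    codings = pd.DataFrame(song_rows)
    for f in scheme:
        codings[f.feature_id] = codings[f.feature_id].astype("Int64")
    societies = pd.DataFrame(soc_rows)
    societies = simulate_geography(config, societies)
    societies["language_id"] = "lang_" + societies["society_id"]
    return codings, societies, truth


def hash_region(label: str) -> int:
    """Stable non-negative integer key for a label (seed-sequence friendly)."""
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def simulate_geography(config: SimConfig, societies: pd.DataFrame) -> pd.DataFrame:
    """Place each region's societies in a Gaussian cluster on the globe.

    Region centres are spread along the equator band; the km spread is
    converted to degrees with the local latitude cosine (adequate for
    cluster scales up to ~1000 km).
    """
    out = societies.copy()
    regions = sorted(out["region_id"].unique())
    centres = {
        r: (float(10.0 * ((i % 5) - 2)), float(-150.0 + 300.0 * i / max(len(regions) - 1, 1)))
        for i, r in enumerate(regions)
    }
    lat_out = np.empty(len(out))
    lon_out = np.empty(len(out))
    for i, (_, row) in enumerate(out.iterrows()):
        rng = _rng(config, 3, hash_region(row["society_id"]))
        clat, clon = centres[row["region_id"]]
        dn, de = rng.normal(0.0, config.cluster_spread_km, size=2)
        lat = clat + dn / 111.32
        lon = clon + de / (111.32 * np.cos(np.radians(clat)))
        lat_out[i] = float(np.clip(lat, -89.9, 89.9))
        lon_out[i] = float((lon + 180.0) % 360.0 - 180.0)
    out["latitude"] = lat_out
    out["longitude"] = lon_out
    return out


def simulate_tree(config: SimConfig, societies: pd.DataFrame) -> dendropy.Tree:
    """A pure-birth (Yule) ultrametric tree, one tip per society's language,
    scaled to root-to-tip depth 1."""
    from dendropy.simulate import treesim

    labels = ["lang_" + s for s in societies["society_id"]]
    seed = int(np.random.SeedSequence([config.seed, 4]).generate_state(1)[0] % (2**31))
    taxa = dendropy.TaxonNamespace(labels)
    tree = treesim.birth_death_tree(
        birth_rate=config.tree_birth_rate,
        death_rate=0.0,
        num_extant_tips=len(labels),
        taxon_namespace=taxa,
        rng=_random.Random(seed),
    )
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree


def simulate_traits(config: SimConfig, societies: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Categorical traits per society, one state per (society, trait).

    Trait states follow the same regional-baseline + society-deviation
    mixture as songs (the style dial is shared), so trait unusualness has
    known structure. Optionally injects missingness at
    ``trait_missing_rate``.
    """
    lam = config.style_strength
    trait_ids = [f"K{i + 1:02d}" for i in range(config.n_kinship)] + [
        f"E{i + 1:02d}" for i in range(config.n_economic)
    ]
    themes = {t: ("kinship" if t.startswith("K") else "economic") for t in trait_ids}
    truth: dict = {"regional": {}, "society": {}}
    rows = []
    for _, row in societies.iterrows():
        region, society = row["region_id"], row["society_id"]
        if region not in truth["regional"]:
            rng_r = _rng(config, 5, hash_region(region))
            truth["regional"][region] = {
                t: rng_r.dirichlet([config.regional_concentration] * config.trait_states)
                for t in trait_ids
            }
        rng_s = _rng(config, 6, hash_region(society))
        mixture = {}
        for t in trait_ids:
            delta = rng_s.dirichlet([config.society_concentration] * config.trait_states)
            mixture[t] = (1 - lam) * truth["regional"][region][t] + lam * delta
        truth["society"][society] = mixture
        for t in trait_ids:
            if config.trait_missing_rate and rng_s.random() < config.trait_missing_rate:
                state = pd.NA
            else:
                state = int(rng_s.choice(np.arange(1, config.trait_states + 1), p=mixture[t]))
            rows.append(
                {"society_id": society, "trait_id": t, "state": state, "theme": themes[t]}
            )
    traits = pd.DataFrame(rows)
    traits["state"] = traits["state"].astype("Int64")
    return traits, truth


def simulate_regression(config: SimConfig, n_obs: int = 500, n_groups: int = 50) -> tuple[pd.DataFrame, dict]:
    """Regression data with known coefficients for recovery tests.

    Covariates ``x1..xP`` are independent standard normals;
    ``response = X beta + u[group] + noise`` with ``u ~ N(0, group_sd^2)``
    and ``noise ~ N(0, residual_sd^2)``. Truth records beta, the realized
    group intercepts and both sds.
    """
    rng = _rng(config, 7)
    beta = np.asarray(config.true_beta, dtype=float)
    p = len(beta)
    X = rng.standard_normal((n_obs, p))
    groups = rng.integers(0, n_groups, size=n_obs)
    u = rng.normal(0.0, config.group_sd, size=n_groups)
    y = X @ beta + u[groups] + rng.normal(0.0, config.residual_sd, size=n_obs)
    df = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(p)])
    df["society_id"] = [f"G{g + 1:03d}" for g in groups]
    df["response"] = y
    df["unit_id"] = [f"obs_{i + 1:05d}" for i in range(n_obs)]
    truth = {
        "beta": beta.tolist(),
        "group_sd": config.group_sd,
        "residual_sd": config.residual_sd,
        "u": u.tolist(),
    }
    return df, truth


def simulate_world(config: SimConfig) -> dict:
    """Generate every input at once: codings, societies, traits, tree, truth."""
    codings, societies, truth_songs = simulate_repertoires(config)
    tree = simulate_tree(config, societies)
    traits, truth_traits = simulate_traits(config, societies)
    return {
        "scheme": scheme_for(config),
        "codings": codings,
        "societies": societies,
        "traits": traits,
        "tree": tree,
        "truth": {"songs": truth_songs, "traits": truth_traits},
    }
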