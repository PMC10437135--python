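import math

import numpy as np
import pandas as pd
import pytest

from songtypicality.data_io import Feature, FeatureScheme
from songtypicality.synthetic_data import SimConfig, simulate_world


@pytest.fixture(scope="session")
def tiny_scheme() -> FeatureScheme:
    """Three features with small state inventories, hand-auditable."""
    return FeatureScheme(
        features=(
            Feature("vocal_org", "vocal organisation", (1, 7, 13)),
            Feature("interval", "interval width", (1, 4, 7, 10)),
            Feature("nasality", "nasality", (1, 10, 13)),
        )
    )


def make_codings(rows, scheme):
    """Build a coding DataFrame from (song, society, region, states...) tuples."""
    cols = ["song_id", "society_id", "region_id"] + scheme.feature_ids
    df = pd.DataFrame(rows, columns=cols)
    for fid in scheme.feature_ids:
        df[fid] = df[fid].astype("Int64")
    return df


@pytest.fixture(scope="session")
def toy_codings(tiny_scheme):
    """Two regions, five societies, hand-countable states."""
    rows = [
        ("s1", "A", "north", 1, 4, 1),
        ("s2", "A", "north", 7, 4, 10),
        ("s3", "B", "north", 1, 7, 1),
        ("s4", "B", "north", 1, 4, 13),
        ("s5", "C", "north", 13, 10, 1),
        ("s6", "D", "south", 7, 7, 10),
        ("s7", "D", "south", 7, 4, 10),
        ("s8", "E", "south", 1, 7, 13),
    ]
    return make_codings(rows, tiny_scheme)


@pytest.fixture(scope="session")
def small_world():
    """A deterministic mid-sized synthetic world shared across tests."""
    return simulate_world(SimConfig(seed=20260927))


@pytest.fixture(scope="session")
def strong_style_world():
    """High style-strength world: societies have spiky idiosyncratic styles."""
    cfg = SimConfig(
        seed=907,
        n_regions=3,
        societies_per_region=10,
        songs_per_society=(10, 16),
        n_features=12,
        style_strength=0.9,
        society_concentration=0.15,
    )
    return simulate_world(cfg)


# ---------------------------------------------------------------------------
# independent naive oracles (deliberately brute-force, no shared code paths)


def naive_song_scores(codings: pd.DataFrame, scheme) -> dict[str, float]:
    """Exhaustive per-song LOSO log-likelihood, recomputed from raw counts."""
    out = {}
    for _, song in codings.iterrows():
        pool = codings[
            (codings["region_id"] == song["region_id"])
            & (codings["society_id"] != song["society_id"])
        ]
        if len(pool) == 0:
            continue
        total = 0.0
        for fid in scheme.feature_ids:
            vals = [int(v) for v in pool[fid].dropna()]
            count = sum(1 for v in vals if v == int(song[fid]))
            p = count / len(vals) if count else 1.0 / (len(pool) + 1)
            total += math.log(p)
        out[str(song["song_id"])] = total
    return out


def naive_trait_scores(traits, societies, theme) -> dict[str, float]:
    """Exhaustive per-society mean LOSO trait log-probability."""
    region_of = dict(zip(societies["society_id"], societies["region_id"]))
    use = traits if theme == "general" else traits[traits["theme"] == theme]
    use = use[use["state"].notna()]
    out = {}
    for society in societies["society_id"]:
        logs = []
        for _, row in use[use["society_id"] == society].iterrows():
            pool = use[
                (use["trait_id"] == row["trait_id"])
                & (use["society_id"] != society)
                & (use["society_id"].map(region_of) == region_of[society])
            ]
            if len(pool) == 0:
                continue
            count = int((pool["state"] == row["state"]).sum())
            p = count / len(pool) if count else 1.0 / (len(pool) + 1)
            logs.append(math.log(p))
        out[society] = float(np.mean(logs)) if logs else float("nan")
    return out


def law_of_cosines_km(lat1, lon1, lat2, lon2, radius=6371.0088):
    """Spherical law of cosines — an independent great-circle formula."""
    p1, l1, p2, l2 = map(math.radians, (lat1, lon1, lat2, lon2))
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(l2 - l1)
    return radius * math.acos(min(1.0, max(-1.0, c)))
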