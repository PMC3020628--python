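"""Bundled reference tables.

The Chilean bull-kelp sampling design (24 localities from Pichicuy at 32°S to
Cape Horn at 56°S with per-locality COI and rbcL sample counts) is published
as a printed table and is therefore shipped as package data.  Coastal
positions are derived from the printed latitudes (~111.32 km per degree along
the near-meridional Chilean coast); the original study's coastal distances
were measured from satellite imagery and were never published numerically.

Regions:

* ``central`` — the 19 localities north of 44°S used for isolation-by-distance;
* ``beach`` — the 16 localities north of 43°S (Pichicuy to Cucao) between
  which beach lengths were measured, yielding the 15 adjacent pairs of the
  disjunction regression.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

KM_PER_DEGREE_LAT = 111.32


def chilean_localities() -> pd.DataFrame:
    """The 24 Chilean sampling localities with per-marker sample counts."""
    ref = resources.files("kelpcoast.data").joinpath("chile_localities.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def chilean_locality_table(region: str | None = None) -> pd.DataFrame:
    """Locality table (locality, order_index, coastal_position_km) for Chile.

    ``region``: None for all 24 localities, ``"central"`` for those north of
    44°S, ``"beach"`` for those north of 43°S.
    """
    df = chilean_localities()
    if region == "central":
        df = df[df["latitude_s"] < 44.0]
    elif region == "beach":
        df = df[df["latitude_s"] < 43.0]
    elif region is not None:
        raise ValueError(f"unknown region {region!r}")
    df = df.sort_values("latitude_s").reset_index(drop=True)
    origin = df["latitude_s"].iloc[0]
    return pd.DataFrame(
        {
            "locality": df["locality"],
            "order_index": range(1, len(df) + 1),
            "coastal_position_km": (
                (df["latitude_s"] - origin) * KM_PER_DEGREE_LAT
            ).round(1),
            "region": df["region"],
        }
    )
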