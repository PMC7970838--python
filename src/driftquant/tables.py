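"""Delimited-text IO for survey, stomach and droplet tables.

Every stage of the pipeline exchanges plain CSV with fixed, documented
headers so field data can be swapped in for the synthetic tables:

========================  =====================================================
file                      columns
========================  =====================================================
stomachs.csv              stomach, station, year, fish_weight, content_weight,
                          empty
subsamples.csv            stomach, replicate, wet_weight, pbs_ratio, v_elution
droplets.csv              well, stomach, replicate, n_total, n_positive,
                          dilution, v_template, v_reaction, v_droplet
visual.csv                station, stomach, larvae_seen, otoliths_seen
plankton.csv              station, lon, lat, date, larval_count,
                          filtered_volume
trawl.csv                 station, lon, lat, date, catch_weight, tow_distance,
                          effective_width
========================  =====================================================
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .ddpcr import DropletReaction, StomachRecord, SubsampleRecord
from .surveys import PlanktonStation, TrawlStation, VisualRecord

__all__ = [
    "read_stomachs", "read_subsamples", "read_droplets",
    "read_visual", "read_plankton", "read_trawl",
    "write_stomachs", "write_subsamples", "write_droplets",
    "write_visual", "write_plankton", "write_trawl",
]


def read_stomachs(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        StomachRecord(
            stomach=str(r.stomach), station=str(r.station), year=int(r.year),
            fish_weight=float(r.fish_weight), content_weight=float(r.content_weight),
            empty=bool(r.empty),
        )
        for r in df.itertuples()
    ]


def read_subsamples(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        SubsampleRecord(
            stomach=str(r.stomach), replicate=int(r.replicate),
            wet_weight=float(r.wet_weight), pbs_ratio=float(r.pbs_ratio),
            v_elution=float(r.v_elution),
        )
        for r in df.itertuples()
    ]


def read_droplets(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        DropletReaction(
            well=str(r.well), stomach=str(r.stomach), replicate=int(r.replicate),
            n_total=int(r.n_total), n_positive=int(r.n_positive),
            dilution=float(r.dilution), v_template=float(r.v_template),
            v_reaction=float(r.v_reaction), v_droplet=float(r.v_droplet),
        )
        for r in df.itertuples()
    ]


def read_visual(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        VisualRecord(
            station=str(r.station), stomach=str(r.stomach),
            larvae_seen=int(r.larvae_seen), otoliths_seen=int(r.otoliths_seen),
        )
        for r in df.itertuples()
    ]


def read_plankton(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        PlanktonStation(
            station=str(r.station), lon=float(r.lon), lat=float(r.lat),
            date=str(r.date), larval_count=int(r.larval_count),
            filtered_volume=float(r.filtered_volume),
        )
        for r in df.itertuples()
    ]


def read_trawl(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        TrawlStation(
            station=str(r.station), lon=float(r.lon), lat=float(r.lat),
            date=str(r.date), catch_weight=float(r.catch_weight),
            tow_distance=float(r.tow_distance), effective_width=float(r.effective_width),
        )
        for r in df.itertuples()
    ]


def _write(records, columns, path) -> None:
    df = pd.DataFrame([[getattr(r, c) for c in columns] for r in records], columns=columns)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")  # round-trip exact


def write_stomachs(records, path) -> None:
    _write(records, ["stomach", "station", "year", "fish_weight", "content_weight", "empty"], path)


def write_subsamples(records, path) -> None:
    _write(records, ["stomach", "replicate", "wet_weight", "pbs_ratio", "v_elution"], path)


def write_droplets(records, path) -> None:
    _write(records, ["well", "stomach", "replicate", "n_total", "n_positive",
                     "dilution", "v_template", "v_reaction", "v_droplet"], path)


def write_visual(records, path) -> None:
    _write(records, ["station", "stomach", "larvae_seen", "otoliths_seen"], path)


def write_plankton(records, path) -> None:
    _write(records, ["station", "lon", "lat", "date", "larval_count", "filtered_volume"], path)


def write_trawl(records, path) -> None:
    _write(records, ["station", "lon", "lat", "date", "catch_weight", "tow_distance",
                     "effective_width"], path)
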