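"""Packaged datasets: the published species-specific assays and the London
air-sampling isolate counts (430 *Penicillium* isolates scored as
*P. chrysogenum*, *P. rubens* or other, per sampling station)."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import CountTable, PrimerTableRow, read_count_table, read_primer_table

__all__ = [
    "load_primer_table",
    "load_station_counts",
    "load_station_groups",
    "load_group_counts",
]


def _data_path(name: str):
    return resources.files("chrysodiag.data").joinpath(name)


def load_primer_table() -> list[PrimerTableRow]:
    """The four published species-specific primer sets."""
    with resources.as_file(_data_path("table1_primers.tsv")) as p:
        return read_primer_table(p)


def load_station_counts() -> CountTable:
    """Per-station isolate counts (chrysogenum / rubens / other)."""
    with resources.as_file(_data_path("table2_stations.csv")) as p:
        return read_count_table(p)


def load_station_groups() -> dict[str, str]:
    """Sampling station -> location group (Underground line / hospital / outdoors)."""
    with resources.as_file(_data_path("table2_station_groups.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["location"], df["group"]))


def load_group_counts() -> CountTable:
    """Isolate counts aggregated to the five location groups."""
    return load_station_counts().aggregate_rows(load_station_groups())
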