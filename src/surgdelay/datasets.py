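"""Packaged national inputs and CSV round-tripping for delay distributions.

Two national delay distributions ship with the package, transcribed from
published week-binned counts of time from diagnosis to surgery:

* ``"us"`` — United States, 2022 incidence (287,850), 13 bins (weeks 1-12
  and >12 weeks at a representative 90 days).
* ``"germany"`` — Germany, 2019 incidence (71,375), 7 bins (weeks 1-6 and
  >7 weeks at a representative 46 days; 48 days is an alternative
  convention selectable via ``open_bin_day``).

Each CSV row is ``label, mass, mass_type, representative_day``; masses
here are absolute M0 counts per bin.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable

from .cohorts import DelayBin, DelayDistribution, PopulationSpec

__all__ = [
    "COUNTRIES",
    "load_delay_distribution",
    "country_population",
    "read_delay_csv",
    "write_delay_csv",
]

COUNTRIES = {
    "us": {
        "file": "us_delay_2022.csv",
        "incidence": 287_850,
        "open_bin_label": ">12w",
        "default_open_bin_day": 90,
    },
    "germany": {
        "file": "germany_delay_2019.csv",
        "incidence": 71_375,
        "open_bin_label": ">7w",
        "default_open_bin_day": 46,
    },
}


def read_delay_csv(path_or_file) -> DelayDistribution:
    """Read a delay distribution from a CSV with the standard columns."""
    if hasattr(path_or_file, "read"):
        rows = list(csv.DictReader(path_or_file))
    else:
        with open(path_or_file, newline="") as fh:
            rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError("empty delay-distribution CSV")
    mass_types = {r["mass_type"].strip() for r in rows}
    if len(mass_types) != 1:
        raise ValueError(f"mixed mass_type values in CSV: {sorted(mass_types)}")
    bins = tuple(
        DelayBin(
            label=r["label"].strip(),
            mass=float(r["mass"]),
            representative_day=float(r["representative_day"]),
        )
        for r in rows
    )
    return DelayDistribution(bins, mass_type=mass_types.pop())  # type: ignore[arg-type]


def write_delay_csv(dist: DelayDistribution, path) -> None:
    """Write a delay distribution to CSV; inverse of :func:`read_delay_csv`."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "mass", "mass_type", "representative_day"])
        for b in dist.bins:
            w.writerow([b.label, repr(b.mass), dist.mass_type, repr(b.representative_day)])


def load_delay_distribution(country: str, open_bin_day: float | None = None) -> DelayDistribution:
    """Load a packaged national delay distribution.

    ``open_bin_day`` overrides the representative day of the open-ended
    last bin (e.g. 48 instead of 46 for Germany's >7-week bin).
    """
    meta = _country_meta(country)
    ref = resources.files("surgdelay.data") / meta["file"]
    with resources.as_file(ref) as p:
        dist = read_delay_csv(Path(p))
    if open_bin_day is not None:
        dist = dist.with_representative_day(meta["open_bin_label"], open_bin_day)
    return dist


def country_population(country: str, **overrides) -> PopulationSpec:
    """PopulationSpec for a packaged country, with optional field overrides."""
    meta = _country_meta(country)
    kwargs = {"incidence": meta["incidence"]}
    kwargs.update(overrides)
    return PopulationSpec(**kwargs)


def _country_meta(country: str) -> dict:
    key = country.strip().lower()
    if key not in COUNTRIES:
        raise ValueError(f"unknown country {country!r}; available: {sorted(COUNTRIES)}")
    return COUNTRIES[key]
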