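"""Packaged leatherback sex-count datasets.

Two small tables ship with the package:

* the East Pacific (Playa Grande, Costa Rica) constant-temperature
  incubation counts at nine temperatures, and
* the four West Pacific (Malaysia) nests incubated at fluctuating
  temperatures, summarized by the median constant-temperature equivalent
  within the thermosensitive period (CTE|TSP) with their sexed counts.

The 33 degC East Pacific condition produced no sexed hatchlings; it is kept
in the table for completeness and dropped automatically by the fitters.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .tsd_curve import SexCountRecord

__all__ = [
    "east_pacific_counts",
    "malaysia_cte_counts",
    "pooled_counts",
    "malaysia_nest_table",
    "write_fixtures",
]

# (temperature degC, males, females)
_EAST_PACIFIC = (
    (28.0, 17, 0),
    (29.0, 9, 1),
    (29.5, 4, 6),
    (30.0, 1, 15),
    (30.5, 0, 10),
    (31.0, 0, 12),
    (31.5, 0, 8),
    (32.0, 0, 19),
    (33.0, 0, 0),
)

# (nest, mean degC, se, median CTE|TSP degC, ci low, ci high, males, females)
_MALAYSIA = (
    ("1C", 27.04, 0.58, 27.31, 27.30, 27.31, 11, 0),
    ("3C", 29.21, 1.01, 28.90, 28.89, 28.91, 9, 0),
    ("4C", 28.95, 1.34, 28.63, 28.62, 28.64, 9, 0),
    ("Oven", 30.42, 0.80, 30.43, 30.43, 30.43, 0, 5),
)


def east_pacific_counts() -> list[SexCountRecord]:
    """Constant-temperature sexed counts from Playa Grande (East Pacific RMU)."""
    return [
        SexCountRecord(
            temperature=t, males=m, females=f,
            rmu="East Pacific", study_id="PlayaGrande",
        )
        for t, m, f in _EAST_PACIFIC
    ]


def malaysia_cte_counts() -> list[SexCountRecord]:
    """Malaysian nests (West Pacific RMU) at their median CTE|TSP."""
    return [
        SexCountRecord(
            temperature=cte, males=m, females=f,
            rmu="West Pacific", study_id="Malaysia", clutch=nest,
        )
        for nest, _, _, cte, _, _, m, f in _MALAYSIA
    ]


def pooled_counts() -> list[SexCountRecord]:
    """All sexed counts printed in the packaged tables (13 records)."""
    return east_pacific_counts() + malaysia_cte_counts()


def malaysia_nest_table() -> pd.DataFrame:
    """Per-nest summary of the four Malaysian nests (CTE, CI, counts)."""
    return pd.DataFrame(
        _MALAYSIA,
        columns=["nest", "mean_tempC", "se_tempC", "median_cte",
                 "ci95_low", "ci95_high", "males", "females"],
    )


def write_fixtures(directory: str | Path) -> list[Path]:
    """Write the packaged tables as the CSV dialects the CLI reads."""
    from .io import write_sexcounts_csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, recs in (
        ("east_pacific_counts.csv", east_pacific_counts()),
        ("malaysia_cte_counts.csv", malaysia_cte_counts()),
        ("pooled_counts.csv", pooled_counts()),
    ):
        path = directory / name
        write_sexcounts_csv(recs, path)
        paths.append(path)
    nest_path = directory / "malaysia_nests.csv"
    malaysia_nest_table().to_csv(nest_path, index=False)
    paths.append(nest_path)
    return paths
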