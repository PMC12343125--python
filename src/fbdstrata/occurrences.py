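"""Cleaning of PBDB-style occurrence tables and per-species age intervals.

An occurrence table is a pandas DataFrame with columns ``occurrence_id``,
``taxon``, ``rank``, ``genus``, ``max_ma``, ``min_ma`` (PBDB export headers
``accepted_name``/``accepted_rank`` are mapped on read). Cleaning mirrors the
usual curation chain for fossil occurrence data ahead of tip-dating: drop
records not identified to species level, drop records with very imprecise
stratigraphic intervals, and drop taxa whose ages are already known from
higher-resolution literature data. One occurrence per species is then drawn
at random to provide that species' age interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OCCURRENCE_COLUMNS",
    "TaxonAgeTable",
    "read_occurrences",
    "write_occurrences",
    "validate_occurrences",
    "clean_occurrences",
    "one_occurrence_per_species",
]

OCCURRENCE_COLUMNS = ["occurrence_id", "taxon", "rank", "genus", "max_ma", "min_ma"]

_PBDB_ALIASES = {"accepted_name": "taxon", "accepted_rank": "rank"}


def validate_occurrences(df: pd.DataFrame) -> None:
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    if df["occurrence_id"].duplicated().any():
        dupes = df.loc[df["occurrence_id"].duplicated(), "occurrence_id"].tolist()
        raise ValueError(f"duplicate occurrence_id values: {dupes[:5]}")
    bad = df[(df["max_ma"] < df["min_ma"]) | (df["min_ma"] < 0)]
    if len(bad):
        raise ValueError(
            f"invalid intervals (need max_ma >= min_ma >= 0) for occurrence_id "
            f"{bad['occurrence_id'].tolist()[:5]}"
        )


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path).rename(columns=_PBDB_ALIASES)
    validate_occurrences(df)
    return df[OCCURRENCE_COLUMNS + [c for c in df.columns if c not in OCCURRENCE_COLUMNS]]


def write_occurrences(df: pd.DataFrame, path) -> None:
    validate_occurrences(df)
    df.to_csv(path, index=False)


def clean_occurrences(df: pd.DataFrame, max_interval_myr: float = 15.0,
                      exclude=frozenset()):
    """Apply the cleaning rules; returns (retained table, audit counts).

    Rules are applied in a fixed order — sub-species-rank identification,
    imprecise interval, excluded taxon — and each dropped record is attributed
    to the first rule it matches, so retained + audit counts always total the
    input count.
    """
    validate_occurrences(df)
    exclude = frozenset(exclude)
    audit = {"rank": 0, "imprecise": 0, "excluded": 0}
    keep = np.ones(len(df), dtype=bool)
    ranks = df["rank"].to_numpy()
    widths = (df["max_ma"] - df["min_ma"]).to_numpy()
    taxa = df["taxon"].to_numpy()
    for i in range(len(df)):
        if ranks[i] != "species":
            audit["rank"] += 1
            keep[i] = False
        elif widths[i] > max_interval_myr:
            audit["imprecise"] += 1
            keep[i] = False
        elif taxa[i] in exclude:
            audit["excluded"] += 1
            keep[i] = False
    return df.loc[keep].reset_index(drop=True), audit


@dataclass
class TaxonAgeTable:
    """Per-taxon stratigraphic interval (max_ma, min_ma) with a derived FAD.

    The default first-appearance convention takes the interval's old bound;
    ``fads(convention="resample")`` instead draws a point uniformly within
    each interval (for sensitivity replicates).
    """

    intervals: dict = field(default_factory=dict)

    def __post_init__(self):
        for taxon, (mx, mn) in self.intervals.items():
            if not (mx >= mn >= 0):
                raise ValueError(f"{taxon}: need max_ma >= min_ma >= 0, got {(mx, mn)}")

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.intervals)

    def __len__(self):
        return len(self.intervals)

    def fads(self, convention: str = "old", rng=None) -> dict:
        if convention == "old":
            return {t: mx for t, (mx, mn) in self.intervals.items()}
        if convention == "resample":
            if rng is None:
                rng = np.random.default_rng()
            return {t: float(rng.uniform(mn, mx)) if mx > mn else mx
                    for t, (mx, mn) in self.intervals.items()}
        raise ValueError(f"unknown FAD convention {convention!r}")

    def subset(self, taxa) -> "TaxonAgeTable":
        taxa = frozenset(taxa)
        missing = taxa - self.taxa
        if missing:
            raise KeyError(f"no age interval for taxa: {sorted(missing)}")
        return TaxonAgeTable({t: self.intervals[t] for t in taxa})

    @classmethod
    def from_csv(cls, path) -> "TaxonAgeTable":
        df = pd.read_csv(path)
        return cls({r.taxon: (float(r.max_ma), float(r.min_ma))
                    for r in df.itertuples()})

    def to_csv(self, path) -> None:
        rows = [{"taxon": t, "max_ma": mx, "min_ma": mn}
                for t, (mx, mn) in sorted(self.intervals.items())]
        pd.DataFrame(rows).to_csv(path, index=False)

    def merged_with(self, other: "TaxonAgeTable") -> "TaxonAgeTable":
        d = dict(self.intervals)
        d.update(other.intervals)
        return TaxonAgeTable(d)


def one_occurrence_per_species(df: pd.DataFrame, seed: int | None = None) -> TaxonAgeTable:
    """Pick one occurrence per species uniformly at random for its age interval."""
    validate_occurrences(df)
    rng = np.random.default_rng(seed)
    intervals = {}
    for taxon, grp in df.sort_values("occurrence_id").groupby("taxon", sort=True):
        row = grp.iloc[int(rng.integers(len(grp)))]
        intervals[taxon] = (float(row["max_ma"]), float(row["min_ma"]))
    return TaxonAgeTable(intervals)
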