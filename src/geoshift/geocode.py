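"""Occurrence-record cleaning, region coding and tiered presence filters.

The pipeline here mirrors standard practice for noisy aggregated occurrence
data (e.g. GBIF exports): rule-based row cleaning with an auditable removal
report, point-in-polygon region assignment, per-species record tabulation,
and increasingly strict presence filters:

===== ================ ================ ============================
level min records      min % of records multiple regions
===== ================ ================ ============================
0     1                —                allowed
1     3                —                allowed
2     3                10               allowed
3     3                10               only the top-count region
===== ================ ================ ============================

Thresholds are inclusive (>= 3 records, >= 10 %).  The percentage base for
level 2 is the species' records assigned to any named region (unassigned
points excluded).  Level-3 ties on the maximum count are broken by the
region precedence order.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import RegionSet, UNASSIGNED

__all__ = [
    "SchemaError", "CleaningReport", "PresenceMatrix",
    "clean_occurrences", "assign_points_to_regions", "tabulate_presence",
    "apply_filter", "match_names", "compute_sampling_fractions",
    "sampling_fraction", "CLEANING_RULES", "DEDUP_DECIMALS",
]

REQUIRED_COLUMNS = ("species", "decimalLongitude", "decimalLatitude")

#: fixed application order of the cleaning rules (each row removed at most
#: once, by the first matching rule)
CLEANING_RULES = ("flagged", "missing_name", "non_numeric", "out_of_range",
                  "lat_eq_lon", "zero_coord", "duplicate")

#: coordinates are compared for deduplication after rounding to this many
#: decimal places (~11 m at the equator)
DEDUP_DECIMALS = 4


class SchemaError(ValueError):
    """An input table is missing a mandatory column."""


@dataclass
class CleaningReport:
    """Per-rule removal counts for one cleaning pass."""

    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        total = self.n_output + sum(self.removed.values())
        if total != self.n_input:
            raise ValueError("removal counts do not conserve row totals")

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps({"n_input": self.n_input, "n_output": self.n_output,
                        "removed": self.removed}, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def clean_occurrences(raw: pd.DataFrame) \
        -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the fixed-order cleaning rules to a raw occurrence table.

    Rules, in order: truthy source flag ("known coordinate issues"),
    missing/blank species name, non-numeric or missing coordinates,
    out-of-range coordinates, latitude == longitude, zero latitude or
    longitude, and deduplication to one record per species per rounded
    location.  Returns the cleaned table (coordinates as floats) and a
    :class:`CleaningReport`.
    """
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    df = raw.reset_index(drop=True)
    n_input = len(df)
    removed = {rule: 0 for rule in CLEANING_RULES}
    alive = np.ones(n_input, dtype=bool)

    def drop(mask: np.ndarray, rule: str) -> None:
        mask = np.asarray(mask, bool) & alive
        removed[rule] += int(mask.sum())
        alive[mask] = False

    if "flag" in df.columns:
        flag = df["flag"]
        truthy = flag.notna() & (flag.astype(str).str.strip() != "") \
            & (flag.astype(str).str.lower() != "false")
        drop(truthy.to_numpy(), "flagged")

    name = df["species"]
    blank = name.isna() | (name.astype(str).str.strip() == "")
    drop(blank.to_numpy(), "missing_name")

    lon = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    lat = pd.to_numeric(df["decimalLatitude"], errors="coerce")
    bad_num = (lon.isna() | lat.isna() | ~np.isfinite(lon.fillna(0))
               | ~np.isfinite(lat.fillna(0)))
    drop(bad_num.to_numpy(), "non_numeric")

    out_range = (lon.abs() > 180) | (lat.abs() > 90)
    drop(out_range.fillna(False).to_numpy(), "out_of_range")

    drop((lat == lon).fillna(False).to_numpy(), "lat_eq_lon")
    drop(((lat == 0) | (lon == 0)).fillna(False).to_numpy(), "zero_coord")

    # deduplicate: one record per species per rounded location
    sub = pd.DataFrame({
        "species": name.astype(str).to_numpy(),
        "lon": lon.round(DEDUP_DECIMALS).to_numpy(),
        "lat": lat.round(DEDUP_DECIMALS).to_numpy(),
    })[alive]
    dup = sub.duplicated(keep="first")
    idx = sub.index[dup]
    mask = np.zeros(n_input, bool)
    mask[idx] = True
    drop(mask, "duplicate")

    out = df.loc[alive].copy()
    out["decimalLongitude"] = lon[alive].astype(float)
    out["decimalLatitude"] = lat[alive].astype(float)
    out = out.reset_index(drop=True)
    report = CleaningReport(n_input, len(out), removed)
    return out, report


def assign_points_to_regions(table: pd.DataFrame,
                             regions: RegionSet) -> pd.DataFrame:
    """Label each cleaned record with its covering region.

    Regions are validated (interior-disjoint) before any assignment.
    Points covered by no polygon are labelled ``unassigned`` and retained;
    they are excluded from presence counts downstream.
    """
    regions.validate()
    out = table.copy()
    out["region"] = regions.assign(
        out["decimalLongitude"].to_numpy(float),
        out["decimalLatitude"].to_numpy(float))
    return out


@dataclass
class PresenceMatrix:
    """Species × region record counts plus filtered presence calls."""

    counts: pd.DataFrame                      # species x region, int
    precedence: list[str]                     # region tie-break order
    presence: pd.DataFrame | None = None      # bool, after apply_filter
    filter_level: int | None = None

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def regions(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str) -> None:
        self.counts.to_csv(path, sep="\t")


def tabulate_presence(labelled: pd.DataFrame,
                      regions: RegionSet | Sequence[str] | None = None) \
        -> PresenceMatrix:
    """Count records per species per region (unassigned rows excluded)."""
    if regions is None:
        names = sorted(r for r in labelled["region"].unique()
                       if r != UNASSIGNED)
    elif isinstance(regions, RegionSet):
        names = list(regions.names)
    else:
        names = list(regions)
    sub = labelled[labelled["region"] != UNASSIGNED]
    counts = (sub.groupby(["species", "region"]).size().unstack(fill_value=0)
              .reindex(columns=names, fill_value=0))
    counts.index.name = "species"
    counts = counts.astype(int)
    return PresenceMatrix(counts=counts, precedence=names)


def apply_filter(matrix: PresenceMatrix, level: int,
                 min_records: int = 3, min_percent: float = 10.0) \
        -> PresenceMatrix:
    """Derive boolean presence calls at the requested filter level."""
    if level not in (0, 1, 2, 3):
        raise ValueError(f"unknown filter level {level!r}")
    counts = matrix.counts
    if level == 0:
        pres = counts >= 1
    else:
        pres = counts >= min_records
        if level >= 2:
            total = counts.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = counts.div(total.replace(0, np.nan), axis=0) * 100.0
            pres &= pct >= min_percent
        if level == 3:
            pres = _restrict_to_top_region(counts, pres, matrix.precedence)
    return PresenceMatrix(counts=counts, precedence=matrix.precedence,
                          presence=pres.astype(bool), filter_level=level)


def _restrict_to_top_region(counts: pd.DataFrame, pres: pd.DataFrame,
                            precedence: list[str]) -> pd.DataFrame:
    """Keep, per species, only the present region with the highest count.

    Ties on the maximum count are broken by the precedence order.
    """
    order = {r: i for i, r in enumerate(precedence)}
    cols = list(counts.columns)
    out = pd.DataFrame(False, index=counts.index, columns=cols)
    for sp in counts.index:
        present = [c for c in cols if pres.at[sp, c]]
        if not present:
            continue
        best = max(present,
                   key=lambda c: (counts.at[sp, c], -order.get(c, 0)))
        out.at[sp, best] = True
    return out


# ----------------------------------------------------------------------
# name matching & sampling fractions
# ----------------------------------------------------------------------
def canonical_name(name: str) -> str:
    """Canonical binomial: underscores to spaces, case-folded, first two
    whitespace-separated tokens."""
    s = re.sub(r"\s+", " ", str(name).replace("_", " ").strip()).casefold()
    return " ".join(s.split(" ")[:2])


def match_names(occ_names: Sequence[str], tip_labels: Sequence[str]) -> dict:
    """One-to-one match of occurrence species names to tree tip labels.

    Matching is exact on canonical binomials.  Canonical collisions (two
    distinct input names mapping to the same canonical form on either side)
    are reported under ``collisions`` and excluded from the mapping rather
    than silently merged.
    """
    def canon_map(names):
        groups: dict[str, list[str]] = {}
        for n in dict.fromkeys(names):   # preserve order, drop repeats
            groups.setdefault(canonical_name(n), []).append(n)
        return groups

    occ = canon_map(occ_names)
    tips = canon_map(tip_labels)
    collisions = sorted(k for k, v in occ.items() if len(v) > 1) \
        + sorted(k for k, v in tips.items() if len(v) > 1)
    mapping = {}
    for key, names in occ.items():
        if len(names) == 1 and key in tips and len(tips[key]) == 1:
            mapping[names[0]] = tips[key][0]
    matched_tips = set(mapping.values())
    unmatched_occ = [n for ns in occ.values() for n in ns
                     if n not in mapping]
    unmatched_tips = [n for ns in tips.values() for n in ns
                      if n not in matched_tips]
    return {"mapping": mapping, "unmatched_occurrences": unmatched_occ,
            "unmatched_tips": unmatched_tips,
            "collisions": sorted(set(collisions))}


def sampling_fraction(n_in_tree: int, n_total: int) -> tuple[float, float]:
    """(raw ratio, ratio rounded to 2 d.p.); NaN if the denominator is 0."""
    if n_total == 0:
        return float("nan"), float("nan")
    raw = n_in_tree / n_total
    return raw, float(np.round(raw, 2))


def compute_sampling_fractions(matrix: PresenceMatrix,
                               tree_tips: Sequence[str],
                               clade_table: Mapping[str, str] | None = None) \
        -> pd.DataFrame:
    """Per-region (optionally per-clade) phylogenetic sampling fractions.

    fraction = (# species present in the region and matched to a tree tip)
    / (# species present in the region).  Requires presence calls
    (run :func:`apply_filter` first).  ``clade_table`` maps species names to
    named clades; when given, fractions are additionally reported per clade
    within each region.
    """
    if matrix.presence is None:
        raise ValueError("presence calls required; run apply_filter first")
    res = match_names(matrix.species, tree_tips)
    in_tree = set(res["mapping"])
    clade_of = None
    if clade_table is not None:
        clade_of = {canonical_name(k): v for k, v in clade_table.items()}

    rows = []

    def emit(region, clade, species):
        n_tot = len(species)
        n_in = sum(1 for s in species if s in in_tree)
        raw, rounded = sampling_fraction(n_in, n_tot)
        rows.append((region, clade, n_tot, n_in, raw, rounded,
                     n_tot == 0))

    for region in matrix.regions:
        present = [sp for sp in matrix.species
                   if matrix.presence.at[sp, region]]
        emit(region, "ALL", present)
        if clade_of is not None:
            clades = sorted(set(clade_of.values()))
            for cl in clades:
                sub = [sp for sp in present
                       if clade_of.get(canonical_name(sp)) == cl]
                emit(region, cl, sub)
    return pd.DataFrame(rows, columns=["region", "clade", "n_total",
                                       "n_in_tree", "fraction_raw",
                                       "fraction", "undefined"])
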