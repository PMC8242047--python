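"""Fossil occurrence tables, stage grids and covariate curves.

Ages are in Ma before present and increase into the past.  All time bins
are half-open ``[older, younger)``: an age falling exactly on a boundary
belongs to the younger bin, except the oldest bin which is closed at both
ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceRecord",
    "OccurrenceTable",
    "AgeResampledDataset",
    "StageGrid",
    "CovariateCurve",
    "FormatError",
    "ValidationError",
    "read_occurrences",
    "write_occurrences",
    "summarize",
    "resample_ages",
    "read_covariate",
    "rescale_covariate",
    "read_stage_table",
    "default_stage_grid",
]

REGIONS = ("new_world", "old_world", "other")

# Cretaceous stage boundaries (ICS 2020) plus the Danian top.
_DEFAULT_STAGES = [
    ("Berriasian", 145.0),
    ("Valanginian", 139.8),
    ("Hauterivian", 132.6),
    ("Barremian", 129.4),
    ("Aptian", 121.4),
    ("Albian", 113.0),
    ("Cenomanian", 100.5),
    ("Turonian", 93.9),
    ("Coniacian", 89.8),
    ("Santonian", 86.3),
    ("Campanian", 83.6),
    ("Maastrichtian", 72.1),
    ("Danian", 66.0),
]
_DANIAN_TOP = 61.6


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


class ValidationError(ValueError):
    """Raised when rows violate the occurrence invariants."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One fossil occurrence with an age-range uncertainty."""

    taxon: str
    min_age: float
    max_age: float
    specimen_id: str | None = None
    region: str | None = None
    clade: str | None = None
    extant: bool = False

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValidationError("taxon must be non-empty")
        if not (self.max_age >= self.min_age >= 0.0):
            raise ValidationError(
                f"require max_age >= min_age >= 0, got "
                f"({self.min_age}, {self.max_age}) for {self.taxon!r}"
            )
        if self.region is not None and self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")


@dataclass
class OccurrenceTable:
    """An ordered collection of occurrence records with a dataset label."""

    records: list[OccurrenceRecord]
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_occurrences(self) -> int:
        return len(self.records)

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.taxon, None)
        return list(seen)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def counts_per_taxon(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.taxon] = out.get(r.taxon, 0) + 1
        return out

    @property
    def singletons(self) -> list[str]:
        return [t for t, k in self.counts_per_taxon().items() if k == 1]

    def min_ages(self) -> np.ndarray:
        return np.array([r.min_age for r in self.records], dtype=float)

    def max_ages(self) -> np.ndarray:
        return np.array([r.max_age for r in self.records], dtype=float)

    def filter(
        self,
        region: str | None = None,
        clade: str | None = None,
        taxa: Iterable[str] | None = None,
        name: str | None = None,
    ) -> "OccurrenceTable":
        """Subset records by region, clade or taxon membership."""
        keep = self.records
        if region is not None:
            if region not in REGIONS:
                raise ValidationError(f"unknown region {region!r}")
            keep = [r for r in keep if r.region == region]
        if clade is not None:
            keep = [r for r in keep if r.clade == clade]
        if taxa is not None:
            tset = set(taxa)
            keep = [r for r in keep if r.taxon in tset]
        return OccurrenceTable(list(keep), name or self.name)

    def by_taxon(self) -> dict[str, list[OccurrenceRecord]]:
        out: dict[str, list[OccurrenceRecord]] = {}
        for r in self.records:
            out.setdefault(r.taxon, []).append(r)
        return out


@dataclass
class AgeResampledDataset:
    """One fixed age per occurrence, drawn inside each record's bounds."""

    table: OccurrenceTable
    ages: np.ndarray
    replicate_index: int
    seed: int

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.shape != (len(self.table),):
            raise ValidationError("one age per occurrence is required")
        lo = self.table.min_ages()
        hi = self.table.max_ages()
        if np.any(self.ages < lo) or np.any(self.ages > hi):
            raise ValidationError("resampled ages must respect record bounds")

    def ages_by_taxon(self) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for rec, age in zip(self.table.records, self.ages):
            out.setdefault(rec.taxon, []).append(age)
        return {t: np.sort(np.array(a))[::-1] for t, a in out.items()}


@dataclass
class StageGrid:
    """Geological stage bins delimited by strictly decreasing boundary ages."""

    boundaries: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.ndim != 1 or len(self.boundaries) < 2:
            raise ValidationError("need at least two boundaries")
        if np.any(np.diff(self.boundaries) >= 0):
            raise ValidationError("boundaries must be strictly decreasing")
        if np.any(self.boundaries < 0):
            raise ValidationError("boundaries must be >= 0")
        if len(self.labels) != len(self.boundaries) - 1:
            raise ValidationError("need one label per bin")

    @property
    def n_stages(self) -> int:
        return len(self.labels)

    @property
    def oldest(self) -> float:
        return float(self.boundaries[0])

    @property
    def youngest(self) -> float:
        return float(self.boundaries[-1])

    def stage_index(self, ages) -> np.ndarray:
        """Bin index for each age; boundary ages go to the younger bin.

        Bin ``j`` spans ``(top_j, base_j]`` in numeric age, so an age equal
        to a shared boundary lands in the bin whose base it is (the younger
        stage).  The oldest bin additionally includes its base.
        """
        a = np.atleast_1d(np.asarray(ages, dtype=float))
        if np.any(a > self.oldest) or np.any(a < self.youngest):
            raise ValidationError("age outside the stage grid span")
        # work on an increasing axis for searchsorted
        inc = self.boundaries[::-1]  # increasing ages
        # find i with inc[i-1] <= a < inc[i]  -> side='right'
        idx_inc = np.searchsorted(inc, a, side="left")
        idx_inc = np.clip(idx_inc, 1, len(inc) - 1)
        j = len(inc) - 1 - idx_inc
        return j if np.ndim(ages) else int(j[0])

    def bin_edges(self, j: int) -> tuple[float, float]:
        """(base, top) of bin j, base older."""
        return float(self.boundaries[j]), float(self.boundaries[j + 1])

    def overlaps(self, older: float, younger: float) -> np.ndarray:
        """Duration of overlap of interval (younger, older) with each bin."""
        base = self.boundaries[:-1]
        top = self.boundaries[1:]
        lo = np.maximum(top, younger)
        hi = np.minimum(base, older)
        return np.maximum(0.0, hi - lo)


def default_stage_grid(oldest: float | None = None) -> StageGrid:
    """Cretaceous stage grid (ICS 2020) with the Danian appended."""
    labels = [s for s, _ in _DEFAULT_STAGES]
    bounds = [b for _, b in _DEFAULT_STAGES] + [_DANIAN_TOP]
    grid = StageGrid(np.array(bounds), labels)
    if oldest is not None:
        keep = grid.boundaries <= oldest
        first = int(np.argmax(keep))
        grid = StageGrid(grid.boundaries[max(first - 1, 0):],
                         grid.labels[max(first - 1, 0):])
    return grid


def read_stage_table(path: str | Path) -> StageGrid:
    """Read a TSV with columns stage, base_age, top_age."""
    df = pd.read_csv(path, sep="\t")
    need = {"stage", "base_age", "top_age"}
    if not need.issubset(df.columns):
        raise FormatError(f"stage table needs columns {sorted(need)}")
    df = df.sort_values("base_age", ascending=False).reset_index(drop=True)
    bounds = list(df["base_age"]) + [float(df["top_age"].iloc[-1])]
    return StageGrid(np.array(bounds, dtype=float), list(df["stage"]))


@dataclass
class CovariateCurve:
    """A time series (age in Ma, value) sampled on a monotone age grid."""

    ages: np.ndarray
    values: np.ndarray
    name: str = "covariate"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.shape != self.values.shape or self.ages.ndim != 1:
            raise ValidationError("ages and values must be 1-D and aligned")
        d = np.diff(self.ages)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ages must be strictly monotone")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")

    def at(self, ages) -> np.ndarray:
        """Linear interpolation at the requested ages."""
        a = self.ages
        v = self.values
        if a[0] > a[-1]:
            a, v = a[::-1], v[::-1]
        q = np.asarray(ages, dtype=float)
        if np.any(q < a[0]) or np.any(q > a[-1]):
            raise ValidationError(f"age outside support of {self.name!r}")
        return np.interp(q, a, v)


def read_covariate(path: str | Path, name: str | None = None) -> CovariateCurve:
    """Read a TSV with columns age, value."""
    df = pd.read_csv(path, sep="\t")
    if not {"age", "value"}.issubset(df.columns):
        raise FormatError("covariate file needs columns age, value")
    nm = name or Path(path).stem
    return CovariateCurve(df["age"].to_numpy(), df["value"].to_numpy(), nm)


def rescale_covariate(
    curve: CovariateCurve,
    window: tuple[float, float],
    step: float = 0.1,
) -> CovariateCurve:
    """Interpolate onto a regular grid over ``window`` and z-score.

    ``window`` is (older, younger) in Ma.  A zero-variance (constant) curve
    is returned as all zeros.  The grid includes both endpoints.
    """
    older, younger = max(window), min(window)
    n = int(round((older - younger) / step)) + 1
    grid = older - step * np.arange(n)
    grid[-1] = max(grid[-1], younger)
    vals = curve.at(grid)
    sd = float(np.std(vals))
    if sd == 0.0:
        z = np.zeros_like(vals)
    else:
        z = (vals - vals.mean()) / sd
    return CovariateCurve(grid, z, curve.name)


_TAXON_ALIASES = ("taxon", "species", "taxon_name", "scientific_name")
_MIN_ALIASES = ("min_age", "minage", "min_ma")
_MAX_ALIASES = ("max_age", "maxage", "max_ma")


def _find_column(cols: Sequence[str], aliases: Sequence[str]) -> str | None:
    low = {c.lower(): c for c in cols}
    for a in aliases:
        if a in low:
            return low[a]
    return None


def read_occurrences(
    path: str | Path,
    dialect: str = "generic_tsv",
    name: str | None = None,
) -> OccurrenceTable:
    """Read an occurrence TSV.

    ``generic_tsv`` expects columns taxon, min_age, max_age with optional
    status, specimen_id, region, clade.  ``pyrate_style`` accepts the
    Species/Status/min_age/max_age layout.  Rows violating the age
    invariants are reported with their (1-based, header-excluded) row
    numbers.
    """
    if dialect not in ("generic_tsv", "pyrate_style"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    tcol = _find_column(cols, _TAXON_ALIASES)
    lo = _find_column(cols, _MIN_ALIASES)
    hi = _find_column(cols, _MAX_ALIASES)
    if tcol is None or lo is None or hi is None:
        raise FormatError(
            f"{path.name}: need a taxon column and min_age/max_age columns; "
            f"found {cols}"
        )
    scol = _find_column(cols, ("status",))
    idcol = _find_column(cols, ("specimen_id", "specimen"))
    rcol = _find_column(cols, ("region",))
    ccol = _find_column(cols, ("clade", "family"))

    records: list[OccurrenceRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(cols, row))
        try:
            rec = OccurrenceRecord(
                taxon=str(d[tcol]).strip(),
                min_age=float(d[lo]),
                max_age=float(d[hi]),
                specimen_id=(str(d[idcol]) if idcol and pd.notna(d[idcol]) else None),
                region=(str(d[rcol]) if rcol and pd.notna(d[rcol]) else None),
                clade=(str(d[ccol]) if ccol and pd.notna(d[ccol]) else None),
                extant=(str(d[scol]).strip().lower() == "extant") if scol else False,
            )
        except (ValidationError, ValueError) as e:
            bad.append((i, str(e)))
            continue
        records.append(rec)
    if bad:
        msg = "; ".join(f"row {i}: {m}" for i, m in bad[:20])
        raise ValidationError(f"{path.name}: {len(bad)} invalid rows ({msg})")
    return OccurrenceTable(records, name or path.stem)


def write_occurrences(table: OccurrenceTable, path: str | Path) -> None:
    """Write the occurrence TSV round-trippably."""
    rows = []
    for r in table.records:
        rows.append(
            {
                "taxon": r.taxon,
                "status": "extant" if r.extant else "extinct",
                "min_age": r.min_age,
                "max_age": r.max_age,
                "specimen_id": r.specimen_id if r.specimen_id is not None else "",
                "region": r.region if r.region is not None else "",
                "clade": r.clade if r.clade is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def summarize(table: OccurrenceTable) -> dict:
    """Exact occurrence/taxon/singleton counts for a non-empty table."""
    if len(table) == 0:
        raise ValidationError("cannot summarize an empty table")
    n_occ = table.n_occurrences
    n_tax = table.n_taxa
    return {
        "name": table.name,
        "n_occurrences": n_occ,
        "n_taxa": n_tax,
        "n_singletons": len(table.singletons),
        "mean_occurrences_per_taxon": n_occ / n_tax,
    }


def resample_ages(
    table: OccurrenceTable,
    n_replicates: int,
    seed: int,
    per: str = "occurrence",
) -> list[AgeResampledDataset]:
    """Draw one age per occurrence uniformly on [min_age, max_age].

    ``per='occurrence'`` draws every occurrence independently;
    ``per='taxon'`` draws a single uniform quantile per taxon per replicate
    and applies it to all of that taxon's intervals.
    Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if per not in ("occurrence", "taxon"):
        raise ValueError("per must be 'occurrence' or 'taxon'")
    rng = np.random.default_rng(seed)
    lo = table.min_ages()
    hi = table.max_ages()
    out = []
    taxa = [r.taxon for r in table.records]
    uniq = list(dict.fromkeys(taxa))
    tindex = np.array([uniq.index(t) for t in taxa])
    for k in range(n_replicates):
        if per == "occurrence":
            u = rng.random(len(table))
        else:
            u = rng.random(len(uniq))[tindex]
        ages = lo + u * (hi - lo)
        out.append(AgeResampledDataset(table, ages, k, seed))
    return out
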