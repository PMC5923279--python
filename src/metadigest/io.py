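"""Core data containers and plain-text I/O for NMR bucket-table chemometrics.

A 1D :sup:`1`H-NMR spectrum is reduced to a *bucket table*: each sample's
spectrum is integrated over a fixed set of chemical-shift intervals
("buckets"), and every row is divided by its total integrated area so that
samples are comparable regardless of absolute signal intensity. The bucket
table (samples x buckets) is the X block of every downstream model; the
digestive-efficiency trait table (AMEn and coefficients of digestive use)
is the Y block.

All file formats are plain text (tab-delimited, UTF-8, '.' decimal) and all
readers validate strictly, reporting the offending line rather than
coercing silently.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger("metadigest")

COMPARTMENTS = ("serum", "ileum", "caecum", "other")

#: canonical trait column order for the trait table TSV
TRAIT_COLUMNS = ("AMEn", "CDU_DM_w2", "CDU_DM_w4", "CDU_S", "CDU_N", "CDU_L")
CDU_COLUMNS = tuple(c for c in TRAIT_COLUMNS if c.startswith("CDU"))
OPTIONAL_TRAIT_COLUMNS = ("body_weight", "fcr")


class ParseError(ValueError):
    """Malformed input file; carries the file and 1-based line number."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class DegenerateSampleError(ValueError):
    """A sample row cannot be normalized (non-positive total area)."""


class SpectralRangeError(ValueError):
    """A bucket lies (partly) outside the sampled spectral range."""


class BucketDefinitionError(ValueError):
    """Bucket definitions overlap or are otherwise inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpectrumRecord:
    """One sampled 1D spectrum: intensity as a function of chemical shift.

    ppm must be strictly monotone; either direction is accepted on input and
    canonicalized to descending (the NMR plotting convention).
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D")
        if self.ppm.size != self.intensity.size:
            raise ValueError(
                f"sample {self.sample_id!r}: ppm and intensity lengths differ "
                f"({self.ppm.size} vs {self.intensity.size})")
        if self.ppm.size < 2:
            raise ValueError("a spectrum needs at least two points")
        d = np.diff(self.ppm)
        if np.all(d > 0):  # ascending: flip to descending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d < 0):
            raise ValueError(f"sample {self.sample_id!r}: ppm not strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite intensities")


@dataclass
class BucketDefinition:
    """A ppm integration interval, optionally with excluded sub-intervals
    (e.g. the residual-water region)."""

    bucket_id: str
    ppm_hi: float
    ppm_lo: float
    exclusions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ppm_hi > self.ppm_lo:
            raise BucketDefinitionError(
                f"bucket {self.bucket_id!r}: ppm_hi must exceed ppm_lo")
        canon = []
        for hi, lo in self.exclusions:
            hi, lo = (hi, lo) if hi >= lo else (lo, hi)
            canon.append((hi, lo))
        self.exclusions = canon

    @property
    def width(self) -> float:
        return self.ppm_hi - self.ppm_lo


def _check_non_overlapping(defs: Sequence[BucketDefinition]) -> None:
    ivals = sorted((d.ppm_lo, d.ppm_hi, d.bucket_id) for d in defs)
    for (lo1, hi1, id1), (lo2, hi2, id2) in zip(ivals, ivals[1:]):
        if lo2 < hi1 - 1e-12:
            raise BucketDefinitionError(
                f"buckets {id1!r} and {id2!r} overlap ({lo2:g} < {hi1:g})")


@dataclass
class BucketTable:
    """Samples x buckets matrix of non-negative intensities for one
    biological compartment, with optional ppm metadata."""

    compartment: str
    data: pd.DataFrame  # index: sample ids, columns: bucket ids
    definitions: list[BucketDefinition] | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}")
        if self.data.isna().any().any():
            raise ValueError("bucket table contains missing cells")
        if not self.data.index.is_unique:
            raise ValueError("duplicate sample ids in bucket table")
        if not self.data.columns.is_unique:
            raise ValueError("duplicate bucket ids in bucket table")
        if (self.data.values < 0).any():
            raise ValueError("bucket intensities must be non-negative")
        if self.definitions is not None:
            ids = [d.bucket_id for d in self.definitions]
            if list(self.data.columns) != ids:
                raise ValueError("bucket definitions do not match table columns")
            _check_non_overlapping(self.definitions)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def bucket_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.values

    def drop_samples(self, ids: Iterable[str]) -> "BucketTable":
        ids = set(ids)
        keep = [s for s in self.data.index if s not in ids]
        return BucketTable(self.compartment, self.data.loc[keep], self.definitions)


@dataclass
class AssignmentMap:
    """bucket_id -> metabolite names assigned to that spectral region.

    An empty list means the bucket is an unassigned spectral region. A bucket
    covering overlapping resonances keeps all names (compound label).
    """

    assignments: dict[str, list[str]]

    def __post_init__(self) -> None:
        for bid, names in self.assignments.items():
            for name in names:
                if not isinstance(name, str) or not name.strip():
                    raise ValueError(f"bucket {bid!r}: empty metabolite name")

    def metabolites_for(self, bucket_id: str) -> list[str]:
        return self.assignments.get(bucket_id, [])

    def label_for(self, bucket_id: str) -> str | None:
        """Compound node label, or None if unassigned."""
        names = self.metabolites_for(bucket_id)
        return " + ".join(names) if names else None

    def check_against(self, table: BucketTable) -> None:
        missing = set(self.assignments) - set(table.bucket_ids)
        if missing:
            raise ValueError(
                f"assignment map references unknown buckets: {sorted(missing)[:5]}")


@dataclass
class TraitTable:
    """Per-bird digestive-efficiency traits.

    AMEn is in kcal per kg dry matter; the coefficients of digestive use
    (CDU, (intake - excreta)/intake) are fractions in [0, 1]. Values supplied
    as percentages are divided by 100 on input.
    """

    data: pd.DataFrame  # index: bird ids

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("duplicate bird ids in trait table")
        missing = [c for c in TRAIT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        amen = self.data["AMEn"].dropna()
        if (amen <= 0).any():
            raise ValueError("AMEn must be positive")
        for c in CDU_COLUMNS:
            col = self.data[c].dropna()
            if ((col < 0) | (col > 1)).any():
                raise ValueError(f"{c} must lie in [0, 1] after canonicalization")

    @property
    def bird_ids(self) -> list[str]:
        return list(self.data.index)

    def complete_cases(self, traits: Sequence[str]) -> "TraitTable":
        """Drop birds with missing values in the requested traits, logging
        the exclusion (birds with missing trait values enter no model that
        needs those traits)."""
        sub = self.data.dropna(subset=list(traits))
        dropped = sorted(set(self.data.index) - set(sub.index))
        if dropped:
            logger.info("trait table: excluded %d bird(s) with missing %s: %s",
                        len(dropped), list(traits), dropped)
        return TraitTable(sub)


# ---------------------------------------------------------------------------
# Spectral bucketing and normalization
# ---------------------------------------------------------------------------

def _trapz_segment(ppm_asc: np.ndarray, intens: np.ndarray,
                   lo: float, hi: float) -> float:
    """Trapezoidal integral of the sampled spectrum over [lo, hi], with the
    interval endpoints linearly interpolated onto the grid."""
    if hi <= lo:
        return 0.0
    inner = (ppm_asc > lo) & (ppm_asc < hi)
    xs = np.concatenate(([lo], ppm_asc[inner], [hi]))
    ys = np.concatenate((
        [np.interp(lo, ppm_asc, intens)],
        intens[inner],
        [np.interp(hi, ppm_asc, intens)],
    ))
    return float(np.trapezoid(ys, xs))


def bucket_spectrum(spec: SpectrumRecord,
                    defs: Sequence[BucketDefinition]) -> np.ndarray:
    """Integrate a spectrum over each bucket interval (trapezoid rule),
    subtracting any excluded sub-intervals.

    Raises :class:`SpectralRangeError` if a bucket extends past the sampled
    ppm range, and :class:`BucketDefinitionError` for overlapping buckets.
    """
    _check_non_overlapping(defs)
    ppm_asc = spec.ppm[::-1]
    intens = spec.intensity[::-1]
    lo_edge, hi_edge = ppm_asc[0], ppm_asc[-1]
    out = np.empty(len(defs))
    for i, d in enumerate(defs):
        if d.ppm_lo < lo_edge - 1e-9 or d.ppm_hi > hi_edge + 1e-9:
            raise SpectralRangeError(
                f"bucket {d.bucket_id!r} [{d.ppm_lo:g}, {d.ppm_hi:g}] outside "
                f"spectral range [{lo_edge:g}, {hi_edge:g}]")
        area = _trapz_segment(ppm_asc, intens, d.ppm_lo, d.ppm_hi)
        for ex_hi, ex_lo in d.exclusions:
            area -= _trapz_segment(ppm_asc, intens,
                                   max(ex_lo, d.ppm_lo), min(ex_hi, d.ppm_hi))
        out[i] = area
    return out


def normalize_total_area(table: BucketTable) -> BucketTable:
    """Divide each sample row by its own total integrated area, so that every
    row sums to 1. Idempotent. Raises :class:`DegenerateSampleError` for a
    row with non-positive total area, naming the sample."""
    sums = table.data.sum(axis=1)
    bad = sums[sums <= 0]
    if len(bad):
        raise DegenerateSampleError(
            f"sample(s) with non-positive total area: {list(bad.index)}")
    return BucketTable(table.compartment, table.data.div(sums, axis=0),
                       table.definitions)


def compute_cdu(fi_dm: float, fw_dm: float) -> float:
    """Coefficient of digestive use from a balance trial:
    (FI_DM - FW_DM) / FI_DM, with FI_DM the dry-matter feed intake and FW_DM
    the dry-matter excreta weight over the same period.

    Scale-invariant in the common unit of intake and excreta. A negative
    value (excreta exceeding intake) is possible in principle and returned
    with a warning.
    """
    if fi_dm <= 0:
        raise ValueError(f"feed intake must be positive (got {fi_dm!r})")
    if fw_dm < 0:
        raise ValueError(f"excreta weight must be non-negative (got {fw_dm!r})")
    if fw_dm > fi_dm:
        warnings.warn(
            f"excreta ({fw_dm}) exceeds intake ({fi_dm}); CDU is negative",
            stacklevel=2)
    return (fi_dm - fw_dm) / fi_dm


# ---------------------------------------------------------------------------
# Trait summaries (violin-plot ingredients)
# ---------------------------------------------------------------------------

@dataclass
class TraitSummary:
    trait: str
    n: int
    mean: float
    sd: float
    min: float
    q1: float
    median: float
    q3: float
    max: float
    density_grid: np.ndarray | None  # None => point mass (constant trait)
    density: np.ndarray | None
    point_mass: bool = False


def summarize_traits(traits: TraitTable,
                     columns: Sequence[str] = TRAIT_COLUMNS,
                     grid_size: int = 512) -> dict[str, TraitSummary]:
    """Descriptive statistics per trait: mean, sd (n-1 denominator),
    quartiles, and a Gaussian-kernel density (Silverman bandwidth) on a
    512-point grid spanning the data +/- 3 bandwidths — the ingredients of a
    violin plot. A constant trait is reported as a point mass."""
    out: dict[str, TraitSummary] = {}
    for col in columns:
        x = traits.data[col].dropna().to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"trait {col!r}: need at least 3 birds, got {x.size}")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        sd = float(np.std(x, ddof=1))
        base = dict(trait=col, n=int(x.size), mean=float(np.mean(x)), sd=sd,
                    min=float(x.min()), q1=float(q1), median=float(med),
                    q3=float(q3), max=float(x.max()))
        if sd == 0.0:
            out[col] = TraitSummary(**base, density_grid=None, density=None,
                                    point_mass=True)
            continue
        kde = gaussian_kde(x, bw_method="silverman")
        bw = sd * kde.factor
        grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
        out[col] = TraitSummary(**base, density_grid=grid, density=kde(grid))
    return out


# ---------------------------------------------------------------------------
# Plain-text readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_rows(path: str | Path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            rows.append((lineno, row))
    if not rows:
        raise ParseError("empty file", path)
    return rows


def _parse_float(cell: str, path, lineno, what: str) -> float:
    try:
        v = float(cell)
    except ValueError:
        raise ParseError(f"non-numeric {what}: {cell!r}", path, lineno) from None
    if not math.isfinite(v):
        raise ParseError(f"non-finite {what}: {cell!r}", path, lineno)
    return v


def write_bucket_table(table: BucketTable, path: str | Path,
                       sidecar: str | Path | None = None) -> None:
    """Write the intensity matrix as TSV (header = bucket ids, first column =
    sample_id) and, if ppm definitions are attached, a metadata sidecar TSV
    with bucket_id, ppm_hi, ppm_lo, compartment."""
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")
    if sidecar is not None:
        if table.definitions is None:
            raise ValueError("bucket table has no ppm definitions to write")
        meta = pd.DataFrame({
            "bucket_id": [d.bucket_id for d in table.definitions],
            "ppm_hi": [d.ppm_hi for d in table.definitions],
            "ppm_lo": [d.ppm_lo for d in table.definitions],
            "compartment": table.compartment,
        })
        meta.to_csv(sidecar, sep="\t", index=False, float_format="%.12g")


def read_bucket_table(path: str | Path, sidecar: str | Path | None = None,
                      compartment: str = "other") -> BucketTable:
    """Strictly parse a bucket-table TSV; every schema violation raises
    :class:`ParseError` with the offending line number."""
    rows = _read_tsv_rows(path)
    head_no, header = rows[0]
    if header[0] != "sample_id":
        raise ParseError(f"first header cell must be 'sample_id', got {header[0]!r}",
                         path, head_no)
    bucket_ids = header[1:]
    if len(set(bucket_ids)) != len(bucket_ids):
        raise ParseError("duplicated bucket ids in header", path, head_no)
    ncol = len(header)
    ids, matrix = [], []
    for lineno, row in rows[1:]:
        if len(row) != ncol:
            raise ParseError(f"ragged row: expected {ncol} cells, got {len(row)}",
                             path, lineno)
        if any(not c.strip() for c in row):
            raise ParseError("missing cell", path, lineno)
        ids.append(row[0])
        matrix.append([_parse_float(c, path, lineno, "intensity") for c in row[1:]])
    if len(set(ids)) != len(ids):
        raise ParseError("duplicated sample ids", path)
    defs = None
    if sidecar is not None:
        defs, compartment = _read_bucket_sidecar(sidecar, bucket_ids)
    data = pd.DataFrame(matrix, index=pd.Index(ids, name="sample_id"),
                        columns=bucket_ids)
    return BucketTable(compartment, data, defs)


def _read_bucket_sidecar(path, bucket_ids):
    rows = _read_tsv_rows(path)
    head_no, header = rows[0]
    expected = ["bucket_id", "ppm_hi", "ppm_lo", "compartment"]
    if header != expected:
        raise ParseError(f"sidecar header must be {expected}", path, head_no)
    defs, comps = [], set()
    for lineno, row in rows[1:]:
        if len(row) != 4:
            raise ParseError("ragged sidecar row", path, lineno)
        defs.append(BucketDefinition(
            row[0],
            _parse_float(row[1], path, lineno, "ppm_hi"),
            _parse_float(row[2], path, lineno, "ppm_lo")))
        comps.add(row[3])
    if [d.bucket_id for d in defs] != list(bucket_ids):
        raise ParseError("sidecar bucket ids do not match table header", path)
    if len(comps) != 1:
        raise ParseError(f"sidecar names several compartments: {sorted(comps)}", path)
    return defs, comps.pop()


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    df = traits.data.copy()
    df.index.name = "bird_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_trait_table(path: str | Path) -> TraitTable:
    """Read the per-bird trait TSV. CDU columns supplied as percentages
    (values > 1.5) are divided by 100 with a logged warning; empty cells are
    missing values."""
    rows = _read_tsv_rows(path)
    head_no, header = rows[0]
    if header[0] != "bird_id":
        raise ParseError(f"first header cell must be 'bird_id', got {header[0]!r}",
                         path, head_no)
    cols = header[1:]
    missing = [c for c in TRAIT_COLUMNS if c not in cols]
    if missing:
        raise ParseError(f"missing trait columns: {missing}", path, head_no)
    unknown = [c for c in cols
               if c not in TRAIT_COLUMNS and c not in OPTIONAL_TRAIT_COLUMNS]
    if unknown:
        raise ParseError(f"unknown trait columns: {unknown}", path, head_no)
    ids, records = [], []
    for lineno, row in rows[1:]:
        if len(row) != len(header):
            raise ParseError(f"ragged row: expected {len(header)} cells, got "
                             f"{len(row)}", path, lineno)
        ids.append(row[0])
        rec = {}
        for c, cell in zip(cols, row[1:]):
            rec[c] = (math.nan if not cell.strip()
                      else _parse_float(cell, path, lineno, c))
        records.append(rec)
    if len(set(ids)) != len(ids):
        raise ParseError("duplicated bird ids", path)
    df = pd.DataFrame(records, index=pd.Index(ids, name="bird_id"))
    for c in CDU_COLUMNS:
        col = df[c]
        pct = col > 1.5
        if pct.any():
            logger.warning("trait column %s: %d value(s) > 1.5 interpreted as "
                           "percent and divided by 100", c, int(pct.sum()))
            df.loc[pct, c] = col[pct] / 100.0
    return TraitTable(df)


def write_assignment_map(amap: AssignmentMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("bucket_id\tmetabolites\n")
        for bid, names in amap.assignments.items():
            fh.write(f"{bid}\t{';'.join(names)}\n")


def read_assignment_map(path: str | Path) -> AssignmentMap:
    rows = _read_tsv_rows(path)
    head_no, header = rows[0]
    if header[:2] != ["bucket_id", "metabolites"]:
        raise ParseError("header must be 'bucket_id<TAB>metabolites'", path, head_no)
    assignments: dict[str, list[str]] = {}
    for lineno, row in rows[1:]:
        if len(row) > 2:
            raise ParseError("ragged row in assignment map", path, lineno)
        bid = row[0]
        if bid in assignments:
            raise ParseError(f"duplicated bucket id {bid!r}", path, lineno)
        cell = row[1] if len(row) == 2 else ""
        names = [n.strip() for n in cell.split(";") if n.strip()]
        assignments[bid] = names
    return AssignmentMap(assignments)


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT metabolite-set library: one set per line, tab-delimited as
    name, description, then members. Returns {name: {description, members}}."""
    library: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("GMT line needs name, description and at least "
                                 "one member", path, lineno)
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in library:
                raise ParseError(f"duplicated set name {name!r}", path, lineno)
            library[name] = {"description": desc,
                             "members": [m.strip() for m in members if m.strip()]}
    if not library:
        raise ParseError("empty GMT file", path)
    return library


def write_gmt(library: Mapping[str, Mapping], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, entry in library.items():
            fh.write("\t".join([name, str(entry.get("description", ""))]
                               + list(entry["members"])) + "\n")
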