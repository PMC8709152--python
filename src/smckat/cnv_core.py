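"""Domain types and file I/O for CNV segment, phenotype, and cytoband data.

A copy number variant (CNV) is the gain (amplification) or loss (deletion)
of a DNA segment relative to the diploid reference.  Each variant carries
four characteristics: start position, end position, type, and dosage (total
copy count; 2 is the diploid reference).  A subject's *CNV profile* is the
position-sorted list of all its variants; the sequential order of that list
is the signal the association test targets.

Coordinates are 1-based inclusive throughout.  UCSC-style inputs (0-based
half-open) are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DELETION",
    "AMPLIFICATION",
    "CNVDataError",
    "CNVRecord",
    "CNVProfile",
    "CNVGroup",
    "GroupSeries",
    "PhenotypeTable",
    "Band",
    "CytobandMap",
    "TableDialect",
    "DIALECTS",
    "normalize_chrom",
    "chrom_sort_key",
    "read_cnv_table",
    "write_cnv_table",
    "read_phenotype",
    "write_phenotype",
    "read_cytoband",
    "filter_region",
]

#: Type codes match the indicator coding of the phenotype model
#: (deletion -> 1, amplification -> 3).
DELETION = 1
AMPLIFICATION = 3

_TYPE_LABEL = {DELETION: "DEL", AMPLIFICATION: "AMP"}

_KNOWN_CHROMS = [str(i) for i in range(1, 23)] + ["X", "Y"]
_CHROM_RANK = {c: i for i, c in enumerate(_KNOWN_CHROMS)}


class CNVDataError(ValueError):
    """Raised for malformed or inconsistent input data."""


def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix and upper-case sex chromosomes."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.lower() in ("x", "y"):
        s = s.upper()
    return s


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Karyotype ordering 1..22, X, Y; unknown labels sort after, lexically."""
    c = normalize_chrom(chrom)
    if c in _CHROM_RANK:
        return (0, _CHROM_RANK[c])
    return (1, c)


@dataclass(frozen=True)
class CNVRecord:
    """One copy number variant: position, type and dosage.

    ``start``/``end`` are 1-based inclusive base-pair coordinates with
    ``end >= start``.  ``cnv_type`` is :data:`DELETION` (1) or
    :data:`AMPLIFICATION` (3).  ``dosage`` is the non-negative total copy
    count; dosage < 2 implies a deletion and > 2 an amplification.  A
    type/dosage mismatch is only warned about, because some datasets carry
    a type call without a true dosage — the type is treated as
    authoritative.
    """

    chrom: str
    start: int
    end: int
    cnv_type: int
    dosage: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CNVDataError(
                f"CNV end < start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.cnv_type not in (DELETION, AMPLIFICATION):
            raise CNVDataError(
                f"cnv_type must be {DELETION} (deletion) or "
                f"{AMPLIFICATION} (amplification), got {self.cnv_type!r}"
            )
        if self.dosage < 0:
            raise CNVDataError(f"negative dosage: {self.dosage}")
        if self.dosage != 2:
            implied = DELETION if self.dosage < 2 else AMPLIFICATION
            if implied != self.cnv_type:
                warnings.warn(
                    f"CNV {self.chrom}:{self.start}-{self.end}: dosage "
                    f"{self.dosage} is inconsistent with type "
                    f"{_TYPE_LABEL[self.cnv_type]}; keeping record as given",
                    stacklevel=2,
                )

    @property
    def length(self) -> int:
        """Segment length in base pairs (inclusive coordinates)."""
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.start, self.end, self.cnv_type)


@dataclass
class CNVProfile:
    """Position-sorted CNVs of one subject.

    Records are sorted on construction by (karyotype chromosome order,
    start, end, type); an empty profile is valid.
    """

    sample_id: str
    records: tuple[CNVRecord, ...] = ()

    def __post_init__(self) -> None:
        self.records = tuple(sorted(self.records, key=CNVRecord.sort_key))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CNVRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class CNVGroup:
    """A contiguous window of ``n`` CNVs taken from a profile."""

    records: tuple[CNVRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise CNVDataError("CNVGroup must contain at least one CNV")
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def size(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CNVRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class GroupSeries:
    """Ordered sliding-window CNV groups of one profile, all of size ``n``.

    For a profile of length ``l`` the series holds ``max(0, l - n + 1)``
    stride-1 windows, ordered by window start.
    """

    groups: tuple[CNVGroup, ...]
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CNVDataError(f"group size must be >= 1, got {self.n}")
        object.__setattr__(self, "groups", tuple(self.groups))
        for g in self.groups:
            if g.size != self.n:
                raise CNVDataError(
                    f"group of size {g.size} in a series built with n={self.n}"
                )

    def __len__(self) -> int:
        return len(self.groups)

    def __getitem__(self, z: int) -> CNVGroup:
        return self.groups[z]

    def __iter__(self) -> Iterator[CNVGroup]:
        return iter(self.groups)


@dataclass
class PhenotypeTable:
    """Binary trait and optional covariates, indexed by sample id.

    ``y`` is 0/1 case-control status; ``covariates`` is an optional numeric
    matrix (one row per sample) such as age and sex.
    """

    sample_ids: list[str]
    y: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.y = np.asarray(self.y, dtype=float)
        if not np.isin(self.y, (0.0, 1.0)).all():
            bad = sorted(set(self.y) - {0.0, 1.0})
            raise CNVDataError(f"phenotype y must be 0/1; found {bad}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise CNVDataError(f"duplicate sample_id(s): {dupes}")
        if len(self.sample_ids) != len(self.y):
            raise CNVDataError("sample_ids and y have different lengths")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, float))
            if self.covariates.shape[0] != len(self.y):
                raise CNVDataError("covariate rows do not match sample count")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    def reordered(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        """Return a copy aligned to ``sample_ids`` (by id, never position)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise CNVDataError(
                f"phenotype table is missing sample(s): {missing}"
            )
        order = [index[s] for s in sample_ids]
        return PhenotypeTable(
            sample_ids=list(sample_ids),
            y=self.y[order],
            covariates=None if self.covariates is None else self.covariates[order],
            covariate_names=list(self.covariate_names),
        )


class Band(NamedTuple):
    """A cytogenetic band: name plus 1-based inclusive interval."""

    name: str
    start: int
    end: int


@dataclass
class CytobandMap:
    """Per-chromosome ordered, non-overlapping cytogenetic band intervals."""

    bands: dict[str, list[Band]]

    def __post_init__(self) -> None:
        for chrom, bands in self.bands.items():
            bands.sort(key=lambda b: (b.start, b.end))
            for a, b in zip(bands, bands[1:]):
                if b.start <= a.end:
                    raise CNVDataError(
                        f"overlapping bands on chromosome {chrom}: "
                        f"{a.name} ({a.start}-{a.end}) and "
                        f"{b.name} ({b.start}-{b.end})"
                    )

    def __len__(self) -> int:
        return sum(len(v) for v in self.bands.values())

    def regions(self) -> list[tuple[str, str, int, int]]:
        """All bands as (label, chrom, start, end), label like ``8p23.1``."""
        out = []
        for chrom in sorted(self.bands, key=chrom_sort_key):
            for band in self.bands[chrom]:
                out.append((f"{chrom}{band.name}", chrom, band.start, band.end))
        return out


# ---------------------------------------------------------------------------
# Table dialects and readers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableDialect:
    """Column conventions of a CNV segment table.

    ``type_map`` maps accepted (case-insensitive) type tokens to the type
    codes; ``zero_based_half_open`` declares BED-style coordinates that are
    shifted to 1-based inclusive on read.
    """

    type_map: Mapping[str, int]
    zero_based_half_open: bool = False

    def parse_type(self, token: str) -> int:
        code = self.type_map.get(str(token).strip().lower())
        if code is None:
            accepted = sorted(self.type_map)
            raise CNVDataError(
                f"unknown CNV type token {token!r}; accepted tokens: {accepted}"
            )
        return code


DIALECTS: dict[str, TableDialect] = {
    "del-amp": TableDialect({"del": DELETION, "amp": AMPLIFICATION}),
    "del-dup": TableDialect({"del": DELETION, "dup": AMPLIFICATION}),
    "numeric": TableDialect({"1": DELETION, "3": AMPLIFICATION}),
    "loss-gain": TableDialect({"loss": DELETION, "gain": AMPLIFICATION}),
}

_CNV_COLUMNS = ["sample", "chrom", "start", "end", "type", "dosage"]


def _resolve_dialect(dialect: TableDialect | str | None) -> TableDialect:
    if dialect is None:
        return DIALECTS["del-amp"]
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise CNVDataError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
            ) from None
    return dialect


def read_cnv_table(
    path, dialect: TableDialect | str | None = None
) -> list[CNVProfile]:
    """Read a tab-separated CNV segment table into one profile per sample.

    Expected header: ``sample  chrom  start  end  type  dosage``.  Rows may
    arrive in any order; each returned profile is position-sorted.  Errors
    name the offending 1-based file line.
    """
    dia = _resolve_dialect(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _CNV_COLUMNS if c not in df.columns]
    if missing:
        raise CNVDataError(f"CNV table {path} is missing column(s) {missing}")
    by_sample: dict[str, list[CNVRecord]] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # 1-based, after the header line
        try:
            start = int(row.start)
            end = int(row.end)
        except (TypeError, ValueError):
            raise CNVDataError(
                f"line {line}: non-integer coordinates "
                f"({row.start!r}, {row.end!r})"
            ) from None
        if dia.zero_based_half_open:
            start += 1
        try:
            dosage = int(row.dosage)
        except (TypeError, ValueError):
            raise CNVDataError(
                f"line {line}: non-integer dosage {row.dosage!r}"
            ) from None
        try:
            record = CNVRecord(
                chrom=normalize_chrom(row.chrom),
                start=start,
                end=end,
                cnv_type=dia.parse_type(row.type),
                dosage=dosage,
            )
        except CNVDataError as exc:
            raise CNVDataError(f"line {line}: {exc}") from None
        by_sample.setdefault(str(row.sample), []).append(record)
    return [
        CNVProfile(sample_id=s, records=tuple(recs))
        for s, recs in by_sample.items()
    ]


def write_cnv_table(
    profiles: Iterable[CNVProfile], path, dialect: TableDialect | str | None = None
) -> None:
    """Write profiles as a 1-based inclusive TSV readable by read_cnv_table."""
    dia = _resolve_dialect(dialect)
    label_of = {code: token.upper() for token, code in dia.type_map.items()}
    rows = []
    for profile in profiles:
        for r in profile:
            start = r.start - 1 if dia.zero_based_half_open else r.start
            rows.append(
                (profile.sample_id, r.chrom, start, r.end,
                 label_of[r.cnv_type], r.dosage)
            )
    pd.DataFrame(rows, columns=_CNV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_phenotype(path, standardize: bool = False) -> PhenotypeTable:
    """Read a phenotype TSV: ``sample  y [cov1 cov2 ...]``.

    ``y`` must be 0/1 with both classes present; any further columns are
    numeric covariates (optionally z-scored with ``standardize``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise CNVDataError(f"phenotype table {path} needs >= 2 columns")
    sample_col, y_col = df.columns[0], df.columns[1]
    try:
        y = df[y_col].astype(float).to_numpy()
    except ValueError:
        raise CNVDataError(f"non-numeric value in phenotype column {y_col!r}") from None
    if not np.isin(y, (0.0, 1.0)).all():
        raise CNVDataError("phenotype y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise CNVDataError("single phenotype class: y has no variation")
    cov_cols = list(df.columns[2:])
    covariates = None
    if cov_cols:
        cols = []
        for c in cov_cols:
            try:
                cols.append(df[c].astype(float).to_numpy())
            except ValueError:
                raise CNVDataError(
                    f"non-numeric value in covariate column {c!r}"
                ) from None
        covariates = np.column_stack(cols)
        if standardize:
            sd = covariates.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            covariates = (covariates - covariates.mean(axis=0)) / sd
    return PhenotypeTable(
        sample_ids=df[sample_col].astype(str).tolist(),
        y=y,
        covariates=covariates,
        covariate_names=cov_cols,
    )


def write_phenotype(pheno: PhenotypeTable, path) -> None:
    data = {"sample": pheno.sample_ids, "y": pheno.y.astype(int)}
    if pheno.covariates is not None:
        names = pheno.covariate_names or [
            f"cov{i+1}" for i in range(pheno.covariates.shape[1])
        ]
        for j, name in enumerate(names):
            data[name] = pheno.covariates[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_cytoband(path, one_based: bool = False) -> CytobandMap:
    """Read a cytogenetic band file.

    Default input is the UCSC ``cytoBand.txt`` layout (chrom, chromStart
    0-based, chromEnd, band, gieStain, no header); intervals are stored
    1-based inclusive (chromStart + 1).  With ``one_based`` the file is a
    headerless 4-column variant (chrom, start, end, band) already 1-based.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if one_based:
        if df.shape[1] < 4:
            raise CNVDataError("1-based cytoband variant needs 4 columns")
        chrom_c, start_c, end_c, band_c = 0, 1, 2, 3
        shift = 0
    else:
        if df.shape[1] < 5:
            raise CNVDataError(
                "UCSC cytoBand format needs 5 columns "
                "(chrom, chromStart, chromEnd, band, gieStain)"
            )
        chrom_c, start_c, end_c, band_c = 0, 1, 2, 3
        shift = 1
    bands: dict[str, list[Band]] = {}
    for _, row in df.iterrows():
        chrom = normalize_chrom(row[chrom_c])
        try:
            start = int(row[start_c]) + shift
            end = int(row[end_c])
        except ValueError:
            raise CNVDataError(
                f"non-integer band coordinates for {row[band_c]!r}"
            ) from None
        bands.setdefault(chrom, []).append(Band(str(row[band_c]), start, end))
    return CytobandMap(bands=bands)


def filter_region(
    profile: CNVProfile, region: str | tuple[str, int, int]
) -> CNVProfile:
    """Restrict a profile to a chromosome or a (chrom, start, end) interval.

    Whole-chromosome regions keep every CNV on that chromosome.  Interval
    regions (e.g. a cytogenetic band) assign a CNV by its midpoint, so that
    a CNV straddling a band boundary belongs to exactly one band of any
    non-overlapping partition.  An empty result is valid.
    """
    if isinstance(region, str):
        chrom = normalize_chrom(region)
        kept = tuple(r for r in profile if normalize_chrom(r.chrom) == chrom)
    else:
        chrom, start, end = region
        chrom = normalize_chrom(chrom)
        kept = tuple(
            r
            for r in profile
            if normalize_chrom(r.chrom) == chrom and start <= r.midpoint <= end
        )
    return CNVProfile(sample_id=profile.sample_id, records=kept)
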