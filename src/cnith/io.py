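"""Data model and readers/writers for allele-specific copy-number inputs.

The pipeline consumes ASCAT-style outputs: per-sample tables of segments with
integer major/minor allele copy numbers, per-sample purity ("aberrant cell
fraction") and ploidy, plus genome coordinates (chromosome lengths and
centromere intervals) and gene annotations.

Conventions
-----------
* Coordinates are 1-based and inclusive at both ends throughout (the ASCAT
  file convention).  :func:`to_zero_based` / :func:`from_zero_based` convert
  at the boundary for interoperability with BED-style half-open intervals.
* Chromosome X is accepted on load but excluded by default from distance and
  scar scoring (see the consuming modules); Y is ignored.
* A profile may carry total copy number only (``n_major``/``n_minor`` absent);
  allele-dependent operations then refuse to run rather than guess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Default column names of the segment-table dialect (remappable).
SEGMENT_COLUMNS = {
    "sample": "sample",
    "chrom": "chrom",
    "start": "startpos",
    "end": "endpos",
    "n_major": "nMajor",
    "n_minor": "nMinor",
}

METADATA_COLUMNS = ["sample", "patient", "timepoint", "site", "imo_cell", "purity", "ploidy"]

VALID_TIMEPOINTS = frozenset({"primary", "relapse"})
VALID_IMO_CELLS = frozenset(f"{c}{r}" for c in "ABC" for r in "123")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicSegment:
    """One constant-copy-number interval.

    ``n_major``/``n_minor`` are ``None`` for total-CN-only input, in which
    case ``total_cn`` must be given explicitly.
    """

    chrom: str
    start: int
    end: int
    n_major: int | None = None
    n_minor: int | None = None
    total_cn: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.start < 1:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: 1-based start must be >= 1"
            )
        if (self.n_major is None) != (self.n_minor is None):
            raise ValidationError("n_major and n_minor must be given together")
        if self.n_major is not None:
            if self.n_minor > self.n_major or self.n_minor < 0:
                raise ValidationError(
                    f"segment {self.chrom}:{self.start}-{self.end}: "
                    f"need n_major >= n_minor >= 0, got ({self.n_major},{self.n_minor})"
                )
            expected = self.n_major + self.n_minor
            if self.total_cn is None:
                object.__setattr__(self, "total_cn", expected)
            elif self.total_cn != expected:
                raise ValidationError(
                    f"total_cn {self.total_cn} != n_major+n_minor {expected}"
                )
        elif self.total_cn is None:
            raise ValidationError("total_cn required when allele columns absent")
        elif self.total_cn < 0:
            raise ValidationError("total_cn must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def has_alleles(self) -> bool:
        return self.n_major is not None

    @property
    def allele_state(self) -> tuple[int, int] | None:
        if self.n_major is None:
            return None
        return (self.n_major, self.n_minor)


@dataclass(frozen=True)
class AllelicCNProfile:
    """Per-sample ordered, non-overlapping allele-specific CN segments."""

    sample_id: str
    segments: tuple[GenomicSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(
            sorted(self.segments, key=lambda s: (_chrom_key(s.chrom), s.start))
        )
        object.__setattr__(self, "segments", segs)
        prev: GenomicSegment | None = None
        for s in segs:
            if prev is not None and s.chrom == prev.chrom and s.start <= prev.end:
                raise ValidationError(
                    f"sample {self.sample_id}: overlapping segments "
                    f"{prev.chrom}:{prev.start}-{prev.end} and {s.chrom}:{s.start}-{s.end}"
                )
            prev = s

    @property
    def chromosomes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.chrom, None)
        return tuple(seen)

    @property
    def has_alleles(self) -> bool:
        return all(s.has_alleles for s in self.segments)

    def by_chrom(self, chrom: str) -> tuple[GenomicSegment, ...]:
        return tuple(s for s in self.segments if s.chrom == chrom)

    def drop_chromosomes(self, chroms: Iterable[str]) -> "AllelicCNProfile":
        drop = set(chroms)
        return AllelicCNProfile(
            self.sample_id, tuple(s for s in self.segments if s.chrom not in drop)
        )

    def footprint(self) -> dict[str, int]:
        """Total covered bp per chromosome (coalesce-invariant)."""
        out: dict[str, int] = {}
        for s in self.segments:
            out[s.chrom] = out.get(s.chrom, 0) + s.length
        return out

    def validate_against(self, genome: "GenomeCoordinates") -> None:
        for s in self.segments:
            if s.chrom not in genome.chrom_lengths:
                raise ValidationError(
                    f"sample {self.sample_id}: unknown chromosome {s.chrom!r}"
                )
            if s.end > genome.chrom_lengths[s.chrom]:
                raise ValidationError(
                    f"sample {self.sample_id}: segment {s.chrom}:{s.start}-{s.end} "
                    f"exceeds chromosome length {genome.chrom_lengths[s.chrom]}"
                )


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one tumor deposit."""

    sample_id: str
    patient_id: str
    timepoint: str
    site_label: str = ""
    imo_cell: str | None = None
    purity: float | None = None
    ploidy: float | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in VALID_TIMEPOINTS:
            raise ValidationError(
                f"sample {self.sample_id}: timepoint {self.timepoint!r} "
                f"not in {sorted(VALID_TIMEPOINTS)}"
            )
        if self.imo_cell is not None and self.imo_cell not in VALID_IMO_CELLS:
            raise ValidationError(
                f"sample {self.sample_id}: IMO cell {self.imo_cell!r} outside the A1..C3 grid"
            )
        if self.purity is not None and not (0.0 < self.purity <= 1.0):
            raise ValidationError(
                f"sample {self.sample_id}: purity {self.purity} outside (0, 1]"
            )
        if self.ploidy is not None and self.ploidy <= 0:
            raise ValidationError(f"sample {self.sample_id}: ploidy must be > 0")


@dataclass(frozen=True)
class GenomeCoordinates:
    """Chromosome lengths and centromere intervals (1-based inclusive)."""

    chrom_lengths: Mapping[str, int]
    centromeres: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for chrom, (cs, ce) in self.centromeres.items():
            if chrom not in self.chrom_lengths:
                raise ValidationError(f"centromere for unknown chromosome {chrom!r}")
            if not (1 <= cs <= ce <= self.chrom_lengths[chrom]):
                raise ValidationError(
                    f"centromere interval {cs}-{ce} outside chromosome {chrom}"
                )

    def arms(self, chrom: str) -> tuple[tuple[int, int], tuple[int, int]]:
        """(p-arm, q-arm) intervals, delimited by the centromere."""
        if chrom not in self.centromeres:
            raise ValidationError(f"no centromere recorded for chromosome {chrom!r}")
        cs, ce = self.centromeres[chrom]
        return (1, cs - 1), (ce + 1, self.chrom_lengths[chrom])


@dataclass(frozen=True)
class GeneAnnotation:
    gene_symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValidationError(f"gene {self.gene_symbol}: bad interval")


# ---------------------------------------------------------------------------
# Coordinate converters (boundary only)
# ---------------------------------------------------------------------------


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_zero_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


# ---------------------------------------------------------------------------
# Coalescing
# ---------------------------------------------------------------------------


def coalesce_profile(p: AllelicCNProfile) -> AllelicCNProfile:
    """Merge adjacent same-chromosome segments with identical CN state.

    Only zero-gap neighbours (``next.start == prev.end + 1``) with identical
    ``(n_major, n_minor)`` — or identical ``total_cn`` for total-only input —
    are merged.  Idempotent; never changes the genomic footprint.
    """
    merged: list[GenomicSegment] = []
    for s in p.segments:
        if merged:
            prev = merged[-1]
            same_state = (
                prev.allele_state == s.allele_state
                if s.has_alleles and prev.has_alleles
                else prev.total_cn == s.total_cn and not s.has_alleles and not prev.has_alleles
            )
            if prev.chrom == s.chrom and prev.end + 1 == s.start and same_state:
                merged[-1] = replace(prev, end=s.end)
                continue
        merged.append(s)
    return AllelicCNProfile(p.sample_id, tuple(merged))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_segment_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    genome: GenomeCoordinates | None = None,
) -> list[AllelicCNProfile]:
    """Read an ASCAT-style segment TSV into one profile per sample.

    ``dialect`` remaps logical column names (keys of ``SEGMENT_COLUMNS``) to
    the file's actual headers.  Allele columns may be absent if the dialect
    maps ``total_cn`` to a column; such profiles support total-CN operations
    only.
    """
    cols = dict(SEGMENT_COLUMNS)
    total_col = None
    if dialect:
        total_col = dialect.pop("total_cn", None) if isinstance(dialect, dict) else None
        cols.update(dialect)
    df = _read_tsv(path)
    have_alleles = cols["n_major"] in df.columns and cols["n_minor"] in df.columns
    needed = [cols[k] for k in ("sample", "chrom", "start", "end")]
    if have_alleles:
        needed += [cols["n_major"], cols["n_minor"]]
    elif total_col is None or total_col not in df.columns:
        raise ValidationError(
            f"{path}: neither allele columns ({cols['n_major']},{cols['n_minor']}) "
            "nor a total-CN column found"
        )
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    profiles: list[AllelicCNProfile] = []
    n_rows = 0
    for sample_id, grp in df.groupby(cols["sample"], sort=True):
        segs = []
        for idx, row in grp.iterrows():
            chrom = str(row[cols["chrom"]])
            if genome is not None and chrom not in genome.chrom_lengths:
                raise ValidationError(
                    f"{path} row {idx}: unknown chromosome {chrom!r} "
                    f"(known: {sorted(genome.chrom_lengths)})"
                )
            if have_alleles:
                nmaj, nmin = int(row[cols["n_major"]]), int(row[cols["n_minor"]])
                if nmaj < 0 or nmin < 0:
                    raise ValidationError(f"{path} row {idx}: negative copy number")
                if nmaj < nmin:  # unordered alleles: normalise to major >= minor
                    nmaj, nmin = nmin, nmaj
                seg = GenomicSegment(
                    chrom, int(row[cols["start"]]), int(row[cols["end"]]), nmaj, nmin
                )
            else:
                tot = int(row[total_col])
                if tot < 0:
                    raise ValidationError(f"{path} row {idx}: negative copy number")
                seg = GenomicSegment(
                    chrom, int(row[cols["start"]]), int(row[cols["end"]]), total_cn=tot
                )
            segs.append(seg)
        n_rows += len(segs)
        try:
            prof = AllelicCNProfile(str(sample_id), tuple(segs))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
        if genome is not None:
            prof.validate_against(genome)
        profiles.append(prof)
    if n_rows != len(df):
        raise ValidationError(f"{path}: row count not conserved")  # pragma: no cover
    return profiles


def write_segment_table(profiles: Iterable[AllelicCNProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for s in p.segments:
            rows.append(
                {
                    "sample": p.sample_id,
                    "chrom": s.chrom,
                    "startpos": s.start,
                    "endpos": s.end,
                    "nMajor": s.n_major if s.n_major is not None else "",
                    "nMinor": s.n_minor if s.n_minor is not None else "",
                }
            )
    pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS.values())).to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path: str | Path) -> list[SampleRecord]:
    df = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample"]),
                patient_id=str(row["patient"]),
                timepoint=str(row["timepoint"]),
                site_label="" if pd.isna(row["site"]) else str(row["site"]),
                imo_cell=None if pd.isna(row["imo_cell"]) else str(row["imo_cell"]),
                purity=None if pd.isna(row["purity"]) else float(row["purity"]),
                ploidy=None if pd.isna(row["ploidy"]) else float(row["ploidy"]),
            )
        )
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample": r.sample_id,
            "patient": r.patient_id,
            "timepoint": r.timepoint,
            "site": r.site_label,
            "imo_cell": "" if r.imo_cell is None else r.imo_cell,
            "purity": "" if r.purity is None else r.purity,
            "ploidy": "" if r.ploidy is None else r.ploidy,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Sample x feature table; first column is the sample id index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    return df


def read_genome(path: str | Path) -> GenomeCoordinates:
    df = _read_tsv(path)
    for c in ("chrom", "length", "cen_start", "cen_end"):
        if c not in df.columns:
            raise ValidationError(f"{path}: missing column {c!r}")
    lengths, cens = {}, {}
    for _, row in df.iterrows():
        chrom = str(row["chrom"])
        lengths[chrom] = int(row["length"])
        if not pd.isna(row["cen_start"]):
            cens[chrom] = (int(row["cen_start"]), int(row["cen_end"]))
    return GenomeCoordinates(lengths, cens)


def write_genome(genome: GenomeCoordinates, path: str | Path) -> None:
    rows = []
    for chrom, length in genome.chrom_lengths.items():
        cs, ce = genome.centromeres.get(chrom, ("", ""))
        rows.append({"chrom": chrom, "length": length, "cen_start": cs, "cen_end": ce})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path, genome: GenomeCoordinates | None = None) -> list[GeneAnnotation]:
    """BED-like TSV ``chrom start end gene`` — 1-based inclusive in this dialect."""
    df = _read_tsv(path)
    for c in ("chrom", "start", "end", "gene"):
        if c not in df.columns:
            raise ValidationError(f"{path}: missing column {c!r}")
    genes = []
    for _, row in df.iterrows():
        g = GeneAnnotation(str(row["gene"]), str(row["chrom"]), int(row["start"]), int(row["end"]))
        if genome is not None:
            if g.chrom not in genome.chrom_lengths:
                raise ValidationError(f"gene {g.gene_symbol}: unknown chromosome {g.chrom!r}")
            if g.end > genome.chrom_lengths[g.chrom]:
                raise ValidationError(f"gene {g.gene_symbol}: outside chromosome {g.chrom}")
        genes.append(g)
    return genes


def metadata_by_sample(records: Iterable[SampleRecord]) -> dict[str, SampleRecord]:
    out = {}
    for r in records:
        if r.sample_id in out:
            raise ValidationError(f"duplicate sample id {r.sample_id!r}")
        out[r.sample_id] = r
    return out
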