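"""I/O for sgRNA libraries, screen count matrices, and protospacer counting.

File formats are plain TSV with header rows:

* library: columns ``sgrna_id``, ``target``, ``protospacer``; a target of
  ``NTC`` (case-insensitive) marks a non-targeting control guide.
* counts: wide TSV, rows ``sgrna_id``, one integer column per sample
  (long format with columns ``sgrna_id``, ``sample``, ``count`` is also
  accepted on read).
* sample sheet: columns ``sample``, ``arm`` (control/treatment),
  ``replicate``, ``doublings`` (population doublings of that sample's arm).

Protospacer counting from FASTQ is exact-match only: each read is trimmed to
a fixed window and compared to the protospacer set; no mismatches or indels
are tolerated.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FormatError",
    "SgRNARecord",
    "SgRNALibrary",
    "ScreenCounts",
    "read_library",
    "write_library",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "count_protospacers",
]

NTC_MARKER = "NTC"
_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates the declared format."""


@dataclass(frozen=True)
class SgRNARecord:
    """One guide: unique id, target gene symbol (or ``NTC``), protospacer."""

    sgrna_id: str
    target: str
    protospacer: str

    def __post_init__(self) -> None:
        if not self.sgrna_id:
            raise FormatError("sgrna_id must be non-empty")
        if not self.protospacer or set(self.protospacer) - _VALID_BASES:
            raise FormatError(
                f"protospacer for {self.sgrna_id!r} must be non-empty "
                f"uppercase ACGT, got {self.protospacer!r}"
            )

    @property
    def is_ntc(self) -> bool:
        return self.target.upper() == NTC_MARKER


@dataclass
class SgRNALibrary:
    """Ordered sgRNA roster with gene index and NTC pool."""

    records: list[SgRNARecord]
    gene_to_sgrnas: dict[str, list[str]] = field(init=False, repr=False)
    ntc_ids: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.sgrna_id in seen:
                raise FormatError(f"duplicate sgrna_id {rec.sgrna_id!r}")
            seen.add(rec.sgrna_id)
        protos = [r.protospacer for r in self.records]
        if len(set(protos)) != len(protos):
            dup = pd.Series(protos).value_counts()
            raise FormatError(
                f"duplicate protospacer sequence(s): {list(dup[dup > 1].index[:3])}"
            )
        self.gene_to_sgrnas = {}
        self.ntc_ids = []
        for rec in self.records:
            if rec.is_ntc:
                self.ntc_ids.append(rec.sgrna_id)
            else:
                self.gene_to_sgrnas.setdefault(rec.target, []).append(rec.sgrna_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def genes(self) -> list[str]:
        return list(self.gene_to_sgrnas)

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_sgrnas)

    @property
    def n_ntc(self) -> int:
        return len(self.ntc_ids)

    @property
    def sgrna_ids(self) -> list[str]:
        return [r.sgrna_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sgrna_id": [r.sgrna_id for r in self.records],
                "target": [r.target for r in self.records],
                "protospacer": [r.protospacer for r in self.records],
            }
        )


@dataclass
class ScreenCounts:
    """Integer count matrix (sgRNA x sample) plus per-sample metadata.

    ``counts`` is indexed by sgrna_id with one column per sample;
    ``samples`` has index ``sample`` and columns ``arm``, ``replicate``,
    ``doublings``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise FormatError("negative counts are not allowed")
        if not np.array_equal(c.values, np.floor(c.values)):
            raise FormatError("counts must be integers")
        self.counts = c.astype(np.int64)
        s = self.samples
        missing = {"arm", "replicate", "doublings"} - set(s.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        unknown = set(s["arm"]) - {"control", "treatment"}
        if unknown:
            raise FormatError(f"unknown arm value(s): {sorted(unknown)}")
        for arm in ("control", "treatment"):
            if not (s["arm"] == arm).any():
                raise FormatError(f"no samples in arm {arm!r}")
        bad = s.index[~(s["doublings"] > 0)]
        if len(bad):
            raise FormatError(f"non-positive or missing doublings for sample(s): {list(bad)}")
        extra = set(c.columns) - set(s.index)
        if extra:
            raise FormatError(f"samples without metadata: {sorted(extra)}")

    def arm_samples(self, arm: str) -> list[str]:
        return list(self.samples.index[self.samples["arm"] == arm])

    def validate_against(self, library: SgRNALibrary) -> None:
        unknown = set(self.counts.index) - set(library.sgrna_ids)
        if unknown:
            raise FormatError(
                f"count rows not present in library: {sorted(unknown)[:5]}"
            )


def read_library(path: str | Path) -> SgRNALibrary:
    """Read a TSV/CSV sgRNA library (columns sgrna_id, target, protospacer)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sgrna_id", "target", "protospacer"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                SgRNARecord(str(row.sgrna_id), str(row.target), str(row.protospacer))
            )
        except FormatError as e:
            raise FormatError(f"{path}, row {i}: {e}") from None
    ids = [r.sgrna_id for r in records]
    dups = pd.Series(ids).value_counts()
    dups = dups[dups > 1]
    if len(dups):
        raise FormatError(f"{path}: duplicate sgrna_id {dups.index[0]!r}")
    return SgRNALibrary(records)


def write_library(library: SgRNALibrary, path: str | Path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "arm", "replicate", "doublings"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing column(s) {sorted(missing)}")
    df = df.set_index("sample")
    bad = df.index[df["doublings"].isna() | ~(df["doublings"] > 0)]
    if len(bad):
        raise FormatError(
            f"{path}: missing or non-positive doublings for sample(s) {list(bad)}"
        )
    return df


def read_counts(counts_path: str | Path, samples_path: str | Path) -> ScreenCounts:
    """Read a counts TSV (wide or long) plus a side-car sample sheet."""
    df = pd.read_csv(counts_path, sep="\t")
    if "sgrna_id" not in df.columns:
        raise FormatError(f"{counts_path}: missing 'sgrna_id' column")
    if {"sample", "count"} <= set(df.columns):  # long format
        wide = df.pivot(index="sgrna_id", columns="sample", values="count")
        if wide.isna().any().any():
            raise FormatError(f"{counts_path}: incomplete long-format table")
        df = wide
    else:
        df = df.set_index("sgrna_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise FormatError(f"{counts_path}: non-numeric count in column {col!r}")
        if (vals < 0).any():
            raise FormatError(f"{counts_path}: negative count in column {col!r}")
        if not np.array_equal(vals.values, np.floor(vals.values)):
            raise FormatError(f"{counts_path}: non-integer count in column {col!r}")
        df[col] = vals.astype(np.int64)
    samples = read_sample_sheet(samples_path)
    missing = set(df.columns) - set(samples.index)
    if missing:
        raise FormatError(
            f"{counts_path}: sample(s) {sorted(missing)} absent from sample sheet"
        )
    return ScreenCounts(df, samples.loc[list(df.columns)])


def write_counts(sc: ScreenCounts, counts_path: str | Path, samples_path: str | Path) -> None:
    """Write wide counts TSV and sample-sheet TSV (lossless round trip)."""
    sc.counts.rename_axis("sgrna_id").to_csv(counts_path, sep="\t")
    sc.samples.rename_axis("sample").to_csv(samples_path, sep="\t")


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_protospacers(
    fastq_path: str | Path,
    library: SgRNALibrary,
    trim_start: int = 0,
    trim_len: int | None = None,
) -> tuple[pd.Series, float]:
    """Count exact protospacer matches in a FASTQ file.

    Each read is trimmed to ``read[trim_start : trim_start + trim_len]`` and
    compared by exact string match to the library's protospacers. Returns the
    per-sgRNA count vector (indexed like the library) and the alignment rate
    (matched reads / total reads).
    """
    lengths = {len(r.protospacer) for r in library.records}
    if len(lengths) != 1:
        raise FormatError(f"protospacers have mixed lengths: {sorted(lengths)}")
    (proto_len,) = lengths
    if trim_len is None:
        trim_len = proto_len
    if trim_len != proto_len:
        raise FormatError(
            f"trim_len {trim_len} != protospacer length {proto_len}"
        )
    if trim_start < 0:
        raise FormatError("trim_start must be >= 0")
    proto_to_id = {r.protospacer: r.sgrna_id for r in library.records}
    counts: dict[str, int] = {r.sgrna_id: 0 for r in library.records}
    total = 0
    matched = 0
    with _open_maybe_gzip(Path(fastq_path)) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            total += 1
            window = seq[trim_start : trim_start + trim_len].upper()
            sid = proto_to_id.get(window)
            if sid is not None:
                counts[sid] += 1
                matched += 1
    rate = matched / total if total else 0.0
    return pd.Series(counts, name="count"), rate
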