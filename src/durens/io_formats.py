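"""Readers and writers for every on-disk representation the pipeline touches.

All external formats are plain text: BED3/BED4 for peak intervals, TSV for
count matrices, sample designs, TSS annotations and per-feature reports, and
JSON sidecars for run parameters.  Genomic coordinates follow the BED
convention throughout — 0-based, half-open — and the TSS of a minus-strand
gene is the *end* of its annotated span.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "ParseError",
    "DesignMismatchError",
    "GenomicInterval",
    "FeatureSet",
    "TssRecord",
    "SampleDesign",
    "CountMatrix",
    "MemoryCallSet",
    "read_bed",
    "write_bed",
    "read_tss",
    "write_tss",
    "read_design",
    "write_design",
    "read_counts",
    "write_counts",
    "write_report",
    "read_report",
]


class ParseError(ValueError):
    """A malformed record in an input file (message names the offending line)."""


class DesignMismatchError(ValueError):
    """Sample identifiers in a data file disagree with the sample design."""


WASHOUT_TREATMENTS = ("none", "media", "rux", "anti_ifng", "isotype")


@dataclass(frozen=True)
class GenomicInterval:
    """A peak locus in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    feature_id: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start for {self.feature_id!r}")
        if not self.start < self.end:
            raise ValueError(
                f"empty or inverted interval for {self.feature_id!r}: "
                f"[{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class FeatureSet:
    """An ordered collection of genomic intervals with unique identifiers.

    The feature set defines the row space of every peak-level matrix; order is
    preserved from the input and subsetting keeps the original order.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._intervals: list[GenomicInterval] = list(intervals)
        ids = [iv.feature_id for iv in self._intervals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        self._index = {fid: i for i, fid in enumerate(ids)}

    @property
    def ids(self) -> list[str]:
        return [iv.feature_id for iv in self._intervals]

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._index

    def __getitem__(self, feature_id: str) -> GenomicInterval:
        return self._intervals[self._index[feature_id]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureSet):
            return NotImplemented
        return self._intervals == other._intervals

    def subset(self, feature_ids: Iterable[str]) -> "FeatureSet":
        """Subset to the given ids, preserving this set's original order."""
        keep = set(feature_ids)
        missing = keep - set(self._index)
        if missing:
            raise KeyError(f"unknown feature ids: {sorted(missing)[:5]}")
        return FeatureSet(iv for iv in self._intervals if iv.feature_id in keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self._intervals],
                "start": [iv.start for iv in self._intervals],
                "end": [iv.end for iv in self._intervals],
                "feature_id": self.ids,
            }
        )


@dataclass(frozen=True)
class TssRecord:
    """Transcription start site of a gene, 0-based."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    protein_coding: bool

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class SampleDesign:
    """Per-sample condition / timepoint / washout-treatment / replicate labels.

    Held as a DataFrame indexed by ``sample_id``; the design is always an
    explicit table, never inferred from sample-id strings.
    """

    REQUIRED = ("condition", "washout_treatment", "timepoint_h", "replicate")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "sample_id" in frame.columns:
            frame = frame.set_index("sample_id")
        frame.index = frame.index.astype(str)
        if frame.index.has_duplicates:
            raise ValueError("duplicate sample_id in design")
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"design missing columns: {missing}")
        if "assay" not in frame.columns:
            frame["assay"] = ""
        frame["assay"] = frame["assay"].fillna("").astype(str)
        bad = set(frame["washout_treatment"]) - set(WASHOUT_TREATMENTS)
        if bad:
            raise ValueError(f"unknown washout_treatment values: {sorted(bad)}")
        frame["timepoint_h"] = frame["timepoint_h"].astype(float)
        frame["replicate"] = frame["replicate"].astype(int)
        if (frame["timepoint_h"] < 0).any() or (frame["replicate"] < 1).any():
            raise ValueError("timepoint_h must be >= 0 and replicate >= 1")
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.frame["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        hit = self.frame.index[self.frame["condition"] == condition]
        if len(hit) == 0:
            raise KeyError(f"no samples for condition {condition!r}")
        return list(hit)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.frame.index

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleDesign):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, tied to a sample design."""

    counts: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids in count matrix")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        unknown = [c for c in self.counts.columns if c not in self.design]
        if unknown:
            raise DesignMismatchError(f"samples not in design: {unknown[:5]}")
        self.counts = self.counts.astype(int)
        self.counts.index.name = "feature_id"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_features(self, feature_ids: Iterable[str]) -> "CountMatrix":
        ids = [f for f in self.counts.index if f in set(feature_ids)]
        return CountMatrix(self.counts.loc[ids], self.design)


@dataclass
class MemoryCallSet:
    """Per-feature memory labels plus the thresholds that produced them."""

    calls: pd.DataFrame  # indexed by feature/gene id
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            raise ValueError("duplicate ids in call set")
        self.calls.index.name = "feature_id"


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path: str | Path) -> FeatureSet:
    """Read BED3/BED4 intervals; column 4 is the feature id when present.

    Missing names are synthesized as ``chrom:start-end``.  Malformed lines
    raise :class:`ParseError` naming the line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            try:
                intervals.append(GenomicInterval(chrom, start, end, name))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return FeatureSet(intervals)


def write_bed(features: FeatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in features:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.feature_id}\n")


# ---------------------------------------------------------------------------
# TSS annotation


def read_tss(path: str | Path) -> list[TssRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    needed = {"gene_id", "chrom", "tss", "strand", "protein_coding"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"{path}: TSS table missing columns {sorted(missing)}")
    coding = df["protein_coding"]
    if coding.dtype != bool:
        coding = coding.astype(str).str.lower().isin(("true", "1", "yes"))
    return [
        TssRecord(r.gene_id, r.chrom, int(r.tss), r.strand, bool(c))
        for r, c in zip(df.itertuples(index=False), coding)
    ]


def write_tss(records: Sequence[TssRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "chrom": [r.chrom for r in records],
            "tss": [r.tss for r in records],
            "strand": [r.strand for r in records],
            "protein_coding": [r.protein_coding for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample design


def read_design(path: str | Path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.frame.reset_index(names="sample_id").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices


def read_counts(path: str | Path, design: SampleDesign) -> CountMatrix:
    """Read a features x samples TSV of integer counts.

    Columns are re-ordered to the design's sample order; every design sample
    must be present in the file and vice versa.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    unknown = [c for c in df.columns if c not in design]
    if unknown:
        raise DesignMismatchError(
            f"{path}: sample columns absent from design: {unknown[:5]}"
        )
    absent = [s for s in design.sample_ids if s not in df.columns]
    if absent:
        raise DesignMismatchError(
            f"{path}: design samples missing from counts: {absent[:5]}"
        )
    values = df[design.sample_ids]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()][0]
        raise ParseError(f"{path}: non-numeric count in column {bad!r}")
    if (numeric.values < 0).any():
        raise ParseError(f"{path}: negative count encountered")
    return CountMatrix(numeric.astype(int), design)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Memory-call reports


def write_report(calls: MemoryCallSet, path: str | Path) -> None:
    """Write a call set as TSV plus a JSON sidecar of run parameters.

    The sidecar lives next to the TSV with a ``.params.json`` suffix.
    """
    path = Path(path)
    calls.calls.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".params.json")
    with open(sidecar, "w") as fh:
        json.dump(calls.params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_report(path: str | Path) -> MemoryCallSet:
    path = Path(path)
    calls = pd.read_csv(path, sep="\t", index_col=0)
    calls.index = calls.index.astype(str)
    sidecar = path.with_suffix(path.suffix + ".params.json")
    params: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            params = json.load(fh)
    return MemoryCallSet(calls, params)
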