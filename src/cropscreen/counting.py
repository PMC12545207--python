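"""Guide and guide x UMI counting from raw paired reads.

Read 1 carries ``stagger + anchor + spacer``; extraction scans the permitted
stagger lengths in increasing order and accepts the first offset where the
anchor matches within the mismatch budget. Spacers are then matched exactly
(zero mismatches) against the library via a hash lookup. For UMI-tagged
readouts the UMI is a configurable slice of read 2 and any record whose UMI
contains an N is discarded before counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam

from .synthetic import DEFAULT_ANCHOR, GuideLibrary


@dataclass
class ReadLayout:
    """Positional layout of the single-guide read architecture."""

    stagger_lengths: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    anchor: str = DEFAULT_ANCHOR
    spacer_length: int = 20
    umi_slice: tuple[int, int] = (0, 26)
    max_anchor_mismatches: int = 1

    def __post_init__(self) -> None:
        if not self.anchor:
            raise ValueError("anchor must be nonempty")
        if self.spacer_length < 15:
            raise ValueError("spacer_length must be >= 15")
        lo, hi = self.umi_slice
        if not (0 <= lo < hi):
            raise ValueError("umi_slice must be a nonempty half-open interval")


@dataclass
class CountQC:
    """Per-sample counting quality metrics."""

    total_reads: int = 0
    mapped_reads: int = 0
    zero_count_guides: int = 0
    gini: float | None = None
    trim_zero_fraction: float = 0.0
    umi_n_discarded: int = 0

    @property
    def alignment_rate(self) -> float:
        return self.mapped_reads / self.total_reads if self.total_reads else 0.0

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "mapped_reads": self.mapped_reads,
            "alignment_rate": self.alignment_rate,
            "zero_count_guides": self.zero_count_guides,
            "gini": self.gini,
            "trim_zero_fraction": self.trim_zero_fraction,
            "umi_n_discarded": self.umi_n_discarded,
        }


@dataclass
class UmiCountTable:
    """Per-sample (guide, UMI) -> read count triples; UMIs never contain N."""

    sample: str
    entries: pd.DataFrame  # columns: guide_id, umi, count

    def __post_init__(self) -> None:
        df = self.entries
        required = {"guide_id", "umi", "count"}
        if set(df.columns) < required:
            raise ValueError(f"UMI table requires columns {sorted(required)}")
        if len(df):
            if df["umi"].str.contains("N").any():
                raise ValueError("UMI table contains an N-bearing UMI")
            if (df["count"] < 1).any():
                raise ValueError("UMI counts must be >= 1")
            if df.duplicated(["guide_id", "umi"]).any():
                raise ValueError("(guide, umi) pairs must be unique per sample")

    @property
    def total(self) -> int:
        return int(self.entries["count"].sum())

    def collapse(self, guide_order: list[str] | None = None) -> pd.Series:
        """Per-guide counts summed over UMIs (zeros kept when order given)."""
        s = self.entries.groupby("guide_id")["count"].sum()
        if guide_order is not None:
            s = s.reindex(guide_order, fill_value=0)
        return s.astype(int)

    def per_umi(self) -> pd.Series:
        """Reads per UMI summed over guides."""
        return self.entries.groupby("umi")["count"].sum().astype(int)

    def to_tsv(self, path: str | Path) -> None:
        out = self.entries.copy()
        out.insert(0, "sample", self.sample)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "UmiCountTable":
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype={"sample": str, "guide_id": str, "umi": str}
        )
        sample = df["sample"].iloc[0] if len(df) else "sample"
        return cls(sample, df[["guide_id", "umi", "count"]].reset_index(drop=True))


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_spacer(read1: str, layout: ReadLayout) -> tuple[str, int] | None:
    """Locate the anchor and return (spacer, stagger length), or None for no hit.

    Stagger lengths are scanned in increasing order; the first offset where the
    anchor matches with at most ``max_anchor_mismatches`` mismatches wins.
    """
    la = len(layout.anchor)
    for stag in sorted(layout.stagger_lengths):
        end = stag + la + layout.spacer_length
        if end > len(read1):
            continue
        if hamming(read1[stag : stag + la], layout.anchor) <= layout.max_anchor_mismatches:
            return read1[stag + la : end], stag
    return None


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence


def gini_index(counts) -> float | None:
    """Gini index of a non-negative count vector.

    Equal to the mean absolute difference over all ordered pairs divided by
    twice the mean: ``G = sum_ij |x_i - x_j| / (2 n^2 mu)``. Computed via the
    equivalent sorted-weight formula. Returns None for an all-zero vector.
    """
    x = np.asarray(counts, dtype=np.float64)
    if x.size == 0 or (x < 0).any():
        raise ValueError("counts must be a nonempty non-negative vector")
    total = x.sum()
    if total == 0:
        return None
    x = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * total))


def count_guides(
    r1: str | Path | Iterable[tuple[str, str]],
    r2: str | Path | Iterable[tuple[str, str]] | None,
    library: GuideLibrary,
    layout: ReadLayout | None = None,
    with_umi: bool = False,
    sample: str = "sample1",
) -> tuple[pd.Series, UmiCountTable | None, CountQC]:
    """Count reads per guide (and per guide x UMI) for one sample.

    Returns a per-guide count Series ordered as the library (zeros kept), an
    optional :class:`UmiCountTable`, and :class:`CountQC`. Spacer matching is
    exact; reads whose spacer is not in the library are dropped and recorded
    in QC. When ``with_umi``, reads whose UMI slice contains an N are
    discarded before counting.
    """
    layout = layout or ReadLayout()
    reads1 = _iter_fastq(r1) if isinstance(r1, (str, Path)) else iter(r1)
    if with_umi:
        if r2 is None:
            raise ValueError("with_umi requires read 2")
        reads2 = _iter_fastq(r2) if isinstance(r2, (str, Path)) else iter(r2)
    else:
        reads2 = None

    spacer_map = library.spacer_to_guide
    counts: dict[str, int] = {g: 0 for g in library.guide_ids}
    umi_counts: dict[tuple[str, str], int] = {}
    qc = CountQC()
    n_no_anchor = 0
    lo, hi = layout.umi_slice

    for name1, seq1 in reads1:
        qc.total_reads += 1
        if reads2 is not None:
            try:
                name2, seq2 = next(reads2)
            except StopIteration as exc:
                raise ValueError("read 2 stream shorter than read 1 stream") from exc
        hit = extract_spacer(seq1, layout)
        if hit is None:
            n_no_anchor += 1
            continue
        spacer, _stagger = hit
        guide = spacer_map.get(spacer)
        if guide is None:
            continue
        if reads2 is not None:
            umi = seq2[lo:hi]
            if "N" in umi:
                qc.umi_n_discarded += 1
                continue
            umi_counts[(guide, umi)] = umi_counts.get((guide, umi), 0) + 1
        counts[guide] += 1
        qc.mapped_reads += 1

    count_series = pd.Series(counts, name=sample).reindex(library.guide_ids)
    qc.zero_count_guides = int((count_series == 0).sum())
    qc.gini = gini_index(count_series.to_numpy()) if count_series.sum() > 0 else None
    qc.trim_zero_fraction = n_no_anchor / qc.total_reads if qc.total_reads else 0.0

    umi_table = None
    if with_umi:
        if umi_counts:
            rows = pd.DataFrame(
                [(g, u, c) for (g, u), c in umi_counts.items()],
                columns=["guide_id", "umi", "count"],
            ).sort_values(["guide_id", "umi"], ignore_index=True)
        else:
            rows = pd.DataFrame(columns=["guide_id", "umi", "count"])
        umi_table = UmiCountTable(sample, rows)
    return count_series, umi_table, qc


@dataclass
class SampleQCThresholds:
    """Inclusive per-sample QC thresholds (pass requires >= each value)."""

    min_alignment_rate: float = 0.625
    min_reads_per_cell: float = 2.0
    min_reads_per_guide: float = 100.0


@dataclass
class SampleQCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)


def apply_sample_qc(
    qc: CountQC,
    thresholds: SampleQCThresholds | None = None,
    reads_per_cell: float | None = None,
    reads_per_guide: float | None = None,
) -> SampleQCResult:
    """Evaluate sample-level QC rules; thresholds are inclusive (>= passes)."""
    t = thresholds or SampleQCThresholds()
    reasons = []
    if qc.alignment_rate < t.min_alignment_rate:
        reasons.append(f"alignment<{t.min_alignment_rate}")
    if reads_per_cell is not None and reads_per_cell < t.min_reads_per_cell:
        reasons.append(f"reads_per_cell<{t.min_reads_per_cell}")
    if reads_per_guide is not None and reads_per_guide < t.min_reads_per_guide:
        reasons.append(f"reads_per_guide<{t.min_reads_per_guide}")
    return SampleQCResult(passed=not reasons, reasons=reasons)


def write_count_table(
    counts: pd.DataFrame | pd.Series,
    library: GuideLibrary,
    path: str | Path,
) -> None:
    """Write counts in the standard screen dialect: sgRNA, gene, one column per sample."""
    if isinstance(counts, pd.Series):
        counts = counts.to_frame()
    out = counts.reindex(library.guide_ids).fillna(0).astype(int)
    out.insert(0, "gene", [library.gene_of(g) for g in out.index])
    out.index.name = "sgRNA"
    out.reset_index().to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a count table written by :func:`write_count_table`.

    Returns a DataFrame indexed by sgRNA with a leading ``gene`` column.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sgRNA" not in df.columns or "gene" not in df.columns:
        raise ValueError("count table must have 'sgRNA' and 'gene' columns")
    return df.set_index("sgRNA")
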