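"""Dual-guide screen processing: positional feature extraction, zero-mismatch
library matching, recombination detection, and representation QC.

A read pair carries four positional features (spacer1, iBAR1, spacer2, iBAR2).
A read is *matched* when the joint 4-tuple equals a library construct,
*recombinant* when each spacer-iBAR half matches some library row but the
combination matches none (template switching), and *unmatched* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import BASES, _apply_errors, _fastq_record


@dataclass(frozen=True)
class DualConstruct:
    construct_id: str
    spacer1: str
    ibar1: str
    spacer2: str
    ibar2: str
    gene1: str
    gene2: str


class DualLibrary:
    """Dual-gRNA construct library with unique (spacer, iBAR) pairings per position."""

    def __init__(self, constructs: Sequence[DualConstruct]):
        constructs = list(constructs)
        if not constructs:
            raise ValueError("dual library must be nonempty")
        ibar_lengths = {len(c.ibar1) for c in constructs} | {len(c.ibar2) for c in constructs}
        if len(ibar_lengths) != 1:
            raise ValueError("iBAR length must be uniform across the library")
        self.constructs = constructs
        self.ibar_length = ibar_lengths.pop()
        self.by_tuple = {
            (c.spacer1, c.ibar1, c.spacer2, c.ibar2): c.construct_id for c in constructs
        }
        if len(self.by_tuple) != len(constructs):
            raise ValueError("duplicate (spacer1, ibar1, spacer2, ibar2) tuples in library")
        self.halves1 = {(c.spacer1, c.ibar1) for c in constructs}
        self.halves2 = {(c.spacer2, c.ibar2) for c in constructs}
        self._by_id = {c.construct_id: c for c in constructs}

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self):
        return iter(self.constructs)

    def __getitem__(self, construct_id: str) -> DualConstruct:
        return self._by_id[construct_id]

    @property
    def construct_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([c.__dict__ for c in self.constructs]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DualLibrary":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        required = {"construct_id", "spacer1", "ibar1", "spacer2", "ibar2", "gene1", "gene2"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dual library missing columns: {sorted(missing)}")
        return cls(
            [
                DualConstruct(
                    r.construct_id, r.spacer1, r.ibar1, r.spacer2, r.ibar2, r.gene1, r.gene2
                )
                for r in df.itertuples()
            ]
        )


@dataclass
class DualLayout:
    """Fixed offsets/lengths of the four positional features.

    Defaults place spacer1+iBAR1 at the start of read 1 and spacer2+iBAR2 at
    the start of read 2 (synthetic layout; real layouts are config-driven).
    """

    spacer_length: int = 20
    ibar_length: int = 6
    spacer1_offset: int = 0
    spacer2_offset: int = 0

    @property
    def ibar1_offset(self) -> int:
        return self.spacer1_offset + self.spacer_length

    @property
    def ibar2_offset(self) -> int:
        return self.spacer2_offset + self.spacer_length


@dataclass
class DualMatch:
    classification: str  # matched | recombinant | unmatched
    construct_id: str | None = None
    features: tuple[str, str, str, str] | None = None


@dataclass
class DualQC:
    percent_perfect: float
    percent_recombination: float
    fold_10_90: float
    n_matched: int
    n_recombinant: int
    n_unmatched: int
    fold_flagged: bool = False


def extract_dual_features(
    read1: str, read2: str, layout: DualLayout | None = None
) -> tuple[str, str, str, str] | None:
    """Pure positional slicing of the four features; None if a read is too short."""
    layout = layout or DualLayout()
    end1 = layout.ibar1_offset + layout.ibar_length
    end2 = layout.ibar2_offset + layout.ibar_length
    if len(read1) < end1 or len(read2) < end2:
        return None
    return (
        read1[layout.spacer1_offset : layout.spacer1_offset + layout.spacer_length],
        read1[layout.ibar1_offset : end1],
        read2[layout.spacer2_offset : layout.spacer2_offset + layout.spacer_length],
        read2[layout.ibar2_offset : end2],
    )


def match_dual(
    features: tuple[str, str, str, str] | None, library: DualLibrary
) -> DualMatch:
    """Classify one read's features against the library (zero mismatches)."""
    if features is None:
        return DualMatch("unmatched")
    construct_id = library.by_tuple.get(features)
    if construct_id is not None:
        return DualMatch("matched", construct_id=construct_id, features=features)
    s1, b1, s2, b2 = features
    if (s1, b1) in library.halves1 and (s2, b2) in library.halves2:
        return DualMatch("recombinant", features=features)
    return DualMatch("unmatched", features=features)


def count_dual(
    read_pairs: Iterable[tuple[str, str]],
    library: DualLibrary,
    layout: DualLayout | None = None,
) -> tuple[pd.Series, list[DualMatch]]:
    """Count matched reads per construct; returns (counts, all classifications)."""
    layout = layout or DualLayout()
    counts = {c: 0 for c in library.construct_ids}
    matches: list[DualMatch] = []
    for r1, r2 in read_pairs:
        m = match_dual(extract_dual_features(r1, r2, layout), library)
        if m.classification == "matched":
            counts[m.construct_id] += 1
        matches.append(m)
    return pd.Series(counts, name="count"), matches


def dual_qc(matches: Sequence[DualMatch], construct_counts: pd.Series) -> DualQC:
    """Representation and recombination QC over classified reads.

    ``percent_recombination`` uses classifiable reads (matched + recombinant)
    as the denominator; ``fold_10_90`` is the ratio of the 90th to the 10th
    percentile (linear interpolation) of per-construct matched counts.
    """
    if not len(matches):
        raise ValueError("at least one read must be processed")
    n_matched = sum(m.classification == "matched" for m in matches)
    n_recomb = sum(m.classification == "recombinant" for m in matches)
    n_unmatched = len(matches) - n_matched - n_recomb
    classifiable = n_matched + n_recomb
    p10, p90 = np.percentile(construct_counts.to_numpy(dtype=float), [10, 90])
    flagged = False
    if p10 <= 0:
        fold = float("inf")
        flagged = True
    else:
        fold = float(p90 / p10)
    return DualQC(
        percent_perfect=n_matched / len(matches),
        percent_recombination=(n_recomb / classifiable) if classifiable else 0.0,
        fold_10_90=fold,
        n_matched=n_matched,
        n_recombinant=n_recomb,
        n_unmatched=n_unmatched,
        fold_flagged=flagged,
    )


def position_effect(
    gene_lfc: pd.DataFrame, essential_genes: set[str] | list[str]
) -> pd.DataFrame:
    """Essential-gene mean lfc for position-1-only vs position-2-only constructs.

    ``gene_lfc`` needs columns gene1, gene2, lfc. A construct is
    position-1-only when gene1 is essential and gene2 is not, and vice versa.
    """
    essential = set(essential_genes)
    e1 = gene_lfc["gene1"].isin(essential)
    e2 = gene_lfc["gene2"].isin(essential)
    rows = []
    for position, mask in (("position1", e1 & ~e2), ("position2", e2 & ~e1)):
        sub = gene_lfc.loc[mask, "lfc"]
        if len(sub):
            rows.append({"position": position, "n": len(sub), "mean_lfc": float(sub.mean())})
    return pd.DataFrame(rows, columns=["position", "n", "mean_lfc"])


def pair_interaction(
    pair_lfc: pd.Series,
    single_lfc: dict[str, float],
) -> pd.Series:
    """Interaction score: pair lfc minus the sum of the corresponding
    single-gene (gene + safe-harbour pair) lfcs. ``pair_lfc`` is indexed by
    (gene1, gene2) tuples; ``single_lfc`` maps gene -> single-knockout lfc."""
    out = {}
    for (g1, g2), v in pair_lfc.items():
        out[(g1, g2)] = v - single_lfc.get(g1, 0.0) - single_lfc.get(g2, 0.0)
    return pd.Series(out, name="interaction")


# ---------------------------------------------------------------------------
# Synthetic dual-read generation (recombination knob lives here)
# ---------------------------------------------------------------------------

def make_dual_library(
    genes: Sequence[str],
    guides_per_gene: int = 2,
    ibar_length: int = 6,
    seed: int = 0,
    include_self_pairs: bool = True,
) -> DualLibrary:
    """Random dual library covering all pairwise gene combinations."""
    rng = np.random.default_rng(seed)
    used: set[str] = set()

    def seq(n: int) -> str:
        while True:
            s = "".join(BASES[b] for b in rng.integers(0, 4, size=n))
            if s not in used:
                used.add(s)
                return s

    # one (spacer, ibar) unit per gene per position per guide index
    units1 = {(g, j): (seq(20), seq(ibar_length)) for g in genes for j in range(guides_per_gene)}
    units2 = {(g, j): (seq(20), seq(ibar_length)) for g in genes for j in range(guides_per_gene)}
    constructs = []
    for i, g1 in enumerate(genes):
        for g2 in genes[i:]:
            if g1 == g2 and not include_self_pairs:
                continue
            for j1 in range(guides_per_gene):
                for j2 in range(guides_per_gene):
                    s1, b1 = units1[(g1, j1)]
                    s2, b2 = units2[(g2, j2)]
                    constructs.append(
                        DualConstruct(
                            f"{g1}.g{j1 + 1}__{g2}.g{j2 + 1}", s1, b1, s2, b2, g1, g2
                        )
                    )
    return DualLibrary(constructs)


def make_unique_dual_library(
    n_constructs: int,
    ibar_length: int = 6,
    seed: int = 0,
) -> DualLibrary:
    """Dual library in which every construct has private halves.

    No cross-combination of two different constructs exists in the library,
    so every template-switching event is detectable as recombinant. Useful
    for calibrating the recombination estimator.
    """
    rng = np.random.default_rng(seed)
    used: set[str] = set()

    def seq(n: int) -> str:
        while True:
            s = "".join(BASES[b] for b in rng.integers(0, 4, size=n))
            if s not in used:
                used.add(s)
                return s

    constructs = [
        DualConstruct(
            f"C{i + 1:04d}", seq(20), seq(ibar_length), seq(20), seq(ibar_length),
            f"GENE{i + 1:04d}A", f"GENE{i + 1:04d}B",
        )
        for i in range(n_constructs)
    ]
    return DualLibrary(constructs)


def emit_dual_reads(
    library: DualLibrary,
    n_reads: int,
    recombination_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
    weights: pd.Series | None = None,
    r1_path: str | Path | None = None,
    r2_path: str | Path | None = None,
    layout: DualLayout | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate dual-construct read pairs with a template-switching knob.

    With probability ``recombination_rate`` a read combines the position-1
    half of one construct with the position-2 half of a *different* construct.
    Returns (read pairs, manifest). Optionally writes FASTQ.
    """
    layout = layout or DualLayout()
    rng = np.random.default_rng(seed)
    n_constructs = len(library)
    if weights is not None:
        p = weights.reindex(library.construct_ids).to_numpy(dtype=float)
        p = p / p.sum()
    else:
        p = np.full(n_constructs, 1.0 / n_constructs)
    picks = rng.choice(n_constructs, size=n_reads, p=p)
    recombine = rng.random(n_reads) < recombination_rate
    partner = rng.integers(0, n_constructs - 1, size=n_reads) if n_constructs > 1 else picks

    pairs: list[tuple[str, str]] = []
    manifest_rows = []
    for i in range(n_reads):
        a = library.constructs[picks[i]]
        if recombine[i] and n_constructs > 1:
            j = partner[i]
            if j >= picks[i]:
                j += 1
            b = library.constructs[j]
            r1 = a.spacer1 + a.ibar1
            r2 = b.spacer2 + b.ibar2
            truth = f"{a.construct_id}|{b.construct_id}"
            is_recomb = True
        else:
            r1 = a.spacer1 + a.ibar1
            r2 = a.spacer2 + a.ibar2
            truth = a.construct_id
            is_recomb = False
        r1 = _apply_errors(r1, error_rate, rng)
        r2 = _apply_errors(r2, error_rate, rng)
        pairs.append((r1, r2))
        manifest_rows.append({"read_id": f"dual:{i}", "truth": truth, "recombinant": is_recomb})

    manifest = pd.DataFrame(manifest_rows)
    if r1_path and r2_path:
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for i, (r1, r2) in enumerate(pairs):
                f1.write(_fastq_record(f"dual:{i}", r1))
                f2.write(_fastq_record(f"dual:{i}", r2))
    return pairs, manifest
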