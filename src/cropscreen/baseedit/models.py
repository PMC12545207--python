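"""Domain types for base-editing design: gene models, editors, guides, outcomes.

Spacer positions are numbered 1..20 from the PAM-distal end (standard
base-editing convention); genomic coordinates are 0-based half-open on the
gene model's own sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

#: Consequence classes ordered most to least severe.
SEVERITY_ORDER = ("nonsense", "splice_site", "missense", "silent", "utr", "intron")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class EditorSpec:
    """A base editor: one fixed conversion on the protospacer strand plus windows."""

    editor_name: str
    ref_base: str  # base converted, read on the protospacer strand
    alt_base: str
    pam_mode: str = "NGG"  # "NGG" or "pamless"
    design_window: tuple[int, int] = (5, 7)  # 1-based inclusive spacer positions
    self_edit_window: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        if (self.ref_base, self.alt_base) not in (("A", "G"), ("C", "T")):
            raise ValueError("conversion must be A->G or C->T on the protospacer strand")
        for lo, hi in (self.design_window, self.self_edit_window):
            if not (1 <= lo <= hi <= 20):
                raise ValueError("editor windows must lie within spacer positions 1-20")
        if self.pam_mode not in ("NGG", "pamless"):
            raise ValueError("pam_mode must be 'NGG' or 'pamless'")

    def with_pam_mode(self, pam_mode: str) -> "EditorSpec":
        return EditorSpec(
            f"{self.editor_name}-{pam_mode}", self.ref_base, self.alt_base,
            pam_mode, self.design_window, self.self_edit_window,
        )


ABE = EditorSpec("ABE", "A", "G")
CBE = EditorSpec("CBE", "C", "T")


@dataclass(frozen=True)
class EditOutcome:
    """Predicted consequence of converting one genomic base."""

    position: int  # genomic, 0-based on the model sequence
    ref: str
    alt: str
    consequence: str
    codon_change: tuple[str, str] | None = None
    residue: int | None = None  # 1-based protein residue, when coding
    aa_change: str | None = None  # e.g. "K16R", "Q30*"

    def __post_init__(self) -> None:
        if self.consequence not in SEVERITY_ORDER:
            raise ValueError(f"unknown consequence {self.consequence!r}")


@dataclass
class BaseEditGuide:
    """One designed tiling guide with predicted edits and exclusion flags."""

    guide_id: str
    spacer: str
    pam: str
    strand: str  # "+" or "-"
    start: int  # genomic start of the protospacer (0-based, plus-strand coords)
    category: str = "target"
    editable_positions: list[int] = field(default_factory=list)
    predicted_edits: list[EditOutcome] = field(default_factory=list)
    excluded: dict[str, bool] = field(default_factory=lambda: {"t_stretch": False, "bsmbi": False})

    @property
    def is_excluded(self) -> bool:
        return any(self.excluded.values())

    def genomic_position(self, spacer_pos: int) -> int:
        """Genomic coordinate of a 1-based spacer position (PAM-distal = 1)."""
        if not (1 <= spacer_pos <= len(self.spacer)):
            raise ValueError("spacer position out of range")
        if self.strand == "+":
            return self.start + spacer_pos - 1
        return self.start + len(self.spacer) - spacer_pos


class GeneModel:
    """A gene with sequence, exon structure and CDS on its own coordinate system.

    ``exons`` and ``cds`` are sorted, non-overlapping, 0-based half-open
    intervals on ``sequence``. ``strand`` is the strand the CDS is encoded on
    relative to the given sequence. The spliced CDS must translate without an
    internal stop codon.
    """

    def __init__(
        self,
        name: str,
        sequence: str,
        exons: list[tuple[int, int]],
        cds: list[tuple[int, int]],
        strand: str = "+",
        flank: int = 20,
    ):
        sequence = sequence.upper()
        self._validate_intervals(exons, len(sequence), "exons")
        self._validate_intervals(cds, len(sequence), "cds")
        for c_lo, c_hi in cds:
            if not any(e_lo <= c_lo and c_hi <= e_hi for e_lo, e_hi in exons):
                raise ValueError("every CDS interval must lie within an exon")
        if strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        self.name = name
        self.sequence = sequence
        self.exons = sorted(exons)
        self.cds = sorted(cds)
        self.strand = strand
        self.flank = flank
        protein = self.translate()
        if "*" in protein[:-1]:
            raise ValueError("spliced CDS contains an internal stop codon")

    @staticmethod
    def _validate_intervals(intervals, seq_len, what):
        prev_end = -1
        for lo, hi in sorted(intervals):
            if not (0 <= lo < hi <= seq_len):
                raise ValueError(f"{what} interval ({lo}, {hi}) out of bounds")
            if lo < prev_end:
                raise ValueError(f"{what} intervals overlap")
            prev_end = hi

    # -- sequence access ----------------------------------------------------

    def spliced_cds(self, sequence: str | None = None) -> str:
        seq = sequence if sequence is not None else self.sequence
        spliced = "".join(seq[lo:hi] for lo, hi in self.cds)
        return revcomp(spliced) if self.strand == "-" else spliced

    def translate(self, sequence: str | None = None) -> str:
        cds = self.spliced_cds(sequence)
        usable = len(cds) - len(cds) % 3
        return str(Seq(cds[:usable]).translate())

    # -- coordinate queries -------------------------------------------------

    def design_region(self) -> list[tuple[int, int]]:
        """Exons extended by ``flank`` bases into each intron or UTR, merged."""
        extended = sorted(
            (max(0, lo - self.flank), min(len(self.sequence), hi + self.flank))
            for lo, hi in self.exons
        )
        merged: list[tuple[int, int]] = []
        for lo, hi in extended:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        return merged

    def overlaps_design_region(self, lo: int, hi: int) -> bool:
        return any(lo < r_hi and r_lo < hi for r_lo, r_hi in self.design_region())

    def splice_site_positions(self) -> set[int]:
        """The two intronic bases flanking each internal exon boundary."""
        positions: set[int] = set()
        n = len(self.exons)
        for i, (lo, hi) in enumerate(self.exons):
            if i > 0:  # intron precedes this exon
                positions.update(p for p in (lo - 2, lo - 1) if p >= 0)
            if i < n - 1:  # intron follows this exon
                positions.update(p for p in (hi, hi + 1) if p < len(self.sequence))
        return positions

    def cds_index(self, position: int) -> int | None:
        """Index of a genomic position within the spliced CDS, or None."""
        offset = 0
        for lo, hi in self.cds:
            if lo <= position < hi:
                idx = offset + (position - lo)
                if self.strand == "-":
                    total = sum(h - l for l, h in self.cds)
                    return total - 1 - idx
                return idx
            offset += hi - lo
        return None

    def in_exon(self, position: int) -> bool:
        return any(lo <= position < hi for lo, hi in self.exons)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_genbank(cls, path: str | Path, flank: int = 20) -> "GeneModel":
        """Build from a GenBank record with exon and CDS features."""
        from Bio import SeqIO

        record = SeqIO.read(str(path), "genbank")
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        strand = "+"
        for feature in record.features:
            parts = [(int(p.start), int(p.end)) for p in feature.location.parts]
            if feature.type == "exon":
                exons.extend(parts)
            elif feature.type == "CDS":
                cds.extend(parts)
                if feature.location.strand == -1:
                    strand = "-"
        if not exons:
            exons = list(cds)
        return cls(record.id, str(record.seq), exons, cds, strand=strand, flank=flank)

    @classmethod
    def from_gff3(
        cls, gff_path: str | Path, fasta_path: str | Path, gene_name: str, flank: int = 20
    ) -> "GeneModel":
        """Build from a GFF3 file plus FASTA (features exon/CDS of one gene)."""
        import gffutils
        from Bio import SeqIO

        db = gffutils.create_db(
            str(gff_path), dbfn=":memory:", merge_strategy="merge", keep_order=True
        )
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        exons, cds = [], []
        seqid = None
        strand = "+"
        for ftype, bucket in (("exon", exons), ("CDS", cds)):
            for feat in db.features_of_type(ftype):
                parents = feat.attributes.get("Parent", []) + feat.attributes.get("gene_id", [])
                names = feat.attributes.get("gene_name", []) + parents
                if gene_name not in names and feat.id != gene_name:
                    continue
                bucket.append((feat.start - 1, feat.end))
                seqid = feat.seqid
                strand = feat.strand
        if not exons and not cds:
            raise ValueError(f"no exon/CDS features found for gene {gene_name!r}")
        if not exons:
            exons = list(cds)
        if seqid not in seqs:
            raise ValueError(f"sequence {seqid!r} not present in FASTA")
        return cls(gene_name, seqs[seqid], exons, cds, strand=strand, flank=flank)
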