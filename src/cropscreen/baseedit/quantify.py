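"""Self-editing-aware counting references and amplicon editing quantification."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .models import EditorSpec


@dataclass
class ExpandedReference:
    """Spacer-variant lookup mapping every sequence to its parent guide.

    Contains each original spacer plus every sequence obtainable by editing
    any non-empty subset of editor-ref bases inside the self-editing window.
    Variants colliding across parents are dropped (with a warning); original
    spacers always survive.
    """

    variant_to_parent: dict[str, str]
    n_variants_per_parent: dict[str, int]
    dropped_collisions: list[str] = field(default_factory=list)

    def lookup(self, sequence: str) -> str | None:
        return self.variant_to_parent.get(sequence)


def self_edit_variants(spacer: str, editor: EditorSpec) -> list[str]:
    """All spacer sequences reachable by self-editing in the editor window.

    Every non-empty subset of editor-ref bases at window positions is
    converted; for m such bases this yields 2^m - 1 variants.
    """
    lo, hi = editor.self_edit_window
    editable = [p for p in range(lo, hi + 1) if spacer[p - 1] == editor.ref_base]
    variants = []
    for r in range(1, len(editable) + 1):
        for subset in itertools.combinations(editable, r):
            chars = list(spacer)
            for p in subset:
                chars[p - 1] = editor.alt_base
            variants.append("".join(chars))
    return variants


def expand_self_edit_reference(library, editor: EditorSpec) -> ExpandedReference:
    """Build the expanded matching reference for one editor chemistry.

    ``library`` is any iterable of records with ``guide_id`` and ``spacer``
    attributes and unique spacers (e.g. a GuideLibrary).
    """
    records = list(library)
    originals = {r.spacer: r.guide_id for r in records}
    if len(originals) != len(records):
        raise ValueError("library spacers must be unique")

    variant_to_parent = dict(originals)
    n_variants = {r.guide_id: 0 for r in records}
    dropped: list[str] = []
    for r in records:
        for variant in self_edit_variants(r.spacer, editor):
            if variant in originals:
                if originals[variant] != r.guide_id:
                    dropped.append(variant)
                    warnings.warn(
                        f"self-edit variant of {r.guide_id!r} collides with original "
                        f"spacer of {originals[variant]!r}; variant dropped"
                    )
                continue
            owner = variant_to_parent.get(variant)
            if owner is not None and owner != r.guide_id:
                # cross-parent collision between two variants: drop entirely
                del variant_to_parent[variant]
                n_variants[owner] -= 1
                dropped.append(variant)
                warnings.warn(
                    f"self-edit variant shared by {owner!r} and {r.guide_id!r} dropped"
                )
                continue
            if owner is None:
                variant_to_parent[variant] = r.guide_id
                n_variants[r.guide_id] += 1
    return ExpandedReference(variant_to_parent, n_variants, dropped)


def count_with_expanded_reference(
    spacers: Iterable[str], reference: ExpandedReference
) -> tuple[dict[str, int], int, int]:
    """Exact-match spacer sequences against an expanded reference.

    Returns (per-parent counts, n_matched, n_total).
    """
    counts: dict[str, int] = {}
    n_matched = 0
    n_total = 0
    for sp in spacers:
        n_total += 1
        parent = reference.lookup(sp)
        if parent is None:
            continue
        counts[parent] = counts.get(parent, 0) + 1
        n_matched += 1
    return counts, n_matched, n_total


@dataclass
class EditingQuantResult:
    fraction_edited: float
    n_edited: int
    n_aligned: int
    n_excluded: int


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    return aligner


def quantify_editing(
    reads: Iterable[str],
    reference: str,
    expected_conversions: Sequence[tuple[int, str, str]],
    min_identity: float = 0.5,
) -> EditingQuantResult:
    """Fraction of amplicon reads carrying an intended base conversion.

    Each read is globally aligned to the reference (substitutions and gaps).
    A read counts as edited iff the alignment contains at least one expected
    ref->alt conversion at an expected site and no insertions or deletions.
    ``expected_conversions`` entries are (0-based reference position, ref
    base, alt base). Reads whose best alignment identity falls below
    ``min_identity`` are excluded and reported.
    """
    reference = reference.upper()
    for pos, ref_base, _alt in expected_conversions:
        if not (0 <= pos < len(reference)) or reference[pos] != ref_base:
            raise ValueError(f"expected conversion at {pos} does not match the reference")

    aligner = _make_aligner()
    n_edited = n_aligned = n_excluded = 0
    expected = {(pos, alt) for pos, _ref, alt in expected_conversions}

    for read in reads:
        read = read.upper()
        if not read:
            n_excluded += 1
            continue
        alignment = aligner.align(reference, read)[0]
        ref_aln, read_aln = alignment[0], alignment[1]
        matches = sum(a == b for a, b in zip(ref_aln, read_aln) if a != "-" and b != "-")
        if matches / max(len(reference), len(read)) < min_identity:
            n_excluded += 1
            continue
        n_aligned += 1
        has_indel = "-" in ref_aln or "-" in read_aln
        if has_indel:
            continue
        ref_pos = 0
        n_conversions = 0
        for a, b in zip(ref_aln, read_aln):
            if a != "-":
                if b != "-" and (ref_pos, b) in expected and a != b:
                    n_conversions += 1
                ref_pos += 1
        if n_conversions >= 1:
            n_edited += 1
    fraction = n_edited / n_aligned if n_aligned else 0.0
    return EditingQuantResult(fraction, n_edited, n_aligned, n_excluded)
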