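"""Rule-based tiling guide design and edit-outcome prediction.

Guides are enumerated on both strands across the design region (exons
extended into introns/UTRs), filtered for T-stretches and BsmBI sites, and
annotated with per-base editing outcomes by re-translating the spliced CDS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    SEVERITY_ORDER,
    BaseEditGuide,
    EditOutcome,
    EditorSpec,
    GeneModel,
    revcomp,
)

BSMBI_SITES = ("CGTCTC", "GAGACG")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _scan_guides(sequence: str, pam_mode: str, id_prefix: str = "g") -> list[BaseEditGuide]:
    """All 20-mer protospacers on both strands of a raw sequence."""
    sequence = sequence.upper()
    n = len(sequence)
    guides: list[BaseEditGuide] = []
    for i in range(n - 19):
        # plus strand: PAM immediately 3' of the 20-mer
        pam = sequence[i + 20 : i + 23]
        if pam_mode != "NGG" or (len(pam) == 3 and pam[1:] == "GG"):
            guides.append(
                BaseEditGuide(
                    guide_id=f"{id_prefix}_{i}_+", spacer=sequence[i : i + 20],
                    pam=pam, strand="+", start=i,
                )
            )
        # minus strand: protospacer occupies the same genomic window, PAM 5' of it
        pam_m = revcomp(sequence[max(0, i - 3) : i])
        if pam_mode != "NGG" or (len(pam_m) == 3 and pam_m[1:] == "GG"):
            guides.append(
                BaseEditGuide(
                    guide_id=f"{id_prefix}_{i}_-", spacer=revcomp(sequence[i : i + 20]),
                    pam=pam_m, strand="-", start=i,
                )
            )
    return guides


def enumerate_guides(
    model: GeneModel, editor: EditorSpec, category: str = "target"
) -> list[BaseEditGuide]:
    """All guides (pre-filter) whose 20-mer overlaps the design region.

    Both strands are scanned. NGG mode requires the PAM immediately 3' of the
    protospacer on its own strand; pamless mode accepts any PAM. Strand-
    distinct guides sharing a genomic window are kept as separate entries.
    """
    if len(model.sequence) < 20:
        return []
    kept = []
    for g in _scan_guides(model.sequence, editor.pam_mode, id_prefix=model.name):
        if not model.overlaps_design_region(g.start, g.start + 20):
            continue
        g.category = category
        g.editable_positions = [
            p for p in range(1, 21) if g.spacer[p - 1] == editor.ref_base
        ]
        kept.append(g)
    return kept


@dataclass
class FilterResult:
    kept: list[BaseEditGuide] = field(default_factory=list)
    excluded: list[BaseEditGuide] = field(default_factory=list)


def filter_guides(guides: list[BaseEditGuide], bsmbi_context: str = "") -> FilterResult:
    """Apply the library design exclusions.

    ``t_stretch``: spacer contains a run of four or more T. ``bsmbi``: the
    spacer plus PAM (plus optional cloning context appended on both sides)
    contains a BsmBI recognition site on either strand.
    """
    result = FilterResult()
    for g in guides:
        screened = f"{bsmbi_context}{g.spacer}{g.pam}{bsmbi_context}"
        g.excluded["t_stretch"] = "TTTT" in g.spacer
        g.excluded["bsmbi"] = any(site in screened for site in BSMBI_SITES)
        (result.excluded if g.is_excluded else result.kept).append(g)
    return result


def summary_consequence(outcomes: list[EditOutcome]) -> str | None:
    """Most severe single consequence (nonsense > splice_site > missense > silent)."""
    if not outcomes:
        return None
    return min((o.consequence for o in outcomes), key=SEVERITY_ORDER.index)


def predict_edits(
    guide: BaseEditGuide,
    editor: EditorSpec,
    model: GeneModel,
    window: tuple[int, int] | None = None,
) -> list[EditOutcome]:
    """Per-base outcomes of converting every editor-ref base in the window.

    Each outcome is classified by re-translating the spliced CDS with that
    single base converted. Splice-site consequences (the two intronic bases
    at each exon boundary) take precedence over coding classification.
    The guide's ``predicted_edits`` list is updated in place.
    """
    lo, hi = window if window is not None else editor.design_window
    seq = model.sequence
    protein_ref = model.translate()
    splice_sites = model.splice_site_positions()

    outcomes: list[EditOutcome] = []
    for p in range(lo, hi + 1):
        if guide.spacer[p - 1] != editor.ref_base:
            continue
        g_pos = guide.genomic_position(p)
        if guide.strand == "+":
            ref_g, alt_g = editor.ref_base, editor.alt_base
        else:
            ref_g = editor.ref_base.translate(_COMPLEMENT)
            alt_g = editor.alt_base.translate(_COMPLEMENT)
        if seq[g_pos] != ref_g:
            raise ValueError(
                f"guide {guide.guide_id!r} does not map to the model sequence at {g_pos}"
            )
        cds_idx = model.cds_index(g_pos)
        if g_pos in splice_sites:
            outcome = EditOutcome(g_pos, ref_g, alt_g, "splice_site")
        elif cds_idx is not None:
            edited = seq[:g_pos] + alt_g + seq[g_pos + 1 :]
            protein_alt = model.translate(edited)
            residue = cds_idx // 3 + 1
            cds_ref = model.spliced_cds()
            cds_alt = model.spliced_cds(edited)
            codon_from = cds_ref[(residue - 1) * 3 : residue * 3]
            codon_to = cds_alt[(residue - 1) * 3 : residue * 3]
            if residue - 1 >= len(protein_ref):
                outcome = EditOutcome(g_pos, ref_g, alt_g, "utr")
            else:
                aa_from = protein_ref[residue - 1]
                aa_to = protein_alt[residue - 1]
                if aa_to == "*" and aa_from != "*":
                    consequence = "nonsense"
                elif aa_to == aa_from:
                    consequence = "silent"
                else:
                    consequence = "missense"
                outcome = EditOutcome(
                    g_pos, ref_g, alt_g, consequence,
                    codon_change=(codon_from, codon_to),
                    residue=residue, aa_change=f"{aa_from}{residue}{aa_to}",
                )
        elif model.in_exon(g_pos):
            outcome = EditOutcome(g_pos, ref_g, alt_g, "utr")
        else:
            outcome = EditOutcome(g_pos, ref_g, alt_g, "intron")
        outcomes.append(outcome)
    guide.predicted_edits = outcomes
    return outcomes


def design_controls(
    editor: EditorSpec,
    safe_harbour_region: str,
    n: int,
    seed: int,
) -> list[BaseEditGuide]:
    """Safe-harbour control guides satisfying the composition quotas.

    Half the controls carry >=1 A but no C in the editor's design window and
    half carry >=1 C but no A (so each half is non-targeting for one editor
    chemistry); within each half, half have an NGG PAM and half a non-NGG
    PAM. When n is not divisible by 4, remainders are assigned in the fixed
    order A/NGG, A/non-NGG, C/NGG, C/non-NGG.
    """
    if n <= 0:
        return []
    lo, hi = editor.design_window
    candidates = _scan_guides(safe_harbour_region, "pamless", id_prefix="SH")
    cells: dict[tuple[str, str], list[BaseEditGuide]] = {
        ("A", "NGG"): [], ("A", "nonNGG"): [], ("C", "NGG"): [], ("C", "nonNGG"): [],
    }
    for g in candidates:
        window = g.spacer[lo - 1 : hi]
        if "A" in window and "C" not in window:
            base_group = "A"
        elif "C" in window and "A" not in window:
            base_group = "C"
        else:
            continue
        pam_group = "NGG" if (len(g.pam) == 3 and g.pam[1:] == "GG") else "nonNGG"
        cells[(base_group, pam_group)].append(g)

    order = [("A", "NGG"), ("A", "nonNGG"), ("C", "NGG"), ("C", "nonNGG")]
    quotas = {cell: n // 4 for cell in order}
    for i in range(n % 4):
        quotas[order[i]] += 1

    rng = np.random.default_rng(seed)
    selected: list[BaseEditGuide] = []
    for cell in order:
        pool = sorted(cells[cell], key=lambda g: g.guide_id)
        want = quotas[cell]
        if len(pool) < want:
            raise ValueError(
                f"safe-harbour region cannot satisfy quota {cell[0]}-only/{cell[1]}: "
                f"need {want}, have {len(pool)}"
            )
        picks = rng.choice(len(pool), size=want, replace=False)
        for idx in sorted(picks):
            g = pool[idx]
            g.category = "safe_harbour"
            selected.append(g)
    return selected


def select_validation_guides(
    z_scores: pd.DataFrame,
    fraction: float = 0.035,
    direction: str = "enriched",
) -> set[str]:
    """Union of top-fraction guides by mean z across donors and per donor.

    ``z_scores`` is indexed by guide id with one column per donor (>= 2
    donors). The cut is ceil(fraction * n) guides per criterion; ties at the
    cut are broken by guide id. ``direction`` is "enriched" (largest z) or
    "depleted" (smallest z).
    """
    if z_scores.shape[1] < 2:
        raise ValueError("need z-scores from at least two donors")
    if direction not in ("enriched", "depleted"):
        raise ValueError("direction must be 'enriched' or 'depleted'")
    n = len(z_scores)
    k = math.ceil(fraction * n)
    if k == 0:
        return set()

    def top(series: pd.Series) -> set[str]:
        sign = -1.0 if direction == "enriched" else 1.0
        ordered = sorted(series.index, key=lambda g: (sign * series[g], g))
        return set(ordered[:k])

    selected = top(z_scores.mean(axis=1))
    for donor in z_scores.columns:
        selected |= top(z_scores[donor])
    return selected


def mutagenesis_map(
    annotations: pd.DataFrame,
    protein_length: int,
    top_n: int = 15,
    direction: str = "enriched",
) -> pd.DataFrame:
    """Residue-level aggregation of guide z-normalized lfc.

    ``annotations`` has one row per (guide, edited residue) with columns
    guide_id, z_lfc, residue, aa_change, consequence. Guides are filtered to
    missense/nonsense consequences; the per-residue score is the mean z_lfc
    of assigned guides (each guide counted once per residue). The ``top``
    column flags the ``top_n`` residues in the requested direction, labelled
    with the amino-acid change of their strongest guide.
    """
    required = {"guide_id", "z_lfc", "residue", "aa_change", "consequence"}
    if set(annotations.columns) < required:
        raise ValueError(f"annotations require columns {sorted(required)}")
    coding = annotations[annotations["consequence"].isin(["missense", "nonsense"])]
    coding = coding[(coding["residue"] >= 1) & (coding["residue"] <= protein_length)]
    coding = coding.drop_duplicates(["guide_id", "residue"])
    if coding.empty:
        return pd.DataFrame(columns=["residue", "n_guides", "mean_z", "label", "top"])

    sign = -1.0 if direction == "enriched" else 1.0
    rows = []
    for residue, group in coding.groupby("residue"):
        best = group.loc[(sign * group["z_lfc"]).idxmin()]
        rows.append(
            {
                "residue": int(residue),
                "n_guides": group["guide_id"].nunique(),
                "mean_z": float(group["z_lfc"].mean()),
                "label": best["aa_change"],
            }
        )
    table = pd.DataFrame(rows).sort_values("residue", ignore_index=True)
    ranked = table.sort_values(
        "mean_z", ascending=(direction == "depleted"), kind="mergesort"
    )
    top_residues = set(ranked.head(top_n)["residue"])
    table["top"] = table["residue"].isin(top_residues)
    return table
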