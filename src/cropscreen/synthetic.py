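"""Synthetic guide libraries, clonal screen truth, and raw paired reads.

The generator reproduces the statistical structure the downstream analysis
assumes: a guide library with target/control categories, clonal founding via
unique UMIs, a transplantation bottleneck, overdispersed clone growth with
per-gene fitness effects, multinomial depth sampling, per-base substitution
error, and variable-length staggers in read 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Constant 8-base anchor between the stagger and the spacer in read 1.
DEFAULT_ANCHOR = "TTGTGGAA"
#: Guide scaffold sequence appended 3' of the spacer in read 1 (padded/truncated
#: so that every read-1 record is exactly READ1_LENGTH bases).
DEFAULT_SCAFFOLD = "GTTTAAGAGCTAAGCTGGAAACAGCATAGCAAGTTTAAATAAGGCTAGTCCGTTATCA"
#: Constant fill 3' of the UMI in read 2.
DEFAULT_READ2_FILL = "GAATTCGATTTCTTGGCTTTATATAT"

READ1_LENGTH = 50
READ2_LENGTH = 26

BSMBI_SITES = ("CGTCTC", "GAGACG")

CATEGORIES = ("target", "essential", "nonessential", "safe_harbour")


class LibraryConstructionError(RuntimeError):
    """Raised when a valid library cannot be constructed (e.g. spacer collision)."""


@dataclass(frozen=True)
class GuideRecord:
    """One guide in a screening library."""

    guide_id: str
    gene: str
    spacer: str
    category: str

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ValueError(
                f"spacer of {self.guide_id!r} has length {len(self.spacer)}, expected 20"
            )
        if set(self.spacer) - set(BASES):
            raise ValueError(f"spacer of {self.guide_id!r} contains non-ACGT characters")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.guide_id!r}")


class GuideLibrary:
    """An ordered collection of :class:`GuideRecord` with unique ids and spacers."""

    def __init__(self, records: Sequence[GuideRecord]):
        records = list(records)
        if not records:
            raise ValueError("a guide library must contain at least one guide")
        ids = [r.guide_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LibraryConstructionError(f"duplicate guide ids: {dupes}")
        spacer_map: dict[str, str] = {}
        for r in records:
            if r.spacer in spacer_map:
                raise LibraryConstructionError(
                    f"spacer collision between {spacer_map[r.spacer]!r} and {r.guide_id!r}"
                )
            spacer_map[r.spacer] = r.guide_id
        self.records = records
        self.spacer_to_guide = spacer_map
        self._by_id = {r.guide_id: r for r in records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, guide_id: str) -> GuideRecord:
        return self._by_id[guide_id]

    def __contains__(self, guide_id: str) -> bool:
        return guide_id in self._by_id

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.gene)
        return list(seen)

    def gene_of(self, guide_id: str) -> str:
        return self._by_id[guide_id].gene

    def genes_in_category(self, category: str) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if r.category == category:
                seen.setdefault(r.gene)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [r.guide_id for r in self.records],
                "gene": [r.gene for r in self.records],
                "spacer": [r.spacer for r in self.records],
                "category": [r.category for r in self.records],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GuideLibrary":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        required = {"guide_id", "gene", "spacer", "category"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"library table missing columns: {sorted(missing)}")
        return cls(
            [
                GuideRecord(row.guide_id, row.gene, row.spacer, row.category)
                for row in df.itertuples()
            ]
        )


@dataclass
class ScreenDesign:
    """Parameters for one simulated pooled screen."""

    guides_per_gene: int = 8
    n_clones_founding: int = 10_000
    bottleneck_fraction: float = 0.3
    n_generations: int = 10
    fitness_by_gene: dict[str, float] = field(default_factory=dict)
    depth: int = 100_000
    error_rate: float = 0.003
    umi_length: int = 12
    stagger_lengths: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    nb_size: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must lie in [0, 0.1]")
        if not (0.0 < self.bottleneck_fraction <= 1.0):
            raise ValueError("bottleneck_fraction must lie in (0, 1]")
        if self.umi_length > READ2_LENGTH:
            raise ValueError("umi_length exceeds read-2 length")


@dataclass(frozen=True)
class CloneTruth:
    """True state of one founder clone within a simulated sample."""

    umi: str
    guide_id: str
    founding_count: int
    final_count: int


@dataclass
class SimulatedSample:
    """Clone truth for one simulated animal/organ."""

    name: str
    clones: list[CloneTruth]
    degenerate: bool = False

    @property
    def total_final(self) -> int:
        return sum(c.final_count for c in self.clones)


def _random_spacer(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=20))


def _spacer_ok(spacer: str) -> bool:
    if "TTTT" in spacer:
        return False
    return not any(site in spacer for site in BSMBI_SITES)


def make_library(
    n_target_genes: int,
    guides_per_gene: int,
    n_essential: int,
    n_nonessential: int,
    n_safe_harbour: int,
    seed: int,
    max_retries: int = 10_000,
) -> GuideLibrary:
    """Construct a random guide library sized like a validation screen.

    ``n_essential``/``n_nonessential``/``n_safe_harbour`` are counts of control
    *guides*; control guides are grouped into genes of ``guides_per_gene``.
    All spacers are unique, contain no run of four or more T, and carry no
    BsmBI recognition site, so that library guides survive the design filters.
    """
    if min(n_target_genes, guides_per_gene, n_essential, n_nonessential, n_safe_harbour) < 0:
        raise ValueError("all counts must be >= 0")
    n_total = n_target_genes * guides_per_gene + n_essential + n_nonessential + n_safe_harbour
    if n_total < 1:
        raise ValueError("library must contain at least one guide")

    rng = np.random.default_rng(seed)
    used: set[str] = set()

    def draw_spacer() -> str:
        for _ in range(max_retries):
            sp = _random_spacer(rng)
            if _spacer_ok(sp) and sp not in used:
                used.add(sp)
                return sp
        raise LibraryConstructionError("could not draw a unique valid spacer")

    records: list[GuideRecord] = []
    for g in range(n_target_genes):
        gene = f"TG{g + 1:03d}"
        for j in range(guides_per_gene):
            records.append(
                GuideRecord(f"{gene}_g{j + 1}", gene, draw_spacer(), "target")
            )

    def add_controls(n: int, prefix: str, category: str) -> None:
        per_gene = max(guides_per_gene, 1)
        for i in range(n):
            gene = f"{prefix}{i // per_gene + 1:02d}"
            records.append(
                GuideRecord(f"{gene}_g{i % per_gene + 1}", gene, draw_spacer(), category)
            )

    add_controls(n_essential, "ESS", "essential")
    add_controls(n_nonessential, "OR", "nonessential")
    add_controls(n_safe_harbour, "SH", "safe_harbour")
    return GuideLibrary(records)


def default_fitness(
    library: GuideLibrary,
    essential_s: float = -0.3,
    target_s: float = 0.0,
) -> dict[str, float]:
    """Shipped fitness preset: essential genes deplete, everything else neutral."""
    fitness = {g: target_s for g in library.genes_in_category("target")}
    fitness.update({g: essential_s for g in library.genes_in_category("essential")})
    return fitness


def expected_frequencies(library: GuideLibrary, design: ScreenDesign) -> dict[str, float]:
    """Expected per-guide final frequencies under deterministic growth."""
    weights = {}
    for r in library:
        s = design.fitness_by_gene.get(r.gene, 0.0)
        weights[r.guide_id] = (1.0 + s) ** design.n_generations
    total = sum(weights.values())
    return {g: w / total for g, w in weights.items()}


def _unique_umis(n: int, length: int, rng: np.random.Generator) -> list[str]:
    if 4**length < n:
        raise ValueError(f"cannot draw {n} unique UMIs of length {length}")
    umis: set[str] = set()
    while len(umis) < n:
        block = rng.integers(0, 4, size=(n - len(umis), length))
        for row in block:
            umis.add("".join(BASES[b] for b in row))
            if len(umis) == n:
                break
    out = sorted(umis)
    rng.shuffle(out)
    return out


def simulate_invivo_screen(
    library: GuideLibrary,
    design: ScreenDesign,
    n_samples: int = 1,
    sample_prefix: str = "organ",
) -> tuple[list[SimulatedSample], dict[str, float]]:
    """Simulate clonal founding, bottleneck, and growth for one or more samples.

    Each founder clone starts from a single transduced cell carrying a unique
    UMI and a uniformly drawn guide. The transplantation bottleneck thins
    founders binomially; growth draws the final clone size from a negative
    binomial with mean ``founding x (1+s)^n_generations`` (overdispersed
    clonal drift, dispersion ``design.nb_size``).
    """
    if len(library) == 0:
        raise ValueError("library must be nonempty")
    rng = np.random.default_rng(design.seed)
    guide_ids = library.guide_ids
    s_per_guide = np.array(
        [design.fitness_by_gene.get(library.gene_of(g), 0.0) for g in guide_ids]
    )
    growth = (1.0 + s_per_guide) ** design.n_generations

    samples: list[SimulatedSample] = []
    for i in range(n_samples):
        n = design.n_clones_founding
        guide_idx = rng.integers(0, len(guide_ids), size=n)
        umis = _unique_umis(n, design.umi_length, rng)
        founding = np.ones(n, dtype=np.int64)
        surviving = rng.binomial(founding, design.bottleneck_fraction)
        if design.n_generations == 0:
            final = surviving.astype(np.int64)
        else:
            mean = surviving * growth[guide_idx]
            final = np.zeros(n, dtype=np.int64)
            pos = mean > 0
            if pos.any():
                size = design.nb_size
                p = size / (size + mean[pos])
                final[pos] = rng.negative_binomial(size, p)
        clones = [
            CloneTruth(umis[j], guide_ids[guide_idx[j]], int(founding[j]), int(final[j]))
            for j in range(n)
        ]
        samples.append(
            SimulatedSample(
                name=f"{sample_prefix}{i + 1}",
                clones=clones,
                degenerate=bool(final.sum() == 0),
            )
        )
    return samples, expected_frequencies(library, design)


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. per-base substitution errors (never to N, never to self)."""
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    if not hit.any():
        return seq
    idx = np.nonzero(hit)[0]
    for i in idx:
        current = chr(arr[i])
        if current not in BASES:
            continue
        alternatives = [b for b in BASES if b != current]
        arr[i] = ord(alternatives[rng.integers(0, 3)])
    return arr.tobytes().decode()


def _fastq_record(read_id: str, seq: str) -> str:
    return f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n"


def emit_reads(
    clones: Sequence[CloneTruth],
    library: GuideLibrary,
    design: ScreenDesign,
    readout: str,
    r1_path: str | Path,
    r2_path: str | Path,
    manifest_path: str | Path,
    sample: str = "sample1",
    anchor: str = DEFAULT_ANCHOR,
    scaffold: str = DEFAULT_SCAFFOLD,
    read2_fill: str = DEFAULT_READ2_FILL,
) -> int:
    """Emit paired FASTQ reads plus a truth manifest; returns the read-pair count.

    Read 1 is ``stagger + anchor + spacer + scaffold`` truncated/padded to 50
    bases; read 2 is ``UMI + constant fill`` truncated to 26 bases for the
    ``invivo_cropseq`` readout, or constant fill only for ``dna_amplicon``.
    Reads per clone are multinomial given final counts and ``design.depth``.
    """
    if readout not in ("dna_amplicon", "invivo_cropseq"):
        raise ValueError(
            f"unsupported readout {readout!r}; combinatorial read emission lives in "
            "cropscreen.combinatorial.emit_dual_reads"
        )
    rng = np.random.default_rng(design.seed)
    clones = list(clones)
    finals = np.array([c.final_count for c in clones], dtype=np.float64)
    total = finals.sum()

    r1_path, r2_path, manifest_path = Path(r1_path), Path(r2_path), Path(manifest_path)
    n_emitted = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2, open(manifest_path, "w") as fm:
        fm.write("read_id\tguide_id\tumi\tsample\n")
        if design.depth == 0 or total == 0:
            return 0
        reads_per_clone = rng.multinomial(design.depth, finals / total)
        stagger_choices = sorted(design.stagger_lengths)
        for clone, n_reads in zip(clones, reads_per_clone):
            if n_reads == 0:
                continue
            spacer = library[clone.guide_id].spacer
            for _ in range(int(n_reads)):
                read_id = f"{sample}:{n_emitted}"
                stag_len = stagger_choices[rng.integers(0, len(stagger_choices))]
                stagger = "".join(BASES[b] for b in rng.integers(0, 4, size=stag_len))
                r1 = (stagger + anchor + spacer + scaffold)[:READ1_LENGTH]
                r1 = r1.ljust(READ1_LENGTH, "A")
                if readout == "invivo_cropseq":
                    r2 = (clone.umi + read2_fill)[:READ2_LENGTH]
                else:
                    r2 = read2_fill[:READ2_LENGTH]
                r2 = r2.ljust(READ2_LENGTH, "A")
                r1 = _apply_errors(r1, design.error_rate, rng)
                r2 = _apply_errors(r2, design.error_rate, rng)
                f1.write(_fastq_record(read_id, r1))
                f2.write(_fastq_record(read_id, r2))
                fm.write(f"{read_id}\t{clone.guide_id}\t{clone.umi}\t{sample}\n")
                n_emitted += 1
    return n_emitted


def simulate_umi_table(
    n_clones: int,
    rng: np.random.Generator,
    clone_mean: float = 200.0,
    clone_sigma: float = 0.4,
    n_background: int | None = None,
    background_mean: float = 2.0,
    background_sigma: float = 0.8,
    sample: str = "organ",
):
    """Per-UMI read counts for a sample with known clone number.

    True clones draw lognormal read counts around ``clone_mean``; background
    UMIs mimic ambient/error-derived molecules (mostly 1-3 reads with a
    lognormal tail crossing the usual 10-read fitting floor, as in real knee
    plots). Returns a UmiCountTable whose first ``n_clones`` UMIs are clones.
    """
    from .counting import UmiCountTable

    if n_background is None:
        n_background = 20 * n_clones
    clone_reads = np.maximum(
        1, np.round(rng.lognormal(np.log(clone_mean), clone_sigma, n_clones))
    ).astype(int)
    bg_reads = np.maximum(
        1, np.round(rng.lognormal(np.log(background_mean), background_sigma, n_background))
    ).astype(int)
    reads = np.concatenate([clone_reads, bg_reads])
    n = reads.size
    width = max(12, int(np.ceil(np.log(n) / np.log(4))) + 2)
    umis = []
    for i in range(n):
        v = i
        digits = []
        for _ in range(width):
            digits.append(BASES[v % 4])
            v //= 4
        umis.append("".join(digits))
    df = pd.DataFrame({"guide_id": "g1", "umi": umis, "count": reads})
    return UmiCountTable(sample, df)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def design_to_yaml(design: ScreenDesign, path: str | Path) -> None:
    import yaml

    payload = dataclasses.asdict(design)
    payload["stagger_lengths"] = list(design.stagger_lengths)
    with open(path, "w") as fh:
        yaml.safe_dump({"screen_design": payload}, fh, sort_keys=False)


def design_from_yaml(path: str | Path) -> ScreenDesign:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)["screen_design"]
    payload["stagger_lengths"] = tuple(payload["stagger_lengths"])
    return ScreenDesign(**payload)
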