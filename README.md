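# cropscreen

Informatics for pooled CRISPR screens with mRNA-based guide readout: from raw
paired reads to guide counts, UMI-based clone estimates, enrichment
statistics, screen-quality scores, dual-guide recombination QC, and tiling
base-editing library design — with a synthetic-data generator standing in for
raw sequencing data, so the whole pipeline is testable offline.

## What's inside

| Module | Purpose |
| --- | --- |
| `cropscreen.synthetic` | Guide libraries, clonal screen simulation (founding → bottleneck → overdispersed growth), paired-read FASTQ emission with staggers, UMIs and substitution error |
| `cropscreen.counting` | Stagger-aware spacer extraction, exact hash matching, guide×UMI counting, Gini index and sample QC |
| `cropscreen.clones` | UMI knee plots, four-parameter sigmoid inflection fits, clone counting, internal-replicate splitting by UMI prefix (4^k tables) |
| `cropscreen.enrichment` | Median-ratio / control-gene normalization, guide log2FC, gene-level permutation test with BH FDR, z-scores, strict hit calling, SSMD |
| `cropscreen.combinatorial` | Positional spacer/iBAR extraction, zero-mismatch dual matching, recombination detection and representation QC |
| `cropscreen.baseedit` | Tiling guide enumeration (NGG / PAM-less, both strands), T-stretch and BsmBI filters, edit-outcome prediction by CDS re-translation, control design, self-editing-aware expanded references, residue mutagenesis maps, amplicon editing quantification |
| `cropscreen.workflow` | YAML-configured end-to-end runs with provenance headers and deterministic reruns |

## Run the tests

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, one test class per acceptance
criterion. Four tests there check deposited library tables and skip unless
those tables are placed under `tests/data/supplementary/`.

## Command line

```bash
cropscreen --help
cropscreen simulate --seed 7 --out sim/
cropscreen count --r1 sim/r1.fastq --r2 sim/r2.fastq \
    --library sim/library.tsv --umi --out counts/
cropscreen clones --umi-counts counts/umi_counts.tsv --exclude-top 50 --min-reads 10
cropscreen split-replicates --umi-counts counts/umi_counts.tsv --prefix-len 2 --out reps/
cropscreen test --counts counts.tsv --test-samples d14 --ref-samples d0 \
    --n-perm 10000 --seed 7 --out gene_results.tsv
cropscreen ssmd --lfc gene_results.tsv --essential ceg.txt --nonessential neg.txt
cropscreen dual-count --r1 r1.fq --r2 r2.fq --library dual_library.tsv --out dual/
cropscreen be-design --gene model.gb --editor ABE --pam-mode pamless --flank 20 --out guides.tsv
cropscreen edit-qc --fastq amplicon.fq --ref locus.fa --conversions 42:A>G,45:A>G
cropscreen run --config examples/demo.yaml
```

An end-to-end demo (simulate → count → split-replicates → clones → test →
ssmd) is in `examples/demo.yaml`; rerunning with the same config and seed
produces byte-identical tables.

## File formats

All tables are TSV. Count tables use the standard screen dialect
(`sgRNA<TAB>gene<TAB><sample…>`); UMI counts are
(`sample, guide_id, umi, count`); dual libraries are
(`construct_id, spacer1, ibar1, spacer2, ibar2, gene1, gene2`); FASTQ is
plain 4-line Phred+33. Pipeline outputs carry a `#`-prefixed provenance
header (version, config hash, seed).
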