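"""Enrichment statistics for pooled screens.

Self-contained replacements for external screen-test tooling: count
normalization (median-ratio or control-guide based), per-guide log2 fold
changes, a gene-level permutation test with Benjamini-Hochberg FDR,
z-normalized effect sizes, strict hit calling, and the SSMD screen-quality
score computed from essential/non-essential control sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SSMDResult:
    ssmd: float
    mean_essential: float
    mean_nonessential: float
    sd_essential: float
    sd_nonessential: float
    n_essential: int
    n_nonessential: int
    low_quality: bool


def normalize(
    table: pd.DataFrame,
    method: str = "median_ratio",
    control_genes: list[str] | None = None,
    gene_col: str = "gene",
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize a count table; returns (normalized counts, size factors).

    ``median_ratio``: per-sample factor = median over guides of
    count / geometric-mean-across-samples, guides with any zero excluded from
    the factor computation. ``control_genes`` restricts the factor computation
    to guides of the given gene set.
    """
    counts = table.drop(columns=[gene_col]) if gene_col in table.columns else table.copy()
    counts = counts.astype(float)

    factor_rows = counts
    if method == "control_genes":
        if not control_genes:
            raise ValueError("control_genes normalization requires a nonempty control set")
        if gene_col not in table.columns:
            raise ValueError("control_genes normalization requires a gene column")
        mask = table[gene_col].isin(control_genes)
        if not mask.any():
            raise ValueError("no guides of the control genes present in the table")
        factor_rows = counts[mask.to_numpy()]
    elif method != "median_ratio":
        raise ValueError(f"unknown normalization method {method!r}")

    usable = factor_rows[(factor_rows > 0).all(axis=1)]
    if usable.empty:
        raise ValueError("no guide has nonzero counts in every sample; cannot derive size factors")
    log_geo_mean = np.log(usable).mean(axis=1)
    factors = np.exp(np.log(usable).sub(log_geo_mean, axis=0).median(axis=0))
    normalized = counts.div(factors, axis=1)
    if gene_col in table.columns:
        normalized.insert(0, gene_col, table[gene_col])
    return normalized, factors


def guide_lfc(
    test: pd.Series,
    ref: pd.Series,
    pseudocount: float = 1.0,
    genes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-guide log2((test + pc) / (ref + pc)); guides zero in both are dropped."""
    test, ref = test.align(ref, join="inner")
    keep = ~((test == 0) & (ref == 0))
    test, ref = test[keep], ref[keep]
    lfc = np.log2((test + pseudocount) / (ref + pseudocount))
    out = pd.DataFrame(
        {"lfc": lfc, "norm_counts_test": test, "norm_counts_ref": ref}
    )
    out.index.name = "guide_id"
    if genes is not None:
        out.insert(0, "gene", genes.reindex(out.index))
    return out


def z_normalize(values: pd.Series | np.ndarray, reference: pd.Series | np.ndarray | None = None):
    """Standard z-transform against a reference population (the values themselves by default)."""
    values = np.asarray(values, dtype=float)
    ref = values if reference is None else np.asarray(reference, dtype=float)
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("reference population standard deviation must be positive")
    return (values - ref.mean()) / sd


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _gene_means(lfc: np.ndarray, gene_idx: np.ndarray, n_genes: int) -> np.ndarray:
    sums = np.bincount(gene_idx, weights=lfc, minlength=n_genes)
    counts = np.bincount(gene_idx, minlength=n_genes)
    return sums / counts


def gene_test(
    stats: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    replicate_lfcs: list[pd.DataFrame] | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Gene-level permutation test on guide log2 fold changes.

    The gene score is the mean guide lfc (averaged additionally over internal
    replicates when ``replicate_lfcs`` is given). The null is built by
    permuting guide-to-gene labels, preserving the number of guides per gene.
    Sampled mode uses two-sided p with +1 smoothing,
    ``p = (1 + #{|null| >= |obs|}) / (n_perm + 1)``; exhaustive mode enumerates
    every distinct label assignment and reports the exact two-sided fraction.
    FDR is Benjamini-Hochberg across genes; z_lfc standardizes gene lfc
    against the distribution of all gene lfcs.
    """
    if "gene" not in stats.columns or "lfc" not in stats.columns:
        raise ValueError("stats requires 'gene' and 'lfc' columns")
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    if replicate_lfcs:
        frames = [stats[["lfc"]]] + [r[["lfc"]] for r in replicate_lfcs]
        lfc = pd.concat(frames, axis=1).mean(axis=1)
        stats = stats.assign(lfc=lfc)

    genes = stats["gene"].to_numpy()
    lfc = stats["lfc"].to_numpy(dtype=float)
    gene_names, gene_idx = np.unique(genes, return_inverse=True)
    n_genes = gene_names.size
    obs = _gene_means(lfc, gene_idx, n_genes)

    if exhaustive:
        exceed = np.zeros(n_genes, dtype=np.int64)
        n_total = 0
        for perm in itertools.permutations(range(lfc.size)):
            null = _gene_means(lfc[list(perm)], gene_idx, n_genes)
            exceed += np.abs(null) >= np.abs(obs) - 1e-12
            n_total += 1
        p = exceed / n_total
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(n_genes, dtype=np.int64)
        work = lfc.copy()
        for _ in range(n_perm):
            rng.shuffle(work)
            null = _gene_means(work, gene_idx, n_genes)
            exceed += np.abs(null) >= np.abs(obs)
        p = (1 + exceed) / (n_perm + 1)

    sd = obs.std(ddof=1) if n_genes > 1 else float("nan")
    z = (obs - obs.mean()) / sd if sd and np.isfinite(sd) and sd > 0 else np.full(n_genes, np.nan)
    result = pd.DataFrame(
        {
            "gene": gene_names,
            "lfc": obs,
            "z_lfc": z,
            "p_value": p,
            "fdr": bh_fdr(p),
            "n_guides": np.bincount(gene_idx, minlength=n_genes),
        }
    )
    return call_hits(result)


def call_hits(
    results: pd.DataFrame, lfc_threshold: float = 1.5, fdr_threshold: float = 0.01
) -> pd.DataFrame:
    """Flag hits with strict inequalities: lfc > threshold AND fdr < threshold."""
    if "fdr" not in results.columns:
        raise ValueError("results must carry an 'fdr' column")
    out = results.copy()
    out["hit"] = (out["lfc"] > lfc_threshold) & (out["fdr"] < fdr_threshold)
    return out


def ssmd(
    lfcs: pd.Series,
    essential_set: set[str] | list[str],
    nonessential_set: set[str] | list[str],
    low_quality_cut: float = 0.5,
) -> SSMDResult:
    """Strictly standardized mean difference between control populations.

    ``ssmd = (mean_e - mean_ne) / sqrt(sd_e^2 + sd_ne^2)`` with sample (n-1)
    standard deviations over the lfc values of set members present in the
    data. The low-quality flag applies the cut to |ssmd| (with essential-gene
    dropout, the signed value is negative by construction).
    """
    essential_set, nonessential_set = set(essential_set), set(nonessential_set)
    if essential_set & nonessential_set:
        raise ValueError("essential and nonessential sets must be disjoint")
    e = lfcs.reindex(sorted(essential_set)).dropna()
    ne = lfcs.reindex(sorted(nonessential_set)).dropna()
    if len(e) < 2 or len(ne) < 2:
        raise ValueError("need >= 2 members of each set with finite lfc")
    mean_e, mean_ne = float(e.mean()), float(ne.mean())
    sd_e, sd_ne = float(e.std(ddof=1)), float(ne.std(ddof=1))
    value = (mean_e - mean_ne) / math.sqrt(sd_e**2 + sd_ne**2)
    return SSMDResult(
        ssmd=value,
        mean_essential=mean_e,
        mean_nonessential=mean_ne,
        sd_essential=sd_e,
        sd_nonessential=sd_ne,
        n_essential=len(e),
        n_nonessential=len(ne),
        low_quality=abs(value) < low_quality_cut,
    )


def paired_lfc(
    pairs: list[tuple[pd.Series, pd.Series]],
    pseudocount: float = 1.0,
    genes: pd.Series | None = None,
) -> pd.DataFrame:
    """Paired-design lfc: compute per-pair guide lfc, then average across pairs."""
    if not pairs:
        raise ValueError("at least one (test, ref) pair required")
    per_pair = [guide_lfc(t, r, pseudocount=pseudocount)["lfc"] for t, r in pairs]
    merged = pd.concat(per_pair, axis=1)
    out = pd.DataFrame({"lfc": merged.mean(axis=1)})
    out.index.name = "guide_id"
    if genes is not None:
        out.insert(0, "gene", genes.reindex(out.index))
    return out
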