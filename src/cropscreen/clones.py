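"""In vivo UMI analytics: knee plots, sigmoid inflection fits, clone estimates,
and internal-replicate count tables from UMI prefixes.

The knee plot ranks UMIs by read count and plots log10(rank) against
log10(reads). A four-parameter sigmoid ``L / (1 + exp(-k (x - x0))) + b`` is
fitted to the retained points; the inflection abscissa ``x0`` separates true
clones from background noise, and the clone count is the number of UMIs with
rank <= round(10 ** x0).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .counting import UmiCountTable

BASES = "ACGT"


@dataclass
class SigmoidFit:
    L: float
    k: float
    x0: float
    b: float
    rss: float
    converged: bool
    n_points: int = 0
    reason: str | None = None


@dataclass
class CloneEstimate:
    x0: float
    clone_count: int
    n_umis_total: int
    n_umis_fit: int


@dataclass
class ReplicateSet:
    """One count table per UMI prefix over {A,C,G,T}^prefix_length."""

    prefix_length: int
    tables: dict[str, pd.Series]

    def __post_init__(self) -> None:
        expected = 4**self.prefix_length
        if len(self.tables) != expected:
            raise ValueError(
                f"expected {expected} tables for prefix length {self.prefix_length}, "
                f"got {len(self.tables)}"
            )


def sigmoid(x, L, k, x0, b):
    return L / (1.0 + np.exp(-k * (x - x0))) + b


def knee_points(umi_counts: UmiCountTable) -> pd.DataFrame:
    """Ordered (rank, reads, log10 rank, log10 reads) per UMI.

    UMIs are sorted by read count descending, ties broken by UMI lexicographic
    order; rank is 1-based.
    """
    per_umi = umi_counts.per_umi()
    if per_umi.empty:
        raise ValueError("at least one UMI required")
    ordered = per_umi.reset_index().rename(columns={"index": "umi"})
    ordered = ordered.sort_values(
        ["count", "umi"], ascending=[False, True], ignore_index=True
    )
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    ordered["log10_rank"] = np.log10(ordered["rank"])
    ordered["log10_reads"] = np.log10(ordered["count"])
    return ordered[["umi", "rank", "count", "log10_rank", "log10_reads"]]


def fit_knee(
    points: pd.DataFrame,
    exclude_top: int = 50,
    min_reads: int = 10,
    min_points: int = 8,
) -> SigmoidFit:
    """Nonlinear least squares of the four-parameter sigmoid on retained points.

    The ``exclude_top`` highest-count UMIs are dropped first, then all UMIs
    with fewer than ``min_reads`` reads. Initialization is multi-start over
    steepness values; the start with the best residual sum of squares wins.
    """
    retained = points.iloc[exclude_top:]
    retained = retained[retained["count"] >= min_reads]
    n = len(retained)
    if n < min_points:
        return SigmoidFit(
            math.nan, math.nan, math.nan, math.nan, math.nan,
            converged=False, n_points=n, reason="insufficient data",
        )
    x = retained["log10_rank"].to_numpy()
    y = retained["log10_reads"].to_numpy()

    b0 = float(y.min())
    span = float(y.max() - y.min())
    # the knee curve decreases in y, so the data's direction sets the sign of L
    direction = -1.0 if y[0] >= y[-1] else 1.0
    L0 = direction * max(span, 1e-6)
    x0_0 = float(np.median(x))

    # x0 is constrained to (a margin around) the observed abscissa range so the
    # inflection cannot run away from the data on degenerate half-knee inputs
    lo_bounds = np.array([-np.inf, -np.inf, float(x.min()) - 0.5, -np.inf])
    hi_bounds = np.array([np.inf, np.inf, float(x.max()) + 0.5, np.inf])
    best = None
    for k0 in (1.0, -1.0, 5.0, -5.0, 20.0, -20.0):
        p0 = np.array([L0, k0, x0_0, b0])
        try:
            res = least_squares(
                lambda p: sigmoid(x, *p) - y, p0, method="trf",
                bounds=(lo_bounds, hi_bounds),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20_000,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if res.success and np.all(np.isfinite(res.x)):
            if best is None or rss < best[1]:
                best = (res.x, rss)
    if best is None:
        return SigmoidFit(
            math.nan, math.nan, math.nan, math.nan, math.nan,
            converged=False, n_points=n, reason="no start converged",
        )
    (L, k, x0, b), rss = best
    return SigmoidFit(float(L), float(k), float(x0), float(b), rss, True, n_points=n)


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def count_clones(fit: SigmoidFit, umi_counts: UmiCountTable) -> CloneEstimate:
    """Clone count = number of UMIs with 1-based rank <= round(10 ** x0)."""
    if not fit.converged:
        raise ValueError(f"cannot count clones from a non-converged fit: {fit.reason}")
    n_total = len(umi_counts.per_umi())
    cut = _round_half_up(10.0**fit.x0)
    clone_count = max(0, min(cut, n_total))
    return CloneEstimate(
        x0=fit.x0, clone_count=clone_count, n_umis_total=n_total, n_umis_fit=fit.n_points
    )


def estimate_clones(
    umi_counts: UmiCountTable, exclude_top: int = 50, min_reads: int = 10
) -> tuple[SigmoidFit, CloneEstimate | None]:
    """Convenience wrapper: knee points -> sigmoid fit -> clone estimate."""
    points = knee_points(umi_counts)
    fit = fit_knee(points, exclude_top=exclude_top, min_reads=min_reads)
    if not fit.converged:
        return fit, None
    return fit, count_clones(fit, umi_counts)


def all_prefixes(prefix_length: int) -> list[str]:
    return ["".join(p) for p in itertools.product(BASES, repeat=prefix_length)]


def split_internal_replicates(
    umi_counts: UmiCountTable, prefix_length: int
) -> ReplicateSet:
    """Partition (guide, UMI) counts into 4^prefix_length internal replicates.

    Each entry is assigned to the table keyed by the first ``prefix_length``
    bases of its UMI; empty prefix groups are kept as all-zero tables.
    Prefix length 0 returns the single collapsed table.
    """
    if not (0 <= prefix_length <= 5):
        raise ValueError("prefix_length must lie in [0, 5]")
    df = umi_counts.entries
    if len(df) and df["umi"].str.contains("N").any():
        raise ValueError("UMIs containing N must be filtered before replicate splitting")
    if len(df) and (df["umi"].str.len() < prefix_length).any():
        raise ValueError("all UMIs must be at least prefix_length long")

    guide_order = sorted(df["guide_id"].unique()) if len(df) else []
    tables: dict[str, pd.Series] = {}
    if prefix_length == 0:
        tables[""] = umi_counts.collapse(guide_order)
        return ReplicateSet(0, tables)

    prefixes = df["umi"].str[:prefix_length] if len(df) else pd.Series(dtype=str)
    grouped = (
        df.assign(prefix=prefixes).groupby(["prefix", "guide_id"])["count"].sum()
        if len(df)
        else pd.Series(dtype=int)
    )
    for prefix in all_prefixes(prefix_length):
        if len(df) and prefix in grouped.index.get_level_values(0):
            s = grouped.loc[prefix].reindex(guide_order, fill_value=0).astype(int)
        else:
            s = pd.Series(0, index=guide_order, dtype=int)
        s.name = f"{umi_counts.sample}.{prefix}"
        tables[prefix] = s
    return ReplicateSet(prefix_length, tables)
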