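"""Nucleotide diversity (pi) and the windowed sweep scan.

pi at a site with k alternate alleles among n called haplotypes is the
proportion of haplotype pairs that differ, 2k(n-k)/(n(n-1)); per-bp window
pi sums site values over a window and divides by the window span (the
convention of the standard windowed-pi tools: invariant sites contribute
zero and the denominator is the full span, not callable bp).

Putative domestication sweeps are 100-kb windows whose wild/cultivated pi
ratio falls in the empirical top 5%; the printed ratio cutoff is always
recomputed from the data, never hard-coded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval

WINDOW_BP = 100_000
SWEEP_TOP_FRAC = 0.05
MIN_ELIGIBLE_WINDOWS = 20


def site_pi(alt_count: int, called_haplotypes: int) -> float:
    """Proportion of differing haplotype pairs at one biallelic site."""
    k, n = alt_count, called_haplotypes
    if not 0 <= k <= n:
        raise ValueError(f"alt count {k} outside [0, {n}]")
    if n < 2:
        raise ValueError("need at least 2 called haplotypes")
    return 2 * k * (n - k) / (n * (n - 1))


def variant_summary(sites: pd.DataFrame, matrix: np.ndarray) -> pd.DataFrame:
    """Per-site alt counts and called-haplotype counts from an indicator
    matrix (-1 = missing). Pairwise-complete: n counts non-missing
    haplotypes at that site."""
    called = (matrix >= 0).sum(axis=1)
    alt = np.where(matrix > 0, 1, 0).sum(axis=1)
    out = sites.copy()
    out["alt_count"] = alt
    out["n_called"] = called
    return out


def windowed_pi(
    variants: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window: int = WINDOW_BP,
) -> pd.DataFrame:
    """Tiled per-bp pi. Windows tile each chromosome from position 0; the
    terminal window is truncated at the chromosome end and its span used as
    the denominator. Sites with fewer than 2 called haplotypes are skipped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    variants = variants[variants["n_called"] >= 2]
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        sub = variants[variants["chrom"] == chrom]
        pis = np.array(
            [site_pi(k, n) for k, n in zip(sub["alt_count"], sub["n_called"])]
        )
        pos = sub["pos"].to_numpy()
        for start in range(0, size, window):
            end = min(start + window, size)
            mask = (pos >= start) & (pos < end)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "pi": float(pis[mask].sum()) / (end - start) if len(pis) else 0.0,
                    "n_sites": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SweepCall:
    windows: pd.DataFrame        # aligned windows with ratio + flag
    threshold: float             # empirical top-5% ratio cutoff
    regions: list[GenomicInterval] = field(default_factory=list)  # merged sweeps


def sweep_scan(
    pi_wild: pd.DataFrame,
    pi_cult: pd.DataFrame,
    top_frac: float = SWEEP_TOP_FRAC,
    min_sites: int = 1,
) -> SweepCall:
    """Flag windows whose pi_wild/pi_cult ratio reaches the top-``top_frac``
    empirical cutoff; adjacent flagged windows merge into sweep regions.

    Eligible windows have cultivated pi > 0 and at least ``min_sites``
    variants in each panel. Fewer than 20 eligible windows is an error (the
    quantile would be unstable).
    """
    merged = pi_wild.merge(
        pi_cult,
        on=["chrom", "start", "end"],
        suffixes=("_wild", "_cult"),
        validate="one_to_one",
    )
    eligible = (
        (merged["pi_cult"] > 0)
        & (merged["n_sites_wild"] >= min_sites)
        & (merged["n_sites_cult"] >= min_sites)
    )
    merged["ratio"] = np.where(eligible, merged["pi_wild"] / merged["pi_cult"], np.nan)
    n_eligible = int(eligible.sum())
    if n_eligible < MIN_ELIGIBLE_WINDOWS:
        raise ValueError(
            f"only {n_eligible} eligible windows; need >= {MIN_ELIGIBLE_WINDOWS}"
        )
    k = math.floor(top_frac * n_eligible)
    ratios = np.sort(merged.loc[eligible, "ratio"].to_numpy())[::-1]
    threshold = float(ratios[k - 1]) if k >= 1 else float("inf")
    merged["is_sweep"] = eligible & (merged["ratio"] >= threshold)
    flagged = merged[merged["is_sweep"]]
    regions: list[GenomicInterval] = []
    for chrom, sub in flagged.groupby("chrom"):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for start, end in zip(sub["start"], sub["end"]):
            if cur_e is not None and start <= cur_e:
                cur_e = max(cur_e, end)
            else:
                if cur_e is not None:
                    regions.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = start, end
        if cur_e is not None:
            regions.append(GenomicInterval(chrom, cur_s, cur_e))
    return SweepCall(merged, threshold, regions)


def acr_pi(
    acrs: dict[str, GenomicInterval],
    variants: pd.DataFrame,
    span: int = 2000,
) -> pd.Series:
    """Mean per-bp pi in a fixed window centered on each peak."""
    variants = variants[variants["n_called"] >= 2]
    by_chrom = {
        chrom: (
            sub["pos"].to_numpy(),
            np.array([site_pi(k, n) for k, n in zip(sub["alt_count"], sub["n_called"])]),
        )
        for chrom, sub in variants.groupby("chrom")
    }
    out = {}
    for name, iv in acrs.items():
        center = iv.midpoint
        lo, hi = max(0, center - span // 2), center + span // 2
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            out[name] = 0.0
            continue
        pos, pis = entry
        i, j = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
        out[name] = float(pis[i:j].sum()) / (hi - lo)
    return pd.Series(out, name="pi")
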