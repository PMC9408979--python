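"""Region-level DNA methylation from per-cytosine CGmap calls.

Levels are read-weighted (bulk): for a region and context, the level is
sum(methylated reads) / sum(total reads) over in-region sites — the
convention of the major bisulfite pipelines — rather than a mean of
per-site ratios. Sites below the coverage filter (default: fewer than 5
reads) are dropped before any region computation.
"""
from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .core import CONTEXTS, GenomicInterval, MethylSite

MIN_COVERAGE = 5


def filter_sites(sites: list[MethylSite], min_cov: int = MIN_COVERAGE) -> list[MethylSite]:
    """Keep cytosines covered by at least ``min_cov`` reads."""
    return [s for s in sites if s.total >= min_cov]


def region_methylation(
    region: GenomicInterval, sites: list[MethylSite], context: str
) -> float:
    """Weighted methylation level of one region in one context.

    NaN when the region holds no covered site of the context.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    m = t = 0
    for s in sites:
        if s.context == context and region.contains_point(s.chrom, s.pos):
            m += s.methylated
            t += s.total
    if t == 0:
        return float("nan")
    return m / t


class MethylIndex:
    """Position-sorted per-(chrom, context) arrays for bulk region queries."""

    def __init__(self, sites: list[MethylSite]):
        grouped: dict[tuple[str, str], list[MethylSite]] = defaultdict(list)
        for s in sites:
            grouped[(s.chrom, s.context)].append(s)
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for key, ss in grouped.items():
            ss.sort(key=lambda s: s.pos)
            self._data[key] = (
                np.array([s.pos for s in ss]),
                np.array([s.methylated for s in ss]),
                np.array([s.total for s in ss]),
            )

    def region_level(self, region: GenomicInterval, context: str) -> tuple[float, int]:
        """(weighted level, covered-site count); level is NaN at count 0."""
        entry = self._data.get((region.chrom, context))
        if entry is None:
            return float("nan"), 0
        pos, mc, tot = entry
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        if hi == lo:
            return float("nan"), 0
        t = int(tot[lo:hi].sum())
        if t == 0:
            return float("nan"), 0
        return float(mc[lo:hi].sum()) / t, hi - lo


def region_methylation_table(
    regions: dict[str, GenomicInterval], sites: list[MethylSite]
) -> pd.DataFrame:
    """Tidy per-region per-context levels (region, context, level, n_sites)."""
    index = MethylIndex(sites)
    rows = []
    for name, region in regions.items():
        for context in CONTEXTS:
            level, n = index.region_level(region, context)
            rows.append(
                {"region": name, "context": context, "level": level, "n_sites": n}
            )
    return pd.DataFrame(rows)


def methylation_signal(
    sites: list[MethylSite], chrom_sizes: dict[str, int], context: str
) -> dict[str, np.ndarray]:
    """Per-base site-level methylation ratio arrays (NaN where no site) for
    metaprofile plotting."""
    arrays = {c: np.full(n, np.nan) for c, n in chrom_sizes.items()}
    for s in sites:
        if s.context == context and s.chrom in arrays and s.total > 0:
            arrays[s.chrom][s.pos] = s.methylated / s.total
    return arrays
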