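"""Tissue specificity of chromatin accessibility by Shannon entropy.

Per-peak read counts across tissues are normalized to reads per million
(RPM); the entropy of the normalized row measures how concentrated the
accessibility is. Rows are ranked ascending by entropy and the lowest 15%
(most concentrated) are called tissue-specific, each attributed to its
highest-RPM tissue.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


def rpm_matrix(counts: pd.DataFrame, totals: dict[str, int] | pd.Series) -> pd.DataFrame:
    """counts (peaks x tissues) -> RPM = count * 1e6 / total mapped reads."""
    totals = pd.Series(totals)
    missing = set(counts.columns) - set(totals.index)
    if missing:
        raise ValueError(f"missing mapped-read totals for tissues: {sorted(missing)}")
    if (totals[counts.columns] <= 0).any():
        raise ValueError("mapped-read totals must be positive")
    return counts * 1e6 / totals[counts.columns]


def shannon_entropy(rpm_row) -> float:
    """Entropy in bits of a non-negative row; NaN for an all-zero row.

    Invariant under positive rescaling of the row; 0*log(0) contributes 0.
    """
    vals = np.asarray(rpm_row, dtype=float)
    if (vals < 0).any():
        raise ValueError("RPM values must be non-negative")
    total = vals.sum()
    if total == 0:
        return float("nan")
    p = vals / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def call_specific(rpm: pd.DataFrame, top_frac: float = 0.15) -> pd.DataFrame:
    """Rank peaks ascending by entropy and flag the top 15% as specific.

    Exactly ``floor(top_frac * N)`` peaks are flagged, where N counts only
    quantifiable rows (nonzero total RPM); all-zero rows get NaN entropy and
    are never specific. Ties in entropy break by higher maximal RPM, then
    peak id. ``specific_tissue`` is the argmax-RPM tissue for flagged peaks.
    """
    if len(rpm) == 0:
        raise ValueError("empty RPM matrix")
    entropy = rpm.apply(shannon_entropy, axis=1)
    max_rpm = rpm.max(axis=1)
    out = pd.DataFrame(
        {
            "entropy_bits": entropy,
            "max_rpm": max_rpm,
            "is_specific": False,
            "specific_tissue": ".",
        },
        index=rpm.index,
    )
    quantifiable = out.index[entropy.notna()]
    n_specific = math.floor(top_frac * len(quantifiable))
    if n_specific > 0:
        order = sorted(
            quantifiable,
            key=lambda i: (entropy[i], -max_rpm[i], str(i)),
        )
        chosen = order[:n_specific]
        out.loc[chosen, "is_specific"] = True
        out.loc[chosen, "specific_tissue"] = rpm.loc[chosen].idxmax(axis=1)
    out["rank"] = entropy.rank(method="first").astype("Int64")
    return out


def fold_change(rpm_row: pd.Series, specific_tissue: str, eps: float = 0.01) -> float:
    """(max-tissue RPM + eps) / (mean of the other tissues + eps)."""
    top = rpm_row[specific_tissue]
    others = rpm_row.drop(specific_tissue)
    return (top + eps) / (others.mean() + eps)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def superfamily_enrichment(
    drawn: dict[str, int], population: dict[str, int]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of TE superfamilies among TEs
    overlapping tissue-specific peaks.

    ``population`` counts every TE per superfamily genome-wide; ``drawn``
    counts those overlapping the specific peaks. P = P(X >= observed) with
    population size M, superfamily size n, draws N. BH q-values included.
    """
    M = sum(population.values())
    N = sum(drawn.values())
    rows = []
    for sf, n in sorted(population.items()):
        k = drawn.get(sf, 0)
        if k > N:
            raise ValueError(f"{sf}: observed {k} exceeds total draws {N}")
        if k > n:
            raise ValueError(f"{sf}: observed {k} exceeds superfamily size {n}")
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append({"superfamily": sf, "observed": k, "population": n, "p_value": p})
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df
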