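"""Duplicate-gene pairs: TSS accessibility status, subgroup partition,
NG86 Ka/Ks estimation, and the accessibility/expression divergence contrast.

The Ka/Ks estimator is the classic Nei-Gojobori (NG86) counting method:
per-codon synonymous site fractions averaged over the two sequences,
differences classified by averaging over all minimal substitution pathways
(pathways passing through a stop codon are excluded unless every pathway is
blocked), proportions corrected for multiple hits with the Jukes-Cantor
formula d = -(3/4) ln(1 - (4/3) p), and omega = Ka/Ks. Significance of
Ka != Ks comes from a two-sided Fisher exact test on the rounded 2x2 table
of synonymous/nonsynonymous differences vs remaining sites.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu

from .core import GeneModel, GenomicInterval

BASES = "ACGT"

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


def translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def validate_cds(cds: str, name: str = "cds") -> None:
    if len(cds) % 3:
        raise ValueError(f"{name}: length {len(cds)} not divisible by 3")
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in CODON_TABLE:
            raise ValueError(f"{name}: invalid codon {codon!r} at position {i}")
        if codon in STOP_CODONS and i < len(cds) - 3:
            raise ValueError(f"{name}: internal stop codon at position {i}")


@lru_cache(maxsize=64)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes creating a stop codon count as
    nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                n_syn += 1
        syn += n_syn / 3
    return syn, 3 - syn


@lru_cache(maxsize=4096)
def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over minimal substitution pathways; stop-codon intermediates excluded
    unless every pathway is blocked."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TABLE[cur] == CODON_TABLE[nxt] and nxt not in STOP_CODONS and cur not in STOP_CODONS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((blocked, sd, nd))
    open_paths = [(sd, nd) for blocked, sd, nd in pathways if not blocked]
    if not open_paths:
        open_paths = [(sd, nd) for _, sd, nd in pathways]
    s = sum(sd for sd, _ in open_paths) / len(open_paths)
    n = sum(nd for _, nd in open_paths) / len(open_paths)
    return s, n


def jukes_cantor(p: float) -> float:
    """Multiple-hit corrected distance; NaN when p >= 3/4 (saturated)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    Ka: float
    Ks: float
    omega: float  # NaN when Ks is 0 or undefined
    p_value: float


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks for one codon-aligned pair."""
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must be codon-aligned to equal length")
    validate_cds(cds_a, "cds_a")
    validate_cds(cds_b, "cds_b")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = codon_differences(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    omega = Ka / Ks if Ks and not math.isnan(Ks) and Ks > 0 and not math.isnan(Ka) else float("nan")
    # fractional NG86 counts rounded for the exact test; at tiny S the
    # difference count can exceed the site count (saturation), clamp at 0
    table = np.array(
        [
            [round(Sd), max(0, round(S - Sd))],
            [round(Nd), max(0, round(N - Nd))],
        ]
    )
    _, p_value = fisher_exact(table, alternative="two-sided")
    return KaKsResult(S, N, Sd, Nd, Ka, Ks, omega, float(p_value))


def filter_pairs(pairs: pd.DataFrame, max_ks: float = 5.0, max_p: float = 0.05) -> pd.DataFrame:
    """Drop saturated (Ks > 5.0) and non-significant (p > 0.05) pairs.

    Both cutoffs are inclusive on the retained side: Ks == 5.0 and
    p == 0.05 survive.
    """
    keep = (pairs["Ks"] <= max_ks) & (pairs["p_value"] <= max_p)
    return pairs[keep.fillna(False)].copy()


# ---------------------------------------------------------------------------
# Codon alignment (plumbing for raw, unaligned CDS input)
# ---------------------------------------------------------------------------

def codon_align_pair(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-align two CDS by aligning their proteins (Needleman-Wunsch,
    BLOSUM62, affine gaps) and back-threading codons; columns with a gap in
    either sequence are dropped so the result satisfies the NG86 contract."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    validate_cds(cds_a, "cds_a")
    validate_cds(cds_b, "cds_b")
    prot_a, prot_b = translate(cds_a).rstrip("*"), translate(cds_b).rstrip("*")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    aln = aligner.align(prot_a, prot_b)[0]
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for col_a, col_b in zip(aln[0], aln[1]):
        if col_a != "-" and col_b != "-":
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
        if col_a != "-":
            ia += 1
        if col_b != "-":
            ib += 1
    return "".join(out_a), "".join(out_b)


# ---------------------------------------------------------------------------
# TSS accessibility status and subgroup partition
# ---------------------------------------------------------------------------

TSS_WINDOW_BP = 500

DUPLICATE_MODES = ("WGD", "tandem", "proximal", "transposed", "dispersed")


def tss_window(gene: GeneModel, window: int = TSS_WINDOW_BP) -> GenomicInterval:
    """Closed +/-window around the TSS, i.e. [TSS-500, TSS+500] inclusive."""
    tss = gene.tss
    return GenomicInterval(
        gene.interval.chrom, max(0, tss - window), tss + window + 1
    )


def tss_acr_status(
    gene: GeneModel,
    acrs: list[tuple[GenomicInterval, bool]],
    window: int = TSS_WINDOW_BP,
) -> str:
    """'te_acr' if a TE-derived peak overlaps the TSS window (TE-derived
    dominates), else 'regular_acr' if any peak does, else 'none'."""
    win = tss_window(gene, window)
    status = "none"
    for iv, te_derived in acrs:
        if win.overlaps(iv):
            if te_derived:
                return "te_acr"
            status = "regular_acr"
    return status


def assign_subgroup(status_a: str, status_b: str) -> str:
    """Partition by joint TSS status: 1 = both TE-derived; 2 = one
    TE-derived, other regular; 3 = one TE-derived, other none; pairs with
    no TE-derived copy stay unassigned."""
    pair = sorted([status_a, status_b])
    if pair == ["te_acr", "te_acr"]:
        return "1"
    if pair == ["regular_acr", "te_acr"]:
        return "2"
    if pair == ["none", "te_acr"]:
        return "3"
    return "unassigned"


def assign_subgroups(pairs: pd.DataFrame) -> pd.DataFrame:
    """Add a ``subgroup`` column from ``tss_acr_a`` / ``tss_acr_b``."""
    out = pairs.copy()
    out["subgroup"] = [
        assign_subgroup(a, b) for a, b in zip(out["tss_acr_a"], out["tss_acr_b"])
    ]
    return out


def subgroup_partition_check(pairs: pd.DataFrame) -> bool:
    """|g1| + |g2| + |g3| must equal the pairs with >= 1 TE-derived copy."""
    assigned = (pairs["subgroup"] != "unassigned").sum()
    with_te = (
        (pairs["tss_acr_a"] == "te_acr") | (pairs["tss_acr_b"] == "te_acr")
    ).sum()
    return int(assigned) == int(with_te)


# ---------------------------------------------------------------------------
# Accessibility vs expression divergence
# ---------------------------------------------------------------------------

def divergence_association(
    pairs: pd.DataFrame,
    eps: float = 0.01,
    fc_cutoff: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Split pairs by expression divergence and compare accessibility shifts.

    Expects columns fpkm_a/fpkm_b (expression) and rpm_a/rpm_b (TSS-peak
    accessibility). Adds |log2 FC| columns, splits at expression fold
    change ``fc_cutoff`` (ratio exactly at the cutoff goes to the low
    group), and rank-sum-tests the accessibility change between groups.
    """
    out = pairs.copy()
    out["fc_expression"] = np.abs(
        np.log2((out["fpkm_a"] + eps) / (out["fpkm_b"] + eps))
    )
    out["fc_accessibility"] = np.abs(
        np.log2((out["rpm_a"] + eps) / (out["rpm_b"] + eps))
    )
    cut = np.log2(fc_cutoff)
    out["expression_group"] = np.where(
        out["fc_expression"] > cut, f">{fc_cutoff:g}", f"<={fc_cutoff:g}"
    )
    hi = out.loc[out["fc_expression"] > cut, "fc_accessibility"]
    lo = out.loc[out["fc_expression"] <= cut, "fc_accessibility"]
    summary: dict = {
        "n_high": int(len(hi)),
        "n_low": int(len(lo)),
        "median_fc_accessibility_high": float(hi.median()) if len(hi) else float("nan"),
        "median_fc_accessibility_low": float(lo.median()) if len(lo) else float("nan"),
    }
    if len(hi) and len(lo):
        stat, p = mannwhitneyu(hi, lo, alternative="greater")
        summary["rank_sum_p"] = float(p)
    else:
        summary["rank_sum_p"] = float("nan")
    return out, summary
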