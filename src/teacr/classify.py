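"""Positional classification of merged ACRs relative to gene models.

Classes:

* ``pACR`` — overlaps the 2-kb window upstream of a TSS (promoter ACR)
* ``gACR`` — overlaps a gene body (genic ACR)
* ``dnACR`` — overlaps the 2-kb window downstream of a TTS
* ``dACR`` — more than 2 kb from every gene body (distal ACR)

Precedence for peaks touching several windows: pACR > gACR > dnACR > dACR.
Windows are strand-aware: for a minus-strand gene, "upstream" lies to the
right of the gene body.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval

logger = logging.getLogger("teacr")

CLASSES = ("pACR", "dACR", "gACR", "dnACR")


@dataclass(frozen=True)
class PositionalClass:
    acr_id: str
    acr_class: str
    anchor_gene: str | None
    tss_distance: int | None  # signed; negative = upstream of the TSS


def promoter_window(gene: GeneModel, promoter_bp: int = 2000) -> GenomicInterval | None:
    """2-kb (by default) window upstream of the TSS; None if the gene abuts
    the chromosome start and has no upstream room."""
    iv = gene.interval
    if iv.strand == "+":
        start, end = max(0, iv.start - promoter_bp), iv.start
    else:
        start, end = iv.end, iv.end + promoter_bp
    if end <= start:
        return None
    return GenomicInterval(iv.chrom, start, end)


def downstream_window(gene: GeneModel, downstream_bp: int = 2000) -> GenomicInterval | None:
    iv = gene.interval
    if iv.strand == "+":
        start, end = iv.end, iv.end + downstream_bp
    else:
        start, end = max(0, iv.start - downstream_bp), iv.start
    if end <= start:
        return None
    return GenomicInterval(iv.chrom, start, end)


def _signed_tss_distance(acr: GenomicInterval, gene: GeneModel) -> int:
    """Distance from the ACR midpoint to the TSS, negative when the midpoint
    lies upstream of the gene (strand-aware)."""
    delta = acr.midpoint - gene.tss
    return delta if gene.interval.strand == "+" else -delta


def classify_position(
    acr: GenomicInterval,
    genes: list[GeneModel],
    acr_id: str = "acr",
    promoter_bp: int = 2000,
    downstream_bp: int = 2000,
) -> PositionalClass:
    """Classify one ACR against all genes (brute-force scan).

    A peak whose nearest gene-body edge sits at exactly the window width
    (gap == 2000) overlaps no half-open flank window but is still "within
    2 kb" of the gene; it is assigned the flank class of that side rather
    than dACR, which is reserved for gaps strictly beyond 2 kb.
    """
    if not genes:
        return PositionalClass(acr_id, "dACR", None, None)

    promoter_hit: GeneModel | None = None
    body_hit: GeneModel | None = None
    down_hit: GeneModel | None = None
    nearest: GeneModel | None = None
    nearest_gap: float = float("inf")
    for gene in genes:
        gap = acr.gap_to(gene.interval)
        if gap < nearest_gap:
            nearest, nearest_gap = gene, gap
        pw = promoter_window(gene, promoter_bp)
        if pw is not None and acr.overlaps(pw):
            if promoter_hit is None or abs(_signed_tss_distance(acr, gene)) < abs(
                _signed_tss_distance(acr, promoter_hit)
            ):
                promoter_hit = gene
        if acr.overlaps(gene.interval):
            body_hit = body_hit or gene
        dw = downstream_window(gene, downstream_bp)
        if dw is not None and acr.overlaps(dw):
            down_hit = down_hit or gene

    if promoter_hit is not None:
        return PositionalClass(
            acr_id, "pACR", promoter_hit.gene_id, _signed_tss_distance(acr, promoter_hit)
        )
    if body_hit is not None:
        return PositionalClass(
            acr_id, "gACR", body_hit.gene_id, _signed_tss_distance(acr, body_hit)
        )
    if down_hit is not None:
        return PositionalClass(
            acr_id, "dnACR", down_hit.gene_id, _signed_tss_distance(acr, down_hit)
        )
    assert nearest is not None
    if nearest_gap > promoter_bp:
        return PositionalClass(
            acr_id, "dACR", nearest.gene_id, _signed_tss_distance(acr, nearest)
        )
    # gap == window width exactly: attribute to the flank of the nearest side
    iv = nearest.interval
    acr_is_left = acr.end <= iv.start
    upstream_side = (iv.strand == "+") == acr_is_left
    return PositionalClass(
        acr_id,
        "pACR" if upstream_side else "dnACR",
        nearest.gene_id,
        _signed_tss_distance(acr, nearest),
    )


def classify_positions(
    acrs: dict[str, GenomicInterval] | list[GenomicInterval],
    genes: list[GeneModel],
    promoter_bp: int = 2000,
    downstream_bp: int = 2000,
) -> pd.DataFrame:
    """Classify a collection; returns a tidy table (one row per ACR).

    For large inputs, genes are pre-bucketed per chromosome to avoid the
    full cross product.
    """
    if isinstance(acrs, dict):
        items = list(acrs.items())
    else:
        items = [(f"acr_{i + 1}", iv) for i, iv in enumerate(acrs)]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    rows = []
    for acr_id, iv in items:
        res = classify_position(
            iv, by_chrom.get(iv.chrom, []), acr_id, promoter_bp, downstream_bp
        )
        rows.append(
            {
                "acr_id": res.acr_id,
                "class": res.acr_class,
                "anchor_gene": res.anchor_gene or ".",
                "tss_distance": res.tss_distance if res.tss_distance is not None else ".",
            }
        )
    return pd.DataFrame(rows)


def class_breakdown(class_counts: dict[str, int]) -> pd.DataFrame:
    """Bookkeeping for a classified catalogue: counts, total and one-decimal
    percentages per positional class."""
    total = sum(class_counts.values())
    rows = [
        {"class": c, "count": n, "percent": round(100 * n / total, 1)}
        for c, n in class_counts.items()
    ]
    df = pd.DataFrame(rows)
    df.attrs["total"] = total
    return df


def rpkm(count: int, length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase per million mapped reads."""
    if length_bp <= 0 or total_mapped <= 0:
        raise ValueError("length and total mapped reads must be positive")
    return count * 1e9 / (length_bp * total_mapped)


def accessibility_tertiles(ids: list[str], rpkm_values) -> dict[str, str]:
    """Split peaks into low / mid / high accessibility thirds by RPKM.

    Tertile sizes differ by at most one; ties at a boundary break by
    lexicographic peak id. Degenerate all-equal input collapses to "mid"
    with a warning.
    """
    vals = np.asarray(rpkm_values, dtype=float)
    if len(ids) != len(vals):
        raise ValueError("ids and rpkm values must align")
    if not np.all(np.isfinite(vals)) or (vals < 0).any():
        raise ValueError("RPKM values must be finite and non-negative")
    if len(ids) == 0:
        return {}
    if np.all(vals == vals[0]):
        logger.warning("all RPKM values equal; assigning every peak to 'mid'")
        return {i: "mid" for i in ids}
    order = sorted(range(len(ids)), key=lambda i: (vals[i], ids[i]))
    chunks = np.array_split(np.array(order), 3)
    labels = {}
    for chunk, label in zip(chunks, ("low", "mid", "high")):
        for i in chunk:
            labels[ids[int(i)]] = label
    return labels


def acr_related_genes(
    genes: list[GeneModel],
    acrs: dict[str, GenomicInterval] | list[GenomicInterval],
    flank_bp: int = 2000,
) -> dict[str, list[str]]:
    """Genes whose extended span (body +/- 2 kb) overlaps >= 1 ACR by >= 1 bp.

    The extension is symmetric in genome coordinates (upstream of the TSS
    and downstream of the TTS both widen the span), so strand drops out.
    """
    if isinstance(acrs, dict):
        items = list(acrs.items())
    else:
        items = [(f"acr_{i + 1}", iv) for i, iv in enumerate(acrs)]
    from .intervals import IntervalIndex

    index = IntervalIndex([iv for _, iv in items])
    name_of = {iv: name for name, iv in items}
    related: dict[str, list[str]] = {}
    for g in genes:
        iv = g.interval
        span = GenomicInterval(iv.chrom, max(0, iv.start - flank_bp), iv.end + flank_bp)
        hits = index.overlapping(span)
        if hits:
            related[g.gene_id] = sorted(name_of[h] for h in hits)
    return related
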