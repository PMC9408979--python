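"""Readers and writers for the external formats the pipeline touches.

Everything is emitted in 0-based half-open coordinates: GFF3 and CGmap are
1-based in the file and converted on ingest. BED/narrowPeak/bedGraph are
already 0-based half-open.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CONTEXTS, Acr, GeneModel, GenomicInterval, MethylSite, ValidationError

logger = logging.getLogger("teacr")


class ParseError(ValueError):
    """Raised for malformed input lines; message carries the line number."""


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Acr]:
    """Read BED3/BED6/narrowPeak into peaks.

    The narrowPeak 10th column, when present and not -1, is taken as the
    summit offset; otherwise the summit defaults to the peak midpoint.
    """
    peaks: list[Acr] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"peak_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            summit = -1
            if len(fields) >= 10:
                try:
                    summit = int(fields[9])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad summit column") from exc
            try:
                interval = GenomicInterval(chrom, start, end, strand)
                peaks.append(Acr(interval, name, summit_offset=summit))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: list[Acr], path: str | Path, narrowpeak: bool = False) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if narrowpeak:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}"
                    f"\t0\t-1\t-1\t{p.summit_offset}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\n")


def write_intervals_bed(intervals, path: str | Path, names=None) -> None:
    """BED4 dump of bare intervals (e.g. merged peaks, sweep regions)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_te_bed(path: str | Path, class_column: int = 4, superfamily_column: int = 5):
    """Read a TE annotation BED with class / superfamily label columns.

    Column indices are 0-based and configurable because repeat-annotation
    pipelines disagree about where the superfamily lives.
    """
    from .core import TeFeature

    tes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= max(class_column, superfamily_column):
                raise ParseError(f"{path}:{lineno}: missing TE label columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                tes.append(
                    TeFeature(iv, fields[superfamily_column], fields[class_column])
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return tes


def write_te_bed(tes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, te in enumerate(tes):
            iv = te.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tTE_{i + 1}\t{te.te_class}"
                f"\t{te.superfamily}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Extract ``gene`` features from a GFF3 file, in file order.

    GFF3 is 1-based closed; coordinates are converted to 0-based half-open.
    Strandless genes are rejected because promoter/downstream assignment
    needs an orientation.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=None):
        if feat.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {feat.id}: strand {feat.strand!r} — genes must be stranded"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        genes.append(GeneModel(iv, feat.id))
    return genes


def write_gff3_genes(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tteacr\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}"
                f"\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# CGmap methylation calls
# ---------------------------------------------------------------------------

def read_cgmap(path: str | Path) -> list[MethylSite]:
    """Read CGmap rows (chrom, nuc, pos1, context, dinuc, level, mC, cov).

    Positions convert to 0-based. Sites with zero coverage are retained but
    flagged uncovered via ``MethylSite.covered``.
    """
    sites: list[MethylSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: expected 8 CGmap columns")
            chrom, _nuc, pos1, context = fields[0], fields[1], fields[2], fields[3]
            if context not in CONTEXTS:
                raise ValidationError(f"{path}:{lineno}: unknown context {context!r}")
            try:
                site = MethylSite(
                    chrom, int(pos1) - 1, context, int(fields[6]), int(fields[7])
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            sites.append(site)
    return sites


def write_cgmap(sites: list[MethylSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            level = f"{s.methylated / s.total:.4f}" if s.total else "na"
            dinuc = s.context[:2] if s.context != "CG" else "CG"
            fh.write(
                f"{s.chrom}\tC\t{s.pos + 1}\t{s.context}\t{dinuc}\t{level}"
                f"\t{s.methylated}\t{s.total}\n"
            )


# ---------------------------------------------------------------------------
# VCF (GT-only subset)
# ---------------------------------------------------------------------------

def read_vcf_lite(path: str | Path):
    """Read biallelic SNPs into a haplotype indicator matrix.

    Returns ``(sites, matrix, n_skipped)`` where ``sites`` is a DataFrame
    with columns chrom/pos (0-based) and ``matrix`` is int8 of shape
    (n_sites, 2 x n_samples) holding 0 (ref), 1 (alt) or -1 (missing).
    Multi-allelic records are skipped with a logged count; half-missing
    diploid genotypes are treated as fully missing.
    """
    from cyvcf2 import VCF

    chroms: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gts = var.genotypes  # [a, b, phased] per sample
        row = np.empty(2 * len(gts), dtype=np.int8)
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:  # half-missing -> fully missing (conservative pi)
                a = b = -1
            row[2 * i] = a
            row[2 * i + 1] = b
        chroms.append(var.CHROM)
        positions.append(var.POS - 1)
        rows.append(row)
    vcf.close()
    if n_skipped:
        logger.warning("%s: skipped %d multi-allelic records", path, n_skipped)
    sites = pd.DataFrame({"chrom": chroms, "pos": positions})
    matrix = (
        np.vstack(rows) if rows else np.empty((0, 0), dtype=np.int8)
    )
    return sites, matrix, n_skipped


def write_vcf(path: str | Path, chrom_sizes: dict[str, int], records, samples) -> None:
    """Write a minimal GT-only VCF. ``records`` yields
    (chrom, pos0, ref, alt, list-of-"a/b" genotype strings)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for chrom, pos0, ref, alt, gts in records:
            fh.write(
                f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph / per-base signal
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="t",  # skips optional "track" line
    )
    return df


def bedgraph_to_arrays(
    df: pd.DataFrame, chrom_sizes: dict[str, int], fill: float = 0.0
) -> dict[str, np.ndarray]:
    """Expand bedGraph runs to per-base arrays (positions absent from the
    file get ``fill``; pass ``nan`` for score tracks where absent != 0)."""
    arrays = {c: np.full(size, fill, dtype=float) for c, size in chrom_sizes.items()}
    for chrom, sub in df.groupby("chrom"):
        if chrom not in arrays:
            continue
        arr = arrays[chrom]
        for start, end, value in sub[["start", "end", "value"]].itertuples(index=False):
            arr[start:end] = value
    return arrays


def write_bedgraph(arrays: dict[str, np.ndarray], path: str | Path, decimals: int = 4) -> None:
    """Run-length-encode per-base arrays into bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in arrays:
            vals = np.round(arrays[chrom], decimals)
            if vals.size == 0:
                continue
            change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Read-count down-sampling
# ---------------------------------------------------------------------------

def downsample_counts(counts, target_total: int, seed: int):
    """Subsample per-region read counts to ``target_total`` without
    replacement (multivariate hypergeometric), mirroring the equal-depth
    normalization applied before comparing tissues.

    Reproducible for a fixed seed; the output always sums to exactly
    ``target_total`` and zeros stay zero.
    """
    arr = np.asarray(counts, dtype=np.int64)
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    total = int(arr.sum())
    if target_total > total:
        raise ValidationError(
            f"target_total {target_total} exceeds available reads {total}"
        )
    if target_total == total:
        return arr.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr, target_total).astype(np.int64)


# ---------------------------------------------------------------------------
# Config / logging backbone
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
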