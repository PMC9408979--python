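"""Synthetic miniature genome with the structure the analysis assumes.

The generator emits every input the pipeline consumes — gene models, TE
annotation, per-tissue peak sets with read counts, ATAC coverage, CGmap
methylation calls, wild/cultivated genotype panels and duplicate-gene CDS
pairs — together with ground-truth tables, so every stage can be tested
end-to-end without external downloads.

Structural features emulated:

* a configurable fraction of peaks strictly >50% covered by TE sequence
  (TE-derived), the rest kept clear of the threshold;
* hypermethylated TE bodies with hypomethylated embedded peaks;
* tissue-restricted accessibility for a minority of peaks (one high-count
  tissue, low counts elsewhere);
* diversity-depleted 100-kb windows in the cultivated panel (sweeps);
* duplicate gene pairs with controlled synonymous / nonsynonymous
  divergence and correlated accessibility/expression shifts.

One global seed drives per-component child generators derived by fixed
offsets, so each component is individually reproducible and the whole
bundle is byte-identical for a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .core import Acr, GeneModel, GenomicInterval, MethylSite, TeFeature
from .duplicates import (
    CODON_TABLE,
    STOP_CODONS,
    codon_sites,
    jukes_cantor,
)

TISSUES = ("YL", "FL", "RT", "SP", "LP", "YP")

#: superfamily -> (weight, min length, max length); DNA transposons dominate
#: copy number while retrotransposons carry the long elements, mirroring the
#: composition of a TE-rich cereal genome.
TE_SUPERFAMILIES = {
    "Mutator": (0.18, 300, 3000, "DNA"),
    "hAT": (0.13, 300, 3000, "DNA"),
    "Helitron": (0.13, 500, 4000, "DNA"),
    "PIF_Harbinger": (0.12, 100, 500, "DNA"),
    "Tc1_Mariner": (0.07, 100, 600, "DNA"),
    "CACTA": (0.07, 1000, 5000, "DNA"),
    "Gypsy": (0.12, 2000, 6000, "retrotransposon"),
    "Copia": (0.08, 1500, 5000, "retrotransposon"),
    "LINE": (0.06, 1000, 5000, "retrotransposon"),
    "SINE": (0.04, 150, 400, "retrotransposon"),
}

# published rice catalogue subgroup mix (29 : 532 : 509 of 1070 pairs)
SUBGROUP_FRACTIONS = (29 / 1070, 532 / 1070, 509 / 1070)


class SimulationError(RuntimeError):
    """Raised when a placement constraint cannot be satisfied."""


@dataclass
class SimConfig:
    """Study conditions for the miniature genome."""

    n_chroms: int = 4
    chrom_len: int = 1_500_000
    n_genes: int = 600
    n_tes: int = 1200
    n_acrs: int = 1000
    frac_te_derived_acrs: float = 0.08
    frac_tissue_specific: float = 0.15
    tissues: tuple[str, ...] = TISSUES
    te_body_methylation: dict = field(
        default_factory=lambda: {"CG": 0.80, "CHG": 0.60, "CHH": 0.15}
    )
    acr_methylation: dict = field(
        default_factory=lambda: {"CG": 0.05, "CHG": 0.03, "CHH": 0.02}
    )
    background_methylation: dict = field(
        default_factory=lambda: {"CG": 0.40, "CHG": 0.20, "CHH": 0.05}
    )
    n_sweeps: int = 3
    sweep_pi_reduction: float = 10.0
    n_gene_pairs: int = 60
    ks_range: tuple[float, float] = (0.05, 1.0)
    omega_range: tuple[float, float] = (0.1, 0.5)
    cds_codons: int = 400
    seed: int = 0
    # sampling depths / rates
    methylation_depth: float = 10.0
    methylation_site_rate: float = 0.05
    variant_density: float = 0.004
    wild_diploids: int = 5       # five wild plants -> 10 haplotypes
    cult_diploids: int = 10
    window_bp: int = 100_000
    # read-count model
    common_mean: float = 60.0
    specific_high_mean: float = 240.0
    specific_low_mean: float = 6.0
    nb_dispersion: float = 10.0
    te_acr_count_factor: float = 0.7  # TE-derived peaks are less accessible
    library_scale: float = 5.0        # mapped total = scale x in-peak reads

    def __post_init__(self) -> None:
        for frac in (self.frac_te_derived_acrs, self.frac_tissue_specific):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.sweep_pi_reduction < 1:
            raise ValueError("sweep_pi_reduction must be >= 1")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_len for i in range(self.n_chroms)}


@dataclass
class SimBundle:
    """Paths to everything the generator wrote."""

    out_dir: Path
    config: SimConfig
    genome_fa: Path
    chrom_sizes_tsv: Path
    genes_gff3: Path
    tes_bed: Path
    acr_narrowpeaks: dict[str, Path]
    counts_tsv: Path
    totals_tsv: Path
    coverage_bedgraph: Path
    cgmap: Path
    wild_vcf: Path
    cult_vcf: Path
    cds_fasta: Path
    pairs_tsv: Path
    expression_tsv: Path
    truth_acrs_tsv: Path
    truth_sweeps_tsv: Path
    truth_pairs_tsv: Path


# child-generator offsets (fixed; component-level reproducibility)
_OFFSETS = {
    "sequence": 1, "genes": 2, "tes": 3, "acrs": 4, "counts": 5,
    "methylation": 6, "genotypes": 7, "cds": 8, "coverage": 9, "pairs": 10,
    "expression": 11,
}


def _rng(config: SimConfig, component: str) -> np.random.Generator:
    return np.random.default_rng((config.seed * 131 + _OFFSETS[component]) % (2**31))


# ---------------------------------------------------------------------------
# CDS pair mutagenesis
# ---------------------------------------------------------------------------

def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    sense = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)
    return "".join(rng.choice(sense) for _ in range(n_codons))


def _codon_candidates(codon: str) -> tuple[list, list]:
    """Single-nt changes of ``codon`` split into (synonymous, nonsynonymous),
    excluding changes that create a stop codon."""
    syn, nonsyn = [], []
    aa = CODON_TABLE[codon]
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            (syn if CODON_TABLE[alt] == aa else nonsyn).append((pos, base))
    return syn, nonsyn


def mutate_cds_pair(
    ancestral_cds: str,
    target_syn_subs: int,
    target_nonsyn_subs: int,
    seed: int,
) -> tuple[str, str, dict[str, int]]:
    """Diverge a copy of the ancestral CDS by exact substitution counts.

    Substitutions are applied one at a time to the second copy; each is
    classified (synonymous / nonsynonymous) in the codon context current at
    the time of application, and changes that would create a stop codon are
    never drawn. Returns (cds_a, cds_b, truth counts).
    """
    from .duplicates import validate_cds

    validate_cds(ancestral_cds, "ancestral_cds")
    rng = np.random.default_rng(seed)
    codons = [ancestral_cds[i : i + 3] for i in range(0, len(ancestral_cds), 3)]
    cands = [_codon_candidates(c) for c in codons]
    plan = ["S"] * target_syn_subs + ["N"] * target_nonsyn_subs
    rng.shuffle(plan)
    applied = {"syn": 0, "nonsyn": 0}
    for kind in plan:
        idx = 0 if kind == "S" else 1
        weights = np.array([len(c[idx]) for c in cands], dtype=float)
        total = weights.sum()
        if total == 0:
            raise SimulationError(
                f"no remaining {'synonymous' if kind == 'S' else 'nonsynonymous'} "
                "substitution is possible; lower the targets"
            )
        j = int(rng.choice(len(codons), p=weights / total))
        pos, base = cands[j][idx][int(rng.integers(len(cands[j][idx])))]
        codons[j] = codons[j][:pos] + base + codons[j][pos + 1 :]
        cands[j] = _codon_candidates(codons[j])
        applied["syn" if kind == "S" else "nonsyn"] += 1
    return ancestral_cds, "".join(codons), applied


# ---------------------------------------------------------------------------
# Placement helpers
# ---------------------------------------------------------------------------

def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    margin = 5000
    k = 0
    for ci, chrom in enumerate(sorted(config.chrom_sizes)):
        n = per_chrom[ci]
        usable = config.chrom_len - 2 * margin
        slot = usable // max(n, 1)
        if slot < 4500:
            raise SimulationError("chromosome too short for the requested gene count")
        for i in range(n):
            length = int(rng.integers(1000, 3001))
            lo = margin + i * slot
            start = lo + int(rng.integers(0, slot - length - 1000))
            strand = "+" if rng.random() < 0.5 else "-"
            k += 1
            genes.append(
                GeneModel(
                    GenomicInterval(chrom, start, start + length, strand),
                    f"gene_{k:04d}",
                )
            )
    return genes


def _union_cov(iv: GenomicInterval, spans: list[tuple[int, int]]) -> float:
    segs = sorted(
        (max(iv.start, s), min(iv.end, e)) for s, e in spans if s < iv.end and e > iv.start
    )
    cov = 0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                cov += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        cov += cur_e - cur_s
    return cov / iv.length


def _overlaps_any(chrom: str, start: int, end: int, zones: dict[str, list]) -> bool:
    return any(s < end and e > start for s, e in zones.get(chrom, ()))


def _truth_position(iv: GenomicInterval, genes: list[GeneModel], flank: int = 2000) -> str:
    """Generator-side positional truth (same published rule, coded inline)."""
    in_promoter = in_body = in_down = False
    nearest = math.inf
    nearest_gene = None
    for g in genes:
        gi = g.interval
        if gi.chrom != iv.chrom:
            continue
        gap = iv.gap_to(gi)
        if gap < nearest:
            nearest, nearest_gene = gap, g
        if iv.overlaps(gi):
            in_body = True
        if gi.strand == "+":
            up = (max(0, gi.start - flank), gi.start)
            down = (gi.end, gi.end + flank)
        else:
            up = (gi.end, gi.end + flank)
            down = (max(0, gi.start - flank), gi.start)
        if up[0] < up[1] and iv.start < up[1] and up[0] < iv.end:
            in_promoter = True
        if down[0] < down[1] and iv.start < down[1] and down[0] < iv.end:
            in_down = True
    if in_promoter:
        return "pACR"
    if in_body:
        return "gACR"
    if in_down:
        return "dnACR"
    if nearest > flank or nearest_gene is None:
        return "dACR"
    gi = nearest_gene.interval
    acr_left = iv.end <= gi.start
    return "pACR" if (gi.strand == "+") == acr_left else "dnACR"


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig, out_dir: str | Path) -> SimBundle:
    """Write the full synthetic bundle to ``out_dir`` and return its paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom_sizes = config.chrom_sizes
    chroms = sorted(chrom_sizes)

    # --- genome sequence -------------------------------------------------
    rng_seq = _rng(config, "sequence")
    base_arr = np.frombuffer(b"ACGT", dtype="S1")
    genome = {
        c: rng_seq.choice(base_arr, size=chrom_sizes[c], p=[0.28, 0.22, 0.22, 0.28])
        .tobytes()
        .decode()
        for c in chroms
    }

    # --- genes and duplicate-pair designations ---------------------------
    rng_genes = _rng(config, "genes")
    genes = _place_genes(config, rng_genes)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    gene_index_in_chrom: dict[str, int] = {}
    for g in genes:
        lst = genes_by_chrom.setdefault(g.interval.chrom, [])
        gene_index_in_chrom[g.gene_id] = len(lst)
        lst.append(g)

    rng_pairs = _rng(config, "pairs")
    n_pairs = config.n_gene_pairs
    g1 = max(1, round(SUBGROUP_FRACTIONS[0] * n_pairs)) if n_pairs else 0
    g2 = round(SUBGROUP_FRACTIONS[1] * n_pairs)
    g3 = n_pairs - g1 - g2
    if g3 < 0:
        raise SimulationError("n_gene_pairs too small for the subgroup mix")
    # non-adjacent genes only, so designated TSS neighbourhoods never collide
    eligible = [
        g.gene_id for g in genes if gene_index_in_chrom[g.gene_id] % 2 == 0
    ]
    if len(eligible) < 2 * n_pairs:
        raise SimulationError("not enough well-spaced genes for the requested pairs")
    chosen = list(rng_pairs.choice(eligible, size=2 * n_pairs, replace=False))
    gene_of = {g.gene_id: g for g in genes}
    pair_defs = []  # (pair_id, gene_a, gene_b, status_a, status_b)
    statuses = (
        [("te_acr", "te_acr")] * g1
        + [("te_acr", "regular_acr")] * g2
        + [("te_acr", "none")] * g3
    )
    modes = rng_pairs.choice(
        ["WGD", "tandem", "proximal", "transposed", "dispersed"], size=n_pairs
    )
    for i, (sa, sb) in enumerate(statuses):
        pair_defs.append(
            (f"pair_{i + 1:04d}", chosen[2 * i], chosen[2 * i + 1], sa, sb, modes[i])
        )

    # designation per gene: te / regular / none
    designation: dict[str, str] = {}
    for _pid, ga, gb, sa, sb, _m in pair_defs:
        designation[ga] = {"te_acr": "te", "regular_acr": "regular", "none": "none"}[sa]
        designation[gb] = {"te_acr": "te", "regular_acr": "regular", "none": "none"}[sb]

    # TSS windows of all pair genes are reserved: generic peaks stay out
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for gid, _ in designation.items():
        g = gene_of[gid]
        reserved[g.interval.chrom].append((g.tss - 600, g.tss + 601))

    # --- designated TEs + peaks around pair-gene TSSs ---------------------
    rng_tes = _rng(config, "tes")
    rng_acrs = _rng(config, "acrs")
    tes: list[TeFeature] = []
    te_clear: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}  # no-TE zones
    acrs: list[dict] = []  # dicts; finalized later
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}  # peak spans

    def add_acr(chrom, start, end, role, te_cov):
        name = f"acr_{len(acrs) + 1:05d}"
        occupied[chrom].append((start - 20, end + 20))
        acrs.append(
            {
                "acr_id": name, "chrom": chrom, "start": int(start), "end": int(end),
                "summit_offset": int((end - start) // 3 + rng_acrs.integers(0, max(1, (end - start) // 3))),
                "role": role, "te_coverage": float(te_cov),
                "te_derived": bool(te_cov > 0.5), "specific_tissue": ".",
            }
        )
        return name

    sf_names = sorted(TE_SUPERFAMILIES)
    sf_weights = np.array([TE_SUPERFAMILIES[s][0] for s in sf_names])
    sf_weights = sf_weights / sf_weights.sum()
    dna_sfs = [s for s in sf_names if TE_SUPERFAMILIES[s][3] == "DNA"]

    for gid, kind in sorted(designation.items()):
        g = gene_of[gid]
        chrom, tss = g.interval.chrom, g.tss
        if kind == "te":
            sf = dna_sfs[int(rng_tes.integers(len(dna_sfs)))]
            te_len = int(rng_tes.integers(1400, 2601))
            te_start = max(0, tss - te_len // 2)
            tes.append(
                TeFeature(GenomicInterval(chrom, te_start, te_start + te_len), sf)
            )
            acr_len = int(rng_acrs.integers(300, 501))
            center = tss + int(rng_acrs.integers(-100, 101))
            a_start = max(te_start, center - acr_len // 2)
            a_end = min(te_start + te_len, a_start + acr_len)
            add_acr(chrom, a_start, a_end, f"pair_te:{gid}", 1.0)
        elif kind == "regular":
            acr_len = int(rng_acrs.integers(300, 501))
            center = tss + int(rng_acrs.integers(-100, 101))
            a_start = max(0, center - acr_len // 2)
            add_acr(chrom, a_start, a_start + acr_len, f"pair_regular:{gid}", 0.0)
            te_clear[chrom].append((a_start - 100, a_start + acr_len + 100))
        # "none": reserved window stays empty

    # --- generic TEs ------------------------------------------------------
    n_generic_tes = config.n_tes - len(tes)
    for _ in range(max(0, n_generic_tes)):
        for _try in range(200):
            sf = rng_tes.choice(sf_names, p=sf_weights)
            _w, lo, hi, _cls = TE_SUPERFAMILIES[sf]
            length = int(rng_tes.integers(lo, hi + 1))
            chrom = chroms[int(rng_tes.integers(len(chroms)))]
            start = int(rng_tes.integers(0, chrom_sizes[chrom] - length))
            if _overlaps_any(chrom, start, start + length, te_clear):
                continue
            tes.append(TeFeature(GenomicInterval(chrom, start, start + length), sf))
            break
        else:
            raise SimulationError("could not place a TE clear of reserved peak zones")

    te_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for t in tes:
        te_spans[t.interval.chrom].append((t.interval.start, t.interval.end))
    big_tes = [t for t in tes if t.interval.length >= 400]

    # --- generic peaks ----------------------------------------------------
    n_te_target = round(config.frac_te_derived_acrs * config.n_acrs)
    n_designated_te = sum(1 for a in acrs if a["te_derived"])
    n_generic_te = max(0, n_te_target - n_designated_te)
    n_generic = config.n_acrs - len(acrs)
    n_generic_plain = n_generic - n_generic_te
    if n_generic_plain < 0:
        raise SimulationError("frac_te_derived_acrs incompatible with pair designations")

    for _ in range(n_generic_te):
        for _try in range(500):
            te = big_tes[int(rng_acrs.integers(len(big_tes)))]
            ti = te.interval
            acr_len = int(rng_acrs.integers(200, min(601, ti.length + 1)))
            cov = rng_acrs.uniform(0.55, 1.0)
            ov = max(int(round(cov * acr_len)), acr_len // 2 + 1)
            chrom = ti.chrom
            if rng_acrs.random() < 0.5:
                start = ti.end - ov              # peak juts out to the right
            else:
                start = ti.start + ov - acr_len  # juts out to the left
            end = start + acr_len
            if start < 0 or end > chrom_sizes[chrom]:
                continue
            if _overlaps_any(chrom, start, end, occupied):
                continue
            if _overlaps_any(chrom, start, end, reserved):
                continue
            true_cov = _union_cov(GenomicInterval(chrom, start, end), te_spans[chrom])
            if true_cov <= 0.52:  # other TEs may not rescue the intended overlap
                continue
            add_acr(chrom, start, end, "generic", true_cov)
            break
        else:
            raise SimulationError("could not place a TE-derived peak above the coverage threshold")

    for _ in range(n_generic_plain):
        for _try in range(500):
            acr_len = int(rng_acrs.integers(200, 601))
            chrom = chroms[int(rng_acrs.integers(len(chroms)))]
            start = int(rng_acrs.integers(0, chrom_sizes[chrom] - acr_len))
            end = start + acr_len
            if _overlaps_any(chrom, start, end, occupied):
                continue
            if _overlaps_any(chrom, start, end, reserved):
                continue
            cov = _union_cov(GenomicInterval(chrom, start, end), te_spans[chrom])
            if cov > 0.45:  # keep a margin below the >50% rule
                continue
            add_acr(chrom, start, end, "generic", cov)
            break
        else:
            raise SimulationError("could not place a peak below the TE-coverage threshold")

    # --- tissue specificity ----------------------------------------------
    generic_ids = [a["acr_id"] for a in acrs if a["role"] == "generic"]
    n_specific = round(config.frac_tissue_specific * config.n_acrs)
    if n_specific > len(generic_ids):
        raise SimulationError("frac_tissue_specific exceeds the generic peak pool")
    specific_ids = (
        list(rng_acrs.choice(generic_ids, size=n_specific, replace=False))
        if n_specific
        else []
    )
    tissue_list = list(config.tissues)
    by_id = {a["acr_id"]: a for a in acrs}
    for i, acr_id in enumerate(sorted(specific_ids)):
        by_id[acr_id]["specific_tissue"] = tissue_list[i % len(tissue_list)]

    # --- positional truth -------------------------------------------------
    for a in acrs:
        iv = GenomicInterval(a["chrom"], a["start"], a["end"])
        a["position_class"] = _truth_position(iv, genes_by_chrom.get(a["chrom"], []))

    acrs.sort(key=lambda a: (a["chrom"], a["start"]))

    # --- read counts ------------------------------------------------------
    rng_counts = _rng(config, "counts")
    r = config.nb_dispersion

    def nb(mean: float, size=None):
        return rng_counts.negative_binomial(r, r / (r + mean), size=size)

    counts = pd.DataFrame(
        0, index=[a["acr_id"] for a in acrs], columns=tissue_list, dtype=np.int64
    )
    for a in acrs:
        factor = config.te_acr_count_factor if a["te_derived"] else 1.0
        if a["specific_tissue"] != ".":
            for t in tissue_list:
                mean = (
                    config.specific_high_mean
                    if t == a["specific_tissue"]
                    else config.specific_low_mean
                )
                counts.loc[a["acr_id"], t] = int(nb(mean * factor))
        else:
            for t in tissue_list:
                counts.loc[a["acr_id"], t] = int(nb(config.common_mean * factor))

    # accessibility divergence for pairs with both copies quantified
    acr_of_gene = {}
    for a in acrs:
        if a["role"].startswith("pair_"):
            acr_of_gene[a["role"].split(":", 1)[1]] = a["acr_id"]
    analysis_tissue = "SP" if "SP" in tissue_list else tissue_list[0]
    rng_expr = _rng(config, "expression")
    expression = {g.gene_id: float(rng_expr.lognormal(2.0, 1.0)) for g in genes}
    pair_truth_rows = []
    for pid, ga, gb, sa, sb, mode in pair_defs:
        delta_e = float(rng_expr.normal(0.0, 1.5))
        delta_a = 0.6 * delta_e + float(rng_expr.normal(0.0, 0.5))
        expression[gb] = expression[ga] / 2**delta_e
        if ga in acr_of_gene and gb in acr_of_gene:
            ca = int(counts.loc[acr_of_gene[ga], analysis_tissue])
            counts.loc[acr_of_gene[gb], analysis_tissue] = max(
                1, int(round(ca / 2**delta_a))
            )
        pair_truth_rows.append(
            {
                "pair_id": pid, "gene_a": ga, "gene_b": gb, "mode": mode,
                "tss_acr_a": sa, "tss_acr_b": sb,
                "delta_expression_log2": delta_e, "delta_accessibility_log2": delta_a,
            }
        )

    totals = {t: int(counts[t].sum() * config.library_scale) for t in tissue_list}

    # --- coverage track (analysis tissue) ---------------------------------
    cov_arrays = {c: np.full(chrom_sizes[c], 0.5) for c in chroms}
    mean_count = max(float(counts[analysis_tissue].mean()), 1.0)
    for a in acrs:
        c0 = counts.loc[a["acr_id"], analysis_tissue]
        height = 10.0 * float(c0) / mean_count
        length = a["end"] - a["start"]
        summit = a["start"] + a["summit_offset"]
        pos = np.arange(a["start"], a["end"])
        tri = 1.0 - np.abs(pos - summit) / max(summit - a["start"], a["end"] - summit, 1)
        cov_arrays[a["chrom"]][a["start"] : a["end"]] += height * np.clip(tri, 0, None)

    # --- methylation ------------------------------------------------------
    rng_me = _rng(config, "methylation")
    acr_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for a in acrs:
        acr_spans[a["chrom"]].append((a["start"], a["end"]))
    sites: list[MethylSite] = []
    for chrom in chroms:
        seq = np.frombuffer(genome[chrom].encode(), dtype="S1")
        zone = np.zeros(chrom_sizes[chrom], dtype=np.int8)  # 0 bg, 1 TE, 2 peak
        for s, e in te_spans[chrom]:
            zone[max(0, s) : e] = 1
        for s, e in acr_spans[chrom]:
            zone[max(0, s) : e] = 2
        is_c = seq == b"C"
        is_g = seq == b"G"
        # plus-strand cytosines
        pos_c = np.flatnonzero(is_c[:-2])
        ctx_c = np.where(
            is_g[pos_c + 1], "CG", np.where(is_g[pos_c + 2], "CHG", "CHH")
        )
        # minus-strand cytosines (G on the plus strand)
        pos_g = np.flatnonzero(is_g)
        pos_g = pos_g[pos_g >= 2]
        ctx_g = np.where(
            is_c[pos_g - 1], "CG", np.where(is_c[pos_g - 2], "CHG", "CHH")
        )
        pos_all = np.concatenate([pos_c, pos_g])
        ctx_all = np.concatenate([ctx_c, ctx_g])
        order = np.argsort(pos_all, kind="stable")
        pos_all, ctx_all = pos_all[order], ctx_all[order]
        keep = rng_me.random(len(pos_all)) < config.methylation_site_rate
        pos_all, ctx_all = pos_all[keep], ctx_all[keep]
        level_map = {
            0: config.background_methylation,
            1: config.te_body_methylation,
            2: config.acr_methylation,
        }
        p = np.array(
            [level_map[int(zone[pp])][cc] for pp, cc in zip(pos_all, ctx_all)]
        )
        depth = rng_me.poisson(config.methylation_depth, size=len(pos_all))
        meth = rng_me.binomial(depth, p)
        for pp, cc, mm, dd in zip(pos_all, ctx_all, meth, depth):
            sites.append(MethylSite(chrom, int(pp), str(cc), int(mm), int(dd)))

    # --- genotype panels --------------------------------------------------
    rng_gt = _rng(config, "genotypes")
    n_windows_total = sum(
        math.ceil(chrom_sizes[c] / config.window_bp) for c in chroms
    )
    all_windows = [
        (c, w * config.window_bp, min((w + 1) * config.window_bp, chrom_sizes[c]))
        for c in chroms
        for w in range(math.ceil(chrom_sizes[c] / config.window_bp))
    ]
    if config.n_sweeps > n_windows_total:
        raise SimulationError("more sweeps requested than windows available")
    sweep_idx = sorted(
        rng_gt.choice(n_windows_total, size=config.n_sweeps, replace=False)
    ) if config.n_sweeps else []
    sweep_windows = [all_windows[int(i)] for i in sweep_idx]
    sweep_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for c, s, e in sweep_windows:
        sweep_by_chrom[c].append((s, e))

    def make_panel(n_diploids: int, thin_sweeps: bool):
        records = []
        for chrom in chroms:
            n_sites = rng_gt.poisson(config.variant_density * chrom_sizes[chrom])
            pos = np.sort(
                rng_gt.choice(chrom_sizes[chrom], size=n_sites, replace=False)
            )
            if thin_sweeps and config.sweep_pi_reduction > 1:
                keep = np.ones(len(pos), dtype=bool)
                for s, e in sweep_by_chrom[chrom]:
                    inside = (pos >= s) & (pos < e)
                    keep[inside] &= (
                        rng_gt.random(int(inside.sum())) < 1.0 / config.sweep_pi_reduction
                    )
                pos = pos[keep]
            freqs = rng_gt.uniform(0.05, 0.95, size=len(pos))
            for pp, fq in zip(pos, freqs):
                hap = (rng_gt.random(2 * n_diploids) < fq).astype(int)
                gts = [f"{hap[2 * i]}/{hap[2 * i + 1]}" for i in range(n_diploids)]
                ref = genome[chrom][pp]
                alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
                records.append((chrom, int(pp), ref, alt, gts))
        return records

    wild_records = make_panel(config.wild_diploids, thin_sweeps=False)
    cult_records = make_panel(config.cult_diploids, thin_sweeps=True)

    # --- CDS pairs --------------------------------------------------------
    rng_cds = _rng(config, "cds")
    cds_seqs: dict[str, str] = {}
    for row in pair_truth_rows:
        anc = random_cds(config.cds_codons, rng_cds)
        s_anc = n_anc = 0.0
        for i in range(0, len(anc), 3):
            s, n = codon_sites(anc[i : i + 3])
            s_anc += s
            n_anc += n
        ks = float(rng_cds.uniform(*config.ks_range))
        omega = float(rng_cds.uniform(*config.omega_range))
        ka = omega * ks
        # targets are substitution EVENTS; truth rates are events per site,
        # which the JC-corrected NG86 estimate is built to recover
        t_syn = int(round(ks * s_anc))
        t_non = int(round(ka * n_anc))
        sub_seed = int(rng_cds.integers(0, 2**31 - 1))
        cds_a, cds_b, applied = mutate_cds_pair(anc, t_syn, t_non, sub_seed)
        cds_seqs[f"{row['pair_id']}_a"] = cds_a
        cds_seqs[f"{row['pair_id']}_b"] = cds_b
        row.update(
            {
                "syn_subs": applied["syn"],
                "nonsyn_subs": applied["nonsyn"],
                "ks_true": applied["syn"] / s_anc,
                "ka_true": applied["nonsyn"] / n_anc,
            }
        )
        row["omega_true"] = (
            row["ka_true"] / row["ks_true"] if row["ks_true"] else float("nan")
        )

    # --- write everything -------------------------------------------------
    paths = {}
    paths["genome_fa"] = out / "genome.fa"
    tio.write_fasta(genome, paths["genome_fa"])
    paths["chrom_sizes_tsv"] = out / "chrom.sizes"
    with open(paths["chrom_sizes_tsv"], "w") as fh:
        for c in chroms:
            fh.write(f"{c}\t{chrom_sizes[c]}\n")
    paths["genes_gff3"] = out / "genes.gff3"
    tio.write_gff3_genes(genes, paths["genes_gff3"])
    paths["tes_bed"] = out / "tes.bed"
    tio.write_te_bed(tes, paths["tes_bed"])

    acr_narrowpeaks = {}
    for t in tissue_list:
        peaks = [
            Acr(
                GenomicInterval(a["chrom"], a["start"], a["end"]),
                a["acr_id"],
                a["summit_offset"],
            )
            for a in acrs
            if a["specific_tissue"] in (".", t)
        ]
        p = out / f"acrs_{t}.narrowPeak"
        tio.write_bed(peaks, p, narrowpeak=True)
        acr_narrowpeaks[t] = p

    paths["counts_tsv"] = out / "acr_counts.tsv"
    counts.rename_axis("acr_id").to_csv(paths["counts_tsv"], sep="\t")
    paths["totals_tsv"] = out / "totals.tsv"
    pd.Series(totals, name="total_mapped").rename_axis("tissue").to_csv(
        paths["totals_tsv"], sep="\t"
    )
    paths["coverage_bedgraph"] = out / f"coverage_{analysis_tissue}.bedGraph"
    tio.write_bedgraph(cov_arrays, paths["coverage_bedgraph"])
    paths["cgmap"] = out / "methylation.cgmap"
    tio.write_cgmap(sites, paths["cgmap"])
    paths["wild_vcf"] = out / "wild.vcf"
    tio.write_vcf(
        paths["wild_vcf"], chrom_sizes, wild_records,
        [f"wild_{i + 1}" for i in range(config.wild_diploids)],
    )
    paths["cult_vcf"] = out / "cultivated.vcf"
    tio.write_vcf(
        paths["cult_vcf"], chrom_sizes, cult_records,
        [f"cult_{i + 1}" for i in range(config.cult_diploids)],
    )
    paths["cds_fasta"] = out / "cds_pairs.fa"
    tio.write_fasta(cds_seqs, paths["cds_fasta"])

    pairs_df = pd.DataFrame(pair_truth_rows)
    paths["pairs_tsv"] = out / "pairs.tsv"
    pairs_df[["pair_id", "gene_a", "gene_b", "mode"]].to_csv(
        paths["pairs_tsv"], sep="\t", index=False
    )
    paths["expression_tsv"] = out / "expression.tsv"
    pd.Series(expression, name=f"fpkm_{analysis_tissue}").rename_axis("gene_id").to_csv(
        paths["expression_tsv"], sep="\t", float_format="%.4f"
    )

    truth_acrs = pd.DataFrame(acrs)[
        [
            "acr_id", "chrom", "start", "end", "summit_offset", "te_derived",
            "te_coverage", "position_class", "specific_tissue", "role",
        ]
    ]
    paths["truth_acrs_tsv"] = out / "truth_acrs.tsv"
    truth_acrs.to_csv(paths["truth_acrs_tsv"], sep="\t", index=False, float_format="%.4f")
    paths["truth_sweeps_tsv"] = out / "truth_sweeps.tsv"
    pd.DataFrame(sweep_windows, columns=["chrom", "start", "end"]).to_csv(
        paths["truth_sweeps_tsv"], sep="\t", index=False
    )
    paths["truth_pairs_tsv"] = out / "truth_pairs.tsv"
    pairs_df.to_csv(paths["truth_pairs_tsv"], sep="\t", index=False, float_format="%.6f")

    return SimBundle(
        out_dir=out, config=config, acr_narrowpeaks=acr_narrowpeaks, **paths
    )
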