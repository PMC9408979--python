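"""Generator structure: file validity, truth bookkeeping, determinism."""
import filecmp

import numpy as np
import pandas as pd
import pytest

from teacr import io as tio
from teacr.duplicates import translate
from teacr.simulate import (
    SimConfig,
    SimulationError,
    mutate_cds_pair,
    random_cds,
    simulate_genome,
)

from conftest import SMALL_CONFIG


class TestMutateCdsPair:
    ANC = random_cds(30, np.random.default_rng(0))

    def test_zero_targets_identity(self):
        a, b, applied = mutate_cds_pair(self.ANC, 0, 0, seed=1)
        assert a == b == self.ANC
        assert applied == {"syn": 0, "nonsyn": 0}

    def test_synonymous_only_preserves_protein(self):
        a, b, applied = mutate_cds_pair(self.ANC, 3, 0, seed=2)
        assert translate(a) == translate(b)
        assert applied["syn"] == 3
        ndiff = sum(x != y for x, y in zip(a, b))
        assert 1 <= ndiff <= 3  # repeat hits may coincide, never exceed targets

    def test_nonsynonymous_changes_protein(self):
        a, b, applied = mutate_cds_pair(self.ANC, 0, 5, seed=3)
        assert translate(a) != translate(b)
        assert "*" not in translate(b)  # stops never created

    def test_unachievable_target_errors(self):
        with pytest.raises(SimulationError):
            mutate_cds_pair("ATGTGG", 5, 0, seed=1)  # Met+Trp have no syn changes

    def test_seeded_reproducibility(self):
        r1 = mutate_cds_pair(self.ANC, 4, 4, seed=9)
        r2 = mutate_cds_pair(self.ANC, 4, 4, seed=9)
        assert r1 == r2


class TestBundleStructure:
    def test_files_pass_their_readers(self, small_bundle):
        b = small_bundle
        genes = tio.read_gff3_genes(b.genes_gff3)
        tes = tio.read_te_bed(b.tes_bed)
        assert len(genes) == b.config.n_genes
        assert len(tes) == b.config.n_tes
        for path in b.acr_narrowpeaks.values():
            peaks = tio.read_bed(path)
            assert all(p.summit_offset < p.interval.length for p in peaks)
        sites = tio.read_cgmap(b.cgmap)
        assert len(sites) > 100
        vsites, matrix, skipped = tio.read_vcf_lite(b.wild_vcf)
        assert skipped == 0
        assert matrix.shape == (len(vsites), 2 * b.config.wild_diploids)
        seqs = tio.read_fasta(b.cds_fasta)
        assert len(seqs) == 2 * b.config.n_gene_pairs

    def test_truth_te_fraction_matches_config(self, small_bundle):
        from teacr.simulate import SUBGROUP_FRACTIONS

        cfg = small_bundle.config
        truth = pd.read_csv(small_bundle.truth_acrs_tsv, sep="\t")
        assert len(truth) == cfg.n_acrs
        # TE-derived peaks designated at pair-gene TSSs can exceed the target
        g1 = max(1, round(SUBGROUP_FRACTIONS[0] * cfg.n_gene_pairs))
        g2 = round(SUBGROUP_FRACTIONS[1] * cfg.n_gene_pairs)
        designated = 2 * g1 + g2 + (cfg.n_gene_pairs - g1 - g2)
        expected = max(round(cfg.frac_te_derived_acrs * cfg.n_acrs), designated)
        assert int(truth["te_derived"].sum()) == expected

    def test_counts_cover_every_acr_and_tissue(self, small_bundle):
        counts = pd.read_csv(small_bundle.counts_tsv, sep="\t", index_col=0)
        truth = pd.read_csv(small_bundle.truth_acrs_tsv, sep="\t")
        assert sorted(counts.index) == sorted(truth["acr_id"])
        assert list(counts.columns) == list(small_bundle.config.tissues)

    def test_tissue_specific_peaks_restricted_to_their_tissue(self, small_bundle):
        truth = pd.read_csv(small_bundle.truth_acrs_tsv, sep="\t")
        specific = truth[truth["specific_tissue"] != "."]
        assert len(specific) == round(
            small_bundle.config.frac_tissue_specific * small_bundle.config.n_acrs
        )
        for tissue, path in small_bundle.acr_narrowpeaks.items():
            names = {p.name for p in tio.read_bed(path)}
            for row in specific.itertuples():
                present = row.acr_id in names
                assert present == (row.specific_tissue == tissue)

    def test_zero_specific_fraction(self, tmp_path):
        cfg = dict(SMALL_CONFIG)
        cfg["frac_tissue_specific"] = 0.0
        bundle = simulate_genome(SimConfig(seed=3, **cfg), tmp_path / "z")
        truth = pd.read_csv(bundle.truth_acrs_tsv, sep="\t")
        assert (truth["specific_tissue"] == ".").all()


class TestNeutralPanels:
    def test_no_reduction_leaves_panels_indistinguishable(self, tmp_path):
        """With the sweep depletion switched off, wild and cultivated
        window-pi distributions agree (KS test over 200 windows)."""
        from scipy.stats import ks_2samp

        from teacr.popgen import variant_summary, windowed_pi

        cfg = SimConfig(
            seed=5, n_chroms=2, chrom_len=10_000_000, n_genes=60, n_tes=150,
            n_acrs=100, n_gene_pairs=6, n_sweeps=3, sweep_pi_reduction=1.0,
            methylation_site_rate=0.002, cds_codons=60,
        )
        bundle = simulate_genome(cfg, tmp_path / "neutral")
        sizes = {
            c: int(s)
            for c, s in (line.split("\t") for line in open(bundle.chrom_sizes_tsv))
        }
        pis = {}
        for label, path in (("wild", bundle.wild_vcf), ("cult", bundle.cult_vcf)):
            sites, matrix, _ = tio.read_vcf_lite(path)
            pis[label] = windowed_pi(variant_summary(sites, matrix), sizes)
        assert len(pis["wild"]) == 200
        assert ks_2samp(pis["wild"]["pi"], pis["cult"]["pi"]).pvalue > 0.01


class TestDeterminism:
    def test_same_seed_byte_identical_bundle(self, tmp_path):
        cfg = SimConfig(seed=21, **SMALL_CONFIG)
        b1 = simulate_genome(cfg, tmp_path / "one")
        b2 = simulate_genome(cfg, tmp_path / "two")
        files = sorted(p.name for p in b1.out_dir.iterdir())
        assert files == sorted(p.name for p in b2.out_dir.iterdir())
        for name in files:
            assert filecmp.cmp(b1.out_dir / name, b2.out_dir / name, shallow=False), name

    def test_different_seed_differs(self, tmp_path):
        cfg1 = SimConfig(seed=21, **SMALL_CONFIG)
        cfg2 = SimConfig(seed=22, **SMALL_CONFIG)
        b1 = simulate_genome(cfg1, tmp_path / "one")
        b2 = simulate_genome(cfg2, tmp_path / "two")
        assert not filecmp.cmp(b1.genome_fa, b2.genome_fa, shallow=False)
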