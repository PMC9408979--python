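"""NG86 Ka/Ks, pair filters, TSS status and subgroup partition."""
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from teacr.core import GeneModel, GenomicInterval
from teacr.duplicates import (
    CODON_TABLE,
    STOP_CODONS,
    assign_subgroup,
    assign_subgroups,
    codon_align_pair,
    codon_differences,
    codon_sites,
    divergence_association,
    filter_pairs,
    ng86_kaks,
    subgroup_partition_check,
    tss_acr_status,
)

SENSE_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)


def brute_force_codon_differences(c1, c2):
    """Independent pathway enumeration for difference classification."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if (
                CODON_TABLE[cur] == CODON_TABLE[nxt]
                and nxt not in STOP_CODONS
                and cur not in STOP_CODONS
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((blocked, sd, nd))
    kept = [(s, n) for b, s, n in results if not b] or [
        (s, n) for _, s, n in results
    ]
    return (
        sum(s for s, _ in kept) / len(kept),
        sum(n for _, n in kept) / len(kept),
    )


class TestSiteCounting:
    def test_sites_sum_to_three_per_codon(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert 0 <= s <= 3

    def test_fourfold_and_nondegenerate(self):
        s, _ = codon_sites("GGG")  # glycine: 3rd position fully synonymous
        assert s == pytest.approx(1.0)
        s, _ = codon_sites("TGG")  # tryptophan: nothing synonymous
        assert s == pytest.approx(0.0)


class TestNg86:
    def test_identical_sequences(self):
        cds = "ATGGCTAAA"
        res = ng86_kaks(cds, cds)
        assert res.Ka == 0.0 and res.Ks == 0.0
        assert np.isnan(res.omega)

    def test_single_synonymous_difference(self):
        res = ng86_kaks("TTT", "TTC")  # Phe -> Phe
        assert res.Sd == pytest.approx(1.0)
        assert res.Nd == 0.0
        assert res.Ka == 0.0
        # in a longer context the synonymous rate is positive and finite
        res = ng86_kaks("TTTATGGCTAAA", "TTCATGGCTAAA")
        assert res.Sd == pytest.approx(1.0) and res.Nd == 0.0
        assert res.Ka == 0.0 and res.Ks > 0

    def test_symmetry(self):
        rng = np.random.default_rng(10)
        a = "".join(rng.choice(SENSE_CODONS, size=20))
        b = "".join(rng.choice(SENSE_CODONS, size=20))
        r1, r2 = ng86_kaks(a, b), ng86_kaks(b, a)
        assert (r1.S, r1.N, r1.Sd, r1.Nd) == (r2.S, r2.N, r2.Sd, r2.Nd)

    def test_site_conservation(self):
        rng = np.random.default_rng(11)
        a = "".join(rng.choice(SENSE_CODONS, size=30))
        b = "".join(rng.choice(SENSE_CODONS, size=30))
        res = ng86_kaks(a, b)
        assert res.S + res.N == pytest.approx(3 * 30)

    def test_difference_counts_match_pathway_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = "".join(rng.choice(SENSE_CODONS, size=10))
            b = "".join(rng.choice(SENSE_CODONS, size=10))
            res = ng86_kaks(a, b)
            sd = nd = 0.0
            for i in range(0, 30, 3):
                s, n = brute_force_codon_differences(a[i : i + 3], b[i : i + 3])
                sd += s
                nd += n
            assert res.Sd == pytest.approx(sd)
            assert res.Nd == pytest.approx(nd)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_kaks("ATGTAAGCT", "ATGTAAGCT")

    def test_codon_difference_dispatch(self):
        for c1, c2 in [("TTT", "TTC"), ("AAA", "CCC"), ("ATG", "CGT")]:
            assert codon_differences(c1, c2) == pytest.approx(
                brute_force_codon_differences(c1, c2)
            )


class TestFilterPairs:
    def make(self, ks, p):
        return pd.DataFrame({"Ks": ks, "p_value": p})

    def test_saturation_boundary_inclusive(self):
        df = self.make([5.0, 5.01], [0.01, 0.01])
        assert filter_pairs(df)["Ks"].tolist() == [5.0]

    def test_significance_boundary(self):
        df = self.make([1.0, 1.0, 1.0], [0.05, 0.06, 0.001])
        assert len(filter_pairs(df)) == 2

    def test_nan_ks_dropped(self):
        df = self.make([np.nan, 1.0], [0.01, 0.01])
        assert len(filter_pairs(df)) == 1


class TestCodonAlign:
    def test_identical_pass_through(self):
        a = "ATGGCTAAAGGT"
        aligned_a, aligned_b = codon_align_pair(a, a)
        assert aligned_a == aligned_b == a

    def test_substituted_pair_keeps_frame(self):
        a = "ATGGCTAAAGGTTTC"
        b = "ATGGCGAAAGGTTTT"  # two synonymous changes
        aa, bb = codon_align_pair(a, b)
        assert len(aa) == len(bb)
        assert len(aa) % 3 == 0


def make_gene(tss, strand="+", gene_id="g", chrom="chr1"):
    if strand == "+":
        return GeneModel(GenomicInterval(chrom, tss, tss + 2000, strand), gene_id)
    return GeneModel(GenomicInterval(chrom, tss - 1999, tss + 1, strand), gene_id)


class TestTssStatus:
    def test_te_acr_dominates(self):
        g = make_gene(10_000)
        acrs = [
            (GenomicInterval("chr1", 9_800, 10_000), False),
            (GenomicInterval("chr1", 10_100, 10_300), True),
        ]
        assert tss_acr_status(g, acrs) == "te_acr"

    def test_regular_when_no_te(self):
        g = make_gene(10_000)
        assert tss_acr_status(g, [(GenomicInterval("chr1", 9_800, 10_000), False)]) == "regular_acr"

    def test_window_closed_at_500(self):
        g = make_gene(10_000)
        # peak whose last base is exactly TSS-500: inside the closed window
        at_edge = [(GenomicInterval("chr1", 9_400, 9_501), False)]
        assert tss_acr_status(g, at_edge) == "regular_acr"
        # peak ending one bp earlier (501 bp away): outside
        outside = [(GenomicInterval("chr1", 9_400, 9_500), False)]
        assert tss_acr_status(g, outside) == "none"


class TestSubgroups:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("te_acr", "te_acr", "1"),
            ("te_acr", "regular_acr", "2"),
            ("regular_acr", "te_acr", "2"),
            ("te_acr", "none", "3"),
            ("regular_acr", "none", "unassigned"),
            ("none", "none", "unassigned"),
        ],
    )
    def test_mapping(self, a, b, expected):
        assert assign_subgroup(a, b) == expected

    def test_partition_property(self):
        rng = np.random.default_rng(13)
        statuses = rng.choice(["te_acr", "regular_acr", "none"], size=(200, 2))
        pairs = pd.DataFrame(statuses, columns=["tss_acr_a", "tss_acr_b"])
        out = assign_subgroups(pairs)
        assert subgroup_partition_check(out)


class TestDivergenceAssociation:
    def test_identical_copies_zero_and_cutoff_inclusive(self):
        pairs = pd.DataFrame(
            {
                "fpkm_a": [10.0, 40.0], "fpkm_b": [10.0, 20.0],
                "rpm_a": [5.0, 5.0], "rpm_b": [5.0, 5.0],
            }
        )
        out, _ = divergence_association(pairs, eps=0.0)
        assert out.loc[0, "fc_expression"] == 0.0
        # ratio exactly 2 goes to the low group
        assert out.loc[1, "expression_group"] == "<=2"

    def test_rank_sum_detects_correlated_divergence(self):
        rng = np.random.default_rng(14)
        n = 200
        delta_e = rng.normal(0, 2.0, n)
        delta_a = 0.8 * delta_e + rng.normal(0, 0.3, n)
        pairs = pd.DataFrame(
            {
                "fpkm_a": 10 * 2.0 ** delta_e, "fpkm_b": 10.0,
                "rpm_a": 5 * 2.0 ** delta_a, "rpm_b": 5.0,
            }
        )
        out, summary = divergence_association(pairs)
        assert summary["rank_sum_p"] < 0.001
        assert (
            summary["median_fc_accessibility_high"]
            > summary["median_fc_accessibility_low"]
        )
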