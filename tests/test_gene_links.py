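"""Filters, LD expansion, SNP-to-gene channels, and association-set assembly."""

import numpy as np
import pandas as pd
import pytest

from genesupport import gene_links


def gwas_frame(p_values, **overrides):
    n = len(p_values)
    base = {
        "snp_id": [f"rs{i}" for i in range(n)],
        "trait_heading": ["t"] * n,
        "p_value": p_values,
        "date_added": ["2015-01-01"] * n,
        "study_type": ["case_control"] * n,
        "odds_ratio": [1.1] * n,
        "provisional": [False] * n,
        "drug_response": [False] * n,
        "somatic": [False] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestSignificanceFilter:
    def test_boundary_p_kept_and_above_dropped(self):
        out = gene_links.filter_gwas(gwas_frame([1e-8, 2e-8]))
        assert out["p_value"].tolist() == [1e-8]

    def test_counts_on_mixed_table(self):
        out = gene_links.filter_gwas(gwas_frame([1e-9, 1e-8, 5e-8, 1e-7, 0.04]))
        assert len(out) == 2

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            gene_links.filter_gwas(gwas_frame([0.0]))

    def test_idempotent(self):
        once = gene_links.filter_gwas(gwas_frame([1e-9, 1e-8, 5e-8]))
        twice = gene_links.filter_gwas(once)
        pd.testing.assert_frame_equal(once, twice)


class TestCuratedFilter:
    def test_flagged_rows_dropped(self):
        table = pd.DataFrame({
            "gene_id": list("abcdef"),
            "trait_heading": ["t"] * 6,
            "date_added": ["2012-01-01"] * 6,
            "provisional": [True, False, False, False, False, False],
            "drug_response": [False, True, False, False, False, False],
            "somatic": [False, False, True, False, False, False],
        })
        out = gene_links.filter_omim(table)
        assert sorted(out["gene_id"]) == ["d", "e", "f"]


class TestLdExpansion:
    def test_empty_table_yields_self_pairs_only(self):
        out = gene_links.ld_expand(["rs1", "rs2"], pd.DataFrame(columns=["snp_a", "snp_b", "r2"]))
        assert len(out) == 2
        assert (out["r2"] == 1.0).all()
        assert out["lead_snp"].tolist() == out["ld_snp"].tolist()

    def test_threshold_inclusive(self):
        ld = pd.DataFrame({"snp_a": ["rs1", "rs1"], "snp_b": ["p1", "p2"],
                           "r2": [0.5, 0.49]})
        out = gene_links.ld_expand(["rs1"], ld, 0.5)
        assert set(out["ld_snp"]) == {"rs1", "p1"}

    def test_symmetric_lookup(self):
        ld = pd.DataFrame({"snp_a": ["p1"], "snp_b": ["rs1"], "r2": [0.8]})
        out = gene_links.ld_expand(["rs1"], ld, 0.5)
        assert set(out["ld_snp"]) == {"rs1", "p1"}

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        leads = [f"rs{i}" for i in range(4)]
        ld = pd.DataFrame({
            "snp_a": rng.choice(leads + ["x1", "x2"], size=10),
            "snp_b": [f"p{i}" for i in range(10)],
            "r2": rng.uniform(0, 1, size=10).round(3),
        })
        out = gene_links.ld_expand(leads, ld, 0.5)
        expected = {(lead, lead) for lead in leads}
        for row in ld.itertuples(index=False):
            if row.snp_a in leads and row.r2 >= 0.5:
                expected.add((row.snp_a, row.snp_b))
        assert set(zip(out["lead_snp"], out["ld_snp"])) == expected


GENES = pd.DataFrame({
    "gene_id": ["g1", "g2", "g3"],
    "chromosome": ["1", "1", "2"],
    "start": [100_000, 500_000, 100_000],
    "end": [110_000, 520_000, 130_000],
    "protein_coding": [True, True, False],
})


class TestDistanceChannel:
    def make_pairs(self, positions):
        snps = pd.DataFrame(
            [(f"s{i}", c, p) for i, (c, p) in enumerate(positions)],
            columns=["snp_id", "chromosome", "position"],
        )
        pairs = pd.DataFrame({"lead_snp": snps["snp_id"], "ld_snp": snps["snp_id"],
                              "r2": 1.0})
        return pairs, snps

    def test_window_boundary_closed(self):
        pairs, snps = self.make_pairs([("1", 95_000), ("1", 94_999)])
        out = gene_links.link_by_distance(pairs, snps, GENES, window_bp=5000)
        assert out.loc[out["gene_id"] == "g1", "lead_snp"].tolist() == ["s0"]

    def test_matches_brute_force_interval_test(self):
        rng = np.random.default_rng(1)
        positions = [(str(rng.integers(1, 3)), int(rng.integers(50_000, 600_000)))
                     for _ in range(6)]
        pairs, snps = self.make_pairs(positions)
        out = set(zip(*gene_links.link_by_distance(pairs, snps, GENES)[
            ["lead_snp", "gene_id"]].T.values))
        expected = set()
        for (snp, chrom, pos) in snps.itertuples(index=False):
            for g in GENES.itertuples(index=False):
                if chrom == g.chromosome and g.start - 5000 <= pos <= g.end + 5000:
                    expected.add((snp, g.gene_id))
        assert out == expected


class TestFunctionalChannels:
    PAIRS = pd.DataFrame({"lead_snp": ["rs1"], "ld_snp": ["p1"], "r2": [0.9]})

    def test_eqtl_strictly_below_cutoff(self):
        eqtl = pd.DataFrame({"snp_id": ["p1", "p1"], "gene_id": ["g1", "g2"],
                             "tissue": ["a", "a"], "p_value": [9.9e-7, 1e-6]})
        out = gene_links.link_by_eqtl(self.PAIRS, eqtl)
        assert out["gene_id"].tolist() == ["g1"]

    def test_eqtl_stringent_cutoff_variant(self):
        eqtl = pd.DataFrame({"snp_id": ["p1"], "gene_id": ["g1"],
                             "tissue": ["a"], "p_value": [1e-9]})
        assert len(gene_links.link_by_eqtl(self.PAIRS, eqtl, p_cutoff=1e-12)) == 0
        assert len(gene_links.link_by_eqtl(self.PAIRS, eqtl, p_cutoff=1e-6)) == 1

    def test_dhs_boundary_kept(self):
        dhs = pd.DataFrame({"snp_id": ["p1", "p1"], "gene_id": ["g1", "g2"],
                            "perm_p": [0.001, 0.5]})
        out = gene_links.link_by_dhs(self.PAIRS, dhs, perm_p_cutoff=0.001)
        assert out["gene_id"].tolist() == ["g1"]


class TestAssembly:
    def setup_method(self):
        self.gwas = gwas_frame([1e-9], snp_id=["rs1"], trait_heading=["t1"])
        self.omim = pd.DataFrame({
            "gene_id": ["g1"], "trait_heading": ["t2"],
            "date_added": ["2012-06-01"],
            "provisional": [False], "drug_response": [False], "somatic": [False],
        })
        self.ld = pd.DataFrame({"snp_a": ["rs1"], "snp_b": ["m1"], "r2": [0.93]})
        self.snps = pd.DataFrame({
            "snp_id": ["rs1", "m1"], "chromosome": ["1", "1"],
            "position": [100_500, 101_000],
        })
        self.eqtl = pd.DataFrame({"snp_id": ["m1"], "gene_id": ["g1"],
                                  "tissue": ["a"], "p_value": [1e-8]})
        self.consequences = pd.DataFrame({"snp_id": ["m1"], "severity": ["MODERATE"]})

    def assemble(self, **kw):
        ld_pairs = gene_links.ld_expand(self.gwas["snp_id"], self.ld, 0.5)
        args = dict(ld_pairs=ld_pairs, snp_positions=self.snps, eqtl=self.eqtl,
                    consequences=self.consequences)
        args.update(kw)
        return gene_links.assemble_association_set(self.gwas, self.omim, GENES, **args)

    def test_channels_accumulate_on_one_link(self):
        links = self.assemble()
        gwas_link = links.loc[links["source"] == "GWAS"].iloc[0]
        assert gwas_link["gene_id"] == "g1"
        assert gwas_link["channels"] == "distance,eqtl"

    def test_non_protein_coding_removed(self):
        omim = self.omim.assign(gene_id=["g3"])
        links = gene_links.assemble_association_set(self.gwas.iloc[:0], omim, GENES)
        assert len(links) == 0

    def test_unknown_gene_rejected(self):
        omim = self.omim.assign(gene_id=["nope"])
        with pytest.raises(ValueError, match="nope"):
            gene_links.assemble_association_set(self.gwas.iloc[:0], omim, GENES)

    def test_deleterious_r2_is_max_over_partners(self):
        links = self.assemble()
        gwas_link = links.loc[links["source"] == "GWAS"].iloc[0]
        assert gwas_link["deleterious_r2"] == pytest.approx(0.93)

    def test_curated_channel_label(self):
        links = self.assemble()
        omim_link = links.loc[links["source"] == "OMIM"].iloc[0]
        assert omim_link["channels"] == "curated"


class TestDeleteriousSubset:
    def test_boundary_and_missing(self, link_frame):
        links = link_frame([
            ("g1", "t", "GWAS", "distance", "2015", "2015", 0.9),
            ("g2", "t", "GWAS", "distance", "2015", "2015", 0.89),
            ("g3", "t", "GWAS", "distance", "2015", "2015", np.nan),
            ("g4", "t", "OMIM", "curated", "2012", "2012", np.nan),
        ])
        out = gene_links.deleterious_subset(links, 0.9)
        assert sorted(out["gene_id"]) == ["g1", "g4"]

    def test_monotone_shrinkage_in_threshold(self, link_frame):
        rng = np.random.default_rng(2)
        links = link_frame([
            (f"g{i}", "t", "GWAS", "distance", "2015", "2015",
             float(rng.uniform(0, 1)))
            for i in range(30)
        ])
        sizes = [len(gene_links.deleterious_subset(links, r))
                 for r in np.linspace(0, 1, 11)]
        assert sizes == sorted(sizes, reverse=True)
        prev = set(gene_links.deleterious_subset(links, 0.3)["gene_id"])
        tighter = set(gene_links.deleterious_subset(links, 0.7)["gene_id"])
        assert tighter <= prev
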