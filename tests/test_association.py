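"""Kinship, the P3D mixed-model scan, QTL merging, LD and eQTLs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from itrait.association import (assign_candidate_genes, compute_kinship_and_pcs,
                                compute_ld_r2, map_eqtls, merge_qtls, mlm_scan,
                                significance_threshold)
from itrait.genotypes import GenotypeMatrix


class TestThreshold:
    def test_threshold_times_n_is_one_exactly(self):
        for n in (1, 137, 558_650, 1_250_000):
            assert significance_threshold(n) * n == 1.0

    def test_printed_form_at_study_marker_count(self):
        assert f"{significance_threshold(558_650):.1e}" == "1.8e-06"

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold(0)


def toy_matrix(mat, pos=None):
    mat = np.asarray(mat, dtype=np.int8)
    n, m = mat.shape
    pos = np.asarray(pos) if pos is not None else np.arange(1, m + 1) * 1000
    return GenotypeMatrix(mat, np.array([f"s{j}" for j in range(m)], object),
                          np.array(["chr1"] * m, object), pos,
                          np.array([f"a{i}" for i in range(n)], object))


class TestKinship:
    def test_matches_brute_force_cross_product(self):
        gm = toy_matrix([[0, 1, 2], [1, 1, 0], [2, 0, 1]])
        K, _ = compute_kinship_and_pcs(gm, n_pcs=1)
        X = gm.matrix.astype(float)
        p = X.mean(axis=0) / 2
        M = X - 2 * p
        expected = M @ M.T / (2 * np.sum(p * (1 - p)))
        assert np.allclose(K, expected)

    def test_duplicated_individuals_share_the_diagonal_value(self):
        gm = toy_matrix([[2, 0, 2, 0, 2], [2, 0, 2, 0, 2], [1, 1, 1, 1, 1],
                         [1, 1, 0, 1, 1], [0, 1, 1, 1, 0], [1, 2, 1, 1, 1]])
        K, _ = compute_kinship_and_pcs(gm, n_pcs=1)
        assert K[0, 1] == pytest.approx(K[0, 0]) == pytest.approx(K[1, 1])
        assert K[0, 1] == pytest.approx(K.diagonal().max())

    def test_psd_and_symmetric(self, small_genotypes):
        K, Q = compute_kinship_and_pcs(small_genotypes)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-8
        assert Q.shape == (small_genotypes.n_individuals, 3)  # 3 PCs default

    def test_monomorphic_only_rejected(self):
        gm = toy_matrix([[2, 2], [2, 2], [2, 2]])
        with pytest.raises(ValueError):
            compute_kinship_and_pcs(gm)


class TestMLMScan:
    def test_planted_snp_detected_with_sane_statistics(self, small_genotypes):
        rng = np.random.default_rng(8)
        x = small_genotypes.matrix[:, 17].astype(float)
        y = 1.5 * x + rng.normal(size=small_genotypes.n_individuals)
        res = mlm_scan(small_genotypes, y)
        tab = res.table.dropna(subset=["p"])
        assert tab.p.between(0, 1).all()
        assert tab.pve.between(0, 100).all()
        assert res.table.p.idxmin() == 17
        assert res.table.p.iloc[17] < res.threshold
        # PVE of the planted SNP: beta^2 var(x)/var(y)
        expected_pve = 1.5 ** 2 * x.var() / y.var() * 100
        assert res.table.pve.iloc[17] == pytest.approx(expected_pve, rel=0.2)

    def test_zero_variance_snp_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
        mat[:, 4] = 1
        gm = toy_matrix(mat)
        y = rng.normal(size=60)
        with pytest.warns(UserWarning, match="zero variance"):
            res = mlm_scan(gm, y)
        assert np.isnan(res.table.p.iloc[4])

    def test_trait_aligned_by_accession_index(self, small_genotypes):
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=small_genotypes.n_individuals),
                      index=small_genotypes.accessions)
        res1 = mlm_scan(small_genotypes, y)
        res2 = mlm_scan(small_genotypes, y.sample(frac=1.0, random_state=0))
        assert np.allclose(res1.table.p.dropna(), res2.table.p.dropna())


from conftest import brute_force_clusters  # noqa: E402  independent oracle


class TestMergeQTLs:
    def make(self, positions, chrom="chr1"):
        return pd.DataFrame({"snp": [f"s{i}" for i in range(len(positions))],
                             "chrom": chrom, "pos": positions,
                             "trait": "t"})

    def test_single_snp_interval_definition(self):
        (q,) = merge_qtls(self.make([1_000_000]))
        assert (q.start, q.end) == (900_000, 1_100_000)

    def test_two_snps_within_window_merge(self):
        (q,) = merge_qtls(self.make([1_000_000, 1_050_000]))
        assert (q.start, q.end) == (900_000, 1_150_000)
        assert len(q.snps) == 2

    def test_transitive_chain_and_break(self):
        chain = merge_qtls(self.make([1, 90_001, 180_001]))
        assert len(chain) == 1  # pairwise gaps of 90 kb chain transitively
        split = merge_qtls(self.make([1, 101_002]))
        assert len(split) == 2

    def test_start_floored_at_one(self):
        (q,) = merge_qtls(self.make([50_000]))
        assert q.start == 1

    def test_chromosomes_never_merge(self):
        df = pd.concat([self.make([500_000], "chr1"),
                        self.make([500_000], "chr2")])
        assert len(merge_qtls(df)) == 2

    def test_traits_unioned(self):
        df = self.make([1_000_000, 1_050_000])
        df["trait"] = ["tA", "tB"]
        (q,) = merge_qtls(df)
        assert q.traits == {"tA", "tB"}

    @given(st.lists(st.integers(min_value=1, max_value=2_000_000),
                    min_size=1, max_size=40, unique=True))
    def test_matches_brute_force_closure(self, positions):
        qtls = merge_qtls(self.make(sorted(positions)))
        got = sorted((q.start, q.end) for q in qtls)
        expected = [(max(lo - 100_000, 1), hi + 100_000)
                    for lo, hi in brute_force_clusters(positions, 100_000)]
        assert got == expected


class TestAssignCandidateGenes:
    ann = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                        "start": [1000], "end": [2000], "strand": ["+"]})

    def snps(self, positions):
        return pd.DataFrame({"snp": [f"s{p}" for p in positions],
                             "chrom": "chr1", "pos": positions})

    def test_snp_inside_gene_hits(self):
        hits = assign_candidate_genes(self.snps([1500]), self.ann)
        assert list(hits.gene_id) == ["g1"]

    @pytest.mark.parametrize("pos,expected", [(1000, 1), (2000, 1),
                                              (999, 0), (2001, 0)])
    def test_inclusive_boundary_semantics(self, pos, expected):
        assert len(assign_candidate_genes(self.snps([pos]), self.ann)) == expected

    def test_multi_overlap_yields_all_genes(self):
        ann = pd.DataFrame({"gene_id": ["g1", "g2"], "chrom": "chr1",
                            "start": [1000, 1400], "end": [2000, 2400],
                            "strand": "+"})
        hits = assign_candidate_genes(self.snps([1500]), ann)
        assert set(hits.gene_id) == {"g1", "g2"}

    def test_malformed_rows_skipped_with_warning(self):
        ann = pd.DataFrame({"gene_id": ["bad", "g1"], "chrom": "chr1",
                            "start": [3000, 1000], "end": [2500, 2000],
                            "strand": "+"})
        with pytest.warns(UserWarning, match="malformed"):
            hits = assign_candidate_genes(self.snps([1500]), ann)
        assert list(hits.gene_id) == ["g1"]

    def test_matches_brute_force_interval_lookup(self, rng):
        pos = rng.integers(1, 100_000, size=200)
        snps = self.snps(list(pos))
        starts = np.sort(rng.choice(np.arange(1, 90_000, 450), 30, replace=False))
        ann = pd.DataFrame({"gene_id": [f"g{i}" for i in range(30)],
                            "chrom": "chr1", "start": starts,
                            "end": starts + 300, "strand": "+"})
        hits = assign_candidate_genes(snps, ann)
        expected = {(f"s{p}", f"g{i}") for p in pos for i in range(30)
                    if starts[i] <= p <= starts[i] + 300}
        assert set(zip(hits.snp, hits.gene_id)) == expected


class TestLD:
    def test_identical_columns_give_one(self):
        x = np.array([0, 1, 2, 1, 0, 2])
        assert compute_ld_r2(x, x) == pytest.approx(1.0)

    def test_symmetry_and_allele_flip_invariance(self, rng):
        a = rng.integers(0, 3, size=100)
        b = rng.integers(0, 3, size=100)
        assert compute_ld_r2(a, b) == pytest.approx(compute_ld_r2(b, a))
        assert compute_ld_r2(2 - a, b) == pytest.approx(compute_ld_r2(a, b))

    def test_independent_snps_near_zero(self, rng):
        a = rng.binomial(2, 0.3, size=10_000)
        b = rng.binomial(2, 0.3, size=10_000)
        assert compute_ld_r2(a, b) < 0.01

    def test_hand_computed_toy(self):
        a = np.array([0.0, 0, 1, 1, 2, 2])
        b = np.array([0.0, 1, 1, 1, 1, 2])
        r = np.corrcoef(a, b)[0, 1]
        assert compute_ld_r2(a, b) == pytest.approx(r * r)

    def test_zero_variance_undefined(self):
        assert np.isnan(compute_ld_r2(np.ones(10), np.arange(10)))

    def test_missing_pairwise_deleted(self):
        a = np.array([0, 1, 2, np.nan, 2])
        b = np.array([0, 1, 2, 0, -1])
        assert compute_ld_r2(a, b) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def planted():
    from itrait.simulate import (make_annotations, simulate_genotypes,
                                 simulate_expression_panel)

    gm = simulate_genotypes(150, 200, seed=51)
    ann = make_annotations(gm, 6, seed=52)
    panel = simulate_expression_panel(gm, ann, n_local=1, n_distant=1,
                                      effect=3.0, noise_sd=0.5,
                                      prop_dynamic=0.0, seed=53)
    records = map_eqtls(gm, panel.expression, ann, threshold=1e-8)
    return panel, {r.gene: r for r in records}


class TestMapEQTLs:
    def test_planted_local_static_recovered(self, planted):
        panel, by_gene = planted
        snp, gene, kind, active = [e for e in panel.planted_eqtls
                                   if e[2] == "local"][0]
        rec = by_gene[gene]
        assert rec.kind == "local"
        assert rec.dynamics == "static"
        assert rec.snp == snp

    def test_planted_distant_recovered(self, planted):
        panel, by_gene = planted
        snp, gene, kind, active = [e for e in panel.planted_eqtls
                                   if e[2] == "distant"][0]
        rec = by_gene[gene]
        assert rec.kind == "distant"
        assert rec.snp == snp

    def test_dynamic_eqtl_detected_in_one_condition(self):
        from itrait.simulate import (make_annotations, simulate_genotypes,
                                     simulate_expression_panel)

        gm = simulate_genotypes(150, 200, seed=61)
        ann = make_annotations(gm, 4, seed=62)
        panel = simulate_expression_panel(gm, ann, n_local=0, n_distant=1,
                                          effect=3.0, noise_sd=0.5,
                                          prop_dynamic=1.0, seed=63)
        snp, gene, _, active = panel.planted_eqtls[0]
        records = {r.gene: r for r in
                   map_eqtls(gm, panel.expression, ann, threshold=1e-8)}
        assert records[gene].dynamics == "dynamic"
        assert records[gene].conditions == active

    def test_local_window_boundary_inclusive(self):
        # SNP exactly at gene_start - 10,000 is local
        rng = np.random.default_rng(7)
        n = 120
        m_bg = 50  # unlinked background SNPs keep the kinship diffuse
        mat = rng.binomial(2, 0.4, size=(n, 3 + m_bg)).astype(np.int8)
        ids = np.array(["sA", "sB", "sC"]
                       + [f"bg{j}" for j in range(m_bg)], object)
        chrom = np.array(["chr1"] * 3 + ["chr2"] * m_bg, object)
        pos = np.concatenate([[40_000, 90_000, 500_000],
                              np.arange(1, m_bg + 1) * 10_000])
        gm = GenotypeMatrix(mat, ids, chrom, pos,
                            np.array([f"a{i}" for i in range(n)], object))
        ann = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                            "start": [50_000], "end": [52_000],
                            "strand": ["+"]})
        expr = []
        for cond in ("WW", "DS"):
            expr.append(pd.DataFrame({
                "accession": gm.accessions, "gene": "g1", "condition": cond,
                "value": 3.0 * mat[:, 0] + rng.normal(scale=0.3, size=n)}))
        records = map_eqtls(gm, pd.concat(expr), ann, threshold=1e-8)
        assert records and records[0].kind == "local"

    def test_unannotated_gene_skipped_with_warning(self, small_genotypes):
        expr = pd.DataFrame({"accession": small_genotypes.accessions,
                             "gene": "ghost", "condition": "WW",
                             "value": np.arange(150.0)})
        ann = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                            "start": [1], "end": [100], "strand": ["+"]})
        with pytest.warns(UserWarning, match="absent"):
            assert map_eqtls(small_genotypes, expr, ann) == []
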