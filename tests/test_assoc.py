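"""Genotype QC, PCs, the association scan and QTL interval rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uavqtl import assoc as ac
from uavqtl import synthfield as sf


def tiny_matrix(dosage_cols, chrom=None, pos=None):
    d = np.asarray(dosage_cols, dtype=np.int8).T
    n_lines, n_snps = d.shape
    chrom = chrom if chrom is not None else np.ones(n_snps, dtype=int)
    pos = pos if pos is not None else (np.arange(n_snps) + 1) * 1000
    return ac.GenotypeMatrix(
        np.array([f"L{i}" for i in range(n_lines)]), d,
        np.array([f"s{j}" for j in range(n_snps)]), chrom, pos)


# ------------------------------------------------------------------ filter

def test_filter_maf_boundaries():
    # 20 lines: frequencies 0.5 (kept), 0 (dropped), exactly 0.05 (dropped: strict)
    half = [1] * 20
    mono = [0] * 20
    rare = [2] + [0] * 19  # 2/40 alleles = 0.05
    gm = tiny_matrix([half, mono, rare])
    kept = ac.filter_maf(gm, 0.05)
    assert list(kept.snp_ids) == ["s0"]


def test_filter_maf_empty_result_errors():
    gm = tiny_matrix([[0] * 10])
    with pytest.raises(ValueError):
        ac.filter_maf(gm, 0.05)


def test_maf_ignores_missing_calls():
    col = [2, 2, -1, -1, 0, 0, 0, 0]
    gm = tiny_matrix([col])
    assert gm.maf()[0] == pytest.approx(4 / 12)


# --------------------------------------------------------------------- pca

def test_pcs_orthogonal_and_separate_structure():
    gm = sf.simulate_genotypes(200, 2000, fst=0.15, seed=31)
    pcs = ac.compute_pcs(gm, 5)
    gram = pcs.T @ pcs
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8
    grp = np.array([0] * 100 + [1] * 100)
    assert abs(np.corrcoef(pcs[:, 0], grp)[0, 1]) > 0.9


def test_pcs_rank_one_matrix():
    base = np.tile(np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 2], dtype=np.int8), (6, 1)).T
    gm = tiny_matrix(base.T)
    pcs = ac.compute_pcs(gm, 1)
    # a rank-1 standardized matrix is fully captured by one component
    z = (base - base.mean(0)) / base.std(0)
    total = np.sum(z**2)
    assert np.sum(pcs[:, 0] ** 2) == pytest.approx(total, rel=1e-8)


def test_pcs_invalid_k():
    gm = sf.simulate_genotypes(20, 50, seed=32)
    with pytest.raises(ValueError):
        ac.compute_pcs(gm, 0)
    with pytest.raises(ValueError):
        ac.compute_pcs(gm, 20)


# -------------------------------------------------------------------- scan

def test_scan_planted_signal_attains_minimum_p():
    gm = sf.simulate_genotypes(252, 2000, fst=0.0, seed=33)
    gm = ac.filter_maf(gm, 0.05)
    rng = np.random.default_rng(34)
    j = 700
    y = 2.0 * gm.dosages[:, j] + rng.normal(0, 0.5, 252)
    res = ac.gwas_scan(gm, y)
    assert res.table["p"].idxmin() == j
    assert res.table["p"].min() < 1.0 / 10_000


def test_scan_oracle_against_statsmodels():
    """Per-SNP beta/se/p must match an independent OLS fit."""
    import statsmodels.api as sm
    gm = sf.simulate_genotypes(60, 30, fst=0.1, seed=35)
    rng = np.random.default_rng(36)
    y = rng.normal(0, 1, 60)
    covs = rng.normal(size=(60, 2))
    res = ac.gwas_scan(gm, y, covariates=covs)
    for j in [0, 7, 19]:
        g = gm.dosages[:, j].astype(float)
        if g.std() == 0:
            continue
        X = sm.add_constant(np.column_stack([covs, g]))
        fit = sm.OLS(y, X).fit()
        assert res.table["beta"][j] == pytest.approx(fit.params[-1], rel=1e-8)
        assert res.table["se"][j] == pytest.approx(fit.bse[-1], rel=1e-8)
        assert res.table["p"][j] == pytest.approx(fit.pvalues[-1], rel=1e-6)


def test_scan_handles_missing_dosages():
    gm = sf.simulate_genotypes(80, 200, seed=37, missing_rate=0.05)
    rng = np.random.default_rng(38)
    res = ac.gwas_scan(gm, rng.normal(0, 1, 80))
    assert res.table["p"].notna().mean() > 0.9


def test_scan_rejects_constant_phenotype():
    gm = sf.simulate_genotypes(50, 20, seed=39)
    with pytest.raises(ValueError):
        ac.gwas_scan(gm, np.ones(50))


def test_scan_drops_collinear_covariates(caplog):
    gm = sf.simulate_genotypes(60, 40, seed=40)
    rng = np.random.default_rng(41)
    y = rng.normal(0, 1, 60)
    c1 = rng.normal(size=60)
    covs = np.column_stack([c1, 2 * c1])  # second column redundant
    with caplog.at_level("WARNING"):
        res = ac.gwas_scan(gm, y, covariates=covs)
    assert "collinear" in caplog.text
    assert res.n_covariates == 1


def test_pc_covariates_control_structure_confounding():
    """A group-correlated, non-genetic phenotype shift inflates the naive
    scan under fst = 0.1 structure; 5 PCs bring the genomic inflation
    factor back into [0.8, 1.2]."""
    from scipy.stats import chi2
    gm = sf.simulate_genotypes(252, 4000, fst=0.1, seed=50)
    rng = np.random.default_rng(51)
    grp = np.array([0] * 126 + [1] * 126)
    y = 2.0 * grp + rng.normal(0, 1, 252)

    def lam(covs):
        res = ac.gwas_scan(gm, y, covariates=covs)
        q = chi2.isf(res.table["p"].dropna(), 1)
        return np.median(q) / chi2.isf(0.5, 1)

    adjusted = lam(ac.compute_pcs(gm, 5))
    assert 0.8 <= adjusted <= 1.2
    assert lam(None) > 1.2


# --------------------------------------------------------------- threshold

def test_bonferroni_exact_and_errors():
    assert ac.bonferroni_threshold(1) == 1.0
    assert ac.bonferroni_threshold(10_000) == 1e-4
    with pytest.raises(ValueError):
        ac.bonferroni_threshold(0)


@given(st.integers(min_value=1, max_value=10**9))
@settings(max_examples=50, deadline=None)
def test_bonferroni_product_identity(n):
    # exact up to one floating-point ulp: the cutoff is literally 1/n
    assert ac.bonferroni_threshold(n) * n == pytest.approx(1.0, abs=1e-15)


# -------------------------------------------------------------------- qtls

def result_from(sig):
    """Build an AssociationResult with given significant SNPs
    [(chrom, pos, p), ...] amid a null background of N = 1000."""
    rows = [{"snp_id": f"x{i}", "chrom": c, "pos": p, "beta": 1.0, "se": 0.1,
             "p": pv} for i, (c, p, pv) in enumerate(sig)]
    rows += [{"snp_id": f"bg{i}", "chrom": 9, "pos": (i + 1) * 10_000,
              "beta": 0.0, "se": 0.1, "p": 0.5} for i in range(997)]
    table = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return ac.AssociationResult(table, 1000, ac.bonferroni_threshold(1000),
                                trait="PH_4", group="BOTH")


def test_single_significant_snp_interval():
    qtls = ac.call_qtls(result_from([(1, 500_000, 1e-9)]), flank=100_000)
    assert len(qtls) == 1
    q = qtls[0]
    assert (q.chrom, q.start, q.end) == (1, 400_000, 600_000)
    assert q.peak_pos == 500_000


def test_no_significant_snps_empty_list():
    assert ac.call_qtls(result_from([])) == []


def test_overlapping_intervals_merge_with_best_peak():
    qtls = ac.call_qtls(result_from([(1, 500_000, 1e-8), (1, 650_000, 1e-9)]),
                        flank=100_000)
    assert len(qtls) == 1
    q = qtls[0]
    assert (q.start, q.end) == (400_000, 750_000)
    assert q.peak_pos == 650_000 and q.peak_p == 1e-9


def test_interval_clipped_at_one():
    qtls = ac.call_qtls(result_from([(1, 50_000, 1e-9)]), flank=100_000)
    assert qtls[0].start == 1


def test_called_intervals_disjoint_and_cover_all_significant():
    rng = np.random.default_rng(42)
    sig = [(int(c), int(p), 1e-8) for c, p in
           zip(rng.integers(1, 4, 30), rng.integers(1, 5_000_000, 30))]
    res = result_from(sig)
    qtls = ac.call_qtls(res, flank=100_000)
    by_chrom = {}
    for q in qtls:
        by_chrom.setdefault(q.chrom, []).append((q.start, q.end))
    for ivals in by_chrom.values():
        ivals.sort()
        assert all(a[1] < b[0] for a, b in zip(ivals, ivals[1:]))
    for c, p, _ in sig:
        assert sum(q.chrom == c and q.start <= p <= q.end for q in qtls) == 1


def make_qtl(chrom, start, end, p=1e-8, trait="PH_4", group="BOTH"):
    return ac.QTLRecord(chrom, start, end, f"s{start}", (start + end) // 2, p,
                        traits=(trait,), groups=(group,))


def test_merge_respects_chromosomes_and_overlap():
    a, b = make_qtl(1, 100, 300), make_qtl(2, 100, 300)
    assert ac.merge_qtls([a, b]) == [a, b]
    c, d = make_qtl(2, 100_000, 300_000, p=1e-8), make_qtl(2, 250_000, 500_000, p=1e-9)
    merged = ac.merge_qtls([c, d])
    assert len(merged) == 1
    assert (merged[0].start, merged[0].end) == (100_000, 500_000)
    assert merged[0].peak_p == 1e-9


def test_merge_near_requires_flag():
    a = make_qtl(2, 1_000_000, 1_200_000, trait="PH_1")
    b = make_qtl(2, 2_000_000, 2_200_000, trait="PH_4")  # 0.8 Mb gap
    assert len(ac.merge_qtls([a, b], gap_max=1_000_000, merge_near=False)) == 2
    merged = ac.merge_qtls([a, b], gap_max=1_000_000, merge_near=True)
    assert len(merged) == 1
    assert merged[0].traits == ("PH_1", "PH_4")


def test_bed_conversion_is_zero_based_half_open(tmp_path):
    path = tmp_path / "q.bed"
    ac.qtls_to_bed([make_qtl(3, 400_001, 600_000)], path)
    chrom, start, end = path.read_text().split("\t")[:3]
    assert (chrom, start, end) == ("chr3", "400000", "600000")
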