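"""Genotype QC, association scan, significance threshold, QTL intervals.

The scan is a per-SNP ordinary linear model (phenotype ~ dosage + optional
principal-component covariates).  Genome-wide significance uses the adjusted
Bonferroni cutoff P <= 1/N with N the number of SNPs tested.  Each
significant SNP spawns a +/-100 kb interval; overlapping intervals on a
chromosome are unioned into QTLs whose peak is the contained SNP with the
lowest p-value, and QTLs from different trait/group scans can be merged when
they overlap (or lie within a gap limit, when explicitly allowed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "AssociationResult",
    "QTLRecord",
    "filter_maf",
    "compute_pcs",
    "gwas_scan",
    "bonferroni_threshold",
    "call_qtls",
    "merge_qtls",
    "qtls_to_bed",
    "qtls_to_json",
]

MISSING = -1  # dosage sentinel


@dataclass
class GenotypeMatrix:
    """Lines x SNPs minor-allele dosage matrix with physical SNP positions.

    ``dosages`` holds {0, 1, 2} calls plus -1 for missing; ``chrom`` and
    ``pos`` are per-SNP 1-based physical coordinates, non-decreasing within
    each chromosome.
    """

    line_ids: np.ndarray
    dosages: np.ndarray  # (n_lines, n_snps) int8
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.line_ids = np.asarray(self.line_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom, dtype=int)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n_lines, n_snps = self.dosages.shape
        if not (len(self.line_ids) == n_lines and len(self.snp_ids) == n_snps
                and len(self.chrom) == n_snps and len(self.pos) == n_snps):
            raise ValueError("genotype matrix metadata lengths inconsistent")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or -1 (missing)")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls."""
        d = self.dosages.astype(float)
        obs = d != MISSING
        n_called = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(obs, d, 0.0).sum(axis=0) / (2.0 * n_called)
        freq = np.where(n_called > 0, freq, np.nan)
        return np.minimum(freq, 1.0 - freq)

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.line_ids, self.dosages[:, idx],
                              self.snp_ids[idx], self.chrom[idx], self.pos[idx])

    def take_lines(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.line_ids[idx], self.dosages[idx],
                              self.snp_ids, self.chrom, self.pos)

    def to_files(self, matrix_path: str | Path, map_path: str | Path) -> None:
        """Write a delimited dosage matrix plus a (snp_id, chrom, pos) map."""
        mat = pd.DataFrame(self.dosages, index=self.line_ids, columns=self.snp_ids)
        mat.index.name = "line_id"
        mat.to_csv(matrix_path)
        pd.DataFrame({"snp_id": self.snp_ids, "chrom": self.chrom,
                      "pos": self.pos}).to_csv(map_path, index=False)

    @classmethod
    def from_files(cls, matrix_path: str | Path, map_path: str | Path) -> "GenotypeMatrix":
        mat = pd.read_csv(matrix_path, index_col=0)
        snp_map = pd.read_csv(map_path).set_index("snp_id").loc[mat.columns]
        return cls(mat.index.to_numpy(), mat.to_numpy(dtype=np.int8),
                   mat.columns.to_numpy(), snp_map["chrom"].to_numpy(),
                   snp_map["pos"].to_numpy())


@dataclass
class AssociationResult:
    """Per-SNP scan output with its Bonferroni threshold (1/N)."""

    table: pd.DataFrame  # snp_id, chrom, pos, beta, se, p
    n_snps: int
    threshold: float
    trait: str = ""
    group: str = ""
    n_covariates: int = 0

    def significant(self) -> pd.DataFrame:
        p = self.table["p"]
        return self.table[p.notna() & (p <= self.threshold)]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class QTLRecord:
    """1-based closed genomic interval around genome-wide-significant SNPs."""

    chrom: int
    start: int
    end: int
    peak_snp: str
    peak_pos: int
    peak_p: float
    traits: tuple[str, ...] = ()
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("QTL interval must satisfy 1 <= start <= end")

    def overlaps(self, other: "QTLRecord") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


def filter_maf(genotypes: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Retain SNPs with MAF strictly greater than ``maf_min``.

    MAF is computed on the non-missing calls of the supplied matrix, so QC on
    a subpopulation uses that subpopulation's frequencies only.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    maf = genotypes.maf()
    keep = np.nan_to_num(maf, nan=0.0) > maf_min
    if not keep.any():
        raise ValueError(
            f"no SNP passes MAF > {maf_min}; lower the threshold or check input")
    return genotypes.take_snps(np.flatnonzero(keep))


def compute_pcs(genotypes: GenotypeMatrix, k: int = 5) -> np.ndarray:
    """Top-k principal-component scores of the standardized dosage matrix.

    Missing dosages are imputed to the per-SNP mean (PCA only); columns are
    centred and scaled to unit variance, zero-variance columns dropped.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= min(genotypes.n_lines, genotypes.n_snps):
        raise ValueError("k must be smaller than both matrix dimensions")
    d = genotypes.dosages.astype(float)
    obs = d != MISSING
    col_mean = np.where(obs, d, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    d = np.where(obs, d, col_mean[None, :])
    sd = d.std(axis=0)
    keep = sd > 0
    z = (d[:, keep] - d[:, keep].mean(axis=0)) / sd[keep]
    return PCA(n_components=k, svd_solver="full").fit_transform(z)


def _ols_scan_dense(y: np.ndarray, g: np.ndarray, q: np.ndarray):
    """Vectorized per-SNP OLS after projecting out the covariate basis q."""
    n, p = q.shape
    ry = y - q @ (q.T @ y)
    rg = g - q @ (q.T @ g)
    ss_g = np.einsum("ij,ij->j", rg, rg)
    ok = ss_g > 1e-12
    beta = np.full(g.shape[1], np.nan)
    se = np.full(g.shape[1], np.nan)
    pval = np.full(g.shape[1], np.nan)
    df = n - p - 1
    if df <= 0:
        raise ValueError("not enough observations for the covariate count")
    gy = rg.T @ ry
    beta[ok] = gy[ok] / ss_g[ok]
    rss = float(ry @ ry) - np.where(ok, beta**2 * ss_g, 0.0)
    sigma2 = rss / df
    with np.errstate(invalid="ignore", divide="ignore"):
        se[ok] = np.sqrt(sigma2[ok] / ss_g[ok])
        tstat = beta[ok] / se[ok]
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
    return beta, se, pval, int((~ok).sum())


def gwas_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    trait: str = "",
    group: str = "",
) -> AssociationResult:
    """Per-SNP linear-model association scan with optional covariates.

    Fits ``phenotype ~ dosage + covariates`` per SNP on complete cases and
    reports the dosage coefficient's two-sided p-value.  SNPs with zero
    dosage variance are skipped (p = NaN) and counted in the log; collinear
    covariates are dropped.  The result carries the 1/N threshold.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != genotypes.n_lines:
        raise ValueError("phenotype length must equal the number of lines")
    keep_lines = np.isfinite(y)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != genotypes.n_lines:
            raise ValueError("covariate rows must equal the number of lines")
        keep_lines &= np.all(np.isfinite(covariates), axis=1)
    if keep_lines.sum() < 10:
        raise ValueError("fewer than 10 complete cases")
    y = y[keep_lines]
    if np.ptp(y) == 0:
        raise ValueError("phenotype has zero variance")
    gm = genotypes.take_lines(np.flatnonzero(keep_lines))

    x = np.ones((len(y), 1))
    if covariates is not None:
        c = covariates[keep_lines]
        full = np.hstack([x, c])
        # drop collinear covariate columns (rank-revealing QR on the pivoted set)
        rank = np.linalg.matrix_rank(full)
        if rank < full.shape[1]:
            kept, basis = [0], x
            for j in range(c.shape[1]):
                cand = np.hstack([basis, c[:, j : j + 1]])
                if np.linalg.matrix_rank(cand) > basis.shape[1]:
                    basis = cand
                    kept.append(j + 1)
            logger.warning("dropped %d collinear covariate(s)",
                           full.shape[1] - basis.shape[1])
            full = basis
        x = full
    q, _ = np.linalg.qr(x)
    n_cov = x.shape[1] - 1

    d = gm.dosages
    has_missing = np.any(d == MISSING, axis=0)
    beta = np.full(gm.n_snps, np.nan)
    se = np.full(gm.n_snps, np.nan)
    pval = np.full(gm.n_snps, np.nan)
    n_skipped = 0

    dense = np.flatnonzero(~has_missing)
    if dense.size:
        b, s, p, skipped = _ols_scan_dense(y, d[:, dense].astype(float), q)
        beta[dense], se[dense], pval[dense] = b, s, p
        n_skipped += skipped
    for j in np.flatnonzero(has_missing):
        gj = d[:, j].astype(float)
        obs = gj != MISSING
        if obs.sum() <= x.shape[1] + 1 or np.ptp(gj[obs]) == 0:
            n_skipped += 1
            continue
        qj, _ = np.linalg.qr(x[obs])
        b, s, p, skipped = _ols_scan_dense(y[obs], gj[obs, None], qj)
        beta[j], se[j], pval[j] = b[0], s[0], p[0]
        n_skipped += skipped
    if n_skipped:
        logger.warning("scan skipped %d SNP(s) with zero dosage variance", n_skipped)

    table = pd.DataFrame({
        "snp_id": gm.snp_ids, "chrom": gm.chrom, "pos": gm.pos,
        "beta": beta, "se": se, "p": pval,
    })
    return AssociationResult(table, gm.n_snps, bonferroni_threshold(gm.n_snps),
                             trait=trait, group=group, n_covariates=n_cov)


def bonferroni_threshold(n_snps: int) -> float:
    """Adjusted-Bonferroni genome-wide cutoff: exactly 1/N for N SNPs."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    return 1.0 / n_snps


def call_qtls(result: AssociationResult, flank: int = 100_000) -> list[QTLRecord]:
    """Build QTL intervals of +/-``flank`` bp around significant SNPs.

    Every SNP with p <= 1/N spawns [pos - flank, pos + flank] clipped at 1;
    overlapping intervals on a chromosome are unioned and each union's peak
    is its lowest-p significant SNP (ties broken by lowest position).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    sig = result.significant().sort_values(["chrom", "pos"], kind="mergesort")
    qtls: list[QTLRecord] = []
    for _, row in sig.iterrows():
        start = max(1, int(row["pos"]) - flank)
        end = int(row["pos"]) + flank
        rec = QTLRecord(int(row["chrom"]), start, end, str(row["snp_id"]),
                        int(row["pos"]), float(row["p"]),
                        traits=(result.trait,) if result.trait else (),
                        groups=(result.group,) if result.group else ())
        if qtls and qtls[-1].chrom == rec.chrom and rec.start <= qtls[-1].end:
            prev = qtls[-1]
            better = (rec.peak_p, rec.peak_pos) < (prev.peak_p, prev.peak_pos)
            qtls[-1] = QTLRecord(
                prev.chrom, prev.start, max(prev.end, rec.end),
                rec.peak_snp if better else prev.peak_snp,
                rec.peak_pos if better else prev.peak_pos,
                min(prev.peak_p, rec.peak_p),
                traits=prev.traits, groups=prev.groups)
        else:
            qtls.append(rec)
    return qtls


def merge_qtls(
    qtls: list[QTLRecord],
    gap_max: int = 1_000_000,
    merge_near: bool = False,
) -> list[QTLRecord]:
    """Merge QTLs from multiple scans into unique loci.

    Overlapping records are always merged.  Records separated by less than
    ``gap_max`` merge only when ``merge_near`` is set — that rule models the
    cross-study criterion (nearby intervals known to be one locus elsewhere),
    which requires an explicit user decision rather than a literature lookup.
    """
    if not qtls:
        return []
    ordered = sorted(qtls, key=lambda r: (r.chrom, r.start, r.end))
    merged = [ordered[0]]
    for rec in ordered[1:]:
        cur = merged[-1]
        gap = rec.start - cur.end - 1
        if rec.chrom == cur.chrom and (rec.start <= cur.end or
                                       (merge_near and gap < gap_max)):
            better = (rec.peak_p, rec.peak_pos) < (cur.peak_p, cur.peak_pos)
            merged[-1] = QTLRecord(
                cur.chrom, cur.start, max(cur.end, rec.end),
                rec.peak_snp if better else cur.peak_snp,
                rec.peak_pos if better else cur.peak_pos,
                min(cur.peak_p, rec.peak_p),
                traits=tuple(dict.fromkeys(cur.traits + rec.traits)),
                groups=tuple(dict.fromkeys(cur.groups + rec.groups)))
        else:
            merged.append(rec)
    return merged


def qtls_to_bed(qtls: list[QTLRecord], path: str | Path) -> None:
    """Write QTLs as BED (0-based half-open; internal 1-based closed)."""
    with open(path, "w") as fh:
        for q in qtls:
            name = ";".join(q.traits) or q.peak_snp
            fh.write(f"chr{q.chrom}\t{q.start - 1}\t{q.end}\t{name}\t{q.peak_p:.3g}\n")


def qtls_to_json(qtls: list[QTLRecord], path: str | Path) -> None:
    recs = [{"chrom": q.chrom, "start": q.start, "end": q.end,
             "peak_snp": q.peak_snp, "peak_pos": q.peak_pos, "peak_p": q.peak_p,
             "traits": list(q.traits), "groups": list(q.groups)} for q in qtls]
    Path(path).write_text(json.dumps(recs, indent=2))
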