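"""Mixed-linear-model association mapping with P3D, QTL merging and eQTLs.

The scan fits y = Q alpha + u + e with u ~ N(0, sigma2_g K) where K is the
VanRaden kinship and Q the leading genotype principal components (Q+K
model).  Variance components are estimated once on the no-SNP null model
by REML on the eigenbasis of K ("uncompressed P3D": no per-SNP REML, no
compression of individuals) and each SNP is then tested by a
generalized-least-squares Wald test with those components fixed.
Genome-wide significance is the uniform 1/n-markers threshold.

Significant SNPs within 100 kb of each other are merged transitively and
each cluster, expanded by 100 kb on both sides, is a QTL.  eQTLs are the
same scan applied to expression traits per watering condition: local if
the most significant SNP lies within the gene span +/- 10 kb, distant
otherwise; static if detected under both conditions, dynamic if under
exactly one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .genotypes import GenotypeMatrix

__all__ = ["compute_kinship_and_pcs", "mlm_scan", "significance_threshold",
           "merge_qtls", "assign_candidate_genes", "compute_ld_r2",
           "map_eqtls", "QTLInterval", "EQTLRecord", "MLMResult"]

QTL_WINDOW = 100_000
EQTL_LOCAL_WINDOW = 10_000


@dataclass
class QTLInterval:
    chrom: str
    start: int
    end: int
    snps: list
    traits: set = field(default_factory=set)


@dataclass
class EQTLRecord:
    snp: str
    gene: str
    conditions: tuple
    p_values: dict
    kind: str       # local | distant
    dynamics: str   # static | dynamic


@dataclass
class MLMResult:
    table: pd.DataFrame          # snp, chrom, pos, p, beta, se, pve
    threshold: float
    h2_null: float
    sigma2_g: float
    sigma2_e: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table.p <= self.threshold]


def significance_threshold(n_markers: int) -> float:
    """The uniform p <= 1/n genome-wide threshold (1.8e-6 at n = 558,650)."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    return 1.0 / n_markers


def compute_kinship_and_pcs(genotypes: GenotypeMatrix, n_pcs: int = 3):
    """VanRaden kinship K and the leading principal components Q.

    K = M M' / (2 sum p(1-p)) with M the allele-frequency-centered
    genotype matrix: symmetric, positive semidefinite, diagonal near 1.
    Q holds the first ``n_pcs`` PC scores of the centered matrix.
    """
    X = genotypes.matrix.astype(float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 individuals and >= 1 SNP")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    M = X[:, poly] - 2.0 * p[poly]
    K = M @ M.T / (2.0 * np.sum(p[poly] * (1.0 - p[poly])))
    K = (K + K.T) / 2.0
    Xc = X - X.mean(axis=0)
    n_pcs = min(n_pcs, min(Xc.shape) - 1)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    Q = U[:, :n_pcs] * S[:n_pcs]
    return K, Q


def _reml_h2(yt: np.ndarray, Xt: np.ndarray, eig: np.ndarray):
    """Profile REML of h2 = sigma2_g/(sigma2_g+sigma2_e) on the eigenbasis."""
    n, p = Xt.shape

    def crit(h2):
        w = h2 * eig + (1.0 - h2)
        sw = np.sqrt(w)
        Xw, yw = Xt / sw[:, None], yt / sw
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        if rss <= 0:
            rss = 1e-300
        _, logdet = np.linalg.slogdet(Xw.T @ Xw)
        return 0.5 * ((n - p) * np.log(rss / (n - p))
                      + np.log(w).sum() + logdet)

    grid = np.linspace(1e-4, 1 - 1e-4, 64)
    vals = [crit(h) for h in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(crit, bounds=(lo, hi), method="bounded")
    h2 = float(res.x)
    w = h2 * eig + (1.0 - h2)
    sw = np.sqrt(w)
    Xw, yw = Xt / sw[:, None], yt / sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    sigma2 = float(resid @ resid) / (n - p)
    return h2, sigma2


def mlm_scan(genotypes: GenotypeMatrix, trait: pd.Series | np.ndarray,
             K: np.ndarray | None = None, Q: np.ndarray | None = None,
             n_pcs: int = 3, trait_name: str = "trait") -> MLMResult:
    """Q+K mixed-model scan of one trait (replicates pre-averaged).

    ``trait`` is indexed by accession (a pandas Series) or aligned to the
    genotype rows.  Returns per-SNP p, effect beta, its standard error and
    PVE = beta^2 Var(g)/Var(y) x 100, plus the 1/n-markers threshold.
    SNPs with zero variance among phenotyped lines are skipped (NaN row).
    """
    if isinstance(trait, pd.Series):
        y = trait.reindex(genotypes.accessions).to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    keep = ~np.isnan(y)
    if keep.sum() < 5:
        raise ValueError("too few phenotyped lines")
    X = genotypes.matrix[keep].astype(float)
    y = y[keep]
    n = y.size

    if K is None or Q is None:
        K_full, Q_full = compute_kinship_and_pcs(genotypes, n_pcs)
        K = K_full if K is None else K
        Q = Q_full if Q is None else Q
    K = np.asarray(K)[np.ix_(keep, keep)] if K.shape[0] != n else np.asarray(K)
    Q = np.asarray(Q)[keep] if Q.shape[0] != n else np.asarray(Q)

    X0 = np.column_stack([np.ones(n), Q])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValueError("singular covariate configuration: structure "
                         "covariates (Q) are collinear with the intercept")

    eig, U = np.linalg.eigh(K)
    eig = np.clip(eig, 0.0, None)
    yt, X0t = U.T @ y, U.T @ X0
    h2, sigma2 = _reml_h2(yt, X0t, eig)

    # P3D: freeze the components, whiten once, test every SNP by GLS Wald
    w = h2 * eig + (1.0 - h2)
    D = U / np.sqrt(w)           # rows of D.T transform to the whitened space
    yw = D.T @ y
    X0w = D.T @ X0
    Gw = D.T @ X
    # residualize on the null design (Frisch-Waugh)
    Q0, _ = np.linalg.qr(X0w)
    yr = yw - Q0 @ (Q0.T @ yw)
    Gr = Gw - Q0 @ (Q0.T @ Gw)

    gss = np.einsum("ij,ij->j", Gr, Gr)
    ok = gss > 1e-10
    beta = np.full(X.shape[1], np.nan)
    se = np.full(X.shape[1], np.nan)
    pval = np.full(X.shape[1], np.nan)
    df = n - X0.shape[1] - 1
    gy = Gr.T @ yr
    beta[ok] = gy[ok] / gss[ok]
    rss = float(yr @ yr) - beta[ok] ** 2 * gss[ok]
    rss = np.clip(rss, 1e-300, None)
    se[ok] = np.sqrt(rss / df / gss[ok])
    tstat = beta[ok] / se[ok]
    pval[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
    pval[ok] = np.clip(pval[ok], np.finfo(float).tiny, 1.0)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} SNP(s) with zero variance among "
                      "phenotyped lines skipped")

    var_y = y.var()
    var_g = X.var(axis=0)
    pve = np.clip(beta ** 2 * var_g / var_y * 100.0, 0.0, 100.0) \
        if var_y > 0 else np.zeros(X.shape[1])

    table = pd.DataFrame({
        "snp": genotypes.snp_ids, "chrom": genotypes.chrom,
        "pos": genotypes.pos, "trait": trait_name,
        "p": pval, "beta": beta, "se": se, "pve": pve,
    })
    return MLMResult(table, significance_threshold(genotypes.n_snps),
                     h2, h2 * sigma2, (1 - h2) * sigma2)


def merge_qtls(snps: pd.DataFrame, window: int = QTL_WINDOW
               ) -> list[QTLInterval]:
    """Transitive 100-kb merging of significant SNPs into QTL intervals.

    SNPs on the same chromosome closer than ``window`` are merged,
    repeatedly, until no pair within ``window`` spans two clusters; each
    cluster is reported as [min_pos - window (floored at 1), max_pos +
    window] with the supporting traits unioned.
    """
    if snps.empty:
        return []
    has_trait = "trait" in snps.columns
    out = []
    for chrom, grp in snps.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        pos = grp.pos.to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, pos.size - 1]
        for s, e in zip(starts, ends):
            members = grp.iloc[s:e + 1]
            out.append(QTLInterval(
                chrom=str(chrom),
                start=max(int(pos[s]) - window, 1),
                end=int(pos[e]) + window,
                snps=list(members.snp) if "snp" in grp.columns
                     else list(members.index),
                traits=set(members.trait) if has_trait else set(),
            ))
    return out


def assign_candidate_genes(snps: pd.DataFrame, annotations: pd.DataFrame
                           ) -> pd.DataFrame:
    """SNP -> gene hits for SNPs inside gene spans (1-based inclusive).

    A SNP overlapping several genes yields one row per gene; SNPs in no
    gene yield nothing.  Malformed annotation rows (end < start or
    non-numeric coordinates) are skipped with a warning.
    """
    ann = annotations.copy()
    ann["start"] = pd.to_numeric(ann["start"], errors="coerce")
    ann["end"] = pd.to_numeric(ann["end"], errors="coerce")
    bad = ann.start.isna() | ann.end.isna() | (ann.end < ann.start)
    if bad.any():
        warnings.warn(f"skipping {int(bad.sum())} malformed annotation row(s)")
        ann = ann[~bad]
    hits = []
    for chrom, genes in ann.groupby("chrom"):
        sub = snps[snps.chrom == chrom]
        for _, g in genes.iterrows():
            inside = sub[(sub.pos >= g.start) & (sub.pos <= g.end)]
            for _, s in inside.iterrows():
                hits.append({"snp": s.snp, "chrom": chrom, "pos": s.pos,
                             "gene_id": g.gene_id})
    return pd.DataFrame(hits, columns=["snp", "chrom", "pos", "gene_id"])


def compute_ld_r2(snp_a, snp_b) -> float:
    """Squared Pearson correlation of two additive genotype columns.

    Missing entries (NaN or -1) are pairwise-deleted; zero variance in
    either column makes r2 undefined (NaN).
    """
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    a = np.where(a < 0, np.nan, a)
    b = np.where(b < 0, np.nan, b)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def map_eqtls(genotypes: GenotypeMatrix, expression: pd.DataFrame,
              annotations: pd.DataFrame, threshold: float | None = None,
              conditions=("WW", "DS"), n_pcs: int = 3) -> list[EQTLRecord]:
    """Scan expression traits per condition; classify detected eQTLs.

    ``expression`` columns: accession, gene, condition, value.  Per gene
    and condition the MLM scan is run; if any SNP clears the threshold
    (default 1/n markers) the most significant one is recorded.  kind is
    local iff that SNP lies within the gene span +/- 10 kb (inclusive at
    both window boundaries); dynamics is static when the gene is detected
    under both conditions and dynamic under exactly one.
    """
    thr = threshold if threshold is not None \
        else significance_threshold(genotypes.n_snps)
    K, Q = compute_kinship_and_pcs(genotypes, n_pcs)
    ann = annotations.set_index("gene_id")

    best: dict[str, dict] = {}
    for gene, grp in expression.groupby("gene"):
        if gene not in ann.index:
            warnings.warn(f"gene {gene} absent from annotations; skipped")
            continue
        for cond in conditions:
            sub = grp[grp.condition == cond]
            if sub.empty:
                continue
            y = sub.set_index("accession")["value"]
            res = mlm_scan(genotypes, y, K=K, Q=Q, trait_name=str(gene))
            sig = res.table.dropna(subset=["p"])
            sig = sig[sig.p <= thr]
            if sig.empty:
                continue
            top = sig.loc[sig.p.idxmin()]
            entry = best.setdefault(gene, {"conds": {}, "top": None})
            entry["conds"][cond] = (top.snp, float(top.p))
            if entry["top"] is None or top.p < entry["top"][2]:
                entry["top"] = (top.snp, top.chrom, float(top.p), int(top.pos))

    records = []
    for gene, entry in best.items():
        snp, chrom, p, pos = entry["top"]
        g = ann.loc[gene]
        local = (chrom == g.chrom
                 and g.start - EQTL_LOCAL_WINDOW <= pos <= g.end + EQTL_LOCAL_WINDOW)
        conds = tuple(c for c in conditions if c in entry["conds"])
        records.append(EQTLRecord(
            snp=snp, gene=gene, conditions=conds,
            p_values={c: entry["conds"][c][1] for c in conds},
            kind="local" if local else "distant",
            dynamics="static" if len(conds) == len(conditions) else "dynamic",
        ))
    return records
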