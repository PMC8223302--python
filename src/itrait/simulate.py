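"""Simulators for genotype, phenotype and expression panels with planted truth.

The generators mirror the study conditions of a greenhouse drought trial on
an association mapping panel: 368 inbred accessions phenotyped in 2
replicates under well-watered (WW) and drought-stressed (DS) arms, SNPs
restricted to minor-allele frequency >= 0.05, and broad-sense heritability
H2 = sigma2_G / (sigma2_G + sigma2_e / r) with a population median around
0.4.  Every generator is a pure function of its arguments including the
seed, so panels are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "SimulatedPanel",
    "SimulatedExpressionPanel",
    "simulate_genotypes",
    "simulate_trait_panel",
    "simulate_expression_panel",
]


@dataclass
class SimulatedPanel:
    """A trait panel with known genetic architecture.

    ``trait_values`` is a long table with columns
    accession / replicate / treatment (WW|DS) / time / value.
    ``true_h2`` equals sigma2_G/(sigma2_G + sigma2_e/r) by construction.
    """

    genotypes: GenotypeMatrix
    causal_snps: list              # (snp_id, beta) pairs
    trait_values: pd.DataFrame
    true_h2: float
    sigma2_G: float
    sigma2_e: float
    n_replicates: int
    treatment_effect: float
    seed: int
    genetic_values: np.ndarray = field(default=None, repr=False)


@dataclass
class SimulatedExpressionPanel:
    """Expression traits (accession x gene x condition) with planted eQTLs.

    ``planted_eqtls`` rows are (snp_id, gene_id, kind local|distant,
    conditions tuple of active arms).
    """

    expression: pd.DataFrame       # columns accession/gene/condition/value
    gene_annotations: pd.DataFrame  # gene_id, chrom, start, end, strand
    planted_eqtls: list
    seed: int


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_min: float = 0.05,
    n_chromosomes: int = 10,
    seed: int = 0,
    n_subpops: int = 1,
    fst: float = 0.1,
    chrom_length: int = 300_000_000,
) -> GenotypeMatrix:
    """Sample a biallelic SNP panel with every realized MAF >= ``maf_min``.

    Per SNP an ancestral allele frequency is drawn uniformly on
    [maf_min, 1 - maf_min] and genotypes are Binomial(2, p) per individual
    (inbred-panel LD is not modelled).  With ``n_subpops`` > 1, subpopulation
    frequencies diverge around the ancestral one under a Balding-Nichols
    F-model with divergence ``fst``, giving kinship/PC structure for the
    Q+K model to absorb.  Columns whose realized sample MAF falls below
    ``maf_min`` are redrawn, enforcing the MAF >= 0.05 admissibility rule
    of the association analysis at the generator.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if not 0 < maf_min < 0.5:
        raise ValueError("maf_min must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)

    membership = rng.integers(0, n_subpops, size=n_individuals)
    mat = np.empty((n_individuals, n_snps), dtype=np.int8)
    for j in range(n_snps):
        for _ in range(1000):
            p = rng.uniform(maf_min, 1.0 - maf_min)
            if n_subpops > 1:
                a, b = p * (1 - fst) / fst, (1 - p) * (1 - fst) / fst
                p_sub = rng.beta(a, b, size=n_subpops)
                col = rng.binomial(2, p_sub[membership]).astype(np.int8)
            else:
                col = rng.binomial(2, p, size=n_individuals).astype(np.int8)
            freq = col.mean() / 2.0
            if min(freq, 1 - freq) >= maf_min:
                mat[:, j] = col
                break
        else:  # pragma: no cover - essentially unreachable
            raise RuntimeError("could not satisfy MAF constraint")

    # spread SNPs over chromosomes with strictly increasing positions
    chrom_of = np.sort(rng.integers(0, n_chromosomes, size=n_snps))
    chrom = np.asarray([f"chr{c + 1}" for c in chrom_of], dtype=object)
    pos = np.empty(n_snps, dtype=np.int64)
    for c in range(n_chromosomes):
        idx = np.flatnonzero(chrom_of == c)
        if idx.size:
            p = np.sort(rng.integers(1, chrom_length, size=idx.size))
            # nudge duplicates upward to keep positions strictly increasing
            p += np.arange(idx.size)
            pos[idx] = p
    snp_ids = np.asarray(
        [f"{chrom[j]}.s_{pos[j]}" for j in range(n_snps)], dtype=object)
    accessions = np.asarray([f"acc{i:04d}" for i in range(n_individuals)],
                            dtype=object)
    return GenotypeMatrix(mat, snp_ids, chrom, pos, accessions)


def simulate_trait_panel(
    genotypes: GenotypeMatrix,
    h2: float = 0.4,
    r: int = 2,
    n_causal: int = 10,
    treatment_effect: float = 0.0,
    seed: int = 0,
    times=(1,),
    drought_effect_sd: float = 0.0,
    heavy_tail_df: float | None = None,
    baseline: float = 10.0,
) -> SimulatedPanel:
    """Simulate an i-trait as genotype effect + treatment shift + noise.

    The accession genetic value is the sum of ``n_causal`` planted SNP
    effects plus a polygenic deviation, rescaled so the realized genetic
    variance is exactly sigma2_G.  Variance components follow the
    convention sigma2_G = h2 and sigma2_e = r * (1 - h2), which makes the
    construction identity H2 = sigma2_G/(sigma2_G + sigma2_e/r) = h2 hold
    for any replicate count.  DS values add ``treatment_effect`` plus
    per-causal-SNP drought-specific effects (sd ``drought_effect_sd``) so
    DS/WW ratio traits carry genuine genetic signal.  ``heavy_tail_df``
    switches replicate noise from Gaussian to Student-t (same variance) to
    exercise the 3-sigma outlier filter.  ``baseline`` shifts both arms so
    DS/WW ratio traits are well-behaved (no division by near-zero values).
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must lie in [0, 1]")
    if r < 1:
        raise ValueError("need at least 1 replicate")
    if n_causal > genotypes.n_snps:
        raise ValueError("n_causal exceeds the number of SNPs")
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals

    sigma2_G = float(h2)
    sigma2_e = float(r * (1.0 - h2))

    causal_idx = rng.choice(genotypes.n_snps, size=n_causal, replace=False)
    beta = rng.normal(size=n_causal)
    g = genotypes.matrix[:, causal_idx].astype(float) @ beta
    g = g + rng.normal(size=n) * max(0.5 * np.std(g), 0.25)  # polygenic part
    g = g - g.mean()
    sd = g.std()
    if h2 == 0 or sd == 0:
        g = np.zeros(n)
        scale = 0.0
    else:
        scale = np.sqrt(sigma2_G) / sd
        g = g * scale
    causal = [(genotypes.snp_ids[causal_idx[k]], float(beta[k] * scale))
              for k in range(n_causal)]

    gamma = rng.normal(scale=drought_effect_sd, size=n_causal)
    ds_shift = genotypes.matrix[:, causal_idx].astype(float) @ gamma

    def noise(size):
        if sigma2_e == 0:
            return np.zeros(size)
        if heavy_tail_df is not None:
            df = float(heavy_tail_df)
            z = rng.standard_t(df, size=size)
            return z * np.sqrt(sigma2_e * (df - 2) / df)
        return rng.normal(scale=np.sqrt(sigma2_e), size=size)

    rows = []
    for t in times:
        for treatment in ("WW", "DS"):
            base = baseline + (g if treatment == "WW"
                               else g + treatment_effect + ds_shift)
            for rep in range(1, r + 1):
                vals = base + noise(n)
                rows.append(pd.DataFrame({
                    "accession": genotypes.accessions,
                    "replicate": rep,
                    "treatment": treatment,
                    "time": t,
                    "value": vals,
                }))
    table = pd.concat(rows, ignore_index=True)
    true_h2 = sigma2_G / (sigma2_G + sigma2_e / r) if sigma2_G > 0 else 0.0
    return SimulatedPanel(genotypes, causal, table, true_h2, sigma2_G,
                          sigma2_e, r, treatment_effect, seed,
                          genetic_values=g)


LOCAL_WINDOW = 10_000  # bp flank defining a local (cis) eQTL


def simulate_expression_panel(
    genotypes: GenotypeMatrix,
    annotations: pd.DataFrame,
    n_local: int = 1,
    n_distant: int = 1,
    effect: float = 1.0,
    seed: int = 0,
    noise_sd: float = 1.0,
    prop_dynamic: float = 0.5,
    conditions=("WW", "DS"),
) -> SimulatedExpressionPanel:
    """Plant local and distant eQTLs into a two-condition expression panel.

    A local eQTL SNP lies within ``LOCAL_WINDOW`` (10 kb) of its gene span;
    a distant eQTL SNP lies beyond it (different chromosome preferred).
    Static eQTLs are active under both conditions, dynamic ones under
    exactly one (alternating, starting with DS); the first
    round(prop_dynamic * n) planted eQTLs of each kind are dynamic.
    """
    if annotations is None or len(annotations) == 0:
        raise ValueError("annotations must be non-empty")
    rng = np.random.default_rng(seed)
    ann = annotations.reset_index(drop=True)

    def snp_gene_distance(j, gene):
        if genotypes.chrom[j] != gene.chrom:
            return np.inf
        p = genotypes.pos[j]
        if gene.start <= p <= gene.end:
            return 0
        return min(abs(p - gene.start), abs(p - gene.end))

    local_pairs, distant_pairs = [], []
    for _, gene in ann.iterrows():
        for j in range(genotypes.n_snps):
            d = snp_gene_distance(j, gene)
            if d <= LOCAL_WINDOW:
                local_pairs.append((j, gene.gene_id))
            else:
                distant_pairs.append((j, gene.gene_id))
    if n_local > 0 and not local_pairs:
        raise ValueError("infeasible design: no SNP within 10 kb of any gene")
    if n_local > len(local_pairs) or n_distant > len(distant_pairs):
        raise ValueError("requested more eQTLs than admissible SNP/gene pairs")

    def pick(pairs, k, used_genes):
        # one eQTL per gene keeps planted labels unambiguous downstream
        chosen, order = [], rng.permutation(len(pairs))
        for i in order:
            if len(chosen) == k:
                break
            j, g = pairs[i]
            if g not in used_genes:
                chosen.append((j, g))
                used_genes.add(g)
        if len(chosen) < k:
            raise ValueError("not enough distinct genes for the requested eQTLs")
        return chosen

    used: set = set()
    planted = []
    chosen = ([(j, g, "local") for j, g in pick(local_pairs, n_local, used)] +
              [(j, g, "distant") for j, g in pick(distant_pairs, n_distant, used)])
    n_dyn = {"local": round(prop_dynamic * n_local),
             "distant": round(prop_dynamic * n_distant)}
    seen = {"local": 0, "distant": 0}
    for j, gene_id, kind in chosen:
        if seen[kind] < n_dyn[kind]:
            active = (conditions[1 if seen[kind] % 2 == 0 else 0],)
        else:
            active = tuple(conditions)
        seen[kind] += 1
        planted.append((genotypes.snp_ids[j], gene_id, kind, active))

    by_gene: dict = {}
    for snp_id, gene_id, kind, active in planted:
        by_gene.setdefault(gene_id, []).append((snp_id, active))

    rows = []
    for _, gene in ann.iterrows():
        base = rng.normal(scale=0.5)
        for cond in conditions:
            expr = base + rng.normal(scale=noise_sd, size=genotypes.n_individuals)
            for snp_id, active in by_gene.get(gene.gene_id, []):
                if cond in active:
                    expr = expr + effect * genotypes.column(snp_id)
            rows.append(pd.DataFrame({
                "accession": genotypes.accessions,
                "gene": gene.gene_id,
                "condition": cond,
                "value": expr,
            }))
    expression = pd.concat(rows, ignore_index=True)
    return SimulatedExpressionPanel(expression, ann, planted, seed)


def make_annotations(genotypes: GenotypeMatrix, n_genes: int,
                     gene_length: int = 3000, seed: int = 0,
                     near_snp_fraction: float = 0.5) -> pd.DataFrame:
    """Place gene models on the simulated genome (GFF3-style 1-based spans).

    A fraction of genes is anchored near randomly chosen SNPs (within the
    10-kb local window) so local eQTL designs are feasible; the rest are
    placed uniformly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    chroms = pd.unique(genotypes.chrom)
    for k in range(n_genes):
        if k < near_snp_fraction * n_genes and genotypes.n_snps:
            j = int(rng.integers(genotypes.n_snps))
            start = max(1, int(genotypes.pos[j]) + int(rng.integers(-8000, 8000)))
            chrom = genotypes.chrom[j]
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, 200_000_000))
        rows.append({"gene_id": f"gene{k:04d}", "chrom": chrom,
                     "start": start, "end": start + gene_length - 1,
                     "strand": "+" if rng.random() < 0.5 else "-"})
    return pd.DataFrame(rows)
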