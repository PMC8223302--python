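"""Genomic prediction and i-trait marker selection.

RR-BLUP fits y = 1 mu + Z u with u ~ N(0, sigma2_u I); the variance ratio
lambda = sigma2_e/sigma2_u is estimated by REML on the eigenbasis of ZZ'
and marker effects are the BLUP solution of the ridge system.  Bayes A
gives each marker its own variance with a scaled-inverse-chi-square prior,
sampled by Gibbs; in the large-prior-degrees-of-freedom limit it collapses
to the ridge solution.  Gene sets are evaluated by repeated 50/50
train/test splits with accuracy = Pearson r(predicted, observed), candidate
(top-k genes' best SNPs) against size-matched random draws.  Stepwise
forward/backward regression selects ratio i-traits that explain survival
rate, and four remote-sensing indexes (red valley, green peak, green-peak
area, red-edge area) summarize the average-reflectance spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = ["RRBLUPModel", "BayesAModel", "fit_rrblup", "fit_bayes_a",
           "evaluate_genomic_selection", "stepwise_trait_markers",
           "compute_spectral_indexes", "SpectralIndexSet", "MarkerPanel"]


@dataclass
class RRBLUPModel:
    mu: float
    effects: np.ndarray
    marker_means: np.ndarray
    sigma2_u: float
    sigma2_e: float
    lam: float

    def predict(self, Z_new: np.ndarray) -> np.ndarray:
        Zc = np.asarray(Z_new, dtype=float) - self.marker_means
        return self.mu + Zc @ self.effects


@dataclass
class BayesAModel:
    mu: float
    effects: np.ndarray           # posterior means
    marker_means: np.ndarray
    sigma2_e_samples: np.ndarray = field(repr=False, default=None)

    def predict(self, Z_new: np.ndarray) -> np.ndarray:
        Zc = np.asarray(Z_new, dtype=float) - self.marker_means
        return self.mu + Zc @ self.effects


def fit_rrblup(Z: np.ndarray, y: np.ndarray,
               lam: float | None = None) -> RRBLUPModel:
    """Ridge-regression BLUP of marker effects.

    With ``lam`` given, effects are the closed-form ridge solution
    (Z'Z + lam I)^-1 Z'(y - mu) computed through the equivalent n x n
    system Z'(ZZ' + lam I)^-1 (y - mu); otherwise lambda = sigma2_e /
    sigma2_u comes from REML.  Marker columns are centered on training
    means, so a zero-variance marker gets an exactly zero effect, and a
    constant phenotype yields zero effects with mean-only predictions.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = Z.shape
    if n < 2 or m < 1:
        raise ValueError("need >= 2 training lines and >= 1 marker")
    means = Z.mean(axis=0)
    Zc = Z - means
    if np.ptp(y) == 0:
        return RRBLUPModel(float(y.mean()), np.zeros(m), means, 0.0, 0.0,
                           np.inf)

    G = Zc @ Zc.T
    eig, U = np.linalg.eigh((G + G.T) / 2.0)
    eig = np.clip(eig, 0.0, None)
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)

    if lam is None:
        def crit(log_lam):
            l = np.exp(log_lam)
            w = eig + l          # V = sigma2_u (ZZ' + lam I)
            Xw = ones_t / np.sqrt(w)
            yw = yt / np.sqrt(w)
            mu = float(Xw @ yw / (Xw @ Xw))
            rss = float(((yw - mu * Xw) ** 2).sum())
            return 0.5 * ((n - 1) * np.log(rss / (n - 1)) + np.log(w).sum()
                          + np.log(float(Xw @ Xw)))

        res = minimize_scalar(crit, bounds=(-12.0, 12.0), method="bounded")
        lam = float(np.exp(res.x))

    w = eig + lam
    Xw, yw = ones_t / np.sqrt(w), yt / np.sqrt(w)
    mu = float(Xw @ yw / (Xw @ Xw))
    sigma2_u = float(((yw - mu * Xw) ** 2).sum()) / max(n - 1, 1)
    # u_hat = Z' (ZZ' + lam I)^-1 (y - mu)  ==  (Z'Z + lam I)^-1 Z'(y - mu)
    alpha = U @ ((yt - mu * ones_t) / w)
    effects = Zc.T @ alpha
    return RRBLUPModel(mu, effects, means, sigma2_u, lam * sigma2_u, lam)


def fit_bayes_a(Z: np.ndarray, y: np.ndarray, n_iter: int = 5000,
                burn_in: int = 1000, thin: int = 5, df0: float = 5.0,
                scale0: float | None = None, seed: int = 0) -> BayesAModel:
    """Bayes A Gibbs sampler: per-marker scaled-inverse-chi-square variances.

    Updates cycle over marker effects (conjugate normal), marker variances
    (inverse chi-square with df0 + 1), the intercept and the residual
    variance.  ``scale0`` defaults so the prior mode of each marker
    variance matches half the phenotypic variance spread over the markers
    (a BGLR-like R2 = 0.5 rule).  Fully seeded and deterministic.
    """
    if n_iter <= burn_in:
        raise ValueError("chain length must exceed burn-in")
    if df0 <= 0 or (scale0 is not None and scale0 <= 0):
        raise ValueError("prior df and scale must be positive")
    rng = np.random.default_rng(seed)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = Z.shape
    means = Z.mean(axis=0)
    Zc = Z - means
    xtx = np.einsum("ij,ij->j", Zc, Zc)
    var_y = y.var()
    if var_y == 0:
        return BayesAModel(float(y.mean()), np.zeros(m), means,
                           np.zeros(1))
    sum_x2 = max(xtx.sum() / n, 1e-12)
    if scale0 is None:
        scale0 = 0.5 * var_y / sum_x2 * (df0 + 2.0) / df0

    mu = float(y.mean())
    u = np.zeros(m)
    sigma2_j = np.full(m, df0 * scale0 / (df0 + 2.0))
    sigma2_e = var_y * 0.5
    e = y - mu
    keep_effects = np.zeros(m)
    keep_sigma_e = []
    kept = 0
    df_e, s_e = 5.0, var_y * 0.5

    for it in range(n_iter):
        # intercept
        mu_new = rng.normal(mu + e.mean(), np.sqrt(sigma2_e / n))
        e += mu - mu_new
        mu = mu_new
        # marker effects and their variances
        for j in range(m):
            if xtx[j] <= 1e-12:
                u[j] = 0.0
                continue
            e += Zc[:, j] * u[j]
            c = xtx[j] / sigma2_e + 1.0 / sigma2_j[j]
            mean_j = (Zc[:, j] @ e) / sigma2_e / c
            u[j] = rng.normal(mean_j, np.sqrt(1.0 / c))
            e -= Zc[:, j] * u[j]
            sigma2_j[j] = ((df0 * scale0 + u[j] ** 2)
                           / rng.chisquare(df0 + 1.0))
        # residual variance
        sigma2_e = ((e @ e + df_e * s_e) / rng.chisquare(n + df_e))
        if it >= burn_in and (it - burn_in) % thin == 0:
            keep_effects += u
            keep_sigma_e.append(sigma2_e)
            kept += 1

    return BayesAModel(mu, keep_effects / kept, means,
                       np.asarray(keep_sigma_e))


def _accuracy(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1])


def evaluate_genomic_selection(
    genotypes, phenotype: np.ndarray, candidate_snps: list[str],
    ks=(1, 10, 20, 30, 40, 50, 100, "all"), n_repeats: int = 100,
    n_random_draws: int = 50, model: str = "rrblup", seed: int = 0,
    train_fraction: float = 0.5, bayes_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Candidate vs size-matched random gene-set prediction accuracies.

    ``candidate_snps`` is the ranked list of best SNPs per candidate gene
    (most significant first).  For each set size k the top-k candidate
    SNPs and ``n_random_draws`` random size-matched sets from the
    non-candidate pool are evaluated over ``n_repeats`` 50/50 train/test
    splits; accuracy is Pearson r(predicted, observed) on the test half.
    Returns one row per (k, set label, repeat) plus a Welch t comparison
    per k.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    all_ids = list(genotypes.snp_ids)
    cand_idx = [genotypes.snp_index(s) for s in candidate_snps]
    pool = np.asarray([i for i in range(len(all_ids)) if i not in set(cand_idx)])
    n = len(y)
    n_train = int(round(train_fraction * n))
    bayes_kwargs = bayes_kwargs or {}

    def fit_predict(cols, train, test, rep_seed):
        Z = genotypes.matrix[:, cols].astype(float)
        if model == "rrblup":
            mdl = fit_rrblup(Z[train], y[train])
        elif model == "bayesa":
            mdl = fit_bayes_a(Z[train], y[train], seed=rep_seed, **bayes_kwargs)
        else:
            raise ValueError(f"unknown model {model!r}")
        return _accuracy(mdl.predict(Z[test]), y[test])

    rows = []
    for k in ks:
        if k == "all":
            c_cols = np.arange(genotypes.n_snps)
        else:
            kk = min(int(k), len(cand_idx))
            if kk < k:
                warnings.warn(f"k={k} larger than candidate pool; truncated "
                              f"to {kk}")
            c_cols = np.asarray(cand_idx[:kk])
        random_sets = []
        for _ in range(n_random_draws):
            if k == "all":
                random_sets.append(np.arange(genotypes.n_snps))
            else:
                random_sets.append(rng.choice(pool, size=len(c_cols),
                                              replace=False))
        for rep in range(n_repeats):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            rows.append({"k": k, "set": "candidate", "repeat": rep,
                         "accuracy": fit_predict(c_cols, train, test,
                                                 seed + rep)})
            rset = random_sets[rep % n_random_draws]
            rows.append({"k": k, "set": "random", "repeat": rep,
                         "accuracy": fit_predict(rset, train, test,
                                                 seed + rep)})
    table = pd.DataFrame(rows)
    summary = []
    for k, grp in table.groupby("k", sort=False):
        ca = grp[grp.set == "candidate"].accuracy
        ra = grp[grp.set == "random"].accuracy
        t = stats.ttest_ind(ca, ra, equal_var=False, alternative="greater")
        summary.append({"k": k, "candidate_mean": ca.mean(),
                        "candidate_sd": ca.std(), "random_mean": ra.mean(),
                        "random_sd": ra.std(), "p_greater": float(t.pvalue)})
    table.attrs["summary"] = pd.DataFrame(summary)
    return table


@dataclass
class MarkerPanel:
    """Stepwise-selected i-trait markers for a quantitative outcome."""

    steps: pd.DataFrame   # step, trait, partial_r2, cumulative_r2
    selected: list

    @property
    def cumulative_r2(self) -> float:
        return float(self.steps.cumulative_r2.iloc[-1]) if len(self.steps) else 0.0


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def stepwise_trait_markers(traits: pd.DataFrame, outcome,
                           entry_alpha: float = 0.05,
                           removal_alpha: float = 0.10,
                           max_steps: int = 20) -> MarkerPanel:
    """Forward stepwise regression with backward elimination.

    At each step the candidate with the smallest partial-F p-value enters
    if p < ``entry_alpha``; after each entry, included predictors whose
    partial-F p exceeds ``removal_alpha`` are dropped.  Stops at
    ``max_steps`` entries or when no candidate is admissible.  Predictors
    collinear with the current model (residual variance below tolerance)
    never enter.
    """
    y = np.asarray(outcome, dtype=float)
    X = traits.to_numpy(dtype=float)
    ok_rows = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X = y[ok_rows], X[ok_rows]
    n = y.size
    names = list(traits.columns)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("outcome has no variance")

    included: list[int] = []
    steps = []
    step = 0
    while step < max_steps:
        base = np.column_stack([np.ones(n)] + [X[:, j] for j in included])
        rss_base = _ols_rss(base, y)
        best = None
        for j in range(X.shape[1]):
            if j in included:
                continue
            xj = X[:, j]
            resid = xj - base @ np.linalg.lstsq(base, xj, rcond=None)[0]
            if float(resid @ resid) < 1e-8 * max(float(xj @ xj), 1.0):
                continue  # collinear with current model
            rss_new = _ols_rss(np.column_stack([base, xj]), y)
            df2 = n - base.shape[1] - 1
            if df2 <= 0 or rss_new <= 0:
                continue
            f = (rss_base - rss_new) / (rss_new / df2)
            p = float(stats.f.sf(f, 1, df2))
            if best is None or p < best[1]:
                best = (j, p, rss_new)
        if best is None or best[1] >= entry_alpha:
            break
        j, p, rss_new = best
        included.append(j)
        step += 1
        steps.append({"step": step, "trait": names[j],
                      "partial_r2": (rss_base - rss_new) / tss,
                      "p_entry": p,
                      "cumulative_r2": 1.0 - rss_new / tss})
        # backward pass
        changed = True
        while changed and len(included) > 1:
            changed = False
            cols = np.column_stack([np.ones(n)] + [X[:, i] for i in included])
            rss_full = _ols_rss(cols, y)
            worst = None
            for pos, i in enumerate(included):
                reduced = np.delete(cols, pos + 1, axis=1)
                rss_red = _ols_rss(reduced, y)
                df2 = n - cols.shape[1]
                f = (rss_red - rss_full) / (rss_full / df2)
                p_i = float(stats.f.sf(max(f, 0.0), 1, df2))
                if worst is None or p_i > worst[1]:
                    worst = (i, p_i)
            if worst and worst[1] > removal_alpha:
                included.remove(worst[0])
                changed = True
    step_df = pd.DataFrame(steps, columns=["step", "trait", "partial_r2",
                                           "p_entry", "cumulative_r2"])
    return MarkerPanel(step_df, [names[j] for j in included])


@dataclass
class SpectralIndexSet:
    red_valley_reflectance: float
    green_peak_reflectance: float
    green_peak_area: float
    red_edge_area: float


# standard remote-sensing windows (nm)
GREEN_PEAK_WINDOW = (500.0, 590.0)
RED_VALLEY_WINDOW = (620.0, 700.0)
RED_EDGE_WINDOW = (680.0, 760.0)


def compute_spectral_indexes(average: np.ndarray,
                             wavelengths: np.ndarray | None = None
                             ) -> SpectralIndexSet:
    """Chlorophyll/water indexes from the average-reflectance spectrum.

    green peak = max A over 500-590 nm; red valley = min A over 620-700 nm;
    green-peak area = trapezoidal integral of A over 500-590 nm; red-edge
    area = trapezoidal integral of dA/d(lambda) over 680-760 nm.  Computed
    on averages, so they are invariant to plant pixel count.
    """
    from .hsi import band_wavelengths

    A = np.asarray(average, dtype=float)
    lam = (np.asarray(wavelengths, dtype=float) if wavelengths is not None
           else band_wavelengths(A.size))
    if lam.min() > GREEN_PEAK_WINDOW[0] or lam.max() < RED_EDGE_WINDOW[1]:
        raise ValueError("spectrum does not cover the 500-760 nm index windows")

    def window(lo, hi):
        return (lam >= lo) & (lam <= hi)

    gp = window(*GREEN_PEAK_WINDOW)
    rv = window(*RED_VALLEY_WINDOW)
    re = window(*RED_EDGE_WINDOW)
    dA = np.gradient(A, lam)
    return SpectralIndexSet(
        red_valley_reflectance=float(A[rv].min()),
        green_peak_reflectance=float(A[gp].max()),
        green_peak_area=float(np.trapezoid(A[gp], lam[gp])),
        red_edge_area=float(np.trapezoid(dA[re], lam[re])),
    )
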