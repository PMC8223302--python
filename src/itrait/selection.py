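"""Drought-trait selection: trait-table assembly and the four-stage filter.

Stages, applied in order to each candidate i-trait:

1. 3-sigma (PauTa) outlier removal -- values outside mean +/- 3 sd of the
   raw column are missing-coded (single pass; 99.7% normal coverage).
2. Welch t-test of WW vs DS accession means; keep if p < alpha (0.05).
3. Multilayer-perceptron importance for WW/DS classification: permutation
   importance normalized to the maximum = 100%, averaged over five
   repeated fits; keep if the mean normalized importance >= 50%.
4. Broad-sense heritability H2 = sigma2_G/(sigma2_G + sigma2_e/r) from a
   one-way random-effects model with accession as the random effect; keep
   if H2 >= 0.2 in either watering condition.

A trait survives only if it passes stages 2-4 after stage-1 cleaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TraitTable", "HeritabilityEstimate", "SelectionConfig",
           "assemble_trait_table", "filter_outliers_3sigma", "ttest_filter",
           "mlp_importance_filter", "estimate_heritability", "run_selection"]

VIEWS = ("WW", "DS", "R")


@dataclass
class TraitTable:
    """Wide accession x replicate table of i-trait columns.

    Columns are named ``<trait>_D<day>_<view>`` with view in {WW, DS, R}
    (R = the DS/WW ratio).  ``meta`` maps each column id to its base trait,
    day, view and modality.
    """

    wide: pd.DataFrame            # index (accession, replicate)
    meta: pd.DataFrame            # column_id, trait, day, view, modality

    @property
    def n_columns(self) -> int:
        return self.wide.shape[1]

    def counts_by_modality(self) -> pd.Series:
        return self.meta.groupby("modality")["column_id"].count()


@dataclass
class HeritabilityEstimate:
    trait: str
    sigma2_G: float
    sigma2_e: float
    r: float
    flagged: bool = False

    @property
    def H2(self) -> float:
        denom = self.sigma2_G + self.sigma2_e / self.r
        return self.sigma2_G / denom if denom > 0 else 0.0


@dataclass
class SelectionConfig:
    alpha: float = 0.05
    mlp_repeats: int = 5
    mlp_cutoff_pct: float = 50.0
    mlp_hidden: int = 64
    mlp_max_iter: int = 300
    h2_cutoff: float = 0.2
    seed: int = 0


def assemble_trait_table(records: pd.DataFrame,
                         rel_eps: float = 1e-12) -> TraitTable:
    """Pivot long trait records into the WW/DS/ratio wide table.

    ``records`` columns: accession, replicate, treatment (WW|DS), day,
    modality, trait, value.  Ratio columns (view "R") are DS/WW per
    accession-replicate-day and exist only where both arms were measured;
    a WW value within machine-scaled epsilon of zero missing-codes the
    ratio.  The full seedling+flowering design (RGB 67 traits x 10 days,
    HSI 2000 x 4, CT 100 x 3, each in 3 treatment views) yields
    2010 + 24,000 + 900 = 26,910 columns.
    """
    req = {"accession", "replicate", "treatment", "day", "modality",
           "trait", "value"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")

    wide = records.pivot_table(
        index=["accession", "replicate"],
        columns=["trait", "day", "treatment"],
        values="value", aggfunc="first", observed=True)
    modality_of = (records.drop_duplicates("trait")
                   .set_index("trait")["modality"].to_dict())

    data, meta = {}, []
    pairs = sorted({(t, d) for t, d, _ in wide.columns},
                   key=lambda td: (str(td[0]), td[1]))
    scale = records["value"].abs().max()
    eps = rel_eps * (scale if np.isfinite(scale) and scale > 0 else 1.0)
    for trait, day in pairs:
        ww = wide[(trait, day, "WW")] if (trait, day, "WW") in wide.columns else None
        ds = wide[(trait, day, "DS")] if (trait, day, "DS") in wide.columns else None
        for view, col in (("WW", ww), ("DS", ds)):
            if col is not None:
                cid = f"{trait}_D{day}_{view}"
                data[cid] = col
                meta.append((cid, trait, day, view, modality_of[trait]))
        if ww is not None and ds is not None:
            cid = f"{trait}_D{day}_R"
            ratio = ds / ww.where(ww.abs() > eps)
            data[cid] = ratio
            meta.append((cid, trait, day, "R", modality_of[trait]))
    wide_out = pd.DataFrame(data, index=wide.index)
    meta_df = pd.DataFrame(meta, columns=["column_id", "trait", "day",
                                          "view", "modality"])
    return TraitTable(wide_out, meta_df)


def filter_outliers_3sigma(values: pd.Series | np.ndarray,
                           column_stats: tuple | None = None):
    """Single-pass PauTa criterion: NaN-out values beyond mean +/- 3 sd.

    Mean and sd come from the raw column (not recomputed after removals),
    matching the 99.7% normal-coverage reading of the rule; passing
    ``column_stats`` = (mean, sd) re-applies a previous pass's bounds, under
    which the filter is idempotent.  Returns the cleaned column and the
    removal count.  Zero variance removes nothing.
    """
    if isinstance(values, pd.Series):
        x = values.astype(float)
    else:
        x = pd.Series(np.asarray(values, dtype=float))
    ok = x.notna()
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing values")
    if column_stats is not None:
        mu, sd = column_stats
    else:
        mu, sd = x[ok].mean(), x[ok].std(ddof=1)
    if sd == 0:
        return x, 0
    bad = ok & ((x < mu - 3 * sd) | (x > mu + 3 * sd))
    cleaned = x.mask(bad)
    return cleaned, int(bad.sum())


def ttest_filter(ww, ds, alpha: float = 0.05):
    """Two-sided Welch t-test of WW vs DS; keep iff p < alpha.

    Returns (p_value, keep, reason).  Fewer than two observations in either
    group drops the trait with reason "insufficient observations".
    """
    ww = np.asarray(ww, dtype=float)
    ds = np.asarray(ds, dtype=float)
    ww, ds = ww[~np.isnan(ww)], ds[~np.isnan(ds)]
    if ww.size < 2 or ds.size < 2:
        return np.nan, False, "insufficient observations"
    if ww.std() == 0 and ds.std() == 0 and ww.mean() == ds.mean():
        return 1.0, False, "identical groups"
    p = float(stats.ttest_ind(ww, ds, equal_var=False).pvalue)
    if np.isnan(p):
        return 1.0, False, "degenerate variance"
    return p, p < alpha, ""


def mlp_importance_filter(X: pd.DataFrame, labels, n_repeats: int = 5,
                          cutoff_pct: float = 50.0, seed: int = 0,
                          hidden: int = 64, max_iter: int = 300,
                          perm_repeats: int = 3):
    """Permutation importance of each trait for WW/DS classification.

    A single-hidden-layer perceptron is trained on standardized traits;
    per-trait permutation importance is normalized so the most important
    trait scores 100%, and the normalized scores are averaged over
    ``n_repeats`` independently seeded fits (five by default).  Returns a
    DataFrame (importance_pct, keep) plus a low-class-separation flag when
    the model does no better than chance.
    """
    from sklearn.inspection import permutation_importance
    from sklearn.neural_network import MLPClassifier
    from sklearn.preprocessing import StandardScaler

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    Xv = X.fillna(X.mean())
    Xs = StandardScaler().fit_transform(Xv.to_numpy(dtype=float))
    scores = np.zeros(X.shape[1])
    accs = []
    for rep in range(n_repeats):
        clf = MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=max_iter,
                            early_stopping=True, random_state=seed + rep)
        clf.fit(Xs, y)
        accs.append(clf.score(Xs, y))
        imp = permutation_importance(clf, Xs, y, n_repeats=perm_repeats,
                                     random_state=seed + rep).importances_mean
        imp = np.clip(imp, 0.0, None)
        top = imp.max()
        scores += (imp / top * 100.0) if top > 0 else np.zeros_like(imp)
    scores /= n_repeats
    majority = max(np.mean(y == y[0]), 1 - np.mean(y == y[0]))
    low_separation = bool(np.mean(accs) <= majority + 0.05)
    report = pd.DataFrame({"importance_pct": scores,
                           "keep": scores >= cutoff_pct}, index=X.columns)
    return report, low_separation


def estimate_heritability(values: pd.DataFrame, r: int | None = None,
                          trait: str = "") -> HeritabilityEstimate:
    """Variance components of a one-way random-effects (accession) model.

    ``values`` needs columns accession and value, one row per replicate
    observation.  The ANOVA estimator (which coincides with REML for the
    balanced interior case) gives sigma2_e = MS_within and
    sigma2_G = (MS_between - MS_within)/n0, negative components truncated
    at zero; H2 then follows the sigma2_G/(sigma2_G + sigma2_e/r) formula.
    """
    df = values.dropna(subset=["value"])
    groups = df.groupby("accession")["value"]
    a = groups.ngroups
    if a < 2:
        raise ValueError("need >= 2 accessions")
    n_i = groups.count()
    N = int(n_i.sum())
    if r is None:
        r = float(n_i.mean())
    if N == a:  # all single-replicate: error variance inestimable
        return HeritabilityEstimate(trait, np.nan, np.nan, r, flagged=True)
    grand = df["value"].mean()
    means = groups.mean()
    ss_between = float((n_i * (means - grand) ** 2).sum())
    ss_within = float(((df["value"] - df["accession"].map(means)) ** 2).sum())
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - float((n_i ** 2).sum()) / N) / (a - 1)
    sigma2_e = ms_within
    sigma2_G = max((ms_between - ms_within) / n0, 0.0)
    return HeritabilityEstimate(trait, sigma2_G, sigma2_e, r)


def run_selection(table: TraitTable, design: pd.DataFrame | None = None,
                  config: SelectionConfig | None = None) -> pd.DataFrame:
    """Apply the four-stage filter; one report row per (trait, day).

    The report carries, per base trait and day: the 3-sigma removal count,
    Welch-t p-value, mean normalized MLP importance, per-condition H2
    estimates, the per-stage keep flags and their conjunction ``keep``.
    A kept base trait retains its WW, DS and ratio columns.
    """
    cfg = config or SelectionConfig()
    if table.wide.shape[1] == 0:
        return pd.DataFrame(columns=["trait", "day", "n_outliers", "p_ttest",
                                     "importance_pct", "h2_ww", "h2_ds",
                                     "keep_ttest", "keep_mlp", "keep_h2",
                                     "keep"])

    wide = table.wide.copy()
    removed = {}
    for cid in wide.columns:
        col = wide[cid]
        if col.notna().sum() >= 2:
            wide[cid], removed[cid] = filter_outliers_3sigma(col)
        else:
            removed[cid] = 0

    meta = table.meta.set_index("column_id")
    bases = (meta[meta.view.isin(["WW", "DS"])]
             .groupby(["trait", "day"]).groups)

    # stacked rows = accession x replicate x treatment for the MLP stage
    def stacked(cids_by_base):
        frames = []
        for view in ("WW", "DS"):
            cols = {f"{t}|D{d}": f"{t}_D{d}_{view}" for t, d in cids_by_base
                    if f"{t}_D{d}_{view}" in wide.columns}
            if not cols:
                continue
            f = wide[list(cols.values())].copy()
            f.columns = list(cols.keys())
            f["__label__"] = view
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    rows = []
    ttest_pass = {}
    for (trait, day) in bases:
        ww_id, ds_id = f"{trait}_D{day}_WW", f"{trait}_D{day}_DS"
        if ww_id in wide.columns and ds_id in wide.columns:
            ww = wide[ww_id].groupby(level="accession").mean()
            ds = wide[ds_id].groupby(level="accession").mean()
            p, keep_t, reason = ttest_filter(ww, ds, cfg.alpha)
        else:
            p, keep_t = np.nan, False
        ttest_pass[(trait, day)] = keep_t
        rows.append({"trait": trait, "day": day,
                     "n_outliers": sum(removed.get(c, 0) for c in
                                       (ww_id, ds_id) if c in removed),
                     "p_ttest": p, "keep_ttest": keep_t})
    report = pd.DataFrame(rows)
    if report.empty:
        report["keep"] = []
        return report

    survivors = [bd for bd, ok in ttest_pass.items() if ok]
    report["importance_pct"] = np.nan
    report["keep_mlp"] = False
    report["low_separation"] = False
    if survivors:
        stack = stacked(survivors)
        X = stack.drop(columns="__label__")
        mlp_rep, low_sep = mlp_importance_filter(
            X, stack["__label__"], n_repeats=cfg.mlp_repeats,
            cutoff_pct=cfg.mlp_cutoff_pct, seed=cfg.seed,
            hidden=cfg.mlp_hidden, max_iter=cfg.mlp_max_iter)
        for (trait, day) in survivors:
            key = f"{trait}|D{day}"
            sel = (report.trait == trait) & (report.day == day)
            report.loc[sel, "importance_pct"] = mlp_rep.loc[key, "importance_pct"]
            report.loc[sel, "keep_mlp"] = bool(mlp_rep.loc[key, "keep"])
            report.loc[sel, "low_separation"] = low_sep

    h2_ww, h2_ds = [], []
    accessions = wide.index.get_level_values("accession")
    for _, row in report.iterrows():
        for view, store in (("WW", h2_ww), ("DS", h2_ds)):
            cid = f"{row.trait}_D{row.day}_{view}"
            if cid in wide.columns:
                df = pd.DataFrame({"accession": accessions,
                                   "value": wide[cid].to_numpy()})
                try:
                    est = estimate_heritability(df, trait=cid)
                    store.append(est.H2 if not est.flagged else np.nan)
                except ValueError:
                    store.append(np.nan)
            else:
                store.append(np.nan)
    report["h2_ww"] = h2_ww
    report["h2_ds"] = h2_ds
    report["keep_h2"] = (report[["h2_ww", "h2_ds"]].max(axis=1)
                         >= cfg.h2_cutoff)
    report["keep"] = report.keep_ttest & report.keep_mlp & report.keep_h2
    return report
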