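"""Statistical validation harness.

Implements the evaluation battery used to judge pCR predictions against
observed outcomes: exact binomial (Clopper–Pearson) intervals on confusion
metrics, AUROC with percentile-bootstrap intervals, a threefold
cross-validated logistic clinical comparator, log-rank / Kaplan–Meier /
Cox survival comparison between prediction groups, Pearson correlation
with Fisher-transform significance, and the overall-plus-subgroup
metrics report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import OneHotEncoder
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass
class ConfusionTable:
    """Predicted-pCR vs observed-pCR counts."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @classmethod
    def from_predictions(cls, predicted, observed) -> "ConfusionTable":
        p = np.asarray(predicted, dtype=bool)
        o = np.asarray(observed, dtype=bool)
        if p.shape != o.shape:
            raise ValueError("prediction/truth length mismatch")
        return cls(TP=int(np.sum(p & o)), FP=int(np.sum(p & ~o)),
                   FN=int(np.sum(~p & o)), TN=int(np.sum(~p & ~o)))


@dataclass
class StatsConfig:
    level: float = 0.95
    bootstrap_replicates: int = 1000
    bootstrap_seed: int = 0
    cv_folds: int = 3
    cv_seed: int = 0
    survival_horizon_years: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValueError("confidence level must be in (0, 1)")
        if self.bootstrap_replicates < 1 or self.cv_folds < 2:
            raise ValueError("replicates >= 1 and folds >= 2 required")


def clopper_pearson(successes: int, trials: int, level: float = 0.95
                    ) -> tuple[float, float]:
    """Exact central binomial interval via Beta quantiles (proportions)."""
    if not (0 <= successes <= trials) or trials < 1:
        raise ValueError("require 0 <= successes <= trials, trials >= 1")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    hi = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lo, hi


def confusion_metrics(t: ConfusionTable, cfg: StatsConfig | None = None) -> dict:
    """Sensitivity, specificity, accuracy with Clopper–Pearson CIs.

    Returns raw proportions; zero-denominator metrics are omitted and named
    in the 'flags' entry.  Percent formatting is left to the report layer.
    """
    cfg = cfg or StatsConfig()
    if t.n == 0:
        raise ValueError("empty confusion table")
    out: dict = {"flags": []}
    for name, num, den in (("sensitivity", t.TP, t.TP + t.FN),
                           ("specificity", t.TN, t.TN + t.FP),
                           ("accuracy", t.TP + t.TN, t.n)):
        if den == 0:
            out["flags"].append(f"{name}: zero denominator")
            continue
        lo, hi = clopper_pearson(num, den, cfg.level)
        out[name] = {"estimate": num / den, "ci": (lo, hi), "num": num, "den": den}
    return out


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann–Whitney statistic; ties count 1/2)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def bootstrap_auroc_ci(scores, labels, cfg: StatsConfig | None = None
                       ) -> tuple[float, float]:
    """Percentile bootstrap CI for AUROC over case resampling (fixed seed).

    Replicates in which a resample contains one class only are redrawn.
    """
    cfg = cfg or StatsConfig()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(cfg.bootstrap_seed)
    n = len(scores)
    vals = []
    while len(vals) < cfg.bootstrap_replicates:
        idx = rng.integers(0, n, n)
        if len(np.unique(labels[idx])) < 2:
            continue
        vals.append(roc_auc_score(labels[idx], scores[idx]))
    alpha = 1 - cfg.level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def cv_logistic_comparator(features: pd.DataFrame, labels,
                           cfg: StatsConfig | None = None) -> dict:
    """Clinical-covariate logistic comparator, scored out-of-fold.

    Models are trained on two thirds of the cohort and score the held-out
    third, stratified by outcome; every case is scored exactly once by a
    model that never saw it.  Categorical columns are one-hot encoded with
    first-level reference; numeric columns are standardized on the training
    fold.  Returns out-of-fold scores and their pooled AUROC.
    """
    cfg = cfg or StatsConfig()
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < cfg.cv_folds:
        raise ValueError("need n >= number of folds")
    cat_cols = [c for c in features.columns
                if features[c].dtype == object or str(features[c].dtype) == "category"]
    num_cols = [c for c in features.columns if c not in cat_cols]
    enc = OneHotEncoder(drop="first", handle_unknown="ignore", sparse_output=False)
    X_cat = enc.fit_transform(features[cat_cols]) if cat_cols else np.empty((n, 0))
    X_num = features[num_cols].to_numpy(dtype=float) if num_cols else np.empty((n, 0))
    X = np.hstack([X_num, X_cat])

    scores = np.full(n, np.nan)
    flags: list[str] = []
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.cv_seed)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:  # degenerate fold: score with prevalence
            flags.append(f"fold {fold}: single-class training set")
            scores[te] = float(np.mean(y[tr]))
            continue
        mu = X[tr, :len(num_cols)].mean(axis=0) if num_cols else None
        sd = X[tr, :len(num_cols)].std(axis=0) if num_cols else None
        Xtr, Xte = X[tr].copy(), X[te].copy()
        if num_cols:
            sd = np.where(sd > 0, sd, 1.0)
            Xtr[:, :len(num_cols)] = (Xtr[:, :len(num_cols)] - mu) / sd
            Xte[:, :len(num_cols)] = (Xte[:, :len(num_cols)] - mu) / sd
        model = LogisticRegression(max_iter=2000)
        model.fit(Xtr, y[tr])
        scores[te] = model.predict_proba(Xte)[:, 1]
    return {"scores": scores, "auroc": auroc(scores, y), "flags": flags,
            "encoder_categories": {c: list(cats) for c, cats in
                                   zip(cat_cols, enc.categories_)} if cat_cols else {}}


def survival_compare(times, events, groups, cfg: StatsConfig | None = None) -> dict:
    """Compare time-to-event outcomes between two prediction groups.

    Returns the log-rank statistic and p-value, Kaplan–Meier survival at the
    horizon per group, and the hazard ratio (group 1 vs 0) from a
    single-covariate Cox fit.  When a group has no events the HR is flagged
    rather than computed, matching the convention of reporting 'HR not
    computed due to lack of events'.
    """
    cfg = cfg or StatsConfig()
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups, dtype=int)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if e.sum() == 0:
        return {"flag": "no events: test undefined"}
    res = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
    out: dict = {"logrank_statistic": float(res.test_statistic),
                 "p_value": float(res.p_value), "flag": ""}
    km = {}
    for grp in (0, 1):
        f = KaplanMeierFitter()
        f.fit(t[g == grp], e[g == grp])
        km[grp] = float(f.predict(cfg.survival_horizon_years))
    out["survival_at_horizon"] = km
    if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
        out["hazard_ratio"] = None
        out["flag"] = "HR not computed due to lack of events"
    else:
        df = pd.DataFrame({"T": t, "E": e, "group": g})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        out["hazard_ratio"] = float(np.exp(cph.params_["group"]))
        ci = cph.confidence_intervals_
        out["hazard_ratio_ci"] = (float(np.exp(ci.iloc[0, 0])),
                                  float(np.exp(ci.iloc[0, 1])))
    return out


def pearson_fisher(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p from the Fisher z transformation.

    z = atanh(r) * sqrt(n - 3), referred to the standard normal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return r, float(p)


def _fmt_pct(p: float) -> str:
    return f"{100.0 * p:.1f}"


def table2_report(df: pd.DataFrame, cfg: StatsConfig | None = None,
                  subgroup_cols: tuple = ("subtype", "regimen_class"),
                  min_subgroup_n: int = 5) -> pd.DataFrame:
    """Overall + per-subgroup prediction metrics table.

    df needs boolean columns 'predicted_pcr' and 'observed_pcr' plus the
    subgroup label columns.  Returns one row per group with n, predicted-pCR
    count, and accuracy/sensitivity/specificity as raw proportions, CI
    bounds, and one-decimal percent renderings.  Small subgroups are
    retained but flagged; empty subgroups are omitted.
    """
    cfg = cfg or StatsConfig()
    for col in ("predicted_pcr", "observed_pcr"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    bad = [c for c in subgroup_cols if c not in df.columns]
    if bad:
        raise ValueError(f"unknown subgroup label column(s) {bad}")

    def row(name: str, sub: pd.DataFrame) -> dict:
        t = ConfusionTable.from_predictions(sub["predicted_pcr"], sub["observed_pcr"])
        m = confusion_metrics(t, cfg)
        r = {"group": name, "n": t.n, "n_predicted_pcr": t.TP + t.FP,
             "flag": "small-n" if t.n < min_subgroup_n else ""}
        for key in ("accuracy", "sensitivity", "specificity"):
            if key in m:
                r[key] = m[key]["estimate"]
                r[f"{key}_ci_low"], r[f"{key}_ci_high"] = m[key]["ci"]
                r[f"{key}_display"] = (f"{_fmt_pct(m[key]['estimate'])} "
                                       f"({_fmt_pct(m[key]['ci'][0])}–"
                                       f"{_fmt_pct(m[key]['ci'][1])})")
            else:
                r[key] = np.nan
                r["flag"] = (r["flag"] + "; " if r["flag"] else "") + f"{key} undefined"
        return r

    rows = [row("Overall", df)]
    for col in subgroup_cols:
        for val, sub in df.groupby(col, sort=True):
            if len(sub) == 0:
                continue
            rows.append(row(f"{col}={val}", sub))
    return pd.DataFrame(rows)
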