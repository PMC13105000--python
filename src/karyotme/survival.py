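"""Arm-level Cox survival landscape, KM stratification, and the 1q
expression-inference score.

SCNAs are categorized for survival with strict +/-0.3 thresholds (Gain /
Loss / Neutral). Per arm, two univariate Cox proportional-hazards contrasts
are fit — Gain vs Neutral (Loss samples excluded) and Loss vs Neutral (Gain
excluded) — and summarized as a signed landscape: +(-log10 p) when HR > 1
(worse survival with the event), negative when protective. P-values are
BH-adjusted across arms within each direction. Cox fits use lifelines with
Efron ties handling.

For cohorts with transcriptome but no DNA copy number, chromosome 1q gain is
inferred from expression: a panel of genes with high DNA-RNA (Spearman)
concordance is selected in a reference cohort, each panel gene's log1p
expression is z-scored across samples, the per-sample mean z is the 1q
expression score, and the top quartile of scores is classified 1q-gain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .data_io import CopyNumberProfile, ExpressionMatrix
from .errors import ConfigError, DataError, DegenerateDataError

SURVIVAL_GAIN_THRESHOLD = 0.3
SURVIVAL_LOSS_THRESHOLD = -0.3

COX_COLUMNS = [
    "term", "direction", "hazard_ratio", "ci_low", "ci_high", "p", "q",
    "n", "n_events", "signed_score", "skip_reason",
]


@dataclass
class SurvivalCategorization:
    """Samples x features table of Gain/Loss/Neutral survival categories."""

    categories: pd.DataFrame
    gain_thr: float = SURVIVAL_GAIN_THRESHOLD
    loss_thr: float = SURVIVAL_LOSS_THRESHOLD


@dataclass
class ExpressionScore1q:
    """Per-sample 1q expression score and top-quartile gain classification."""

    scores: pd.Series
    gain: pd.Series  # boolean, True = classified 1q-gain
    panel: tuple
    metadata: dict = field(default_factory=dict)


def categorize_for_survival(
    profile: CopyNumberProfile,
    gain_thr: float = SURVIVAL_GAIN_THRESHOLD,
    loss_thr: float = SURVIVAL_LOSS_THRESHOLD,
) -> SurvivalCategorization:
    """Categorize log2 CN into Gain (> gain_thr) / Loss (< loss_thr) / Neutral.

    Inequalities are strict; a value exactly at a threshold is Neutral.
    Missing values stay missing.
    """
    if not (loss_thr < 0 < gain_thr):
        raise ConfigError(
            f"thresholds must satisfy loss_thr < 0 < gain_thr; "
            f"got {gain_thr}, {loss_thr}"
        )
    vals = profile.values.to_numpy(dtype=float)
    out = np.full(vals.shape, np.nan, dtype=object)
    with np.errstate(invalid="ignore"):
        out[vals > gain_thr] = "Gain"
        out[vals < loss_thr] = "Loss"
        out[(vals <= gain_thr) & (vals >= loss_thr)] = "Neutral"
    return SurvivalCategorization(
        categories=pd.DataFrame(out, index=profile.values.index,
                                columns=profile.values.columns),
        gain_thr=gain_thr, loss_thr=loss_thr,
    )


def _fit_univariate_cox(df: pd.DataFrame, term: str):
    cph = CoxPHFitter()
    cph.fit(df, duration_col="os_time", event_col="os_event")
    s = cph.summary.loc[term]
    return (
        float(np.exp(s["coef"])),
        float(np.exp(s["coef lower 95%"])),
        float(np.exp(s["coef upper 95%"])),
        float(s["p"]),
    )


def cox_landscape(
    clinical: pd.DataFrame,
    categories: SurvivalCategorization,
    min_events: int = 10,
) -> pd.DataFrame:
    """Genome-wide SCNA-survival association landscape.

    Per arm and direction, a univariate Cox fit of the event indicator
    (samples of the opposite category excluded). Signed score is
    +(-log10 p) for HR > 1 (worse survival), negative for HR < 1. BH
    adjustment across arms within each direction. Degenerate contrasts are
    kept as rows with a skip reason.
    """
    surv = clinical[["os_time", "os_event"]].dropna()
    rows = []
    for feature in categories.categories.columns:
        cat = categories.categories[feature].reindex(surv.index)
        for direction, other in (("Gain", "Loss"), ("Loss", "Gain")):
            mask = cat.isin([direction, "Neutral"])
            sub = surv[mask.to_numpy(dtype=bool)].copy()
            sub["event_arm"] = (cat[mask] == direction).astype(float)
            row = {
                "term": feature, "direction": direction.lower(),
                "hazard_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "q": np.nan, "n": int(len(sub)),
                "n_events": int(sub["os_event"].sum()),
                "signed_score": np.nan, "skip_reason": None,
            }
            if sub["event_arm"].nunique() < 2:
                row["skip_reason"] = "no_group_variation"
            elif sub["os_event"].sum() < min_events:
                row["skip_reason"] = "too_few_events"
            else:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        hr, lo, hi, p = _fit_univariate_cox(
                            sub[["os_time", "os_event", "event_arm"]], "event_arm"
                        )
                    row.update(hazard_ratio=hr, ci_low=lo, ci_high=hi, p=p)
                except Exception:
                    row["skip_reason"] = "fit_failed"
            rows.append(row)
    results = pd.DataFrame(rows, columns=COX_COLUMNS)
    for direction in ("gain", "loss"):
        mask = results["direction"].eq(direction) & results["p"].notna()
        if mask.any():
            results.loc[mask, "q"] = multipletests(
                results.loc[mask, "p"].to_numpy(), method="fdr_bh"
            )[1]
    with np.errstate(divide="ignore"):
        magnitude = -np.log10(results["p"])
    results["signed_score"] = np.where(
        results["hazard_ratio"] > 1, magnitude, -magnitude
    )
    results.loc[results["p"].isna(), "signed_score"] = np.nan
    return results


def km_logrank(clinical: pd.DataFrame, group_labels: pd.Series):
    """Kaplan-Meier curves per group plus a two-sided log-rank test.

    Returns ``(curves, test)`` where ``curves`` is a long DataFrame of
    (group, time, survival) product-limit coordinates and ``test`` a dict
    with the log-rank statistic, degrees of freedom, and p-value.
    """
    surv = clinical[["os_time", "os_event"]].dropna()
    labels = group_labels.reindex(surv.index).dropna()
    surv = surv.loc[labels.index]
    groups = labels.unique()
    if len(groups) < 2:
        raise DegenerateDataError("log-rank test requires at least 2 groups")
    for g in groups:
        if surv.loc[labels == g, "os_event"].sum() < 1:
            raise DegenerateDataError(f"group {g!r} has no events")
    curves = []
    for g in sorted(groups, key=str):
        sub = surv[labels == g]
        km = KaplanMeierFitter()
        km.fit(sub["os_time"], sub["os_event"], label=str(g))
        sf = km.survival_function_
        curves.append(pd.DataFrame({
            "group": str(g),
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        }))
    test = multivariate_logrank_test(
        surv["os_time"], labels.astype(str), surv["os_event"]
    )
    return (
        pd.concat(curves, ignore_index=True),
        {"statistic": float(test.test_statistic),
         "df": int(test.degrees_of_freedom),
         "p": float(test.p_value)},
    )


def select_1q_panel(
    cn_gene: CopyNumberProfile,
    expr: ExpressionMatrix,
    arm: str = "1q",
    k: int = 50,
    gene_arms: pd.Series | None = None,
) -> list[str]:
    """Select the expression-inference panel: top-k genes by DNA-RNA
    concordance.

    Candidates are the genes shared between the copy-number and expression
    inputs (restricted to ``arm`` when a gene->arm mapping is supplied).
    Concordance is Spearman rho between per-sample copy number and
    expression; the top ``k`` genes are returned with exact ties broken
    lexicographically by gene symbol. Fewer than ``k`` eligible genes is an
    error.
    """
    candidates = [g for g in cn_gene.feature_ids if g in expr.values.columns]
    if gene_arms is not None:
        candidates = [g for g in candidates if gene_arms.get(g) == arm]
    shared = [s for s in cn_gene.values.index if s in expr.values.index]
    if len(shared) < 3:
        raise DataError("panel selection needs >= 3 shared samples")
    concordance = {}
    for gene in candidates:
        x = cn_gene.values.loc[shared, gene].to_numpy(dtype=float)
        y = expr.values.loc[shared, gene].to_numpy(dtype=float)
        mask = ~(np.isnan(x) | np.isnan(y))
        if mask.sum() < 3 or np.all(x[mask] == x[mask][0]) or np.all(y[mask] == y[mask][0]):
            continue
        concordance[gene] = float(scipy.stats.spearmanr(x[mask], y[mask])[0])
    if len(concordance) < k:
        raise DataError(
            f"only {len(concordance)} eligible {arm} genes with a defined "
            f"concordance; need {k}"
        )
    ranked = sorted(concordance.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:k]]


def score_1q_from_expression(
    expr: ExpressionMatrix,
    panel,
    min_panel_fraction: float = 0.8,
) -> ExpressionScore1q:
    """Per-sample 1q expression score and top-quartile gain classification.

    Each panel gene's log1p expression is z-scored across samples; the score
    is the mean z over the panel (absent panel genes — up to 20% — contribute
    a zero z; constant genes are dropped with a warning). The top
    ``ceil(n/4)`` samples by score are classified 1q-gain.
    """
    panel = list(panel)
    n = len(expr.sample_ids)
    if n < 4:
        raise DataError("1q scoring requires at least 4 samples")
    present = [g for g in panel if g in expr.values.columns]
    if len(present) < min_panel_fraction * len(panel):
        raise DataError(
            f"only {len(present)}/{len(panel)} panel genes present; "
            f"need >= {min_panel_fraction:.0%}"
        )
    logx = np.log1p(expr.values[present].to_numpy(dtype=float))
    sd = logx.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        dropped = [g for g, c in zip(present, constant) if c]
        warnings.warn(
            f"dropping {len(dropped)} constant panel gene(s): {dropped[:5]}",
            stacklevel=2,
        )
    z = np.zeros_like(logx)
    keep = ~constant
    z[:, keep] = (logx[:, keep] - logx[:, keep].mean(axis=0)) / sd[keep]
    # absent genes contribute 0 z-scores; denominator is the full panel size
    scores = pd.Series(
        z.sum(axis=1) / len(panel), index=expr.values.index, name="score_1q"
    )
    n_gain = math.ceil(n / 4)
    cutoff_order = scores.rank(method="first", ascending=False)
    gain = cutoff_order <= n_gain
    gain.name = "gain_1q"
    return ExpressionScore1q(
        scores=scores, gain=gain, panel=tuple(panel),
        metadata={"n_gain": n_gain, "quartile_rule": "top ceil(n/4) by score",
                  "missing_panel_genes": [g for g in panel if g not in present]},
    )


MULTIVARIATE_COVARIATES = ("gain_1q", "cd8_high", "b_high", "tmb_high",
                           "pdl1_positive")


def build_multivariate_frame(
    clinical: pd.DataFrame,
    score1q: ExpressionScore1q | None = None,
    tmb_cutoff: float = 10.0,
    infiltration_quantile: float = 0.5,
) -> pd.DataFrame:
    """Binary-code the multivariate Cox covariates.

    ``gain_1q`` from the expression score (or an existing clinical column);
    CD8/B-cell high = above the cohort quantile (median by default); TMB high
    = >= 10 mut/Mb (inclusive, unlike the strict SCNA thresholds); PD-L1
    positivity as recorded.
    """
    df = clinical.copy()
    if score1q is not None:
        df["gain_1q"] = score1q.gain.reindex(df.index).astype(float)
    elif "gain_1q" not in df.columns:
        raise DataError("no 1q gain status: pass score1q or a gain_1q column")
    if "cd8_fraction" in df.columns:
        df["cd8_high"] = (
            df["cd8_fraction"] > df["cd8_fraction"].quantile(infiltration_quantile)
        ).where(df["cd8_fraction"].notna()).astype(float)
    if "b_fraction" in df.columns:
        df["b_high"] = (
            df["b_fraction"] > df["b_fraction"].quantile(infiltration_quantile)
        ).where(df["b_fraction"].notna()).astype(float)
    if "tmb" in df.columns:
        df["tmb_high"] = (df["tmb"] >= tmb_cutoff).where(df["tmb"].notna()).astype(float)
    if "pdl1_positive" in df.columns:
        df["pdl1_positive"] = df["pdl1_positive"].astype(float)
    return df


def multivariate_cox(
    clinical: pd.DataFrame,
    covariates=MULTIVARIATE_COVARIATES,
) -> pd.DataFrame:
    """Joint Cox model over binary-coded covariates (forest-table output).

    Complete cases only (the count is reported per term as ``n``). Constant
    or duplicated covariate columns are rejected by name. Output rows follow
    the order of ``covariates``.
    """
    covariates = [c for c in covariates]
    missing = [c for c in covariates if c not in clinical.columns]
    if missing:
        raise DataError(f"missing covariate column(s): {missing}")
    cols = ["os_time", "os_event"] + covariates
    df = clinical[cols].dropna().copy()
    df["os_event"] = df["os_event"].astype(float)
    if len(df) < 10:
        raise DegenerateDataError(f"only {len(df)} complete cases")
    for c in covariates:
        if df[c].nunique() < 2:
            raise DataError(f"covariate {c!r} is constant in complete cases")
    for i, a in enumerate(covariates):
        for b in covariates[i + 1:]:
            if df[a].equals(df[b]):
                raise DataError(f"covariates {a!r} and {b!r} are identical")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="os_time", event_col="os_event")
    rows = []
    for term in covariates:
        s = cph.summary.loc[term]
        rows.append({
            "term": term,
            "hazard_ratio": float(np.exp(s["coef"])),
            "ci_low": float(np.exp(s["coef lower 95%"])),
            "ci_high": float(np.exp(s["coef upper 95%"])),
            "p": float(s["p"]),
            "n": int(len(df)),
            "n_events": int(df["os_event"].sum()),
        })
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out[["term", "hazard_ratio", "ci_low", "ci_high", "p", "q",
                "n", "n_events"]]
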