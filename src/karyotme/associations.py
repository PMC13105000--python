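"""Direction-stratified association models between SCNAs and immune phenotypes.

For every feature (arm, cytoband, or gene) four logistic models are fit per
cohort: {gain, loss} x {cold, hot}. The outcome is the indicator of the
phenotype class; the predictors are the feature's continuous log2 copy number
plus the sample aneuploidy score (AS) to absorb global chromosomal-instability
burden. Direction stratification removes confounding between gains and
losses: samples called *loss* at a feature are excluded from that feature's
gain model and vice versa (the discrete call is used only for exclusion, the
predictor stays continuous). Cell-type abundances get the same treatment with
linear models. P-values are Benjamini-Hochberg adjusted within (tumor type,
level, direction, phenotype) groups.

Results are DataFrames with the :data:`ASSOCIATION_COLUMNS` schema; features
that cannot be fit are kept as rows with a ``skip_reason`` code and missing
statistics, so nothing disappears silently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .data_io import CopyNumberProfile
from .errors import ConfigError, DataError
from .immune_scoring import CellTypeScoreTable, ImmuneScoreTable
from .scna_calls import AneuploidyScoreTable, SCNACallTable

ASSOCIATION_COLUMNS = [
    "tumor_type", "level", "feature_id", "direction", "phenotype",
    "effect", "p", "q", "n_used", "signed_score", "skip_reason",
]

DEFAULT_GROUP_KEYS = ("tumor_type", "level", "direction", "phenotype")

#: Skip-reason codes emitted by the model fitters.
SKIP_TOO_FEW = "too_few_samples"
SKIP_NO_OUTCOME_VARIATION = "no_outcome_variation"
SKIP_CONSTANT_PREDICTOR = "constant_predictor"
SKIP_FIT_FAILED = "fit_failed"


def _opposite(direction: str) -> str:
    if direction == "gain":
        return "loss"
    if direction == "loss":
        return "gain"
    raise ConfigError(f"direction must be 'gain' or 'loss', got {direction!r}")


def _result_row(tumor_type, level, feature, direction, phenotype,
                effect=np.nan, p=np.nan, n_used=0, skip_reason=None):
    return {
        "tumor_type": tumor_type, "level": level, "feature_id": feature,
        "direction": direction, "phenotype": phenotype, "effect": effect,
        "p": p, "q": np.nan, "n_used": int(n_used), "signed_score": np.nan,
        "skip_reason": skip_reason,
    }


def fit_is_logistic(
    profile: CopyNumberProfile,
    calls: SCNACallTable,
    is_table: ImmuneScoreTable,
    as_table: AneuploidyScoreTable,
    direction: str,
    phenotype: str,
    tumor_type: str = "cohort",
    min_samples: int = 20,
    drop_intermediate: bool = False,
    return_diagnostics: bool = False,
) -> pd.DataFrame:
    """Per-feature logistic regression of a binarized immune class on log2 CN.

    Outcome: indicator(is_class == phenotype) against all other samples
    (intermediates count as 0 unless ``drop_intermediate``). Predictors:
    the feature's continuous log2 CN and the AS. Samples whose call at a
    feature is the opposite direction are excluded from that feature's model.

    With ``return_diagnostics`` the per-feature list of used sample ids is
    also returned, so exclusion can be audited.
    """
    if phenotype not in ("cold", "hot"):
        raise ConfigError(f"phenotype must be 'cold' or 'hot', got {phenotype!r}")
    opposite = _opposite(direction)
    samples = profile.values.index
    cls = is_table.is_class.reindex(samples)
    as_scores = as_table.scores.reindex(samples)
    rows, diagnostics = [], {}
    for feature in profile.values.columns:
        cn = profile.values[feature]
        call = calls.calls[feature].reindex(samples)
        mask = (call != opposite) & cn.notna() & as_scores.notna() & cls.notna()
        if drop_intermediate:
            mask &= cls.isin(["cold", "hot"])
        used = samples[mask.to_numpy(dtype=bool)]
        diagnostics[feature] = list(used)
        y = (cls.loc[used] == phenotype).astype(float)
        row = _result_row(tumor_type, profile.level, feature, direction,
                          phenotype, n_used=len(used))
        if len(used) < min_samples:
            row["skip_reason"] = SKIP_TOO_FEW
        elif y.nunique() < 2:
            row["skip_reason"] = SKIP_NO_OUTCOME_VARIATION
        elif cn.loc[used].nunique() < 2:
            row["skip_reason"] = SKIP_CONSTANT_PREDICTOR
        else:
            X = sm.add_constant(
                pd.DataFrame({"cn": cn.loc[used], "AS": as_scores.loc[used]})
            )
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if not fit.mle_retvals.get("converged", True):
                    raise RuntimeError("no convergence")
                row["effect"] = float(fit.params["cn"])
                row["p"] = float(fit.pvalues["cn"])
            except Exception:
                row["skip_reason"] = SKIP_FIT_FAILED
        rows.append(row)
    results = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    if return_diagnostics:
        return results, diagnostics
    return results


def _normal_scores(values: pd.Series) -> pd.Series:
    """Rank-based inverse-normal (Blom-style) transform."""
    ranks = values.rank(method="average")
    return pd.Series(
        scipy.stats.norm.ppf((ranks - 0.5) / len(values)),
        index=values.index,
    )


def fit_celltype_linear(
    profile: CopyNumberProfile,
    calls: SCNACallTable,
    celltypes: CellTypeScoreTable,
    as_table: AneuploidyScoreTable,
    direction: str,
    tumor_type: str = "cohort",
    min_samples: int = 20,
    rank_transform: bool = True,
    return_diagnostics: bool = False,
) -> pd.DataFrame:
    """Per-(feature, cell type) linear regression of abundance on log2 CN.

    Cell-type enrichment scores are rank-transformed to normal scores by
    default (xCell scores are heavily skewed); ``rank_transform=False`` keeps
    the raw scale. Exclusion and covariates mirror :func:`fit_is_logistic`.
    A negative effect means lower abundance with higher copy number.
    """
    opposite = _opposite(direction)
    samples = profile.values.index
    as_scores = as_table.scores.reindex(samples)
    rows, diagnostics = [], {}
    for feature in profile.values.columns:
        cn = profile.values[feature]
        call = calls.calls[feature].reindex(samples)
        base_mask = (call != opposite) & cn.notna() & as_scores.notna()
        for cell_type in celltypes.scores.columns:
            score = celltypes.scores[cell_type].reindex(samples)
            mask = base_mask & score.notna()
            used = samples[mask.to_numpy(dtype=bool)]
            diagnostics[(feature, cell_type)] = list(used)
            row = _result_row(tumor_type, profile.level, feature, direction,
                              cell_type, n_used=len(used))
            if len(used) < min_samples:
                row["skip_reason"] = SKIP_TOO_FEW
            elif score.loc[used].nunique() < 2:
                row["skip_reason"] = SKIP_NO_OUTCOME_VARIATION
            elif cn.loc[used].nunique() < 2:
                row["skip_reason"] = SKIP_CONSTANT_PREDICTOR
            else:
                y = score.loc[used]
                if rank_transform:
                    y = _normal_scores(y)
                X = sm.add_constant(
                    pd.DataFrame({"cn": cn.loc[used], "AS": as_scores.loc[used]})
                )
                try:
                    fit = sm.OLS(y, X).fit()
                    row["effect"] = float(fit.params["cn"])
                    row["p"] = float(fit.pvalues["cn"])
                except Exception:
                    row["skip_reason"] = SKIP_FIT_FAILED
            rows.append(row)
    results = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    if return_diagnostics:
        return results, diagnostics
    return results


def bh_adjust(
    results: pd.DataFrame, group_keys=DEFAULT_GROUP_KEYS
) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment within each group.

    Rows with missing p (skipped fits) keep a missing q. Also fills the
    ``signed_score`` column: sign * (-log10 q), positive for hot / higher
    abundance, negative for cold / lower abundance.
    """
    out = results.copy()
    valid = out["p"].notna()
    pvals = out.loc[valid, "p"]
    if ((pvals < 0) | (pvals > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    group_keys = [k for k in group_keys if k in out.columns]
    out["q"] = np.nan
    if valid.any():
        for _, idx in out.loc[valid].groupby(group_keys, dropna=False).groups.items():
            out.loc[idx, "q"] = multipletests(
                out.loc[idx, "p"].to_numpy(), method="fdr_bh"
            )[1]
    sign = np.where(
        out["phenotype"].eq("hot"), 1.0,
        np.where(out["phenotype"].eq("cold"), -1.0, np.sign(out["effect"])),
    )
    with np.errstate(divide="ignore"):
        out["signed_score"] = sign * (-np.log10(out["q"]))
    return out


def build_signed_landscape(
    results_cold: pd.DataFrame, results_hot: pd.DataFrame
) -> pd.DataFrame:
    """Collapse cold and hot models into one signed score per (feature, direction).

    For each (feature, direction) the smaller adjusted p of the two phenotype
    models wins: positive -log10(q) when hot wins, negative when cold wins;
    exact ties break toward cold. A missing counterpart model leaves the
    available one in charge.
    """
    def prep(df, tag):
        sub = df[df["q"].notna()][["feature_id", "direction", "q"]].copy()
        return sub.rename(columns={"q": f"q_{tag}"})

    merged = prep(results_cold, "cold").merge(
        prep(results_hot, "hot"), on=["feature_id", "direction"], how="outer"
    )
    qc = merged["q_cold"].to_numpy(dtype=float)
    qh = merged["q_hot"].to_numpy(dtype=float)
    # cold wins ties and wins when hot is missing
    hot_wins = np.where(np.isnan(qc), True, np.where(np.isnan(qh), False, qh < qc))
    q_min = np.where(hot_wins, qh, qc)
    with np.errstate(divide="ignore"):
        magnitude = -np.log10(q_min)
    merged["winner"] = np.where(hot_wins, "hot", "cold")
    merged["q"] = q_min
    merged["signed_score"] = np.where(hot_wins, magnitude, -magnitude)
    # -0.0 when both q == 1
    merged.loc[merged["q"] == 1.0, "signed_score"] = 0.0
    return merged[["feature_id", "direction", "winner", "q", "signed_score"]]


def filter_celltype_associations(
    gain_results: pd.DataFrame,
    loss_results: pd.DataFrame,
    p_max: float = 0.2,
) -> pd.DataFrame:
    """Keep cell-type associations that are nominally supported and
    directionally consistent.

    Drops any association with p > ``p_max``. Then drops gain/loss pairs
    whose effects share a sign (a gain lowering and a loss also lowering the
    same cell type is biologically incoherent — consistent pairs have
    opposite-signed effects). An association without a fitted counterpart
    cannot be checked and is retained on the p criterion alone.
    """
    keys = ["tumor_type", "level", "feature_id", "phenotype"]
    both = pd.concat([gain_results, loss_results], ignore_index=True)
    both = both[both["p"].notna() & (both["p"] <= p_max)]
    eff = pd.concat([gain_results, loss_results], ignore_index=True).pivot_table(
        index=keys, columns="direction", values="effect", aggfunc="first"
    )
    if {"gain", "loss"}.issubset(eff.columns):
        inconsistent = eff[
            (np.sign(eff["gain"]) == np.sign(eff["loss"]))
            & (eff["gain"] != 0) & (eff["loss"] != 0)
        ].index
        idx = pd.MultiIndex.from_frame(both[keys])
        both = both[~idx.isin(inconsistent)]
    return both.reset_index(drop=True)


def count_significant_by_celltype(
    results: pd.DataFrame, q_thr: float = 0.05
) -> pd.DataFrame:
    """Tally significant cell-type associations by (cell type, direction,
    low/high abundance).

    ``abundance`` is "low" for negative effects (higher copy number, less of
    the cell type) and "high" for positive ones.
    """
    sig = results[results["q"].notna() & (results["q"] < q_thr)].copy()
    if sig.empty:
        return pd.DataFrame(columns=["phenotype", "direction", "abundance", "count"])
    sig["abundance"] = np.where(sig["effect"] < 0, "low", "high")
    counts = (
        sig.groupby(["phenotype", "direction", "abundance"])
        .size().rename("count").reset_index()
    )
    return counts


def compare_proportions_by_scna(
    proportions: pd.DataFrame,
    scna_status: pd.Series,
    feature_id: str = "feature",
) -> pd.DataFrame:
    """Welch t-tests of per-patient cell-type fractions by SCNA status.

    ``proportions`` is patients x cell types; ``scna_status`` a boolean
    series (True = altered) over the same patients. Each group needs at
    least 2 patients. Positive t means higher mean fraction in the altered
    group.
    """
    status = scna_status.reindex(proportions.index)
    if status.isna().any():
        raise DataError("scna_status missing for some patients")
    altered = proportions[status.astype(bool)]
    unaltered = proportions[~status.astype(bool)]
    if len(altered) < 2 or len(unaltered) < 2:
        raise DataError(
            f"each SCNA status group needs >= 2 patients "
            f"(altered={len(altered)}, unaltered={len(unaltered)})"
        )
    rows = []
    for cell_type in proportions.columns:
        a = altered[cell_type].dropna().to_numpy()
        b = unaltered[cell_type].dropna().to_numpy()
        if np.var(a) == 0 and np.var(b) == 0:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t, p = np.sign(a.mean() - b.mean()) * np.inf, 0.0
        else:
            t, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "feature_id": feature_id, "cell_type": cell_type,
            "mean_altered": a.mean(), "mean_unaltered": b.mean(),
            "t": float(t), "p": float(p),
            "n_altered": len(a), "n_unaltered": len(b),
        })
    return pd.DataFrame(rows)
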