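"""TUSON-Immune: gene-level prediction of immune Oncogenes (iOG) and Tumor
immune Suppressor Genes (TiSG).

Each gene is scored by three correlation parameters (Spearman by default,
matching the rank-based immune score): DNA:IS (copy number vs immune score),
RNA:IS (expression vs immune score), and DNA:RNA (copy number vs expression,
the dosage-sensitivity check). P-values are BH-adjusted per parameter within
a tumor type. Calls then follow fixed sign/threshold rules:

* iOG — gene in an amplified region with all three rho > 0 and all three
  adjusted p < 0.05;
* TiSG — gene in a deleted region with DNA:RNA rho > 0, DNA:IS and RNA:IS
  rho < 0, all three adjusted p < 0.05.

The TiSG sign convention is implemented as stated; ``flip_is_sign`` flips
the required sign of the two IS correlations for users who prefer the
opposite biological reading (a deleted immune suppressor tracking positively
with immunity). Region eligibility ("amplified"/"deleted") is frequency
based: a gene qualifies when it is gain-/loss-called in at least 10% of
cohort samples (the more frequent direction wins when both qualify).

A Random Forest classifier over user-supplied per-gene features, trained on
a curated gold-standard gene list, complements the rule-based TiSG calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict, train_test_split
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .data_io import CopyNumberProfile, ExpressionMatrix
from .errors import ConfigError, DataError
from .immune_scoring import ImmuneScoreTable
from .scna_calls import SCNACallTable, call_scna

GENE_STATS_COLUMNS = [
    "tumor_type", "gene_id", "region_class",
    "rho_dna_is", "rho_rna_is", "rho_dna_rna",
    "p_dna_is", "p_rna_is", "p_dna_rna",
    "q_dna_is", "q_rna_is", "q_dna_rna",
    "call",
]

PARAMETERS = ("dna_is", "rna_is", "dna_rna")


def classify_gene_regions(
    calls: SCNACallTable, freq_threshold: float = 0.1
) -> pd.Series:
    """Assign each gene to amplified / deleted / neither by call frequency.

    A gene is *amplified* when gain-called in >= ``freq_threshold`` of
    non-missing samples, *deleted* when loss-called at that frequency; if
    both qualify the more frequent direction wins (ties break to amplified).
    """
    df = calls.calls
    n = df.notna().sum(axis=0)
    gain_freq = df.eq("gain").sum(axis=0) / n.replace(0, np.nan)
    loss_freq = df.eq("loss").sum(axis=0) / n.replace(0, np.nan)
    out = pd.Series("neither", index=df.columns, dtype=object)
    amp = gain_freq >= freq_threshold
    dele = loss_freq >= freq_threshold
    out[amp & ~dele] = "amplified"
    out[dele & ~amp] = "deleted"
    both = amp & dele
    out[both & (gain_freq >= loss_freq)] = "amplified"
    out[both & (gain_freq < loss_freq)] = "deleted"
    return out


def _safe_corr(x, y, method):
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    if method == "spearman":
        rho, p = scipy.stats.spearmanr(x, y)
    else:
        rho, p = scipy.stats.pearsonr(x, y)
    return float(rho), float(p)


def gene_immune_correlations(
    cn_gene: CopyNumberProfile,
    expr: ExpressionMatrix,
    is_table: ImmuneScoreTable,
    calls: SCNACallTable | None = None,
    tumor_type: str = "cohort",
    method: str = "spearman",
    region_freq_threshold: float = 0.1,
) -> pd.DataFrame:
    """Compute the three TUSON-Immune correlation parameters per gene.

    Samples are intersected across the three inputs (at least 10 required);
    the IS enters as its rank value. BH adjustment is applied per parameter.
    Genes with a constant vector get missing rho for that parameter. When
    ``calls`` is omitted region eligibility is derived from ``cn_gene`` with
    default thresholds.
    """
    if method not in ("spearman", "pearson"):
        raise ConfigError(f"method must be 'spearman' or 'pearson', got {method!r}")
    shared = [
        s for s in cn_gene.values.index
        if s in expr.values.index and s in is_table.table.index
    ]
    if len(shared) < 10:
        raise DataError(
            f"only {len(shared)} shared samples across CN/expression/IS; need >= 10"
        )
    genes = [g for g in cn_gene.feature_ids if g in expr.values.columns]
    if not genes:
        raise DataError("no genes shared between copy-number and expression inputs")
    if calls is None:
        calls = call_scna(cn_gene)
    region = classify_gene_regions(calls, freq_threshold=region_freq_threshold)
    is_rank = is_table.is_rank.loc[shared].to_numpy(dtype=float)
    rows = []
    for gene in genes:
        dna = cn_gene.values.loc[shared, gene].to_numpy(dtype=float)
        rna = expr.values.loc[shared, gene].to_numpy(dtype=float)
        rho_di, p_di = _safe_corr(dna, is_rank, method)
        rho_ri, p_ri = _safe_corr(rna, is_rank, method)
        rho_dr, p_dr = _safe_corr(dna, rna, method)
        rows.append({
            "tumor_type": tumor_type, "gene_id": gene,
            "region_class": region.get(gene, "neither"),
            "rho_dna_is": rho_di, "rho_rna_is": rho_ri, "rho_dna_rna": rho_dr,
            "p_dna_is": p_di, "p_rna_is": p_ri, "p_dna_rna": p_dr,
            "q_dna_is": np.nan, "q_rna_is": np.nan, "q_dna_rna": np.nan,
            "call": "none",
        })
    stats = pd.DataFrame(rows, columns=GENE_STATS_COLUMNS)
    for param in PARAMETERS:
        valid = stats[f"p_{param}"].notna()
        if valid.any():
            stats.loc[valid, f"q_{param}"] = multipletests(
                stats.loc[valid, f"p_{param}"].to_numpy(), method="fdr_bh"
            )[1]
    return stats


def call_iog_tisg(
    stats: pd.DataFrame, q_thr: float = 0.05, flip_is_sign: bool = False
) -> pd.DataFrame:
    """Apply the iOG/TiSG sign-and-threshold rules to per-gene statistics.

    All comparisons are strict (q < ``q_thr``); any missing parameter
    disqualifies a gene. See the module docstring for the rules.
    """
    out = stats.copy()
    q_ok = (
        (out["q_dna_is"] < q_thr)
        & (out["q_rna_is"] < q_thr)
        & (out["q_dna_rna"] < q_thr)
    ).fillna(False)
    is_sign = -1.0 if flip_is_sign else 1.0
    iog = (
        out["region_class"].eq("amplified") & q_ok
        & (out["rho_dna_rna"] > 0)
        & (is_sign * out["rho_dna_is"] > 0)
        & (is_sign * out["rho_rna_is"] > 0)
    )
    tisg = (
        out["region_class"].eq("deleted") & q_ok
        & (out["rho_dna_rna"] > 0)
        & (is_sign * out["rho_dna_is"] < 0)
        & (is_sign * out["rho_rna_is"] < 0)
    )
    out["call"] = np.where(iog, "iOG", np.where(tisg, "TiSG", "none"))
    return out


def lasso_select_parameters(
    candidate_features: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    cv: int = 5,
) -> list[str]:
    """L1-penalized logistic feature selection for the gene-calling parameters.

    Features are standardized; the penalty strength is chosen by seeded
    cross-validation. Returns the features with nonzero coefficients,
    ordered by decreasing |coefficient|. With perfectly collinear
    informative features the L1 path keeps at least one of each group but
    may drop duplicates arbitrarily.
    """
    if candidate_features.shape[1] < 2:
        raise DataError("need at least 2 candidate features")
    y = labels.reindex(candidate_features.index).astype(int)
    if y.nunique() < 2:
        raise DataError("labels must contain both classes")
    X = StandardScaler().fit_transform(candidate_features.to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = LogisticRegressionCV(
            penalty="l1", solver="liblinear", Cs=10, scoring="neg_log_loss",
            cv=StratifiedKFold(cv, shuffle=True, random_state=seed),
            random_state=seed, max_iter=2000,
        ).fit(X, y.to_numpy())
    # one-standard-error rule: strongest penalty whose CV log-loss is within
    # one SE of the best, the glmnet convention for sparse selection
    scores = list(model.scores_.values())[0]  # folds x Cs
    mean, se = scores.mean(axis=0), scores.std(axis=0, ddof=1) / np.sqrt(cv)
    best = int(np.argmax(mean))
    threshold = mean[best] - se[best]
    chosen = next(i for i in range(len(model.Cs_)) if mean[i] >= threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        refit = LogisticRegression(
            penalty="l1", solver="liblinear", C=model.Cs_[chosen],
            random_state=seed, max_iter=2000,
        ).fit(X, y.to_numpy())
    coefs = pd.Series(refit.coef_[0], index=candidate_features.columns)
    selected = coefs[coefs != 0].abs().sort_values(ascending=False)
    return list(selected.index)


@dataclass
class TisgClassifier:
    """Fitted Random-Forest TiSG scorer with its validation metrics."""

    model: RandomForestClassifier
    cv_auroc: float
    test_auroc: float
    feature_names: list
    metadata: dict

    def predict_scores(self, features: pd.DataFrame) -> pd.Series:
        X = features[self.feature_names].to_numpy(dtype=float)
        return pd.Series(
            self.model.predict_proba(X)[:, 1], index=features.index, name="tisg_score"
        )


def train_tisg_classifier(
    features: pd.DataFrame,
    gold_standard,
    negative_ratio: float = 5.0,
    test_fraction: float = 0.25,
    n_estimators: int = 300,
    cv: int = 5,
    seed: int = 0,
) -> TisgClassifier:
    """Train the Random-Forest TiSG classifier against a gold-standard list.

    Positives are the gold-standard genes present in ``features``; negatives
    are sampled from the remaining genes at ``negative_ratio`` : 1 (seeded).
    Reports a stratified cross-validated AUROC on the training split and a
    held-out test AUROC. At least 10 positives are required.
    """
    gold = [g for g in gold_standard if g in features.index]
    if len(gold) < 10:
        raise DataError(
            f"only {len(gold)} gold-standard genes found in the feature table; "
            "need >= 10 to validate"
        )
    rng = np.random.default_rng(seed)
    background = features.index.difference(gold)
    n_neg = min(len(background), int(round(negative_ratio * len(gold))))
    negatives = list(rng.choice(np.asarray(background, dtype=object), size=n_neg,
                                replace=False))
    idx = gold + negatives
    X = features.loc[idx].to_numpy(dtype=float)
    y = np.array([1] * len(gold) + [0] * len(negatives))
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    folds = StratifiedKFold(cv, shuffle=True, random_state=seed)
    cv_scores = cross_val_predict(
        model, X_train, y_train, cv=folds, method="predict_proba"
    )[:, 1]
    cv_auroc = float(roc_auc_score(y_train, cv_scores))
    model.fit(X_train, y_train)
    test_auroc = float(roc_auc_score(y_test, model.predict_proba(X_test)[:, 1]))
    return TisgClassifier(
        model=model, cv_auroc=cv_auroc, test_auroc=test_auroc,
        feature_names=list(features.columns),
        metadata={
            "seed": seed, "n_positives": len(gold), "n_negatives": len(negatives),
            "negative_ratio": negative_ratio, "test_fraction": test_fraction,
            "cv_folds": cv, "n_estimators": n_estimators,
        },
    )


def recurrence_summary(
    calls_by_tumor_type: dict,
    gene_arms: pd.Series,
    min_types: int = 3,
) -> dict:
    """Cross-tumor-type recurrence of iOG/TiSG calls.

    ``calls_by_tumor_type`` maps tumor type -> called stats table (output of
    :func:`call_iog_tisg`). Returns per-gene counts of each call across
    tumor types and per-arm tallies restricted to genes called in at least
    ``min_types`` tumor types; genes without an arm assignment are tallied
    under "unassigned" with a warning.
    """
    records = []
    for tumor_type, table in calls_by_tumor_type.items():
        called = table[table["call"].isin(["iOG", "TiSG"])]
        for _, row in called.iterrows():
            records.append((row["gene_id"], row["call"], tumor_type))
    per_gene = (
        pd.DataFrame(records, columns=["gene_id", "call", "tumor_type"])
        .groupby(["gene_id", "call"])["tumor_type"].nunique()
        .rename("n_tumor_types").reset_index()
        if records else
        pd.DataFrame(columns=["gene_id", "call", "n_tumor_types"])
    )
    recurrent = per_gene[per_gene["n_tumor_types"] >= min_types].copy()
    arms = recurrent["gene_id"].map(gene_arms)
    if arms.isna().any():
        missing = sorted(recurrent.loc[arms.isna(), "gene_id"].unique())
        warnings.warn(
            f"{len(missing)} recurrent gene(s) lack an arm assignment: "
            f"{missing[:5]}", stacklevel=2,
        )
    recurrent["arm"] = arms.fillna("unassigned")
    per_arm = (
        recurrent.groupby(["arm", "call"]).size().rename("count").reset_index()
        if len(recurrent) else
        pd.DataFrame(columns=["arm", "call", "count"])
    )
    return {"per_gene": per_gene, "per_arm": per_arm, "min_types": min_types}
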