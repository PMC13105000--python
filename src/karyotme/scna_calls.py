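"""Purity/ploidy adjustment, discrete gain/loss calling, aneuploidy score.

A segment (or arm/cytoband/gene feature) is a gain when log2(CN) > 0.2 and a
loss when log2(CN) < -0.2, with strict inequalities; values exactly at a
threshold are neutral. The aneuploidy score (AS) of a sample is the sum of
|log2(CN)| over all non-missing features at the analysis level — a global
chromosomal-instability burden used as a covariate downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CopyNumberProfile
from .errors import ConfigError, DataError

GAIN_THRESHOLD = 0.2
LOSS_THRESHOLD = -0.2

#: Floor applied to the corrected tumor copy number before taking log2.
CN_EPSILON = 0.01


@dataclass
class SCNACallTable:
    """Discrete gain/neutral/loss calls on the same axes as a profile.

    ``calls`` holds strings {"gain", "neutral", "loss"} with NaN for missing.
    """

    level: str
    calls: pd.DataFrame
    gain_thr: float = GAIN_THRESHOLD
    loss_thr: float = LOSS_THRESHOLD
    metadata: dict = field(default_factory=dict)


@dataclass
class AneuploidyScoreTable:
    """Per-sample aneuploidy score at one resolution level."""

    level: str
    scores: pd.Series  # sample_id -> AS (NaN when all features missing)


def adjust_for_purity_ploidy(
    profile: CopyNumberProfile,
    clinical: pd.DataFrame,
    on_missing: str = "skip",
) -> CopyNumberProfile:
    """Correct a bulk log2 copy-number profile for tumor purity and ploidy.

    The observed bulk measurement is modelled as a mixture of tumor at purity
    ``alpha`` and diploid normal: ``CN_obs = 2 * 2**log2_raw``. The tumor
    component is ``CN_t = (CN_obs - 2 * (1 - alpha)) / alpha``, floored at a
    small positive epsilon, and re-expressed relative to tumor ploidy as
    ``log2(CN_t / ploidy)``. At purity 1 and ploidy 2 this is the identity.

    Samples without purity/ploidy are skipped with a warning (``on_missing=
    "skip"``) or rejected (``on_missing="error"``); skipped samples keep their
    raw values and are listed in the result metadata.
    """
    if on_missing not in ("skip", "error"):
        raise ConfigError("on_missing must be 'skip' or 'error'")
    values = profile.values.copy()
    skipped = []
    for sample in values.index:
        if sample in clinical.index:
            purity = clinical.loc[sample].get("purity", np.nan)
            ploidy = clinical.loc[sample].get("ploidy", np.nan)
        else:
            purity = ploidy = np.nan
        if pd.isna(purity) or pd.isna(ploidy):
            if on_missing == "error":
                raise DataError(f"sample {sample!r} lacks purity/ploidy estimates")
            skipped.append(sample)
            continue
        if not (0 < purity <= 1):
            raise DataError(f"sample {sample!r}: purity {purity} outside (0, 1]")
        if ploidy <= 0:
            raise DataError(f"sample {sample!r}: ploidy {ploidy} must be positive")
        raw = values.loc[sample].to_numpy(dtype=float)
        cn_obs = 2.0 * np.power(2.0, raw)
        cn_t = (cn_obs - 2.0 * (1.0 - purity)) / purity
        cn_t = np.maximum(cn_t, CN_EPSILON)
        values.loc[sample] = np.log2(cn_t / ploidy)
    if skipped:
        warnings.warn(
            f"{len(skipped)} sample(s) lack purity/ploidy and were not adjusted: "
            f"{skipped[:5]}", stacklevel=2,
        )
    meta = dict(profile.metadata)
    meta["purity_ploidy_adjusted"] = True
    meta["adjustment_skipped"] = skipped
    return CopyNumberProfile(level=profile.level, values=values, metadata=meta)


def call_scna(
    profile: CopyNumberProfile,
    gain_thr: float = GAIN_THRESHOLD,
    loss_thr: float = LOSS_THRESHOLD,
) -> SCNACallTable:
    """Threshold a profile into discrete gain/neutral/loss calls.

    Inequalities are strict: a value exactly at a threshold is neutral.
    Missing values stay missing.
    """
    if not (loss_thr < 0 < gain_thr):
        raise ConfigError(
            f"thresholds must satisfy loss_thr < 0 < gain_thr; "
            f"got gain_thr={gain_thr}, loss_thr={loss_thr}"
        )
    vals = profile.values.to_numpy(dtype=float)
    out = np.full(vals.shape, np.nan, dtype=object)
    with np.errstate(invalid="ignore"):
        out[vals > gain_thr] = "gain"
        out[vals < loss_thr] = "loss"
        out[(vals <= gain_thr) & (vals >= loss_thr)] = "neutral"
    calls = pd.DataFrame(out, index=profile.values.index, columns=profile.values.columns)
    return SCNACallTable(
        level=profile.level, calls=calls, gain_thr=gain_thr, loss_thr=loss_thr,
        metadata={"gain_thr": gain_thr, "loss_thr": loss_thr},
    )


def aneuploidy_score(profile: CopyNumberProfile) -> AneuploidyScoreTable:
    """Per-sample sum of |log2(CN)| over non-missing features.

    Samples with every feature missing get a missing score (with a warning);
    the score is not rescaled by the number of contributing features.
    """
    abs_vals = profile.values.abs()
    scores = abs_vals.sum(axis=1, skipna=True)
    all_missing = abs_vals.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} sample(s) have no non-missing features; "
            "aneuploidy score set to missing", stacklevel=2,
        )
        scores[all_missing] = np.nan
    scores.name = "aneuploidy_score"
    return AneuploidyScoreTable(level=profile.level, scores=scores)
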