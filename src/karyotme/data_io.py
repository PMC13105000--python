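"""Readers, writers, and segment-to-feature mapping.

All tabular copy-number and expression data are held as pandas DataFrames
wrapped in light dataclasses. On-disk matrices follow the field convention
(features in rows, samples in columns); in memory everything is oriented
samples x features. Missing values are NaN in memory and the literal token
``NA`` on disk; they are never imputed here.

Coordinates are 0-based half-open internally. SEG files come in two common
dialects; the reader takes an explicit flag for 1-based-inclusive input
rather than guessing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError

LEVELS = ("arm", "cytoband", "gene")

CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X", "Y")

#: Canonical arm names, acrocentric p-arms (13p..15p, 21p, 22p) included for
#: completeness; callers typically restrict to the arms present in their map.
ARM_NAMES = tuple(f"{c}{a}" for c in CHROMOSOMES for a in ("p", "q"))

_ARM_RE = re.compile(r"^(?:[1-9]|1[0-9]|2[0-2]|X|Y)[pq]$")
_CYTOBAND_RE = re.compile(r"^(?:[1-9]|1[0-9]|2[0-2]|X|Y)[pq]\d+(?:\.\d+)?$")
_GENE_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9_.@-]*$")

_NA_TOKENS = {"", "NA", "NaN", "nan", "N/A", "null", "NULL"}


def _validate_feature_names(feature_ids, level: str) -> None:
    if level == "arm":
        pattern = _ARM_RE
    elif level == "cytoband":
        pattern = _CYTOBAND_RE
    elif level == "gene":
        pattern = _GENE_RE
    else:
        raise ConfigError(f"unknown level {level!r}; expected one of {LEVELS}")
    bad = [f for f in feature_ids if not pattern.match(str(f))]
    if bad:
        raise DataError(
            f"feature ids do not match the {level!r} naming convention: "
            f"{bad[:5]}{'...' if len(bad) > 5 else ''}"
        )


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = sorted(set(s[s.duplicated()]))
        raise DataError(f"duplicate {what}: {dups[:5]}")


@dataclass
class CopyNumberProfile:
    """Samples x features matrix of log2 copy number at one resolution level.

    ``values``: DataFrame indexed by sample id with feature-id columns; cells
    are log2(CN/ploidy) (0 = copy-neutral), finite or NaN.
    """

    level: str
    values: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ConfigError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, "feature ids")
        _validate_feature_names(self.values.columns, self.level)
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise DataError("copy-number values must be finite or missing (NaN)")
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class SegmentTable:
    """Per-sample copy-number segments, 0-based half-open coordinates."""

    segments: pd.DataFrame  # sample_id, chromosome, start, end, log2_cn

    def __post_init__(self):
        df = self.segments
        required = ["sample_id", "chromosome", "start", "end", "log2_cn"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataError(f"segment table missing columns: {missing}")
        if df["log2_cn"].isna().any():
            raise DataError("segment log2_cn must not be NaN")
        bad = df[df["start"] >= df["end"]]
        if len(bad):
            row = bad.iloc[0]
            raise DataError(
                f"segment with start >= end: {row['sample_id']} "
                f"{row['chromosome']}:{row['start']}-{row['end']}"
            )
        unknown = sorted(set(df["chromosome"]) - set(CHROMOSOMES))
        if unknown:
            raise DataError(f"unknown chromosome name(s): {unknown}")


@dataclass
class CytobandMap:
    """Cytoband intervals (UCSC cytoBand.txt), 0-based half-open."""

    bands: pd.DataFrame  # chromosome, start, end, band_name, arm

    def __post_init__(self):
        df = self.bands
        required = ["chromosome", "start", "end", "band_name", "arm"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataError(f"cytoband map missing columns: {missing}")
        for chrom, grp in df.groupby("chromosome", sort=False):
            grp = grp.sort_values("start")
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise DataError(f"overlapping cytobands on chromosome {chrom}")
        self.bands = (
            df.sort_values(["chromosome", "start"]).reset_index(drop=True)
        )

    def arm_intervals(self) -> pd.DataFrame:
        """One interval per arm: (chromosome, start, end, feature)."""
        g = self.bands.groupby(["chromosome", "arm"], sort=False)
        out = g.agg(start=("start", "min"), end=("end", "max")).reset_index()
        out["feature"] = out["chromosome"].astype(str) + out["arm"]
        return out[["chromosome", "start", "end", "feature"]]

    def band_intervals(self) -> pd.DataFrame:
        """One interval per major cytoband (sub-bands like 1q21.1 merged into 1q21)."""
        df = self.bands.copy()
        major = df["band_name"].str.replace(r"\.\d+$", "", regex=True)
        df["feature"] = df["chromosome"].astype(str) + major
        g = df.groupby(["chromosome", "feature"], sort=False)
        out = g.agg(start=("start", "min"), end=("end", "max")).reset_index()
        return out[["chromosome", "start", "end", "feature"]]


@dataclass
class ExpressionMatrix:
    """Samples x genes matrix of non-negative normalized expression."""

    values: pd.DataFrame

    def __post_init__(self):
        _check_unique(self.values.index, "sample ids")
        _check_unique(self.values.columns, "gene ids")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise DataError("expression values must be finite")
        if vals.size and not np.isnan(vals).all() and np.nanmin(vals) < 0:
            raise DataError("expression values must be non-negative")
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list:
        return list(self.values.columns)


#: Clinical table columns. Optional columns may be absent or NaN; os_time /
#: os_event are required for survival analysis.
CLINICAL_COLUMNS = [
    "sample_id", "tumor_type", "os_time", "os_event", "tmb", "pdl1_positive",
    "cd8_fraction", "b_fraction", "purity", "ploidy",
]


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table; returns it indexed by sample_id."""
    df = clinical.copy()
    if "sample_id" in df.columns:
        _check_unique(df["sample_id"], "sample ids")
        df = df.set_index("sample_id")
    if "os_time" in df.columns and (df["os_time"].dropna() < 0).any():
        raise DataError("os_time must be nonnegative")
    for col in ("cd8_fraction", "b_fraction"):
        if col in df.columns:
            v = df[col].dropna()
            if ((v < 0) | (v > 1)).any():
                raise DataError(f"{col} must lie in [0, 1]")
    if "purity" in df.columns:
        v = df["purity"].dropna()
        if ((v <= 0) | (v > 1)).any():
            raise DataError("purity must lie in (0, 1]")
    if "ploidy" in df.columns and (df["ploidy"].dropna() <= 0).any():
        raise DataError("ploidy must be positive")
    return df


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _normalize_chromosome(token: str) -> str:
    t = str(token).strip()
    if t.lower().startswith("chr"):
        t = t[3:]
    if t == "23":
        t = "X"
    elif t == "24":
        t = "Y"
    if t not in CHROMOSOMES:
        raise FormatError(f"unknown chromosome name: {token!r}")
    return t


def read_copy_number_table(path, level: str) -> CopyNumberProfile:
    """Read a GISTIC2-style features-x-samples TSV into a profile.

    First column holds feature ids; remaining columns are samples. ``NA``
    cells become missing values, never zero.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError(
            f"{path}: expected a feature-id column plus at least one sample column"
        )
    feature_col = raw.columns[0]
    features = raw[feature_col].astype(str)
    if features.duplicated().any():
        dups = sorted(set(features[features.duplicated()]))
        raise FormatError(f"{path}: duplicated feature row(s): {dups[:5]}")
    mat = np.full((len(raw), raw.shape[1] - 1), np.nan)
    for j, col in enumerate(raw.columns[1:]):
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell in _NA_TOKENS:
                continue
            try:
                mat[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at feature "
                    f"{features.iloc[i]!r}, sample column {col!r}"
                ) from None
    values = pd.DataFrame(mat.T, index=list(raw.columns[1:]), columns=list(features))
    return CopyNumberProfile(level=level, values=values)


_SEG_COLUMN_ALIASES = {
    "sample_id": {"sample", "sample_id", "id", "sampleid", "samplename"},
    "chromosome": {"chrom", "chromosome", "chr"},
    "start": {"start", "loc.start", "start_position", "startpos"},
    "end": {"end", "loc.end", "end_position", "endpos", "stop"},
    "log2_cn": {"seg.mean", "segment_mean", "log2", "log2_cn", "mean", "segmean"},
}


def read_segments(path, one_based_inclusive: bool = False) -> SegmentTable:
    """Read a SEG file.

    The default dialect is 0-based half-open; pass ``one_based_inclusive=True``
    for the other common dialect (start is decremented on load, end kept).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    rename = {}
    for canonical, aliases in _SEG_COLUMN_ALIASES.items():
        for col in df.columns:
            if col.strip().lower() in aliases:
                rename[col] = canonical
                break
    df = df.rename(columns=rename)
    missing = [c for c in _SEG_COLUMN_ALIASES if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: could not identify SEG column(s) {missing}")
    df = df[list(_SEG_COLUMN_ALIASES)].copy()
    df["chromosome"] = [_normalize_chromosome(c) for c in df["chromosome"]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if one_based_inclusive:
        df["start"] = df["start"] - 1
    df["log2_cn"] = df["log2_cn"].astype(float)
    df["sample_id"] = df["sample_id"].astype(str)
    return SegmentTable(df.reset_index(drop=True))


def read_cytoband_map(path) -> CytobandMap:
    """Read a UCSC cytoBand.txt file (chrom, start, end, band, stain; no header)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chromosome", "start", "end", "band_name", "stain"],
    )
    df["chromosome"] = [_normalize_chromosome(c) for c in df["chromosome"]]
    arm = df["band_name"].astype(str).str[0]
    if not arm.isin(["p", "q"]).all():
        bad = sorted(set(df.loc[~arm.isin(["p", "q"]), "band_name"]))
        raise FormatError(f"{path}: band names must start with p or q: {bad[:5]}")
    df["arm"] = arm
    return CytobandMap(df[["chromosome", "start", "end", "band_name", "arm"]])


def map_segments_to_features(
    segments: SegmentTable,
    bands: CytobandMap,
    level: str,
    min_coverage: float = 0.5,
    reduction: str = "weighted_mean",
) -> CopyNumberProfile:
    """Collapse segments onto arm or cytoband features.

    Each feature value is the overlap-length-weighted mean (or median) of
    segment log2_cn over the feature's interval; features covered by segments
    over less than ``min_coverage`` of their length are set to missing.
    """
    if level not in ("arm", "cytoband"):
        raise ConfigError("segment mapping supports levels 'arm' and 'cytoband'")
    if reduction not in ("weighted_mean", "weighted_median"):
        raise ConfigError(f"unknown reduction {reduction!r}")
    intervals = bands.arm_intervals() if level == "arm" else bands.band_intervals()
    seg = segments.segments
    samples = list(dict.fromkeys(seg["sample_id"]))
    features = list(intervals["feature"])
    mat = np.full((len(samples), len(features)), np.nan)
    by_sample_chrom = {
        key: grp for key, grp in seg.groupby(["sample_id", "chromosome"], sort=False)
    }
    for si, sample in enumerate(samples):
        any_overlap = False
        for fi, row in intervals.iterrows():
            grp = by_sample_chrom.get((sample, row["chromosome"]))
            if grp is None:
                continue
            ov_start = np.maximum(grp["start"].to_numpy(), row["start"])
            ov_end = np.minimum(grp["end"].to_numpy(), row["end"])
            lengths = np.clip(ov_end - ov_start, 0, None).astype(float)
            covered = lengths.sum()
            feat_len = row["end"] - row["start"]
            if covered <= 0 or covered / feat_len < min_coverage:
                continue
            any_overlap = True
            vals = grp["log2_cn"].to_numpy()
            keep = lengths > 0
            if reduction == "weighted_mean":
                mat[si, fi] = np.average(vals[keep], weights=lengths[keep])
            else:
                order = np.argsort(vals[keep])
                v, w = vals[keep][order], lengths[keep][order]
                cum = np.cumsum(w)
                mat[si, fi] = v[np.searchsorted(cum, cum[-1] / 2.0)]
        if not any_overlap:
            warnings.warn(
                f"sample {sample!r}: no feature reaches minimum coverage; "
                "row is all-missing", stacklevel=2,
            )
    values = pd.DataFrame(mat, index=samples, columns=features)
    return CopyNumberProfile(
        level=level, values=values,
        metadata={"min_coverage": min_coverage, "reduction": reduction},
    )


def read_expression_table(path) -> ExpressionMatrix:
    """Read a genes-x-samples expression TSV (first column = gene symbols)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(_NA_TOKENS),
                     float_precision="round_trip")
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicated gene row(s): {dups[:5]}")
    return ExpressionMatrix(df.T)


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical TSV (one row per sample); returns it indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", na_values=list(_NA_TOKENS),
                     float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: clinical table requires a sample_id column")
    for col in ("os_event", "pdl1_positive"):
        if col in df.columns:
            df[col] = df[col].map(_parse_bool)
    return validate_clinical(df)


def _parse_bool(v):
    if pd.isna(v):
        return np.nan
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    if s in {"1.0", "0.0"}:
        return s == "1.0"
    raise FormatError(f"cannot interpret {v!r} as a boolean")


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _repr_float(v) -> str:
    return repr(float(v))


def write_table(obj, path) -> None:
    """Write any tabular object to TSV with deterministic column order.

    Missing values are encoded as ``NA``; floats use repr round-tripping.
    DataFrames are written with their index when it is named or non-default.
    """
    if isinstance(obj, CopyNumberProfile):
        df = obj.values.T.rename_axis(obj.level)  # features x samples on disk
        df.to_csv(path, sep="\t", na_rep="NA", float_format=_repr_float)
    elif isinstance(obj, ExpressionMatrix):
        df = obj.values.T.rename_axis("gene")
        df.to_csv(path, sep="\t", na_rep="NA", float_format=_repr_float)
    elif isinstance(obj, SegmentTable):
        obj.segments.to_csv(path, sep="\t", na_rep="NA", index=False, float_format=_repr_float)
    elif isinstance(obj, CytobandMap):
        obj.bands.to_csv(path, sep="\t", na_rep="NA", index=False, float_format=_repr_float)
    elif isinstance(obj, pd.DataFrame):
        write_index = obj.index.name is not None or not isinstance(
            obj.index, pd.RangeIndex
        )
        obj.to_csv(path, sep="\t", na_rep="NA", index=write_index, float_format=_repr_float)
    elif isinstance(obj, pd.Series):
        obj.to_frame().to_csv(path, sep="\t", na_rep="NA", float_format=_repr_float)
    else:
        raise ConfigError(f"do not know how to write object of type {type(obj)!r}")


def read_result_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` for a plain DataFrame."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                       float_precision="round_trip")
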