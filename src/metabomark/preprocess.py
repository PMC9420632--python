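"""Feature-table preprocessing for untargeted metabolomics intensity data.

The canonical pipeline mirrors common practice for QTOF-MS plasma profiling:

1. censor low peaks: any absolute intensity below ``min_intensity`` is
   treated as not detected (missing);
2. the 80% rule: keep only features observed in at least a fraction
   ``presence_rule`` of samples;
3. half-minimum imputation: a feature's remaining missing cells are filled
   with half its smallest observed intensity;
4. log transform followed by Pareto scaling (mean-centre, divide by the
   square root of the column standard deviation).

Each step is a pure function on :class:`FeatureTable`; :func:`run_preprocess`
chains them in the canonical order and records provenance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "PreprocessConfig",
    "ScaledMatrix",
    "PreprocessReport",
    "filter_low_intensity",
    "presence_threshold",
    "apply_presence_rule",
    "impute_half_min",
    "log_pareto",
    "run_preprocess",
]


@dataclass
class FeatureTable:
    """A samples x features table of absolute intensities with group labels.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id, columns are feature ids. Missing
        measurements are ``NaN``; all observed values must be >= 0.
    groups
        Group label per sample, aligned with ``intensities.index``.
    feature_mz
        Optional m/z annotation per feature (Da, typically 50-1000).
    feature_name
        Optional metabolite name per feature.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    feature_mz: pd.Series | None = None
    feature_name: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.intensities.index
        cols = self.intensities.columns
        if idx.duplicated().any():
            raise ValueError(f"duplicate sample ids: {sorted(idx[idx.duplicated()])}")
        if cols.duplicated().any():
            raise ValueError(f"duplicate feature ids: {sorted(cols[cols.duplicated()])}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative")
        self.groups = pd.Series(self.groups, dtype=object)
        if not self.groups.index.equals(idx):
            # accept positional alignment for plain sequences
            if len(self.groups) != len(idx):
                raise ValueError("groups must have one label per sample")
            self.groups.index = idx
        for attr in ("feature_mz", "feature_name"):
            s = getattr(self, attr)
            if s is not None:
                s = pd.Series(s)
                if len(s) != len(cols):
                    raise ValueError(f"{attr} must have one entry per feature")
                s.index = cols
                setattr(self, attr, s)

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(),
            self.groups.copy(),
            None if self.feature_mz is None else self.feature_mz.copy(),
            None if self.feature_name is None else self.feature_name.copy(),
        )

    def subset_groups(self, labels: list[str]) -> "FeatureTable":
        """Restrict to the samples whose group label is in ``labels``."""
        missing = set(labels) - set(self.groups)
        if missing:
            raise ValueError(f"unknown group labels: {sorted(missing)}")
        mask = self.groups.isin(labels).to_numpy()
        return FeatureTable(
            self.intensities.loc[mask],
            self.groups.loc[mask],
            self.feature_mz,
            self.feature_name,
        )

    def select_features(self, feature_ids: list[str]) -> "FeatureTable":
        return FeatureTable(
            self.intensities[feature_ids],
            self.groups,
            None if self.feature_mz is None else self.feature_mz.loc[feature_ids],
            None if self.feature_name is None else self.feature_name.loc[feature_ids],
        )


@dataclass
class PreprocessConfig:
    """Settings for the preprocessing chain.

    ``min_intensity`` censors weak peaks per cell; ``presence_rule`` is the
    minimum observed fraction a feature must reach (80% rule); ``rounding``
    converts that fraction to a sample count; ``log_base`` is used before
    Pareto scaling; ``sample_normalization`` optionally divides each sample
    by its own median intensity (dilution correction) before the log step.
    """

    min_intensity: float = 1000.0
    presence_rule: float = 0.8
    rounding: str = "floor"  # {"floor", "ceil"}
    log_base: str = "10"  # {"10", "e"}
    sample_normalization: str = "none"  # {"none", "median"}

    def __post_init__(self) -> None:
        if self.min_intensity < 0:
            raise ValueError("min_intensity must be >= 0")
        if not (0 < self.presence_rule <= 1):
            raise ValueError("presence_rule must be in (0, 1]")
        if self.rounding not in ("floor", "ceil"):
            raise ValueError("rounding must be 'floor' or 'ceil'")
        if str(self.log_base) not in ("10", "e"):
            raise ValueError("log_base must be '10' or 'e'")
        if self.sample_normalization not in ("none", "median"):
            raise ValueError("sample_normalization must be 'none' or 'median'")


@dataclass
class ScaledMatrix:
    """Log-transformed, Pareto-scaled data ready for latent-variable models.

    Every column has mean zero; column j was divided by sqrt(sd_j) of its
    log column, so its variance equals that standard deviation. Columns
    that were constant on the log scale are all-zero and listed in
    ``zero_variance_features``.
    """

    values: pd.DataFrame
    column_means: pd.Series
    column_sds: pd.Series
    provenance: list = field(default_factory=list)
    zero_variance_features: list = field(default_factory=list)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class PreprocessReport:
    n_cells_censored: int = 0
    n_features_in: int = 0
    n_features_kept: int = 0
    presence_threshold: int = 0
    n_cells_imputed: int = 0
    steps: list = field(default_factory=list)


def filter_low_intensity(table: FeatureTable, min_intensity: float) -> FeatureTable:
    """Set every observed cell below ``min_intensity`` to missing.

    The filter acts per cell (a weak peak in one sample does not remove the
    feature everywhere); "below" is strict, so a cell equal to the threshold
    is retained. Dimensions are unchanged.
    """
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    out = table.copy()
    out.intensities = out.intensities.where(
        out.intensities.isna() | (out.intensities >= min_intensity)
    )
    return out


def presence_threshold(n_samples: int, presence_rule: float = 0.8, rounding: str = "floor") -> int:
    """Minimum number of observed samples a feature needs under the 80% rule.

    With 176 samples and the default floor convention this is
    floor(0.8 * 176) = 140.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (0 < presence_rule <= 1):
        raise ValueError("presence_rule must be in (0, 1]")
    # guard against binary-float artefacts such as 0.8*15 = 12.000000000000002
    x = round(presence_rule * n_samples, 9)
    if rounding == "floor":
        return int(math.floor(x))
    if rounding == "ceil":
        return int(math.ceil(x))
    raise ValueError("rounding must be 'floor' or 'ceil'")


def apply_presence_rule(table: FeatureTable, threshold_count: int) -> FeatureTable:
    """Keep exactly the features observed in >= ``threshold_count`` samples."""
    if threshold_count < 0:
        raise ValueError("threshold_count must be >= 0")
    counts = table.intensities.notna().sum(axis=0)
    keep = [f for f in table.feature_ids if counts[f] >= threshold_count]
    if not keep:
        warnings.warn("presence rule removed every feature", stacklevel=2)
        return FeatureTable(
            table.intensities.iloc[:, :0],
            table.groups,
            None if table.feature_mz is None else table.feature_mz.iloc[:0],
            None if table.feature_name is None else table.feature_name.iloc[:0],
        )
    return table.select_features(keep)


def impute_half_min(table: FeatureTable) -> FeatureTable:
    """Fill each feature's missing cells with half its minimum observed value.

    Pools all samples (irrespective of group) when taking the minimum.
    Raises for any feature with no observed values, since no minimum exists.
    """
    out = table.copy()
    counts = out.intensities.notna().sum(axis=0)
    empty = [f for f in out.feature_ids if counts[f] == 0]
    if empty:
        raise ValueError(
            f"cannot impute features with no observed values: {empty[:10]}"
        )
    fill = out.intensities.min(axis=0, skipna=True) / 2.0
    out.intensities = out.intensities.fillna(fill)
    return out


def log_pareto(table: FeatureTable, config: PreprocessConfig | None = None) -> ScaledMatrix:
    """Log-transform then Pareto-scale a complete intensity table.

    Pareto scaling centres each log column and divides by the square root of
    its standard deviation (n-1 denominator): a compromise between no
    scaling and unit-variance scaling that damps but does not erase the
    fold-change structure. Constant columns become all-zero and are flagged.
    """
    config = config or PreprocessConfig()
    vals = table.intensities.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing values present: impute (impute_half_min) first")
    if (vals <= 0).any():
        raise ValueError("non-positive intensities present: filter/impute first")
    logv = np.log10(vals) if str(config.log_base) == "10" else np.log(vals)
    means = logv.mean(axis=0)
    sds = logv.std(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros(vals.shape[1])
    centred = logv - means
    zero_var = sds <= 0
    scale = np.sqrt(np.where(zero_var, 1.0, sds))
    scaled = np.where(zero_var, 0.0, centred / scale)
    flagged = [f for f, z in zip(table.feature_ids, zero_var) if z]
    prov = [f"log{config.log_base}", "pareto"]
    if flagged:
        prov.append(f"zero_variance_features={flagged}")
    return ScaledMatrix(
        values=pd.DataFrame(scaled, index=table.sample_ids, columns=table.feature_ids),
        column_means=pd.Series(means, index=table.feature_ids),
        column_sds=pd.Series(sds, index=table.feature_ids),
        provenance=prov,
        zero_variance_features=flagged,
    )


def _normalize_median(table: FeatureTable) -> FeatureTable:
    """Divide each sample by its median intensity, rescaled to the grand median."""
    out = table.copy()
    med = out.intensities.median(axis=1, skipna=True)
    if (med <= 0).any():
        raise ValueError("sample median <= 0; cannot median-normalize")
    grand = float(med.median())
    out.intensities = out.intensities.div(med, axis=0) * grand
    return out


def run_preprocess(
    table: FeatureTable, config: PreprocessConfig | None = None
) -> tuple[FeatureTable, ScaledMatrix, PreprocessReport]:
    """Run the canonical chain: censor -> 80% rule -> impute -> log/Pareto.

    Returns the imputed raw-intensity table (the scale on which fold changes
    and ROC cut-points are computed), the scaled matrix for modelling, and a
    report of what each stage did.
    """
    config = config or PreprocessConfig()
    report = PreprocessReport(n_features_in=table.n_features)

    n_missing0 = int(table.intensities.isna().to_numpy().sum())
    t1 = filter_low_intensity(table, config.min_intensity)
    report.n_cells_censored = int(t1.intensities.isna().to_numpy().sum()) - n_missing0
    report.steps.append(f"filter_low_intensity(min={config.min_intensity})")

    thr = presence_threshold(t1.n_samples, config.presence_rule, config.rounding)
    report.presence_threshold = thr
    t2 = apply_presence_rule(t1, thr)
    report.n_features_kept = t2.n_features
    report.steps.append(f"apply_presence_rule(threshold={thr})")

    report.n_cells_imputed = int(t2.intensities.isna().to_numpy().sum())
    t3 = impute_half_min(t2) if t2.n_features else t2
    report.steps.append("impute_half_min")

    if config.sample_normalization == "median":
        t3 = _normalize_median(t3)
        report.steps.append("median_normalize")

    scaled = log_pareto(t3, config)
    scaled.provenance = report.steps + scaled.provenance
    report.steps.append(f"log_pareto(base={config.log_base})")
    return t3, scaled, report
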