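"""Reading/writing feature tables, pipeline configuration, and the
end-to-end comparison runner.

File dialect: the data file is CSV or TSV with the sample id in the first
column and one column per feature; empty cells or the token ``NA`` mark
missing measurements. Sample metadata is a CSV/TSV with ``sample_id`` and
``group`` columns. An optional feature-annotation file carries
``feature_id``, ``mz`` and ``name`` columns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomarkers import BiomarkerReport, build_report
from .chemometrics import compute_vip
from .preprocess import FeatureTable, PreprocessConfig, run_preprocess
from .univariate import ThresholdPolicy, univariate_screen
from .validation import ModelSpec, check_validity, cross_validate_q2, permutation_test

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "Comparison",
    "PipelineConfig",
    "RunLog",
    "run_comparison",
    "run_all",
]

_MISSING_TOKENS = ["", "NA"]


def _read_delim(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, na_values=_MISSING_TOKENS, keep_default_na=False)


def read_feature_table(
    data_path, metadata_path, features_path=None, transpose: bool = False
) -> FeatureTable:
    """Load and validate a feature table plus its sample metadata.

    Sample order follows the data file; group labels are joined by id.
    ``transpose=True`` accepts features-as-rows exports.
    """
    df = _read_delim(data_path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = None
    if transpose:
        df = df.T
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate feature columns: {dups}")
    df = df.astype(float)
    if (df < 0).any().any():
        raise ValueError("negative intensity found in data file")

    meta = _read_delim(metadata_path)
    cols = {c.lower(): c for c in meta.columns}
    if "sample_id" not in cols or "group" not in cols:
        raise ValueError("metadata must contain 'sample_id' and 'group' columns")
    meta = meta.set_index(meta[cols["sample_id"]].astype(str))
    unmatched = [s for s in df.index if s not in meta.index]
    if unmatched:
        raise ValueError(f"samples absent from metadata: {unmatched}")
    groups = meta.loc[df.index, cols["group"]].astype(str)
    groups.index = df.index

    mz = name = None
    if features_path is not None:
        feats = _read_delim(features_path)
        fcols = {c.lower(): c for c in feats.columns}
        if "feature_id" not in fcols:
            raise ValueError("feature annotation needs a 'feature_id' column")
        feats = feats.set_index(feats[fcols["feature_id"]].astype(str))
        if "mz" in fcols:
            mz = feats[fcols["mz"]].reindex(df.columns).astype(float)
        if "name" in fcols:
            name = feats[fcols["name"]].reindex(df.columns)
    return FeatureTable(df, groups, feature_mz=mz, feature_name=name)


def write_feature_table(table: FeatureTable, data_path, metadata_path, features_path=None) -> None:
    """Write the CSV/TSV dialect read by :func:`read_feature_table`."""
    data_path = Path(data_path)
    sep = "\t" if data_path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    out = table.intensities.copy()
    out.index.name = "sample_id"
    out.to_csv(data_path, sep=sep, na_rep="NA", float_format="%.17e")
    meta = pd.DataFrame({"sample_id": table.sample_ids, "group": table.groups.to_numpy()})
    meta.to_csv(metadata_path, sep=sep, index=False)
    if features_path is not None:
        feats = pd.DataFrame({"feature_id": table.feature_ids})
        if table.feature_mz is not None:
            feats["mz"] = table.feature_mz.to_numpy()
        if table.feature_name is not None:
            feats["name"] = table.feature_name.to_numpy()
        feats.to_csv(features_path, sep=sep, index=False)


@dataclass
class Comparison:
    """One comparison design: which labels enter, and what is 'case'.

    With both ``case`` and ``control`` non-empty, samples are pooled into a
    two-class contrast (labels kept verbatim when each side is a single
    group). With ``control`` empty, all ``case`` labels enter a multi-class
    model.
    """

    name: str
    case: list[str]
    control: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_orthogonal: int = 1
    n_components: int | None = None
    n_folds: int = 7
    n_permutations: int = 200
    alpha: float = 0.05
    top_k: int = 4
    seed: int = 0
    comparisons: list[Comparison] = field(default_factory=list)
    output_dir: str | None = None
    data_path: str | None = None
    metadata_path: str | None = None
    features_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 20:
            raise ValueError("n_permutations must be >= 20")
        self.comparisons = [
            c if isinstance(c, Comparison) else Comparison(**c) for c in self.comparisons
        ]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "preprocess" in raw and isinstance(raw["preprocess"], dict):
            raw["preprocess"] = PreprocessConfig(**raw["preprocess"])
        return cls(**raw)

    def comparison(self, name: str) -> Comparison:
        for c in self.comparisons:
            if c.name == name:
                return c
        raise KeyError(f"unknown comparison {name!r}")


class RunLog:
    """Deterministic, append-only record of pipeline stages and seeds.

    Records carry a monotone step index rather than wall-clock time so that
    identical runs produce byte-identical logs (and checksums).
    """

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, stage: str, **info) -> None:
        self.records.append({"step": len(self.records), "stage": stage, **info})

    def to_text(self) -> str:
        return "\n".join(json.dumps(r, sort_keys=True, default=str) for r in self.records)

    def checksum(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()

    def write(self, path) -> None:
        Path(path).write_text(self.to_text() + "\n")


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministically split the root seed per named stage."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_comparison(
    config: PipelineConfig,
    comparison_name: str,
    table: FeatureTable | None = None,
    log: RunLog | None = None,
) -> BiomarkerReport:
    """Execute one comparison end to end and (optionally) write artifacts.

    Stages: subset samples -> preprocess (censor, 80% rule, impute,
    log/Pareto) -> fit OPLS-DA or multi-class PLS-DA -> cross-validate Q2 ->
    permutation test -> validity checklist -> VIP + nonparametric screen ->
    ranked biomarker report with ROC cut-points. An invalid model does not
    abort: the report is produced and flagged.
    """
    comp = config.comparison(comparison_name)
    log = log if log is not None else RunLog()
    if table is None:
        if config.data_path is None or config.metadata_path is None:
            raise ValueError("no table given and no data/metadata paths in config")
        table = read_feature_table(config.data_path, config.metadata_path, config.features_path)

    wanted = list(comp.case) + list(comp.control)
    sub = table.subset_groups(wanted)
    if comp.control and (len(comp.case) > 1 or len(comp.control) > 1):
        pooled = np.where(sub.groups.isin(comp.case), "case", "control")
        sub = FeatureTable(sub.intensities, pd.Series(pooled, index=sub.intensities.index),
                           sub.feature_mz, sub.feature_name)
        case_label = "case"
    elif comp.control:
        case_label = comp.case[0]
    else:
        case_label = None
    log.add("subset", comparison=comp.name, n_samples=sub.n_samples,
            labels=sorted(set(sub.groups)))

    imputed, scaled, prep = run_preprocess(sub, config.preprocess)
    log.add("preprocess", cells_censored=prep.n_cells_censored,
            features_in=prep.n_features_in, features_kept=prep.n_features_kept,
            presence_threshold=prep.presence_threshold, cells_imputed=prep.n_cells_imputed)
    if imputed.n_features == 0:
        raise ValueError("preprocessing removed every feature")

    labels = sorted(set(sub.groups))
    spec = ModelSpec(
        kind="oplsda" if len(labels) == 2 else "plsda",
        n_orthogonal=config.n_orthogonal,
        n_components=config.n_components,
    )
    model = spec.fit(scaled, sub.groups.to_numpy())
    cv_seed = _stage_seed(config.seed, f"{comp.name}:cv")
    cv = cross_validate_q2(scaled, sub.groups.to_numpy(), spec,
                           n_folds=config.n_folds, seed=cv_seed)
    perm_seed = _stage_seed(config.seed, f"{comp.name}:perm")
    perm = permutation_test(scaled, sub.groups.to_numpy(), spec,
                            n_permutations=config.n_permutations, seed=perm_seed,
                            n_folds=config.n_folds)
    validity = check_validity(model, cv, perm)
    log.add("model", kind=model.kind, r2x=round(model.r2x, 4), r2y=round(model.r2y, 4),
            q2=round(cv.q2, 4), cv_seed=cv_seed, perm_seed=perm_seed,
            q2_intercept=round(perm.intercept_q2, 4), valid=validity.valid)

    vip = compute_vip(model)
    policy = ThresholdPolicy(alpha=config.alpha,
                             family_size=max(int((vip.vip > 1).sum()), 1))
    uni = univariate_screen(imputed, vip, policy=policy, case_label=case_label)
    log.add("univariate", family_size=policy.family_size,
            corrected_threshold=policy.corrected_threshold,
            n_pass_vip=sum(u.passes_vip for u in uni),
            n_pass_both=sum(u.passes_vip and u.passes_p for u in uni))

    report = build_report(imputed, uni, top_k=config.top_k, case_label=case_label,
                          comparison_name=comp.name)
    report.validity = validity
    log.add("report", selected=report.selected)

    if config.output_dir:
        out = Path(config.output_dir) / comp.name
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv")
        vip.vip.rename("VIP").to_csv(out / "vip.csv", float_format="%.6g")
        pd.DataFrame(
            {"correlation": perm.perm_correlations, "r2y": perm.perm_r2y, "q2": perm.perm_q2}
        ).to_csv(out / "permutation_rounds.csv", index=False, float_format="%.6g")
        summary = {
            "r2x": model.r2x, "r2y": model.r2y, "q2": cv.q2,
            "q2_intercept": perm.intercept_q2, "r2_intercept": perm.intercept_r2,
            "valid": validity.valid,
            "flags": {k: getattr(validity, k) for k in
                      ("r2x_ok", "r2y_gt_q2", "gap_ok", "q2_intercept_ok")},
        }
        (out / "model_summary.json").write_text(json.dumps(summary, indent=2, default=str))
        log.write(out / "run.log")
    return report


def run_all(config: PipelineConfig, table: FeatureTable | None = None) -> dict[str, BiomarkerReport]:
    """Run every configured comparison; returns reports keyed by name."""
    log = RunLog()
    log.add("config", seed=config.seed, n_comparisons=len(config.comparisons))
    return {
        c.name: run_comparison(config, c.name, table=table, log=log)
        for c in config.comparisons
    }
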