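"""Cross-validated predictability (Q2), permutation testing, and the
model-validity checklist for OPLS-DA / PLS-DA models.

Q2 is a regression-style statistic: stratified folds are held out, the model
is refit with the same component structure, the held-out centred dummy rows
are predicted, and Q2 = 1 - PRESS/SSY. The permutation test refits the model
under uniformly shuffled class labels and regresses the permuted R2Y and Q2
values against the label correlation (the unpermuted model anchors the line
at correlation 1); a sound model shows an original Q2 above every permuted
one and a Q2-line intercept below 0.05.

The validity checklist combines four conventional flags: R2X > 0.5,
R2Y > Q2, R2Y - Q2 < 0.3, and the permutation Q2 intercept < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .chemometrics import OplsdaModel, _as_array, dummy_matrix, fit_oplsda, fit_plsda_multiclass

__all__ = [
    "ModelSpec",
    "CvResult",
    "PermutationResult",
    "ValidityReport",
    "cross_validate_q2",
    "permutation_test",
    "check_validity",
    "plot_permutation",
]


@dataclass
class ModelSpec:
    """Component structure to refit during validation.

    ``kind='auto'`` picks two-class OPLS-DA (with ``n_orthogonal``
    components) or multi-class PLS-DA (with ``n_components``) by label count.
    """

    kind: str = "auto"  # {"auto", "oplsda", "plsda"}
    n_orthogonal: int = 1
    n_components: int | None = None

    def fit(self, x, groups) -> OplsdaModel:
        labels = sorted(set(np.asarray(groups).tolist()))
        kind = self.kind
        if kind == "auto":
            kind = "oplsda" if len(labels) == 2 else "plsda"
        if kind == "oplsda":
            return fit_oplsda(x, groups, n_orthogonal=self.n_orthogonal)
        return fit_plsda_multiclass(x, groups, n_components=self.n_components)


@dataclass
class CvResult:
    q2: float
    n_folds: int
    fold_assignment: np.ndarray
    press: float
    ssy: float


@dataclass
class PermutationResult:
    n_permutations: int
    perm_correlations: np.ndarray
    perm_r2y: np.ndarray
    perm_q2: np.ndarray
    intercept_r2: float
    intercept_q2: float
    original_r2y: float
    original_q2: float


@dataclass
class ValidityReport:
    r2x_ok: bool
    r2y_gt_q2: bool
    gap_ok: bool
    q2_intercept_ok: bool
    details: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return self.r2x_ok and self.r2y_gt_q2 and self.gap_ok and self.q2_intercept_ok


def cross_validate_q2(
    x, groups, model_spec: ModelSpec | None = None, n_folds: int = 7, seed: int = 0
) -> CvResult:
    """Stratified k-fold Q2 = 1 - PRESS/SSY for the given model structure.

    Predictions for held-out samples are taken on the raw dummy-regression
    scale (no class-assignment thresholding); each fold's model centres its
    own training dummy, and predictions are shifted back onto the scale of
    the full centred dummy before squared errors accumulate.
    """
    model_spec = model_spec or ModelSpec()
    X, _ = _as_array(x)
    g = np.asarray(groups)
    Y_full, means_full, labels = dummy_matrix(g)
    smallest = min(int((g == lab).sum()) for lab in labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > smallest:
        raise ValueError(
            f"n_folds={n_folds} exceeds the smallest class size {smallest}; "
            "choose fewer folds so every class appears in every training split"
        )
    skf = StratifiedKFold(n_splits=int(n_folds), shuffle=True, random_state=int(seed) % (2**31))
    fold_assignment = np.empty(len(g), dtype=int)
    press = 0.0
    for k, (tr, te) in enumerate(skf.split(X, g)):
        fold_assignment[te] = k
        model = model_spec.fit(X[tr], g[tr])
        if model.class_labels != labels:
            raise ValueError("a training split lost a class; use fewer folds")
        yhat_centred = model.predict(X[te])
        means_tr = np.asarray(model.dummy_coding["y_means"], dtype=float)
        yhat_full = yhat_centred + means_tr - means_full
        press += float(((Y_full[te] - yhat_full) ** 2).sum())
    ssy = float((Y_full**2).sum())
    return CvResult(
        q2=1.0 - press / ssy,
        n_folds=int(n_folds),
        fold_assignment=fold_assignment,
        press=press,
        ssy=ssy,
    )


def _n_distinct_permutations(g: np.ndarray) -> float:
    n = len(g)
    out = math.factorial(n)
    for lab in set(g.tolist()):
        out //= math.factorial(int((g == lab).sum()))
    return out


def _dummy_correlation(y_perm: np.ndarray, y_orig: np.ndarray) -> float:
    """Mean absolute column-wise Pearson correlation of two centred dummies."""
    cors = []
    for j in range(y_orig.shape[1]):
        a, b = y_perm[:, j], y_orig[:, j]
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        cors.append(abs(float(a @ b)) / denom if denom > 0 else 0.0)
    return float(np.mean(cors))


def permutation_test(
    x,
    groups,
    model_spec: ModelSpec | None = None,
    n_permutations: int = 200,
    seed: int = 0,
    n_folds: int = 7,
) -> PermutationResult:
    """Refit under shuffled labels; summarize R2Y/Q2 against label correlation.

    Each round draws a uniform permutation of the labels (the identity is
    rejected and redrawn), refits the model, and records its R2Y and
    cross-validated Q2 together with the correlation between permuted and
    original centred dummies. Intercepts come from least-squares lines
    through all permuted points plus the original model at correlation 1.
    """
    model_spec = model_spec or ModelSpec()
    X, _ = _as_array(x)
    g = np.asarray(groups)
    if n_permutations < 20:
        raise ValueError("n_permutations must be >= 20")
    if _n_distinct_permutations(g) - 1 < n_permutations:
        raise ValueError(
            "fewer distinct label permutations exist than requested rounds"
        )
    Y_orig, _, _ = dummy_matrix(g)
    original = model_spec.fit(X, g)
    ss = np.random.SeedSequence(int(seed) % (2**31))
    child = ss.spawn(n_permutations + 1)
    original_q2 = cross_validate_q2(
        X, g, model_spec, n_folds=n_folds, seed=int(child[0].generate_state(1)[0] % (2**31))
    ).q2

    cors = np.empty(n_permutations)
    r2ys = np.empty(n_permutations)
    q2s = np.empty(n_permutations)
    for i in range(n_permutations):
        rng = np.random.default_rng(child[i + 1])
        while True:
            perm = rng.permutation(len(g))
            if not np.array_equal(perm, np.arange(len(g))):
                break
        g_perm = g[perm]
        cors[i] = _dummy_correlation(Y_orig[perm], Y_orig)
        m = model_spec.fit(X, g_perm)
        r2ys[i] = m.r2y
        q2s[i] = cross_validate_q2(
            X, g_perm, model_spec, n_folds=n_folds,
            seed=int(child[i + 1].generate_state(1)[0] % (2**31)),
        ).q2

    xs = np.concatenate([cors, [1.0]])
    int_r2 = float(np.polyfit(xs, np.concatenate([r2ys, [original.r2y]]), 1)[1])
    int_q2 = float(np.polyfit(xs, np.concatenate([q2s, [original_q2]]), 1)[1])
    return PermutationResult(
        n_permutations=n_permutations,
        perm_correlations=cors,
        perm_r2y=r2ys,
        perm_q2=q2s,
        intercept_r2=int_r2,
        intercept_q2=int_q2,
        original_r2y=original.r2y,
        original_q2=original_q2,
    )


def check_validity(
    model: OplsdaModel, cv: CvResult, perm: PermutationResult | None = None
) -> ValidityReport:
    """Apply the four-flag validity checklist to a fitted model.

    R2X > 0.5 (the model describes most of X), R2Y > Q2 (fit beats
    prediction, as it must), R2Y - Q2 < 0.3 (no gross overfitting), and the
    permutation Q2 intercept < 0.05. Without a permutation result the last
    flag is False and marked as not evaluated.
    """
    r2x_ok = model.r2x > 0.5
    r2y_gt_q2 = model.r2y > cv.q2
    gap_ok = (model.r2y - cv.q2) < 0.3
    details = {
        "r2x": (model.r2x, "> 0.5"),
        "r2y_vs_q2": ((model.r2y, cv.q2), "r2y > q2"),
        "gap": (model.r2y - cv.q2, "< 0.3"),
    }
    if perm is not None:
        q2_int_ok = perm.intercept_q2 < 0.05
        details["q2_intercept"] = (perm.intercept_q2, "< 0.05")
    else:
        q2_int_ok = False
        details["q2_intercept"] = (None, "< 0.05 (not evaluated)")
    return ValidityReport(
        r2x_ok=bool(r2x_ok),
        r2y_gt_q2=bool(r2y_gt_q2),
        gap_ok=bool(gap_ok),
        q2_intercept_ok=bool(q2_int_ok),
        details=details,
    )


def plot_permutation(perm: PermutationResult, path) -> None:
    """R2Y/Q2 versus label correlation, with the fitted regression lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(perm.perm_correlations, perm.perm_r2y, c="tab:green", s=14, label="R2Y (permuted)")
    ax.scatter(perm.perm_correlations, perm.perm_q2, c="tab:blue", s=14, label="Q2 (permuted)")
    ax.scatter([1.0], [perm.original_r2y], c="tab:green", marker="*", s=120, label="R2Y (model)")
    ax.scatter([1.0], [perm.original_q2], c="tab:blue", marker="*", s=120, label="Q2 (model)")
    xs = np.concatenate([perm.perm_correlations, [1.0]])
    for ys, y0, color in (
        (np.concatenate([perm.perm_r2y, [perm.original_r2y]]), perm.intercept_r2, "tab:green"),
        (np.concatenate([perm.perm_q2, [perm.original_q2]]), perm.intercept_q2, "tab:blue"),
    ):
        slope, intercept = np.polyfit(xs, ys, 1)
        grid = np.linspace(0, 1, 20)
        ax.plot(grid, intercept + slope * grid, color=color, lw=1, alpha=0.7)
    ax.set_xlabel("correlation with original labels")
    ax.set_ylabel("R2Y / Q2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
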