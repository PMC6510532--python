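"""Attack-decision analysis.

The pipeline mirrors a three-step design:

1. **Effect estimation.**  Test-trial attacks on focal prey are fit with a
   binomial-logit model with *no intercept and no trait main effects* — a
   deliberate marginality violation that makes the per-experiment trait
   effects directly readable from the coefficient vector::

       attacked ~ 0 + experiment + subject
                    + reliable:experiment + unreliable:experiment
                    + reliable:experiment:order + unreliable:experiment:order

   Reliable-trait values are recoded to good/bad ('G'/'B') so both traits
   enter as centered binaries; subjects enter as fixed effects (a random
   effect is deliberately out of scope); presentation order is centered.

2. **Within-experiment contrasts.**  Per experiment, the difference
   (relative use of the reliable trait) and the sum (total discrimination)
   of the two trait effects, with delta-method standard errors — exact
   ``sqrt(c' Sigma c)`` for linear functions.

3. **Between-experiment comparisons.**  All pairwise differences of those
   contrasts, Bonferroni-adjusted confidence intervals, and a compact letter
   display in which experiments share a letter iff their difference's CI
   includes zero.

A separate likelihood-ratio test compares the recoded (lumped) model against
one keeping the original focal reliable values distinct (up to two good and
two bad per experiment); both violate marginality, which is irrelevant to the
comparison of fit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from preycat import communities as _comm

__all__ = [
    "AnalysisError",
    "FitResult",
    "ContrastResult",
    "GroupingResult",
    "prepare_table",
    "build_design",
    "fit_logit",
    "fit_model",
    "linear_contrast",
    "trait_contrasts",
    "pairwise_groupings",
    "split_value_lrt",
    "summarize_effects",
    "simulate_attacks",
    "round_sig",
    "REQUIRED_RECORD_COLUMNS",
]


class AnalysisError(ValueError):
    pass


#: Columns prepare_table needs from a tidy attack-record table.
REQUIRED_RECORD_COLUMNS = (
    "subject",
    "experiment",
    "trial",
    "order",
    "reliable_label",
    "reliable_polarity",
    "unreliable_label",
    "attacked",
)

#: Absolute coefficient size beyond which we flag likely complete separation.
SEPARATION_THRESHOLD = 15.0


# ---------------------------------------------------------------------------
# results containers


@dataclass(frozen=True)
class FitResult:
    """Fitted binomial-logit model: coefficients, covariance, log-likelihood."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    converged: bool
    separation: bool
    nobs: int

    @property
    def term_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.params.index)}

    def __post_init__(self) -> None:
        if list(self.cov.index) != list(self.params.index):
            raise AnalysisError("covariance rows must match coefficient names")


@dataclass(frozen=True)
class ContrastResult:
    """Point estimate of a linear function of coefficients, on log-odds."""

    label: str
    estimate: float
    se: float | None = None
    level: float = 0.95
    ci: tuple[float, float] | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @staticmethod
    def from_estimate(
        label: str, estimate: float, se: float | None = None, level: float = 0.95
    ) -> "ContrastResult":
        ci = None
        if se is not None:
            z = scipy.stats.norm.ppf(0.5 + level / 2)
            ci = (estimate - z * se, estimate + z * se)
        return ContrastResult(label=label, estimate=float(estimate), se=se, level=level, ci=ci)


@dataclass(frozen=True)
class GroupingResult:
    """Pairwise comparisons of per-experiment contrasts with letter groups."""

    estimates: dict[int, ContrastResult]
    pairwise: pd.DataFrame  # exp_a, exp_b, estimate, se, ci_lo, ci_hi, significant
    letters: dict[int, str]
    alpha: float
    n_comparisons: int


# ---------------------------------------------------------------------------
# table preparation


def default_label_sets(
    good_abundances: Mapping[int, Sequence[int]] | None = None,
) -> tuple[dict[int, frozenset[str]], dict[int, frozenset[str]]]:
    """(trained, focal) reliable-label sets per experiment, from the default
    (or overridden) community designs."""
    trained: dict[int, frozenset[str]] = {}
    focal: dict[int, frozenset[str]] = {}
    for experiment_id in _comm.EXPERIMENT_IDS:
        kwargs = {}
        if good_abundances is not None and experiment_id in good_abundances:
            kwargs["good_abundances"] = good_abundances[experiment_id]
        spec = _comm.build_training_community(experiment_id, **kwargs)
        trained[experiment_id] = spec.reliable_labels
        focal[experiment_id] = spec.focal_reliable_labels
    return trained, focal


def prepare_table(
    records: pd.DataFrame,
    trained_labels: Mapping[int, frozenset[str]] | None = None,
    focal_labels: Mapping[int, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Reduce raw attack records to the modeling table.

    Keeps test-trial rows for focal prey whose reliable value was present in
    that experiment's training community (test-only values are eliminated),
    recodes the reliable value to good/bad, and centers the binary traits and
    the order covariate.
    """
    missing = [c for c in REQUIRED_RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise AnalysisError(f"records are missing required columns: {missing}")
    if trained_labels is None or focal_labels is None:
        default_trained, default_focal = default_label_sets()
        trained_labels = trained_labels or default_trained
        focal_labels = focal_labels or default_focal

    df = records.loc[records["trial"] == "test"].copy()
    if df.empty:
        raise AnalysisError("no test-trial records found")

    def _keep(row) -> bool:
        exp = int(row["experiment"])
        label = row["reliable_label"]
        return label in trained_labels.get(exp, frozenset()) and label in focal_labels.get(
            exp, frozenset()
        )

    df = df.loc[df.apply(_keep, axis=1)].copy()
    if df.empty:
        raise AnalysisError("no focal test-trial rows survive filtering")

    df["attacked"] = df["attacked"].astype(bool).astype(int)
    df["R_recoded"] = np.where(df["reliable_polarity"] == "+", "G", "B")
    r01 = (df["R_recoded"] == "G").astype(float)
    u01 = (df["unreliable_label"] == "U+").astype(float)
    df["R_c"] = r01 - r01.mean()
    df["U_c"] = u01 - u01.mean()
    df["order_c"] = df["order"].astype(float) - df["order"].astype(float).mean()
    df["experiment"] = df["experiment"].astype(int)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# design matrices


def _split_value_columns(df: pd.DataFrame, experiment: int) -> list[str]:
    """Focal reliable labels of one experiment, good values first, with the
    last bad value dropped (absorbed by the experiment dummy) so the lumped
    binary coding stays nested inside the split coding."""
    labels = sorted(df.loc[df["experiment"] == experiment, "reliable_label"].unique())
    good = [l for l in labels if l.endswith("+")]
    bad = [l for l in labels if l.endswith("-")]
    return good + bad[:-1]


def build_design(
    table: pd.DataFrame, split_reliable: bool = False
) -> tuple[np.ndarray, pd.DataFrame]:
    """Response vector and named design matrix for the no-intercept model.

    Column blocks: experiment dummies, subject dummies (first subject
    dropped), then per experiment the trait terms — centered-binary
    ``R:exp{e}`` / ``U:exp{e}`` (or raw focal-value dummies when
    ``split_reliable``) and the trait-by-order interactions.  All-zero
    columns (e.g. order terms in a single-rank table) are dropped.
    """
    y = table["attacked"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {}
    experiments = sorted(table["experiment"].unique())
    subjects = sorted(table["subject"].unique())

    for e in experiments:
        cols[f"exp{e}"] = (table["experiment"] == e).to_numpy(dtype=float)
    for s in subjects[1:]:
        cols[f"subj[{s}]"] = (table["subject"] == s).to_numpy(dtype=float)

    for e in experiments:
        d = (table["experiment"] == e).to_numpy(dtype=float)
        if split_reliable:
            for label in _split_value_columns(table, e):
                cols[f"Rval[{label}]:exp{e}"] = (
                    (table["reliable_label"] == label).to_numpy(dtype=float) * d
                )
        else:
            cols[f"R:exp{e}"] = table["R_c"].to_numpy() * d
        cols[f"U:exp{e}"] = table["U_c"].to_numpy() * d
    for e in experiments:
        d = (table["experiment"] == e).to_numpy(dtype=float)
        cols[f"R:exp{e}:order"] = table["R_c"].to_numpy() * table["order_c"].to_numpy() * d
        cols[f"U:exp{e}:order"] = table["U_c"].to_numpy() * table["order_c"].to_numpy() * d

    X = pd.DataFrame(cols, index=table.index)
    nonzero = (X != 0).any(axis=0)
    return y, X.loc[:, nonzero]


# ---------------------------------------------------------------------------
# fitting


def _loglik(beta: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    eta = X @ beta
    # log(p) = -log1p(exp(-eta)); log(1-p) = -log1p(exp(eta))
    return float(-(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)).sum())


def fit_logit(y: np.ndarray, X: pd.DataFrame, ridge: float = 0.0) -> FitResult:
    """Maximum-likelihood Bernoulli-logit fit of a named design matrix.

    ``ridge`` adds an optional quadratic penalty (off by default) as a
    documented deviation switch for completely separated simulated data; the
    covariance is then the inverse penalized Hessian.
    """
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise AnalysisError("design matrix is rank deficient")
    if ridge < 0:
        raise AnalysisError("ridge must be >= 0")

    if ridge == 0.0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, Xv, family=sm.families.Binomial())
            res = model.fit(maxiter=200, tol=1e-10)
        beta = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        loglik = _loglik(beta, y, Xv)
        converged = bool(res.converged)
    else:
        beta = np.zeros(Xv.shape[1])
        converged = False
        for _ in range(200):
            eta = Xv @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1 - p)
            grad = Xv.T @ (y - p) - ridge * beta
            hess = (Xv * w[:, None]).T @ Xv + ridge * np.eye(Xv.shape[1])
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                converged = True
                break
        cov = np.linalg.inv(hess)
        loglik = _loglik(beta, y, Xv)

    separation = bool(np.max(np.abs(beta)) > SEPARATION_THRESHOLD) or not converged
    return FitResult(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=loglik,
        converged=converged,
        separation=separation,
        nobs=len(y),
    )


def fit_model(
    table: pd.DataFrame, split_reliable: bool = False, ridge: float = 0.0
) -> FitResult:
    """Fit the no-intercept binomial-logit model to a prepared table."""
    if table.empty:
        raise AnalysisError("empty analysis table")
    if table["subject"].nunique() < 2:
        raise AnalysisError("need at least two subjects")
    y, X = build_design(table, split_reliable=split_reliable)
    return fit_logit(y, X, ridge=ridge)


def simulate_attacks(
    X: pd.DataFrame | np.ndarray, beta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw Bernoulli responses from the model form at known coefficients."""
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
    p = 1.0 / (1.0 + np.exp(-(Xv @ np.asarray(beta, dtype=float))))
    return (rng.random(len(p)) < p).astype(float)


# ---------------------------------------------------------------------------
# contrasts


def linear_contrast(
    fit: FitResult,
    weights: Mapping[str, float],
    label: str = "",
    level: float = 0.95,
) -> ContrastResult:
    """Estimate c'beta with its exact delta-method (Wald) standard error
    sqrt(c' Sigma c)."""
    missing = [k for k in weights if k not in fit.term_index]
    if missing:
        raise AnalysisError(f"terms not in the fitted model: {missing}")
    c = pd.Series(0.0, index=fit.params.index)
    for k, w in weights.items():
        c[k] = w
    estimate = float(c @ fit.params)
    se = float(np.sqrt(c @ fit.cov @ c))
    return ContrastResult.from_estimate(label, estimate, se, level)


def _experiments_in_fit(fit: FitResult) -> list[int]:
    return sorted(
        int(name[5:]) for name in fit.params.index
        if name.startswith("R:exp") and ":order" not in name
    )


_CONTRAST_WEIGHTS = {
    "reliable": (1.0, 0.0),
    "unreliable": (0.0, 1.0),
    "difference": (1.0, -1.0),
    "sum": (1.0, 1.0),
}


def trait_contrasts(
    fit: FitResult, level: float = 0.95
) -> dict[int, dict[str, ContrastResult]]:
    """Per experiment: both trait effects, their difference (relative use of
    the reliable trait), and their sum (total discrimination)."""
    out: dict[int, dict[str, ContrastResult]] = {}
    for e in _experiments_in_fit(fit):
        per: dict[str, ContrastResult] = {}
        for name, (wr, wu) in _CONTRAST_WEIGHTS.items():
            weights = {f"R:exp{e}": wr, f"U:exp{e}": wu}
            weights = {k: v for k, v in weights.items() if v != 0}
            per[name] = linear_contrast(fit, weights, label=f"{name} (exp {e})", level=level)
        out[e] = per
    return out


def summarize_effects(
    beta_reliable: float, beta_unreliable: float
) -> dict[str, ContrastResult]:
    """Contrast summary from two bare log-odds effects (no uncertainty):
    each effect, their difference, and their sum, with odds ratios."""
    return {
        "reliable": ContrastResult.from_estimate("reliable", beta_reliable),
        "unreliable": ContrastResult.from_estimate("unreliable", beta_unreliable),
        "difference": ContrastResult.from_estimate(
            "difference", beta_reliable - beta_unreliable
        ),
        "sum": ContrastResult.from_estimate("sum", beta_reliable + beta_unreliable),
    }


def round_sig(x: float, digits: int = 3) -> float:
    """Round to significant figures (as printed summaries do)."""
    if x == 0:
        return 0.0
    magnitude = int(np.floor(np.log10(abs(x))))
    return float(round(x, digits - 1 - magnitude))


# ---------------------------------------------------------------------------
# pairwise groupings


def _compact_letter_display(
    items: Sequence[int], significant: set[tuple[int, int]], order_by: Mapping[int, float]
) -> dict[int, str]:
    """Insert-and-absorb compact letter display.

    Two items share a letter iff no significant difference separates them.
    Items are processed in descending estimate order; ties broken by id.
    """
    ranked = sorted(items, key=lambda e: (-order_by[e], e))
    columns: list[set[int]] = [set(ranked)]
    for a, b in significant:
        for col in list(columns):
            if a in col and b in col:
                col_a = col - {b}
                col_b = col - {a}
                columns.remove(col)
                for new in (col_a, col_b):
                    if not any(new <= other for other in columns):
                        columns.append(new)
    # absorb: drop columns contained in another
    columns = [c for c in columns if not any(c < o for o in columns)]
    # letter assignment in a stable order
    columns.sort(key=lambda c: min(ranked.index(e) for e in c))
    letters: dict[int, str] = {e: "" for e in items}
    for i, col in enumerate(columns):
        letter = chr(ord("a") + i)
        for e in ranked:
            if e in col:
                letters[e] += letter
    return letters


def pairwise_groupings(
    fit: FitResult, kind: str = "difference", alpha: float = 0.05, level: float = 0.95
) -> GroupingResult:
    """All pairwise between-experiment comparisons of a within-experiment
    trait contrast, with Bonferroni-adjusted confidence intervals.

    The difference-of-differences for experiments (a, b) is a single linear
    function of coefficients, so its delta-method SE is exact.  Two
    experiments land in the same letter group iff the adjusted CI of their
    difference includes zero.
    """
    if kind not in _CONTRAST_WEIGHTS:
        raise AnalysisError(f"unknown contrast kind {kind!r}")
    wr, wu = _CONTRAST_WEIGHTS[kind]
    experiments = _experiments_in_fit(fit)
    if len(experiments) < 2:
        raise AnalysisError("need at least two experiments for pairwise comparisons")

    per_experiment = trait_contrasts(fit, level=level)
    estimates = {e: per_experiment[e][kind] for e in experiments}
    pairs = list(itertools.combinations(experiments, 2))
    m = len(pairs)
    adj_level = 1 - alpha / m

    rows = []
    significant: set[tuple[int, int]] = set()
    for a, b in pairs:
        weights: dict[str, float] = {}
        for term, w in ((f"R:exp{a}", wr), (f"U:exp{a}", wu)):
            if w:
                weights[term] = weights.get(term, 0.0) + w
        for term, w in ((f"R:exp{b}", -wr), (f"U:exp{b}", -wu)):
            if w:
                weights[term] = weights.get(term, 0.0) + w
        res = linear_contrast(fit, weights, label=f"{kind}: exp{a} - exp{b}", level=adj_level)
        lo, hi = res.ci
        sig = not (lo <= 0.0 <= hi)
        if sig:
            significant.add((a, b))
        rows.append(
            {
                "exp_a": a, "exp_b": b,
                "estimate": res.estimate, "se": res.se,
                "ci_lo": lo, "ci_hi": hi,
                "significant": sig,
            }
        )

    letters = _compact_letter_display(
        experiments, significant, {e: estimates[e].estimate for e in experiments}
    )
    return GroupingResult(
        estimates=estimates,
        pairwise=pd.DataFrame(rows),
        letters=letters,
        alpha=alpha,
        n_comparisons=m,
    )


# ---------------------------------------------------------------------------
# split-vs-lumped likelihood-ratio test


def split_value_lrt(
    table: pd.DataFrame, ridge: float = 0.0
) -> dict[str, float]:
    """Likelihood-ratio test: distinct focal reliable values vs the lumped
    good/bad recoding.

    Returns ``chi2 = 2 * (loglik_split - loglik_lumped)``, degrees of freedom
    computed structurally from the two parameterizations, and the chi-square
    p-value.  The split model nests the lumped one, so chi2 >= 0 up to
    numerical tolerance.
    """
    lumped = fit_model(table, split_reliable=False, ridge=ridge)
    split = fit_model(table, split_reliable=True, ridge=ridge)
    df = len(split.params) - len(lumped.params)
    if df <= 0:
        raise AnalysisError(
            "split model adds no parameters; need experiments with more than "
            "two focal reliable values"
        )
    chi2 = max(0.0, 2.0 * (split.loglik - lumped.loglik))
    return {
        "chi2": chi2,
        "df": float(df),
        "p": float(scipy.stats.chi2.sf(chi2, df)),
        "loglik_lumped": lumped.loglik,
        "loglik_split": split.loglik,
    }
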