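"""Inclusion rules, mixed-effects condition models, paired contrasts, FDR,
and the parental-stress covariate.

Coherence tables are modelled with a linear mixed model containing a random
intercept per dyad, fit by maximum likelihood (not REML) so that likelihood
ratio tests on fixed effects between nested models are valid.  Model
complexity grows stepwise: candidate terms (age, trial, data type, condition,
interactions) are added in a fixed order and retained only when the LRT
against the current best model reaches p < 0.05.  Post hoc condition
contrasts use one-sided paired t-tests on within-dyad differences — the
"paired Welch" phrasing common in this literature is internally inconsistent
(the Welch correction applies to unpaired samples), so the paired t on
differences is the default and an unpaired Welch variant is available — with
Benjamini–Hochberg FDR control across comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import (
    AlignmentError,
    DegenerateTestError,
    InvalidInputError,
    ModelSpecError,
)

#: Reference level for condition contrasts.
REFERENCE_CONDITION = "individual"

#: Stepwise candidate order used by the study design.
DEFAULT_CANDIDATE_TERMS = ("age", "trial", "ssr_applied", "condition")


# ---------------------------------------------------------------------------
# Inclusion rules
# ---------------------------------------------------------------------------

@dataclass
class InclusionDecision:
    dyad_id: str
    included: bool
    reasons: list[str] = field(default_factory=list)
    valid_rois: dict[str, list[str]] = field(default_factory=dict)  # role -> ROIs
    trials_per_condition: dict[str, int] = field(default_factory=dict)


def apply_inclusion(
    table: pd.DataFrame,
    roi_validity_by_dyad: dict[str, dict[str, dict[str, bool]]],
    min_trials: int = 2,
    min_valid_rois: int = 1,
) -> tuple[pd.DataFrame, list[InclusionDecision]]:
    """Filter a dyad coherence table by the cohort inclusion rules.

    A dyad is included iff every participant contributes at least one valid
    ROI (a ROI is valid with >= 2 valid long channels; validity is computed
    upstream and passed per dyad as role -> roi -> bool) and the dyad
    completed at least ``min_trials`` trials of every condition present.
    """
    decisions: list[InclusionDecision] = []
    kept: list[str] = []
    for dyad_id, sub in table.groupby("dyad_id", sort=True):
        reasons: list[str] = []
        validity = roi_validity_by_dyad.get(str(dyad_id), {})
        valid_rois = {
            role: [r for r, ok in rois.items() if ok] for role, rois in validity.items()
        }
        for role in ("child", "mother"):
            if len(valid_rois.get(role, [])) < min_valid_rois:
                reasons.append(f"{role} has <{min_valid_rois} valid ROI")
        trials = sub.groupby("condition")["trial"].nunique().to_dict()
        for cond, k in trials.items():
            if k < min_trials:
                reasons.append(f"<{min_trials} trials of {cond}")
        included = not reasons
        decisions.append(
            InclusionDecision(str(dyad_id), included, reasons, valid_rois, trials)
        )
        if included:
            kept.append(dyad_id)
    return table[table["dyad_id"].isin(kept)].copy(), decisions


# ---------------------------------------------------------------------------
# Mixed models and stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    formula: str
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    random_intercept_var: float
    llf: float
    n_obs: int
    n_fixed: int
    converged: bool


@dataclass
class LrtResult:
    term: str
    chi2: float
    df: int
    p: float
    retained: bool


def _condition_formula_term() -> str:
    return f"C(condition, Treatment('{REFERENCE_CONDITION}'))"


def _expand_term(term: str) -> str:
    # Categorical condition gets an explicit reference level.
    return term.replace("condition", _condition_formula_term())


def fit_mixed_model(
    table: pd.DataFrame,
    fixed_terms: tuple[str, ...] = ("condition",),
    response: str = "mean_wtc",
    group: str = "dyad_id",
) -> ModelFit:
    """Fit ``response ~ fixed_terms + (1 | group)`` by maximum likelihood."""
    if table[group].nunique() < 2:
        raise ModelSpecError("need at least two groups for a random intercept")
    rhs = " + ".join(_expand_term(t) for t in fixed_terms) if fixed_terms else "1"
    formula = f"{response} ~ {rhs}"
    data = table.dropna(subset=[response]).copy()
    res = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.mixedlm(formula, data, groups=data[group])
        # Variance components on the boundary can break individual
        # optimisers; fall through a small sequence before giving up.
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            # A degenerate profile (zero residual variance) shows up as a
            # non-finite likelihood or non-finite coefficients: keep trying.
            if np.isfinite(cand.llf) and np.all(np.isfinite(np.asarray(cand.fe_params))):
                res = cand
                break
            last_exc = ModelSpecError(f"non-finite likelihood with {method}")
    if res is None:
        raise ModelSpecError(str(last_exc))
    if np.any(~np.isfinite(list(res.fe_params))):
        raise ModelSpecError("non-finite fixed-effect estimates")
    fe = list(res.fe_params.index)
    return ModelFit(
        formula=formula,
        params={k: float(res.fe_params[k]) for k in fe},
        bse={k: float(res.bse[k]) for k in fe},
        pvalues={k: float(res.pvalues[k]) for k in fe},
        random_intercept_var=float(np.squeeze(res.cov_re)),
        llf=float(res.llf),
        n_obs=int(res.nobs),
        n_fixed=len(fe),
        converged=bool(res.converged),
    )


def likelihood_ratio_test(null: ModelFit, alt: ModelFit, term: str = "") -> LrtResult:
    """LRT between nested ML fits; df = fixed-parameter count difference."""
    df = alt.n_fixed - null.n_fixed
    if df < 0:
        raise ModelSpecError("models are not nested in the stated order")
    chi2 = max(0.0, 2.0 * (alt.llf - null.llf))
    p = 1.0 if df == 0 else float(sps.chi2.sf(chi2, df))
    return LrtResult(term=term, chi2=chi2, df=df, p=p, retained=p < 0.05)


def stepwise_lrt(
    table: pd.DataFrame,
    candidate_terms: tuple[str, ...] = DEFAULT_CANDIDATE_TERMS,
    response: str = "mean_wtc",
    group: str = "dyad_id",
    alpha: float = 0.05,
) -> tuple[ModelFit, list[LrtResult]]:
    """Grow the model stepwise from the null ``response ~ (1 | group)``.

    Each candidate term is tested by LRT against the current best model and
    retained iff p < alpha.  Terms missing from the table, or constant in it,
    are skipped (recorded with chi2 = 0, retained = False).
    """
    best_terms: list[str] = []
    best = fit_mixed_model(table, tuple(best_terms), response, group)
    history: list[LrtResult] = []
    for term in candidate_terms:
        base_col = term.split(":")[0].split("*")[0]
        if base_col not in table.columns or table[base_col].nunique() <= 1:
            history.append(LrtResult(term=term, chi2=0.0, df=0, p=1.0, retained=False))
            continue
        candidate = fit_mixed_model(table, tuple(best_terms + [term]), response, group)
        lrt = likelihood_ratio_test(best, candidate, term)
        history.append(lrt)
        if lrt.retained:
            best_terms.append(term)
            best = candidate
    return best, history


def condition_effects(fit: ModelFit) -> dict[str, tuple[float, float, float]]:
    """Extract (beta, SE, p) of each non-reference condition from a fit."""
    out = {}
    for name, beta in fit.params.items():
        if name.startswith("C(condition"):
            level = name.split("[T.")[-1].rstrip("]")
            out[level] = (beta, fit.bse[name], fit.pvalues[name])
    return out


# ---------------------------------------------------------------------------
# Paired contrasts and FDR
# ---------------------------------------------------------------------------

def paired_onesided_test(
    a: np.ndarray,
    b: np.ndarray,
    alternative: str = "greater",
    paired: bool = True,
) -> tuple[float, float, float]:
    """One-sided test of ``a`` vs ``b`` aligned by dyad.

    Paired (default): t = mean(d) / (sd(d)/sqrt(n)) on d = a - b with
    df = n - 1.  ``paired=False`` falls back to the unpaired Welch test.
    Returns (t, df, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AlignmentError("paired test requires equal-length 1-D samples")
    if a.size < 3:
        raise InvalidInputError("need at least three pairs")
    if alternative not in {"greater", "less"}:
        raise InvalidInputError(f"unknown alternative {alternative!r}")
    if not paired:
        res = sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
        return float(res.statistic), float(res.df), float(res.pvalue)
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("all within-dyad differences identical")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = float(sps.t.sf(t, df) if alternative == "greater" else sps.t.cdf(t, df))
    return float(t), float(df), p


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Parental Stress Scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PssScore:
    total: int
    outlier: bool = False


def pss_score(items: list[int] | np.ndarray) -> PssScore:
    """Sum an 18-item, 1-5 Likert parental-stress questionnaire (range 18-90)."""
    items = np.asarray(items)
    if items.shape != (18,):
        raise InvalidInputError("expected exactly 18 items")
    if np.any(~np.isfinite(items.astype(float))) or np.any((items < 1) | (items > 5)):
        raise InvalidInputError("items must be integers in 1..5")
    return PssScore(total=int(items.sum()))


def pss_outlier_filter(scores: list[PssScore] | list[int], n_sd: float = 2.0) -> list[PssScore]:
    """Flag cohort-level outliers beyond mean +/- n_sd standard deviations.

    Flags are computed on the full sample before any modelling, matching the
    convention of removing extreme questionnaire totals prior to analysis.
    """
    totals = np.array([s.total if isinstance(s, PssScore) else int(s) for s in scores], float)
    mu, sd = totals.mean(), totals.std(ddof=1) if totals.size > 1 else 0.0
    lo, hi = mu - n_sd * sd, mu + n_sd * sd
    return [PssScore(int(t), bool(t < lo or t > hi)) for t in totals]
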