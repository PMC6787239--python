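"""Case-control statistics linking microcalcification clusters to risk.

The cluster count per woman enters a logistic regression for case-control
status alongside established risk factors (age, BMI, percent density, HRT,
parity, smoking, diabetes, age at menopause). Model discrimination is
internally validated with Harrell's bootstrap optimism correction ("honest"
AUC). A separate scan fits age-adjusted models of cluster presence
(0 vs 1+) on healthy controls, one risk factor at a time.

Conventions: odds ratios are exp(coefficient); 95% CIs are Wald intervals
exp(b +/- 1.96 se); per-term p-values come from likelihood-ratio tests
(chi-square difference of deviances, df = number of columns the term spans).
Reference levels: HRT = never, smoking = never, diabetes = no,
breastfeeding = never. Each model is fitted on its own complete cases.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .types import SubjectRecord

__all__ = [
    "FitResult",
    "SeparationError",
    "records_to_frame",
    "fit_logistic",
    "build_reproductive_covariate",
    "add_reproductive_covariate",
    "honest_auc",
    "HonestAUC",
    "riskfactor_scan",
    "or_for_difference",
    "descriptive_table",
    "RISK_MODEL_COVARIATES",
]

#: default reference level for each categorical covariate
CATEGORICAL_REFERENCES = {
    "hrt": "never",
    "smoking": "never",
    "diabetes": "no",
    "breastfeeding": "never",
    "repro9": "nulliparous",
}

#: adjustment set of the primary risk model (plus mcc_total as the exposure)
RISK_MODEL_COVARIATES = [
    "age_yr",
    "bmi_kg_m2",
    "pd_percent",
    "hrt",
    "parity",
    "smoking",
    "diabetes",
    "age_menopause_yr",
]


class SeparationError(ValueError):
    """Raised when the likelihood is unbounded (perfectly separated data)."""


@dataclass
class FitResult:
    """Logistic-regression fit summary.

    ``table`` is indexed by coefficient name with columns ``coef``, ``se``,
    ``odds_ratio``, ``ci_low``, ``ci_high``; ``lrt_p`` maps each covariate
    term (possibly spanning several coefficients) to its likelihood-ratio
    p-value.
    """

    table: pd.DataFrame
    lrt_p: dict[str, float]
    log_likelihood: float
    n_used: int

    def odds_ratio(self, name: str) -> float:
        return float(self.table.loc[name, "odds_ratio"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Flatten SubjectRecords into the analysis DataFrame."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.subject_id,
                "status": r.status,
                "is_case": r.is_case,
                "age_yr": r.age_yr,
                "bmi_kg_m2": r.bmi_kg_m2,
                "pd_percent": r.pd_percent,
                "hrt": r.hrt,
                "parity": r.parity,
                "smoking": r.smoking,
                "diabetes": r.diabetes,
                "age_menopause_yr": r.age_menopause_yr,
                "breastfeeding": r.breastfeeding,
                "breastfeeding_months": r.breastfeeding_months,
                "age_first_birth_yr": r.age_first_birth_yr,
                "mcc_left": r.mcc_left,
                "mcc_right": r.mcc_right,
                "mcc_total": r.mcc_total,
            }
        )
    return pd.DataFrame(rows)


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return records_to_frame(data)


def _is_categorical(series: pd.Series) -> bool:
    return series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype) or series.dtype == bool


def _build_design(
    df: pd.DataFrame,
    covariates: Sequence[str],
    references: Optional[dict[str, str]] = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-encode covariates with fixed reference levels.

    Returns the design matrix (with constant) and a map from covariate term
    to the design columns it spans.
    """
    refs = dict(CATEGORICAL_REFERENCES)
    if references:
        refs.update(references)
    cols: dict[str, np.ndarray] = {}
    term_columns: dict[str, list[str]] = {}
    for cov in covariates:
        s = df[cov]
        if _is_categorical(s):
            levels = [lv for lv in pd.unique(s.dropna())]
            ref = refs.get(cov)
            if ref is None or ref not in levels:
                ref = sorted(map(str, levels))[0]
            others = sorted(str(lv) for lv in levels if str(lv) != str(ref))
            names = []
            for lv in others:
                name = f"{cov}[{lv}]"
                cols[name] = (s.astype(str) == lv).to_numpy(dtype=float)
                names.append(name)
            term_columns[cov] = names
        else:
            cols[cov] = s.to_numpy(dtype=float)
            term_columns[cov] = [cov]
    X = pd.DataFrame(cols, index=df.index)
    X.insert(0, "const", 1.0)
    return X, term_columns


def _fit_mle(y: np.ndarray, X: pd.DataFrame):
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("singular design matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(method="newton", disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # Newton's Hessian degenerates when the likelihood is unbounded
            # (separation); a gradient method still walks far enough to flag it
            fit = sm.Logit(y, X).fit(method="bfgs", disp=0, maxiter=500)
        except Exception as exc:  # statsmodels' own separation error
            if "erfect" in type(exc).__name__ or "erfect" in str(exc):
                raise SeparationError(str(exc)) from exc
            raise
    params = np.asarray(fit.params, dtype=float)
    if np.any(np.abs(params[1:]) > 25):
        worst = X.columns[1:][int(np.argmax(np.abs(params[1:])))]
        raise SeparationError(f"perfect separation detected for covariate '{worst}'")
    return fit


def fit_logistic(
    data,
    outcome: str,
    covariates: Sequence[str],
    references: Optional[dict[str, str]] = None,
    lrt: bool = True,
) -> FitResult:
    """Maximum-likelihood logistic regression with per-term LRT p-values.

    ``data`` is a DataFrame or an iterable of :class:`SubjectRecord`;
    ``outcome`` names a 0/1 column (``is_case`` is derived from ``status``
    automatically for records). Rows with missing values in the outcome or
    any covariate are dropped (complete-case analysis). ``lrt=False`` skips
    the per-term reduced-model refits (useful in simulation loops where only
    the coefficients are needed).
    """
    df = _as_frame(data)
    if outcome == "is_case" and "is_case" not in df.columns and "status" in df.columns:
        df = df.assign(is_case=(df["status"] == "case").astype(int))
    used = df[[outcome, *covariates]].dropna()
    y = used[outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    X, term_columns = _build_design(used, covariates, references)
    n_params = X.shape[1]
    if len(used) < 10 * n_params:
        warnings.warn(
            f"only {len(used)} complete cases for {n_params} parameters "
            "(< 10 events per parameter guideline)",
            UserWarning,
            stacklevel=2,
        )
    fit = _fit_mle(y, X)
    params = pd.Series(np.asarray(fit.params, dtype=float), index=X.columns)
    se = pd.Series(np.asarray(fit.bse, dtype=float), index=X.columns)
    table = pd.DataFrame(
        {
            "coef": params,
            "se": se,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - 1.96 * se),
            "ci_high": np.exp(params + 1.96 * se),
        }
    )
    lrt_p: dict[str, float] = {}
    if lrt:
        for term, names in term_columns.items():
            if not names:  # categorical term collapsed to its reference only
                lrt_p[term] = float("nan")
                continue
            X_red = X.drop(columns=names)
            fit_red = _fit_mle(y, X_red)
            stat = 2.0 * (fit.llf - fit_red.llf)
            lrt_p[term] = float(sps.chi2.sf(max(stat, 0.0), df=len(names)))
    return FitResult(
        table=table,
        lrt_p=lrt_p,
        log_likelihood=float(fit.llf),
        n_used=int(len(used)),
    )


# ---------------------------------------------------------------------------
# 9-level reproductive covariate
# ---------------------------------------------------------------------------

#: age-at-first-birth strata (years) for parous women
AFB_CUTPOINTS = (23.0, 27.0)

REPRO9_LEVELS = (
    "nulliparous",
    "parous_bfnever_afb<23",
    "parous_bfnever_afb23-27",
    "parous_bfnever_afb>27",
    "parous_bfever_afb<23",
    "parous_bfever_afb23-27",
    "parous_bfever_afb>27",
    "parous_bfnever_afbmissing",
    "parous_bfever_afbmissing",
)


def build_reproductive_covariate(
    parity: int,
    breastfeeding: Optional[str],
    age_first_birth: Optional[float],
) -> Optional[str]:
    """Combine parity, breastfeeding and age at first birth into 9 levels.

    Nulliparous women form their own level regardless of the other fields.
    Parous women are cross-classified by breastfeeding (never/ever) and
    age-at-first-birth stratum (<23, 23-27, >27, or missing). Parous women
    with missing breastfeeding status cannot be classified and get ``None``
    (flagged for complete-case exclusion).
    """
    if parity is None or (isinstance(parity, float) and np.isnan(parity)):
        raise ValueError("parity must be known")
    if parity == 0:
        return "nulliparous"
    if breastfeeding is None or (isinstance(breastfeeding, float) and np.isnan(breastfeeding)):
        return None
    bf = "bfnever" if breastfeeding == "never" else "bfever"
    if age_first_birth is None or (isinstance(age_first_birth, float) and np.isnan(age_first_birth)):
        return f"parous_{bf}_afbmissing"
    lo, hi = AFB_CUTPOINTS
    if age_first_birth < lo:
        stratum = f"afb<{lo:.0f}"
    elif age_first_birth <= hi:
        stratum = f"afb{lo:.0f}-{hi:.0f}"
    else:
        stratum = f"afb>{hi:.0f}"
    return f"parous_{bf}_{stratum}"


def add_reproductive_covariate(df: pd.DataFrame, column: str = "repro9") -> pd.DataFrame:
    """Return a copy of ``df`` with the 9-level covariate (None -> NaN)."""
    out = df.copy()
    out[column] = [
        build_reproductive_covariate(p, bf, afb)
        for p, bf, afb in zip(df["parity"], df["breastfeeding"], df["age_first_birth_yr"])
    ]
    return out


# ---------------------------------------------------------------------------
# Honest (optimism-corrected) AUC
# ---------------------------------------------------------------------------


class HonestAUC(NamedTuple):
    apparent: float
    optimism: float
    honest: float


def honest_auc(
    data,
    covariates: Sequence[str],
    outcome: str = "is_case",
    n_boot: int = 1000,
    seed: int = 0,
    references: Optional[dict[str, str]] = None,
) -> HonestAUC:
    """Bootstrap optimism-corrected c-statistic (Harrell internal validation).

    The apparent AUC is the c-statistic of the model fitted and evaluated on
    the full data. For each bootstrap resample the model is refitted and the
    optimism is the AUC on the resample minus the AUC of the same model
    evaluated on the original data; the honest AUC is the apparent AUC minus
    the mean optimism. Ties contribute 1/2. Fully determined by ``seed``.
    Resamples on which the fit fails (single outcome class, separation,
    non-convergence) are redrawn, up to ``5 * n_boot`` attempts.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    df = _as_frame(data)
    if outcome == "is_case" and "is_case" not in df.columns and "status" in df.columns:
        df = df.assign(is_case=(df["status"] == "case").astype(int))
    used = df[[outcome, *covariates]].dropna()
    y = used[outcome].to_numpy(dtype=float)
    X, _ = _build_design(used, covariates, references)
    Xv = X.to_numpy(dtype=float)

    # degenerate case: a covariate that reproduces the outcome exactly gives
    # an unbounded likelihood but a well-defined c-statistic of 1
    for j in range(1, Xv.shape[1]):
        col = Xv[:, j]
        if len(np.unique(col)) > 1:
            a = roc_auc_score(y, col)
            if a in (0.0, 1.0):
                return HonestAUC(apparent=1.0, optimism=0.0, honest=1.0)

    def _auc_of_fit(y_fit, X_fit):
        fit = _fit_mle(y_fit, pd.DataFrame(X_fit, columns=X.columns))
        return np.asarray(fit.params, dtype=float)

    beta_full = _auc_of_fit(y, Xv)
    apparent = float(roc_auc_score(y, Xv @ beta_full))

    rng = np.random.default_rng(seed)
    n = len(y)
    optimisms: list[float] = []
    attempts = 0
    while len(optimisms) < n_boot:
        attempts += 1
        if attempts > 5 * n_boot:
            raise RuntimeError("too many failed bootstrap fits")
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        try:
            beta = _auc_of_fit(yb, Xv[idx])
        except (SeparationError, ValueError):
            continue
        auc_boot = roc_auc_score(yb, Xv[idx] @ beta)
        auc_orig = roc_auc_score(y, Xv @ beta)
        optimisms.append(float(auc_boot - auc_orig))
    optimism = float(np.mean(optimisms))
    return HonestAUC(apparent=apparent, optimism=optimism, honest=apparent - optimism)


# ---------------------------------------------------------------------------
# Age-adjusted risk-factor scan on controls
# ---------------------------------------------------------------------------


def riskfactor_scan(
    data,
    factors: Sequence[str],
    age_col: str = "age_yr",
    alpha: float = 0.05,
    family_size: Optional[int] = None,
) -> pd.DataFrame:
    """Association of risk factors with cluster presence among controls.

    The outcome is the binary indicator of having at least one
    microcalcification cluster (``mcc_total >= 1``). One age-adjusted
    logistic model is fitted per factor (the age model itself is unadjusted);
    each uses its own complete cases. Returns one row per reported
    coefficient with the factor-level likelihood-ratio p-value and a
    Bonferroni flag at family size ``family_size`` (default: number of
    factors supplied).
    """
    df = _as_frame(data)
    if "status" in df.columns and (df["status"] != "control").any():
        raise ValueError("riskfactor_scan expects controls only")
    df = df.assign(mcc_pos=(df["mcc_total"] >= 1).astype(int))
    if df["mcc_pos"].nunique() < 2:
        raise ValueError("outcome has a single class (no or all cluster-positive women)")
    family = family_size if family_size is not None else len(factors)
    rows = []
    for factor in factors:
        sub_cols = ["mcc_pos", age_col] if factor == age_col else ["mcc_pos", age_col, factor]
        sub = df[list(dict.fromkeys(sub_cols))].dropna()
        if factor in sub.columns and sub[factor].nunique() < 2:
            warnings.warn(f"factor '{factor}' is constant in controls; skipped", UserWarning)
            continue
        covs = [age_col] if factor == age_col else [age_col, factor]
        res = fit_logistic(sub, "mcc_pos", covs)
        names = [c for c in res.table.index if c == factor or c.startswith(f"{factor}[")]
        p = res.lrt_p[factor]
        for name in names:
            lo, hi = res.ci(name)
            rows.append(
                {
                    "factor": factor,
                    "term": name,
                    "odds_ratio": res.odds_ratio(name),
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_lrt": p,
                    "n": res.n_used,
                    "bonferroni_significant": bool(p < alpha / family),
                }
            )
    return pd.DataFrame(rows)


def or_for_difference(or_per_unit: float, delta: float) -> float:
    """Odds ratio for a ``delta``-unit difference given a per-unit OR.

    ``exp(delta * log(or_per_unit))`` — e.g. the odds ratio between women
    differing by 75 percentage points of density, given the per-point OR.
    """
    return float(np.exp(delta * np.log(or_per_unit)))


def descriptive_table(data) -> pd.DataFrame:
    """Case/control descriptive summary with unadjusted LRT p-values.

    Continuous covariates are summarised as mean (sd) and tested with a
    single-covariate logistic model; categoricals as counts (%) per level
    with a term-level LRT.
    """
    df = _as_frame(data)
    if "is_case" not in df.columns:
        df = df.assign(is_case=(df["status"] == "case").astype(int))
    continuous = [
        "age_yr", "bmi_kg_m2", "pd_percent", "parity",
        "age_first_birth_yr", "breastfeeding_months", "age_menopause_yr",
    ]
    categorical = ["hrt", "smoking", "breastfeeding", "diabetes"]
    rows = []
    for cov in continuous + categorical:
        if cov not in df.columns:
            continue
        sub = df[["is_case", cov]].dropna()
        try:
            p = fit_logistic(sub, "is_case", [cov]).lrt_p[cov]
        except ValueError:
            p = float("nan")
        if cov in continuous:
            for grp, label_ in ((1, "cases"), (0, "controls")):
                vals = sub.loc[sub["is_case"] == grp, cov]
                rows.append({"covariate": cov, "level": "", "group": label_,
                             "summary": f"{vals.mean():.3f} (±{vals.std():.3f})", "p": p})
        else:
            for grp, label_ in ((1, "cases"), (0, "controls")):
                vals = sub.loc[sub["is_case"] == grp, cov]
                counts = vals.value_counts()
                for level, cnt in counts.items():
                    rows.append({
                        "covariate": cov, "level": str(level), "group": label_,
                        "summary": f"{cnt} ({100 * cnt / len(vals):.1f}%)", "p": p,
                    })
    return pd.DataFrame(rows)
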