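"""Statistical evaluation of fatigue indicators against subjective fatigue.

The centrepiece is a three-level linear mixed model for the FSS-S raw score:
measurement occasions (level 1) nested in rested/drowsy condition sessions
(level 2) nested in subjects (level 3), with random intercepts at levels 2 and
3 and maximum-likelihood estimation,

    fss_s_ijk = b0 + b1*time_ijk [+ b2*indicator_ijk] + u_i + v_ij + e_ijk,

where u_i ~ N(0, var_subject), v_ij ~ N(0, var_condition), e_ijk ~
N(0, var_residual).  :class:`SubjectiveFatigueModel` specifies and fits the
model (estimation delegates to statsmodels' MixedLM); the surrounding
quantities — intraclass correlations, Nakagawa marginal/conditional R²,
per-level delta R², and likelihood-ratio model comparison — are computed here.

Also provided: paired t-tests with a dependent-samples Cohen's d, and ROC
analysis with a stratified percentile-bootstrap confidence interval and a
Youden-optimal threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsError",
    "DegenerateDataError",
    "PairedTestResult",
    "RocResult",
    "ModelFit",
    "FatigueModelResults",
    "ModelComparison",
    "SubjectiveFatigueModel",
    "paired_test",
    "roc_analysis",
    "fit_three_level",
    "icc",
    "r2_nakagawa",
    "delta_r2",
    "compare_models",
]


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


class DegenerateDataError(StatsError):
    """Data without the variation the requested statistic needs."""


# ---------------------------------------------------------------------------
# paired comparison

@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    d: float


def paired_test(
    pre: Sequence[float], post: Sequence[float], method: str = "dunlap"
) -> PairedTestResult:
    """Paired Student's t-test with a dependent-samples effect size.

    ``t`` is the one-sample t on the differences ``post - pre`` with
    ``df = n - 1``.  Cohen's d for dependent samples uses, by default, the
    correlation-corrected form d = t * sqrt(2 (1 - r) / n) (with r the
    pre/post correlation), which reduces to mean difference over the common
    SD when the two occasions share a standard deviation.  ``method="dz"``
    instead divides the mean difference by the SD of the differences.
    """
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if pre.shape != post.shape or pre.ndim != 1:
        raise StatsError("pre and post must be equal-length 1-D samples")
    n = len(pre)
    if n < 2:
        raise StatsError("paired test needs at least two pairs")
    diff = post - pre
    sd_diff = float(np.std(diff, ddof=1))
    if sd_diff == 0.0:
        if float(np.mean(diff)) == 0.0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, d=0.0)
        raise DegenerateDataError("differences have zero variance")
    t = float(np.mean(diff) / (sd_diff / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    if method == "dz":
        d = float(np.mean(diff) / sd_diff)
    elif method == "dunlap":
        sd_pre = float(np.std(pre, ddof=1))
        sd_post = float(np.std(post, ddof=1))
        if sd_pre == 0.0 or sd_post == 0.0:
            raise DegenerateDataError("a measurement occasion has zero variance")
        r = float(np.corrcoef(pre, post)[0, 1])
        d = float(t * math.sqrt(2.0 * (1.0 - r) / n))
    else:
        raise StatsError(f"unknown effect-size method {method!r}")
    return PairedTestResult(t=t, df=n - 1, p=p, d=d)


# ---------------------------------------------------------------------------
# ROC

@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    optimal_threshold: float
    sensitivity: float
    specificity: float
    n_boot: int


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formula; ties count one half."""
    scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(scores)
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC analysis treating higher scores as evidence for the positive class.

    AUC is computed by the Mann-Whitney rank formula; the 95% confidence
    interval is a stratified (within-class) percentile bootstrap.  The
    operating threshold maximises Youden's J = sensitivity + specificity - 1
    over midpoints between adjacent distinct scores, predicting positive for
    scores strictly above the threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise StatsError("scores and labels must be equal-length 1-D arrays")
    if n_boot < 1:
        raise StatsError("n_boot must be at least 1")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise StatsError("both classes must be present")
    auc = _rank_auc(pos, neg)

    distinct = np.unique(scores)
    if len(distinct) > 1:
        candidates = (distinct[:-1] + distinct[1:]) / 2.0
    else:
        candidates = distinct
    best = None
    for thr in candidates:
        sens = float(np.mean(pos > thr))
        spec = float(np.mean(neg <= thr))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    _, thr, sens, spec = best

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        boots[b] = _rank_auc(bp, bn)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(
        auc=auc,
        ci_low=float(lo),
        ci_high=float(hi),
        optimal_threshold=float(thr),
        sensitivity=sens,
        specificity=spec,
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# three-level mixed model

@dataclass(frozen=True)
class ModelFit:
    """Estimates from one three-level model fit.

    ``fixed_effects`` maps effect name to ``(estimate, standard_error)``;
    the three variance components are on the response scale; ``aic``
    satisfies ``aic = 2 * n_params - 2 * loglik``.
    """

    name: str
    fixed_effects: dict
    var_subject: float
    var_condition: float
    var_residual: float
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_obs: Optional[int] = None
    fixed_effect_variance: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.var_subject, self.var_condition, self.var_residual) < 0:
            raise StatsError("variance components must be non-negative")
        if not math.isclose(self.aic, 2 * self.n_params - 2 * self.loglik, rel_tol=1e-9, abs_tol=1e-6):
            raise StatsError("aic inconsistent with n_params and loglik")

    @classmethod
    def from_minus2ll(
        cls, name: str, minus2ll: float, n_params: int, aic: Optional[float] = None, **kw
    ) -> "ModelFit":
        """Build a comparison-only fit from a reported -2 log-likelihood."""
        defaults = dict(
            fixed_effects={}, var_subject=0.0, var_condition=0.0, var_residual=0.0,
            converged=True,
        )
        defaults.update(kw)
        return cls(
            name=name,
            loglik=-minus2ll / 2.0,
            aic=aic if aic is not None else 2 * n_params + minus2ll,
            n_params=n_params,
            **defaults,
        )

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.loglik

    def summary(self) -> str:
        lines = [
            f"Three-level mixed model: {self.name}",
            f"  N obs: {self.n_obs}   log-likelihood: {self.loglik:.3f}   "
            f"AIC: {self.aic:.2f}   params: {self.n_params}   converged: {self.converged}",
            "  Fixed effects (estimate, SE, z, p):",
        ]
        for name, (est, se) in self.fixed_effects.items():
            if se and se > 0:
                z = est / se
                p = 2.0 * sps.norm.sf(abs(z))
                lines.append(f"    {name:<18} {est:>10.3f} {se:>8.3f} {z:>7.3f} {p:>8.4f}")
            else:
                lines.append(f"    {name:<18} {est:>10.3f}")
        lines += [
            "  Variance components:",
            f"    level 3 subjects            {self.var_subject:>10.2f}",
            f"    level 2 condition sessions  {self.var_condition:>10.2f}",
            f"    level 1 residual            {self.var_residual:>10.2f}",
        ]
        return "\n".join(lines)


#: Results alias in the Model/Results idiom; `SubjectiveFatigueModel.fit()` returns this.
FatigueModelResults = ModelFit


class SubjectiveFatigueModel:
    """Three-level mixed model of FSS-S raw scores.

    Parameters
    ----------
    data
        Tidy table with one row per subject x condition x occasion.
    predictors
        Subset of ``{"time", "indicator"}`` entering as fixed effects.  The
        indicator column is z-standardised over all rows before entry.
    indicator_col
        Which indicator column feeds the ``indicator`` predictor.
    """

    REQUIRED = ("subject", "condition", "occasion")

    def __init__(
        self,
        data: pd.DataFrame,
        predictors: Sequence[str] = (),
        response: str = "fss_s",
        indicator_col: str = "indicator",
        name: Optional[str] = None,
    ):
        unknown = set(predictors) - {"time", "indicator"}
        if unknown:
            raise StatsError(f"unknown predictors: {sorted(unknown)}")
        needed = list(self.REQUIRED) + [response]
        if "indicator" in predictors:
            needed.append(indicator_col)
        missing = [c for c in needed if c not in data.columns]
        if missing:
            raise StatsError(f"missing required columns: {missing}")
        if data["subject"].nunique() < 2:
            raise StatsError("need at least two subjects")
        y = data[response].to_numpy(dtype=np.float64)
        if np.std(y) == 0.0:
            raise DegenerateDataError(f"response column {response!r} is constant")
        self.data = data
        self.predictors = tuple(predictors)
        self.response = response
        self.indicator_col = indicator_col
        self.name = name or ("M:" + "+".join(("intercept",) + self.predictors))

        d = pd.DataFrame(
            {
                "y": y,
                "subject": data["subject"].to_numpy(),
                "cond": data["condition"].astype(str).to_numpy(),
                "time": data["occasion"].to_numpy(dtype=np.float64),
            }
        )
        if "indicator" in predictors:
            ind = data[indicator_col].to_numpy(dtype=np.float64)
            sd = ind.std(ddof=0)
            if sd == 0.0:
                raise DegenerateDataError(f"indicator column {indicator_col!r} is constant")
            d["ind"] = (ind - ind.mean()) / sd
        self._frame = d

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "SubjectiveFatigueModel":
        return cls(data, **kwargs)

    def fit(self, method: str = "lbfgs", maxiter: int = 2000) -> FatigueModelResults:
        """Fit by maximum likelihood; returns a :class:`FatigueModelResults`."""
        import statsmodels.formula.api as smf
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        terms = ["1"]
        if "time" in self.predictors:
            terms.append("time")
        if "indicator" in self.predictors:
            terms.append("ind")
        formula = "y ~ " + " + ".join(terms)
        md = smf.mixedlm(
            formula,
            self._frame,
            groups="subject",
            re_formula="1",
            vc_formula={"cond": "0 + C(cond)"},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = md.fit(reml=False, method=method, maxiter=maxiter)
        rename = {"Intercept": "intercept", "time": "time", "ind": "indicator"}
        fe = {
            rename.get(k, k): (float(res.fe_params[k]), float(res.bse_fe[k]))
            for k in res.fe_params.index
        }
        var_subject = float(res.cov_re.iloc[0, 0])
        var_condition = float(res.vcomp[0])
        var_residual = float(res.scale)
        n_params = len(fe) + 3
        loglik = float(res.llf)
        X = np.column_stack(
            [np.ones(len(self._frame))]
            + [self._frame[t].to_numpy() for t in terms if t != "1"]
        )
        linpred = X @ res.fe_params.to_numpy()
        return FatigueModelResults(
            name=self.name,
            fixed_effects=fe,
            var_subject=max(var_subject, 0.0),
            var_condition=max(var_condition, 0.0),
            var_residual=var_residual,
            loglik=loglik,
            aic=2 * n_params - 2 * loglik,
            n_params=n_params,
            converged=bool(res.converged),
            n_obs=len(self._frame),
            fixed_effect_variance=float(np.var(linpred)),
        )


def fit_three_level(
    data: pd.DataFrame,
    predictors: Sequence[str] = (),
    indicator_col: str = "indicator",
    **kwargs,
) -> FatigueModelResults:
    """Specify and fit a three-level model in one call."""
    return SubjectiveFatigueModel(
        data, predictors=predictors, indicator_col=indicator_col, **kwargs
    ).fit()


# ---------------------------------------------------------------------------
# variance decomposition

def icc(fit: ModelFit) -> tuple[float, float]:
    """Intraclass correlations ``(icc_level2, icc_level3)`` of an intercept-only fit.

    Level 2 is the condition-session share, level 3 the subject share, each
    relative to the total variance across all three levels.
    """
    extra = [k for k in fit.fixed_effects if k != "intercept"]
    if extra:
        raise StatsError(f"ICCs are defined on the intercept-only model; fit has {extra}")
    total = fit.var_subject + fit.var_condition + fit.var_residual
    if total == 0.0:
        raise DegenerateDataError("all variance components are zero")
    return fit.var_condition / total, fit.var_subject / total


def r2_nakagawa(
    fit: ModelFit, fixed_effect_variance: Optional[float] = None
) -> tuple[float, float]:
    """Marginal and conditional R² for a mixed model.

    marginal = sf2 / (sf2 + var_subject + var_condition + var_residual);
    conditional adds the random-intercept variances to the numerator.  ``sf2``
    is the variance of the fixed-effect linear predictor, taken from the fit
    unless supplied explicitly.
    """
    sf2 = fixed_effect_variance if fixed_effect_variance is not None else fit.fixed_effect_variance
    if sf2 is None:
        raise StatsError("fixed_effect_variance unavailable on this fit")
    if sf2 < 0:
        raise StatsError("fixed_effect_variance must be non-negative")
    denom = sf2 + fit.var_subject + fit.var_condition + fit.var_residual
    if denom == 0.0:
        raise DegenerateDataError("total variance is zero")
    marginal = sf2 / denom
    conditional = (sf2 + fit.var_subject + fit.var_condition) / denom
    return marginal, conditional


def delta_r2(fit_ref: ModelFit, fit_new: ModelFit) -> dict:
    """Per-level proportional variance change between nested fits.

    For each level, ``(var_ref - var_new) / var_ref``; negative values (a
    variance increase) are reported as-is, and a level with zero reference
    variance yields ``None``.
    """
    if fit_ref.n_obs is not None and fit_new.n_obs is not None and fit_ref.n_obs != fit_new.n_obs:
        raise StatsError("fits are not on the same data")
    out = {}
    for level, ref, new in (
        ("subject", fit_ref.var_subject, fit_new.var_subject),
        ("condition", fit_ref.var_condition, fit_new.var_condition),
        ("residual", fit_ref.var_residual, fit_new.var_residual),
    ):
        out[level] = None if ref == 0.0 else (ref - new) / ref
    return out


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio comparison table over an ordered nested model sequence."""

    table: pd.DataFrame

    def summary(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.3f}")


def compare_models(
    fits: Sequence[ModelFit], references: Optional[Sequence[Optional[int]]] = None
) -> ModelComparison:
    """Compare an ordered sequence of nested model fits.

    ``references[i]`` names the index of the fit that fit ``i`` is tested
    against with a likelihood-ratio chi-square (df = parameter difference).
    The default mirrors the evaluation workflow: the second model is tested
    against the first (adding the time trend), every later model against the
    second (each adding one indicator).
    """
    if len(fits) < 2:
        raise StatsError("need at least two fits to compare")
    if references is None:
        references = [None, 0] + [1] * (len(fits) - 2)
    if len(references) != len(fits):
        raise StatsError("references must align with fits")
    n_obs = {f.n_obs for f in fits if f.n_obs is not None}
    if len(n_obs) > 1:
        raise StatsError("fits are not on the same data")
    rows = []
    for i, fit in enumerate(fits):
        ref = references[i]
        if ref is None:
            chi2 = p = np.nan
            vs = ""
        else:
            ref_fit = fits[ref]
            ddf = fit.n_params - ref_fit.n_params
            if ddf <= 0:
                raise StatsError(
                    f"{fit.name} must have more parameters than its reference {ref_fit.name}"
                )
            chi2 = ref_fit.minus2ll - fit.minus2ll
            p = float(sps.chi2.sf(max(chi2, 0.0), ddf))
            vs = ref_fit.name
        rows.append(
            dict(
                model=fit.name,
                aic=fit.aic,
                minus2ll=fit.minus2ll,
                df=fit.n_params,
                vs=vs,
                chi2=chi2,
                p=p,
            )
        )
    return ModelComparison(table=pd.DataFrame(rows))
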