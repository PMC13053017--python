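"""Mixed-effects analyses of the trial table, statsmodels-style.

Each analysis is a Model class built from the tidy trial DataFrame whose
``fit()`` returns a :class:`MixedFitResults` carrying estimates, standard
errors, p-values and a ``summary()`` table:

* :class:`ConditionAsynchronyModel` — asynchrony (ms) on timing condition,
  cell-means parameterization, random intercepts for speaker and item
  (crossed).
* :class:`GradientAsynchronyModel` — asynchrony on the signed syllable
  distance between competitor and target (mismatching, correct productions).
* :class:`IntensityBoostModel` — peak envelope amplitude of the prominent
  syllable on the movement flag (biomechanical intensity boost).
* :class:`AccuracyByMovementModel` — logistic model of correct L2 prominence
  placement on the movement flag.

Timing outcomes use an identity-link linear mixed model (estimates are in
ms); the binary accuracy outcome uses a logistic mixed model.  p-values use
the large-sample normal approximation throughout, judged against an adjusted
alpha of 0.016 by default.  Non-convergence is flagged on the results, never
silently ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import DataError, ParameterError
from .trials import CONDITIONS, TrialRecord

__all__ = [
    "DEFAULT_ALPHA",
    "MixedFitResults",
    "ConditionAsynchronyModel",
    "GradientAsynchronyModel",
    "IntensityBoostModel",
    "AccuracyByMovementModel",
    "fit_condition_model",
    "fit_gradient_model",
    "movement_boost_test",
    "accuracy_by_movement_test",
    "records_to_dataframe",
]

#: Adjusted significance level (0.05 over three confirmatory questions).
DEFAULT_ALPHA = 0.016

ANALYSIS_CONDITIONS = [c for c in CONDITIONS if c != "excluded"]


def records_to_dataframe(records) -> pd.DataFrame:
    """Trial records (DataFrame, dicts or :class:`TrialRecord`s) -> DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = [r if isinstance(r, dict) else vars(r) for r in records]
    return pd.DataFrame(rows)


@dataclass
class MixedFitResults:
    """Estimates, uncertainties and diagnostics of one mixed-model fit."""

    terms: list[str]
    estimates: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    alpha: float = DEFAULT_ALPHA
    converged: bool = True
    method: str = ""
    nobs: int = 0
    random_effects_sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.terms)
        if not (len(self.estimates) == len(self.bse) == len(self.pvalues) == n):
            raise DataError("one estimate/SE/p triple per term required")

    def __getitem__(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.bse[self.terms.index(term)])

    def pvalue(self, term: str) -> float:
        return float(self.pvalues[self.terms.index(term)])

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = sp_stats.norm.ppf(0.5 + level / 2)
        est, se = self[term], self.se(term)
        return est - z * se, est + z * se

    def summary(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.estimates / self.bse
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "se": self.bse,
                "z": z,
                "p": self.pvalues,
                "significant": self.pvalues < self.alpha,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = "" if self.converged else " (NOT CONVERGED)"
        return f"<MixedFitResults {self.method}{tag}\n{self.summary()}\n>"


def _normal_p(est: np.ndarray, se: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(np.asarray(est) / np.asarray(se))
    return 2 * sp_stats.norm.sf(z)


class _LinearMixedBase:
    """Shared machinery: crossed-intercept MixedLM with an OLS fallback.

    The crossed speaker+item random intercepts are expressed as two variance
    components over a single all-inclusive group.  When the mixed solver
    fails (degenerate zero-variance data, singular fits) we fall back to OLS
    on the fixed design — in those limits the fixed effects coincide — and
    flag the results as not converged by the mixed route.
    """

    fixed_formula: str = ""
    method_name: str = ""

    def __init__(
        self,
        data: pd.DataFrame,
        alpha: float = DEFAULT_ALPHA,
        re_speaker: bool = True,
        re_item: bool = True,
    ) -> None:
        self.data = data.reset_index(drop=True)
        self.alpha = alpha
        self.re_speaker = re_speaker
        self.re_item = re_item

    @classmethod
    def from_records(cls, records, **kwargs):
        return cls(records_to_dataframe(records), **kwargs)

    def _vc_formulas(self) -> dict:
        vc = {}
        if self.re_speaker and self.data["speaker_id"].nunique() > 1:
            vc["speaker"] = "0 + C(speaker_id)"
        if self.re_item and self.data["item_id"].nunique() > 1:
            vc["item"] = "0 + C(item_id)"
        return vc

    def _fit_linear(self, formula: str, df: pd.DataFrame) -> MixedFitResults:
        vc = self._vc_formulas()
        mixed_ok = True
        params = bse = None
        re_sd: dict = {}
        if vc:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = MixedLM.from_formula(
                        formula,
                        groups=np.ones(len(df)),
                        vc_formula=vc,
                        re_formula="0",
                        data=df,
                    )
                    res = model.fit(reml=True, method="lbfgs")
                params = np.asarray(res.fe_params)
                k = len(params)
                bse = np.asarray(res.bse[:k])
                terms = list(res.fe_params.index)
                mixed_ok = bool(res.converged) and np.all(np.isfinite(params)) \
                    and np.all(np.isfinite(bse))
                re_sd = {
                    name: float(np.sqrt(max(res.vcomp[i], 0.0)))
                    for i, name in enumerate(model.exog_vc.names)
                }
                re_sd["residual"] = float(np.sqrt(res.scale))
            except Exception:
                mixed_ok = False
        else:
            mixed_ok = False

        if not mixed_ok or params is None:
            import statsmodels.formula.api as smf

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.ols(formula, data=df).fit()
            params = np.asarray(res.params)
            bse = np.asarray(res.bse)
            terms = list(res.params.index)
            converged = False if vc else True  # OLS is exact when no RE asked
        else:
            converged = True

        return MixedFitResults(
            terms=terms,
            estimates=params,
            bse=bse,
            pvalues=_normal_p(params, bse),
            alpha=self.alpha,
            converged=converged,
            method=self.method_name,
            nobs=len(df),
            random_effects_sd=re_sd,
        )


class ConditionAsynchronyModel(_LinearMixedBase):
    """Asynchrony (ms) on timing condition, cell means, crossed intercepts.

    Uses movement trials with a defined asynchrony and a non-excluded
    condition.  The cell-means parameterization (no global intercept) makes
    each term directly the estimated mean asynchrony of one condition.
    """

    method_name = "LMM asynchrony_ms ~ 0 + condition + (1|speaker) + (1|item)"

    def fit(self) -> MixedFitResults:
        df = self.data
        df = df[
            df["movement"].astype(bool)
            & df["asynchrony_ms"].notna()
            & df["condition"].isin(ANALYSIS_CONDITIONS)
        ].copy()
        if df["speaker_id"].nunique() < 2 or df["item_id"].nunique() < 2:
            raise DataError("condition model needs >=2 speakers and >=2 items")
        present = [c for c in ANALYSIS_CONDITIONS if (df["condition"] == c).any()]
        df["condition"] = pd.Categorical(df["condition"], categories=present)
        res = self._fit_linear("asynchrony_ms ~ 0 + C(condition)", df)
        res.terms = [t.split("[")[-1].rstrip("]") for t in res.terms]
        return res


class GradientAsynchronyModel(_LinearMixedBase):
    """Asynchrony on signed competitor-to-target distance (in syllables).

    Restricted to mismatching items produced with correct L2 prominence, in
    movement trials.  Negative distance = the competitor precedes the target;
    the slope is the gradient temporal attraction in ms per syllable.
    """

    method_name = "LMM asynchrony_ms ~ distance + (1|speaker) + (1|item)"

    def fit(self) -> MixedFitResults:
        df = self.data
        df = df[
            df["movement"].astype(bool)
            & df["asynchrony_ms"].notna()
            & df["condition"].isin(["precede_correct", "follow_correct"])
        ].copy()
        if df.empty:
            raise DataError("no mismatching correct movement trials")
        if df["distance"].nunique() < 2:
            raise ParameterError(
                "distance is constant; the gradient slope is unidentified"
            )
        res = self._fit_linear("asynchrony_ms ~ distance", df)
        res.terms = ["intercept" if t == "Intercept" else t for t in res.terms]
        return res


class IntensityBoostModel(_LinearMixedBase):
    """Peak envelope amplitude of the prominent syllable on the movement flag."""

    method_name = "LMM peak_intensity ~ movement + (1|speaker) + (1|item)"

    def fit(self) -> MixedFitResults:
        df = self.data[self.data["peak_intensity"].notna()].copy()
        df["movement"] = df["movement"].astype(bool).astype(int)
        if df["movement"].nunique() < 2:
            raise ParameterError(
                "need both movement and no-movement trials for the boost test"
            )
        res = self._fit_linear("peak_intensity ~ movement", df)
        res.terms = [
            "intercept" if t == "Intercept" else ("movement" if "movement" in t else t)
            for t in res.terms
        ]
        return res


class AccuracyByMovementModel:
    """Logistic mixed model: correct L2 prominence placement on movement.

    Random intercepts for speaker and item enter as variance components in a
    variational-Bayes logistic GLMM; estimates are posterior means on the
    log-odds scale, SEs posterior SDs, p-values by normal approximation.
    """

    method_name = "GLMM(logit) correct ~ movement + (1|speaker) + (1|item)"

    def __init__(self, data: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> None:
        self.data = data.reset_index(drop=True)
        self.alpha = alpha

    @classmethod
    def from_records(cls, records, **kwargs):
        return cls(records_to_dataframe(records), **kwargs)

    def fit(self) -> MixedFitResults:
        df = self.data.copy()
        df["movement"] = df["movement"].astype(bool).astype(int)
        if df["movement"].nunique() < 2:
            raise ParameterError(
                "need both movement and no-movement trials for the accuracy test"
            )
        df["correct"] = (df["production_class"] == "correct_L2").astype(int)
        vc = {}
        if df["speaker_id"].nunique() > 1:
            vc["speaker"] = "0 + C(speaker_id)"
        if df["item_id"].nunique() > 1:
            vc["item"] = "0 + C(item_id)"
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = BinomialBayesMixedGLM.from_formula(
                    "correct ~ movement", vc, df
                )
                res = model.fit_vb()
            est = np.asarray(res.fe_mean)
            se = np.asarray(res.fe_sd)
            terms = list(model.fep_names)
        except Exception:
            import statsmodels.formula.api as smf

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.logit("correct ~ movement", data=df).fit(disp=0)
            est = np.asarray(res.params)
            se = np.asarray(res.bse)
            terms = list(res.params.index)
            converged = False
        terms = ["intercept" if t == "Intercept" else t for t in terms]
        return MixedFitResults(
            terms=terms,
            estimates=est,
            bse=se,
            pvalues=_normal_p(est, se),
            alpha=self.alpha,
            converged=converged,
            method=self.method_name,
            nobs=len(df),
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_condition_model(records, alpha: float = DEFAULT_ALPHA, **kw) -> MixedFitResults:
    """Per-condition asynchrony estimates; see :class:`ConditionAsynchronyModel`."""
    return ConditionAsynchronyModel.from_records(records, alpha=alpha, **kw).fit()


def fit_gradient_model(records, alpha: float = DEFAULT_ALPHA, **kw) -> MixedFitResults:
    """Gradient attraction slope; see :class:`GradientAsynchronyModel`."""
    return GradientAsynchronyModel.from_records(records, alpha=alpha, **kw).fit()


def movement_boost_test(records, alpha: float = DEFAULT_ALPHA, **kw) -> MixedFitResults:
    """Movement effect on peak intensity; see :class:`IntensityBoostModel`."""
    return IntensityBoostModel.from_records(records, alpha=alpha, **kw).fit()


def accuracy_by_movement_test(records, alpha: float = DEFAULT_ALPHA) -> MixedFitResults:
    """Movement effect on production accuracy; see :class:`AccuracyByMovementModel`."""
    return AccuracyByMovementModel.from_records(records, alpha=alpha).fit()
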