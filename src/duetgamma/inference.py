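"""Posterior-draw summarization and the probability-of-difference rule.

Models are fitted by restricted maximum likelihood (mixed models when a
grouping factor is supplied, ordinary least squares otherwise).  The
fitted coefficients are then treated pseudo-Bayesianly: under flat
priors ``p(beta) ~ 1`` and ``p(sigma^2) ~ 1/sigma^2``, draws of the
residual variance come from its scaled inverse-chi-squared posterior and
coefficient draws from a multivariate normal centred on the estimates,
with the coefficient covariance rescaled by each variance draw.  A
contrast is summarized by the draw mean, the 2.5-97.5% credible interval
and the directional posterior probability; an effect is "meaningful"
when that probability exceeds 0.95.

Variance components beyond the residual variance are fixed at their
estimates when drawing (stated approximation).  Random-factor structures
that fail to converge on small data degrade gracefully to simpler fits,
with the simplification logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from duetgamma.datamodel_io import ValidationError
from duetgamma.lfp_ars import LOG_EPS

logger = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """Point estimates and uncertainty of a fitted linear (mixed) model."""

    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    sigma2: float
    df_resid: float
    random_factors: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        k = len(self.names)
        if len(set(self.names)) != k:
            raise ValidationError("coefficient names must be unique")
        if self.beta.shape != (k,) or self.cov.shape != (k, k):
            raise ValidationError("beta/cov shapes do not match coefficient names")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValidationError("coefficient covariance must be symmetric")
        eigvals = np.linalg.eigvalsh((self.cov + self.cov.T) / 2)
        if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
            raise ValidationError("coefficient covariance must be positive semi-definite")


def _residual_diagnostics(resid: np.ndarray, fitted: np.ndarray) -> dict:
    """Normality and homoscedasticity summaries for the fit report."""
    resid = np.asarray(resid, dtype=float)
    diagnostics: dict = {"n": int(resid.size)}
    if resid.size >= 8:
        from scipy import stats

        diagnostics["shapiro_p"] = float(stats.shapiro(resid[:5000]).pvalue)
        median = np.median(fitted)
        lower, upper = resid[fitted <= median], resid[fitted > median]
        if len(lower) > 1 and len(upper) > 1:
            diagnostics["variance_ratio"] = float(
                np.var(upper, ddof=1) / max(np.var(lower, ddof=1), 1e-300)
            )
    return diagnostics


def fit_model(
    data: pd.DataFrame,
    formula: str,
    groups: str | None = None,
    re_formula: str | None = None,
) -> ModelFit:
    """Fit ``formula`` by REML — mixed model if ``groups`` names a random
    factor, OLS otherwise.

    A mixed fit that fails to converge (or is singular) degrades to OLS
    with a log notice.  Rank-deficient fixed effects are an error listing
    the aliased terms.
    """
    if groups is not None and data[groups].nunique() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data=data, groups=data[groups],
                                    re_formula=re_formula)
                result = model.fit(reml=True)
            if np.all(np.isfinite(result.bse_fe)):
                fe_names = list(result.fe_params.index)
                return ModelFit(
                    names=fe_names,
                    beta=result.fe_params.to_numpy(),
                    cov=result.cov_params().loc[fe_names, fe_names].to_numpy(),
                    sigma2=float(result.scale),
                    df_resid=float(len(data) - len(fe_names)),
                    random_factors=(groups,),
                    diagnostics=_residual_diagnostics(
                        np.asarray(result.resid), np.asarray(result.fittedvalues)
                    ),
                )
            logger.info("fit_model: mixed fit non-finite; falling back to OLS")
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.info("fit_model: mixed fit failed (%s); falling back to OLS", exc)

    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        _, r = np.linalg.qr(model.exog)
        aliased = [
            model.exog_names[j]
            for j in range(model.exog.shape[1])
            if abs(r[min(j, r.shape[0] - 1), j]) < 1e-10
        ]
        raise ValidationError(f"rank-deficient design; aliased terms: {aliased}")
    result = model.fit()
    return ModelFit(
        names=list(result.params.index),
        beta=result.params.to_numpy(),
        cov=result.cov_params().to_numpy(),
        sigma2=float(result.scale),
        df_resid=float(result.df_resid),
        diagnostics=_residual_diagnostics(
            np.asarray(result.resid), np.asarray(result.fittedvalues)
        ),
    )


def posterior_draws(
    fit: ModelFit, n: int = 10000, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw coefficients from the flat-prior joint posterior.

    For each draw, ``sigma^2`` comes from its scaled inverse-chi-squared
    posterior (``df * sigma2_hat / chi2(df)``) and the coefficient vector
    from a multivariate normal centred at the estimates with the fit's
    covariance rescaled by ``sigma^2 / sigma2_hat``.  Returns an
    ``(n, k)`` matrix; deterministic for a fixed seed.
    """
    if n < 1:
        raise ValidationError("need at least one draw")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(fit.names)
    cov = (fit.cov + fit.cov.T) / 2
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eigvals, eigvecs = np.linalg.eigh(cov)
        eigvals = np.clip(eigvals, 0.0, None)
        chol = eigvecs * np.sqrt(eigvals)
    df = max(fit.df_resid, 1.0)
    sigma2_draws = df * fit.sigma2 / rng.chisquare(df, size=n)
    scale = np.sqrt(sigma2_draws / fit.sigma2) if fit.sigma2 > 0 else np.ones(n)
    z = rng.standard_normal((n, k))
    return fit.beta[None, :] + scale[:, None] * (z @ chol.T)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summary of one contrast."""

    name: str
    mean: float
    cri_low: float
    cri_high: float
    prob_direction: float
    direction: str  # "+" or "-"
    prob_positive: float

    @property
    def meaningful(self) -> bool:
        return self.prob_direction > 0.95

    @property
    def decision(self) -> str:
        return "meaningful" if self.meaningful else "not-meaningful"


def summarize_contrast(
    draws: np.ndarray, contrast: Sequence[float], name: str = "contrast"
) -> PosteriorSummary:
    """Summarize ``draws @ contrast``: mean, 95% CrI and direction probability.

    ``prob_direction`` is the larger of the two directional posterior
    fractions (draws > 0 vs < 0), with the direction attached; the
    decision applies the > 0.95 rule.
    """
    draws = np.asarray(draws, dtype=float)
    contrast = np.asarray(contrast, dtype=float)
    if draws.ndim != 2 or contrast.shape != (draws.shape[1],):
        raise ValidationError(
            f"contrast length {contrast.shape} does not match draw width {draws.shape}"
        )
    values = draws @ contrast
    prob_positive = float(np.mean(values > 0))
    prob_negative = float(np.mean(values < 0))
    if prob_positive >= prob_negative:
        prob_direction, direction = prob_positive, "+"
    else:
        prob_direction, direction = prob_negative, "-"
    low, high = np.percentile(values, [2.5, 97.5])
    mean = float(values.mean())
    return PosteriorSummary(
        name=name,
        mean=mean,
        cri_low=float(min(low, mean)),
        cri_high=float(max(high, mean)),
        prob_direction=prob_direction,
        direction=direction,
        prob_positive=prob_positive,
    )


def contrast_vector(names: Sequence[str], weights: Mapping[str, float]) -> np.ndarray:
    """Build a contrast over named coefficients; unknown names are errors."""
    unknown = sorted(set(weights) - set(names))
    if unknown:
        raise ValidationError(f"unknown coefficients in contrast: {unknown}")
    return np.array([weights.get(name, 0.0) for name in names], dtype=float)


def _treatment_term(names: Sequence[str]) -> str | None:
    for name in names:
        if name.startswith("C(treatment") or name.startswith("treatment["):
            return name
    return None


def run_paper_contrasts(
    ars_table: pd.DataFrame,
    response: str = "log_ars_sq",
    group_col: str = "stimulus_label",
    random_col: str | None = "bird_id",
    n_draws: int = 10000,
    seed: int | None = None,
    min_rows: int = 4,
) -> pd.DataFrame:
    """Treatment (NB vs B) contrasts per stimulus/call type on an ARS table.

    For each level of ``group_col`` (falling back to ``call_type`` when
    absent), fits ``response ~ treatment`` — with a random intercept per
    ``random_col`` when that column varies — draws the flat-prior
    posterior, and summarizes the B-minus-NB contrast.  The default
    response is the log-squared ARS, computed from the ``ars`` column
    with the epsilon floor.  Groups with missing cells are skipped with a
    notice.  Returns one row per contrast: estimate, CrI bounds,
    directional probability and decision.
    """
    table = ars_table.copy()
    if group_col not in table.columns:
        group_col = "call_type"
    if response == "log_ars_sq" and "log_ars_sq" not in table.columns:
        if "ars" not in table.columns:
            raise ValidationError("ars_table must have an 'ars' column")
        table = table[table["ars"].abs() >= LOG_EPS].copy()
        table["log_ars_sq"] = np.log(table["ars"] ** 2)

    rng = np.random.default_rng(seed)
    rows = []
    for level, group in table.groupby(group_col, sort=True):
        if group["treatment"].nunique() < 2 or len(group) < min_rows:
            logger.info("run_paper_contrasts: skipping %s=%r (missing cells)",
                        group_col, level)
            continue
        use_random = (
            random_col is not None
            and random_col in group.columns
            and group[random_col].nunique() > 1
        )
        fit = fit_model(
            group,
            f"{response} ~ C(treatment, Treatment('NB'))",
            groups=random_col if use_random else None,
        )
        term = _treatment_term(fit.names)
        if term is None:
            logger.info("run_paper_contrasts: no treatment term for %r; skipped", level)
            continue
        draws = posterior_draws(fit, n=n_draws, seed=rng)
        summary = summarize_contrast(
            draws, contrast_vector(fit.names, {term: 1.0}), name=f"{level}:B-NB"
        )
        rows.append(
            {
                "contrast": summary.name,
                group_col: level,
                "estimate": summary.mean,
                "cri_low": summary.cri_low,
                "cri_high": summary.cri_high,
                "prob_direction": summary.prob_direction,
                "direction": summary.direction,
                "decision": summary.decision,
                "n_obs": len(group),
            }
        )
    return pd.DataFrame(rows)


def report_text(contrasts: pd.DataFrame) -> str:
    """Human-readable summary of a contrast table (no multiplicity correction
    is applied; the contrast count is stated so readers can judge)."""
    if len(contrasts) == 0:
        return "No contrasts could be computed (empty dataset).\n"
    lines = [f"{len(contrasts)} contrasts (no multiple-testing correction applied):"]
    for row in contrasts.itertuples():
        lines.append(
            f"  {row.contrast}: estimate {row.estimate:+.4f} "
            f"[{row.cri_low:+.4f}, {row.cri_high:+.4f}], "
            f"P(direction {row.direction}) = {row.prob_direction:.4f} -> {row.decision}"
        )
    return "\n".join(lines) + "\n"
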