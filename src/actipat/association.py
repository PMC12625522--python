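"""Gamma/log-link association models between activity metrics and clinical scores.

Each model regresses one activity metric (daily walking, standing, sitting or
lying minutes, or daily sedentary-to-active transitions) on the six clinical
predictors — the four NPI subsyndromes, the SPPB total, and the ordinal
severity group — in a single gamma GLM with log link. On the log-link scale a
coefficient beta means a multiplicative change exp(beta) in the expected
metric per unit predictor, reported alongside as a percent change
100*(exp(beta)-1).

Estimation is maximum likelihood by iteratively reweighted least squares
(statsmodels), with the dispersion estimated by Pearson chi-square / (n - p)
and Wald standard errors, p-values and 95% confidence intervals.

The fitted direction follows the reported table structure (activity as
outcome, clinical scores as predictors); the prose reading "more activity,
higher physical function" is the same association read in reverse, and the
results object surfaces both readings without any causal claim.

Usage::

    model = ActivityAssociationModel.from_tables(summary_df, clinical_df)
    res = model.fit(zero_policy="shift")
    print(res.summary())
    res.to_frame()          # tidy outcome x predictor table
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("actipat")

__all__ = [
    "PREDICTORS",
    "OUTCOMES",
    "GLMResult",
    "ActivityAssociationModel",
    "AssociationResults",
    "fit_gamma_glm",
    "interpret_coefficient",
]

#: The six clinical predictors entering every model (plus an intercept).
PREDICTORS: tuple[str, ...] = (
    "npi_agitation",
    "npi_psychosis",
    "npi_affective",
    "npi_apathy",
    "sppb_total",
    "severity",
)

#: Outcome metric -> measurement resolution (used by the zero-shift policy).
OUTCOMES: dict[str, float] = {
    "walking_min": 1.0,
    "standing_min": 1.0,
    "sitting_min": 1.0,
    "lying_min": 1.0,
    "transitions_per_day": 1.0,
}

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class RankDeficientError(ValueError):
    """The design matrix has collinear columns."""


class ConvergenceError(RuntimeError):
    """IRLS did not converge within the iteration budget."""


def interpret_coefficient(beta: float, ndigits: int | None = 0) -> float:
    """Percent change in the expected outcome per unit predictor.

    ``100 * (exp(beta) - 1)``, rounded to ``ndigits`` (pass ``None`` for the
    unrounded value). E.g. beta = 0.35 reads as a +42% change.
    """
    if not np.isfinite(beta):
        raise ValueError(f"beta must be finite, got {beta!r}")
    pct = 100.0 * np.expm1(beta)
    return float(pct) if ndigits is None else float(round(pct, ndigits))


@dataclass(frozen=True)
class GLMResult:
    """One fitted gamma/log model: the coefficient block for one outcome."""

    outcome: str
    table: pd.DataFrame  # index: predictor; coef, se, p, ci_lo, ci_hi, pct_change
    dispersion: float
    n: int
    n_zero_shifted: int = 0
    deviance: float = float("nan")

    def coef(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "coef"])

    def pct_change(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "pct_change"])


def fit_gamma_glm(
    outcome: Sequence[float],
    design: pd.DataFrame,
    outcome_name: str = "y",
    *,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> GLMResult:
    """Fit a gamma GLM with log link by IRLS.

    ``design`` must already contain the intercept column if one is wanted
    (see :func:`statsmodels.api.add_constant`). The outcome must be strictly
    positive; zero handling happens upstream.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.astype(float)
    n, p = X.shape
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("gamma outcome must be finite and strictly positive")
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # name the columns involved: those whose removal restores full rank
        collinear = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear column(s): {collinear}"
        )
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit(maxiter=maxiter, tol=tol, scale="X2")  # Pearson dispersion
    if not res.converged:
        raise ConvergenceError(
            f"IRLS did not converge in {maxiter} iterations for outcome "
            f"{outcome_name!r}; deviance trace: {getattr(res, 'fit_history', {}).get('deviance', [])}"
        )
    coefs = pd.Series(res.params, index=X.columns)
    ses = pd.Series(res.bse, index=X.columns)
    pvals = pd.Series(res.pvalues, index=X.columns)
    table = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "p": pvals,
            "ci_lo": coefs - _Z95 * ses,
            "ci_hi": coefs + _Z95 * ses,
            "pct_change": [interpret_coefficient(b, ndigits=None) for b in coefs],
        }
    )
    return GLMResult(
        outcome=outcome_name,
        table=table,
        dispersion=float(res.scale),
        n=n,
        deviance=float(res.deviance),
    )


class ActivityAssociationModel:
    """The five activity-metric gamma/log association models, in one object.

    Built from a merged per-participant frame holding the five activity
    outcomes and six clinical predictors; :meth:`fit` returns an
    :class:`AssociationResults`.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in (*OUTCOMES, *PREDICTORS) if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing column(s): {missing}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_tables(
        cls,
        summaries: pd.DataFrame,
        clinical: pd.DataFrame,
        on: str = "participant_id",
    ) -> "ActivityAssociationModel":
        """Join the activity-summary and scored-clinical tables 1:1 on id."""
        left_ids = set(summaries[on])
        right_ids = set(clinical[on])
        orphans = left_ids.symmetric_difference(right_ids)
        if orphans:
            raise ValueError(
                f"summary/clinical tables do not join 1:1; orphan ids: "
                f"{sorted(orphans)[:10]}{'...' if len(orphans) > 10 else ''}"
            )
        merged = summaries.merge(clinical, on=on, validate="1:1")
        return cls(merged)

    def fit(
        self,
        zero_policy: str = "shift",
        outcomes: Sequence[str] | None = None,
    ) -> "AssociationResults":
        """Fit one gamma/log GLM per activity outcome.

        ``zero_policy`` handles outcome values of exactly zero, which are
        incompatible with the gamma likelihood: ``shift`` adds half the
        metric's resolution (0.5 min for times, 0.5 for transition counts) to
        the zero values only, logging how many were shifted; ``drop`` removes
        those participants from that model.
        """
        if zero_policy not in ("shift", "drop"):
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
        outcomes = tuple(outcomes) if outcomes is not None else tuple(OUTCOMES)
        results: dict[str, GLMResult] = {}
        for outcome in outcomes:
            cols = [outcome, *PREDICTORS]
            sub = self.data[cols].dropna()
            y = sub[outcome].to_numpy(dtype=float)
            zeros = y == 0.0
            n_shifted = 0
            if zeros.any():
                if zero_policy == "shift":
                    y = y + np.where(zeros, OUTCOMES[outcome] / 2.0, 0.0)
                    n_shifted = int(zeros.sum())
                    logger.info(
                        "%s: shifted %d zero outcome(s) by %.2g",
                        outcome,
                        n_shifted,
                        OUTCOMES[outcome] / 2.0,
                    )
                else:
                    sub = sub[~zeros]
                    y = y[~zeros]
                    logger.info("%s: dropped %d zero outcome(s)", outcome, int(zeros.sum()))
            X = sm.add_constant(sub[list(PREDICTORS)], prepend=True)
            res = fit_gamma_glm(y, X, outcome_name=outcome)
            results[outcome] = GLMResult(
                outcome=outcome,
                table=res.table,
                dispersion=res.dispersion,
                n=res.n,
                n_zero_shifted=n_shifted,
                deviance=res.deviance,
            )
        return AssociationResults(results=results, zero_policy=zero_policy)


@dataclass(frozen=True)
class AssociationResults:
    """Fitted coefficient blocks for the five activity outcomes."""

    results: dict[str, GLMResult]
    zero_policy: str

    def __getitem__(self, outcome: str) -> GLMResult:
        return self.results[outcome]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: one row per outcome x predictor (no intercepts)."""
        rows = []
        for outcome, res in self.results.items():
            for predictor in PREDICTORS:
                r = res.table.loc[predictor]
                rows.append(
                    {
                        "outcome": outcome,
                        "predictor": predictor,
                        "coef": r["coef"],
                        "se": r["se"],
                        "p": r["p"],
                        "ci_lo": r["ci_lo"],
                        "ci_hi": r["ci_hi"],
                        "pct_change": r["pct_change"],
                        "n": res.n,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Printable block-per-outcome coefficient table."""
        lines = [
            "Gamma/log-link associations: activity metrics ~ NPI subsyndromes "
            "+ SPPB + severity",
            f"zero handling: {self.zero_policy}",
            "exp(coef) multiplies the expected activity metric per unit "
            "predictor; read in reverse, a positive coefficient also means "
            "higher predictor values accompany more of that activity "
            "(cross-sectional association, no causal direction).",
            "",
        ]
        for outcome, res in self.results.items():
            lines.append(f"[{outcome}]  n={res.n}  dispersion={res.dispersion:.3f}"
                         + (f"  zeros shifted={res.n_zero_shifted}" if res.n_zero_shifted else ""))
            lines.append(
                f"  {'predictor':<16}{'coef':>8}{'se':>8}{'p':>9}"
                f"{'95% CI':>20}{'pct':>8}"
            )
            for predictor in PREDICTORS:
                r = res.table.loc[predictor]
                ci = f"[{r['ci_lo']:.2f}, {r['ci_hi']:.2f}]"
                lines.append(
                    f"  {predictor:<16}{r['coef']:>8.3f}{r['se']:>8.3f}"
                    f"{r['p']:>9.3f}{ci:>20}{r['pct_change']:>7.1f}%"
                )
            lines.append("")
        return "\n".join(lines)
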