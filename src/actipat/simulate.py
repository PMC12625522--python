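"""Synthetic nursing-home cohorts: semi-Markov activity sequences + clinical scores.

The study's raw data are not public, so every pipeline stage is exercised on
synthetic cohorts built from the published descriptive statistics. Each
participant's 24-h behaviour is a semi-Markov process over the four analysis
states (walking, standing, sitting, lying): the next state follows an embedded
Markov chain (no self-transitions in the defaults) and the dwell time in each
state is log-normal in minutes, rounded to whole 60-s epochs with a floor of
one epoch.

The default parameters are derived analytically from the published group-level
descriptives rather than tuned: given per-group daily time-use targets
``T_s`` (minutes) and a counted-transition target ``tr``, the embedded chain's
stationary distribution ``pi`` fixes the mean dwells

    m_s = T_s * C / pi_s,   C = [pi_Si*(P_Si,St + P_Si,W) + pi_L*(P_L,St + P_L,W)] / tr,

because the expected fraction of time in state s is pi_s*E[dwell_s] /
sum_k pi_k*E[dwell_k] and the counted sedentary-to-active transition rate is
the bout rate times the counted-pair probability mass. The log-normal location
for each state is then solved so that the *discretised* dwell mean (rounded,
floored at 1 min) hits ``m_s`` exactly.

Between-participant heterogeneity enters as (a) a common "tempo" multiplier on
all dwell times (log-normal, centred so the expected transition rate is
unchanged), which spreads daily transition counts without moving time-use
fractions, and (b) small independent per-state dwell multipliers that spread
time-use across participants.

Clinical scores are generated after the activity sequences: each score is a
group-level baseline (from the published group means) plus a configured linear
"truth" loading on the participant's standardised activity metrics, plus
noise, clipped into the instrument's valid range. With all truth loadings zero
the clinical table is exactly independent of the activity table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .clinical import NPI_ITEM_NAMES
from .epochs import ActivityLabel, EpochSeries, ValidSegment
from .metrics import (
    COUNTED_TRANSITION_PAIRS,
    ActivitySummary,
    Bout,
    DailyTimeUse,
    TransitionSummary,
    bin_bouts,
)

logger = logging.getLogger("actipat")

__all__ = [
    "STATE_ORDER",
    "GroupActivityParams",
    "GroupClinicalParams",
    "AssociationTruth",
    "GroupConfig",
    "CohortConfig",
    "SimulatedCohort",
    "simulate_bout_sequence",
    "simulate_activity_sequence",
    "summary_from_bouts",
    "simulate_clinical_outcomes",
    "simulate_cohort",
    "simulate_summaries",
    "default_config_from_paper",
    "null_config",
    "discretized_lognormal_mean",
    "lognormal_mu_for_mean",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
]

#: State order used by all parameter arrays.
STATE_ORDER: tuple[ActivityLabel, ...] = (
    ActivityLabel.WALKING,
    ActivityLabel.STANDING,
    ActivityLabel.SITTING,
    ActivityLabel.LYING,
)

#: Log-scale dwell spreads per state: tight for the short upright bouts,
#: wide for the long-tailed sedentary ones.
DEFAULT_DWELL_SIGMA: tuple[float, ...] = (0.55, 0.80, 1.10, 1.00)

#: Default embedded chain (rows/cols in STATE_ORDER, no self-transitions).
#: All moves are allowed — lying -> sitting happens — and only the four
#: counted pairs feed the transition metric.
DEFAULT_TRANSITION = np.array(
    [
        [0.00, 0.55, 0.40, 0.05],
        [0.40, 0.00, 0.50, 0.10],
        [0.12, 0.45, 0.00, 0.43],
        [0.05, 0.15, 0.80, 0.00],
    ]
)

#: Fixed standardisation constants for the truth loadings (cohort-level
#: centres/scales, so the generative coefficients do not depend on the data).
METRIC_CENTER = {
    "walking_min": 17.6,
    "standing_min": 66.0,
    "sitting_min": 594.0,
    "lying_min": 762.0,
    "transitions_per_day": 22.0,
}
METRIC_SCALE = {
    "walking_min": 10.0,
    "standing_min": 40.0,
    "sitting_min": 120.0,
    "lying_min": 120.0,
    "transitions_per_day": 15.0,
}

_SUBSYNDROME_ITEMS = {
    "agitation": ("agitation_aggression", "disinhibition", "irritability"),
    "psychosis": ("delusions", "hallucinations"),
    "affective": ("depression", "anxiety"),
    "apathy": ("apathy",),
}
_OTHER_ITEMS = ("euphoria", "aberrant_motor", "nighttime_behavior", "appetite_eating")


def discretized_lognormal_mean(mu: float, sigma: float, kmax: int = 6000) -> float:
    """Mean of ``max(round(X), 1)`` for X ~ LogNormal(mu, sigma) in minutes."""
    k = np.arange(1, kmax)
    upper = stats.lognorm.cdf(k + 0.5, s=sigma, scale=np.exp(mu))
    lower = stats.lognorm.cdf(k - 0.5, s=sigma, scale=np.exp(mu))
    p = upper - lower
    p[0] = upper[0]  # all mass below 1.5 rounds up to the 1-epoch floor
    tail = 1.0 - upper[-1]
    return float((k * p).sum() + tail * kmax)


def lognormal_mu_for_mean(target: float, sigma: float) -> float:
    """Solve the log-normal location so the discretised dwell mean hits ``target``.

    Targets below the smallest achievable discretised mean (the 1-epoch floor
    pushes it slightly above 1 min) clamp to the lower bound.
    """
    lo, hi = -4.0, 9.0
    if discretized_lognormal_mean(lo, sigma) >= target:
        return lo
    return float(
        optimize.brentq(
            lambda mu: discretized_lognormal_mean(mu, sigma) - target, lo, hi, xtol=1e-10
        )
    )


@dataclass(frozen=True)
class GroupActivityParams:
    """Semi-Markov parameters for one severity group.

    ``dwell_mu``/``dwell_sigma`` are log-normal parameters of dwell time in
    minutes per state; ``transition`` is the embedded chain (row-stochastic).
    ``tempo_sd`` and ``state_sd`` are log-scale SDs of the per-participant
    dwell multipliers described in the module docstring.
    """

    dwell_mu: np.ndarray
    dwell_sigma: np.ndarray
    transition: np.ndarray
    tempo_sd: float = 0.45
    state_sd: float = 0.20

    def __post_init__(self) -> None:
        P = np.asarray(self.transition, dtype=float)
        mu = np.asarray(self.dwell_mu, dtype=float)
        sg = np.asarray(self.dwell_sigma, dtype=float)
        if P.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4 (W, St, Si, L)")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must be non-negative and sum to 1")
        if mu.shape != (4,) or sg.shape != (4,):
            raise ValueError("dwell_mu and dwell_sigma must have 4 entries")
        if np.any(~np.isfinite(mu)) or np.any(sg < 0):
            raise ValueError("dwell parameters must be finite, sigma >= 0")
        object.__setattr__(self, "dwell_mu", mu)
        object.__setattr__(self, "dwell_sigma", sg)
        object.__setattr__(self, "transition", P)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the embedded chain."""
        w, v = np.linalg.eig(self.transition.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
        pi = np.abs(pi)
        return pi / pi.sum()

    def mean_dwell_minutes(self) -> np.ndarray:
        """Discretised mean dwell per state (whole-epoch rounding, 1-min floor)."""
        return np.array(
            [
                discretized_lognormal_mean(m, s)
                for m, s in zip(self.dwell_mu, self.dwell_sigma)
            ]
        )

    def expected_time_fractions(self) -> np.ndarray:
        """Expected long-run fraction of time per state: pi_s m_s / sum pi_k m_k."""
        pi = self.stationary()
        m = self.mean_dwell_minutes()
        return pi * m / (pi * m).sum()

    def expected_transitions_per_day(self) -> float:
        """Expected counted sedentary-to-active transitions per 24 h."""
        pi = self.stationary()
        m = self.mean_dwell_minutes()
        pair_mass = 0.0
        for frm, to in COUNTED_TRANSITION_PAIRS:
            i = STATE_ORDER.index(frm)
            j = STATE_ORDER.index(to)
            pair_mass += pi[i] * self.transition[i, j]
        return float(1440.0 / (pi * m).sum() * pair_mass)


@dataclass(frozen=True)
class GroupClinicalParams:
    """Clinical-score generator baselines for one severity group."""

    npi_subsyndrome_means: dict[str, float]  # agitation/psychosis/affective/apathy
    npi_other_item_mean: float  # mean per unclustered item
    sppb_mean: float
    has_dementia: bool
    cdr_range: tuple[float, float] | None  # None for the non-dementia group
    mci_prob: float = 1.0  # P(MCI flag) within the non-dementia group
    sppb_noise_sd: float = 1.8


@dataclass(frozen=True)
class AssociationTruth:
    """Generative loadings of clinical scores on standardised activity metrics.

    ``sppb`` and each ``npi[subsyndrome]`` map metric name ->
    coefficient per 1-scale-unit of the standardised metric (centres/scales
    are the fixed module-level constants). All-zero loadings make the clinical
    table independent of activity.
    """

    sppb: dict[str, float] = field(default_factory=dict)
    npi: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def null(cls) -> "AssociationTruth":
        return cls(sppb={}, npi={})

    def is_null(self) -> bool:
        return not any(self.sppb.values()) and not any(
            v for d in self.npi.values() for v in d.values()
        )


@dataclass(frozen=True)
class GroupConfig:
    name: str
    severity: int  # ordinal 1-4
    n: int
    activity: GroupActivityParams
    clinical: GroupClinicalParams
    wear_days: int = 2

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.wear_days < 1:
            raise ValueError("wear_days must be >= 1")


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupConfig, ...]
    truth: AssociationTruth
    seed: int = 0
    epoch_seconds: int = 60

    @property
    def n_participants(self) -> int:
        return sum(g.n for g in self.groups)


# ---------------------------------------------------------------------------
# sequence simulation


def simulate_bout_sequence(
    params: GroupActivityParams,
    total_minutes: int,
    rng: np.random.Generator,
    dwell_mu: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (states, whole-minute durations) covering exactly ``total_minutes``.

    The first state is drawn from the embedded chain's stationary
    distribution; the final dwell is truncated at the horizon.
    """
    mu = params.dwell_mu if dwell_mu is None else dwell_mu
    sigma = params.dwell_sigma
    cum = np.cumsum(params.transition, axis=1)
    pi = params.stationary()
    states: list[int] = []
    durs: list[int] = []
    s = int(rng.choice(4, p=pi))
    acc = 0
    while acc < total_minutes:
        d = max(1, int(np.rint(rng.lognormal(mu[s], sigma[s]))))
        states.append(s)
        durs.append(d)
        acc += d
        s = int(np.searchsorted(cum[s], rng.random()))
    durs[-1] -= acc - total_minutes
    if durs[-1] == 0:
        states.pop()
        durs.pop()
    return np.asarray(states, dtype=np.int8), np.asarray(durs, dtype=np.int64)


def _participant_dwell_mu(
    params: GroupActivityParams, rng: np.random.Generator
) -> np.ndarray:
    """Per-participant dwell locations: common tempo + per-state jitter.

    The tempo multiplier is log-normal with log-mean ``+tempo_sd^2/2`` so that
    the expected bout (and hence transition) *rate* E[1/tempo] equals 1.
    """
    tempo = rng.normal(params.tempo_sd**2 / 2.0, params.tempo_sd)
    jitter = rng.normal(0.0, params.state_sd, size=4)
    return params.dwell_mu + tempo + jitter


def simulate_activity_sequence(
    params: GroupActivityParams,
    duration_hours: float = 24.0,
    seed: int | np.random.Generator | None = None,
    participant_id: str = "sim",
    start_time: str | pd.Timestamp = "2018-01-01 00:00:00",
    epoch_seconds: int = 60,
    *,
    individual: bool = False,
) -> EpochSeries:
    """Simulate one epoch-label series of at least ``duration_hours``.

    Identical seeds give identical sequences. With ``individual=True`` the
    per-participant dwell multipliers are drawn first (the cohort generator's
    behaviour); by default the group-level parameters are used as-is.
    """
    if duration_hours < 24.0:
        raise ValueError("simulated records must span at least 24 h")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = _participant_dwell_mu(params, rng) if individual else None
    total = int(round(duration_hours * 60))
    states, durs = simulate_bout_sequence(params, total, rng, dwell_mu=mu)
    labels = np.repeat(states, durs)
    if epoch_seconds != 60:
        labels = np.repeat(labels, 60 // epoch_seconds)
    return EpochSeries(
        participant_id=participant_id,
        start_time=pd.Timestamp(start_time),
        labels=labels.astype(np.int8),
        epoch_seconds=epoch_seconds,
    )


def summary_from_bouts(
    states: np.ndarray,
    durations: np.ndarray,
    n_valid_days: int,
    participant_id: str = "sim",
) -> ActivitySummary:
    """Pattern metrics computed directly from a bout list (generator fast path).

    Produces exactly what `summarize_participant` returns on the expanded
    epoch sequence of the same bouts (the horizon is an exact number of days,
    so there is no trailing remainder).
    """
    durations = np.asarray(durations, dtype=float)
    states = np.asarray(states)
    per_state = np.zeros(4)
    np.add.at(per_state, states, durations)
    tu = DailyTimeUse(*(per_state / n_valid_days))
    starts = np.concatenate([[0], np.cumsum(durations[:-1])]).astype(int)
    bouts = [
        Bout(ActivityLabel(int(s)), int(st), float(d))
        for s, st, d in zip(states, starts, durations)
    ]
    hists = bin_bouts(bouts, n_valid_days)
    a, b = states[:-1], states[1:]
    per_pair = {
        pair: int(np.count_nonzero((a == int(pair[0])) & (b == int(pair[1]))))
        for pair in COUNTED_TRANSITION_PAIRS
    }
    return ActivitySummary(
        participant_id=participant_id,
        n_valid_days=n_valid_days,
        time_use=tu,
        bout_histograms=hists,
        transitions=TransitionSummary(per_pair, n_valid_days=n_valid_days),
    )


# ---------------------------------------------------------------------------
# clinical-score simulation


def _standardised_metrics(summary_df: pd.DataFrame) -> pd.DataFrame:
    z = pd.DataFrame(index=summary_df.index)
    for m, c in METRIC_CENTER.items():
        z[m] = (summary_df[m] - c) / METRIC_SCALE[m]
    return z


def simulate_clinical_outcomes(
    summary_df: pd.DataFrame,
    group_of: Sequence[GroupConfig],
    truth: AssociationTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate the raw clinical table conditional on the activity summaries.

    ``group_of`` gives each participant's :class:`GroupConfig` (aligned with
    ``summary_df`` rows). Scores are clipped into their instrument ranges; a
    clipping rate above 20% logs a warning because heavy clipping distorts the
    configured truth.
    """
    z = _standardised_metrics(summary_df)
    n = len(summary_df)
    rows = []
    n_clipped = 0
    n_scores = 0
    for i in range(n):
        g = group_of[i]
        c = g.clinical
        row: dict[str, object] = {"participant_id": summary_df["participant_id"].iloc[i]}
        # NPI items: Poisson around the per-item mean; truth loadings shift
        # the subsyndrome-level mean, split equally across its items.
        for sub, items in _SUBSYNDROME_ITEMS.items():
            base = c.npi_subsyndrome_means[sub] / len(items)
            load = truth.npi.get(sub, {})
            shift = sum(beta * z[m].iloc[i] for m, beta in load.items()) / len(items)
            lam = max(base + shift, 0.0)
            for item in items:
                v = int(rng.poisson(lam))
                n_scores += 1
                if v > 12:
                    v = 12
                    n_clipped += 1
                row[f"npi_{item}"] = v
        for item in _OTHER_ITEMS:
            v = int(rng.poisson(c.npi_other_item_mean))
            n_scores += 1
            if v > 12:
                v = 12
                n_clipped += 1
            row[f"npi_{item}"] = v
        # SPPB: latent group baseline + truth loading + noise, clip to 0-12
        latent = c.sppb_mean + sum(
            beta * z[m].iloc[i] for m, beta in truth.sppb.items()
        )
        latent += rng.normal(0.0, c.sppb_noise_sd)
        t = int(np.clip(np.rint(latent), 0, 12))
        n_scores += 1
        if not np.isclose(t, latent, atol=0.5):
            n_clipped += 1
        balance = min(4, t)
        gait = min(4, t - balance)
        chair = t - balance - gait
        row["sppb_balance"] = balance
        row["sppb_gait"] = gait
        row["sppb_chair"] = chair
        row["dx_dementia"] = c.has_dementia
        row["dx_mci"] = (not c.has_dementia) and bool(rng.random() < c.mci_prob)
        if c.has_dementia:
            lo, hi = c.cdr_range
            grid = np.arange(lo, hi + 0.25, 0.5)
            row["cdr_sob"] = float(rng.choice(grid))
        else:
            row["cdr_sob"] = np.nan
        row["age"] = float(np.clip(np.rint(rng.normal(87.7, 7.5)), 70, 103))
        row["sex"] = "female" if rng.random() < 0.62 else "male"
        row["bmi"] = float(np.clip(np.round(rng.normal(26.0, 5.5), 1), 16, 52))
        rows.append(row)
    rate = n_clipped / max(n_scores, 1)
    if rate > 0.20:
        logger.warning(
            "clinical-score clipping rate %.1f%% exceeds 20%%: the configured "
            "truth loadings are distorted",
            100 * rate,
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated cohort plus its ground-truth ledger."""

    config: CohortConfig
    series: list[EpochSeries]
    clinical: pd.DataFrame
    summaries: pd.DataFrame  # the generator's own bout-level bookkeeping
    truth: dict

    def write(self, out_dir) -> dict[str, Path]:
        """Write epochs.csv, clinical.csv and truth.json in pipeline formats."""
        from .epochs import write_epoch_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "epochs": out / "epochs.csv",
            "clinical": out / "clinical.csv",
            "truth": out / "truth.json",
        }
        write_epoch_csv(self.series, paths["epochs"])
        self.clinical.to_csv(paths["clinical"], index=False)
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return paths


def _truth_ledger(config: CohortConfig) -> dict:
    groups = {}
    for g in config.groups:
        frac = g.activity.expected_time_fractions()
        groups[g.name] = {
            "n": g.n,
            "severity": g.severity,
            "wear_days": g.wear_days,
            "expected_minutes_per_day": {
                st.name.lower(): float(f * 1440.0)
                for st, f in zip(STATE_ORDER, frac)
            },
            "expected_transitions_per_day": g.activity.expected_transitions_per_day(),
            "mean_dwell_minutes": {
                st.name.lower(): float(m)
                for st, m in zip(STATE_ORDER, g.activity.mean_dwell_minutes())
            },
        }
    return {
        "seed": config.seed,
        "groups": groups,
        "association_truth": {
            "note": "generative loadings of clinical scores on standardised "
            "activity metrics (not reverse-regression coefficients)",
            "sppb": config.truth.sppb,
            "npi": config.truth.npi,
            "metric_center": METRIC_CENTER,
            "metric_scale": METRIC_SCALE,
        },
    }


def _simulate_participants(
    config: CohortConfig, rng: np.random.Generator, expand_epochs: bool
):
    series: list[EpochSeries] = []
    summaries: list[ActivitySummary] = []
    group_of: list[GroupConfig] = []
    i = 0
    for g in config.groups:
        for _ in range(g.n):
            pid = f"NH{i:04d}"
            i += 1
            mu = _participant_dwell_mu(g.activity, rng)
            total = g.wear_days * 1440
            states, durs = simulate_bout_sequence(g.activity, total, rng, dwell_mu=mu)
            summaries.append(summary_from_bouts(states, durs, g.wear_days, pid))
            group_of.append(g)
            if expand_epochs:
                labels = np.repeat(states, durs)
                if config.epoch_seconds != 60:
                    labels = np.repeat(labels, 60 // config.epoch_seconds)
                series.append(
                    EpochSeries(
                        participant_id=pid,
                        start_time=pd.Timestamp("2018-01-01 00:00:00"),
                        labels=labels.astype(np.int8),
                        epoch_seconds=config.epoch_seconds,
                    )
                )
    return series, summaries, group_of


def simulate_summaries(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast path: activity-summary and clinical tables without epoch expansion.

    Metric-identical to running the full pipeline on the expanded epoch
    sequences (verified property), and used where many replicate cohorts are
    needed.
    """
    from .metrics import summaries_to_frame

    rng = rng or np.random.default_rng(config.seed)
    _, summaries, group_of = _simulate_participants(config, rng, expand_epochs=False)
    summary_df = summaries_to_frame(summaries)
    clinical_df = simulate_clinical_outcomes(summary_df, group_of, config.truth, rng)
    return summary_df, clinical_df


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a full cohort: epoch series, clinical table, truth ledger."""
    from .metrics import summaries_to_frame

    rng = np.random.default_rng(config.seed)
    series, summaries, group_of = _simulate_participants(config, rng, expand_epochs=True)
    summary_df = summaries_to_frame(summaries)
    clinical_df = simulate_clinical_outcomes(summary_df, group_of, config.truth, rng)
    return SimulatedCohort(
        config=config,
        series=series,
        clinical=clinical_df,
        summaries=summary_df,
        truth=_truth_ledger(config),
    )


# ---------------------------------------------------------------------------
# default configuration from the published descriptives

# Per-group targets. Daily minutes (walking, standing, sitting, lying) and
# counted transitions/day: standing (mild, severe), lying (no/MCI, mild,
# severe) and all four transition means are published group values; the
# remaining cells are back-solved so the size-weighted cohort means equal the
# published overall means (17.6 / 66 / 594 / 762 min and 22 transitions), with
# sitting as the 1440-minute remainder.
_GROUP_TARGETS: tuple[dict, ...] = (
    dict(
        name="no_mci",
        severity=1,
        n=25,
        minutes=(18.0, 70.0, 617.0, 735.0),
        transitions=22.0,
        npi=dict(agitation=1.04, psychosis=0.68, affective=0.92, apathy=0.08),
        npi_other=0.19,
        sppb=1.84,
        dementia=False,
        cdr=None,
        mci_prob=0.84,  # 21 of 25 in this combined group carry an MCI diagnosis
    ),
    dict(
        name="mild",
        severity=2,
        n=73,
        minutes=(22.0, 89.3, 602.7, 726.0),
        transitions=27.0,
        npi=dict(agitation=2.58, psychosis=0.96, affective=1.58, apathy=0.44),
        npi_other=0.34,
        sppb=2.68,
        dementia=True,
        cdr=(4.5, 9.0),
        mci_prob=0.0,
    ),
    dict(
        name="moderate",
        severity=3,
        n=47,
        minutes=(16.0, 42.5, 594.5, 787.0),
        transitions=21.0,
        npi=dict(agitation=7.04, psychosis=3.04, affective=3.38, apathy=1.04),
        npi_other=0.71,
        sppb=1.85,
        dementia=True,
        cdr=(9.5, 15.5),
        mci_prob=0.0,
    ),
    dict(
        name="severe",
        severity=4,
        n=18,
        minutes=(6.0, 27.3, 525.7, 881.0),
        transitions=10.0,
        npi=dict(agitation=6.44, psychosis=1.56, affective=3.61, apathy=2.28),
        npi_other=0.33,
        sppb=0.28,
        dementia=True,
        cdr=(16.0, 18.0),
        mci_prob=0.0,
    ),
)

#: Default truth loadings: physical function loads positively on walking,
#: standing and transitions and negatively on lying (the association the
#: study reports); the NPI subsyndromes carry no loading (none was found).
DEFAULT_TRUTH = AssociationTruth(
    sppb={
        "walking_min": 0.9,
        "standing_min": 0.5,
        "transitions_per_day": 0.8,
        "lying_min": -0.3,
    },
    npi={},
)


def _activity_params_from_targets(
    minutes: Sequence[float],
    transitions: float,
    transition_matrix: np.ndarray = DEFAULT_TRANSITION,
    dwell_sigma: Sequence[float] = DEFAULT_DWELL_SIGMA,
    tempo_sd: float = 0.45,
    state_sd: float = 0.20,
) -> GroupActivityParams:
    """Back-solve dwell locations from time-use and transition targets."""
    P = np.asarray(transition_matrix, dtype=float)
    tmp = GroupActivityParams(
        dwell_mu=np.zeros(4), dwell_sigma=np.asarray(dwell_sigma), transition=P
    )
    pi = tmp.stationary()
    pair_mass = 0.0
    for frm, to in COUNTED_TRANSITION_PAIRS:
        i = STATE_ORDER.index(frm)
        j = STATE_ORDER.index(to)
        pair_mass += pi[i] * P[i, j]
    C = pair_mass / transitions
    target_dwell = np.asarray(minutes, dtype=float) * C / pi
    mu = np.array(
        [lognormal_mu_for_mean(t, s) for t, s in zip(target_dwell, dwell_sigma)]
    )
    return GroupActivityParams(
        dwell_mu=mu,
        dwell_sigma=np.asarray(dwell_sigma, dtype=float),
        transition=P,
        tempo_sd=tempo_sd,
        state_sd=state_sd,
    )


def _scaled_sizes(base: Sequence[int], total: int) -> list[int]:
    """Scale group sizes to a new total, largest-remainder rounding."""
    base = np.asarray(base, dtype=float)
    exact = base / base.sum() * total
    sizes = np.floor(exact).astype(int)
    sizes = np.maximum(sizes, 1)
    rem = total - sizes.sum()
    order = np.argsort(-(exact - np.floor(exact)))
    for k in range(abs(int(rem))):
        sizes[order[k % 4]] += int(np.sign(rem))
    return [int(s) for s in sizes]


def default_config_from_paper(
    n_participants: int | None = None,
    wear_days: int = 2,
    seed: int = 0,
    truth: AssociationTruth | None = None,
) -> CohortConfig:
    """The study-conditions cohort configuration.

    Four severity groups (default sizes 25/73/47/18, total 163) whose
    simulated cohorts reproduce the published overall daily means and the
    severity gradients (less standing, more lying and about 10 transitions in
    severe dementia). ``n_participants`` rescales the group sizes
    proportionally.
    """
    sizes = [g["n"] for g in _GROUP_TARGETS]
    if n_participants is not None:
        sizes = _scaled_sizes(sizes, n_participants)
    groups = []
    for g, n in zip(_GROUP_TARGETS, sizes):
        groups.append(
            GroupConfig(
                name=g["name"],
                severity=g["severity"],
                n=n,
                wear_days=wear_days,
                activity=_activity_params_from_targets(g["minutes"], g["transitions"]),
                clinical=GroupClinicalParams(
                    npi_subsyndrome_means=dict(g["npi"]),
                    npi_other_item_mean=g["npi_other"],
                    sppb_mean=g["sppb"],
                    has_dementia=g["dementia"],
                    cdr_range=g["cdr"],
                    mci_prob=g["mci_prob"],
                ),
            )
        )
    return CohortConfig(
        groups=tuple(groups),
        truth=truth if truth is not None else DEFAULT_TRUTH,
        seed=seed,
    )


def null_config(
    n_participants: int = 163, wear_days: int = 1, seed: int = 0
) -> CohortConfig:
    """A no-association cohort: identical activity process in all groups and
    all truth loadings zero, so every predictor of the association models is
    truly null (the type-I-error study condition)."""
    base = default_config_from_paper(wear_days=wear_days, seed=seed)
    overall = _activity_params_from_targets((17.6, 66.0, 594.4, 762.0), 22.0)
    sizes = _scaled_sizes([g.n for g in base.groups], n_participants)
    groups = tuple(
        dataclasses.replace(g, activity=overall, n=n, wear_days=wear_days)
        for g, n in zip(base.groups, sizes)
    )
    return CohortConfig(groups=groups, truth=AssociationTruth.null(), seed=seed)


# ---------------------------------------------------------------------------
# config (de)serialisation


def config_to_dict(config: CohortConfig) -> dict:
    return {
        "seed": config.seed,
        "epoch_seconds": config.epoch_seconds,
        "truth": {"sppb": dict(config.truth.sppb), "npi": {k: dict(v) for k, v in config.truth.npi.items()}},
        "groups": [
            {
                "name": g.name,
                "severity": g.severity,
                "n": g.n,
                "wear_days": g.wear_days,
                "activity": {
                    "dwell_mu": g.activity.dwell_mu.tolist(),
                    "dwell_sigma": g.activity.dwell_sigma.tolist(),
                    "transition": g.activity.transition.tolist(),
                    "tempo_sd": g.activity.tempo_sd,
                    "state_sd": g.activity.state_sd,
                },
                "clinical": {
                    "npi_subsyndrome_means": dict(g.clinical.npi_subsyndrome_means),
                    "npi_other_item_mean": g.clinical.npi_other_item_mean,
                    "sppb_mean": g.clinical.sppb_mean,
                    "has_dementia": g.clinical.has_dementia,
                    "cdr_range": list(g.clinical.cdr_range) if g.clinical.cdr_range else None,
                    "mci_prob": g.clinical.mci_prob,
                    "sppb_noise_sd": g.clinical.sppb_noise_sd,
                },
            }
            for g in config.groups
        ],
    }


def config_from_dict(d: Mapping) -> CohortConfig:
    groups = tuple(
        GroupConfig(
            name=g["name"],
            severity=int(g["severity"]),
            n=int(g["n"]),
            wear_days=int(g.get("wear_days", 2)),
            activity=GroupActivityParams(
                dwell_mu=np.asarray(g["activity"]["dwell_mu"], dtype=float),
                dwell_sigma=np.asarray(g["activity"]["dwell_sigma"], dtype=float),
                transition=np.asarray(g["activity"]["transition"], dtype=float),
                tempo_sd=float(g["activity"].get("tempo_sd", 0.45)),
                state_sd=float(g["activity"].get("state_sd", 0.20)),
            ),
            clinical=GroupClinicalParams(
                npi_subsyndrome_means=dict(g["clinical"]["npi_subsyndrome_means"]),
                npi_other_item_mean=float(g["clinical"]["npi_other_item_mean"]),
                sppb_mean=float(g["clinical"]["sppb_mean"]),
                has_dementia=bool(g["clinical"]["has_dementia"]),
                cdr_range=tuple(g["clinical"]["cdr_range"]) if g["clinical"]["cdr_range"] else None,
                mci_prob=float(g["clinical"].get("mci_prob", 0.0)),
                sppb_noise_sd=float(g["clinical"].get("sppb_noise_sd", 1.8)),
            ),
        )
        for g in d["groups"]
    )
    truth = AssociationTruth(
        sppb=dict(d.get("truth", {}).get("sppb", {})),
        npi={k: dict(v) for k, v in d.get("truth", {}).get("npi", {}).items()},
    )
    return CohortConfig(
        groups=groups,
        truth=truth,
        seed=int(d.get("seed", 0)),
        epoch_seconds=int(d.get("epoch_seconds", 60)),
    )


def load_config(path) -> CohortConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: CohortConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
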