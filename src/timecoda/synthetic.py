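"""Synthetic cohorts with known ground truth.

No raw accelerometer or weight data are distributable for this design, so
every downstream stage is exercised against simulated cohorts whose
generating mechanism mirrors the analysis model: person-level 4-part daily
time-use compositions are logistic-normal (multivariate normal on ILR
coordinates, guaranteeing positivity), and the 6-month percent total weight
loss (%TWL) outcome is linear in those ILR coordinates plus a surgery-type
term and Gaussian noise. Because the generator is linear on the ILR scale,
the true effect of any time reallocation is available in closed form
(:func:`true_reallocation_effect`) and serves as the analytic oracle for
coverage and parameter-recovery checks.

An optional minute-level generator emits epoch records (counts/min, wear
and sleep flags) so the epoch-classification stage can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coda import (
    BEHAVIORS,
    MINUTES_PER_DAY,
    IlrBasis,
    closure,
    ilr,
    ilr_inverse,
    pivot_basis,
    reallocate,
)

#: Fixed basis in which the generator's ILR-scale parameters are expressed.
GENERATOR_BASIS: IlrBasis = pivot_basis("sleep")

#: Cohort mean minutes/day in sleep, SB, LPA, MVPA.
DEFAULT_MEAN_MINUTES = np.array([447.3, 583.7, 366.0, 42.6])

#: Cohort SDs of the same four behaviors (minutes/day), used to scale the
#: default between-person covariance.
DEFAULT_SD_MINUTES = np.array([70.7, 100.9, 75.3, 23.0])

#: SB / LPA / MVPA counts-per-minute bands (half-open).
COUNT_BANDS = {"sb": (0.0, 2000.0), "lpa": (2000.0, 7500.0),
               "mvpa": (7500.0, np.inf)}


def default_ilr_covariance() -> np.ndarray:
    """Between-person ILR covariance implied by independent log-normal parts.

    The log-scale SD of each behavior is taken as its coefficient of
    variation (sd/mean of the minute summaries), a first-order match to the
    observed minute SDs. The clr covariance of independent log parts with
    variances v is G diag(v) G with G = I - J/4; projecting through the
    generator basis gives a full-rank 3x3 ILR covariance.
    """
    v = (DEFAULT_SD_MINUTES / DEFAULT_MEAN_MINUTES) ** 2
    G = np.eye(4) - np.full((4, 4), 0.25)
    clr_cov = G @ np.diag(v) @ G
    V = GENERATOR_BASIS.matrix
    return V @ clr_cov @ V.T


def default_beta_ilr(sb_to_mvpa_15min: float = 0.92) -> np.ndarray:
    """Outcome coefficients on the generator-basis ILR coordinates.

    A pure-MVPA clr direction (the composition's MVPA log share against the
    rest), scaled so that reallocating 15 min from SB to MVPA at the mean
    composition changes expected %TWL by ``sb_to_mvpa_15min`` — the
    magnitude typical of this literature.
    """
    c = np.array([-0.25, -0.25, -0.25, 0.75])  # clr contrast on MVPA
    beta_unit = GENERATOR_BASIS.matrix @ c  # beta s.t. beta.z == c.clr(x)
    ref = closure(DEFAULT_MEAN_MINUTES)
    d = ilr(reallocate(ref, "sb", "mvpa", 15.0), GENERATOR_BASIS) - ilr(
        ref, GENERATOR_BASIS
    )
    return (sb_to_mvpa_15min / float(d @ beta_unit)) * beta_unit


@dataclass
class CohortSimConfig:
    """Generating parameters for a synthetic pre-surgery cohort.

    Attributes
    ----------
    n_participants : int
        Cohort size (the motivating study analysed 45).
    mean_minutes : array-like of 4 floats
        Mean daily minutes in sleep, SB, LPA, MVPA; the compositional mean
        of the simulated cohort converges to its closure.
    ilr_covariance : (3, 3) array
        Between-person covariance of ILR coordinates (generator basis).
        Must be symmetric positive semi-definite; the zero matrix gives a
        degenerate cohort at the mean composition.
    beta0 : float
        Expected %TWL at the mean composition for the reference surgery (SG).
    beta_ilr : array-like of 3 floats
        Outcome coefficients on the centred ILR coordinates.
    surgery_effect : float
        Additive %TWL difference for RYGB relative to SG.
    p_rygb : float
        Probability of RYGB (vs sleeve gastrectomy).
    sigma_eps : float
        Residual SD of %TWL.
    seed : int or None
        RNG seed; identical config + seed gives an identical cohort.
    """

    n_participants: int = 45
    mean_minutes: np.ndarray = field(
        default_factory=lambda: DEFAULT_MEAN_MINUTES.copy())
    ilr_covariance: np.ndarray = field(default_factory=default_ilr_covariance)
    beta0: float = 23.8
    beta_ilr: np.ndarray = field(default_factory=default_beta_ilr)
    surgery_effect: float = 3.0
    p_rygb: float = 0.20
    sigma_eps: float = 5.1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.mean_minutes = np.asarray(self.mean_minutes, dtype=float)
        self.ilr_covariance = np.asarray(self.ilr_covariance, dtype=float)
        self.beta_ilr = np.asarray(self.beta_ilr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.mean_minutes.shape != (4,) or np.any(self.mean_minutes <= 0):
            raise ValueError("mean_minutes must be 4 strictly positive values")
        S = self.ilr_covariance
        if S.shape != (3, 3) or not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("ilr_covariance must be symmetric 3x3")
        w = np.linalg.eigvalsh(S)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise ValueError("ilr_covariance is not positive semi-definite")
        if self.beta_ilr.shape != (3,):
            raise ValueError("beta_ilr must have 3 entries")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")
        if not 0.0 <= self.p_rygb <= 1.0:
            raise ValueError("p_rygb must be in [0, 1]")

    def _cov_factor(self) -> np.ndarray:
        w, U = np.linalg.eigh(self.ilr_covariance)
        return U * np.sqrt(np.clip(w, 0.0, None))

    def mean_ilr(self) -> np.ndarray:
        """ILR coordinates of the mean composition (generator basis)."""
        return ilr(closure(self.mean_minutes), GENERATOR_BASIS)


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Draw a cohort table: composition, covariates, surgery type, %TWL.

    Compositions are logistic-normal around the configured mean; the
    outcome is ``beta0 + beta_ilr . (z - mu_z) + surgery_effect 1[RYGB] +
    eps`` with ``eps ~ N(0, sigma_eps^2)``, so ``beta0`` is the expected
    %TWL for an SG patient at the mean composition. Age, sex, race and
    pre-surgery BMI are simulated with realistic marginals but zero true
    effect, exercising the covariate-screening step downstream.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    mu_z = config.mean_ilr()

    z = mu_z + rng.standard_normal((n, 3)) @ config._cov_factor().T
    comps = ilr_inverse(z, GENERATOR_BASIS, MINUTES_PER_DAY)

    rygb = rng.random(n) < config.p_rygb
    age = rng.normal(45.2, 11.3, n)
    female = rng.random(n) < 0.889
    white = rng.random(n) < 0.591
    bmi = rng.normal(46.4, 7.7, n)
    eps = rng.normal(0.0, config.sigma_eps, n)

    twl = (config.beta0
           + (z - mu_z) @ config.beta_ilr
           + config.surgery_effect * rygb
           + eps)

    out = pd.DataFrame({
        "participant_id": [f"P{i + 1:03d}" for i in range(n)],
        "sleep_min": comps[:, 0],
        "sb_min": comps[:, 1],
        "lpa_min": comps[:, 2],
        "mvpa_min": comps[:, 3],
        "age": age,
        "sex": np.where(female, "F", "M"),
        "race": np.where(white, "White", "Other"),
        "bmi_pre": bmi,
        "surgery": np.where(rygb, "RYGB", "SG"),
        "twl_pct": twl,
    })
    return out


def true_reallocation_effect(config: CohortSimConfig,
                             frm: int | str, to: int | str,
                             delta: float) -> float:
    """Exact expected %TWL change for a reallocation, from the generator.

    Computed analytically as ``beta_ilr . (z(reallocated) - z(reference))``
    at the reference composition ``closure(mean_minutes)``. Raises
    :class:`~timecoda.coda.InfeasibleReallocationError` under the same rule
    as the estimation module.
    """
    ref = closure(config.mean_minutes, MINUTES_PER_DAY)
    if delta == 0:
        from .coda import behavior_index
        if behavior_index(frm) == behavior_index(to):
            raise ValueError("source and destination behaviors must differ")
        return 0.0
    new = reallocate(ref, frm, to, delta)
    d = ilr(new, GENERATOR_BASIS) - ilr(ref, GENERATOR_BASIS)
    return float(d @ config.beta_ilr)


# ---------------------------------------------------------------------------
# minute-level epoch streams


@dataclass
class MinuteSimConfig:
    """Generating parameters for minute-epoch wrist-count streams.

    The sleep window (clock minutes, possibly spanning midnight) is flagged
    as sleep; wake minutes are assigned a behavior with probabilities
    ``wake_probs`` (SB, LPA, MVPA) and a counts/min value drawn from that
    behavior's log-normal ``(median, log_sd)``. Each distribution must put
    at least 95% of its mass inside its behavior's cut-point band so the
    stream round-trips through epoch classification. Non-wear is per-minute
    Bernoulli with probability ``nonwear_gap_rate / 24``.
    """

    sleep_onset: int = 1380   # 23:00
    sleep_offset: int = 387   # 06:27 -> 447 min of sleep
    count_distributions: dict = field(default_factory=lambda: {
        "sleep": (30.0, 1.0),
        "sb": (300.0, 0.9),
        "lpa": (3800.0, 0.28),
        "mvpa": (11000.0, 0.2),
    })
    wake_probs: np.ndarray = field(default_factory=lambda: (
        np.array([583.7, 366.0, 42.6]) / (583.7 + 366.0 + 42.6)))
    nonwear_gap_rate: float = 0.0
    n_days: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        self.wake_probs = np.asarray(self.wake_probs, dtype=float)
        self.validate()

    @property
    def sleep_minutes_per_day(self) -> int:
        return (self.sleep_offset - self.sleep_onset) % 1440

    def validate(self) -> None:
        for m in (self.sleep_onset, self.sleep_offset):
            if not 0 <= m < 1440:
                raise ValueError("sleep onset/offset must be clock minutes in [0, 1440)")
        if self.sleep_onset == self.sleep_offset:
            raise ValueError("sleep window is degenerate: onset equals offset")
        if not 0.0 <= self.nonwear_gap_rate <= 24.0:
            raise ValueError("nonwear_gap_rate must be in [0, 24] hours/day")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.wake_probs.shape != (3,) or np.any(self.wake_probs < 0):
            raise ValueError("wake_probs must be 3 non-negative values")
        if not np.isclose(self.wake_probs.sum(), 1.0):
            raise ValueError("wake_probs must sum to 1")
        for b, (lo, hi) in COUNT_BANDS.items():
            med, sd = self.count_distributions[b]
            dist = stats.lognorm(s=sd, scale=med)
            mass = dist.cdf(hi) - dist.cdf(lo)
            if mass < 0.95:
                raise ValueError(
                    f"counts distribution for {b!r} places only {mass:.3f} "
                    f"of its mass inside the [{lo:g}, {hi:g}) band")


def simulate_minute_stream(config: MinuteSimConfig,
                           participant_id: str = "P001",
                           start_date: str = "2024-01-01") -> pd.DataFrame:
    """Emit ``n_days`` x 1440 epoch records for one participant.

    Columns: ``participant_id, timestamp, counts, wear, sleep`` — the epoch
    CSV schema consumed by :mod:`timecoda.epochs`.
    """
    rng = np.random.default_rng(config.seed)
    minute = np.arange(1440)
    if config.sleep_onset < config.sleep_offset:
        sleep = (minute >= config.sleep_onset) & (minute < config.sleep_offset)
    else:
        sleep = (minute >= config.sleep_onset) | (minute < config.sleep_offset)

    wake_behaviors = np.array(["sb", "lpa", "mvpa"])
    frames = []
    t0 = pd.Timestamp(start_date)
    for day in range(config.n_days):
        behavior = np.where(
            sleep, "sleep",
            rng.choice(wake_behaviors, size=1440, p=config.wake_probs))
        meds = np.array([config.count_distributions[b][0] for b in behavior])
        sds = np.array([config.count_distributions[b][1] for b in behavior])
        counts = meds * np.exp(sds * rng.standard_normal(1440))
        wear = rng.random(1440) >= config.nonwear_gap_rate / 24.0
        frames.append(pd.DataFrame({
            "participant_id": participant_id,
            "timestamp": t0 + pd.Timedelta(days=day)
            + pd.to_timedelta(minute, unit="min"),
            "counts": np.round(counts, 1),
            "wear": wear.astype(int),
            "sleep": sleep.astype(int),
        }))
    return pd.concat(frames, ignore_index=True)
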