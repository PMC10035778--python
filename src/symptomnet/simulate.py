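"""Synthetic sessional cohorts with the structure the analysis assumes.

Each patient carries 16 ordinal items (0-3) at three occasions — assessment
(session 1), first treatment session (session 2) and the final session —
plus covariates and a binary treatment label (1 = CBT, 0 = CfD). Items are
generated by thresholding correlated latent Gaussians; occasions follow a
latent AR(1) process so that regression to the mean between the two
candidate baselines is present by construction; treatment is assigned by a
logistic model on covariates (confounding); treatment acts on the change
between session 2 and the final session, both directly (per-item shifts)
and by moderating symptom-symptom couplings of the change innovation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .items import (
    ETHNICITY_CATEGORIES,
    ITEM_CODES,
    N_ITEMS,
    item_columns,
)

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "filter_min_sessions",
    "assignment_design",
    "default_latent_correlation",
    "write_cohort_csv",
    "read_cohort_csv",
]

# Thresholds mapping a standard-normal latent to {0,1,2,3}. Placed to give
# the right-skewed severity marginals typical of treatment-seeking samples
# (per-item mean ~1.8 at baseline, falling to ~1.1 by the final session via
# the latent drifts below).
ORDINAL_THRESHOLDS = (-1.3, -0.3, 0.6)

# Covariates entering the treatment-assignment logistic model, in order.
ASSIGNMENT_COVARIATES = [
    "age",
    "gender",
    "employed",
    "medication",
    "impairment",
    "s1_total",
]


def default_latent_correlation() -> np.ndarray:
    """Two-block correlation for baseline items.

    Within-questionnaire correlations 0.40 (depression) / 0.45 (anxiety),
    cross-questionnaire 0.25 — the usual magnitudes for PHQ-9/GAD-7 item
    intercorrelations.
    """
    corr = np.full((N_ITEMS, N_ITEMS), 0.25)
    corr[:9, :9] = 0.40
    corr[9:, 9:] = 0.45
    np.fill_diagonal(corr, 1.0)
    return corr


def _default_couplings() -> list[tuple[int, int, float]]:
    # Control-arm conditional dependencies of the change innovation
    # (0-based indices into d1..d9,a1..a7).
    return [
        (0, 4, 0.30),   # anhedonia - appetite
        (1, 7, 0.30),   # depressed mood - psychomotor
        (2, 3, 0.30),   # sleep - fatigue
        (8, 6, 0.30),   # suicidal ideation - concentration
        (8, 13, 0.25),  # suicidal ideation - restlessness
        (9, 10, 0.30),  # nervousness - uncontrollable worry
        (10, 11, 0.30), # uncontrollable - excessive worry
        (14, 15, 0.30), # easily annoyed - apprehensive expectation
    ]


def _default_direct_effects() -> np.ndarray:
    # CBT reduces the worry/relaxation items more; CfD reduces thoughts of
    # failure more. Negative = larger reduction under treatment=1 (CBT).
    eff = np.zeros(N_ITEMS)
    eff[11] = -0.3  # excessive worry
    eff[12] = -0.3  # trouble relaxing
    eff[15] = -0.3  # apprehensive expectation
    eff[5] = 0.3    # failure (CfD advantage)
    return eff


def _default_moderation() -> list[tuple[int, int, float]]:
    # Treatment-specific shifts of the change couplings.
    return [
        (8, 6, 0.20),    # suicidal-concentration stronger under CBT
        (14, 15, -0.20), # annoyed-apprehensive stronger under CfD
    ]


@dataclass
class CohortConfig:
    """Generating parameters for one synthetic cohort.

    Parameters
    ----------
    n_per_arm : nominal arm size; ``2 * n_per_arm`` patients are generated
        and treatment assigned stochastically, so realized arms are only
        approximately equal when confounding is present.
    latent_correlation : 16x16 positive-definite correlation of the
        baseline latent severity.
    direct_effects : per-item treatment shift (latent SD units) applied to
        the session-2 -> final change under treatment=1.
    couplings : (i, j, w) control-arm conditional couplings of the change
        innovation, encoded as off-diagonal precision weights.
    moderation_effects : (i, j, delta) shifts of those couplings under
        treatment=1.
    confounding_strength : logistic coefficients of treatment assignment on
        the standardized covariates ``age, gender, employed, medication,
        impairment, s1_total`` (in that order).
    regression_to_mean : latent autocorrelation between consecutive
        occasions; values < 1 produce regression to the mean.
    exact_change_precision : when True, the final-session innovation
        covariance is adjusted so that the *latent* session-2 -> final
        change has exactly the sparse conditional-dependence graph given
        by ``couplings`` (plus moderation in arm 1); with the default
        False, the AR carry-over adds a weak dense background to the
        change distribution, as in real sessional data.
    waiting_drift, treatment_drift : latent mean shifts applied at session 2
        and at the final session (both arms), reproducing the improvement
        while waiting and during treatment.
    """

    n_per_arm: int = 2000
    latent_correlation: np.ndarray = field(default_factory=default_latent_correlation)
    direct_effects: np.ndarray = field(default_factory=_default_direct_effects)
    couplings: list = field(default_factory=_default_couplings)
    moderation_effects: list = field(default_factory=_default_moderation)
    confounding_strength: np.ndarray = field(
        default_factory=lambda: np.array([0.4, 0.3, 0.0, 0.2, 0.1, 0.2])
    )
    regression_to_mean: float = 0.7
    waiting_drift: float = -0.25
    treatment_drift: float = -0.55
    exact_change_precision: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.latent_correlation = np.asarray(self.latent_correlation, dtype=float)
        self.direct_effects = np.asarray(self.direct_effects, dtype=float)
        self.confounding_strength = np.asarray(self.confounding_strength, dtype=float)
        if self.latent_correlation.shape != (N_ITEMS, N_ITEMS):
            raise ValueError("latent_correlation must be 16x16")
        if np.linalg.eigvalsh(self.latent_correlation).min() <= 0:
            raise ValueError("latent_correlation must be positive definite")
        if self.direct_effects.shape != (N_ITEMS,):
            raise ValueError("direct_effects must have length 16")
        for i, j, _ in list(self.couplings) + list(self.moderation_effects):
            if not (0 <= i < N_ITEMS and 0 <= j < N_ITEMS) or i == j:
                raise ValueError(f"coupling index pair ({i}, {j}) out of range")
        if not 0.0 <= self.regression_to_mean <= 1.0:
            raise ValueError("regression_to_mean must be in [0, 1]")

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)


def _innovation_correlation(config: CohortConfig, arm: int) -> np.ndarray:
    """Correlation of the final-session change innovation for one arm.

    Couplings are placed on the precision matrix (negated off-diagonals so
    positive weights give positive partial correlations), inverted, and
    rescaled to unit marginal variance.
    """
    prec = np.eye(N_ITEMS)
    for i, j, w in config.couplings:
        prec[i, j] -= w
        prec[j, i] -= w
    if arm == 1:
        for i, j, delta in config.moderation_effects:
            prec[i, j] -= delta
            prec[j, i] -= delta
    if np.linalg.eigvalsh(prec).min() <= 1e-10:
        raise ValueError(
            "coupling/moderation weights yield a non-positive-definite "
            "innovation precision; reduce their magnitudes"
        )
    cov = np.linalg.inv(prec)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _ordinalize(latent: np.ndarray) -> np.ndarray:
    return np.digitize(latent, ORDINAL_THRESHOLDS).astype(np.int64)


def assignment_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Standardized covariate matrix used by the assignment model.

    Recomputable from a generated cohort, so recovery of the generating
    coefficients can be checked by refitting a logistic model.
    """
    s1 = cohort[item_columns("s1")].sum(axis=1)
    raw = pd.DataFrame(
        {
            "age": cohort["age"],
            "gender": cohort["gender"],
            "employed": cohort["employed"],
            "medication": cohort["medication"],
            "impairment": cohort["impairment"],
            "s1_total": s1,
        }
    )
    return (raw - raw.mean()) / raw.std(ddof=0)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_arm
    rho = config.regression_to_mean

    # --- covariates -----------------------------------------------------
    age = rng.normal(41.0, 13.0, n).clip(18, 90)
    gender = rng.binomial(1, 0.31, n)  # 1 = male
    employed = rng.binomial(1, 0.60, n)
    medication = rng.binomial(1, 0.35, n)
    ethnicity = rng.choice(
        ETHNICITY_CATEGORIES, size=n, p=[0.595, 0.065, 0.145, 0.12, 0.006, 0.069]
    )

    # --- baseline latent severity and session-1 items -------------------
    chol = np.linalg.cholesky(config.latent_correlation)
    z1 = rng.standard_normal((n, N_ITEMS)) @ chol.T
    items_s1 = _ordinalize(z1)

    # Functional impairment (WSAS-like total, 0-40) tracks latent severity.
    impairment = np.rint(20.0 + 4.0 * z1.mean(axis=1) + rng.normal(0, 6, n)).clip(0, 40)

    # --- treatment assignment (confounded) ------------------------------
    raw = np.column_stack(
        [age, gender, employed, medication, impairment, items_s1.sum(axis=1)]
    )
    std = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    lin = std @ config.confounding_strength
    treatment = rng.binomial(1, 1.0 / (1.0 + np.exp(-(lin - lin.mean()))))

    # --- session 2: AR(1) with waiting-period drift ----------------------
    e2 = rng.standard_normal((n, N_ITEMS)) @ chol.T
    z2 = config.waiting_drift + rho * z1 + np.sqrt(1.0 - rho**2) * e2
    items_s2 = _ordinalize(z2)

    # --- final session: AR(1) + treatment effects on the change ----------
    u = np.empty((n, N_ITEMS))
    for arm in (0, 1):
        mask = treatment == arm
        cov_u = _innovation_correlation(config, arm)
        if config.exact_change_precision:
            # solve (1-rho)^2 S_L + (1-rho^2) S_u = s * S_graph for S_u so
            # the latent change keeps the sparse graph exactly
            a, b = (1.0 - rho) ** 2, 1.0 - rho**2
            cov_u = ((a + b) * cov_u - a * config.latent_correlation) / b
            if np.linalg.eigvalsh(cov_u).min() <= 1e-10:
                raise ValueError(
                    "exact_change_precision infeasible for this latent "
                    "correlation / coupling combination"
                )
        chol_u = np.linalg.cholesky(cov_u)
        u[mask] = rng.standard_normal((int(mask.sum()), N_ITEMS)) @ chol_u.T
    z3 = (
        config.treatment_drift
        + rho * z2
        + treatment[:, None] * config.direct_effects[None, :]
        + np.sqrt(1.0 - rho**2) * u
    )
    items_final = _ordinalize(z3)

    # --- attendance and waiting time -------------------------------------
    n_sessions = np.maximum(1, rng.poisson(10.5 + 0.5 * treatment))
    days = np.rint(rng.normal(59.9 + 6.5 * treatment, 49.0)).clip(0, None)

    out = {"patient_id": [f"p{k:06d}" for k in range(n)], "treatment": treatment}
    for occ, items in (("s1", items_s1), ("s2", items_s2), ("final", items_final)):
        for c, code in enumerate(ITEM_CODES):
            out[f"{code}_{occ}"] = items[:, c]
    out.update(
        age=np.rint(age).astype(int),
        gender=gender,
        employed=employed,
        medication=medication,
        ethnicity=ethnicity,
        impairment=impairment.astype(int),
        n_sessions=n_sessions,
        days_s1_to_s2=days.astype(int),
    )
    return pd.DataFrame(out)


def filter_min_sessions(cohort: pd.DataFrame, minimum: int = 5) -> pd.DataFrame:
    """Keep patients who attended at least ``minimum`` sessions (default 5)."""
    if minimum < 1:
        raise ValueError("minimum must be >= 1")
    return cohort.loc[cohort["n_sessions"] >= minimum]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = [c for c in ("patient_id", "treatment", "n_sessions") if c not in cohort]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    return cohort
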