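"""Propensity-score estimation and Mahalanobis-within-caliper 1:1 matching.

Treatment assignment in routine-care cohorts is not random, so the two
arms are balanced on observed covariates before network estimation: a
main-effects logistic model gives each patient a propensity of receiving
treatment 1; the larger arm is then pruned to the smaller by greedy 1:1
nearest-neighbour matching without replacement, with candidates restricted
to a caliper on the logit propensity (default 0.25 SD) and chosen by
smallest Mahalanobis distance over the matching covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .items import ETHNICITY_CATEGORIES, item_columns

__all__ = [
    "MatchConfig",
    "MatchedSample",
    "PropensityMatcher",
    "estimate_propensity",
    "match",
    "default_matching_covariates",
    "standardized_mean_differences",
]


def default_matching_covariates() -> list[str]:
    """Session-1 item scores plus the demographic/clinical covariates."""
    return item_columns("s1") + [
        "gender",
        "employed",
        "medication",
        "age",
        "ethnicity",
        "impairment",
    ]


@dataclass
class MatchConfig:
    """Caliper width (in SDs of the logit propensity), 1:1, no replacement."""

    caliper: float = 0.25
    ratio: int = 1
    replacement: bool = False
    covariate_list: list = field(default_factory=default_matching_covariates)

    def __post_init__(self) -> None:
        if self.caliper <= 0:
            raise ValueError("caliper must be > 0")
        if self.ratio != 1 or self.replacement:
            raise ValueError("only 1:1 matching without replacement is supported")


@dataclass
class MatchedSample:
    pairs: list  # (treatment-1 id, treatment-0 id)
    propensity: pd.Series
    balance_table: pd.DataFrame  # per covariate: smd_before, smd_after

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def matched_ids(self) -> list:
        return [i for pair in self.pairs for i in pair]

    def pairs_to_csv(self, path) -> None:
        pd.DataFrame(self.pairs, columns=["treated_id", "control_id"]).to_csv(
            path, index=False
        )

    def balance_to_json(self, path) -> None:
        self.balance_table.to_json(path, orient="index", double_precision=10)


def _design_matrix(records: pd.DataFrame, covariate_list) -> pd.DataFrame:
    """Numeric design with ethnicity expanded to indicator columns."""
    cols = []
    for cov in covariate_list:
        if cov == "ethnicity":
            dummies = pd.get_dummies(records["ethnicity"], prefix="ethnicity")
            # drop one reference level; keep a fixed ordering
            ordered = [
                f"ethnicity_{c}" for c in ETHNICITY_CATEGORIES[1:] if f"ethnicity_{c}" in dummies
            ]
            cols.append(dummies.reindex(columns=ordered, fill_value=0).astype(float))
        else:
            cols.append(records[[cov]].astype(float))
    return pd.concat(cols, axis=1)


def _find_separating_covariate(X: pd.DataFrame, t: np.ndarray) -> str | None:
    for c in X.columns:
        x = X[c].to_numpy()
        if x[t == 1].min() > x[t == 0].max() or x[t == 0].min() > x[t == 1].max():
            return c
    return None


def estimate_propensity(
    records: pd.DataFrame,
    covariate_list=None,
    return_model: bool = False,
):
    """Fitted probabilities of treatment=1 from a main-effects logistic model.

    Raises on perfect separation, naming the separating covariate when one
    can be identified.
    """
    covariate_list = covariate_list or default_matching_covariates()
    X = _design_matrix(records, covariate_list)
    t = records["treatment"].to_numpy()
    if len(np.unique(t)) < 2:
        raise ValueError("both treatment arms must be present")
    X = X.loc[:, X.std(ddof=0) > 0]  # drop constant columns (absent categories)
    culprit = _find_separating_covariate(X, t)
    if culprit is not None:
        raise ValueError(
            f"propensity model is perfectly separated (separating covariate: {culprit})"
        )
    exog = sm.add_constant(X.to_numpy(dtype=float))
    try:
        with warnings.catch_warnings():
            # quasi-separation of rare indicator levels inflates their
            # coefficients without harming the fitted probabilities; only a
            # degenerate likelihood is fatal
            warnings.simplefilter("ignore")
            model = sm.Logit(t, exog)
            try:
                res = model.fit(disp=0, maxiter=200)
            except np.linalg.LinAlgError:
                # Newton can hit a singular Hessian when a rare indicator
                # level is quasi-separated; BFGS does not need the inverse
                res = model.fit(disp=0, maxiter=500, method="bfgs")
        if not np.isfinite(res.params).all():
            raise PerfectSeparationError("non-finite coefficients")
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise ValueError(f"propensity model could not be fitted: {err}") from err
    scores = pd.Series(res.predict(exog), index=records.index, name="propensity")
    scores = scores.clip(1e-12, 1 - 1e-12)
    if return_model:
        return scores, res, list(X.columns)
    return scores


def standardized_mean_differences(
    records: pd.DataFrame, covariate_list, subset_index=None, denom: pd.Series = None
) -> pd.Series:
    """Arm-1 minus arm-0 mean over pooled SD, per (indicator-coded) covariate.

    ``denom`` fixes the SD denominators (conventionally the pre-matching
    ones) so before/after values are on a common scale.
    """
    X = _design_matrix(records, covariate_list)
    t = records["treatment"]
    if denom is None:
        v1 = X[t == 1].var(ddof=1)
        v0 = X[t == 0].var(ddof=1)
        denom = np.sqrt((v1 + v0) / 2.0)
    if subset_index is not None:
        X, t = X.loc[subset_index], t.loc[subset_index]
    diff = X[t == 1].mean() - X[t == 0].mean()
    return diff / denom.replace(0.0, np.nan)


class PropensityMatcher:
    """Estimator-style wrapper: ``fit(records)`` -> fitted matching attributes.

    Attributes after ``fit``: ``propensity_`` (per-patient score),
    ``pairs_`` (id pairs, treatment-1 first), ``balance_table_`` (SMD
    before/after per covariate), ``matched_ids_``.
    """

    def __init__(self, caliper: float = 0.25, covariate_list=None):
        self.caliper = caliper
        self.covariate_list = covariate_list

    def get_params(self, deep: bool = True) -> dict:
        return {"caliper": self.caliper, "covariate_list": self.covariate_list}

    def set_params(self, **params) -> "PropensityMatcher":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, records: pd.DataFrame) -> "PropensityMatcher":
        config = MatchConfig(
            caliper=self.caliper,
            covariate_list=self.covariate_list or default_matching_covariates(),
        )
        propensity = estimate_propensity(records, config.covariate_list)
        sample = match(records, propensity, config)
        self.propensity_ = sample.propensity
        self.pairs_ = sample.pairs
        self.balance_table_ = sample.balance_table
        self.matched_ids_ = sample.matched_ids
        self.matched_sample_ = sample
        return self

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        """Rows of ``records`` retained by the match, in pair order."""
        idx = records.set_index("patient_id").loc[self.matched_ids_].index
        return records.set_index("patient_id").loc[idx].reset_index()

    def fit_transform(self, records: pd.DataFrame) -> pd.DataFrame:
        return self.fit(records).transform(records)


def match(
    records: pd.DataFrame, propensity: pd.Series, config: MatchConfig = None
) -> MatchedSample:
    """Greedy caliper matching; see the module docstring for the procedure.

    The majority arm plays the role of the treated side and is pruned down
    to the minority arm size. Treated units are processed in descending
    propensity order; distance ties break on the smallest control position.
    If no treated unit has any within-caliper candidate the result is an
    empty ``MatchedSample`` with a warning.
    """
    config = config or MatchConfig()
    t = records["treatment"].to_numpy()
    ids = records["patient_id"].to_numpy()
    p = propensity.to_numpy()
    logit = np.log(p / (1.0 - p))
    width = config.caliper * logit.std(ddof=1)

    majority = 1 if (t == 1).sum() >= (t == 0).sum() else 0
    treated_pos = np.flatnonzero(t == majority)
    control_pos = np.flatnonzero(t != majority)

    X = _design_matrix(records, config.covariate_list).to_numpy(dtype=float)
    VI = np.linalg.pinv(np.atleast_2d(np.cov(X, rowvar=False)))

    order = treated_pos[np.argsort(-p[treated_pos], kind="stable")]
    available = dict.fromkeys(control_pos.tolist())  # insertion-ordered set
    pairs_pos: list[tuple[int, int]] = []
    for ti in order:
        if not available:
            break
        cand = np.fromiter(available.keys(), dtype=int)
        cand = cand[np.abs(logit[cand] - logit[ti]) <= width]
        if cand.size == 0:
            continue
        d = X[cand] - X[ti]
        maha = np.einsum("ij,jk,ik->i", d, VI, d)
        best = cand[int(np.argmin(maha))]  # argmin keeps first on ties
        pairs_pos.append((ti, best))
        del available[best]

    if not pairs_pos:
        warnings.warn("no within-caliper matches found; returning empty sample")

    # report pairs as (treatment-1 id, treatment-0 id) regardless of which
    # arm was the majority
    pairs = [
        (ids[a], ids[b]) if majority == 1 else (ids[b], ids[a])
        for a, b in pairs_pos
    ]
    matched_pos = [i for ab in pairs_pos for i in ab]
    smd_before = standardized_mean_differences(records, config.covariate_list)
    v1 = _design_matrix(records, config.covariate_list)[t == 1].var(ddof=1)
    v0 = _design_matrix(records, config.covariate_list)[t == 0].var(ddof=1)
    denom = np.sqrt((v1 + v0) / 2.0)
    smd_after = standardized_mean_differences(
        records,
        config.covariate_list,
        subset_index=records.index[matched_pos] if matched_pos else records.index[:0],
        denom=denom,
    )
    balance = pd.DataFrame({"smd_before": smd_before, "smd_after": smd_after})
    return MatchedSample(
        pairs=pairs,
        propensity=pd.Series(p, index=records.index, name="propensity"),
        balance_table=balance,
    )
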