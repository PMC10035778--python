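"""Change-score operationalizations of symptom change.

Five methods, each applied per item against a chosen baseline occasion:

- ``FS`` final score: post
- ``DS`` difference score: post - pre
- ``PC`` proportional change: 100 * (post - pre) / pre
- ``RP`` residual score: post minus its OLS prediction from pre
- ``RC`` residual change score: DS minus its OLS prediction from pre

RP and RC are algebraically identical when the regressions are fitted by
OLS on the same sample (the DS-on-pre slope equals the post-on-pre slope
minus one), which :func:`residual_identity_check` verifies numerically.
The residualizing regressions are fitted on the full supplied sample,
pooled across treatment arms, so the treatment contrast is not absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .items import NODE_LABELS

__all__ = [
    "ChangeSpec",
    "ChangeMatrix",
    "ChangeScorer",
    "compute_change",
    "residual_identity_check",
]

METHODS = ("FS", "DS", "PC", "RP", "RC")
BASELINES = ("session1", "session2")


@dataclass(frozen=True)
class ChangeSpec:
    """A change-score method paired with a baseline occasion.

    ``FS`` ignores the baseline values but keeps the choice as metadata so
    grid labels stay unambiguous.
    """

    method: str
    baseline: str = "session2"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.baseline not in BASELINES:
            raise ValueError(
                f"baseline must be one of {BASELINES}, got {self.baseline!r}"
            )

    def label(self, matched: bool = False) -> str:
        """Model label, e.g. ``RC2`` or ``RCX2`` for a matched sample."""
        digit = "1" if self.baseline == "session1" else "2"
        return f"{self.method}{'X' if matched else ''}{digit}"


@dataclass
class ChangeMatrix:
    """Per-patient, per-item change scores plus a mask of undefined entries."""

    values: pd.DataFrame
    spec: ChangeSpec
    missing_mask: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.missing_mask is None:
            self.missing_mask = self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.to_numpy().sum())

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.columns = [f"{self.spec.label()}_{c}" for c in out.columns]
        out.to_csv(path, index=False)


def _as_frame(x, name: str) -> pd.DataFrame:
    df = pd.DataFrame(x)
    if df.shape[1] == len(NODE_LABELS) and not all(
        isinstance(c, str) for c in df.columns
    ):
        df.columns = NODE_LABELS
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, [0.0, 1.0, 2.0, 3.0])
    if not ok.all():
        raise ValueError(f"{name} entries must be in {{0,1,2,3}} or missing")
    return df.astype(float)


class ChangeScorer:
    """Transformer-style interface around :func:`compute_change`.

    ``fit`` learns the per-item residualizing regressions (a no-op for FS,
    DS and PC); ``transform`` produces the change matrix. ``fit_transform``
    on one sample reproduces :func:`compute_change` exactly.
    """

    def __init__(self, method: str = "RC", baseline: str = "session2"):
        self.method = method
        self.baseline = baseline

    def get_params(self, deep: bool = True) -> dict:
        return {"method": self.method, "baseline": self.baseline}

    def set_params(self, **params) -> "ChangeScorer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @property
    def spec_(self) -> ChangeSpec:
        return ChangeSpec(self.method, self.baseline)

    def fit(self, pre, post) -> "ChangeScorer":
        spec = self.spec_
        pre_f, post_f = _as_frame(pre, "pre"), _as_frame(post, "post")
        if pre_f.shape != post_f.shape:
            raise ValueError("pre and post must have the same shape")
        p, q = pre_f.to_numpy(), post_f.to_numpy()
        self.coef_ = np.zeros((2, p.shape[1]))  # rows: intercept, slope
        if spec.method in ("RP", "RC"):
            if p.shape[0] < 2:
                raise ValueError("residual scores need at least 2 patients")
            target = q if spec.method == "RP" else q - p
            for j in range(p.shape[1]):
                obs = ~(np.isnan(p[:, j]) | np.isnan(target[:, j]))
                if obs.sum() < 2:
                    raise ValueError(
                        "residual scores need at least 2 complete cases per item"
                    )
                x, y = p[obs, j], target[obs, j]
                vx = x.var()
                slope = 0.0 if vx == 0 else np.cov(x, y, bias=True)[0, 1] / vx
                self.coef_[:, j] = (y.mean() - slope * x.mean(), slope)
        self.columns_ = list(pre_f.columns)
        return self

    def transform(self, pre, post) -> ChangeMatrix:
        spec = self.spec_
        pre_f, post_f = _as_frame(pre, "pre"), _as_frame(post, "post")
        p, q = pre_f.to_numpy(), post_f.to_numpy()
        ds = q - p
        if spec.method == "FS":
            vals = q
        elif spec.method == "DS":
            vals = ds
        elif spec.method == "PC":
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.where(p == 0, np.nan, 100.0 * ds / p)
        elif spec.method == "RP":
            vals = q - (self.coef_[0] + self.coef_[1] * p)
        else:  # RC
            vals = ds - (self.coef_[0] + self.coef_[1] * p)
        values = pd.DataFrame(vals, columns=pre_f.columns, index=pre_f.index)
        return ChangeMatrix(values=values, spec=spec)

    def fit_transform(self, pre, post) -> ChangeMatrix:
        return self.fit(pre, post).transform(pre, post)


def compute_change(pre, post, spec: ChangeSpec) -> ChangeMatrix:
    """Compute one change-score matrix; see the module docstring for formulas.

    PC entries with a zero baseline are undefined and flagged in
    ``missing_mask`` rather than imputed; RP/RC regressions are fitted on
    the full supplied sample.
    """
    return ChangeScorer(spec.method, spec.baseline).fit_transform(pre, post)


def residual_identity_check(pre, post) -> float:
    """Max absolute elementwise difference between RP and RC scores.

    Exact OLS on a shared sample makes the two residual formulations
    identical, so this should be at numerical zero.
    """
    rp = compute_change(pre, post, ChangeSpec("RP")).values.to_numpy()
    rc = compute_change(pre, post, ChangeSpec("RC")).values.to_numpy()
    return float(np.nanmax(np.abs(rp - rc)))
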