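"""Moderated network estimation with a binary treatment node.

The 16 symptom-change scores form the nodes of a conditional-dependence
network; a binary treatment indicator (1 = CBT, 0 = CfD) enters every
nodewise regression both directly and through treatment x symptom product
terms, so the model captures (a) symptom-symptom edges in the reference
arm, (b) direct treatment-to-symptom associations — the mean difference in
each symptom's change between arms controlling for all other symptom
changes — and (c) moderation: treatment-specific shifts of pairwise edges.

Estimation is nodewise: each node's change score is regressed on the other
15 (standardized) change scores, the treatment indicator and the 15
product terms, with an elastic-net penalty whose weight and mixing
parameter are chosen by K-fold cross-validation (default 10-fold, shared
fold assignment across nodes derived from the run seed). Neighbourhoods
are combined with the AND rule: an edge or moderation term survives only
when selected in both of its two regressions, its weight being the mean of
the two coefficients (zero when their signs conflict). The treatment node
is exogenous — no regression with treatment as the outcome is estimated —
so direct associations come solely from the symptom regressions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .items import NODE_LABELS

__all__ = [
    "ModeratedNetworkEstimator",
    "BootstrapSummary",
    "RedundancyConfig",
    "nodewise_fit",
    "assemble_network",
    "condition_on_treatment",
    "bootstrap_network",
    "redundancy_check",
]

L1_RATIOS = (0.25, 0.5, 0.75, 1.0)
_ZERO_TOL = 1e-12


def _complete_rows(X: np.ndarray, treatment: np.ndarray):
    ok = ~np.isnan(X).any(axis=1)
    return X[ok], treatment[ok], int((~ok).sum())


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        warnings.warn(f"constant change-score column(s) {bad.tolist()}; left at zero")
        sd = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=0)) / sd


def nodewise_fit(
    change_matrix,
    treatment_vector,
    node_index: int,
    folds: int = 10,
    l1_ratios=L1_RATIOS,
    alpha: float | None = None,
    l1_ratio: float | None = None,
    n_alphas: int = 40,
    threshold: str | float | None = "lw",
    random_state: int = 0,
) -> dict:
    """One node's elastic-net neighbourhood regression.

    Regresses node ``node_index``'s (standardized) change score on the
    other 15 standardized change scores, the raw 0/1 treatment indicator
    and the 15 treatment x score products. With ``alpha=None`` the penalty
    weight and mixing parameter are selected by ``folds``-fold CV at the
    minimum mean prediction error; passing ``alpha`` (and ``l1_ratio``)
    fixes the penalty instead. Returns coefficients on the
    standardized-predictor scale.

    Cross-validated lasso-type selection at the CV minimum is not
    model-selection consistent: it retains many tiny spurious
    coefficients. Following standard practice for nodewise graphical-model
    estimation, coefficients below a Loh-Wainwright-style threshold
    ``tau = sqrt(d) * sqrt(log(p) / n)`` (``d=2`` for pairwise-plus-
    moderation models, ``p`` = number of predictors) are set to zero when
    ``threshold='lw'`` (the default); a float fixes ``tau`` directly and
    ``None`` disables thresholding.
    """
    X = np.asarray(pd.DataFrame(change_matrix), dtype=float)
    t = np.asarray(treatment_vector, dtype=float)
    X, t, _ = _complete_rows(X, t)
    n, p = X.shape
    Z = _standardize(X)
    others = [j for j in range(p) if j != node_index]
    design = np.column_stack([Z[:, others], t, t[:, None] * Z[:, others]])
    y = X[:, node_index]
    if y.std() == 0:
        warnings.warn(f"node {node_index} outcome is constant; returning zero model")
        coef = np.zeros(design.shape[1])
        sel_alpha, sel_l1 = np.inf, 1.0
    else:
        y = (y - y.mean()) / y.std(ddof=0)
        if alpha is not None:
            model = ElasticNet(
                alpha=alpha, l1_ratio=l1_ratio if l1_ratio is not None else 0.5,
                max_iter=10_000,
            )
            model.fit(design, y)
            coef, sel_alpha = model.coef_, alpha
            sel_l1 = model.l1_ratio
        else:
            cv = KFold(n_splits=folds, shuffle=True, random_state=random_state)
            model = ElasticNetCV(
                l1_ratio=list(l1_ratios), alphas=n_alphas, cv=cv, max_iter=10_000,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(design, y)
            coef, sel_alpha, sel_l1 = model.coef_, model.alpha_, model.l1_ratio_
    if threshold is not None:
        tau = (
            np.sqrt(2.0 * np.log(design.shape[1]) / n)
            if threshold == "lw"
            else float(threshold)
        )
        # compare on the standardized-coefficient scale: the treatment and
        # product columns are not unit-variance, so their raw coefficients
        # overstate the standardized contribution by 1/sd
        scale = design.std(axis=0, ddof=0)
        coef = np.where(np.abs(coef) * scale < tau, 0.0, coef)
    m = p - 1
    neighbors = np.zeros(p)
    interactions = np.zeros(p)
    neighbors[others] = coef[:m]
    interactions[others] = coef[m + 1 :]
    return {
        "node": node_index,
        "neighbors": neighbors,
        "treatment": float(coef[m]),
        "interactions": interactions,
        "alpha": float(sel_alpha),
        "l1_ratio": float(sel_l1),
        "n_rows": n,
    }


def assemble_network(fits: list[dict], node_labels=None):
    """Combine nodewise fits with the AND rule.

    Edge (i, j) is nonzero only when j's coefficient in i's regression and
    i's in j's are both nonzero; the weight is their mean, or 0 when the
    signs conflict. The same rule applies to the treatment x symptom
    product terms (moderation). The direct treatment association for node
    j is the treatment coefficient of j's own regression — the exogenous
    treatment node has no regression of its own, so no AND counterpart
    exists.
    """
    nodes = sorted(f["node"] for f in fits)
    p = len(nodes)
    if nodes != list(range(p)):
        raise ValueError("need exactly one fit per node, nodes 0..p-1")
    by_node = {f["node"]: f for f in fits}
    pairwise = np.zeros((p, p))
    moderation = np.zeros((p, p))
    direct = np.array([by_node[j]["treatment"] for j in range(p)])
    for i in range(p):
        for j in range(i + 1, p):
            for key, mat in (("neighbors", pairwise), ("interactions", moderation)):
                a = by_node[i][key][j]
                b = by_node[j][key][i]
                if abs(a) > _ZERO_TOL and abs(b) > _ZERO_TOL:
                    mat[i, j] = mat[j, i] = 0.0 if a * b < 0 else (a + b) / 2.0
    direct[np.abs(direct) <= _ZERO_TOL] = 0.0
    labels = list(node_labels) if node_labels is not None else list(NODE_LABELS[:p])
    meta = {
        f["node"]: {k: f[k] for k in ("alpha", "l1_ratio", "n_rows")} for f in fits
    }
    return pairwise, direct, moderation, labels, meta


class ModeratedNetworkEstimator(BaseEstimator):
    """Scikit-learn style estimator for the moderated symptom network.

    Parameters
    ----------
    folds : CV folds for penalty selection (default 10).
    l1_ratios : candidate elastic-net mixing parameters.
    alpha, l1_ratio : fix the penalty instead of cross-validating.
    n_alphas : length of the penalty path per mixing parameter.
    threshold : post-selection coefficient threshold ('lw', a float, or
        None; see :func:`nodewise_fit`).
    random_state : seeds the shared CV fold assignment.

    Attributes (after ``fit``)
    --------------------------
    pairwise_ : (16, 16) symmetric reference-arm (treatment=0) edge weights.
    direct_ : (16,) treatment->symptom associations.
    moderation_ : (16, 16) symmetric treatment x edge interaction weights.
    node_labels_ : node names.
    fit_meta_ : per-node selected penalties, plus the run seed and the
        number of complete-case rows used.
    """

    def __init__(
        self,
        folds: int = 10,
        l1_ratios=L1_RATIOS,
        alpha: float | None = None,
        l1_ratio: float | None = None,
        n_alphas: int = 40,
        threshold: str | float | None = "lw",
        random_state: int = 0,
    ):
        self.folds = folds
        self.l1_ratios = l1_ratios
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.n_alphas = n_alphas
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, treatment) -> "ModeratedNetworkEstimator":
        frame = pd.DataFrame(X)
        labels = (
            list(frame.columns)
            if all(isinstance(c, str) for c in frame.columns)
            else list(NODE_LABELS[: frame.shape[1]])
        )
        Xv = frame.to_numpy(dtype=float)
        t = np.asarray(treatment, dtype=float)
        if Xv.shape[0] != t.shape[0]:
            raise ValueError("X and treatment must have the same number of rows")
        if not np.isin(t[~np.isnan(t)], [0.0, 1.0]).all():
            raise ValueError("treatment must be binary 0/1")
        Xc, tc, n_dropped = _complete_rows(Xv, t)
        fits = [
            nodewise_fit(
                Xc,
                tc,
                j,
                folds=self.folds,
                l1_ratios=self.l1_ratios,
                alpha=self.alpha,
                l1_ratio=self.l1_ratio,
                n_alphas=self.n_alphas,
                threshold=self.threshold,
                random_state=self.random_state,
            )
            for j in range(Xv.shape[1])
        ]
        pairwise, direct, moderation, labels, meta = assemble_network(fits, labels)
        self.pairwise_ = pairwise
        self.direct_ = direct
        self.moderation_ = moderation
        self.node_labels_ = labels
        self.fit_meta_ = {
            "nodes": meta,
            "random_state": self.random_state,
            "n_rows": int(Xc.shape[0]),
            "n_dropped_incomplete": n_dropped,
        }
        return self

    def condition_on_treatment(self, arm: int) -> np.ndarray:
        """Arm-specific pairwise matrix: arm 0 -> pairwise; arm 1 ->
        pairwise + moderation (entrywise)."""
        return condition_on_treatment(self, arm)

    # --- export ---------------------------------------------------------

    def to_edge_list(self, inclusion: pd.DataFrame | None = None) -> pd.DataFrame:
        """Long-format edge list (pairwise, direct and moderation rows)."""
        rows = []
        p = len(self.node_labels_)
        for i in range(p):
            for j in range(i + 1, p):
                for kind, mat in (
                    ("pairwise", self.pairwise_),
                    ("moderation", self.moderation_),
                ):
                    if mat[i, j] != 0.0:
                        rows.append(
                            (self.node_labels_[i], self.node_labels_[j], kind, mat[i, j])
                        )
        for j in range(p):
            if self.direct_[j] != 0.0:
                rows.append(("treatment", self.node_labels_[j], "direct", self.direct_[j]))
        out = pd.DataFrame(rows, columns=["node_i", "node_j", "type", "weight"])
        if inclusion is not None:
            out = out.merge(inclusion, on=["node_i", "node_j", "type"], how="left")
        return out

    def to_json(self, path=None):
        payload = {
            "node_labels": self.node_labels_,
            "pairwise": self.pairwise_.tolist(),
            "direct": self.direct_.tolist(),
            "moderation": self.moderation_.tolist(),
            "fit_meta": self.fit_meta_,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_networkx(self, arm: int | None = None):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_labels_)
        mat = self.pairwise_ if arm is None else self.condition_on_treatment(arm)
        p = len(self.node_labels_)
        for i in range(p):
            for j in range(i + 1, p):
                if mat[i, j] != 0.0:
                    g.add_edge(self.node_labels_[i], self.node_labels_[j], weight=mat[i, j])
        return g


def condition_on_treatment(network, arm: int) -> np.ndarray:
    if arm not in (0, 1):
        raise ValueError("arm must be 0 or 1")
    if arm == 0:
        return network.pairwise_.copy()
    return network.pairwise_ + network.moderation_


# --- bootstrap stability ------------------------------------------------


@dataclass
class BootstrapSummary:
    """Case-resampling bootstrap of the full fit (CV included).

    ``inclusion`` is the proportion of resamples in which a parameter was
    nonzero; ``quantile_low``/``quantile_high`` are the 2.5% / 97.5%
    bootstrap quantiles.
    """

    n_boot: int
    node_labels: list
    inclusion: dict = field(default_factory=dict)
    quantile_low: dict = field(default_factory=dict)
    quantile_high: dict = field(default_factory=dict)
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        p = len(self.node_labels)
        for kind in ("pairwise", "moderation"):
            for i in range(p):
                for j in range(i + 1, p):
                    rows.append(
                        (
                            self.node_labels[i],
                            self.node_labels[j],
                            kind,
                            self.inclusion[kind][i, j],
                            self.quantile_low[kind][i, j],
                            self.quantile_high[kind][i, j],
                        )
                    )
        for j in range(p):
            rows.append(
                (
                    "treatment",
                    self.node_labels[j],
                    "direct",
                    self.inclusion["direct"][j],
                    self.quantile_low["direct"][j],
                    self.quantile_high["direct"][j],
                )
            )
        return pd.DataFrame(
            rows,
            columns=["node_i", "node_j", "type", "inclusion", "q025", "q975"],
        )


def bootstrap_network(
    change_matrix,
    treatment_vector,
    n_boot: int = 1000,
    seed: int = 0,
    **estimator_params,
) -> BootstrapSummary:
    """Refit the whole pipeline (penalty selection included) on ``n_boot``
    case resamples; deterministic given ``seed``."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = pd.DataFrame(change_matrix).to_numpy(dtype=float)
    t = np.asarray(treatment_vector, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    draws = {"pairwise": [], "direct": [], "moderation": []}
    labels = None
    n_failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        est = ModeratedNetworkEstimator(
            random_state=int(rng.integers(0, 2**31 - 1)), **estimator_params
        )
        try:
            est.fit(X[idx], t[idx])
        except Exception as err:  # refit failures are counted, not fatal
            warnings.warn(f"bootstrap resample {b} failed: {err}")
            n_failed += 1
            continue
        labels = est.node_labels_
        draws["pairwise"].append(est.pairwise_)
        draws["direct"].append(est.direct_)
        draws["moderation"].append(est.moderation_)
    if labels is None:
        raise RuntimeError("every bootstrap resample failed")
    summary = BootstrapSummary(n_boot=n_boot, node_labels=labels, n_failed=n_failed)
    for kind, stack in draws.items():
        arr = np.stack(stack)
        summary.inclusion[kind] = (np.abs(arr) > _ZERO_TOL).mean(axis=0)
        summary.quantile_low[kind] = np.quantile(arr, 0.025, axis=0)
        summary.quantile_high[kind] = np.quantile(arr, 0.975, axis=0)
    return summary


# --- node redundancy (goldbricker-style) --------------------------------


@dataclass
class RedundancyConfig:
    """Thresholds for the dependent-correlations redundancy screen.

    A candidate pair must first correlate at least ``min_pair_correlation``
    with each other; it is flagged when at least ``shared_threshold`` of
    its correlation-profile comparisons (over all third nodes) show no
    significant difference at level ``alpha``.
    """

    shared_threshold: float = 0.75
    alpha: float = 0.05
    min_pair_correlation: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.shared_threshold <= 1:
            raise ValueError("shared_threshold must be in (0, 1]")


def _williams_t(r_ik: float, r_jk: float, r_ij: float, n: int) -> float:
    """Two-sided p for H0: corr(i,k) == corr(j,k), dependent correlations
    sharing node k (Williams' t, the form used by psych::r.test)."""
    diff = r_ik - r_jk
    if diff == 0.0:
        return 1.0
    det = 1 - r_ik**2 - r_jk**2 - r_ij**2 + 2 * r_ik * r_jk * r_ij
    rbar2 = ((r_ik + r_jk) / 2.0) ** 2
    denom = 2 * ((n - 1) / (n - 3)) * det + rbar2 * (1 - r_ij) ** 3
    if denom <= 0:
        return 1.0
    tstat = diff * np.sqrt((n - 1) * (1 + r_ij) / denom)
    return float(2 * stats.t.sf(abs(tstat), df=n - 3))


def redundancy_check(
    item_matrix, config: RedundancyConfig | None = None
) -> pd.DataFrame:
    """Flag node pairs whose correlation profiles are indistinguishable.

    Operates on cross-sectional item scores at a single timepoint. For
    each sufficiently correlated pair (i, j), every third node k yields a
    dependent-correlations test of corr(i,k) vs corr(j,k); the pair is
    flagged when the proportion of non-significant comparisons reaches the
    shared threshold. Returns a DataFrame of flagged pairs (possibly
    empty) with the proportion shared.
    """
    config = config or RedundancyConfig()
    frame = pd.DataFrame(item_matrix)
    labels = (
        list(frame.columns)
        if all(isinstance(c, str) for c in frame.columns)
        else list(range(frame.shape[1]))
    )
    X = frame.to_numpy(dtype=float)
    n, p = X.shape
    if p < 3:
        raise ValueError("redundancy check needs at least 3 nodes")
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(X, rowvar=False)
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            r_ij = R[i, j]
            if not np.isfinite(r_ij) or abs(r_ij) < config.min_pair_correlation:
                continue
            ks = [k for k in range(p) if k not in (i, j)]
            pvals = [_williams_t(R[i, k], R[j, k], r_ij, n) for k in ks]
            prop_shared = float(np.mean([pv > config.alpha for pv in pvals]))
            if prop_shared >= config.shared_threshold:
                rows.append((labels[i], labels[j], r_ij, prop_shared))
    return pd.DataFrame(
        rows, columns=["node_i", "node_j", "pair_correlation", "proportion_shared"]
    )
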