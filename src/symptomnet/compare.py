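"""Cross-variant comparison of moderated networks.

The analysis is repeated over a grid of change-score operationalizations
(FS/DS/PC/RP/RC), baselines (session 1 vs session 2) and samples (whole vs
propensity-matched); variants are then compared by Pearson-correlating
their 16-entry direct-association vectors and the 120 upper-triangular
entries of their moderation matrices. Labels follow the method letter +
optional ``X`` (matched sample) + baseline digit convention, e.g. ``RCX2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .change import ChangeSpec, compute_change
from .items import NODE_LABELS, item_columns
from .network import ModeratedNetworkEstimator

__all__ = ["ComparisonReport", "compare_direct", "run_variant_grid", "default_grid"]

_BASELINE_SESSION = {"session1": "s1", "session2": "s2"}


@dataclass
class ComparisonReport:
    variant_labels: list
    direct_corr: pd.DataFrame
    moderation_corr: pd.DataFrame

    def to_csv(self, direct_path, moderation_path) -> None:
        self.direct_corr.to_csv(direct_path)
        self.moderation_corr.to_csv(moderation_path)

    def to_json(self, path=None):
        payload = {
            "variant_labels": self.variant_labels,
            "direct_corr": self.direct_corr.to_dict(),
            "moderation_corr": self.moderation_corr.to_dict(),
        }
        if path is None:
            return payload
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def plot_heatmap(self, which: str = "direct", ax=None):
        """Minimal heat-map rendering of one correlation matrix."""
        import matplotlib.pyplot as plt

        mat = self.direct_corr if which == "direct" else self.moderation_corr
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90)
        ax.set_yticks(range(len(mat.index)), mat.index)
        ax.figure.colorbar(im, ax=ax)
        return ax


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance parameter vector; correlation undefined")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def compare_direct(networks: dict) -> ComparisonReport:
    """Pairwise Pearson correlations of direct vectors and (flattened
    upper-triangular) moderation matrices across labelled networks."""
    labels = list(networks)
    ref_nodes = networks[labels[0]].node_labels_
    for lab in labels:
        if networks[lab].node_labels_ != ref_nodes:
            raise ValueError(f"network {lab!r} has different node labels")
    p = len(ref_nodes)
    iu = np.triu_indices(p, k=1)
    direct = {lab: networks[lab].direct_ for lab in labels}
    moder = {lab: networks[lab].moderation_[iu] for lab in labels}
    d_mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    m_mat = d_mat.copy()
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            d_mat.loc[la, lb] = d_mat.loc[lb, la] = _safe_corr(direct[la], direct[lb])
            m_mat.loc[la, lb] = m_mat.loc[lb, la] = _safe_corr(moder[la], moder[lb])
    return ComparisonReport(variant_labels=labels, direct_corr=d_mat, moderation_corr=m_mat)


def default_grid() -> list[tuple[str, str, str]]:
    """The analysis grid: all five methods x both baselines on the whole
    sample, plus the residual models (session-2 baseline, the preferred
    specification) on the matched sample — 12 models in total."""
    grid = [
        (m, b, "whole")
        for m in ("FS", "DS", "PC", "RP", "RC")
        for b in ("session1", "session2")
    ]
    grid += [(m, "session2", "matched") for m in ("RP", "RC")]
    return grid


def run_variant_grid(
    cohort: pd.DataFrame,
    grid=None,
    matched_ids=None,
    seed: int = 0,
    **network_params,
) -> dict:
    """Fit one moderated network per (method, baseline, sample) cell.

    ``matched_ids`` (patient ids retained by matching) must be provided
    when any cell requests the matched sample. Change scores are computed
    on the sample entering the network, so residualizing regressions are
    refitted within the matched subset. Deterministic given ``seed``.
    """
    grid = grid if grid is not None else default_grid()
    networks: dict[str, ModeratedNetworkEstimator] = {}
    for method, baseline, sample in grid:
        if sample == "matched":
            if matched_ids is None:
                raise ValueError("matched sample requested but matched_ids is None")
            data = cohort[cohort["patient_id"].isin(set(matched_ids))]
        else:
            data = cohort
        spec = ChangeSpec(method, baseline)
        pre = data[item_columns(_BASELINE_SESSION[baseline])].copy()
        post = data[item_columns("final")].copy()
        pre.columns = post.columns = NODE_LABELS
        cm = compute_change(pre, post, spec)
        if cm.n_missing:
            warnings.warn(
                f"{spec.label(sample == 'matched')}: {cm.n_missing} undefined "
                "change entries dropped (complete-case rows)"
            )
        est = ModeratedNetworkEstimator(random_state=seed, **network_params)
        est.fit(cm.values, data["treatment"].to_numpy())
        networks[spec.label(matched=sample == "matched")] = est
    return networks
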