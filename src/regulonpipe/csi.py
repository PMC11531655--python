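"""Connection Specificity Index (CSI) and regulon-module discovery.

The CSI of a regulon pair (i, j) measures how *specifically* the two
co-vary: it is the fraction of other regulons k whose correlation with
either i or j falls below the pair's own correlation minus a margin
delta. Pairs with a high mutual correlation that is not shared with the
rest of the network approach CSI 1; promiscuously correlated pairs fall
toward 0. Modules are flat clusters obtained by Ward-linkage
hierarchical clustering of CSI row vectors cut at a fixed height, and a
module's activity in a cell is the unweighted mean RAS of its members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .datatypes import ActivityMatrix

logger = logging.getLogger(__name__)

__all__ = ["CSIMatrix", "ModuleAssignment", "compute_csi", "cut_modules", "module_activity"]


@dataclass
class CSIMatrix:
    """Regulons × regulons CSI values with the underlying Pearson matrix."""

    values: pd.DataFrame
    correlation: pd.DataFrame
    delta: float

    @property
    def regulons(self) -> pd.Index:
        return self.values.index


@dataclass
class ModuleAssignment:
    """Regulon → module id (M1..Mk in dendrogram-leaf order of appearance)."""

    labels: pd.Series  # regulon -> "M<k>"
    cut_height: float

    @property
    def modules(self) -> list:
        """Module ids M1..Mk in numeric order."""
        return sorted(set(self.labels), key=lambda m: int(m[1:]))


def compute_csi(activity: ActivityMatrix, delta: float = 0.05) -> CSIMatrix:
    """CSI over all regulon pairs of an activity matrix.

    ``CSI(i,j) = |{k != i,j : r(i,k) < r(i,j) - delta  and
    r(j,k) < r(i,j) - delta}| / (N - 2)`` with strict inequalities, where
    r is the Pearson correlation of RAS rows. The diagonal is 1 by
    convention. Constant RAS rows get correlation 0 against everything
    (logged) rather than NaN.
    """
    A = activity.values.to_numpy()
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"CSI needs >= 3 regulons, got {n}")
    sd = A.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "compute_csi: constant RAS rows (correlation set to 0): %s",
            list(activity.regulons[constant]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(A)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)

    csi = np.ones((n, n))
    others = np.arange(n)
    for i in range(n):
        for j in range(i + 1, n):
            mask = (others != i) & (others != j)
            t = r[i, j] - delta
            count = np.sum((r[i, mask] < t) & (r[j, mask] < t))
            csi[i, j] = csi[j, i] = count / (n - 2)
    idx = activity.regulons
    return CSIMatrix(
        values=pd.DataFrame(csi, index=idx, columns=idx),
        correlation=pd.DataFrame(r, index=idx, columns=idx),
        delta=delta,
    )


def cut_modules(
    csi: CSIMatrix, linkage: str = "ward", height: float = 8.0
) -> ModuleAssignment:
    """Cut the CSI-row dendrogram at a fixed height into modules.

    Clusters CSI row vectors with Euclidean distance and the given
    linkage, then takes flat clusters below ``height``. Module ids are
    renamed M1..Mk by order of first appearance along the dendrogram
    leaves, so the naming is deterministic. Singleton modules are
    permitted; raising the height never increases the module count.
    """
    X = csi.values.to_numpy()
    if not np.isfinite(X).all():
        raise ValueError("CSI matrix contains non-finite entries")
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    flat = hierarchy.fcluster(Z, t=height, criterion="distance")
    leaves = hierarchy.leaves_list(Z)
    rename: Dict[int, str] = {}
    for leaf in leaves:
        c = flat[leaf]
        if c not in rename:
            rename[c] = f"M{len(rename) + 1}"
    labels = pd.Series([rename[c] for c in flat], index=csi.regulons, name="module")
    logger.info("cut_modules: %d modules at height %.3g", len(rename), height)
    return ModuleAssignment(labels=labels, cut_height=height)


def module_activity(
    activity: ActivityMatrix, modules: ModuleAssignment
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean member RAS per module and per-condition module contrasts.

    Returns ``(module × cell activity, summary)`` where the summary has
    one row per module with per-condition means and the WT−MUT
    difference (NaN when the metadata carries no condition column).
    """
    missing = set(activity.regulons) - set(modules.labels.index)
    if missing:
        raise ValueError(f"module assignment does not cover regulons: {sorted(missing)[:5]}")
    module_ids = modules.modules
    rows = {}
    for mod in module_ids:
        members = modules.labels.index[modules.labels == mod]
        rows[mod] = activity.values.loc[members].mean(axis=0)
    act = pd.DataFrame(rows).T  # modules x cells

    summary = pd.DataFrame(index=act.index)
    if "condition" in activity.cell_meta:
        cond = activity.cell_meta["condition"]
        for c in ["WT", "MUT"]:
            cells = cond.index[cond == c]
            summary[f"mean_{c}"] = act[cells].mean(axis=1) if len(cells) else np.nan
        summary["diff_WT_minus_MUT"] = summary["mean_WT"] - summary["mean_MUT"]
    else:
        summary["mean_WT"] = np.nan
        summary["mean_MUT"] = np.nan
        summary["diff_WT_minus_MUT"] = np.nan
    summary.index.name = "module"
    return act, summary
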