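"""Captured-ensemble composition per cluster and Holm-Sidak-adjusted
between-condition comparisons.

Fractions (cells in cluster / cells in sample) are the analysis unit, since
sample depth varies; per cluster an unpaired two-sided t-test across samples
compares conditions, and p-values are adjusted across clusters with the
Holm-Sidak step-down procedure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .data import validate_annotation

logger = logging.getLogger(__name__)


def composition(ann: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, cluster) cell counts and within-sample fractions.

    The output covers the full sample x cluster grid; clusters absent from a
    sample get count 0 and fraction 0. Fractions sum to 1 within each sample.
    """
    ann = validate_annotation(ann)
    if ann.empty:
        raise ValueError("annotation table is empty")
    counts = (
        ann.groupby(["sample", "cluster"], sort=True).size().rename("n_cells")
    )
    samples = sorted(ann["sample"].unique())
    clusters = sorted(ann["cluster"].unique())
    grid = pd.MultiIndex.from_product([samples, clusters], names=["sample", "cluster"])
    counts = counts.reindex(grid, fill_value=0).reset_index()
    totals = counts.groupby("sample")["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    condition_of = ann.drop_duplicates("sample").set_index("sample")["condition"]
    counts["condition"] = counts["sample"].map(condition_of)
    return counts.loc[:, ["sample", "condition", "cluster", "n_cells", "fraction"]]


def holm_sidak_adjust(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjustment: monotone 1 - (1 - p_(i))^(m - i + 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # p == 1 hits log1p(-1) internally
        return multipletests(p, method="holm-sidak")[1]


def compare_conditions(
    tab: pd.DataFrame, control: str, treated: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-cluster comparison of composition fractions between two conditions.

    ``tab`` is the output of :func:`composition`. Each condition needs at
    least two samples. Clusters with identical zero-variance fractions in
    both groups get p = 1 by convention (logged).
    """
    for cond in (control, treated):
        n = tab.loc[tab["condition"] == cond, "sample"].nunique()
        if n < 2:
            raise ValueError(f"condition {cond!r} has {n} sample(s); need >= 2")
    rows = []
    for cluster, sub in tab.groupby("cluster", sort=True):
        x = sub.loc[sub["condition"] == control, "fraction"].to_numpy(dtype=float)
        y = sub.loc[sub["condition"] == treated, "fraction"].to_numpy(dtype=float)
        if np.allclose(x.var(), 0) and np.allclose(y.var(), 0):
            if np.isclose(x.mean(), y.mean()):
                p = 1.0
                logger.warning("cluster %r: identical zero-variance groups, p set to 1", cluster)
            else:
                p = 0.0
                logger.warning(
                    "cluster %r: zero-variance groups with different means, p set to 0", cluster
                )
        else:
            p = float(scipy.stats.ttest_ind(x, y, equal_var=True).pvalue)
        rows.append(
            {
                "cluster": cluster,
                f"mean_frac_{control}": float(x.mean()),
                f"mean_frac_{treated}": float(y.mean()),
                "delta": float(y.mean() - x.mean()),
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_sidak_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    return out
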