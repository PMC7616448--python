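"""Activity-enrichment calling with interval-resampled background genes.

The procedure builds a candidate gene pool (highly variable genes merged with
top per-cluster marker genes), splits it into feature genes (the IEG panel
members present in the pool) and background genes, then repeatedly (default
100 times) draws an expression-stratified random background set — the
background genes are ranked by mean expression, cut into 50 rank intervals,
and 50 genes are drawn from each interval — and scores every cell by the
difference between its mean feature-gene expression and its mean sampled
background expression. A cell is called active when the mean differential
expression is positive and the empirical p-value (add-one-smoothed fraction
of repetitions with a non-positive difference) is below ``alpha``. At the
default 100 repetitions and ``alpha = 0.01`` this requires a positive
difference in every repetition.

Cluster-level "robustly perturbed" verdicts require a consistent,
per-evaluation-significant shift of the active fraction between conditions
at all three marker thresholds (k = 250, 500, 1000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator

from ._ranking import rank_order, split_near_equal
from .data import CountMatrix, GeneSet
from .preprocess import log_normalize

logger = logging.getLogger(__name__)

#: Marker-count thresholds of the three consensus evaluations.
DEFAULT_EVALUATION_KS = (250, 500, 1000)


@dataclass(frozen=True)
class EnrichmentParams:
    """Configuration of one enrichment evaluation.

    top_k_markers: marker genes kept per cluster when building the pool;
    n_hvg: highly variable genes merged into the pool; n_intervals /
    genes_per_interval: background stratification (50 x 50 by default);
    n_reps: background resampling repetitions; alpha: empirical p threshold
    for an active call; rank_by: expression summary used to rank background
    genes ('normalized_mean' or 'raw_mean').
    """

    top_k_markers: int = 250
    n_hvg: int = 2000
    n_intervals: int = 50
    genes_per_interval: int = 50
    n_reps: int = 100
    alpha: float = 0.01
    seed: int = 0
    rank_by: str = "normalized_mean"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_intervals < 1 or self.genes_per_interval < 1:
            raise ValueError("n_intervals and genes_per_interval must be >= 1")
        if self.rank_by not in ("normalized_mean", "raw_mean"):
            raise ValueError("rank_by must be 'normalized_mean' or 'raw_mean'")


@dataclass(frozen=True)
class GenePool:
    """Candidate gene pool split into feature (IEG) and background genes."""

    pool: tuple[str, ...]
    feature: tuple[str, ...]
    background: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.feature) | set(self.background) != set(self.pool):
            raise ValueError("feature and background must partition the pool")
        if set(self.feature) & set(self.background):
            raise ValueError("feature and background overlap")
        if not self.background:
            raise ValueError("background gene set is empty")


@dataclass
class ActivityCall:
    """Per-cell activity calls of one evaluation.

    ``table`` is indexed by cell id with columns ``mean_diff`` (mean over
    repetitions of the feature-minus-background difference), ``emp_p`` and
    ``active``. ``diffs`` keeps the per-repetition differences
    (n_reps x n_cells) so the summary can be re-derived.
    """

    table: pd.DataFrame
    diffs: np.ndarray
    params: EnrichmentParams
    pool_size: int
    n_feature: int


@dataclass
class ClusterActivity:
    """Cluster-level consensus across the three marker-threshold evaluations."""

    per_evaluation: pd.DataFrame
    clusters: pd.DataFrame


# --------------------------------------------------------------------- HVGs

def _dispersion_ranking(
    means: pd.Series, variances: pd.Series, n_mean_bins: int = 20
) -> list[str]:
    """Genes ordered by binned-dispersion z-score (descending), ties by symbol."""
    informative = variances > 0
    means = means[informative]
    variances = variances[informative]
    if means.empty:
        return []
    dispersion = variances / means
    n_bins = min(n_mean_bins, len(means))
    from ._ranking import rank_bins

    bins = rank_bins(means, n_bins)
    disp = dispersion.reindex(bins.index)
    z = pd.Series(0.0, index=disp.index)
    for b, members in disp.groupby(bins).groups.items():
        vals = disp.loc[members]
        sd = vals.std(ddof=1)
        if np.isfinite(sd) and sd > 0:
            z.loc[members] = (vals - vals.mean()) / sd
    order = pd.DataFrame({"z": -z, "g": z.index.astype(str)}).sort_values(
        ["z", "g"], kind="mergesort"
    )
    return order["g"].tolist()


def select_hvgs(matrix: CountMatrix, n_hvg: int = 2000, n_mean_bins: int = 20) -> list[str]:
    """Top ``n_hvg`` genes by dispersion of normalized expression.

    Dispersion (variance/mean) is z-scored within 20 rank bins of mean
    expression so that variability is judged against genes of similar
    abundance. Constant genes are never selected; if fewer informative genes
    exist than requested, all are returned with a warning.
    """
    norm = matrix.require_normalized()
    means, variances = _gene_moments(norm)
    ranking = _dispersion_ranking(
        pd.Series(means, index=matrix.gene_symbols),
        pd.Series(variances, index=matrix.gene_symbols),
        n_mean_bins,
    )
    if len(ranking) < n_hvg:
        logger.warning(
            "only %d informative genes available (requested %d)", len(ranking), n_hvg
        )
        return ranking
    return ranking[:n_hvg]


def _gene_moments(norm) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and (ddof=1) variance of a sparse genes x cells layer."""
    n = norm.shape[1]
    mean = np.asarray(norm.mean(axis=1)).ravel()
    sq = np.asarray(norm.multiply(norm).mean(axis=1)).ravel()
    var = (sq - mean**2) * (n / max(n - 1, 1))
    return mean, np.maximum(var, 0.0)


# ------------------------------------------------------------------- markers

def rank_markers(matrix: CountMatrix, ann: pd.DataFrame) -> dict[str, list[str]]:
    """Full per-cluster marker ranking (one-vs-rest Wilcoxon rank-sum).

    Per cluster, every gene is tested two-sided (asymptotic, tie- and
    continuity-corrected) against all other cells on normalized expression;
    genes are ranked by ascending p, ties broken by descending log
    fold-change (difference of mean log-normalized expression) and then by
    symbol.
    """
    labels = ann.set_index("cell_id")["cluster"]
    missing = [c for c in matrix.cell_ids if c not in labels.index]
    if missing:
        raise KeyError(f"cell without cluster annotation: {missing[0]!r}")
    labels = labels.loc[list(matrix.cell_ids)]
    M = np.asarray(matrix.require_normalized().todense(), dtype=np.float64)
    return _rank_markers_arrays(M, list(matrix.gene_symbols), labels.to_numpy())


def _rank_markers_arrays(
    M: np.ndarray, symbols: Sequence[str], labels: np.ndarray
) -> dict[str, list[str]]:
    clusters = pd.unique(labels)
    sizes = {c: int((labels == c).sum()) for c in clusters}
    small = [c for c in clusters if sizes[c] < 3]
    if small:
        logger.warning("clusters with < 3 cells skipped for marker ranking: %s", small)
    usable = [c for c in clusters if sizes[c] >= 3]
    if len(usable) < 2:
        raise ValueError("marker ranking needs at least 2 clusters with >= 3 cells")
    rankings: dict[str, list[str]] = {}
    symbols = np.asarray(symbols, dtype=object)
    for c in usable:
        mask = labels == c
        x = M[:, mask]
        y = M[:, ~mask]
        res = scipy.stats.mannwhitneyu(
            x, y, axis=1, alternative="two-sided", method="asymptotic"
        )
        pvals = np.asarray(res.pvalue, dtype=float)
        lfc = x.mean(axis=1) - y.mean(axis=1)
        order = pd.DataFrame({"p": pvals, "neg_lfc": -lfc, "g": symbols}).sort_values(
            ["p", "neg_lfc", "g"], kind="mergesort"
        )
        rankings[str(c)] = order["g"].tolist()
    return rankings


def top_markers(matrix: CountMatrix, ann: pd.DataFrame, k: int) -> dict[str, list[str]]:
    """Top ``k`` marker genes per cluster (see :func:`rank_markers`)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return {c: genes[:k] for c, genes in rank_markers(matrix, ann).items()}


# ----------------------------------------------------------------- gene pool

def build_gene_pool(
    hvgs: Sequence[str],
    markers: Mapping[str, Sequence[str]] | Sequence[str],
    ieg: GeneSet,
) -> GenePool:
    """Merge HVGs and markers into a pool; split into feature and background."""
    marker_union: set[str] = set()
    if isinstance(markers, Mapping):
        for genes in markers.values():
            marker_union.update(genes)
    else:
        marker_union.update(markers)
    pool = sorted(set(hvgs) | marker_union)
    if not pool:
        raise ValueError("gene pool is empty")
    feature = sorted(set(pool) & set(ieg.symbols))
    background = sorted(set(pool) - set(feature))
    if not feature:
        raise ValueError("no activity genes in pool")
    if not background:
        raise ValueError("background gene pool is empty")
    return GenePool(pool=tuple(pool), feature=tuple(feature), background=tuple(background))


# ------------------------------------------------------ background resampling

def _background_means(matrix: CountMatrix, pool: GenePool, rank_by: str) -> pd.Series:
    rows = matrix.gene_indices(pool.background)
    if rank_by == "raw_mean":
        means = np.asarray(matrix.counts[rows].mean(axis=1)).ravel()
    else:
        means = np.asarray(matrix.require_normalized()[rows].mean(axis=1)).ravel()
    return pd.Series(means, index=list(pool.background))


def _intervals_from_means(means: pd.Series, n_intervals: int) -> list[list[str]]:
    order = rank_order(means)
    # degenerate pools: never more intervals than background genes
    sizes = split_near_equal(len(order), min(n_intervals, len(order)))
    out, start = [], 0
    for s in sizes:
        out.append(order[start : start + s])
        start += s
    return out


def sample_background(
    matrix: CountMatrix,
    pool: GenePool,
    n_intervals: int = 50,
    genes_per_interval: int = 50,
    rng: np.random.Generator | int | None = None,
    rank_by: str = "normalized_mean",
) -> list[str]:
    """One stratified background draw: rank background genes by expression,
    cut into ``n_intervals`` rank intervals, draw ``genes_per_interval`` from
    each without replacement (all genes when an interval is smaller)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    intervals = _intervals_from_means(_background_means(matrix, pool, rank_by), n_intervals)
    return _draw_background(intervals, genes_per_interval, rng)


def _draw_background(
    intervals: list[list[str]], genes_per_interval: int, rng: np.random.Generator
) -> list[str]:
    drawn: list[str] = []
    for members in intervals:
        if len(members) <= genes_per_interval:
            drawn.extend(members)
        else:
            drawn.extend(rng.choice(members, size=genes_per_interval, replace=False))
    return drawn


# --------------------------------------------------------------- active calls

def activity_score_once(
    matrix: CountMatrix, feature: Sequence[str], bg_sample: Sequence[str]
) -> pd.Series:
    """Per-cell mean feature expression minus mean background-sample expression."""
    if not len(feature) or not len(bg_sample):
        raise ValueError("feature and background gene lists must be non-empty")
    norm = matrix.require_normalized()
    f = np.asarray(norm[matrix.gene_indices(feature)].mean(axis=0)).ravel()
    b = np.asarray(norm[matrix.gene_indices(bg_sample)].mean(axis=0)).ravel()
    return pd.Series(f - b, index=list(matrix.cell_ids), name="diff")


def empirical_p(diffs: np.ndarray) -> np.ndarray:
    """Add-one-smoothed per-cell empirical p: (1 + #{reps with diff <= 0}) / (1 + n_reps)."""
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n_reps = diffs.shape[0]
    return (1.0 + (diffs <= 0).sum(axis=0)) / (1.0 + n_reps)


def call_active(
    matrix: CountMatrix, pool: GenePool, params: EnrichmentParams
) -> ActivityCall:
    """Run the repeated background-resampling procedure and call active cells.

    Each repetition draws a fresh stratified background sample and computes
    the per-cell feature-minus-background difference; a cell is active iff
    its mean difference is positive and its empirical p is below
    ``params.alpha``.
    """
    rng = np.random.default_rng(params.seed)
    feat_rows = matrix.gene_indices(pool.feature)
    norm = matrix.require_normalized()
    # dense pool-restricted view keeps the repetition loop cheap
    bg_rows = matrix.gene_indices(pool.background)
    bg_dense = np.asarray(norm[bg_rows].todense(), dtype=np.float32)
    bg_pos = {g: i for i, g in enumerate(pool.background)}
    f = np.asarray(norm[feat_rows].mean(axis=0)).ravel()

    intervals = _intervals_from_means(
        _background_means(matrix, pool, params.rank_by), params.n_intervals
    )
    diffs = np.empty((params.n_reps, matrix.n_cells), dtype=np.float64)
    for r in range(params.n_reps):
        sample = _draw_background(intervals, params.genes_per_interval, rng)
        rows = np.asarray([bg_pos[g] for g in sample], dtype=int)
        diffs[r] = f - bg_dense[rows].mean(axis=0)

    mean_diff = diffs.mean(axis=0)
    emp_p = empirical_p(diffs)
    active = (mean_diff > 0) & (emp_p < params.alpha)
    table = pd.DataFrame(
        {"mean_diff": mean_diff, "emp_p": emp_p, "active": active},
        index=pd.Index(list(matrix.cell_ids), name="cell_id"),
    )
    return ActivityCall(
        table=table,
        diffs=diffs,
        params=params,
        pool_size=len(pool.pool),
        n_feature=len(pool.feature),
    )


def run_evaluation(
    matrix: CountMatrix,
    ann: pd.DataFrame,
    ieg: GeneSet,
    params: EnrichmentParams,
    marker_ranking: Mapping[str, list[str]] | None = None,
) -> tuple[ActivityCall, GenePool]:
    """One full evaluation: HVGs + top-k markers -> pool -> active calls."""
    if matrix.normalized is None:
        matrix = log_normalize(matrix)
    hvgs = select_hvgs(matrix, params.n_hvg)
    if marker_ranking is None:
        marker_ranking = rank_markers(matrix, ann)
    markers = {c: genes[: params.top_k_markers] for c, genes in marker_ranking.items()}
    pool = build_gene_pool(hvgs, markers, ieg)
    return call_active(matrix, pool, params), pool


# ------------------------------------------------------------------ consensus

def consensus_robust(
    calls: Mapping[int, ActivityCall],
    ann: pd.DataFrame,
    control_condition: str,
    treated_condition: str,
    per_eval_alpha: float = 0.05,
    min_cells: int = 10,
) -> ClusterActivity:
    """Cluster-level consensus over the marker-threshold evaluations.

    A cluster is robustly perturbed (direction 'up' or 'down') iff in every
    evaluation the treated-minus-control difference of active fractions has
    the same sign and a two-sided Fisher's exact test on the active/inactive
    x condition table is significant at ``per_eval_alpha``. Clusters with
    fewer than ``min_cells`` cells in either condition are excluded.
    """
    if not calls:
        raise ValueError("no evaluations supplied")
    meta = ann.set_index("cell_id")
    for cond in (control_condition, treated_condition):
        if cond not in set(meta["condition"]):
            raise ValueError(f"condition {cond!r} absent from annotation")
    rows = []
    excluded: set[str] = set()
    clusters = sorted(meta["cluster"].unique())
    for k in sorted(calls):
        table = calls[k].table
        unknown = table.index.difference(meta.index)
        if len(unknown):
            raise KeyError(f"called cell without annotation: {unknown[0]!r}")
        joined = table.join(meta, how="left")
        for cluster in clusters:
            sub = joined[joined["cluster"] == cluster]
            ctrl = sub[sub["condition"] == control_condition]
            trt = sub[sub["condition"] == treated_condition]
            if len(ctrl) < min_cells or len(trt) < min_cells:
                excluded.add(cluster)
                continue
            a_c, a_t = int(ctrl["active"].sum()), int(trt["active"].sum())
            n_c, n_t = len(ctrl), len(trt)
            _, p = scipy.stats.fisher_exact(
                [[a_t, n_t - a_t], [a_c, n_c - a_c]], alternative="two-sided"
            )
            rows.append(
                {
                    "cluster": cluster,
                    "k": k,
                    "n_control": n_c,
                    "n_active_control": a_c,
                    "frac_control": a_c / n_c,
                    "n_treated": n_t,
                    "n_active_treated": a_t,
                    "frac_treated": a_t / n_t,
                    "delta": a_t / n_t - a_c / n_c,
                    "fisher_p": float(p),
                }
            )
    for cluster in sorted(excluded):
        logger.warning(
            "cluster %r excluded from consensus (fewer than %d cells in a condition "
            "or missing from an evaluation)",
            cluster,
            min_cells,
        )
    per_eval = pd.DataFrame(rows)
    verdicts = []
    n_evals = len(calls)
    evaluated = [] if per_eval.empty else sorted(per_eval["cluster"].unique())
    for cluster in evaluated:
        sub = per_eval[per_eval["cluster"] == cluster]
        if len(sub) < n_evals:
            continue
        sig = (sub["fisher_p"] < per_eval_alpha).all()
        if sig and (sub["delta"] > 0).all():
            verdicts.append({"cluster": cluster, "robust": True, "direction": "up"})
        elif sig and (sub["delta"] < 0).all():
            verdicts.append({"cluster": cluster, "robust": True, "direction": "down"})
        else:
            verdicts.append({"cluster": cluster, "robust": False, "direction": "none"})
    return ClusterActivity(per_evaluation=per_eval, clusters=pd.DataFrame(verdicts))


# ------------------------------------------------------------------ estimator

class ActivityEnrichmentCaller(BaseEstimator):
    """Scikit-learn-style estimator for the enrichment active-cell caller.

    ``fit`` takes a cells x genes DataFrame of log-normalized expression and
    per-cell cluster labels ``y``, and learns the candidate gene pool
    (HVGs merged with top-k cluster markers, split into feature and
    background genes). ``predict`` runs the background-resampling procedure
    and returns the boolean active call per cell.

    Attributes
    ----------
    hvgs_ : list of str
    marker_ranking_ : dict cluster -> full marker ordering
    pool_ : GenePool
    """

    def __init__(
        self,
        feature_genes=None,
        top_k_markers: int = 250,
        n_hvg: int = 2000,
        n_intervals: int = 50,
        genes_per_interval: int = 50,
        n_reps: int = 100,
        alpha: float = 0.01,
        random_state: int = 0,
        rank_by: str = "normalized_mean",
    ):
        self.feature_genes = feature_genes
        self.top_k_markers = top_k_markers
        self.n_hvg = n_hvg
        self.n_intervals = n_intervals
        self.genes_per_interval = genes_per_interval
        self.n_reps = n_reps
        self.alpha = alpha
        self.random_state = random_state
        self.rank_by = rank_by

    def _params(self) -> EnrichmentParams:
        return EnrichmentParams(
            top_k_markers=self.top_k_markers,
            n_hvg=self.n_hvg,
            n_intervals=self.n_intervals,
            genes_per_interval=self.genes_per_interval,
            n_reps=self.n_reps,
            alpha=self.alpha,
            seed=self.random_state,
            rank_by=self.rank_by,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "ActivityEnrichmentCaller":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a cells x genes pandas DataFrame")
        if y is None:
            raise ValueError("cluster labels y are required to rank marker genes")
        if self.feature_genes is None or not list(self.feature_genes):
            raise ValueError("feature_genes must be a non-empty sequence")
        params = self._params()
        y = np.asarray([str(v) for v in y], dtype=object)
        if len(y) != X.shape[0]:
            raise ValueError("y length must equal the number of cells")
        M = X.to_numpy(dtype=np.float64).T  # genes x cells
        symbols = [str(c) for c in X.columns]
        means = pd.Series(M.mean(axis=1), index=symbols)
        variances = pd.Series(M.var(axis=1, ddof=1), index=symbols)
        ranking = _dispersion_ranking(means, variances)
        if len(ranking) < params.n_hvg:
            logger.warning("only %d informative genes (requested %d)", len(ranking), params.n_hvg)
        self.hvgs_ = ranking[: params.n_hvg]
        self.marker_ranking_ = _rank_markers_arrays(M, symbols, y)
        markers = {c: g[: params.top_k_markers] for c, g in self.marker_ranking_.items()}
        ieg = GeneSet(name="feature", symbols=tuple(dict.fromkeys(self.feature_genes)))
        self.pool_ = build_gene_pool(self.hvgs_, markers, ieg)
        self.n_features_in_ = X.shape[1]
        return self

    def score_cells(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-cell mean_diff, emp_p and active flag for ``X``."""
        if not hasattr(self, "pool_"):
            raise ValueError("ActivityEnrichmentCaller instance is not fitted yet")
        params = self._params()
        missing = [g for g in self.pool_.pool if g not in X.columns]
        if missing:
            raise ValueError(f"pool genes missing from X: {missing[:5]}")
        rng = np.random.default_rng(params.seed)
        bg_dense = X.loc[:, list(self.pool_.background)].to_numpy(dtype=np.float32).T
        f = X.loc[:, list(self.pool_.feature)].to_numpy(dtype=np.float64).mean(axis=1)
        means = pd.Series(bg_dense.mean(axis=1), index=list(self.pool_.background))
        intervals = _intervals_from_means(means.astype(float), params.n_intervals)
        bg_pos = {g: i for i, g in enumerate(self.pool_.background)}
        diffs = np.empty((params.n_reps, X.shape[0]))
        for r in range(params.n_reps):
            sample = _draw_background(intervals, params.genes_per_interval, rng)
            rows = np.asarray([bg_pos[g] for g in sample], dtype=int)
            diffs[r] = f - bg_dense[rows].mean(axis=0)
        mean_diff = diffs.mean(axis=0)
        emp_p = empirical_p(diffs)
        return pd.DataFrame(
            {
                "mean_diff": mean_diff,
                "emp_p": emp_p,
                "active": (mean_diff > 0) & (emp_p < params.alpha),
            },
            index=X.index,
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.score_cells(X)["active"].to_numpy()

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X, y).predict(X)
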