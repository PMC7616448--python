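"""Per-cell IEG module scoring against expression-binned control genes.

The module score of a cell is the mean log-normalized expression of the
feature (IEG) genes minus the mean over a control pool of genes with similar
average expression: the gene universe is ranked by mean expression, cut into
``n_bins`` rank intervals, and for every feature gene ``n_ctrl_per_gene``
non-feature genes are drawn without replacement from its interval. Controls
are drawn once per run, so scores are comparable across cells.

``IEGModuleScorer`` is a scikit-learn transformer over cells x genes frames
of log-normalized expression; the module-level functions mirror it on
:class:`~iegactivity.data.CountMatrix` inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._ranking import rank_bins
from .data import CountMatrix, GeneSet
from .preprocess import log_normalize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModuleScoreParams:
    """Knobs of the binned-control module score.

    n_bins: number of average-expression rank intervals the gene universe is
    cut into; n_ctrl_per_gene: control genes drawn per feature gene; seed:
    RNG seed for the control draw; presentation_offset: constant added for
    display only (never used in positivity or activity calls).
    """

    n_bins: int = 24
    n_ctrl_per_gene: int = 100
    seed: int = 0
    presentation_offset: float = 0.05

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_ctrl_per_gene < 1:
            raise ValueError("n_ctrl_per_gene must be >= 1")


@dataclass
class ModuleScores:
    """Per-cell module scores plus the configuration that produced them."""

    scores: pd.Series
    params: ModuleScoreParams
    feature_set: str
    feature_genes: tuple[str, ...] = ()
    control_genes: tuple[str, ...] = ()


class IEGModuleScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer computing binned-control gene-module scores.

    Parameters
    ----------
    feature_genes : sequence of str
        Gene symbols of the feature module (e.g. the IEG panel).
    n_bins : int, default 24
        Number of mean-expression rank bins over the gene universe.
    n_ctrl_per_gene : int, default 100
        Control genes sampled (without replacement, within bin, excluding all
        feature genes) per feature gene; bins smaller than the request
        contribute all their eligible genes.
    random_state : int, default 0
        Seed of the control-gene draw. Sampling operates on a symbol-sorted
        gene universe, so results do not depend on input column order.

    Attributes
    ----------
    feature_genes_ : list of str
        Feature genes found in the training frame.
    gene_bins_ : pandas.Series
        Bin index per gene of the training frame.
    control_genes_ : list of str
        Union of the per-feature control draws (deduplicated, sorted).
    """

    def __init__(
        self,
        feature_genes=None,
        n_bins: int = 24,
        n_ctrl_per_gene: int = 100,
        random_state: int = 0,
    ):
        self.feature_genes = feature_genes
        self.n_bins = n_bins
        self.n_ctrl_per_gene = n_ctrl_per_gene
        self.random_state = random_state

    # ------------------------------------------------------------------- fit
    def fit(self, X: pd.DataFrame, y=None) -> "IEGModuleScorer":
        X = _validate_frame(X)
        if self.feature_genes is None or len(list(self.feature_genes)) == 0:
            raise ValueError("feature_genes must be a non-empty sequence of gene symbols")
        if self.n_bins < 1 or self.n_ctrl_per_gene < 1:
            raise ValueError("n_bins and n_ctrl_per_gene must be >= 1")
        if self.n_bins > X.shape[1]:
            raise ValueError(
                f"n_bins={self.n_bins} exceeds the number of genes ({X.shape[1]})"
            )
        features = [str(g) for g in self.feature_genes]
        present = [g for g in features if g in X.columns]
        missing = sorted(set(features) - set(present))
        if missing:
            logger.warning("feature genes absent from matrix, dropped: %s", ", ".join(missing))
        if not present:
            raise ValueError("no feature genes present in the expression frame")

        gene_means = X.mean(axis=0)
        self.gene_bins_ = rank_bins(gene_means, self.n_bins)
        feature_set = set(present)
        rng = np.random.default_rng(self.random_state)
        controls: set[str] = set()
        any_eligible = False
        # canonical symbol order makes the draw independent of column order
        for gene in sorted(present):
            b = self.gene_bins_.loc[gene]
            members = self.gene_bins_.index[self.gene_bins_.to_numpy() == b]
            eligible = sorted(g for g in members if g not in feature_set)
            if not eligible:
                continue
            any_eligible = True
            take = min(self.n_ctrl_per_gene, len(eligible))
            controls.update(rng.choice(eligible, size=take, replace=False))
        if not any_eligible:
            raise ValueError("no eligible control genes (feature set covers its bins)")
        self.feature_genes_ = sorted(present)
        self.control_genes_ = sorted(controls)
        self.n_features_in_ = X.shape[1]
        return self

    # ------------------------------------------------------------- transform
    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Return raw module scores, shape ``(n_cells, 1)``."""
        self._check_fitted()
        X = _validate_frame(X)
        missing = [g for g in self.feature_genes_ + self.control_genes_ if g not in X.columns]
        if missing:
            raise ValueError(f"genes used at fit time are missing from X: {missing[:5]}")
        scores = (
            X.loc[:, self.feature_genes_].mean(axis=1)
            - X.loc[:, self.control_genes_].mean(axis=1)
        )
        return scores.to_numpy(dtype=np.float64).reshape(-1, 1)

    def score_frame(self, X: pd.DataFrame) -> pd.Series:
        """Module scores as a Series indexed by cell id."""
        return pd.Series(self.transform(X).ravel(), index=X.index, name="module_score")

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["module_score"], dtype=object)

    def _check_fitted(self) -> None:
        if not hasattr(self, "control_genes_"):
            raise ValueError("IEGModuleScorer instance is not fitted yet")


def _validate_frame(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("expected a cells x genes pandas DataFrame of log-normalized expression")
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("empty expression frame")
    return X


# ------------------------------------------------------- CountMatrix wrappers

def bin_genes_by_mean(matrix: CountMatrix, n_bins: int) -> pd.Series:
    """Bin genes into ``n_bins`` rank intervals of mean normalized expression."""
    norm = matrix.require_normalized()
    if n_bins > matrix.n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds number of genes ({matrix.n_genes})")
    means = pd.Series(
        np.asarray(norm.mean(axis=1)).ravel(), index=matrix.gene_symbols
    )
    return rank_bins(means, n_bins)


def module_score(
    matrix: CountMatrix,
    features: GeneSet,
    params: ModuleScoreParams = ModuleScoreParams(),
) -> ModuleScores:
    """Per-cell module score of ``features`` on a (normalized) count matrix."""
    if matrix.normalized is None:
        matrix = log_normalize(matrix)
    X = matrix.to_frame("normalized")
    scorer = IEGModuleScorer(
        feature_genes=list(features),
        n_bins=params.n_bins,
        n_ctrl_per_gene=params.n_ctrl_per_gene,
        random_state=params.seed,
    ).fit(X)
    return ModuleScores(
        scores=scorer.score_frame(X),
        params=params,
        feature_set=features.name,
        feature_genes=tuple(scorer.feature_genes_),
        control_genes=tuple(scorer.control_genes_),
    )


def ieg_positivity(scores: ModuleScores | pd.Series, ann: pd.DataFrame) -> pd.Series:
    """Percent of cells per cluster with a strictly positive module score.

    A zero score does not count as positive. Clusters in the annotation with
    no scored cells are excluded with a warning.
    """
    values = scores.scores if isinstance(scores, ModuleScores) else scores
    ann_idx = ann.set_index("cell_id")
    unscored = ann_idx.index.difference(values.index)
    covered = ann_idx.drop(index=unscored)
    if len(covered) < len(ann_idx):
        logger.warning("%d annotated cells have no score and were ignored", len(unscored))
    missing_ann = values.index.difference(ann_idx.index)
    if len(missing_ann):
        raise KeyError(f"scored cell without annotation: {missing_ann[0]!r}")
    out = {}
    for cluster, members in covered.groupby("cluster").groups.items():
        vals = values.loc[members]
        out[cluster] = 100.0 * float((vals > 0).sum()) / len(vals)
    dropped = set(ann_idx["cluster"]) - set(out)
    for cluster in sorted(dropped):
        logger.warning("cluster %r has no scored cells; excluded from positivity", cluster)
    return pd.Series(out, name="pct_ieg_positive").sort_index()


def presentation_score(
    scores: ModuleScores | pd.Series, offset: float | None = None
) -> pd.Series:
    """Shift scores by the presentation offset (display only; default +0.05)."""
    if isinstance(scores, ModuleScores):
        values = scores.scores
        if offset is None:
            offset = scores.params.presentation_offset
    else:
        values = scores
        if offset is None:
            offset = 0.05
    return (values + offset).rename("presentation_score")
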