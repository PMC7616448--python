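"""Gene-pool construction, background resampling and active-cell calling."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import iegactivity as ia
from iegactivity.enrichment import (
    ActivityCall,
    EnrichmentParams,
    _intervals_from_means,
)


def _normalized_matrix(counts, genes=None, cells=None):
    genes = genes or [f"g{i:03d}" for i in range(counts.shape[0])]
    cells = cells or [f"c{j:03d}" for j in range(counts.shape[1])]
    return ia.log_normalize(ia.CountMatrix(genes, cells, counts))


# ---------------------------------------------------------------------- HVGs

def test_constant_gene_never_selected():
    counts = np.vstack([np.full(20, 5), np.random.default_rng(0).integers(0, 9, (6, 20))])
    m = _normalized_matrix(counts)
    # g000 is constant across cells after normalization only if totals are equal;
    # force exact constancy by giving every cell identical totals
    counts = np.vstack([np.full(20, 5), np.tile([[3], [1], [2], [0], [4], [5]], 20)[:, :20]])
    m = _normalized_matrix(counts)
    hv = ia.select_hvgs(m, 3)
    assert "g000" not in hv


def test_select_hvgs_matches_dispersion_oracle():
    """30-gene toy: ranking equals a brute-force binned-dispersion computation."""
    rng = np.random.default_rng(4)
    counts = rng.negative_binomial(2, 0.3, size=(30, 40))
    m = _normalized_matrix(counts)
    hv = ia.select_hvgs(m, 10, n_mean_bins=3)

    norm = m.normalized.toarray()
    means = norm.mean(axis=1)
    variances = norm.var(axis=1, ddof=1)
    genes = np.array(m.gene_symbols)
    keep = variances > 0
    order = sorted(np.flatnonzero(keep), key=lambda i: (means[i], genes[i]))
    sizes = [len(order) // 3 + (1 if b < len(order) % 3 else 0) for b in range(3)]
    z = np.zeros(30)
    pos = 0
    for s in sizes:
        members = order[pos : pos + s]
        pos += s
        disp = np.array([variances[i] / means[i] for i in members])
        sd = disp.std(ddof=1)
        if sd > 0:
            zz = (disp - disp.mean()) / sd
        else:
            zz = np.zeros_like(disp)
        for i, v in zip(members, zz):
            z[i] = v
    expected = sorted(np.flatnonzero(keep), key=lambda i: (-z[i], genes[i]))[:10]
    assert hv == [genes[i] for i in expected]


def test_select_hvgs_requesting_all(small_synthetic):
    m = ia.log_normalize(small_synthetic.matrix)
    hv = ia.select_hvgs(m, m.n_genes + 50)
    assert len(hv) <= m.n_genes
    assert len(set(hv)) == len(hv)


# ------------------------------------------------------------------- markers

def test_exclusive_gene_is_top_marker():
    counts = np.zeros((4, 12), dtype=int)
    counts[0, :6] = 5          # g000 exclusive to cluster A
    counts[1:] = np.random.default_rng(1).integers(1, 4, (3, 12))
    m = _normalized_matrix(counts)
    ann = pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "cluster": ["A"] * 6 + ["B"] * 6,
            "sample": "s1",
            "condition": "x",
        }
    )
    markers = ia.top_markers(m, ann, 2)
    assert markers["A"][0] == "g000"


def test_marker_ranking_matches_rank_sum_oracle():
    """10-gene, 3-cluster fixture: ordering matches a hand-written rank-sum test."""
    rng = np.random.default_rng(9)
    counts = rng.integers(0, 5, size=(10, 24))
    m = _normalized_matrix(counts)
    labels = np.repeat(["A", "B", "C"], 8)
    ann = pd.DataFrame(
        {"cell_id": m.cell_ids, "cluster": labels, "sample": "s1", "condition": "x"}
    )
    ranking = ia.rank_markers(m, ann)

    norm = m.normalized.toarray()
    genes = np.array(m.gene_symbols)
    for cluster in "ABC":
        mask = labels == cluster
        pvals, lfc = [], []
        for g in range(10):
            x, y = norm[g, mask], norm[g, ~mask]
            n1, n2 = len(x), len(y)
            allv = np.concatenate([x, y])
            ranks = scipy.stats.rankdata(allv)
            U1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            mu = n1 * n2 / 2
            _, t = np.unique(allv, return_counts=True)
            tie = (t**3 - t).sum()
            s = np.sqrt(n1 * n2 / 12 * ((n1 + n2 + 1) - tie / ((n1 + n2) * (n1 + n2 - 1))))
            if s == 0:
                p = 1.0
            else:
                z = (max(U1, n1 * n2 - U1) - mu - 0.5) / s
                p = min(1.0, 2 * scipy.stats.norm.sf(z))
            pvals.append(p)
            lfc.append(x.mean() - y.mean())
        expected = [
            genes[i]
            for i in sorted(range(10), key=lambda i: (pvals[i], -lfc[i], genes[i]))
        ]
        assert ranking[cluster] == expected


def test_top_markers_k_exceeding_genes(small_synthetic):
    m = ia.log_normalize(small_synthetic.matrix)
    markers = ia.top_markers(m, small_synthetic.annotation, m.n_genes + 10)
    for genes in markers.values():
        assert len(genes) == m.n_genes
        assert len(set(genes)) == m.n_genes


def test_single_cluster_is_error(tiny_matrix):
    m = ia.log_normalize(tiny_matrix)
    ann = pd.DataFrame(
        {"cell_id": m.cell_ids, "cluster": "only", "sample": "s", "condition": "x"}
    )
    with pytest.raises(ValueError, match="clusters"):
        ia.top_markers(m, ann, 5)


# ----------------------------------------------------------------- gene pool

def test_build_gene_pool_set_algebra():
    ieg = ia.GeneSet("ieg", ("c", "z"))
    pool = ia.build_gene_pool(["a", "b"], {"k": ["b", "c"]}, ieg)
    assert pool.pool == ("a", "b", "c")
    assert pool.feature == ("c",)
    assert pool.background == ("a", "b")

    disjoint = ia.build_gene_pool(["a", "b"], ["c", "d"], ia.GeneSet("i", ("a",)))
    assert len(disjoint.pool) == 4

    with pytest.raises(ValueError, match="no activity genes"):
        ia.build_gene_pool(["a", "b"], ["c"], ia.GeneSet("i", ("zzz",)))
    with pytest.raises(ValueError, match="background"):
        ia.build_gene_pool(["a"], [], ia.GeneSet("i", ("a",)))


# ------------------------------------------------------- background sampling

def test_sample_background_exhausts_small_intervals():
    """100 background genes in 50 intervals of 2 are fully drawn, deterministically."""
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 7, size=(103, 30))
    m = _normalized_matrix(counts)
    pool = ia.build_gene_pool(
        m.gene_symbols, [], ia.GeneSet("ieg", tuple(m.gene_symbols[:3]))
    )
    assert len(pool.background) == 100
    draw1 = ia.sample_background(m, pool, rng=1)
    draw2 = ia.sample_background(m, pool, rng=999)
    assert sorted(draw1) == sorted(pool.background)
    assert sorted(draw2) == sorted(pool.background)


def test_interval_remainder_arithmetic():
    """2609 genes split over 50 intervals: nine of 53, forty-one of 52; 2500 drawn."""
    means = pd.Series(
        np.random.default_rng(5).normal(size=2609),
        index=[f"g{i:04d}" for i in range(2609)],
    )
    intervals = _intervals_from_means(means, 50)
    sizes = [len(iv) for iv in intervals]
    assert sizes == [53] * 9 + [52] * 41
    rng = np.random.default_rng(0)
    from iegactivity.enrichment import _draw_background

    drawn = _draw_background(intervals, 50, rng)
    assert len(drawn) == 2500
    assert len(set(drawn)) == 2500


def test_sample_background_respects_expression_strata():
    rng = np.random.default_rng(2)
    counts = rng.integers(0, 20, size=(40, 25))
    m = _normalized_matrix(counts)
    pool = ia.build_gene_pool(m.gene_symbols, [], ia.GeneSet("i", (m.gene_symbols[0],)))
    draw = ia.sample_background(m, pool, n_intervals=3, genes_per_interval=2, rng=7)
    assert len(draw) == 6
    means = pd.Series(
        np.asarray(m.normalized.mean(axis=1)).ravel(), index=m.gene_symbols
    ).loc[list(pool.background)]
    intervals = _intervals_from_means(means, 3)
    for i, iv in enumerate(intervals):
        assert len(set(draw[i * 2 : i * 2 + 2]) & set(iv)) == 2


# --------------------------------------------------------------- active calls

def test_activity_score_once_hand_computed():
    counts = np.array([[4, 0], [2, 0], [0, 0], [6, 0]])
    m = _normalized_matrix(counts)
    norm = m.normalized.toarray()
    diff = ia.activity_score_once(m, ["g000"], ["g001", "g003"])
    expected = norm[0] - norm[[1, 3]].mean(axis=0)
    assert diff.to_numpy() == pytest.approx(expected)
    # all-zero cell scores 0; identical gene lists cancel exactly
    assert diff.iloc[1] == 0.0
    same = ia.activity_score_once(m, ["g000", "g001"], ["g000", "g001"])
    assert np.allclose(same.to_numpy(), 0.0)


def test_empirical_p_add_one_formula():
    all_positive = np.ones((100, 1))
    assert ia.empirical_p(all_positive)[0] == pytest.approx(1 / 101)
    one_failure = np.ones((100, 1))
    one_failure[17, 0] = -0.2
    assert ia.empirical_p(one_failure)[0] == pytest.approx(2 / 101)
    assert ia.empirical_p(one_failure)[0] >= 0.01  # not active at alpha = 0.01
    rng = np.random.default_rng(0)
    diffs = rng.normal(size=(37, 25))
    p = ia.empirical_p(diffs)
    assert np.all(p >= 1 / 38) and np.all(p <= 1.0)


def test_call_active_determinism_and_invariants(small_synthetic):
    m = ia.log_normalize(small_synthetic.matrix)
    hv = ia.select_hvgs(m, 300)
    markers = ia.top_markers(m, small_synthetic.annotation, 50)
    pool = ia.build_gene_pool(hv, markers, small_synthetic.ieg)
    params = EnrichmentParams(top_k_markers=50, n_hvg=300, n_reps=25, seed=3)
    call1 = ia.call_active(m, pool, params)
    call2 = ia.call_active(m, pool, params)
    pd.testing.assert_frame_equal(call1.table, call2.table)
    np.testing.assert_array_equal(call1.diffs, call2.diffs)
    # summary columns recompute from the stored per-repetition diffs
    assert call1.table["mean_diff"].to_numpy() == pytest.approx(call1.diffs.mean(axis=0))
    np.testing.assert_array_equal(
        call1.table["emp_p"].to_numpy(), ia.empirical_p(call1.diffs)
    )
    p = call1.table["emp_p"]
    assert ((p >= 1 / 26) & (p <= 1.0)).all()
    np.testing.assert_array_equal(
        call1.table["active"].to_numpy(),
        (call1.table["mean_diff"] > 0) & (p < params.alpha),
    )


def test_all_zero_cell_is_not_active():
    counts = np.random.default_rng(0).integers(1, 5, size=(30, 8))
    counts[:, 3] = 0
    m = _normalized_matrix(counts)
    pool = ia.build_gene_pool(m.gene_symbols, [], ia.GeneSet("i", tuple(m.gene_symbols[:4])))
    call = ia.call_active(m, pool, EnrichmentParams(n_reps=10, seed=0))
    row = call.table.iloc[3]
    assert row["mean_diff"] == 0.0
    assert not row["active"]


# ------------------------------------------------------------------ consensus

def _fabricated_calls(active_patterns):
    """Build per-k ActivityCall stubs from {k: (control_active, treated_active)} counts."""
    cells = [f"ctl{i}" for i in range(100)] + [f"trt{i}" for i in range(100)]
    ann = pd.DataFrame(
        {
            "cell_id": cells,
            "cluster": "A",
            "sample": ["s1"] * 100 + ["s2"] * 100,
            "condition": ["control"] * 100 + ["treated"] * 100,
        }
    )
    calls = {}
    for k, (a_ctl, a_trt) in active_patterns.items():
        active = [i < a_ctl for i in range(100)] + [i < a_trt for i in range(100)]
        table = pd.DataFrame(
            {
                "mean_diff": [0.5 if a else -0.5 for a in active],
                "emp_p": [1 / 101 if a else 1.0 for a in active],
                "active": active,
            },
            index=pd.Index(cells, name="cell_id"),
        )
        calls[k] = ActivityCall(
            table=table,
            diffs=np.zeros((1, 200)),
            params=EnrichmentParams(top_k_markers=k),
            pool_size=0,
            n_feature=0,
        )
    return calls, ann


def test_consensus_robust_up():
    """10/100 vs 30/100 at every threshold: robust, direction up, Fisher p ~ 6.5e-4."""
    calls, ann = _fabricated_calls({250: (10, 30), 500: (10, 30), 1000: (10, 30)})
    res = ia.consensus_robust(calls, ann, "control", "treated")
    verdict = res.clusters.set_index("cluster").loc["A"]
    assert verdict["robust"] and verdict["direction"] == "up"
    assert res.per_evaluation["fisher_p"].to_numpy() == pytest.approx(
        [6.504107076034208e-04] * 3
    )


def test_consensus_identical_fractions_not_robust():
    calls, ann = _fabricated_calls({250: (20, 20), 500: (20, 20), 1000: (20, 20)})
    res = ia.consensus_robust(calls, ann, "control", "treated")
    verdict = res.clusters.set_index("cluster").loc["A"]
    assert not verdict["robust"] and verdict["direction"] == "none"


def test_consensus_sign_inconsistency_not_robust():
    calls, ann = _fabricated_calls({250: (10, 40), 500: (10, 40), 1000: (40, 10)})
    res = ia.consensus_robust(calls, ann, "control", "treated")
    verdict = res.clusters.set_index("cluster").loc["A"]
    assert not verdict["robust"] and verdict["direction"] == "none"
    # each evaluation alone is significant; only the sign flip blocks robustness
    assert (res.per_evaluation["fisher_p"] < 0.05).all()


def test_consensus_small_cluster_excluded():
    calls, ann = _fabricated_calls({250: (10, 30)})
    ann = ann.copy()
    ann.loc[ann["cell_id"] == "ctl0", "cluster"] = "tiny"
    res = ia.consensus_robust(calls, ann, "control", "treated")
    assert "tiny" not in set(res.clusters.get("cluster", []))
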