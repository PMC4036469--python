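"""Robust variability, probeset collapsing, homolog mapping, normalization
and the exploratory structure analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from xsig.preprocess import (ClusterResult, collapse_probesets, compute_rse,
                             hierarchical_cluster, map_homologs,
                             median_center_iqr_normalize, pca,
                             resolve_one_to_one, rse_matrix,
                             top_variable_genes)

# ---------------------------------------------------------------- RSE


def huber_scale_oracle(y, tol=1e-10, c=1.345):
    """Scalar iteratively-reweighted Huber location with MAD scale,
    written independently of the vectorized implementation."""
    y = np.asarray(y, dtype=float)
    loc = float(np.median(y))
    scale = 1.4826 * float(np.median(np.abs(y - loc)))
    if scale == 0:
        return 0.0
    for _ in range(10_000):
        u = (y - loc) / scale
        w = np.clip(c / np.maximum(np.abs(u), 1e-300), None, 1.0)
        new = float(np.sum(w * y) / np.sum(w))
        new_scale = 1.4826 * float(np.median(np.abs(y - new)))
        done = abs(new - loc) <= tol * max(new_scale, 1.0)
        loc, scale = new, new_scale
        if done or scale == 0:
            break
    return scale


def test_rse_constant_vector_is_zero():
    assert compute_rse([5, 5, 5, 5]) == 0.0


def test_rse_outlier_vector_matches_oracle():
    # converged Huber scale; close to MASS::rlm's s (~2.23) on this vector
    v = [1, 2, 3, 100]
    assert compute_rse(v) == pytest.approx(huber_scale_oracle(v), abs=1e-6)
    assert 2.0 < compute_rse(v) < 2.4


def test_rse_shift_invariance():
    x = np.array([0.3, -1.2, 2.4, 0.0, 5.1])
    assert compute_rse(x) == pytest.approx(compute_rse(x + 7), abs=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(0.1, 50), st.integers(0, 10_000))
def test_rse_scale_equivariance(c, seed):
    x = np.random.default_rng(seed).normal(size=12)
    assert compute_rse(c * x) == pytest.approx(c * compute_rse(x), rel=1e-6)


def test_rse_agrees_with_oracle_on_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = rng.integers(5, 60)
        x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 4), size=n)
        if rng.uniform() < 0.3:        # occasional gross outlier
            x[0] += rng.uniform(20, 100)
        assert compute_rse(x) == pytest.approx(huber_scale_oracle(x), abs=1e-8)


def test_rse_rejects_short_vectors():
    with pytest.raises(ValueError):
        compute_rse([1.0])


# ---------------------------------------------------- probeset collapsing


def _matrix(rows: dict, samples=None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return df


def test_collapse_keeps_highest_rse_probeset():
    m = _matrix({"ps_a": [1, 1.1, 0.9, 1.0], "ps_b": [0, 2, -2, 4]})
    ann = pd.Series({"ps_a": "g1", "ps_b": "g1"})
    out = collapse_probesets(m, ann)
    assert list(out.index) == ["g1"]
    assert np.allclose(out.loc["g1"], m.loc["ps_b"])


def test_collapse_tie_breaks_lexicographically():
    m = _matrix({"ps_b": [1, 2, 3, 4], "ps_a": [4, 3, 2, 1]})
    ann = pd.Series({"ps_a": "g1", "ps_b": "g1"})
    out = collapse_probesets(m, ann)
    assert np.allclose(out.loc["g1"], m.loc["ps_a"])


def test_collapse_drops_unmapped_and_errors_when_nothing_maps():
    m = _matrix({"ps_a": [1, 2, 3], "ps_x": [9, 9, 9]})
    out = collapse_probesets(m, pd.Series({"ps_a": "g1"}))
    assert list(out.index) == ["g1"]
    with pytest.raises(ValueError, match="mapped"):
        collapse_probesets(m, pd.Series(dtype=object))


def test_collapse_idempotent_on_gene_level_input(genes_small):
    identity = pd.Series(genes_small.index, index=genes_small.index)
    again = collapse_probesets(genes_small, identity)
    pd.testing.assert_frame_equal(again, genes_small.sort_index(),
                                  check_names=False)


def test_collapse_recovers_designated_representatives(gemm_small, genes_small):
    expr, _, _, truth = gemm_small
    # identify the kept probeset per gene by matching row values against expr
    hits = 0
    for gene in genes_small.index:
        rep = truth.representative[gene]
        if np.allclose(genes_small.loc[gene].values, expr.loc[rep].values):
            hits += 1
    assert hits / len(genes_small) >= 0.99


# ---------------------------------------------------------- homolog map


def test_map_homologs_counts_and_universe():
    m = _matrix({f"g{i}": np.random.default_rng(i).normal(size=4)
                 for i in range(10)})
    hmap = pd.DataFrame({"source": [f"g{i}" for i in range(8)],
                         "target": [f"h{i}" for i in range(8)]})
    universe = [f"h{i}" for i in range(6)]
    out = map_homologs(m, hmap, universe)
    assert out.shape == (6, 4)
    assert set(out.index) <= set(universe)


def test_one_to_many_pairs_are_excluded():
    hmap = pd.DataFrame({"source": ["g1", "g1", "g2"],
                         "target": ["h1", "h1b", "h2"]})
    resolved = resolve_one_to_one(hmap)
    assert list(resolved["source"]) == ["g2"]


def test_identity_map_reorders_only():
    m = _matrix({"g2": [1, 2, 3], "g1": [4, 5, 6]})
    hmap = pd.DataFrame({"source": ["g1", "g2"], "target": ["g1", "g2"]})
    out = map_homologs(m, hmap, ["g1", "g2"])
    assert list(out.index) == ["g1", "g2"]
    assert np.allclose(out.loc["g1"], [4, 5, 6])


def test_empty_intersection_raises():
    m = _matrix({"g1": [1, 2, 3]})
    hmap = pd.DataFrame({"source": ["g1"], "target": ["h1"]})
    with pytest.raises(ValueError, match="empty"):
        map_homologs(m, hmap, ["zz"])


# ----------------------------------------------------------- normalization


def test_normalize_hand_example():
    m = _matrix({"g1": [1, 2, 3, 4, 5]})
    out = median_center_iqr_normalize(m)
    assert np.allclose(out.loc["g1"], [-1, -0.5, 0, 0.5, 1])


def test_normalize_constant_gene_flagged():
    m = _matrix({"g1": [3, 3, 3, 3], "g2": [1, 2, 3, 4]})
    out = median_center_iqr_normalize(m)
    assert np.allclose(out.loc["g1"], 0)
    assert out.attrs["zero_iqr_genes"] == ["g1"]


def test_normalize_postconditions_and_idempotence(genes_small):
    out = median_center_iqr_normalize(genes_small)
    med = np.median(out.values, axis=1)
    assert np.abs(med).max() < 1e-12
    q1, q3 = np.percentile(out.values, [25, 75], axis=1)
    assert np.abs((q3 - q1) - 1).max() < 1e-9
    again = median_center_iqr_normalize(out)
    assert np.abs(again.values - out.values).max() < 1e-9


def test_normalize_single_sample_raises():
    with pytest.raises(ValueError):
        median_center_iqr_normalize(_matrix({"g1": [1.0]}))


# ------------------------------------------------------- top variable genes


def test_top_variable_trivial_cases():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.normal(size=(5, 10)) * 0.1,
                     index=[f"g{i}" for i in range(5)])
    m.loc["g3"] += rng.normal(size=10) * 50
    assert top_variable_genes(m, 1) == ["g3"]
    assert set(top_variable_genes(m, 5)) == set(m.index)
    with pytest.raises(ValueError):
        top_variable_genes(m, 6)


def test_planted_genes_enriched_in_top_variable(genes_small, gemm_small):
    _, _, _, truth = gemm_small
    planted = set().union(*truth.planted_up.values(),
                          *truth.planted_down.values())
    top = set(top_variable_genes(genes_small, 500))
    k = len(top & planted)
    # hypergeometric null: 500 draws from n_genes with |planted| successes
    p = stats.hypergeom.sf(k - 1, len(genes_small), len(planted), 500)
    assert p < 1e-6


# ------------------------------------------------------------- clustering


def test_duplicate_samples_merge_at_height_zero():
    rng = np.random.default_rng(1)
    m = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
    m["d"] = m["a"]
    res = hierarchical_cluster(m)
    assert isinstance(res, ClusterResult)
    assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_correlation_distance_ignores_positive_scaling():
    rng = np.random.default_rng(2)
    base = rng.normal(size=20)
    m = pd.DataFrame({"a": base, "b": 3.5 * base, "c": rng.normal(size=20)})
    res = hierarchical_cluster(m)
    lab = res.cut(2)
    assert lab["a"] == lab["b"] != lab["c"]


def test_zero_variance_sample_is_named():
    m = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [1.0, 1, 1],
                      "ok2": [2.0, 1, 3]})
    with pytest.raises(ValueError, match="flat"):
        hierarchical_cluster(m)


def test_kras_genotypes_separate_on_kras_genes(genes_small, gemm_small):
    from sklearn.metrics import adjusted_rand_score

    _, _, design, truth = gemm_small
    kras_genes = sorted(truth.planted_up["Kras"] | truth.planted_down["Kras"])
    tumors = design.index[design["genotype"] != "WT"]
    res = hierarchical_cluster(genes_small.loc[kras_genes, tumors])
    lab = res.cut(2)
    is_kras = design.loc[tumors, "Kras"].values
    assert adjusted_rand_score(is_kras, lab.values) >= 0.8


# -------------------------------------------------------------------- PCA


def test_rank_one_matrix_explains_everything():
    u = np.arange(6, dtype=float)
    v = np.array([1.0, -2.0, 0.5, 3.0])
    m = pd.DataFrame(np.outer(u - u.mean(), v),
                     index=[f"g{i}" for i in range(6)])
    res = pca(m, 2)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)


def test_duplicate_samples_get_identical_coordinates():
    rng = np.random.default_rng(3)
    m = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
    m["e"] = m["a"]
    res = pca(m, 2)
    assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["e"])


def test_pc1_recovers_planted_axis():
    rng = np.random.default_rng(4)
    axis = rng.normal(size=25)
    load = rng.normal(size=60)
    m = pd.DataFrame(np.outer(load, axis) + rng.normal(scale=0.05,
                                                       size=(60, 25)))
    m.index = [f"g{i}" for i in range(60)]
    res = pca(m, 2)
    r = np.corrcoef(res.coordinates["PC1"], axis)[0, 1]
    assert abs(r) >= 0.99


def test_pca_component_limit():
    m = pd.DataFrame(np.random.default_rng(5).normal(size=(10, 4)))
    with pytest.raises(ValueError):
        pca(m, 5)
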