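"""Expression-matrix preprocessing.

Expression matrices are pandas DataFrames with unique feature identifiers
(probesets or genes) as the index and unique sample identifiers as columns;
values are log2 intensities.

The module covers the steps between a summarized microarray matrix and a
cohort ready for signature scoring:

* probeset-to-gene collapsing by maximal robust variability (RSE),
* mouse-to-human homolog mapping restricted to a target gene universe,
* per-gene median-centering / IQR-scaling,
* exploratory structure: top-variable gene selection, average-linkage
  correlation clustering and PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from ._utils import iqr

log = logging.getLogger(__name__)

#: Huber tuning constant for 95% Gaussian efficiency of the location fit.
HUBER_C = 1.345
#: Consistency constant making the MAD unbiased for a Gaussian sigma.
MAD_SCALE = 1.4826


def rse_matrix(values: np.ndarray, tol: float = 1e-12, max_iter: int = 500) -> np.ndarray:
    """Row-wise robust scale estimate (RSE).

    For each row an intercept-only Huber M-estimator of location is fit by
    iteratively reweighted least squares, with the scale re-estimated each
    iteration as ``1.4826 * median(|residual|)`` about the current location
    (MAD-initialized). The returned scale is the MAD-based residual scale at
    the converged location. Rows whose MAD collapses to zero return 0.

    Parameters
    ----------
    values
        2-D array, rows are features, columns samples (>= 2 columns).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] < 2:
        raise ValueError("RSE requires at least 2 observations per feature")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in expression matrix")

    loc = np.median(x, axis=1)
    scale = MAD_SCALE * np.median(np.abs(x - loc[:, None]), axis=1)
    active = scale > 0
    for _ in range(max_iter):
        if not active.any():
            break
        r = x[active] - loc[active, None]
        s = scale[active, None]
        u = np.abs(r) / s
        w = np.where(u <= HUBER_C, 1.0, HUBER_C / np.maximum(u, 1e-300))
        new_loc = (w * x[active]).sum(axis=1) / w.sum(axis=1)
        delta = np.abs(new_loc - loc[active])
        loc[active] = new_loc
        new_scale = MAD_SCALE * np.median(np.abs(x[active] - new_loc[:, None]), axis=1)
        scale[active] = new_scale
        still = (delta > tol * np.maximum(new_scale, 1.0)) & (new_scale > 0)
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    return scale


def compute_rse(values) -> float:
    """RSE of a single vector (length >= 2). See :func:`rse_matrix`."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("compute_rse expects a 1-D vector")
    if v.size < 2:
        raise ValueError("RSE requires at least 2 observations")
    return float(rse_matrix(v[None, :])[0])


def collapse_probesets(m: pd.DataFrame, annotation: pd.Series) -> pd.DataFrame:
    """Collapse a probeset-level matrix to one representative row per gene.

    For each gene the probeset with the largest RSE across samples is kept;
    ties go to the lexicographically smallest probeset id. Probesets absent
    from the annotation (or mapped to a null gene id) are dropped; the count
    is logged.

    Parameters
    ----------
    m
        Probeset-level matrix (probesets x samples).
    annotation
        Mapping probeset id -> gene id (pandas Series indexed by probeset).

    Returns
    -------
    Gene-level matrix indexed by gene id, sorted by gene id.
    """
    _check_matrix(m)
    ann = annotation.dropna()
    mapped = m.index.intersection(ann.index)
    n_dropped = m.shape[0] - len(mapped)
    if n_dropped:
        log.info("collapse_probesets: dropped %d unmapped probesets", n_dropped)
    if len(mapped) == 0:
        raise ValueError("no probesets could be mapped to genes")

    sub = m.loc[mapped]
    rse = pd.Series(rse_matrix(sub.values), index=sub.index)
    sel = (
        pd.DataFrame({"gene": ann.loc[mapped].values, "rse": rse.values,
                      "probeset": mapped})
        .sort_values(["gene", "rse", "probeset"], ascending=[True, False, True],
                     kind="mergesort")
        .drop_duplicates("gene", keep="first")
    )
    out = sub.loc[sel["probeset"].values]
    out.index = pd.Index(sel["gene"].values, name="gene")
    return out.sort_index()


def resolve_one_to_one(homolog_map: pd.DataFrame) -> pd.DataFrame:
    """Restrict a source<->target homolog table to strict one-to-one pairs.

    Any source or target gene participating in a one-to-many relation is
    removed entirely (conservative rule; dropped counts are logged).
    """
    h = homolog_map.iloc[:, :2].drop_duplicates()
    h.columns = ["source", "target"]
    before = len(h)
    h = h[~h["source"].duplicated(keep=False) & ~h["target"].duplicated(keep=False)]
    if len(h) < before:
        log.info("resolve_one_to_one: dropped %d genes in one-to-many relations",
                 before - len(h))
    return h.reset_index(drop=True)


def map_homologs(m: pd.DataFrame, homolog_map: pd.DataFrame,
                 target_universe) -> pd.DataFrame:
    """Re-identify a gene-level matrix in a homologous target namespace.

    Only one-to-one homolog pairs are used (see :func:`resolve_one_to_one`);
    rows are restricted to the intersection with ``target_universe`` and
    sorted by target gene id. Never invents genes: the output index is a
    subset of the target universe.
    """
    _check_matrix(m)
    pairs = resolve_one_to_one(homolog_map)
    pairs = pairs[pairs["source"].isin(m.index)]
    universe = set(target_universe)
    pairs = pairs[pairs["target"].isin(universe)]
    if pairs.empty:
        raise ValueError("homolog mapping produced an empty intersection "
                         "with the target universe")
    dropped = m.shape[0] - len(pairs)
    if dropped:
        log.info("map_homologs: dropped %d genes without usable homologs", dropped)
    out = m.loc[pairs["source"].values]
    out.index = pd.Index(pairs["target"].values, name="gene")
    return out.sort_index()


def median_center_iqr_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Per-gene median-centering and IQR scaling across samples.

    Each row has its median subtracted and is divided by its inter-quartile
    range (Q3 - Q1, linear-interpolation quantiles). Rows with zero IQR are
    centered but left unscaled; their ids are recorded in
    ``result.attrs["zero_iqr_genes"]``.
    """
    _check_matrix(m)
    if m.shape[1] < 2:
        raise ValueError("normalization requires at least 2 samples")
    med = np.median(m.values, axis=1)
    spread = iqr(m.values, axis=1)
    flat = spread == 0
    denom = np.where(flat, 1.0, spread)
    out = m.sub(med, axis=0).div(denom, axis=0)
    out.attrs["zero_iqr_genes"] = list(m.index[flat])
    if flat.any():
        log.info("median_center_iqr_normalize: %d genes with zero IQR left unscaled",
                 int(flat.sum()))
    return out


def top_variable_genes(m: pd.DataFrame, n: int = 500) -> list[str]:
    """The ``n`` most variable genes ranked by RSE (descending, ties by id)."""
    _check_matrix(m)
    if n > m.shape[0]:
        raise ValueError(f"requested top {n} of only {m.shape[0]} genes")
    rse = pd.DataFrame({"rse": rse_matrix(m.values)}, index=m.index)
    # ties broken lexicographically: sort by id first, then stably by RSE
    ranked = rse.sort_index().sort_values("rse", ascending=False, kind="mergesort")
    return list(ranked.index[:n])


@dataclass
class ClusterResult:
    """Average-linkage clustering of samples under 1 - Pearson distance."""

    linkage: np.ndarray
    sample_ids: list[str]
    labels: dict[int, np.ndarray] = field(default_factory=dict)

    def cut(self, k: int) -> pd.Series:
        if k not in self.labels:
            self.labels[k] = fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(self.labels[k], index=self.sample_ids, name=f"k{k}")


def hierarchical_cluster(m: pd.DataFrame, cut_k: tuple[int, ...] = (2,)) -> ClusterResult:
    """UPGMA clustering of samples with distance = 1 - Pearson correlation."""
    _check_matrix(m)
    if m.shape[1] < 3:
        raise ValueError("clustering requires at least 3 samples")
    sd = m.values.std(axis=0)
    if np.any(sd == 0):
        bad = m.columns[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"sample {bad!r} has a zero-variance expression profile")
    d = pdist(m.values.T, metric="correlation")
    # guard tiny negative distances from floating error
    z = linkage(np.maximum(d, 0.0), method="average")
    res = ClusterResult(linkage=z, sample_ids=list(m.columns))
    for k in cut_k:
        res.cut(k)
    return res


@dataclass
class PCAResult:
    coordinates: pd.DataFrame        # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame           # genes x components


def pca(m: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of samples over gene features (genes centered internally).

    Sign convention: each component is flipped so its largest-magnitude gene
    loading is positive, making coordinates deterministic.
    """
    _check_matrix(m)
    if n_components > min(m.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(matrix dims)={min(m.shape)}")
    centered = m.values - m.values.mean(axis=1, keepdims=True)
    # samples as observations
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    total = (s**2).sum()
    ratio = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    coords = u[:, :n_components] * s[:n_components]
    load = vt[:n_components].T
    for j in range(n_components):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1
            coords[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=m.columns, columns=cols),
        explained_variance_ratio=ratio,
        loadings=pd.DataFrame(load, index=m.index, columns=cols),
    )


def _check_matrix(m: pd.DataFrame) -> None:
    if m.index.has_duplicates:
        raise ValueError("duplicate feature identifiers in expression matrix")
    if m.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in expression matrix")
    if not np.all(np.isfinite(m.values)):
        raise ValueError("expression matrix contains non-finite values")
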