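"""Allele-specific signature derivation from a factorial mutant cohort.

Each gene's log2 expression is modelled additively over the four engineered
alleles (Apc, Kras, Braf, Tp53):

    y_s = b0 + b_Apc x_Apc,s + b_Kras x_Kras,s + b_Braf x_Braf,s + b_Tp53 x_Tp53,s + e_s

with all-wild-type samples as baseline and x in {0,1}. Ordinary least
squares per gene; two-sided Wald t-tests with n-5 degrees of freedom.
Genes significantly up (down) for an allele form that allele's up (down)
list; the top-k by p-value become the signature.

No multiple-testing correction is applied by default: gene lists are
defined at a raw per-gene threshold (alpha = 0.01), with Benjamini-Hochberg
adjustment available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ALLELES: tuple[str, ...] = ("Apc", "Kras", "Braf", "Tp53")
INTERCEPT = "intercept"


@dataclass
class AlleleSignature:
    """Ordered up/down gene lists attributed to one mutant allele."""

    allele: str
    up_genes: list[str]
    down_genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down lists overlap")

    def swapped(self) -> "AlleleSignature":
        """Signature with up and down arms exchanged (score negation)."""
        return AlleleSignature(self.allele, list(self.down_genes),
                               list(self.up_genes),
                               {**self.provenance, "swapped": True})

    def translated(self, mapping: pd.Series) -> "AlleleSignature":
        """Signature re-identified through a one-to-one gene mapping.

        Genes absent from the mapping are dropped; order is preserved.
        """
        up = [mapping[g] for g in self.up_genes if g in mapping.index]
        dn = [mapping[g] for g in self.down_genes if g in mapping.index]
        return AlleleSignature(self.allele, up, dn,
                               {**self.provenance, "translated": True})


def design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """[1 | x_Apc x_Kras x_Braf x_Tp53] over the cohort, with rank check."""
    missing = [a for a in ALLELES if a not in design.columns]
    if missing:
        raise ValueError(f"design table lacks allele columns: {missing}")
    x = np.column_stack([np.ones(len(design)),
                         design[list(ALLELES)].values.astype(float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient; collinear column(s): "
            f"{_collinear_columns(x)}")
    return x, [INTERCEPT, *ALLELES]


def _collinear_columns(x: np.ndarray) -> list[str]:
    names = [INTERCEPT, *ALLELES]
    bad = [names[j] for j in range(1, x.shape[1]) if np.ptp(x[:, j]) == 0]
    if not bad:
        full = np.linalg.matrix_rank(x)
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == full:
                bad.append(names[j])
    return bad


def fit_allele_models(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """OLS allele-effect fits for every gene of a cohort.

    Parameters
    ----------
    expr
        Gene-level matrix (genes x samples), samples matching ``design``.
    design
        Per-sample binary indicators for the four alleles (samples x alleles);
        all-zero rows are wild type.

    Returns
    -------
    Long-format table with one row per (gene, term): columns
    ``gene, allele, beta, se, p`` where ``allele`` includes ``intercept``.
    Genes with zero residual variance get p = 0 where beta is nonzero
    (exact fit) and p = 1 where beta is zero (constant gene).
    """
    if list(expr.columns) != list(design.index):
        design = design.loc[expr.columns]
    x, names = design_matrix(design)
    n, k = x.shape
    dof = n - k
    if dof <= 0:
        raise ValueError(f"need more than {k} samples, got {n}")

    xtx_inv = np.linalg.inv(x.T @ x)
    y = expr.values.T                              # samples x genes
    beta = xtx_inv @ x.T @ y                       # k x genes
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    # exact fits (noiseless data): residual variance at rounding level makes
    # t-ratios meaningless; call nonzero coefficients exact and zero ones null
    exact = sigma2 <= 1e-20 * np.maximum((y**2).mean(axis=0), 1.0)
    big = np.abs(beta) > 1e-8
    p[:, exact] = np.where(big[:, exact], 0.0, 1.0)
    se[:, exact] = 0.0

    genes = np.repeat(expr.index.values, k)
    return pd.DataFrame({
        "gene": genes,
        "allele": np.tile(names, expr.shape[0]),
        "beta": beta.T.ravel(),
        "se": se.T.ravel(),
        "p": p.T.ravel(),
    })


def fit_allele_model(y, design: pd.DataFrame) -> pd.DataFrame:
    """Allele-model fit for a single gene's expression vector."""
    y = pd.Series(np.asarray(y, dtype=float), index=design.index)
    expr = pd.DataFrame([y.values], index=["gene"], columns=design.index)
    return fit_allele_models(expr, design).drop(columns="gene")


def derive_allele_gene_lists(effects: pd.DataFrame, alpha: float = 0.01,
                             correction: str | None = None,
                             ) -> dict[str, dict[str, set[str]]]:
    """Per-allele up/down gene sets at significance level ``alpha``.

    A gene enters the up list of an allele iff its two-sided p-value is
    below ``alpha`` and its effect is positive (down: negative). P-values
    are unadjusted unless ``correction`` names a statsmodels method
    (e.g. ``"fdr_bh"``), applied per allele.
    """
    out: dict[str, dict[str, set[str]]] = {}
    for allele in ALLELES:
        sub = effects[effects["allele"] == allele]
        pvals = sub["p"].values
        if correction:
            from statsmodels.stats.multitest import multipletests
            pvals = multipletests(pvals, method=correction)[1]
        sig = pvals < alpha
        out[allele] = {
            "up": set(sub.loc[sig & (sub["beta"].values > 0), "gene"]),
            "down": set(sub.loc[sig & (sub["beta"].values < 0), "gene"]),
        }
    return out


def build_signature(allele: str, lists: dict[str, set[str]],
                    effects: pd.DataFrame, k: int = 100,
                    alpha: float = 0.01) -> AlleleSignature:
    """Top-k signature for one allele from its significant gene sets.

    Ranking: ascending p-value, ties by descending |beta|, then gene id.
    If fewer than ``k`` genes are available in an arm, all are taken and
    the shortfall is recorded in the provenance.
    """
    if not lists["up"] or not lists["down"]:
        raise ValueError(
            f"signature undefined for {allele}: empty "
            f"{'up' if not lists['up'] else 'down'} gene set")
    sub = effects[effects["allele"] == allele].set_index("gene")

    def top(genes: set[str]) -> list[str]:
        t = sub.loc[sorted(genes)].copy()
        t["absb"] = t["beta"].abs()
        t = t.sort_values(["p", "absb"], ascending=[True, False],
                          kind="mergesort")
        return list(t.index[:k])

    up, down = top(lists["up"]), top(lists["down"])
    prov = {"alpha": alpha, "k": k,
            "ranking": "p ascending, ties |beta| descending then gene id",
            "up_shortfall": max(0, k - len(up)),
            "down_shortfall": max(0, k - len(down))}
    if prov["up_shortfall"] or prov["down_shortfall"]:
        log.info("build_signature(%s): shortfall up=%d down=%d", allele,
                 prov["up_shortfall"], prov["down_shortfall"])
    return AlleleSignature(allele, up, down, prov)


def venn_counts(lists: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exact partition counts of the union of per-allele gene sets.

    Returns a map from each nonempty allele combination (sorted tuple) to
    the number of genes belonging to exactly those alleles. Counts sum to
    the size of the union.
    """
    alleles = sorted(lists)
    out: dict[tuple[str, ...], int] = {}
    union = set().union(*lists.values()) if lists else set()
    for r in range(1, len(alleles) + 1):
        for combo in combinations(alleles, r):
            inside = set.intersection(*(lists[a] for a in combo))
            outside = set().union(*(lists[a] for a in alleles
                                    if a not in combo)) if r < len(alleles) else set()
            out[combo] = len(inside - outside)
    assert sum(out.values()) == len(union)
    return out
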