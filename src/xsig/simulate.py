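"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Three generators emulate the study design:

* a factorial mouse tumor cohort (six genotypes over the alleles Apc, Kras,
  Braf, Tp53 plus wild-type normals) profiled at probeset level, with
  additive per-allele effects planted at gene level,
* a human cohort carrying KRAS/BRAF mutation labels whose expression
  receives a configurable fraction of the homologous planted effects, with
  signature-score-linked survival and independent uniform censoring,
* a cell-line panel whose ln IC50 is a linear function of the signature
  score plus noise.

Every generator draws from a named stream keyed by (seed, stage), so the
same configuration always yields bit-identical outputs and adding one
stage never perturbs another. Ground truth (planted gene sets, true
effects, true scores) is returned alongside each dataset for recovery
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._utils import rng_for
from .preprocess import median_center_iqr_normalize, resolve_one_to_one
from .scoring import normalize_scores, score_samples
from .signature import ALLELES, AlleleSignature

#: Genotype -> mutant alleles. Counts in SimConfig mirror the training
#: cohort: 33 tumors across six genotypes plus nine wild-type normals.
GENOTYPE_ALLELES: dict[str, frozenset[str]] = {
    "A": frozenset({"Apc"}),
    "AK": frozenset({"Apc", "Kras"}),
    "AKP": frozenset({"Apc", "Kras", "Tp53"}),
    "AP": frozenset({"Apc", "Tp53"}),
    "AB": frozenset({"Apc", "Braf"}),
    "ABP": frozenset({"Apc", "Braf", "Tp53"}),
    "WT": frozenset(),
}

DEFAULT_N_PER_GENOTYPE = {"A": 7, "AK": 6, "AKP": 8, "AP": 3, "AB": 4,
                          "ABP": 5, "WT": 9}

#: Signal and noise attenuation of non-representative probesets, emulating
#: lower-efficiency probes; guarantees the representative probeset has the
#: largest robust variability.
SECONDARY_ATTENUATION = 0.5

#: Monthly exponential baseline rates of the survival model: independent
#: relapse and death clocks. Death is exponential, so by memorylessness
#: survival after relapse (death - relapse, given relapse first) is also
#: exponential -- every endpoint is exactly proportional-hazards.
BASE_RATE_RELAPSE = 1 / 90.0
BASE_RATE_DEATH = 1 / 120.0

CELL_LINE_COMPOUNDS = ("PD-0325901", "AZD6244")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults matching the
    emulated cohort design (sample counts) or chosen as realistic
    microarray magnitudes (see docs/methods.md)."""

    seed: int = 0
    #: seed for the planted-gene structure only; defaults to ``seed``. Set it
    #: to another cohort's seed to simulate an independent cohort (new
    #: animals, new noise) carrying the same planted biology.
    structure_seed: int | None = None
    n_per_genotype: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GENOTYPE))
    n_genes: int = 10_000
    probesets_per_gene: int | tuple[int, int] = (1, 3)
    n_planted_per_allele: int = 200
    effect_size: float = 1.5
    overlap_fraction: float = 0.1
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    human_cohort_size: int = 600
    mutation_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"KRAS": 0.35, "BRAF": 0.10})
    transfer_fraction: float = 0.8
    survival_log_hr: float = math.log(2.0)
    hazard_on: str = "score"          # "score" (normalized) or "call" (score > 0)
    censor_fraction: float = 0.3
    n_cell_lines: int = 40
    n_background_genes: int = 1000
    ic50_slope: float = -0.5
    ic50_intercept: float = 1.0
    ic50_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if any(v < 0 for v in self.n_per_genotype.values()):
            raise ValueError("genotype counts must be >= 0")
        unknown = set(self.n_per_genotype) - set(GENOTYPE_ALLELES)
        if unknown:
            raise ValueError(f"unknown genotypes: {sorted(unknown)}")
        if self.n_planted_per_allele * len(ALLELES) > self.n_genes:
            raise ValueError(
                f"{self.n_planted_per_allele} planted genes x {len(ALLELES)} "
                f"alleles exceeds n_genes={self.n_genes}")
        for name in ("overlap_fraction", "transfer_fraction", "censor_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, v in dict(self.mutation_prevalence).items():
            if not 0 <= v <= 1:
                raise ValueError(f"mutation prevalence for {name} out of [0,1]")
        if sum(self.mutation_prevalence.values()) > 1:
            raise ValueError("mutation prevalences sum above 1")
        if self.noise_sd < 0 or self.ic50_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.hazard_on not in ("score", "call"):
            raise ValueError("hazard_on must be 'score' or 'call'")
        if self.n_cell_lines < 3:
            raise ValueError("n_cell_lines must be >= 3")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    planted_up: dict[str, set[str]] | None = None
    planted_down: dict[str, set[str]] | None = None
    true_beta: pd.DataFrame | None = None
    representative: dict[str, str] | None = None
    true_score_rank: dict[str, list[str]] | None = None
    mutation_labels: pd.DataFrame | None = None
    transferred_genes: dict[str, set[str]] | None = None
    true_scores: pd.Series | None = None
    linear_predictor: pd.Series | None = None
    relapse_time: pd.Series | None = None
    death_time: pd.Series | None = None
    true_ic50_slope: float | None = None


def _gene_ids(n: int, prefix: str = "g") -> list[str]:
    width = max(5, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def planted_structure(config: SimConfig) -> tuple[dict, dict, pd.DataFrame]:
    """Choose the planted up/down gene sets and true effect matrix.

    Exactly ``n_planted_per_allele`` genes per allele, half up / half down.
    A fraction ``overlap_fraction`` of each allele's genes is reused from
    every previously planted allele (with its direction kept), giving the
    partially overlapping Venn structure of a shared-pathway design.
    Deterministic given the seed; independent of noise settings.
    """
    sseed = (config.seed if config.structure_seed is None
             else config.structure_seed)
    rng = rng_for(sseed, "planting")
    genes = _gene_ids(config.n_genes)
    order = list(rng.permutation(genes))
    fresh = iter(order)
    n = config.n_planted_per_allele
    n_shared = int(round(config.overlap_fraction * n))

    direction: dict[str, dict[str, int]] = {}
    planted_up: dict[str, set[str]] = {}
    planted_down: dict[str, set[str]] = {}
    used: set[str] = set()
    beta = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"),
                        columns=list(ALLELES))
    for i, allele in enumerate(ALLELES):
        members: dict[str, int | None] = {}
        for prev in ALLELES[:i]:
            pool = sorted(set(direction[prev]) - set(members))
            take = min(n_shared, len(pool), n - len(members))
            for g in rng.choice(pool, size=take, replace=False):
                members[g] = direction[prev][g]
        forced_up = sum(1 for d in members.values() if d == 1)
        need_up = n // 2 - forced_up
        n_fresh = n - len(members)
        if need_up < 0 or need_up > n_fresh:
            raise ValueError("overlap_fraction incompatible with balanced "
                             "up/down planting")
        for j in range(n_fresh):
            g = next(fresh)
            while g in used or g in members:
                g = next(fresh)
            members[g] = 1 if j < need_up else -1
        direction[allele] = dict(members)
        used.update(members)
        planted_up[allele] = {g for g, d in members.items() if d == 1}
        planted_down[allele] = {g for g, d in members.items() if d == -1}
        for g, d in members.items():
            beta.loc[g, allele] = d * config.effect_size
    return planted_up, planted_down, beta


def _cohort_design(n_per_genotype: Mapping[str, int]) -> pd.DataFrame:
    rows, ids = [], []
    for geno, count in n_per_genotype.items():
        for i in range(1, count + 1):
            ids.append(f"{geno}_{i:02d}")
            rows.append([int(a in GENOTYPE_ALLELES[geno]) for a in ALLELES])
    design = pd.DataFrame(rows, index=pd.Index(ids, name="sample"),
                          columns=list(ALLELES))
    design["genotype"] = [s.rsplit("_", 1)[0] for s in ids]
    return design


def _true_score_rank(beta: pd.DataFrame, planted_up, planted_down,
                     n_per_genotype) -> dict[str, list[str]]:
    out = {}
    for allele in ALLELES:
        means = {}
        for geno in n_per_genotype:
            x = np.array([int(a in GENOTYPE_ALLELES[geno]) for a in ALLELES])
            signal = beta.values @ x
            sig = pd.Series(signal, index=beta.index)
            means[geno] = (sig.loc[sorted(planted_up[allele])].mean()
                           - sig.loc[sorted(planted_down[allele])].mean())
        out[allele] = sorted(means, key=lambda g: (-means[g], g))
    return out


def simulate_gemm_cohort(config: SimConfig
                         ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, GroundTruth]:
    """Probeset-level expression for the factorial mouse cohort.

    Each gene g has baseline mu_g ~ Normal(baseline_mean, baseline_sd^2)
    and gene-level signal mu_g + sum_a beta_ga x_as. Its representative
    probeset reports the full signal plus Normal(0, noise_sd^2) noise;
    any additional probesets report attenuated signal and noise (factor
    0.5), so the representative deterministically carries the largest
    robust variability.

    Returns (expression [probesets x samples], probeset->gene annotation,
    genotype design with allele indicator columns, ground truth).
    """
    planted_up, planted_down, beta = planted_structure(config)
    rng = rng_for(config.seed, "gemm")
    genes = list(beta.index)
    design = _cohort_design(config.n_per_genotype)
    x = design[list(ALLELES)].values.astype(float)

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=len(genes))
    signal = mu[:, None] + beta.values @ x.T          # genes x samples

    if isinstance(config.probesets_per_gene, int):
        n_ps = np.full(len(genes), config.probesets_per_gene)
    else:
        lo, hi = config.probesets_per_gene
        n_ps = rng.integers(lo, hi + 1, size=len(genes))

    # the first probeset of each gene is the designated representative:
    # it carries the unattenuated signal and noise, so it has the largest
    # robust scale, and in degenerate zero-spread ties the collapse rule's
    # lexicographic tie-break still lands on it
    rows, ps_ids, ps_gene, rep_map = [], [], [], {}
    n_samples = x.shape[0]
    for gi, gene in enumerate(genes):
        for j in range(n_ps[gi]):
            ps = f"{gene}_ps{j + 1}"
            ps_ids.append(ps)
            ps_gene.append(gene)
            if j == 0:
                rep_map[gene] = ps
                rows.append(signal[gi] + rng.normal(0, config.noise_sd, n_samples)
                            if config.noise_sd > 0 else signal[gi].copy())
            else:
                att = mu[gi] + SECONDARY_ATTENUATION * (signal[gi] - mu[gi])
                sd = SECONDARY_ATTENUATION * config.noise_sd
                rows.append(att + rng.normal(0, sd, n_samples)
                            if sd > 0 else att)
    expr = pd.DataFrame(np.vstack(rows), index=pd.Index(ps_ids, name="probeset"),
                        columns=design.index)
    annotation = pd.Series(ps_gene, index=expr.index, name="gene")
    truth = GroundTruth(
        planted_up=planted_up, planted_down=planted_down, true_beta=beta,
        representative=rep_map,
        true_score_rank=_true_score_rank(beta, planted_up, planted_down,
                                         config.n_per_genotype))
    return expr, annotation, design, truth


def make_homolog_map(gene_ids, target_prefix: str = "h",
                     n_unmapped: int = 0, n_one_to_many: int = 0,
                     seed: int = 0) -> pd.DataFrame:
    """Source->target homolog table for the simulated genes.

    By default a complete one-to-one map (``gNNNNN`` -> ``hNNNNN``);
    optionally drops ``n_unmapped`` sources and gives ``n_one_to_many``
    sources a second target, to exercise the resolution rule.
    """
    rng = rng_for(seed, "homologs")
    genes = list(gene_ids)
    targets = [target_prefix + g[1:] for g in genes]
    df = pd.DataFrame({"source": genes, "target": targets})
    if n_unmapped:
        drop = rng.choice(len(df), size=n_unmapped, replace=False)
        df = df.drop(index=df.index[drop])
    if n_one_to_many:
        dup = rng.choice(df.index, size=n_one_to_many, replace=False)
        extra = df.loc[dup].copy()
        extra["target"] = extra["target"] + "_alt"
        df = pd.concat([df, extra], ignore_index=True)
    return df.reset_index(drop=True)


def _tuned_uniform_censoring(death: np.ndarray, target: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Uniform(0, c_max) censoring times with c_max tuned by bisection so
    the expected censored fraction matches ``target``."""
    if target <= 0:
        return np.full(len(death), np.inf)
    lo, hi = 1e-6, 1e7

    def frac(cmax: float) -> float:
        return float(np.mean(np.minimum(death, cmax) / cmax))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return rng.uniform(0, 0.5 * (lo + hi), size=len(death))


def simulate_human_cohort(config: SimConfig,
                          signatures: Mapping[str, AlleleSignature],
                          homolog_map: pd.DataFrame,
                          ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, GroundTruth]:
    """Human-like cohort with mutation labels and score-linked survival.

    Human genes are the homologs of the simulated mouse genes. KRAS- and
    BRAF-mutant samples receive ``transfer_fraction`` of the homologous
    Kras/Braf planted effects. Survival uses independent exponential
    relapse and death clocks whose log hazards both equal
    ``survival_log_hr`` times the normalized Kras signature score (or the
    score > 0 call when ``hazard_on == "call"``), so OS, RFS and SAR are
    all exactly proportional-hazards in that covariate; censoring is
    independent uniform, tuned to ``censor_fraction``. SAR exists only for
    samples whose relapse was observed.
    """
    if not signatures:
        raise ValueError("at least one allele signature is required")
    pairs = resolve_one_to_one(homolog_map)
    if pairs.empty:
        raise ValueError("empty homolog map")
    m2h = pd.Series(pairs["target"].values, index=pairs["source"].values)

    planted_up, planted_down, beta = planted_structure(config)
    rng = rng_for(config.seed, "human")
    n = config.human_cohort_size
    sample_ids = pd.Index([f"P{i:04d}" for i in range(1, n + 1)], name="sample")

    # mutually exclusive mutation labels
    prev = dict(config.mutation_prevalence)
    u = rng.uniform(size=n)
    kras = u < prev.get("KRAS", 0.0)
    braf = (~kras) & (u < prev.get("KRAS", 0.0) + prev.get("BRAF", 0.0))
    labels = pd.DataFrame(
        {"kras_status": np.where(kras, "mutant", "wild-type"),
         "braf_status": np.where(braf, "mutant", "wild-type")},
        index=sample_ids)

    human_genes = sorted(m2h.values)
    h_index = pd.Index(human_genes, name="gene")
    mu = pd.Series(rng.normal(config.baseline_mean, config.baseline_sd,
                              len(human_genes)), index=h_index)
    expr = pd.DataFrame(
        rng.normal(0, config.noise_sd, size=(len(human_genes), n))
        if config.noise_sd > 0 else np.zeros((len(human_genes), n)),
        index=h_index, columns=sample_ids)
    expr = expr.add(mu, axis=0)

    transferred: dict[str, set[str]] = {}
    for allele, mut_mask in (("Kras", kras), ("Braf", braf)):
        mouse_planted = sorted(planted_up[allele] | planted_down[allele])
        mapped = [g for g in mouse_planted if g in m2h.index]
        k = int(round(config.transfer_fraction * len(mapped)))
        chosen = sorted(rng.choice(mapped, size=k, replace=False)) if k else []
        transferred[allele] = {m2h[g] for g in chosen}
        if chosen and mut_mask.any():
            eff = beta.loc[chosen, allele].values
            hgenes = [m2h[g] for g in chosen]
            expr.loc[hgenes, expr.columns[mut_mask]] += eff[:, None]

    # scores via the standard pipeline, on the Kras signature if present
    key = "Kras" if "Kras" in signatures else next(iter(signatures))
    sig = signatures[key]
    if any(g in m2h.index for g in sig.up_genes):
        sig = sig.translated(m2h)
    norm = median_center_iqr_normalize(expr)
    raw = score_samples(norm, sig, min_coverage=0.0)
    try:
        scores = normalize_scores(raw).scores
    except ValueError:       # degenerate spread (e.g. noiseless cohorts)
        scores = raw.scores - np.median(raw.scores.values)

    z = scores.values
    lp = config.survival_log_hr * ((z > 0).astype(float)
                                   if config.hazard_on == "call" else z)
    hazard = np.exp(lp)
    t_relapse = rng.exponential(1.0 / (BASE_RATE_RELAPSE * hazard))
    death = rng.exponential(1.0 / (BASE_RATE_DEATH * hazard))
    relapsed = t_relapse < death
    censor = _tuned_uniform_censoring(death, config.censor_fraction,
                                      rng_for(config.seed, "censoring"))

    os_time = np.minimum(death, censor)
    os_event = (death <= censor).astype(int)
    rfs_raw = np.where(relapsed, t_relapse, death)
    rfs_time = np.minimum(rfs_raw, censor)
    rfs_event = (rfs_raw <= censor).astype(int)
    relapse_obs = relapsed & (t_relapse <= censor)
    sar_time = np.where(relapse_obs, os_time - t_relapse, np.nan)
    sar_event = np.where(relapse_obs, os_event, np.nan)

    extras = rng_for(config.seed, "covariates")
    surv = pd.DataFrame({
        "os_time": os_time, "os_event": os_event,
        "rfs_time": rfs_time, "rfs_event": rfs_event,
        "sar_time": sar_time, "sar_event": sar_event,
        "kras_status": labels["kras_status"].values,
        "braf_status": labels["braf_status"].values,
        "stage": extras.choice(["2", "3"], size=n, p=[0.4, 0.6]),
        "grade": extras.choice(["1", "2", "3"], size=n, p=[0.2, 0.5, 0.3]),
        "msi": extras.choice(["MSS", "MSI"], size=n, p=[0.85, 0.15]),
        "mucinous": extras.choice(["no", "yes"], size=n, p=[0.85, 0.15]),
        "site": extras.choice(["left", "right"], size=n, p=[0.6, 0.4]),
    }, index=sample_ids)

    truth = GroundTruth(
        planted_up=planted_up, planted_down=planted_down, true_beta=beta,
        mutation_labels=labels, transferred_genes=transferred,
        true_scores=scores, linear_predictor=pd.Series(lp, index=sample_ids),
        relapse_time=pd.Series(np.where(relapsed, t_relapse, np.nan),
                               index=sample_ids),
        death_time=pd.Series(death, index=sample_ids))
    mut_labels = labels["kras_status"].rename("kras_status")
    return expr, mut_labels, surv, truth


def simulate_cell_lines(config: SimConfig, signature: AlleleSignature,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Cell-line panel with score-linked ln IC50.

    Each line i has a latent pathway-activation a_i ~ Normal(0,1); the
    signature's up genes gain ``effect_size * a_i`` and its down genes lose
    it, on top of background genes. The panel's signature score (computed
    through the standard scoring pipeline) sets
    ln IC50 = intercept + ic50_slope * score + Normal(0, ic50_noise_sd^2)
    per compound. KRAS-mutant labels are assigned with probability 0.7 to
    lines above the median score and 0.2 below.
    """
    rng = rng_for(config.seed, "cells")
    n = config.n_cell_lines
    ids = pd.Index([f"CL{i:03d}" for i in range(1, n + 1)], name="cell_line")
    up, down = list(signature.up_genes), list(signature.down_genes)
    bg = _gene_ids(config.n_background_genes, prefix="bg")
    genes = pd.Index(sorted(set(up) | set(down) | set(bg)), name="gene")

    a = rng.normal(0, 1, size=n)
    mu = rng.normal(config.baseline_mean, config.baseline_sd, len(genes))
    noise = (rng.normal(0, config.noise_sd, size=(len(genes), n))
             if config.noise_sd > 0 else np.zeros((len(genes), n)))
    expr = pd.DataFrame(mu[:, None] + noise, index=genes, columns=ids)
    expr.loc[expr.index.intersection(up)] += config.effect_size * a
    expr.loc[expr.index.intersection(down)] -= config.effect_size * a

    norm = median_center_iqr_normalize(expr)
    raw = score_samples(norm, signature, min_coverage=0.0)
    scores = normalize_scores(raw).scores

    above = scores.values > np.median(scores.values)
    p_mut = np.where(above, 0.7, 0.2)
    kras = rng.uniform(size=n) < p_mut
    braf = (~kras) & (rng.uniform(size=n) < 0.10)

    rows = []
    for compound in CELL_LINE_COMPOUNDS:
        eps = (rng.normal(0, config.ic50_noise_sd, size=n)
               if config.ic50_noise_sd > 0 else np.zeros(n))
        ln_ic50 = (config.ic50_intercept
                   + config.ic50_slope * scores.values + eps)
        for i, cl in enumerate(ids):
            rows.append({"cell_line": cl, "compound": compound,
                         "ln_ic50": ln_ic50[i],
                         "kras_status": "mutant" if kras[i] else "wild-type",
                         "braf_status": "mutant" if braf[i] else "wild-type"})
    dose = pd.DataFrame(rows)
    truth = GroundTruth(true_scores=scores, true_ic50_slope=config.ic50_slope,
                        mutation_labels=pd.DataFrame(
                            {"kras_status": np.where(kras, "mutant", "wild-type"),
                             "braf_status": np.where(braf, "mutant", "wild-type")},
                            index=ids))
    return expr, dose, truth
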