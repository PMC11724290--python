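"""Synthetic cohorts with the statistical structure of a TWAS simulation study.

Two cohorts (a reference panel used to train expression models and a GWAS
cohort used to test trait association) are drawn from the same variant
layout, so allele frequencies and LD blocks are shared in expectation while
individual genotypes differ.  Expression is additive in a set of causal cis
and grouped trans variants with effect sizes drawn from N(0, 1) and then
rescaled so the cis and trans genetic components hit target heritability
fractions.  Phenotypes follow either a causality architecture (genotype ->
expression -> trait) or horizontal pleiotropy (genotype -> trait directly,
through the same causal variants with independent effects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomics_io import GenotypeMatrix, IntervalSet, SummaryStatsTable, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Knobs of the simulation study; defaults mirror the published design."""

    n_ref: int = 500
    n_gwas: int = 5000
    n_genes: int = 1
    n_cis_candidates: int = 200
    n_trans_regions: int = 10
    variants_per_region: int = 50
    n_causal_cis: int = 5
    n_causal_trans_regions: int = 3
    n_causal_per_trans_region: int = 5
    h2_expr_cis: float = 0.1
    h2_expr_trans: float = 0.2
    h2_trait: float = 0.3
    scenario: str = "causality"
    trait_type: str = "quantitative"
    min_causal_maf: float = 0.01
    ld_rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h2_expr_cis + self.h2_expr_trans > 1 + 1e-12:
            raise ValueError("h2_expr_cis + h2_expr_trans must be <= 1")
        if self.h2_trait > 1 + 1e-12:
            raise ValueError("h2_trait must be <= 1")
        if self.n_causal_cis > self.n_cis_candidates:
            raise ValueError("more causal cis variants than candidates")
        if self.n_causal_trans_regions > self.n_trans_regions:
            raise ValueError("more causal trans regions than regions")
        if self.n_causal_per_trans_region > self.variants_per_region:
            raise ValueError("more causal trans variants than region size")
        if self.scenario not in ("causality", "pleiotropy"):
            raise ValueError(f"unknown scenario: {self.scenario!r}")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type: {self.trait_type!r}")


@dataclass
class TruthRecord:
    """Ground truth of one simulated gene, for parameter-recovery tests."""

    gene_id: str
    cis_variants: list[str] = field(default_factory=list)
    cis_effects: np.ndarray | None = None
    trans_groups: dict[str, list[str]] = field(default_factory=dict)
    trans_effects: dict[str, np.ndarray] = field(default_factory=dict)
    h2_expr_cis: float = 0.0
    h2_expr_trans: float = 0.0
    realized_h2_cis: float = 0.0
    realized_h2_trans: float = 0.0
    sigma_e_expr: float = 0.0
    scenario: str = "causality"

    @property
    def causal_trans_variants(self) -> list[str]:
        return [v for ids in self.trans_groups.values() for v in ids]

    @property
    def all_causal_variants(self) -> list[str]:
        return list(self.cis_variants) + self.causal_trans_variants


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def make_variant_layout(
    blocks: list[tuple[str, int, int]],
    maf_sampler=None,
    seed: int = 0,
    prefix: str = "v",
) -> pd.DataFrame:
    """Lay out variants in LD blocks.

    ``blocks`` is a list of (chrom, start_pos, n_variants); variants within a
    block are spaced 1 kb apart and share an LD block id.  ``maf_sampler``
    maps an rng and a count to MAFs (default: Uniform(0.05, 0.5)).
    """
    rng = np.random.default_rng(seed)
    if maf_sampler is None:
        maf_sampler = lambda r, k: r.uniform(0.05, 0.5, size=k)
    rows = []
    counter = 0
    for block_id, (chrom, start, n) in enumerate(blocks):
        mafs = np.asarray(maf_sampler(rng, n), dtype=float)
        for j in range(n):
            rows.append(
                (f"{prefix}{counter}", chrom, start + 1000 * j, "A", "G", mafs[j], block_id)
            )
            counter += 1
    return pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "ref_allele", "alt_allele", "maf", "block"]
    )


def simulate_genotypes(
    n_samples: int,
    variant_layout: pd.DataFrame,
    ld_rho: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw dosages as two Hardy–Weinberg haplotypes with AR(1)-block LD.

    Each haplotype is a thresholded latent Gaussian AR(1) process within an
    LD block (correlation ``ld_rho`` between adjacent latents), so adjacent
    variants are positively correlated, with correlation increasing in
    ``ld_rho``; allele frequencies equal the layout MAF column in
    expectation regardless of seed.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = len(variant_layout)
    mafs = variant_layout["maf"].to_numpy(float)
    blocks = variant_layout["block"].to_numpy()
    thresholds = stats.norm.ppf(mafs)

    dosages = np.zeros((n_samples, p))
    for _hap in range(2):
        latent = np.empty((n_samples, p))
        prev_block = None
        for j in range(p):
            e = rng.standard_normal(n_samples)
            if j > 0 and blocks[j] == prev_block:
                latent[:, j] = ld_rho * latent[:, j - 1] + np.sqrt(1 - ld_rho**2) * e
            else:
                latent[:, j] = e
            prev_block = blocks[j]
        dosages += (latent < thresholds[None, :]).astype(float)

    variants = [
        VariantRecord(r.variant_id, str(r.chrom), int(r.pos), r.ref_allele, r.alt_allele,
                      float(r.maf))
        for r in variant_layout.itertuples()
    ]
    samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(samples, variants, dosages)


# ---------------------------------------------------------------------------
# heritability machinery
# ---------------------------------------------------------------------------


def rescale_to_heritability(genetic_component: np.ndarray, h2: float) -> float:
    """Noise SD sigma_e with sigma_g^2 / (sigma_g^2 + sigma_e^2) = h2.

    ``sigma_g^2`` is the empirical variance of the realized genetic
    component, so the heritability constraint holds exactly in-sample.
    """
    if not (0 < h2 <= 1):
        raise ValueError(f"h2 must be in (0, 1], got {h2}")
    sigma_g2 = float(np.var(genetic_component))
    if sigma_g2 <= 0:
        raise ValueError("genetic component is constant; heritability undefined")
    return float(np.sqrt(sigma_g2 * (1.0 - h2) / h2))


def simulate_expression(
    genotypes: GenotypeMatrix,
    truth: TruthRecord,
    h2_expr_cis: float,
    h2_expr_trans: float,
    seed: int = 0,
    effects: tuple[np.ndarray, dict[str, np.ndarray]] | None = None,
) -> tuple[np.ndarray, TruthRecord]:
    """Simulate expression additively from the causal layout in ``truth``.

    Effect sizes are drawn from N(0, 1) (unless pre-drawn effects are
    supplied, e.g. to reuse the same architecture in a second cohort) and
    the cis and trans genetic components are separately rescaled so their
    empirical variance fractions equal ``h2_expr_cis`` and ``h2_expr_trans``;
    Gaussian noise supplies the remaining 1 - h2 fraction of unit variance.
    The returned TruthRecord stores the rescaled (per-dosage) effects.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    if effects is None:
        cis_eff = rng.standard_normal(len(truth.cis_variants))
        trans_eff = {
            region: rng.standard_normal(len(ids)) for region, ids in truth.trans_groups.items()
        }
    else:
        cis_eff, trans_eff = effects
        cis_eff = np.asarray(cis_eff, float).copy()
        trans_eff = {k: np.asarray(v, float).copy() for k, v in trans_eff.items()}

    cis_comp = np.zeros(n)
    if truth.cis_variants and h2_expr_cis > 0:
        Xc = genotypes.columns(truth.cis_variants)
        cis_comp = Xc @ cis_eff
        sd = cis_comp.std()
        scale = np.sqrt(h2_expr_cis) / sd if sd > 0 else 0.0
        cis_comp *= scale
        cis_eff = cis_eff * scale
    else:
        cis_eff = np.zeros(len(truth.cis_variants))

    trans_comp = np.zeros(n)
    if truth.trans_groups and h2_expr_trans > 0:
        ids = truth.causal_trans_variants
        eff = np.concatenate([trans_eff[r] for r in truth.trans_groups])
        Xt = genotypes.columns(ids)
        trans_comp = Xt @ eff
        sd = trans_comp.std()
        scale = np.sqrt(h2_expr_trans) / sd if sd > 0 else 0.0
        trans_comp *= scale
        trans_eff = {r: trans_eff[r] * scale for r in truth.trans_groups}
    else:
        trans_eff = {r: np.zeros(len(ids)) for r, ids in truth.trans_groups.items()}

    h2_total = (h2_expr_cis if truth.cis_variants else 0.0) + (
        h2_expr_trans if truth.trans_groups else 0.0
    )
    if h2_total == 0:
        logger.warning("gene %s: zero heritability; expression is pure noise", truth.gene_id)
    sigma_e = float(np.sqrt(max(1.0 - h2_total, 0.0)))
    expr = cis_comp + trans_comp + rng.normal(0.0, sigma_e, size=n)

    tot_var = np.var(expr)
    truth.cis_effects = cis_eff
    truth.trans_effects = trans_eff
    truth.h2_expr_cis = h2_expr_cis
    truth.h2_expr_trans = h2_expr_trans
    truth.realized_h2_cis = float(np.var(cis_comp) / tot_var) if tot_var > 0 else 0.0
    truth.realized_h2_trans = float(np.var(trans_comp) / tot_var) if tot_var > 0 else 0.0
    truth.sigma_e_expr = sigma_e
    return expr, truth


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    expression: np.ndarray,
    scenario: str,
    h2_trait: float,
    trait_type: str = "quantitative",
    seed: int = 0,
    truth: TruthRecord | None = None,
) -> np.ndarray:
    """Simulate a trait under causality or horizontal pleiotropy.

    Causality: the genetic component of the trait *is* the simulated
    expression (mediation).  Pleiotropy: the same causal variants act on the
    trait directly with independent N(0, 1) effects.  Either component is
    rescaled to trait heritability ``h2_trait`` and Gaussian noise is added;
    binary traits threshold the liability at its median (prevalence 0.5).
    """
    rng = np.random.default_rng(seed)
    if scenario == "causality":
        genetic = np.asarray(expression, float)
    elif scenario == "pleiotropy":
        if truth is None:
            raise ValueError("pleiotropy scenario requires the TruthRecord")
        ids = truth.all_causal_variants
        if not ids:
            raise ValueError("pleiotropy scenario requires causal variants in truth")
        genetic = genotypes.columns(ids) @ rng.standard_normal(len(ids))
    else:
        raise ValueError(f"unknown scenario: {scenario!r}")

    if h2_trait <= 0:
        liability = rng.standard_normal(genotypes.n_samples)
    else:
        # normalize the genetic component to variance h2_trait, noise to 1-h2
        sd = genetic.std()
        genetic = genetic * (np.sqrt(h2_trait) / sd)
        sigma_e = rescale_to_heritability(genetic, h2_trait)
        liability = genetic + rng.normal(0.0, sigma_e, size=genotypes.n_samples)
    if trait_type == "binary":
        return (liability > np.median(liability)).astype(float)
    if trait_type != "quantitative":
        raise ValueError(f"unknown trait_type: {trait_type!r}")
    return liability


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def compute_gwas_summary(
    genotypes: GenotypeMatrix, phenotype: np.ndarray, model: str = "linear"
) -> SummaryStatsTable:
    """Per-variant single-variant GWAS with intercept; effect allele = alt.

    Monomorphic variants are flagged with beta = 0, se = inf, pvalue = 1 and
    an ``excluded`` marker.  Linear regressions are solved in closed form
    across variants; logistic regressions by vectorized Newton iterations.
    """
    y = np.asarray(phenotype, float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    if model == "logistic" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logistic model requires a binary 0/1 phenotype")
    X = genotypes.dosages
    mono = X.std(axis=0) == 0
    if model == "linear":
        beta, se = _linear_gwas(X, y)
    elif model == "logistic":
        beta, se = _logistic_gwas(X, y)
    else:
        raise ValueError(f"unknown GWAS model: {model!r}")
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.inf, se)
    z = np.where(np.isfinite(se), beta / se, 0.0)
    pvals = np.where(mono, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    meta = genotypes.metadata_frame()
    df = pd.DataFrame(
        {
            "variant_id": meta["variant_id"],
            "chrom": meta["chrom"],
            "pos": meta["pos"],
            "effect_allele": meta["alt_allele"],
            "other_allele": meta["ref_allele"],
            "beta": beta,
            "se": np.where(mono, 1.0, se),  # placeholder for table invariant
            "pvalue": pvals,
            "excluded": mono,
        }
    )
    # keep the se>0 invariant for monomorphic rows but mark them excluded
    tbl = SummaryStatsTable(df[~df["excluded"]].drop(columns=["excluded"]))
    tbl.n_excluded_monomorphic = int(mono.sum())
    return tbl


def _linear_gwas(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    sxy = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / sxx, 0.0)
        sse = (yc**2).sum() - beta * sxy
        sigma2 = sse / max(n - 2, 1)
        se = np.sqrt(np.where(sxx > 0, sigma2 / sxx, np.inf))
    return beta, se


def _logistic_gwas(X: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10):
    """Per-variant logistic regression (intercept + dosage), Newton in parallel."""
    n, p = X.shape
    a = np.full(p, np.log(y.mean() / (1 - y.mean())) if 0 < y.mean() < 1 else 0.0)
    b = np.zeros(p)
    for _ in range(max_iter):
        eta = a[None, :] + X * b[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = y[:, None] - mu
        g1 = r.sum(axis=0)
        g2 = (X * r).sum(axis=0)
        h11 = w.sum(axis=0)
        h12 = (w * X).sum(axis=0)
        h22 = (w * X**2).sum(axis=0)
        det = h11 * h22 - h12**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        da = (h22 * g1 - h12 * g2) / det
        db = (h11 * g2 - h12 * g1) / det
        # damp huge steps (quasi-separation)
        step = np.maximum(np.abs(da), np.abs(db))
        damp = np.where(step > 10, 10 / step, 1.0)
        a += da * damp
        b += db * damp
        if np.max(np.abs(db)) < tol:
            break
    eta = a[None, :] + X * b[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    h11 = w.sum(axis=0)
    h12 = (w * X).sum(axis=0)
    h22 = (w * X**2).sum(axis=0)
    det = h11 * h22 - h12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, h11 / det, np.inf))
    return b, se


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


@dataclass
class Annotations:
    """Bundle of regulatory annotations consumed by the prioritization step."""

    tf_peaks: dict[str, IntervalSet]
    gene_table: pd.DataFrame  # gene_id, chrom, start, end, strand (incl. TF genes)
    regions: dict[str, IntervalSet]  # dhs / enhancer / promoter
    eqtl: pd.DataFrame  # tf, variant_id, pvalue
    enhancer_links: pd.DataFrame  # tf, chrom, start, end
    interactions: pd.DataFrame  # chrom1,start1,end1,chrom2,start2,end2
    tf_cis_layout: pd.DataFrame  # variant layout of TF cis candidate variants
    planted_tf_genes: set[tuple[str, str]]
    planted_tf_variants: dict[str, list[str]]


def simulate_annotations(config: SimulationConfig, seed: int = 0) -> Annotations:
    """Generate regulatory annotations wired to a recoverable ground truth.

    Each artificial TF gets its own chromosome carrying its gene body and
    ``variants_per_region`` cis candidate variants, all placed in regulatory
    regions (DHS by construction) and linked to the TF by eQTL significance,
    promoter location, or an enhancer–gene link, so the prioritization step
    can recover exactly the planted TF cis-variant sets.  Every (TF, target
    gene) pair is planted as a ChIP-seq peak within ±20 kb of the gene TSS.
    """
    rng = np.random.default_rng(seed)
    n_tf = config.n_trans_regions
    m = config.variants_per_region

    gene_rows = []
    tf_peaks: dict[str, IntervalSet] = {}
    dhs, enh, prom = [], [], []
    eqtl_rows, link_rows, ia_rows = [], [], []
    tf_layout_blocks = []
    planted_tf_variants: dict[str, list[str]] = {}

    # target genes on chr1..; TFs each on their own later chromosome
    for g in range(config.n_genes):
        chrom = f"chr{g + 1}"
        start = 5_000_000
        gene_rows.append((f"gene{g}", chrom, start, start + 10_000, "+"))

    tf_names = [f"TF{t}" for t in range(n_tf)]
    for t, tf in enumerate(tf_names):
        chrom = f"chr{config.n_genes + t + 1}"
        tss = 2_000_000
        gene_rows.append((tf, chrom, tss, tss + 30_000, "+"))
        # cis candidates within +-1 Mb of the TF TSS, in one LD block
        layout = make_variant_layout(
            [(chrom, tss - 500_000, m)], seed=int(rng.integers(2**31)), prefix=f"tf{t}_v"
        )
        tf_layout_blocks.append(layout)
        planted_tf_variants[tf] = layout["variant_id"].tolist()
        # every TF cis variant sits in a DHS
        for r in layout.itertuples():
            dhs.append((chrom, r.pos - 50, r.pos + 50, ""))
        # every TF cis-variant is a significant eQTL for its TF (the null-sim
        # construction); a subset carries additional regulatory evidence
        kinds = rng.choice(["eqtl_only", "promoter", "enhancer", "interaction"],
                           size=m, p=[0.7, 0.1, 0.1, 0.1])
        prom.append((chrom, tss - 2_000, tss + 2_000, tf))
        promoter_offsets = iter(rng.choice(np.arange(-1_500, 1_500), size=m, replace=False))
        for r, kind in zip(layout.itertuples(), kinds):
            eqtl_rows.append((tf, r.variant_id, float(rng.uniform(1e-6, 0.049))))
            if kind == "promoter":
                # relocate the variant into the TF promoter window (unique pos)
                layout.loc[layout["variant_id"] == r.variant_id, "pos"] = int(
                    tss + next(promoter_offsets)
                )
            elif kind == "enhancer":
                enh.append((chrom, r.pos - 100, r.pos + 100, ""))
                link_rows.append((tf, chrom, r.pos - 100, r.pos + 100))
            elif kind == "interaction":
                enh.append((chrom, r.pos - 100, r.pos + 100, ""))
                ia_rows.append((chrom, r.pos - 100, r.pos + 100,
                                chrom, tss - 1_000, tss + 1_000))

    # plant a peak for every TF within +-20 kb of every target gene TSS
    planted_pairs = set()
    for g in range(config.n_genes):
        gid, chrom, start = f"gene{g}", f"chr{g + 1}", 5_000_000
        for tf in tf_names:
            off = int(rng.integers(-19_000, 19_000))
            peak = (chrom, max(start + off - 250, 0), start + off + 250, tf)
            tf_peaks.setdefault(tf, IntervalSet([])).intervals.append(peak)
            planted_pairs.add((tf, gid))

    gene_table = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return Annotations(
        tf_peaks=tf_peaks,
        gene_table=gene_table,
        regions={
            "dhs": IntervalSet(dhs),
            "enhancer": IntervalSet(enh) if enh else IntervalSet([]),
            "promoter": IntervalSet(prom),
        },
        eqtl=pd.DataFrame(eqtl_rows, columns=["tf", "variant_id", "pvalue"]),
        enhancer_links=pd.DataFrame(link_rows, columns=["tf", "chrom", "start", "end"]),
        interactions=pd.DataFrame(
            ia_rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
        ),
        tf_cis_layout=pd.concat(tf_layout_blocks, ignore_index=True),
        planted_tf_genes=planted_pairs,
        planted_tf_variants=planted_tf_variants,
    )
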