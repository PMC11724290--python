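"""Simulation benchmarks: type-I error under the null, power under signal.

The null experiment wires the whole pipeline together: binary phenotypes
drawn independently of genotype, per-variant logistic-regression GWAS
summary statistics, chi-squared-based cis-variant prioritization,
group-lasso + elastic-net model training on a reference cohort with
genuinely heritable expression, and Bonferroni-corrected gene-level
association.  The reported quantity is the family-wise rejection fraction:
the share of replicates in which at least one gene is declared significant.

The power experiment simulates a single causal gene per replicate under a
causality or horizontal-pleiotropy architecture and compares detection
rates of the TF-grouped trans method against cis-only comparators
(all-cis elastic net, random-200-cis elastic net) and a random-group
control with the same group count and sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .expression_models import ModelConfig, residualize_covariates, select_trans_for_gene, train_gene_model
from .genomics_io import GenotypeMatrix
from .regulatory_prioritization import (
    TransGroup,
    build_trans_groups,
    discover_tf_gene_pairs,
    find_tf_cis_variants,
    prioritize_stfcre_variants,
)
from .synthetic_cohort import (
    SimulationConfig,
    TruthRecord,
    compute_gwas_summary,
    make_variant_layout,
    simulate_annotations,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotype,
)
from .twas_association import ReferencePanel, associate_genes

logger = logging.getLogger(__name__)

METHODS = ("transtf", "transtf_random", "cis_all", "cis_random200")


@dataclass
class ExperimentGrid:
    """Grid of power-simulation cells."""

    scenario: str = "causality"
    h2_expr_cis: list[float] = field(default_factory=lambda: [0.1])
    h2_expr_trans: list[float] = field(default_factory=lambda: [0.3])
    h2_trait: list[float] = field(default_factory=lambda: [0.3])
    replicates: int = 100
    methods: tuple[str, ...] = METHODS
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")


# ---------------------------------------------------------------------------
# null experiment
# ---------------------------------------------------------------------------


@dataclass
class NullWorld:
    """Replicate-invariant state of the null simulation."""

    config: SimulationConfig
    layout: pd.DataFrame
    ref: GenotypeMatrix
    gwas_genotypes: GenotypeMatrix
    annotations: object
    gene_bodies: dict[str, tuple[str, int, int]]
    trans_groups: dict[str, list[TransGroup]]
    expression: dict[str, np.ndarray]
    trans_selected: dict[str, list[str]]
    cis_candidates: dict[str, list[str]]
    panel: ReferencePanel
    model_config: ModelConfig


def build_null_world(config: SimulationConfig, model_config: ModelConfig | None = None,
                     seed: int | None = None) -> NullWorld:
    """Generate cohorts, annotations and replicate-invariant model state.

    Expression carries genuine cis and trans heritability (so models pass
    the retention rule); only the phenotype is null.  The group-lasso
    trans-selection depends solely on this fixed reference data, so it is
    computed once here and reused across replicates.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    cfg = config
    mcfg = model_config or ModelConfig(
        lambda_grid_size=30, gl_folds=3, folds=10, n_alphas_enet=30, seed=seeds[0]
    )

    ann = simulate_annotations(cfg, seed=seeds[1])
    gene_blocks = []
    for g in range(cfg.n_genes):
        gene_blocks.append((f"chr{g + 1}", 4_200_000, cfg.n_cis_candidates))
    gene_layout = make_variant_layout(gene_blocks, seed=seeds[2], prefix="cis_v")
    layout = pd.concat([gene_layout, ann.tf_cis_layout], ignore_index=True)
    layout["block"] = pd.factorize(layout["chrom"])[0]  # one LD block per region

    ref = simulate_genotypes(cfg.n_ref, layout, ld_rho=cfg.ld_rho, seed=seeds[3])
    gwas_geno = simulate_genotypes(cfg.n_gwas, layout, ld_rho=cfg.ld_rho, seed=seeds[4])

    # Step I/II on the generated annotations
    tf_names = sorted(ann.planted_tf_variants)
    tf_sets = {
        tf: find_tf_cis_variants(
            tf, ann.gene_table, ann.tf_cis_layout[["variant_id", "chrom", "pos"]],
            [ann.eqtl], ann.regions, ann.enhancer_links, ann.interactions,
        )
        for tf in tf_names
    }
    tf_gene_map = discover_tf_gene_pairs(ann.tf_peaks, ann.gene_table)

    gene_bodies = {}
    trans_groups = {}
    expression = {}
    trans_selected = {}
    cis_candidates = {}
    rng = np.random.default_rng(seeds[5])
    gene_rows = ann.gene_table[~ann.gene_table["gene_id"].str.startswith("TF")]
    var_pos = layout[["variant_id", "chrom", "pos"]]
    for g_idx, grow in enumerate(gene_rows.itertuples()):
        gid = grow.gene_id
        body = (str(grow.chrom), int(grow.start), int(grow.end))
        gene_bodies[gid] = body
        groups = build_trans_groups(gid, body, tf_gene_map, tf_sets, var_pos)
        trans_groups[gid] = groups
        cands = gene_layout[gene_layout["chrom"] == grow.chrom]["variant_id"].tolist()
        cis_candidates[gid] = cands

        eligible = gene_layout[
            (gene_layout["chrom"] == grow.chrom) & (gene_layout["maf"] > cfg.min_causal_maf)
        ]["variant_id"].tolist()
        causal_cis = list(rng.choice(eligible, size=min(cfg.n_causal_cis, len(eligible)),
                                     replace=False))
        causal_tfs = list(rng.choice(tf_names, size=cfg.n_causal_trans_regions, replace=False))
        truth = TruthRecord(
            gene_id=gid,
            cis_variants=causal_cis,
            trans_groups={
                tf: list(rng.choice(ann.planted_tf_variants[tf],
                                    size=cfg.n_causal_per_trans_region, replace=False))
                for tf in causal_tfs
            },
        )
        expr, _ = simulate_expression(
            ref, truth, cfg.h2_expr_cis, cfg.h2_expr_trans, seed=int(rng.integers(2**31))
        )
        expression[gid] = expr
        y = residualize_covariates(expr, None)
        selected, _ = select_trans_for_gene(ref, y, groups, mcfg)
        trans_selected[gid] = selected

    return NullWorld(
        config=cfg,
        layout=layout,
        ref=ref,
        gwas_genotypes=gwas_geno,
        annotations=ann,
        gene_bodies=gene_bodies,
        trans_groups=trans_groups,
        expression=expression,
        trans_selected=trans_selected,
        cis_candidates=cis_candidates,
        panel=ReferencePanel(ref),
        model_config=mcfg,
    )


def run_null_experiment(
    config: SimulationConfig,
    replicates: int = 20,
    seed: int = 0,
    target_count: int = 1000,
    n_binding_sets: int = 100,
    binding_fraction: float = 0.1,
    world: NullWorld | None = None,
) -> dict:
    """Family-wise type-I error of the full pipeline under a null phenotype.

    Each replicate draws a balanced binary phenotype independent of
    genotype, computes logistic-regression GWAS summary statistics,
    prioritizes TF-occupied cis-variants from randomly assigned binding
    sets, trains per-gene elastic-net models (reusing the cached
    group-lasso trans-selections, whose inputs are replicate-invariant) and
    tests every retained gene at the Bonferroni-corrected 0.05 level.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    w = world or build_null_world(config, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]).generate_state(1)[0])
    gene_ids = sorted(w.expression)
    rejected = []
    pooled_pvalues: list[float] = []
    n_failed = 0
    for rep in range(replicates):
        try:
            pheno = rng.binomial(1, 0.5, size=w.gwas_genotypes.n_samples).astype(float)
            gwas = compute_gwas_summary(w.gwas_genotypes, pheno, model="logistic")
            binding = pd.DataFrame(
                rng.random((len(w.layout), n_binding_sets)) < binding_fraction,
                index=w.layout["variant_id"],
                columns=[f"B{j}" for j in range(n_binding_sets)],
            )
            ranked, _ = prioritize_stfcre_variants(gwas, binding, target_count=target_count)
            prioritized = set(ranked)
            models = []
            for gid in gene_ids:
                cis = [v for v in w.cis_candidates[gid] if v in prioritized]
                model = train_gene_model(
                    gid, w.ref, w.expression[gid], None, w.trans_groups[gid], cis,
                    w.model_config, precomputed_trans=w.trans_selected[gid],
                )
                if model is not None:
                    models.append(model)
            results = associate_genes(models, gwas, w.panel)
            pooled_pvalues.extend(r.pvalue for r in results)
            rejected.append(any(r.significant for r in results))
        except Exception:  # a failed replicate is excluded, with a count
            logger.exception("null replicate %d failed; excluded", rep)
            n_failed += 1
    n_ok = len(rejected)
    fwe = float(np.mean(rejected)) if n_ok else float("nan")
    return {
        "family_wise_error": fwe,
        "se": float(np.sqrt(max(fwe * (1 - fwe), 1e-12) / n_ok)) if n_ok else float("nan"),
        "replicates": n_ok,
        "failed_replicates": n_failed,
        "pooled_pvalues": np.asarray(pooled_pvalues),
        "n_genes": len(gene_ids),
    }


# ---------------------------------------------------------------------------
# power experiment
# ---------------------------------------------------------------------------


@dataclass
class PowerWorld:
    """Fixed genotypes/layout for one grid cell."""

    config: SimulationConfig
    layout: pd.DataFrame
    ref: GenotypeMatrix
    gwas_genotypes: GenotypeMatrix
    cis_ids: list[str]
    region_ids: dict[str, list[str]]   # true trans regions
    decoy_ids: dict[str, list[str]]    # random-group control regions
    panel: ReferencePanel


def build_power_world(config: SimulationConfig, seed: int = 0) -> PowerWorld:
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    cfg = config
    n_cis_total = 2 * cfg.n_cis_candidates  # the full +-1 Mb cis set
    blocks = [("chr1", 4_200_000, n_cis_total)]
    for t in range(cfg.n_trans_regions):
        blocks.append((f"chr{t + 2}", 2_000_000, cfg.variants_per_region))
    for t in range(cfg.n_trans_regions):
        blocks.append((f"chr{t + 2}", 8_000_000, cfg.variants_per_region))  # decoys
    layout = make_variant_layout(blocks, seed=seeds[0])
    ref = simulate_genotypes(cfg.n_ref, layout, ld_rho=cfg.ld_rho, seed=seeds[1])
    gwas_geno = simulate_genotypes(cfg.n_gwas, layout, ld_rho=cfg.ld_rho, seed=seeds[2])
    ids = layout["variant_id"].tolist()
    cis_ids = ids[:n_cis_total]
    region_ids, decoy_ids = {}, {}
    off = n_cis_total
    for t in range(cfg.n_trans_regions):
        region_ids[f"TF{t}"] = ids[off + t * cfg.variants_per_region:
                                   off + (t + 1) * cfg.variants_per_region]
    off += cfg.n_trans_regions * cfg.variants_per_region
    for t in range(cfg.n_trans_regions):
        decoy_ids[f"R{t}"] = ids[off + t * cfg.variants_per_region:
                                 off + (t + 1) * cfg.variants_per_region]
    return PowerWorld(cfg, layout, ref, gwas_geno, cis_ids, region_ids, decoy_ids,
                      ReferencePanel(ref))


def _power_replicate(w: PowerWorld, cell: dict, methods: tuple[str, ...],
                     mcfg: ModelConfig, rng: np.random.Generator) -> dict[str, bool]:
    cfg = w.config
    maf = w.layout.set_index("variant_id")["maf"]
    candidates = sorted(rng.choice(w.cis_ids, size=cfg.n_cis_candidates, replace=False))
    eligible = [v for v in candidates if maf[v] > cfg.min_causal_maf]
    causal_cis = list(rng.choice(eligible, size=cfg.n_causal_cis, replace=False))
    causal_tfs = list(rng.choice(sorted(w.region_ids), size=cfg.n_causal_trans_regions,
                                 replace=False))
    truth = TruthRecord(
        gene_id="gene0",
        cis_variants=causal_cis,
        trans_groups={
            tf: list(rng.choice(w.region_ids[tf], size=cfg.n_causal_per_trans_region,
                                replace=False))
            for tf in causal_tfs
        },
    )
    expr_ref, truth = simulate_expression(
        w.ref, truth, cell["h2_cis"], cell["h2_trans"], seed=int(rng.integers(2**31))
    )
    expr_gwas, _ = simulate_expression(
        w.gwas_genotypes, replace(truth), cell["h2_cis"], cell["h2_trans"],
        seed=int(rng.integers(2**31)),
        effects=(truth.cis_effects, truth.trans_effects),
    )
    pheno = simulate_phenotype(
        w.gwas_genotypes, expr_gwas, cell["scenario"], cell["h2_trait"],
        seed=int(rng.integers(2**31)), truth=truth,
    )
    gwas = compute_gwas_summary(w.gwas_genotypes, pheno, model="linear")

    true_groups = [TransGroup(tf, w.region_ids[tf]) for tf in sorted(w.region_ids)]
    decoy_groups = [TransGroup(r, w.decoy_ids[r]) for r in sorted(w.decoy_ids)]
    method_inputs = {
        "transtf": (true_groups, candidates),
        "transtf_random": (decoy_groups, candidates),
        "cis_all": ([], w.cis_ids),
        "cis_random200": ([], candidates),
    }
    out = {}
    for method in methods:
        groups, cis = method_inputs[method]
        model = train_gene_model("gene0", w.ref, expr_ref, None, groups, cis, mcfg)
        if model is None:
            out[method] = False
            continue
        results = associate_genes([model], gwas, w.panel)
        out[method] = bool(results and results[0].significant)
    return out


def run_power_experiment(
    grid: ExperimentGrid,
    base_config: SimulationConfig | None = None,
    model_config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Detection power per grid cell and method, with binomial SEs."""
    cfg = base_config or SimulationConfig()
    mcfg = model_config or ModelConfig(lambda_grid_size=25, gl_folds=3, folds=10,
                                       n_alphas_enet=25, seed=grid.seed)
    rows = []
    cell_idx = 0
    for h2c in grid.h2_expr_cis:
        for h2t in grid.h2_expr_trans:
            for h2y in grid.h2_trait:
                cell_seed = int(
                    np.random.SeedSequence([grid.seed, cell_idx]).generate_state(1)[0]
                    % (2**31)
                )
                w = build_power_world(cfg, seed=cell_seed)
                rng = np.random.default_rng(cell_seed + 1)
                cell = {"scenario": grid.scenario, "h2_cis": h2c, "h2_trans": h2t,
                        "h2_trait": h2y}
                hits = {m: 0 for m in grid.methods}
                for _ in range(grid.replicates):
                    res = _power_replicate(w, cell, grid.methods, mcfg, rng)
                    for m in grid.methods:
                        hits[m] += int(res[m])
                for m in grid.methods:
                    p = hits[m] / grid.replicates
                    rows.append(
                        {
                            "scenario": grid.scenario,
                            "h2_cis": h2c,
                            "h2_trans": h2t,
                            "h2_trait": h2y,
                            "n_causal": cfg.n_causal_cis
                            + cfg.n_causal_trans_regions * cfg.n_causal_per_trans_region,
                            "method": m,
                            "estimate": p,
                            "se": float(np.sqrt(p * (1 - p) / grid.replicates)),
                            "reps": grid.replicates,
                        }
                    )
                cell_idx += 1
    return pd.DataFrame(rows)


def compare_methods(report: pd.DataFrame) -> pd.DataFrame:
    """Rank methods by power within each grid cell; ties share a rank."""
    if report.empty:
        raise ValueError("empty benchmark report")
    out = []
    keys = ["scenario", "h2_cis", "h2_trans", "h2_trait", "n_causal"]
    for cell, grp in report.groupby(keys):
        grp = grp[grp["reps"] > 0]
        if grp.empty:
            logger.warning("cell %s has no replicates; omitted", cell)
            continue
        grp = grp.sort_values(["estimate", "method"], ascending=[False, True]).copy()
        grp["rank"] = grp["estimate"].rank(method="min", ascending=False).astype(int)
        grp["tied"] = grp.duplicated("estimate", keep=False)
        out.append(grp)
    return pd.concat(out, ignore_index=True)
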