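"""Expression prediction model training.

The two-stage trainer first screens TF-labelled trans-variant groups with a
group lasso (between-group sparsity, within-group retention), keeping the
selected groups only when the grouped model itself predicts expression
(cross-validated R^2 at or above a floor).  The surviving trans-variants
are then pooled with the prioritized cis-variants and refit with a
standard elastic net; the final model is retained for association testing
only when its 10-fold cross-validated R^2 exceeds 0.01.

Covariates (genotyping PCs, age, PEER factors, ...) are nuisance terms:
expression is residualized on them before any penalized fitting.
Genotype columns are standardized internally; stored weights are mapped
back to the per-allele (dosage) scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .genomics_io import GenotypeMatrix
from .grouplasso import group_lambda_max, group_lasso_path, group_lasso_solve
from .regulatory_prioritization import TransGroup

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Training knobs (defaults follow common TWAS practice)."""

    alpha_mix: float = 0.5          # elastic-net l1 ratio
    folds: int = 10                 # CV folds for the elastic net / final R^2
    gl_folds: int = 5               # CV folds for the group-lasso lambda choice
    r2_floor: float = 0.01          # retention rule for models and group selection
    group_weighting: bool = True    # multiply each group norm by sqrt(group size)
    lambda_grid_size: int = 100
    lambda_min_ratio: float = 1e-3
    n_alphas_enet: int = 50
    seed: int = 0


@dataclass
class GroupLassoFit:
    lambda_grid: np.ndarray
    chosen_lambda: float
    coefficients: dict[str, np.ndarray]
    selected_groups: list[str]
    cv_r2: float
    objective: float
    duality_gap: float
    group_variants: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class ExpressionModel:
    """Per-gene variant weights on the per-allele scale, plus provenance."""

    gene_id: str
    weights: pd.DataFrame  # variant_id, weight, ref_allele, eff_allele, origin, source_tf
    cv_r2: float
    metadata: dict = field(default_factory=dict)

    @property
    def variant_ids(self) -> list[str]:
        return self.weights["variant_id"].tolist()

    def nonzero(self) -> pd.DataFrame:
        return self.weights[self.weights["weight"] != 0.0]


def residualize_covariates(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Remove the least-squares projection of y onto [1, covariates].

    Collinear covariate columns are handled by the pseudoinverse (dropped
    from the projection with a warning); the residual has mean zero and is
    orthogonal to every covariate.
    """
    y = np.asarray(y, float)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return y - y.mean()
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != len(y):
        raise ValueError("covariate rows must align with samples")
    design = np.column_stack([np.ones(len(y)), C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "covariate matrix rank-deficient (%d < %d); collinear columns dropped",
            rank, design.shape[1],
        )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def cross_validated_r2(trainer, X: np.ndarray, y: np.ndarray, folds: int = 10,
                       seed: int = 0) -> float:
    """Squared Pearson correlation of pooled out-of-fold predictions.

    Returns 0 when the correlation is negative or the pooled predictions
    are constant.
    """
    n = len(y)
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds sample count ({n})")
    preds = np.empty(n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(X):
        est = clone(trainer)
        est.fit(X[train_idx], y[train_idx])
        preds[test_idx] = est.predict(X[test_idx])
    if np.std(preds) == 0 or np.std(y) == 0:
        return 0.0
    r = float(np.corrcoef(preds, y)[0, 1])
    return r * r if r > 0 else 0.0


def fit_group_lasso(
    X: np.ndarray,
    y: np.ndarray,
    groups: list[tuple[str, list[int]]],
    config: ModelConfig | None = None,
    lambda_grid: np.ndarray | None = None,
) -> GroupLassoFit:
    """Fit the grouped trans-variant selection model with CV lambda choice.

    ``groups`` maps group names (TFs) to column index lists of ``X``.
    Columns are standardized internally; the CV criterion is out-of-fold
    MSE, with ties broken toward the sparser (larger) lambda, and the
    reported ``cv_r2`` is the pooled out-of-fold R^2 at the chosen lambda.
    """
    cfg = config or ModelConfig()
    y = np.asarray(y, float)
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    n = len(y)
    if n < cfg.gl_folds:
        raise ValueError(f"n ({n}) smaller than cv folds ({cfg.gl_folds})")
    Xs, _, sd = _standardize(np.asarray(X, float))
    yc = y - y.mean()
    gidx = [np.asarray(ix, int) for _, ix in groups]
    wts = np.array([np.sqrt(len(ix)) if cfg.group_weighting else 1.0 for ix in gidx])

    if lambda_grid is None:
        lam_max = group_lambda_max(Xs, yc, gidx, wts)
        if lam_max <= 0:
            lambda_grid = np.array([0.0])
        else:
            lambda_grid = np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio,
                                       cfg.lambda_grid_size)
    lambda_grid = np.asarray(lambda_grid, float)

    kf = KFold(n_splits=cfg.gl_folds, shuffle=True, random_state=cfg.seed)
    oof = np.empty((n, len(lambda_grid)))
    for train_idx, test_idx in kf.split(Xs):
        # CV only ranks lambdas; a coarse duality-gap target suffices here
        betas = group_lasso_path(Xs[train_idx], yc[train_idx], gidx, lambda_grid, wts,
                                 tol=1e-4)
        oof[test_idx] = Xs[test_idx] @ betas.T
    err = (oof - yc[:, None]) ** 2
    mse = err.mean(axis=0)
    # one-SE rule: sparsest lambda whose CV error is within one standard
    # error of the minimum (guards against over-selection of noise groups)
    i_min = int(np.argmin(mse))
    se_min = float(err[:, i_min].std(ddof=1) / np.sqrt(n))
    within = np.where(mse <= mse[i_min] + se_min)[0]
    best = int(within[np.argmax(lambda_grid[within])])
    chosen = float(lambda_grid[best])

    beta, obj, gap = group_lasso_solve(Xs, yc, gidx, chosen, weights=wts, tol=1e-8)
    coefs = {name: beta[ix] for (name, _), ix in zip(groups, gidx)}
    selected = [name for name, b in coefs.items() if np.linalg.norm(b) > 0]

    pred = oof[:, best]
    if np.std(pred) == 0:
        cv_r2 = 0.0
    else:
        r = float(np.corrcoef(pred, yc)[0, 1])
        cv_r2 = r * r if r > 0 else 0.0
    return GroupLassoFit(
        lambda_grid=lambda_grid,
        chosen_lambda=chosen,
        coefficients=coefs,
        selected_groups=selected,
        cv_r2=cv_r2,
        objective=obj,
        duality_gap=gap,
    )


def select_trans_variants(fit: GroupLassoFit, r2_floor: float = 0.01) -> list[str]:
    """Union of variants in selected groups, empty if the fit predicts poorly."""
    if fit.cv_r2 < r2_floor:
        return []
    out: list[str] = []
    for name in fit.selected_groups:
        out.extend(fit.group_variants.get(name, []))
    return out


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    variant_meta: pd.DataFrame,
    config: ModelConfig | None = None,
    gene_id: str = "",
) -> ExpressionModel | None:
    """Elastic-net weight training over combined cis + trans dosages.

    ``variant_meta`` carries variant_id, ref_allele, alt_allele, origin and
    source_tf per column of ``X``.  The penalty is chosen by internal CV at
    the fixed mixing ``alpha_mix``; weights are mapped back to the
    per-allele scale and the model's CV R^2 comes from a fresh K-fold pass
    with the chosen penalty.
    """
    cfg = config or ModelConfig()
    X = np.asarray(X, float)
    keep = X.std(axis=0) > 0
    if keep.sum() == 0:
        logger.warning("gene %s: no polymorphic predictors; no model", gene_id)
        return None
    X = X[:, keep]
    meta = variant_meta.reset_index(drop=True)[keep].reset_index(drop=True)
    y = np.asarray(y, float)
    Xs, _, sd = _standardize(X)
    folds = min(cfg.folds, len(y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    cv_est = ElasticNetCV(
        l1_ratio=cfg.alpha_mix, alphas=cfg.n_alphas_enet, cv=kf, max_iter=5000,
    )
    with np.errstate(all="ignore"):
        cv_est.fit(Xs, y)
    alpha = float(cv_est.alpha_)
    final = ElasticNet(alpha=alpha, l1_ratio=cfg.alpha_mix, max_iter=5000)
    final.fit(Xs, y)
    cv_r2 = cross_validated_r2(
        ElasticNet(alpha=alpha, l1_ratio=cfg.alpha_mix, max_iter=5000),
        Xs, y, folds=folds, seed=cfg.seed,
    )
    weights = final.coef_ / sd  # back to per-allele dosage scale
    wdf = pd.DataFrame(
        {
            "variant_id": meta["variant_id"],
            "weight": weights,
            "ref_allele": meta["ref_allele"],
            "eff_allele": meta["alt_allele"],
            "origin": meta["origin"],
            "source_tf": meta.get("source_tf", pd.Series([""] * len(meta))),
        }
    )
    for coord in ("chrom", "pos"):
        if coord in meta.columns:
            wdf[coord] = meta[coord]
    return ExpressionModel(
        gene_id=gene_id,
        weights=wdf,
        cv_r2=cv_r2,
        metadata={
            "n_samples": len(y),
            "folds": folds,
            "seed": cfg.seed,
            "alpha_mix": cfg.alpha_mix,
            "lambda": alpha,
            "standardized_fit": True,
        },
    )


def train_gene_model(
    gene_id: str,
    genotypes: GenotypeMatrix,
    expression: np.ndarray,
    covariates: np.ndarray | None,
    trans_groups: list[TransGroup],
    cis_variants: list[str],
    config: ModelConfig | None = None,
    precomputed_trans: list[str] | None = None,
) -> ExpressionModel | None:
    """Full per-gene trainer: residualize -> group lasso -> elastic net.

    Returns the trained model only when its CV R^2 clears the retention
    floor; genes with no trans groups (or no selected group) reduce exactly
    to cis-only elastic-net training.  ``precomputed_trans`` short-circuits
    the group-lasso stage with an already-selected trans-variant list
    (used when the stage's inputs are known to be unchanged).
    """
    cfg = config or ModelConfig()
    y = residualize_covariates(expression, covariates)

    if precomputed_trans is not None:
        selected_trans = list(precomputed_trans)
        source_tf = {}
        for grp in trans_groups:
            for v in grp.variants:
                source_tf[v] = grp.tf
    else:
        selected_trans, source_tf = select_trans_for_gene(genotypes, y, trans_groups, cfg)

    cis = [v for v in cis_variants if v in genotypes._index]
    predictors = cis + [v for v in selected_trans if v not in set(cis)]
    if not predictors:
        logger.warning("gene %s: no predictors; no model", gene_id)
        return None
    X = genotypes.columns(predictors)
    meta = genotypes.subset(predictors).metadata_frame()
    meta["origin"] = ["cis" if v in set(cis) else "trans" for v in predictors]
    meta["source_tf"] = [
        "" if o == "cis" else source_tf.get(v, "") for v, o in zip(predictors, meta["origin"])
    ]
    model = fit_elastic_net(X, y, meta, cfg, gene_id=gene_id)
    if model is None:
        return None
    model.metadata["n_trans_selected"] = len(selected_trans)
    model.metadata["n_cis"] = len(cis)
    if model.cv_r2 <= cfg.r2_floor:
        logger.info("gene %s: cv_r2=%.4f below retention floor; model dropped",
                    gene_id, model.cv_r2)
        return None
    return model


def select_trans_for_gene(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    trans_groups: list[TransGroup],
    config: ModelConfig | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Group-lasso screening of a gene's trans groups; returns (variants, tf map)."""
    cfg = config or ModelConfig()
    source_tf: dict[str, str] = {}
    for grp in trans_groups:
        for v in grp.variants:
            source_tf[v] = grp.tf
    usable = [g for g in trans_groups if g.variants]
    if not usable:
        return [], source_tf
    cols: list[str] = []
    groups: list[tuple[str, list[int]]] = []
    for grp in usable:
        ix = list(range(len(cols), len(cols) + len(grp.variants)))
        cols.extend(grp.variants)
        groups.append((grp.tf, ix))
    X = genotypes.columns(cols)
    fit = fit_group_lasso(X, y, groups, cfg)
    fit.group_variants = {grp.tf: grp.variants for grp in usable}
    return select_trans_variants(fit, cfg.r2_floor), source_tf
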