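"""Summary-statistics association of predicted expression with a trait.

The gene-level statistic is the S-PrediXcan-style weighted sum

    Z_g = sum_{l in model g} w_lg * (sigma_l / sigma_g) * beta_l / se(beta_l)

where ``w_lg`` are the per-allele model weights, ``sigma_l`` the reference
panel dosage SD of variant ``l``, and ``sigma_g = sqrt(w' Gamma w)`` the SD
of the predicted expression under the panel's variant covariance ``Gamma``.
Alleles are harmonized on (chrom, pos, allele pair); a swapped effect
allele flips the GWAS beta sign.  Significance is Bonferroni-corrected
over the genes with retained models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomics_io import GenotypeMatrix, SummaryStatsTable
from .expression_models import ExpressionModel

logger = logging.getLogger(__name__)

RIDGE = 1e-8


class ReferencePanel:
    """Dosage SDs and covariance blocks from a reference genotype cohort."""

    def __init__(self, genotypes: GenotypeMatrix):
        self.genotypes = genotypes
        self._sd = pd.Series(genotypes.dosages.std(axis=0), index=genotypes.variant_ids)

    def sd(self, variant_ids: list[str]) -> np.ndarray:
        return self._sd.loc[variant_ids].to_numpy(float)

    def covariance(self, variant_ids: list[str]) -> np.ndarray:
        X = self.genotypes.columns(variant_ids)
        cov = np.cov(X, rowvar=False, bias=True)  # ddof=0, consistent with sd()
        cov = np.atleast_2d(cov)
        return cov + RIDGE * np.eye(len(variant_ids))


@dataclass
class TwasResult:
    gene_id: str
    zscore: float
    pvalue: float
    n_variants_used: int
    n_variants_missing_in_gwas: int
    lead_variant: str | None = None
    lead_tf: str | None = None
    significant: bool = False


def harmonize_alleles(model: ExpressionModel, gwas: SummaryStatsTable,
                      variant_coords: pd.DataFrame | None = None) -> pd.DataFrame:
    """Align model weights with GWAS effects on (chrom, pos, allele pair).

    Model variants carry their coordinates either in the weight table
    (chrom/pos columns) or in a supplementary ``variant_coords`` frame.
    Returns one row per matched variant with the GWAS beta oriented to the
    model's effect allele; unmatched variants are dropped and counted in
    the frame's ``attrs['n_missing']``.
    """
    w = model.weights
    if "chrom" not in w.columns or "pos" not in w.columns:
        if variant_coords is None:
            raise ValueError("model weights lack coordinates; pass variant_coords")
        w = w.merge(variant_coords[["variant_id", "chrom", "pos"]], on="variant_id")
    coord_index = gwas.coordinate_index()
    rows = []
    n_missing = 0
    for r in w.itertuples():
        key = (str(r.chrom), int(r.pos), frozenset((r.ref_allele, r.eff_allele)))
        gwas_id = coord_index.get(key)
        if gwas_id is None:
            n_missing += 1
            continue
        g = gwas.table.loc[gwas_id]
        if g["effect_allele"] == r.eff_allele and g["other_allele"] == r.ref_allele:
            sign = 1.0
        elif g["effect_allele"] == r.ref_allele and g["other_allele"] == r.eff_allele:
            sign = -1.0
        else:  # same position but different allele pair
            n_missing += 1
            continue
        rows.append(
            (r.variant_id, float(r.weight), sign * float(g["beta"]), float(g["se"]),
             getattr(r, "origin", "cis"), getattr(r, "source_tf", "") or "")
        )
    if not rows:
        raise ValueError(f"gene {model.gene_id}: no model variant matched the GWAS")
    out = pd.DataFrame(rows, columns=["variant_id", "weight", "beta", "se", "origin", "source_tf"])
    out["z"] = out["beta"] / out["se"]
    out.attrs["n_missing"] = n_missing
    return out


def spredixcan_z(
    model: ExpressionModel,
    gwas: SummaryStatsTable,
    panel: ReferencePanel,
    variant_coords: pd.DataFrame | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Gene-level association Z-score and p-value from summary statistics."""
    aligned = harmonize_alleles(model, gwas, variant_coords)
    nz = aligned[aligned["weight"] != 0.0]
    if nz.empty:
        raise ValueError(f"gene {model.gene_id}: all matched weights are zero")
    ids = nz["variant_id"].tolist()
    w = nz["weight"].to_numpy(float)
    sigma_l = panel.sd(ids)
    gamma = panel.covariance(ids)
    sigma_g = float(np.sqrt(w @ gamma @ w))
    if sigma_g <= 0:
        raise ValueError(f"gene {model.gene_id}: degenerate predicted-expression variance")
    z = float(np.sum(w * (sigma_l / sigma_g) * nz["z"].to_numpy(float)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p, aligned


def bonferroni_flag(results: list[TwasResult], alpha: float = 0.05) -> list[TwasResult]:
    """Set the significance flag at the Bonferroni-corrected threshold."""
    n = len(results)
    if n == 0:
        return results
    thresh = alpha / n
    for r in results:
        r.significant = r.pvalue < thresh
    return results


def lead_trans_variant(aligned: pd.DataFrame) -> tuple[str | None, str | None]:
    """Lead variant = largest GWAS |z| among nonzero-weight model variants.

    Returns (variant_id, source_tf) when the lead is a trans variant, else
    (variant_id, None); ties break to the lexicographically smallest id.
    """
    nz = aligned[aligned["weight"] != 0.0].copy()
    if nz.empty:
        return None, None
    nz["absz"] = nz["z"].abs()
    nz = nz.sort_values(["absz", "variant_id"], ascending=[False, True])
    lead = nz.iloc[0]
    if lead["origin"] == "trans" and lead["source_tf"]:
        return str(lead["variant_id"]), str(lead["source_tf"])
    return str(lead["variant_id"]), None


def associate_genes(
    models: list[ExpressionModel],
    gwas: SummaryStatsTable,
    panel: ReferencePanel,
    alpha: float = 0.05,
    variant_coords: pd.DataFrame | None = None,
) -> list[TwasResult]:
    """Run the association test over all retained models, with Bonferroni."""
    results = []
    for m in models:
        try:
            z, p, aligned = spredixcan_z(m, gwas, panel, variant_coords)
        except ValueError as exc:
            logger.warning("%s", exc)
            continue
        lead_var, lead_tf = lead_trans_variant(aligned)
        results.append(
            TwasResult(
                gene_id=m.gene_id,
                zscore=z,
                pvalue=p,
                n_variants_used=int((aligned["weight"] != 0).sum()),
                n_variants_missing_in_gwas=int(aligned.attrs["n_missing"]),
                lead_variant=lead_var,
                lead_tf=lead_tf,
            )
        )
    return bonferroni_flag(results, alpha)


def tf_gene_network(results: list[TwasResult]) -> pd.DataFrame:
    """TF -> gene edges from significant genes with a trans-located lead."""
    edges = sorted(
        {(r.lead_tf, r.gene_id) for r in results if r.significant and r.lead_tf}
    )
    return pd.DataFrame(edges, columns=["tf", "gene"])


def results_frame(results: list[TwasResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "zscore": r.zscore,
                "pvalue": r.pvalue,
                "n_snps_used": r.n_variants_used,
                "n_snps_missing": r.n_variants_missing_in_gwas,
                "lead_variant": r.lead_variant or "",
                "lead_tf": r.lead_tf or "",
                "significant": r.significant,
            }
            for r in results
        ]
    )
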