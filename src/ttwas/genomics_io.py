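"""Readers and writers for the standard formats the pipeline touches.

Conventions enforced throughout:

* variant positions are 1-based (VCF convention);
* interval files (BED) are 0-based half-open, so a variant at position ``p``
  lies inside ``[start, end)`` iff ``start < p <= end``;
* dosages count copies of the *alt* allele and live in ``[0, 2]``;
* variant identity for cross-file matching is ``(chrom, pos, {allele pair})``
  — id strings are carried but never trusted for harmonization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DOSAGE_META_COLS = ["variant_id", "chrom", "pos", "ref_allele", "alt_allele"]


class FormatError(ValueError):
    """A file violated the declared format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with 1-based position and alt-allele frequency."""

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref and alt alleles are identical")
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"{self.variant_id}: maf {self.maf} outside [0, 0.5]")

    @property
    def key(self) -> tuple[str, int, frozenset[str]]:
        """Coordinate+allele identity used for harmonization."""
        return (self.chrom, self.pos, frozenset((self.ref_allele, self.alt_allele)))


class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with variant metadata."""

    def __init__(self, samples: list[str], variants: list[VariantRecord], dosages: np.ndarray):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(samples), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} != ({len(samples)}, {len(variants)})"
            )
        ids = [v.variant_id for v in variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate variant ids: {', '.join(dupes)}")
        if dosages.size and (np.nanmin(dosages) < -1e-9 or np.nanmax(dosages) > 2 + 1e-9):
            raise ValueError("dosages outside [0, 2]")
        self.samples = list(samples)
        self.variants = list(variants)
        self.dosages = dosages
        self._index = {v.variant_id: j for j, v in enumerate(variants)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self._index[variant_id]]

    def columns(self, variant_ids: list[str]) -> np.ndarray:
        idx = [self._index[v] for v in variant_ids]
        return self.dosages[:, idx]

    def subset(self, variant_ids: list[str]) -> "GenotypeMatrix":
        idx = [self._index[v] for v in variant_ids]
        return GenotypeMatrix(
            self.samples, [self.variants[j] for j in idx], self.dosages[:, idx]
        )

    def empirical_maf(self) -> np.ndarray:
        """Minor-allele frequency recomputed from the dosage columns."""
        af = self.dosages.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref_allele": [v.ref_allele for v in self.variants],
                "alt_allele": [v.alt_allele for v in self.variants],
                "maf": [v.maf for v in self.variants],
            }
        )


@dataclass
class IntervalSet:
    """0-based half-open genomic intervals with optional labels."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, _ in self.intervals:
            if start < 0:
                raise ValueError(f"{chrom}:{start}-{end}: start < 0")
            if start >= end:
                raise ValueError(f"{chrom}:{start}-{end}: start >= end")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def contains_position(self, chrom: str, pos: int) -> bool:
        """Whether 1-based position ``pos`` lies in any interval (s < pos <= e)."""
        return any(c == chrom and s < pos <= e for c, s, e, _ in self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[str, int, int, str]]:
        """Intervals overlapping the 0-based half-open query ``[start, end)``."""
        return [
            iv for iv in self.intervals if iv[0] == chrom and iv[1] < end and iv[2] > start
        ]

    @staticmethod
    def union(sets: list["IntervalSet"]) -> "IntervalSet":
        merged: list[tuple[str, int, int, str]] = []
        for s in sets:
            merged.extend(s.intervals)
        return IntervalSet(merged)


class SummaryStatsTable:
    """Per-variant GWAS effect sizes keyed by variant id.

    Wraps a DataFrame with columns chrom, pos, effect_allele, other_allele,
    beta, se, pvalue (index: variant_id).  The p-value is the two-sided
    normal tail of beta/se, filled in when absent.
    """

    REQUIRED = ["variant_id", "effect_allele", "other_allele", "beta", "se"]

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        if df.index.name != "variant_id":
            if "variant_id" not in df.columns:
                raise FormatError("missing required column: variant_id")
            df = df.set_index("variant_id")
        bad_se = df.index[~(df["se"] > 0)]
        if len(bad_se):
            raise FormatError(f"non-positive se for variant(s): {', '.join(map(str, bad_se[:5]))}")
        z = df["beta"].to_numpy(float) / df["se"].to_numpy(float)
        normal_p = 2.0 * stats.norm.sf(np.abs(z))
        if "pvalue" not in df.columns or df["pvalue"].isna().all():
            df["pvalue"] = normal_p
        else:
            given = df["pvalue"].to_numpy(float)
            ok = np.isnan(given) | (np.abs(given - normal_p) <= 1e-6)
            if not ok.all():
                bad = df.index[~ok][:5]
                raise FormatError(
                    "pvalue inconsistent with beta/se under a two-sided normal test "
                    f"for: {', '.join(map(str, bad))}"
                )
            df.loc[df["pvalue"].isna(), "pvalue"] = normal_p[df["pvalue"].isna().to_numpy()]
        df["zscore"] = z
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.table.index

    def chi2(self) -> pd.Series:
        """Per-variant chi-squared statistic (z^2 of beta/se)."""
        return self.table["zscore"] ** 2

    def coordinate_index(self) -> dict[tuple[str, int, frozenset[str]], str]:
        """Map (chrom, pos, allele-pair) -> variant_id for harmonization.

        Built once per table and cached; the table is treated as immutable
        after construction.
        """
        cached = getattr(self, "_coord_index", None)
        if cached is None:
            t = self.table
            cached = {
                (c, int(p), frozenset((ea, oa))): vid
                for vid, c, p, ea, oa in zip(
                    t.index,
                    t["chrom"].to_numpy(),
                    t["pos"].to_numpy(),
                    t["effect_allele"].to_numpy(),
                    t["other_allele"].to_numpy(),
                )
            }
            self._coord_index = cached
        return cached


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str = "vcf", multiallelic: str = "reject") -> GenotypeMatrix:
    """Read a genotype dosage matrix from a VCF or a dosage TSV.

    Parameters
    ----------
    path : str
        Input file.  VCF requires GT or DS fields; the dosage TSV dialect
        has columns variant_id, chrom, pos, ref_allele, alt_allele followed
        by one column per sample ('.' = missing, mean-imputed at load).
    format : {"vcf", "dosage_tsv"}
    multiallelic : {"reject", "split"}
        How to treat VCF records with more than one ALT allele.
    """
    if format == "vcf":
        return _read_vcf(str(path), multiallelic)
    if format == "dosage_tsv":
        return _read_dosage_tsv(str(path))
    raise ValueError(f"unknown genotype format: {format!r}")


def _record_variants(variant, multiallelic: str):
    if len(variant.ALT) != 1:
        if multiallelic == "reject":
            raise FormatError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS} "
                f"({variant.REF}->{','.join(variant.ALT)}); set multiallelic='split' to keep"
            )
        return list(range(len(variant.ALT)))
    return [0]


def _read_vcf(path: str, multiallelic: str) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input") from exc

    try:
        vcf = VCF(path)
    except Exception as exc:
        raise FormatError(f"malformed VCF header in {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_imputed = 0
    for rec in vcf:
        for alt_idx in _record_variants(rec, multiallelic):
            alt = rec.ALT[alt_idx]
            try:
                ds = rec.format("DS")
            except KeyError:
                ds = None
            if ds is not None and len(rec.ALT) == 1:
                col = np.asarray(ds, dtype=float).reshape(len(samples), -1)[:, 0]
                col = np.where((col < 0) | ~np.isfinite(col), np.nan, col)
            else:
                gts = rec.genotype.array()  # (n, ploidy+1); last col is phasing
                alleles = gts[:, :-1]
                missing = (alleles < 0).any(axis=1)
                col = (alleles == alt_idx + 1).sum(axis=1).astype(float)
                col[missing] = np.nan
            if np.isnan(col).any():
                n_imputed += int(np.isnan(col).sum())
                col = np.where(np.isnan(col), np.nanmean(col), col)
            af = col.mean() / 2.0
            vid = rec.ID or f"{rec.CHROM}_{rec.POS}_{rec.REF}_{alt}"
            if len(rec.ALT) > 1:  # split records need distinct ids
                vid = f"{vid}_{alt}"
            variants.append(
                VariantRecord(vid, rec.CHROM, rec.POS, rec.REF, alt, min(af, 1 - af))
            )
            columns.append(col)
    if n_imputed:
        logger.info("mean-imputed %d missing genotype calls in %s", n_imputed, path)
    dosages = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, variants, dosages)


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in DOSAGE_META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"dosage TSV missing column(s): {', '.join(missing)}")
    samples = [c for c in df.columns if c not in DOSAGE_META_COLS]
    raw = df[samples].mask(df[samples] == ".").apply(pd.to_numeric).to_numpy(float).T
    n_missing = int(np.isnan(raw).sum())
    if n_missing:
        logger.info("mean-imputed %d missing dosages in %s", n_missing, path)
        col_means = np.nanmean(raw, axis=0)
        raw = np.where(np.isnan(raw), col_means[None, :], raw)
    variants = [
        VariantRecord(
            str(r.variant_id), str(r.chrom), int(r.pos), str(r.ref_allele),
            str(r.alt_allele), _maf_from(raw[:, j]),
        )
        for j, r in enumerate(df.itertuples())
    ]
    return GenotypeMatrix(samples, variants, raw)


def _maf_from(col: np.ndarray) -> float:
    af = float(np.mean(col)) / 2.0
    return min(af, 1.0 - af)


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write the dosage TSV dialect read back by ``read_genotypes``."""
    meta = gm.metadata_frame().drop(columns=["maf"])
    dose = pd.DataFrame(gm.dosages.T, columns=gm.samples)
    pd.concat([meta.reset_index(drop=True), dose], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_intervals(path) -> IntervalSet:
    """Read a BED3/BED4 file into an IntervalSet (0-based half-open)."""
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start")
            label = parts[3] if len(parts) > 3 else ""
            intervals.append((chrom, start, end, label))
    return IntervalSet(intervals)


def write_intervals(ivs: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in ivs:
            cols = [chrom, str(start), str(end)] + ([label] if label else [])
            fh.write("\t".join(cols) + "\n")


def read_summary_stats(path) -> SummaryStatsTable:
    """Read a GWAS summary-statistics TSV.

    Requires columns variant_id, effect_allele, other_allele, beta, se;
    chrom/pos/pvalue are optional (pvalue recomputed from beta/se when
    absent).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SummaryStatsTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"summary stats missing column(s): {', '.join(missing)}")
    return SummaryStatsTable(df)


def write_summary_stats(ss: SummaryStatsTable, path) -> None:
    ss.table.drop(columns=["zscore"]).to_csv(path, sep="\t", float_format="%.17g")


# --- weight database (PredictDB-style weights + extra tables) --------------


def write_model_db(models: list, path_prefix) -> tuple[str, str]:
    """Write expression models as a PredictDB-style TSV pair.

    ``<prefix>.weights.tsv`` holds one row per (gene, variant) with the
    per-allele weight, alleles, origin (cis/trans) and source TF;
    ``<prefix>.extra.tsv`` holds per-gene CV R^2 and variant counts.
    Genes whose weights are all zero are omitted with a warning.
    """
    gene_ids = [m.gene_id for m in models]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene_id in models: {', '.join(dupes)}")
    weight_rows, extra_rows = [], []
    for m in models:
        nz = m.weights[m.weights["weight"] != 0.0]
        if nz.empty:
            logger.warning("gene %s has no nonzero weights; omitted from model db", m.gene_id)
            continue
        for r in nz.itertuples():
            weight_rows.append(
                (m.gene_id, r.variant_id, r.weight, r.ref_allele, r.eff_allele,
                 r.origin, r.source_tf or "")
            )
        extra_rows.append((m.gene_id, m.cv_r2, len(nz)))
    wpath, epath = f"{path_prefix}.weights.tsv", f"{path_prefix}.extra.tsv"
    pd.DataFrame(
        weight_rows,
        columns=["gene_id", "variant_id", "weight", "ref_allele", "eff_allele", "origin", "source_tf"],
    ).to_csv(wpath, sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(extra_rows, columns=["gene_id", "cv_r2", "n_variants"]).to_csv(
        epath, sep="\t", index=False, float_format="%.17g"
    )
    return wpath, epath


def read_model_db(path_prefix, variant_positions: pd.DataFrame | None = None) -> list:
    """Read back a model database written by :func:`write_model_db`."""
    from .expression_models import ExpressionModel

    weights = pd.read_csv(f"{path_prefix}.weights.tsv", sep="\t", keep_default_na=False,
                          na_values=[], dtype={"source_tf": str},
                          float_precision="round_trip")
    weights["weight"] = weights["weight"].astype(float)
    extra = pd.read_csv(f"{path_prefix}.extra.tsv", sep="\t", float_precision="round_trip")
    models = []
    for gene_id, grp in weights.groupby("gene_id", sort=True):
        cv_r2 = float(extra.loc[extra["gene_id"] == gene_id, "cv_r2"].iloc[0])
        w = grp.drop(columns=["gene_id"]).reset_index(drop=True)
        if variant_positions is not None:
            w = w.merge(variant_positions, on="variant_id", how="left")
        models.append(ExpressionModel(gene_id=gene_id, weights=w, cv_r2=cv_r2, metadata={}))
    return models


def summary_stats_pvalue(beta: float, se: float) -> float:
    """Two-sided normal p-value for a single beta/se pair."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(2.0 * stats.norm.sf(abs(beta) / se))
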