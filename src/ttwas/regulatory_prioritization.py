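"""Prioritization of TF-linked trans-variants and TF-occupied cis-variants.

Step I identifies, for each transcription factor, the cis-variants with
evidence of regulating the TF's own expression: the variant must fall in an
open/regulatory region (DHS, enhancer or promoter) and carry at least one
link to the TF — eQTL significance at nominal P < 0.05, location in the TF
promoter (TSS ± 2 kb), an enhancer linked to the TF, or a chromatin
interaction anchored at the TF promoter.  Step II pairs a TF with every
gene whose TSS has a TF ChIP-seq peak within ±20 kb.  A third operation
ranks TF-occupied cis-variants genome-wide by regressing per-variant GWAS
chi-squared statistics on TF binding status.  Finally, trans-variant groups
for a target gene are assembled from the cis-variant sets of its paired
TFs, keeping only variants >1 Mb from the gene body or on another
chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomics_io import IntervalSet, SummaryStatsTable

logger = logging.getLogger(__name__)

PROMOTER_WINDOW = 2_000
TSS_FLANK = 20_000
TRANS_DISTANCE = 1_000_000


@dataclass
class TFCisVariantSet:
    """Cis-variants with evidence of regulating one TF's expression."""

    tf: str
    variants: list[str]
    evidence: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class TFGeneMap:
    """(TF, gene) pairs with the supporting peak and distance to TSS."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    provenance: dict[tuple[str, str], tuple[tuple[str, int, int, str], int]] = field(
        default_factory=dict
    )

    def tfs_for_gene(self, gene_id: str) -> list[str]:
        return sorted(tf for tf, g in self.pairs if g == gene_id)


@dataclass
class TransGroup:
    tf: str
    variants: list[str]


TransGroupMap = dict[str, list[TransGroup]]


def _gene_tss(row) -> int:
    if row.strand == "+":
        return int(row.start)
    if row.strand == "-":
        return int(row.end)
    raise ValueError(f"gene {row.gene_id}: missing or invalid strand {row.strand!r}")


def find_tf_cis_variants(
    tf: str,
    gene_table: pd.DataFrame,
    candidates: pd.DataFrame,
    eqtl_tables: list[pd.DataFrame],
    regions: dict[str, IntervalSet],
    enhancer_links: pd.DataFrame | None = None,
    interactions: pd.DataFrame | None = None,
    eqtl_alpha: float = 0.05,
) -> TFCisVariantSet:
    """Step I: cis-variants regulating a TF's expression.

    ``candidates`` is a variant table (variant_id, chrom, pos) restricted to
    the TF's cis window.  A candidate is kept iff it lies in the union of
    DHS/enhancer/promoter regions AND at least one link to the TF holds:

    * eQTL P < ``eqtl_alpha`` for this TF in any supplied eQTL table;
    * location in the TF promoter (TSS ± 2 kb);
    * location in an enhancer linked to the TF by the link table;
    * location in one anchor of a chromatin interaction whose other anchor
      overlaps the TF promoter.
    """
    rows = gene_table[gene_table["gene_id"] == tf]
    if rows.empty:
        raise KeyError(f"TF {tf!r} absent from the gene/TSS table")
    tf_row = next(rows.itertuples())
    tss = _gene_tss(tf_row)
    tf_chrom = str(tf_row.chrom)

    open_region = IntervalSet.union(
        [regions.get(k, IntervalSet([])) for k in ("dhs", "enhancer", "promoter")]
    )

    eqtl_hits: set[str] = set()
    for tbl in eqtl_tables:
        if tbl is None or tbl.empty:
            continue
        hits = tbl[(tbl["tf"] == tf) & (tbl["pvalue"] < eqtl_alpha)]
        eqtl_hits.update(hits["variant_id"].astype(str))

    link_ivs = IntervalSet([])
    if enhancer_links is not None and not enhancer_links.empty:
        mine = enhancer_links[enhancer_links["tf"] == tf]
        link_ivs = IntervalSet(
            [(str(r.chrom), int(r.start), int(r.end), tf) for r in mine.itertuples()]
        )

    # interaction anchors whose partner anchor overlaps the TF promoter
    ia_anchors = IntervalSet([])
    if interactions is not None and not interactions.empty:
        prom_s, prom_e = tss - PROMOTER_WINDOW - 1, tss + PROMOTER_WINDOW
        anchors = []
        for r in interactions.itertuples():
            a1 = (str(r.chrom1), int(r.start1), int(r.end1), "")
            a2 = (str(r.chrom2), int(r.start2), int(r.end2), "")
            for a, b in ((a1, a2), (a2, a1)):
                if b[0] == tf_chrom and b[1] < prom_e and b[2] > prom_s:
                    anchors.append(a)
        if anchors:
            ia_anchors = IntervalSet(anchors)

    kept: list[str] = []
    evidence: dict[str, set[str]] = {}
    for r in candidates.itertuples():
        vid, chrom, pos = str(r.variant_id), str(r.chrom), int(r.pos)
        if not open_region.contains_position(chrom, pos):
            continue
        tags = set()
        if vid in eqtl_hits:
            tags.add("eqtl")
        if chrom == tf_chrom and tss - PROMOTER_WINDOW <= pos <= tss + PROMOTER_WINDOW:
            tags.add("promoter")
        if link_ivs.contains_position(chrom, pos):
            tags.add("enhancer_link")
        if ia_anchors.contains_position(chrom, pos):
            tags.add("chromatin_interaction")
        if tags:
            kept.append(vid)
            evidence[vid] = tags
    return TFCisVariantSet(tf=tf, variants=kept, evidence=evidence)


def discover_tf_gene_pairs(
    tf_peaks: dict[str, IntervalSet],
    gene_table: pd.DataFrame,
    window_bp: int = TSS_FLANK,
) -> TFGeneMap:
    """Step II: pair a TF with every gene with a peak within ±window of TSS.

    The TSS is strand-aware (transcript start for '+', transcript end for
    '-'); a pair is emitted iff any peak interval overlaps the closed
    genomic window [TSS - window, TSS + window].
    """
    if "strand" not in gene_table.columns:
        raise ValueError("gene table must carry a strand column")
    out = TFGeneMap()
    for g in gene_table.itertuples():
        tss = _gene_tss(g)
        chrom = str(g.chrom)
        # 1-based closed window [tss-w, tss+w] == 0-based half-open (tss-w-1, tss+w]
        for tf, peaks in tf_peaks.items():
            hits = peaks.overlapping(chrom, tss - window_bp - 1, tss + window_bp)
            if hits:
                peak = min(hits, key=lambda iv: (iv[1], iv[2]))
                midpoint = (peak[1] + peak[2]) // 2
                out.pairs.add((tf, g.gene_id))
                out.provenance[(tf, g.gene_id)] = (peak, int(midpoint - tss))
    return out


def prioritize_stfcre_variants(
    gwas_stats: SummaryStatsTable,
    tf_binding: pd.DataFrame,
    target_count: int = 50_000,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Rank TF-occupied cis-variants by GWAS chi-squared enrichment.

    For each TF (column of the boolean membership matrix ``tf_binding``,
    indexed by variant_id) the per-variant chi-squared statistic is
    regressed on binding status; TFs associated at two-sided P < ``alpha``
    contribute their occupied variants.  The union is ordered by TF
    significance, then variant |z| (descending), then variant id, and
    truncated to ``target_count``.  Returns the ranked variant list and the
    per-TF association table.
    """
    chi2 = gwas_stats.chi2()
    common = tf_binding.index.intersection(chi2.index)
    B = tf_binding.loc[common].to_numpy(bool)
    y = chi2.loc[common].to_numpy(float)
    n = len(common)
    tf_rows = []
    for j, tf in enumerate(tf_binding.columns):
        x = B[:, j].astype(float)
        if x.std() == 0:
            tf_rows.append((tf, 0.0, 1.0))
            continue
        slope, _, _, pval, _ = stats.linregress(x, y)
        tf_rows.append((tf, float(slope), float(pval)))
    tf_assoc = pd.DataFrame(tf_rows, columns=["tf", "slope", "pvalue"]).set_index("tf")

    flagged = tf_assoc[tf_assoc["pvalue"] < alpha].sort_values(["pvalue", "slope"])
    if flagged.empty:
        logger.warning("no TF passed the chi-squared enrichment screen at alpha=%g", alpha)
        return [], tf_assoc
    absz = np.sqrt(chi2)
    ranked: list[str] = []
    seen: set[str] = set()
    for tf in flagged.index:
        members = tf_binding.index[tf_binding[tf].to_numpy(bool)]
        members = [v for v in members if v in absz.index and v not in seen]
        members.sort(key=lambda v: (-absz[v], v))
        for v in members:
            seen.add(v)
            ranked.append(v)
            if len(ranked) >= target_count:
                return ranked, tf_assoc
    return ranked, tf_assoc


def build_trans_groups(
    gene_id: str,
    gene_body: tuple[str, int, int],
    tf_gene_map: TFGeneMap,
    tf_cis_sets: dict[str, TFCisVariantSet],
    variant_positions: pd.DataFrame,
    min_distance: int = TRANS_DISTANCE,
) -> list[TransGroup]:
    """Assemble a gene's TF-labelled trans-variant groups.

    One group per TF paired with the gene, holding that TF's cis-variant
    set after removing variants within ``min_distance`` of the gene body on
    the same chromosome; empty groups are dropped and groups are sorted by
    TF name.
    """
    chrom, body_start, body_end = gene_body
    pos = variant_positions.set_index("variant_id") if variant_positions.index.name != "variant_id" else variant_positions
    groups: list[TransGroup] = []
    for tf in tf_gene_map.tfs_for_gene(gene_id):
        cis_set = tf_cis_sets.get(tf)
        if cis_set is None:
            continue
        kept = []
        for vid in cis_set.variants:
            row = pos.loc[vid]
            if str(row["chrom"]) == str(chrom):
                dist = max(body_start - int(row["pos"]), int(row["pos"]) - body_end, 0)
                if dist <= min_distance:
                    continue
            kept.append(vid)
        if kept:
            groups.append(TransGroup(tf=tf, variants=kept))
    return sorted(groups, key=lambda g: g.tf)


def trans_group_map_to_json(tgm: TransGroupMap) -> dict:
    return {g: [{"tf": grp.tf, "variants": grp.variants} for grp in lst] for g, lst in tgm.items()}


def trans_group_map_from_json(obj: dict) -> TransGroupMap:
    return {
        g: [TransGroup(tf=d["tf"], variants=list(d["variants"])) for d in lst]
        for g, lst in obj.items()
    }
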