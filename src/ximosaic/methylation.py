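"""CpG-island methylation analyses: fold changes, ratios, TSS linkage.

Island abundances are normalized like the RNA libraries (per-sample scaling
on autosomal island totals, so an X-wide methylation change cannot distort
the factors).  The island-level statistic mirrors the expression one:

    ratio = Cre+ / (Cre+ + Cre-)

on normalized per-condition mean abundances — 0.5 when methylation is
untouched, below 0.5 for islands demethylated after Xist deletion.  Islands
are linked to the gene whose TSS lies nearest their midpoint when that
distance is at most 4 kb, and X-linked islands are grouped by their linked
gene's expression tercile to ask whether demethylation tracks expression.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CRE_NEG, CRE_POS, X_CHROM
from .expression import BinComparison, ExpressionBinAssignment, NormalizedCounts
from .dosage import ShiftResult, cumulative_shift_test
from .medseq import IslandCountMatrix

logger = logging.getLogger(__name__)


def normalize_island_counts(
    island_counts: IslandCountMatrix, islands: pd.DataFrame
) -> NormalizedCounts:
    """Per-sample scaling of island counts on autosomal island totals."""
    chrom = islands.set_index("island_id")["chrom"].reindex(island_counts.counts.index)
    auto_mask = (chrom != X_CHROM).to_numpy()
    if not auto_mask.any():
        raise ValueError("need at least one autosomal island to normalize")
    totals = island_counts.counts.loc[auto_mask].sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero autosomal island counts: {bad}")
    target = float(np.exp(np.log(totals).mean()))
    factors = target / totals
    values = island_counts.counts.astype(float).mul(factors, axis=1)
    return NormalizedCounts(values, factors, island_counts.samples.copy(),
                            island_counts.counts)


def island_fold_change(
    island_counts: IslandCountMatrix,
    islands: pd.DataFrame,
    pseudocount: float = 0.5,
) -> tuple:
    """Per-island Cre+/Cre- fold change and the X-vs-autosome shift test.

    Returns (fold-change DataFrame, :class:`~ximosaic.dosage.ShiftResult`).
    Under Xi demethylation the X islands shift left (fc below 1,
    hypomethylation) relative to autosomal islands.
    """
    norm = normalize_island_counts(island_counts, islands)
    pos_cols = norm.condition_samples(CRE_POS)
    neg_cols = norm.condition_samples(CRE_NEG)
    if not pos_cols or not neg_cols:
        raise ValueError("both conditions must be present")
    mean_pos = norm.values[pos_cols].mean(axis=1)
    mean_neg = norm.values[neg_cols].mean(axis=1)
    both_zero = (mean_pos == 0) & (mean_neg == 0)
    if both_zero.any():
        logger.info("dropping %d islands with zero abundance in both conditions",
                    int(both_zero.sum()))
    mean_pos, mean_neg = mean_pos[~both_zero], mean_neg[~both_zero]
    fc = (mean_pos + pseudocount) / (mean_neg + pseudocount)
    chrom = islands.set_index("island_id")["chrom"]
    fcs = pd.DataFrame({
        "island_id": fc.index,
        "chrom": chrom.reindex(fc.index).to_numpy(),
        "mean_mutant": mean_pos.to_numpy(),
        "mean_control": mean_neg.to_numpy(),
        "fc": fc.to_numpy(),
        "log2fc": np.log2(fc.to_numpy()),
    }).reset_index(drop=True)
    shift = cumulative_shift_test(fcs)
    return fcs, shift


def link_islands_to_tss(
    islands: pd.DataFrame, genes: pd.DataFrame, max_distance: int = 4000
) -> pd.DataFrame:
    """Link each island to the gene with the nearest TSS within ``max_distance``.

    Distance is measured from the island midpoint (lower-median position) to
    the TSS, inclusive at the boundary; ties go to the lexicographically
    smaller gene_id.  Unlinked islands get an empty gene_id.  The mapping is
    a function of its inputs (idempotent, at most one gene per island).
    """
    rows = []
    gene_by_chrom = {c: sub for c, sub in genes.groupby("chrom", sort=False)}
    for row in islands.itertuples(index=False):
        mid = row.start + (row.end - row.start - 1) // 2
        sub = gene_by_chrom.get(row.chrom)
        gene_id, dist = "", -1
        if sub is not None and len(sub):
            d = np.abs(sub["tss"].to_numpy(np.int64) - mid)
            best = d.min()
            if best <= max_distance:
                cands = sorted(sub.loc[d == best, "gene_id"])
                gene_id, dist = cands[0], int(best)
        rows.append((row.island_id, gene_id, dist))
    return pd.DataFrame(rows, columns=["island_id", "gene_id", "tss_distance"])


def island_methylation_ratio(
    island_counts: IslandCountMatrix,
    linkage: pd.DataFrame,
    islands: pd.DataFrame,
) -> pd.DataFrame:
    """Per-island Cre+/(Cre+ plus Cre-) methylation-abundance ratio records.

    Abundances are normalized per-condition means; islands with zero total
    are excluded with a logged count.  Linkage columns (gene_id,
    tss_distance) are joined in.
    """
    norm = normalize_island_counts(island_counts, islands)
    pos_cols = norm.condition_samples(CRE_POS)
    neg_cols = norm.condition_samples(CRE_NEG)
    if not pos_cols or not neg_cols:
        raise ValueError("both conditions must be present")
    mean_pos = norm.values[pos_cols].mean(axis=1)
    mean_neg = norm.values[neg_cols].mean(axis=1)
    total = mean_pos + mean_neg
    zero = total == 0
    if zero.any():
        logger.info("excluding %d islands with zero total abundance", int(zero.sum()))
    chrom = islands.set_index("island_id")["chrom"]
    out = pd.DataFrame({
        "island_id": mean_pos.index,
        "chrom": chrom.reindex(mean_pos.index).to_numpy(),
        "cre_pos": mean_pos.to_numpy(),
        "cre_neg": mean_neg.to_numpy(),
        "ratio": np.where(total > 0, mean_pos / total, np.nan),
    }).reset_index(drop=True)
    out = out[~zero.to_numpy()].reset_index(drop=True)
    link = linkage.set_index("island_id")
    out["gene_id"] = link["gene_id"].reindex(out["island_id"]).fillna("").to_numpy()
    out["tss_distance"] = link["tss_distance"].reindex(out["island_id"]).fillna(-1).astype(int).to_numpy()
    return out


def compare_methylation_groups(
    records: pd.DataFrame, bins: ExpressionBinAssignment
) -> BinComparison:
    """Tercile-1 vs terciles-2+3 comparison of X-island methylation ratios.

    X-linked islands are grouped by their linked gene's expression tercile
    (group A: tercile 1, the non-derepressed genes; group B: terciles 2 and 3
    combined); a two-sided pooled-variance Student's t compares the ratios.
    """
    if bins.k != 3:
        raise ValueError("expression bins must be terciles (k=3)")
    x = records[(records["chrom"] == X_CHROM) & (records["gene_id"] != "")]
    tercile = bins.assignments.reindex(x["gene_id"])
    linked = x.loc[tercile.notna().to_numpy()].copy()
    linked["tercile"] = tercile.dropna().astype(int).to_numpy()
    a = linked.loc[linked["tercile"] == 1, "ratio"].dropna().to_numpy()
    b = linked.loc[linked["tercile"].isin((2, 3)), "ratio"].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each expression group needs at least 2 linked X islands")
    from scipy import stats
    if np.isclose(a.mean(), b.mean()) and a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    return BinComparison(
        (1,), (2, 3), len(a), len(b),
        float(a.mean()), float(b.mean()),
        float(a.std(ddof=1)), float(b.std(ddof=1)),
        t, p,
    )
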