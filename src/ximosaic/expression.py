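"""Reactivation-ratio analysis of Cre+ vs Cre- bulk RNA-seq counts.

The central statistic is the per-gene reactivation ratio

    r = mean(Cre+) / (mean(Cre+) + mean(Cre-))

computed on library-normalized counts: 0.5 under intact silencing symmetry,
above 0.5 when the Xi allele is derepressed in some cells.  If a fraction f
of cells carries a fully reactivated Xi allele, the expected ratio is
(1 + f) / (2 + f), which inverts to f = (2r - 1) / (1 - r).

Genes covered by fewer than 20 raw reads (summed over all samples) are
excluded before any stratification; retained X genes are ranked by their
expression in the unperturbed (Cre-) samples and split into equal-size
terciles or quartiles for between-bin Student's t tests.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import CRE_NEG, CRE_POS
from .reactivation import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizedCounts:
    """Library-normalized counts with the per-sample scale factors and raw counts."""

    values: pd.DataFrame
    scale_factors: pd.Series
    samples: pd.DataFrame
    raw: pd.DataFrame

    def condition_samples(self, condition: str) -> list:
        return list(self.samples.loc[self.samples["condition"] == condition, "sample_id"])


def normalize_libraries(counts: CountMatrix, annotation: pd.DataFrame) -> NormalizedCounts:
    """Scale each sample so autosomal totals match their across-sample geometric mean.

    X-linked genes are excluded from the factor computation (an X-wide dosage
    change must not distort the scaling) but share their sample's factor.
    ``annotation`` maps gene_id to chrom.
    """
    chrom = annotation.set_index("gene_id")["chrom"].reindex(counts.counts.index)
    auto_mask = (chrom != "X").to_numpy()
    if not auto_mask.any():
        raise ValueError("need at least one autosomal gene to normalize")
    totals = counts.counts.loc[auto_mask].sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero autosomal reads: {bad}")
    target = float(np.exp(np.log(totals).mean()))
    factors = target / totals
    values = counts.counts.astype(float).mul(factors, axis=1)
    return NormalizedCounts(values, factors, counts.samples.copy(), counts.counts)


def filter_low_coverage(counts: CountMatrix, min_reads: int = 20) -> pd.Index:
    """Genes whose raw-read total over all samples is at least ``min_reads``.

    The boundary follows the strict "fewer than 20 excluded" reading: a gene
    with exactly 20 reads is retained.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = counts.counts.sum(axis=1)
    return counts.counts.index[totals >= min_reads]


def reactivation_ratio(
    norm: NormalizedCounts,
    retained,
    *,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-gene ratio table: Cre+ reads over total (Cre+ plus Cre-) reads.

    ``cre_pos`` and ``cre_neg`` are per-condition means of normalized counts
    (or sums of raw reads with ``pooled=True``).  Genes with a zero
    denominator get a NaN ratio and are excluded downstream.  Returns a
    DataFrame with columns gene_id, cre_pos, cre_neg, total_raw_reads,
    ratio, pass_filter.
    """
    pos_cols = norm.condition_samples(CRE_POS)
    neg_cols = norm.condition_samples(CRE_NEG)
    if not pos_cols or not neg_cols:
        raise ValueError("need at least one sample per condition")
    source = norm.raw if pooled else norm.values
    agg = (lambda df: df.sum(axis=1)) if pooled else (lambda df: df.mean(axis=1))
    cre_pos = agg(source[pos_cols]).astype(float)
    cre_neg = agg(source[neg_cols]).astype(float)
    total = cre_pos + cre_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, cre_pos / total, np.nan)
    retained = pd.Index(retained)
    out = pd.DataFrame({
        "gene_id": norm.values.index,
        "cre_pos": cre_pos.to_numpy(),
        "cre_neg": cre_neg.to_numpy(),
        "total_raw_reads": norm.raw.sum(axis=1).to_numpy(),
        "ratio": ratio,
        "pass_filter": norm.values.index.isin(retained),
    }).reset_index(drop=True)
    n_undef = int(out["ratio"].isna().sum())
    if n_undef:
        logger.info("%d genes with zero total reads have undefined ratios", n_undef)
    return out


@dataclass
class ExpressionBinAssignment:
    """Equal-size expression bins (1 = lowest expression)."""

    k: int
    assignments: pd.Series  # gene_id -> bin index 1..k
    boundaries: list  # expression measure at the upper edge of each bin

    def genes_in(self, bins) -> pd.Index:
        if isinstance(bins, int):
            bins = (bins,)
        mask = self.assignments.isin(bins)
        return self.assignments.index[mask]


def stratify_by_expression(
    ratios: pd.DataFrame, expression_measure: pd.Series, k: int
) -> ExpressionBinAssignment:
    """Rank genes by expression and split into k contiguous equal blocks.

    Ties are broken by lexicographic gene_id; when the gene count is not a
    multiple of k the remainders go to the lowest-expression bins, so bin
    sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    gene_ids = ratios["gene_id"]
    n = len(gene_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genes ({n})")
    measure = expression_measure.reindex(gene_ids)
    if measure.isna().any():
        missing = list(gene_ids[measure.isna().to_numpy()][:3])
        raise ValueError(f"expression measure missing for genes such as {missing}")
    order = sorted(range(n), key=lambda i: (measure.iloc[i], gene_ids.iloc[i]))
    base, rem = divmod(n, k)
    sizes = [base + 1 if b < rem else base for b in range(k)]
    labels = np.empty(n, dtype=int)
    boundaries = []
    pos = 0
    for b, size in enumerate(sizes, start=1):
        idx = order[pos:pos + size]
        labels[idx] = b
        boundaries.append(float(measure.iloc[idx[-1]]))
        pos += size
    assignments = pd.Series(labels, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionBinAssignment(k, assignments, boundaries)


@dataclass
class BinComparison:
    """Two-sample Student's t comparison of ratio values between bins."""

    bin_a: tuple
    bin_b: tuple
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    pvalue: float

    def as_dict(self) -> dict:
        return {
            "bin_a": list(self.bin_a), "bin_b": list(self.bin_b),
            "n_a": self.n_a, "n_b": self.n_b,
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "sd_a": self.sd_a, "sd_b": self.sd_b,
            "t": self.t, "pvalue": self.pvalue,
        }


def compare_bins(
    ratios: pd.DataFrame,
    bins: ExpressionBinAssignment,
    bin_a,
    bin_b,
    *,
    welch: bool = False,
) -> BinComparison:
    """Pooled-variance Student's t test (two-sided) on ratios of two bin groups.

    ``bin_a`` / ``bin_b`` may be a single bin index or an iterable of indices
    (an aggregate, e.g. terciles 2+3 combined).
    """
    bin_a = (bin_a,) if isinstance(bin_a, int) else tuple(bin_a)
    bin_b = (bin_b,) if isinstance(bin_b, int) else tuple(bin_b)
    by_gene = ratios.set_index("gene_id")["ratio"]
    a = by_gene.reindex(bins.genes_in(bin_a)).dropna().to_numpy()
    b = by_gene.reindex(bins.genes_in(bin_b)).dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group must contain at least 2 genes")
    if np.isclose(a.mean(), b.mean()) and a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t, p = 0.0, 1.0  # degenerate: identical constant groups
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
        if not math.isfinite(t):  # zero pooled variance, unequal means
            t = math.copysign(math.inf, a.mean() - b.mean())
            p = 0.0
    return BinComparison(
        bin_a, bin_b, len(a), len(b),
        float(a.mean()), float(b.mean()),
        float(a.std(ddof=1)), float(b.std(ddof=1)),
        t, p,
    )


def estimate_reactivation_fraction(r: float) -> float:
    """Invert the expected ratio (1 + f) / (2 + f) to the per-cell fraction f.

    f = (2 r - 1) / (1 - r); negative for r < 0.5 and reported as-is.
    """
    if not (0 <= r < 1):
        raise ValueError("r must be in [0, 1)")
    return (2 * r - 1) / (1 - r)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct values for a qPCR target and reference gene in sample and calibrator."""

    ct_target_sample: float
    ct_ref_sample: float
    ct_target_calibrator: float
    ct_ref_calibrator: float

    def __post_init__(self):
        for v in (self.ct_target_sample, self.ct_ref_sample,
                  self.ct_target_calibrator, self.ct_ref_calibrator):
            if not math.isfinite(v):
                raise ValueError("Ct values must be finite")


def delta_delta_ct(m: QpcrMeasurement) -> float:
    """Relative expression 2**(-ddCt), reference-normalized and calibrated."""
    ddct = (m.ct_target_sample - m.ct_ref_sample) - (
        m.ct_target_calibrator - m.ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))
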