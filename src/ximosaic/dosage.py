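"""Chromosome-wide dosage-shift analysis of mutant/control fold changes.

Per-gene fold changes fc = (mutant mean + c) / (control mean + c) are
compared between the X chromosome and a reference set of autosomes with a
two-sided Wilcoxon rank-sum test on the fc values, plus empirical CDFs for
cumulative plots and a shared-edge histogram with the mean shift
mean(fc_X) - mean(fc_reference).  The shift is computed on the fold-change
scale (not log2), matching how the expression upshift is quantified; log2
values are carried along for plotting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import CRE_NEG, CRE_POS, X_CHROM
from .expression import NormalizedCounts

logger = logging.getLogger(__name__)


def per_gene_fold_change(
    norm: NormalizedCounts,
    retained,
    pseudocount: float = 0.5,
    *,
    annotation: pd.DataFrame | None = None,
    mutant_condition: str = CRE_POS,
    control_condition: str = CRE_NEG,
) -> pd.DataFrame:
    """Per-gene mutant/control fold change on normalized per-condition means.

    A pseudocount keeps genes with a zero control mean finite; genes with
    zero in both conditions are dropped (their fold change carries no
    signal) with a logged count.  ``annotation`` (gene_id -> chrom) defaults
    to none, in which case gene ids must be resolvable downstream.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mut_cols = norm.condition_samples(mutant_condition)
    ctl_cols = norm.condition_samples(control_condition)
    if not mut_cols or not ctl_cols:
        raise ValueError("both conditions must be present")
    sub = norm.values.loc[norm.values.index.isin(pd.Index(retained))]
    mean_mut = sub[mut_cols].mean(axis=1)
    mean_ctl = sub[ctl_cols].mean(axis=1)
    both_zero = (mean_mut == 0) & (mean_ctl == 0)
    if both_zero.any():
        logger.info("dropping %d genes with zero means in both conditions",
                    int(both_zero.sum()))
    mean_mut, mean_ctl = mean_mut[~both_zero], mean_ctl[~both_zero]
    fc = (mean_mut + pseudocount) / (mean_ctl + pseudocount)
    out = pd.DataFrame({
        "gene_id": fc.index,
        "mean_mutant": mean_mut.to_numpy(),
        "mean_control": mean_ctl.to_numpy(),
        "fc": fc.to_numpy(),
        "log2fc": np.log2(fc.to_numpy()),
    }).reset_index(drop=True)
    if annotation is not None:
        chrom = annotation.set_index("gene_id")["chrom"]
        out.insert(1, "chrom", chrom.reindex(out["gene_id"]).to_numpy())
    return out


@dataclass
class ShiftResult:
    """Result of an X-vs-reference distribution-shift comparison."""

    test_label: str
    reference_label: str
    n_test: int
    n_reference: int
    statistic: float
    pvalue: float
    mean_shift: float
    ecdf_test: tuple  # (sorted values, cumulative fractions)
    ecdf_reference: tuple
    bin_edges: np.ndarray | None = None
    bin_freq_test: np.ndarray | None = None
    bin_freq_reference: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "test": self.test_label, "reference": self.reference_label,
            "n_test": self.n_test, "n_reference": self.n_reference,
            "statistic": self.statistic, "pvalue": self.pvalue,
            "mean_shift": self.mean_shift,
        }


def _ecdf(values: np.ndarray) -> tuple:
    x = np.sort(values)
    y = np.arange(1, len(x) + 1) / len(x)
    return x, y


def cumulative_shift_test(
    fcs: pd.DataFrame,
    test_chrom: str = X_CHROM,
    reference=None,
) -> ShiftResult:
    """Two-sided Wilcoxon rank-sum of test-chromosome vs reference fold changes.

    ``reference`` may be None (all other chromosomes pooled), a single
    chromosome label, or a set of labels — the latter two support
    per-autosome comparisons.
    """
    if "chrom" not in fcs.columns:
        raise ValueError("fold-change table must carry a 'chrom' column")
    chrom = fcs["chrom"]
    test_vals = fcs.loc[chrom == test_chrom, "fc"].to_numpy(float)
    if reference is None:
        ref_mask = chrom != test_chrom
        ref_label = "autosomes"
    else:
        ref_set = {reference} if isinstance(reference, str) else set(reference)
        ref_mask = chrom.isin(ref_set)
        ref_label = "+".join(sorted(ref_set))
    ref_vals = fcs.loc[ref_mask, "fc"].to_numpy(float)
    if len(test_vals) < 2 or len(ref_vals) < 2:
        raise ValueError("each group needs at least 2 genes")
    statistic, pvalue = stats.ranksums(test_vals, ref_vals)
    return ShiftResult(
        test_label=test_chrom,
        reference_label=ref_label,
        n_test=len(test_vals),
        n_reference=len(ref_vals),
        statistic=float(statistic),
        pvalue=float(pvalue),
        mean_shift=float(test_vals.mean() - ref_vals.mean()),
        ecdf_test=_ecdf(test_vals),
        ecdf_reference=_ecdf(ref_vals),
    )


def binned_fold_change(
    fcs: pd.DataFrame,
    test_chrom: str = X_CHROM,
    bin_width: float = 0.05,
) -> tuple:
    """Histogram fold changes on shared edges; returns (bin table, mean shift).

    The mean shift is mean(fc_test) - mean(fc_reference), the scalar used to
    quantify the X-wide expression upshift.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    chrom = fcs["chrom"]
    test_vals = fcs.loc[chrom == test_chrom, "fc"].to_numpy(float)
    ref_vals = fcs.loc[chrom != test_chrom, "fc"].to_numpy(float)
    if len(test_vals) < 1 or len(ref_vals) < 1:
        raise ValueError("each group needs at least 1 gene")
    all_vals = np.concatenate([test_vals, ref_vals])
    lo = np.floor(all_vals.min() / bin_width) * bin_width
    hi = np.ceil(all_vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    freq_test, _ = np.histogram(test_vals, bins=edges)
    freq_ref, _ = np.histogram(ref_vals, bins=edges)
    table = pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "freq_test": freq_test / len(test_vals),
        "freq_reference": freq_ref / len(ref_vals),
    })
    mean_shift = float(test_vals.mean() - ref_vals.mean())
    return table, mean_shift


def control_consistency(
    norm: NormalizedCounts,
    control_samples,
    retained,
    annotation: pd.DataFrame,
    pseudocount: float = 0.5,
) -> ShiftResult:
    """Control-vs-control check: first control over the mean of the rest.

    With at least three control samples, the fold change of the first named
    control relative to the average of the others is computed on normalized
    counts and put through the X-vs-autosome shift test; absent any real
    perturbation the curves should overlap (null behavior).
    """
    control_samples = list(control_samples)
    if len(control_samples) < 3:
        raise ValueError("need at least 3 control samples")
    missing = [s for s in control_samples if s not in norm.values.columns]
    if missing:
        raise ValueError(f"unknown control samples: {missing}")
    sub = norm.values.loc[norm.values.index.isin(pd.Index(retained))]
    first = sub[control_samples[0]]
    rest = sub[control_samples[1:]].mean(axis=1)
    both_zero = (first == 0) & (rest == 0)
    first, rest = first[~both_zero], rest[~both_zero]
    fc = (first + pseudocount) / (rest + pseudocount)
    chrom = annotation.set_index("gene_id")["chrom"]
    fcs = pd.DataFrame({
        "gene_id": fc.index,
        "chrom": chrom.reindex(fc.index).to_numpy(),
        "fc": fc.to_numpy(),
    }).reset_index(drop=True)
    return cumulative_shift_test(fcs)
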