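"""Optional diagnostic plots (requires matplotlib)."""
from __future__ import annotations

from pathlib import Path

import pandas as pd


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_ecdf(shift_result, path) -> str:
    """Cumulative fold-change curves for the test and reference groups."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 3))
    x, y = shift_result.ecdf_reference
    ax.step(x, y, where="post", color="black", label=shift_result.reference_label)
    x, y = shift_result.ecdf_test
    ax.step(x, y, where="post", color="red", label=shift_result.test_label)
    ax.set_xlabel("fold change (mutant/control)")
    ax.set_ylabel("cumulative fraction")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_fold_change_bins(bin_table: pd.DataFrame, path) -> str:
    """Shared-edge fold-change histograms for the two groups."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 3))
    centers = (bin_table["bin_left"] + bin_table["bin_right"]) / 2
    width = (bin_table["bin_right"] - bin_table["bin_left"]).iloc[0]
    ax.bar(centers, bin_table["freq_reference"], width=width * 0.9,
           color="black", alpha=0.5, label="reference")
    ax.bar(centers, bin_table["freq_test"], width=width * 0.9,
           color="red", alpha=0.5, label="test")
    ax.set_xlabel("fold change")
    ax.set_ylabel("fraction of genes")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_run(result, out_dir) -> list:
    """Write the diagnostic plots a full pipeline run supports."""
    out = Path(out_dir)
    written = []
    fcs = pd.read_csv(result.paths["fold_changes"], sep="\t", comment="#")
    from .dosage import cumulative_shift_test
    shift = cumulative_shift_test(fcs)
    written.append(plot_ecdf(shift, out / "expression_ecdf.png"))
    bins = pd.read_csv(result.paths["fold_change_bins"], sep="\t", comment="#")
    written.append(plot_fold_change_bins(bins, out / "expression_bins.png"))
    return written
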