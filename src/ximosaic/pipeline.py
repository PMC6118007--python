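"""End-to-end orchestration: simulate, analyze, report.

A :class:`RunConfig` fully determines a run: fixture parameters, the
reactivation and methylome perturbation, replicate counts and depths, the
analysis thresholds, and a master seed.  Child seeds are derived by a stable
hash of (master seed, stage name, replicate index), so re-running the same
config reproduces every output byte-for-byte.  Every output table carries a
provenance comment (config hash, stage seed) as its first line.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import config_hash, stage_seed
from .genome import CRE_NEG, CRE_POS, X_CHROM, make_genome_fixture, write_fixture
from .reactivation import (CellPopulation, CountMatrix, ReactivationModel,
                           sample_reactivation_states, simulate_bulk_counts)
from .medseq import DigestionModel, IslandCountMatrix, simulate_medseq_samples
from .expression import (compare_bins, estimate_reactivation_fraction,
                         filter_low_coverage, normalize_libraries,
                         reactivation_ratio, stratify_by_expression)
from .dosage import (binned_fold_change, control_consistency,
                     cumulative_shift_test, per_gene_fold_change)
from .methylation import (compare_methylation_groups, island_fold_change,
                          island_methylation_ratio, link_islands_to_tss)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, serializable configuration of a full simulated experiment."""

    # fixture
    n_autosomal_genes: int = 15_000
    n_x_genes: int = 600
    n_islands_per_chrom: int = 600
    expr_mu: float = 0.0
    expr_sigma: float = 2.3
    assayable_fraction: float = 0.5
    n_autosomes: int = 4
    island_near_tss_prob: float = 0.9
    # methylome baseline and perturbation
    p_meth_auto: float = 0.35
    p_meth_xa: float = 0.15
    p_meth_xi: float = 0.85
    demeth_max: float = 0.2
    demeth_e50: float = 1.5
    demeth_h: float = 1.2
    hyper_fraction: float = 0.1
    hyper_boost: float = 0.1
    # reactivation model
    p_max: float = 0.04
    e50: float = 1.5
    hill_h: float = 1.2
    coupling: str = "locus"
    escape_fraction: float = 0.0
    # replicates and depths
    rna_replicates: int = 3
    med_replicates: int = 2
    n_cells_rna: int = 10_000
    n_cells_med: int = 50
    depth: float = 60.0
    dispersion: float = 0.05
    med_depth_scale: float = 1.0
    # analysis thresholds
    min_reads: int = 20
    bins: tuple = (3, 4)
    max_distance: int = 4000
    pseudocount: float = 0.5
    size_window: tuple = (27, 37)
    cut_offset: int = 16
    capture_efficiency: float = 1.0
    # master seed
    seed: int = 0

    def validate(self) -> None:
        if self.rna_replicates < 1 or self.med_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.coupling not in ("locus", "chromosome"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if not all(k >= 2 for k in self.bins):
            raise ValueError("each bin count must be >= 2")
        ReactivationModel(self.p_max, self.e50, self.hill_h)
        DigestionModel(self.cut_offset, tuple(self.size_window),
                       self.capture_efficiency)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bins"] = list(self.bins)
        d["size_window"] = list(self.size_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "bins" in d:
            d["bins"] = tuple(d["bins"])
        if "size_window" in d:
            d["size_window"] = tuple(d["size_window"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


@dataclass
class RunResult:
    """Paths to all outputs plus the summary statistics of a run."""

    out_dir: str
    paths: dict
    summary: dict


def build_fixture(config: RunConfig):
    return make_genome_fixture(
        n_autosomal_genes=config.n_autosomal_genes,
        n_x_genes=config.n_x_genes,
        n_islands_per_chrom=config.n_islands_per_chrom,
        expr_lognormal_params=(config.expr_mu, config.expr_sigma),
        assayable_fraction=config.assayable_fraction,
        seed=stage_seed(config.seed, "fixture"),
        n_autosomes=config.n_autosomes,
        island_near_tss_prob=config.island_near_tss_prob,
        p_meth_auto=config.p_meth_auto,
        p_meth_xa=config.p_meth_xa,
        p_meth_xi=config.p_meth_xi,
        demeth_max=config.demeth_max,
        demeth_e50=config.demeth_e50,
        demeth_h=config.demeth_h,
        hyper_fraction=config.hyper_fraction,
        hyper_boost=config.hyper_boost,
    )


def simulate_rna(config: RunConfig, fixture) -> CountMatrix:
    model = ReactivationModel(config.p_max, config.e50, config.hill_h)
    populations = []
    for cond in (CRE_POS, CRE_NEG):
        tag = "pos" if cond == CRE_POS else "neg"
        for rep in range(config.rna_replicates):
            populations.append(sample_reactivation_states(
                fixture, model, config.n_cells_rna, cond,
                seed=stage_seed(config.seed, f"rna_pop_{tag}", rep),
                coupling=config.coupling,
            ))
    return simulate_bulk_counts(
        fixture, populations, config.depth, config.dispersion,
        seed=stage_seed(config.seed, "rna_counts"),
        escape_fraction=config.escape_fraction,
    )


def simulate_methylation(config: RunConfig, fixture) -> IslandCountMatrix:
    model = DigestionModel(config.cut_offset, tuple(config.size_window),
                           config.capture_efficiency)
    return simulate_medseq_samples(
        fixture, config.med_replicates, config.n_cells_med, model,
        config.med_depth_scale, seed=stage_seed(config.seed, "medseq"),
    )


def _write_table(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    header = "# " + " ".join(f"{k}={v}" for k, v in provenance.items())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def run_full_experiment(config: RunConfig, out_dir) -> RunResult:
    """Simulate a full experiment and run every analysis; write all artifacts."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.hash, "seed": config.seed}
    t0 = time.perf_counter()

    def stage(name):
        logger.info("[%s] %.1fs elapsed", name, time.perf_counter() - t0)

    fixture = build_fixture(config)
    stage("fixture")
    fixture_paths = write_fixture(fixture, out / "fixture")

    counts = simulate_rna(config, fixture)
    stage("rna_sim")
    med_counts = simulate_methylation(config, fixture)
    stage("medseq_sim")

    annotation = fixture.genes[["gene_id", "chrom"]]
    norm = normalize_libraries(counts, annotation)
    retained = filter_low_coverage(counts, config.min_reads)
    ratios = reactivation_ratio(norm, retained)

    x_ids = set(fixture.x_genes["gene_id"])
    x_ratios = ratios[
        ratios["gene_id"].isin(x_ids) & ratios["pass_filter"] & ratios["ratio"].notna()
    ].reset_index(drop=True)
    # stratify on the mean over ALL samples: conditioning on the Cre- mean
    # alone (the ratio's own denominator) injects a regression-to-the-mean
    # bias into the extreme bins; the all-sample mean is symmetric in the
    # two conditions and unbiased under the null
    expr_measure = norm.values.mean(axis=1)

    bin_results, bin_cols = {}, {}
    for k in config.bins:
        bins_k = stratify_by_expression(x_ratios, expr_measure, k)
        bin_cols[k] = bins_k
        means = {
            str(b): float(np.nanmean(
                x_ratios.set_index("gene_id")["ratio"].reindex(bins_k.genes_in(b))))
            for b in range(1, k + 1)
        }
        comparisons = {}
        if k == 3:
            comparisons["t3_vs_t1"] = compare_bins(x_ratios, bins_k, 3, 1).as_dict()
            comparisons["t2_vs_t1"] = compare_bins(x_ratios, bins_k, 2, 1).as_dict()
        else:
            for b in range(2, k + 1):
                comparisons[f"q{b}_vs_q{b-1}"] = compare_bins(
                    x_ratios, bins_k, b, b - 1).as_dict()
        bin_results[str(k)] = {"bin_means": means, "comparisons": comparisons}
    stage("expression")

    bins3 = bin_cols.get(3)
    mean_r = float(x_ratios["ratio"].mean())
    top_tercile_f = None
    if bins3 is not None:
        r3 = float(np.nanmean(
            x_ratios.set_index("gene_id")["ratio"].reindex(bins3.genes_in(3))))
        top_tercile_f = estimate_reactivation_fraction(r3) if r3 < 1 else None

    fcs = per_gene_fold_change(norm, retained, config.pseudocount,
                               annotation=annotation)
    shift = cumulative_shift_test(fcs)
    bin_table, mean_shift = binned_fold_change(fcs)
    per_autosome = {
        chrom: cumulative_shift_test(fcs, X_CHROM, chrom).as_dict()
        for chrom in fixture.autosomes
    }
    controls = norm.condition_samples(CRE_NEG)
    control_result = (control_consistency(norm, controls, retained, annotation,
                                          config.pseudocount).as_dict()
                      if len(controls) >= 3 else None)
    stage("dosage")

    island_fcs, island_shift = island_fold_change(
        med_counts, fixture.islands, config.pseudocount)
    linkage = link_islands_to_tss(fixture.islands, fixture.genes,
                                  config.max_distance)
    island_ratios = island_methylation_ratio(med_counts, linkage, fixture.islands)
    meth_comparison = (compare_methylation_groups(island_ratios, bins3).as_dict()
                       if bins3 is not None else None)
    stage("methylation")

    summary = {
        "config_hash": config.hash,
        "seed": config.seed,
        "expression": {
            "n_retained_x_genes": int(len(x_ratios)),
            "mean_x_ratio": mean_r,
            "estimated_reactivation_fraction_top_tercile": top_tercile_f,
            "bins": bin_results,
        },
        "dosage": {
            "x_vs_autosomes": shift.as_dict(),
            "binned_mean_shift": mean_shift,
            "per_autosome": per_autosome,
            "control_consistency": control_result,
        },
        "methylation": {
            "x_vs_autosomes": island_shift.as_dict(),
            "mean_x_island_ratio": float(
                island_ratios.loc[island_ratios["chrom"] == X_CHROM, "ratio"].mean()),
            "tercile1_vs_terciles23": meth_comparison,
        },
    }

    paths = dict(fixture_paths)
    _write_table(counts.counts.reset_index().rename(columns={"index": "gene_id"}),
                 out / "rna_counts.tsv", prov)
    _write_table(counts.samples, out / "rna_samples.tsv", prov)
    _write_table(med_counts.counts.reset_index().rename(columns={"index": "island_id"}),
                 out / "island_counts.tsv", prov)
    _write_table(med_counts.samples, out / "med_samples.tsv", prov)

    ratio_table = ratios.copy()
    for k, bins_k in bin_cols.items():
        col = bins_k.assignments.reindex(ratio_table["gene_id"])
        ratio_table[f"bin{k}"] = col.fillna(0).astype(int).to_numpy()
    _write_table(ratio_table, out / "ratio_table.tsv", prov)
    _write_table(fcs, out / "fold_changes.tsv", prov)
    _write_table(bin_table, out / "fold_change_bins.tsv", prov)
    _write_table(island_fcs, out / "island_fold_changes.tsv", prov)
    _write_table(island_ratios, out / "island_ratios.tsv", prov)
    _write_table(linkage, out / "island_gene_linkage.tsv", prov)
    config.to_yaml(out / "config.yaml")
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")

    for name in ["rna_counts", "rna_samples", "island_counts", "med_samples",
                 "ratio_table", "fold_changes", "fold_change_bins",
                 "island_fold_changes", "island_ratios", "island_gene_linkage"]:
        paths[name] = str(out / f"{name}.tsv")
    paths["summary"] = str(out / "summary.json")
    paths["config"] = str(out / "config.yaml")
    stage("done")
    return RunResult(str(out), paths, summary)


# ---------------------------------------------------------------------------
# input validation for real-data entry points
# ---------------------------------------------------------------------------

def validate_inputs(counts_path, samples_path, annotation_path) -> list:
    """Validate a counts TSV + sample sheet TSV + gene/island BED triple.

    Returns a list of violation dicts (empty when everything is consistent);
    each violation has ``kind`` and ``message`` keys naming the offending
    sample, column or record.
    """
    violations = []

    def add(kind, message):
        violations.append({"kind": kind, "message": message})

    try:
        counts = pd.read_csv(counts_path, sep="\t", comment="#")
    except Exception as exc:  # unreadable file is an error, not a violation
        raise OSError(f"cannot read counts file {counts_path}: {exc}") from exc
    try:
        samples = pd.read_csv(samples_path, sep="\t", comment="#")
    except Exception as exc:
        raise OSError(f"cannot read sample sheet {samples_path}: {exc}") from exc

    id_col = counts.columns[0]
    if counts[id_col].duplicated().any():
        dups = counts.loc[counts[id_col].duplicated(), id_col].head(3).tolist()
        add("duplicate_id", f"duplicate feature ids in counts: {dups}")

    required = {"sample_id", "condition", "replicate"}
    missing_cols = required - set(samples.columns)
    if missing_cols:
        add("sample_sheet", f"sample sheet missing columns {sorted(missing_cols)}")
    else:
        bad_cond = samples.loc[~samples["condition"].isin([CRE_POS, CRE_NEG])]
        for row in bad_cond.itertuples(index=False):
            add("condition", f"sample {row.sample_id!r} has unknown condition "
                             f"{row.condition!r}")
        sheet_ids = set(samples["sample_id"])
        count_cols = set(counts.columns[1:])
        for col in sorted(count_cols - sheet_ids):
            add("column", f"counts column {col!r} missing from sample sheet")
        for sid in sorted(sheet_ids - count_cols):
            add("column", f"sample {sid!r} has no counts column")

    try:
        bed = pd.read_csv(annotation_path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        bed = pd.DataFrame()
    except Exception as exc:
        raise OSError(f"cannot read BED file {annotation_path}: {exc}") from exc
    if len(bed):
        if bed.shape[1] < 4:
            add("bed", "BED file needs at least 4 columns (chrom, start, end, name)")
        else:
            starts = pd.to_numeric(bed[1], errors="coerce")
            ends = pd.to_numeric(bed[2], errors="coerce")
            if starts.isna().any() or ends.isna().any():
                add("bed", "non-integer coordinates in BED file")
            else:
                bad = bed.loc[(starts < 0) | (ends <= starts)]
                for row in bad.itertuples(index=False):
                    add("bed", f"invalid interval for {row[3]!r}: "
                               f"[{row[1]}, {row[2]})")
            if bed[3].duplicated().any():
                dups = bed.loc[bed[3].duplicated(), 3].head(3).tolist()
                add("duplicate_id", f"duplicate names in BED: {dups}")
    return violations
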