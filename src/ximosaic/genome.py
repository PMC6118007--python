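"""Synthetic genome fixtures for X-inactivation maintenance analyses.

A fixture is a small, fully specified stand-in for a mouse genome annotation:
a handful of synthetic autosomes plus an X chromosome, genes with a TSS,
strand and a per-allele expression rate, CpG islands with explicit CpG site
coordinates, and a methylome giving per-site methylation probabilities for
each allele class (autosomal alleles, active X, inactive X) in both the
Xist-deleted (Cre+) and control (Cre-) conditions.

Coordinates are 0-based, half-open everywhere; BED files are written natively
in that convention. The TSS of a plus-strand gene is its interval start; for
a minus-strand gene it is ``end - 1``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from ._util import hill

logger = logging.getLogger(__name__)

X_CHROM = "X"
CRE_POS = "Cre+"
CRE_NEG = "Cre-"

#: allele classes carried by the methylome
ALLELE_CLASSES = ("auto", "xa", "xi")


@dataclass(frozen=True)
class Gene:
    """A gene: location, strand, and expected reads per active allele."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    expr_rate: float
    start: int = 0
    end: int = 0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.expr_rate <= 0:
            raise ValueError("expr_rate must be positive")


@dataclass(frozen=True)
class CpGIslandDef:
    """A CpG island with the plus-strand C coordinate of each CpG site."""

    island_id: str
    chrom: str
    start: int
    end: int
    cpg_sites: np.ndarray
    assayable: np.ndarray

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("island start must be < end")
        sites = np.asarray(self.cpg_sites)
        if len(sites) and (np.any(np.diff(sites) <= 0)):
            raise ValueError("cpg_sites must be strictly increasing")
        if len(sites) and (sites.min() < self.start or sites.max() >= self.end):
            raise ValueError("cpg_sites must lie in [start, end)")


@dataclass
class MethylomeState:
    """Per-site methylation probabilities by condition and allele class.

    ``probs[condition][allele]`` is a float array aligned with the fixture's
    site table.  Autosomal sites use the "auto" class (both copies share the
    same probability); X sites use "xa" and "xi".  The Cre- Xi probabilities
    are the unperturbed baseline; any Xist-deletion effect lives only in the
    Cre+ Xi entries.
    """

    probs: dict

    def validate(self) -> None:
        for cond in (CRE_NEG, CRE_POS):
            if cond not in self.probs:
                raise ValueError(f"missing condition {cond!r}")
            for allele in ALLELE_CLASSES:
                p = np.asarray(self.probs[cond][allele], dtype=float)
                if np.any((p < 0) | (p > 1)):
                    raise ValueError("methylation probabilities must be in [0, 1]")
        for allele in ("auto", "xa"):
            if not np.array_equal(self.probs[CRE_NEG][allele], self.probs[CRE_POS][allele]):
                raise ValueError(f"{allele} probabilities must be condition-independent")

    def equals(self, other: "MethylomeState") -> bool:
        return all(
            np.array_equal(self.probs[c][a], other.probs[c][a])
            for c in (CRE_NEG, CRE_POS)
            for a in ALLELE_CLASSES
        )


@dataclass
class GenomeFixture:
    """A seeded synthetic genome: chromosomes, genes, CpG islands, methylome."""

    chrom_lengths: dict
    genes: pd.DataFrame
    islands: pd.DataFrame
    sites: pd.DataFrame
    methylome: MethylomeState
    params: dict = field(default_factory=dict)

    @property
    def chroms(self) -> list:
        return list(self.chrom_lengths)

    @property
    def autosomes(self) -> list:
        return [c for c in self.chrom_lengths if c != X_CHROM]

    @property
    def x_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["chrom"] == X_CHROM]

    def gene_records(self) -> Iterator[Gene]:
        for row in self.genes.itertuples(index=False):
            yield Gene(row.gene_id, row.chrom, row.strand, int(row.tss),
                       float(row.expr_rate), int(row.start), int(row.end))

    def island_records(self) -> Iterator[CpGIslandDef]:
        grouped = dict(iter(self.sites.groupby("island_id", sort=False)))
        for row in self.islands.itertuples(index=False):
            sub = grouped.get(row.island_id)
            if sub is None:
                sites = np.empty(0, dtype=np.int64)
                assay = np.empty(0, dtype=bool)
            else:
                sites = sub["pos"].to_numpy(np.int64)
                assay = sub["assayable"].to_numpy(bool)
            yield CpGIslandDef(row.island_id, row.chrom, int(row.start),
                               int(row.end), sites, assay)

    def validate(self) -> None:
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        if (self.genes["expr_rate"] <= 0).any():
            raise ValueError("expr_rate must be positive")
        for row in self.genes.itertuples(index=False):
            if not (0 <= row.tss < self.chrom_lengths[row.chrom]):
                raise ValueError(f"TSS of {row.gene_id} outside chromosome")
        if len(self.islands):
            if (self.islands["start"] >= self.islands["end"]).any():
                raise ValueError("island start must be < end")
        self.methylome.validate()

    def equals(self, other: "GenomeFixture") -> bool:
        return (
            self.chrom_lengths == other.chrom_lengths
            and self.genes.reset_index(drop=True).equals(other.genes.reset_index(drop=True))
            and self.islands.reset_index(drop=True).equals(other.islands.reset_index(drop=True))
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and self.methylome.equals(other.methylome)
            and json.dumps(self.params, sort_keys=True, default=str)
            == json.dumps(other.params, sort_keys=True, default=str)
        )


def make_genome_fixture(
    n_autosomal_genes: int = 15_000,
    n_x_genes: int = 600,
    n_islands_per_chrom: int = 600,
    expr_lognormal_params: tuple = (0.0, 2.3),
    assayable_fraction: float = 0.5,
    seed: int = 0,
    *,
    n_autosomes: int = 4,
    island_near_tss_prob: float = 0.9,
    gene_spacing: int = 12_000,
    gene_length: int = 1_000,
    sites_per_island: tuple = (15, 35),
    site_spacing: tuple = (40, 80),
    p_meth_auto: float = 0.35,
    p_meth_xa: float = 0.15,
    p_meth_xi: float = 0.85,
    demeth_max: float = 0.2,
    demeth_e50: float = 1.5,
    demeth_h: float = 1.2,
    hyper_fraction: float = 0.1,
    hyper_boost: float = 0.1,
) -> GenomeFixture:
    """Build a seeded synthetic genome fixture.

    Genes are laid on a regular grid (one gene per ``gene_spacing`` bp slot)
    on ``n_autosomes`` autosomes plus the X; per-allele expression rates are
    drawn log-normally (default sigma 2.3, chosen so that the top expression
    tercile sits roughly one and two orders of magnitude above the middle and
    bottom terciles).  On each chromosome ``n_islands_per_chrom`` CpG islands
    are attached to a random subset of genes (all of them when there are at
    least as many islands as genes); each island is placed with its midpoint
    within 4 kb of the host TSS with probability ``island_near_tss_prob`` and
    otherwise mid-slot, 6 kb from any TSS, as intergenic background.

    The methylome encodes the Xist-deletion perturbation: on Cre+ Xi alleles,
    TSS-linked islands are demethylated by a factor ``demeth_max`` scaled by a
    Hill response to the host gene's expression rate (highly expressed genes
    lose more methylation), while a random ``hyper_fraction`` of X islands
    instead gain methylation — the bidirectional change with a predominant
    hypomethylation shift.  Cre- and all autosomal/Xa probabilities are
    untouched.
    """
    if n_autosomal_genes < 1 or n_x_genes < 1 or n_islands_per_chrom < 1:
        raise ValueError("gene and island counts must be >= 1")
    if not (0 < assayable_fraction <= 1):
        raise ValueError("assayable_fraction must be in (0, 1]")
    if not (0 <= island_near_tss_prob <= 1):
        raise ValueError("island_near_tss_prob must be a probability")
    if n_autosomes < 1:
        raise ValueError("need at least one autosome")

    mu, sigma = expr_lognormal_params
    rng = np.random.default_rng(seed)

    # chromosome plan: genes split evenly over autosomes, remainder to the first
    per_auto = [n_autosomal_genes // n_autosomes] * n_autosomes
    for i in range(n_autosomal_genes % n_autosomes):
        per_auto[i] += 1
    chrom_plan = [(f"autosome_{i + 1}", n) for i, n in enumerate(per_auto)]
    chrom_plan.append((X_CHROM, n_x_genes))
    for chrom, n_genes in chrom_plan:
        if n_islands_per_chrom > n_genes:
            raise ValueError(
                f"n_islands_per_chrom ({n_islands_per_chrom}) exceeds gene count "
                f"on {chrom} ({n_genes}); islands are attached to distinct genes"
            )

    chrom_lengths = {c: gene_spacing * (n + 1) for c, n in chrom_plan}

    gene_rows = []
    for chrom, n_genes in chrom_plan:
        tss = gene_spacing // 2 + gene_spacing * np.arange(n_genes)
        strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
        expr = rng.lognormal(mu, sigma, n_genes)
        for i in range(n_genes):
            t = int(tss[i])
            if strand[i] == "+":
                start, end = t, t + gene_length
            else:
                end = t + 1
                start = end - gene_length
            gene_rows.append(
                (f"{chrom}_g{i:05d}", chrom, strand[i], start, end, t, float(expr[i]))
            )
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "strand", "start", "end", "tss", "expr_rate"],
    ).astype({"start": np.int64, "end": np.int64, "tss": np.int64})

    island_rows, site_rows = [], []
    lo_n, hi_n = sites_per_island
    lo_s, hi_s = site_spacing
    for chrom, n_genes in chrom_plan:
        sub = genes[genes["chrom"] == chrom].reset_index(drop=True)
        host_idx = np.sort(rng.choice(n_genes, size=n_islands_per_chrom, replace=False))
        near = rng.random(n_islands_per_chrom) < island_near_tss_prob
        for k, gi in enumerate(host_idx):
            tss = int(sub.loc[gi, "tss"])
            n_sites = int(rng.integers(lo_n, hi_n + 1))
            rel = np.concatenate(
                [[0], np.cumsum(rng.integers(lo_s, hi_s + 1, n_sites - 1))]
            ).astype(np.int64)
            span = int(rel[-1]) + 2  # include the G of the last CpG
            if near[k]:
                mid = tss + int(rng.integers(-2500, 2501))
                host = str(sub.loc[gi, "gene_id"])
            else:
                mid = tss + gene_spacing // 2  # mid-slot, >4 kb from any TSS
                host = ""
            start = mid - span // 2
            end = start + span
            assay = rng.random(n_sites) < assayable_fraction
            iid = f"{chrom}_isl{k:05d}"
            island_rows.append((iid, chrom, start, end, host))
            for pos, a in zip(start + rel, assay):
                site_rows.append((iid, chrom, int(pos), bool(a)))

    islands = pd.DataFrame(
        island_rows, columns=["island_id", "chrom", "start", "end", "host_gene_id"]
    ).astype({"start": np.int64, "end": np.int64})
    # bidirectional perturbation: a small random subset of X islands gains
    # methylation on the Cre+ Xi instead of losing it
    is_x = (islands["chrom"] == X_CHROM).to_numpy()
    hyper = np.zeros(len(islands), dtype=bool)
    hyper[is_x] = rng.random(int(is_x.sum())) < hyper_fraction
    islands["hyper"] = hyper

    sites = pd.DataFrame(site_rows, columns=["island_id", "chrom", "pos", "assayable"])
    sites = sites.astype({"pos": np.int64, "assayable": bool})

    methylome = _build_methylome(
        genes, islands, sites,
        p_meth_auto, p_meth_xa, p_meth_xi,
        demeth_max, demeth_e50, demeth_h, hyper_boost,
    )

    params = {
        "seed": int(seed),
        "n_autosomal_genes": int(n_autosomal_genes),
        "n_x_genes": int(n_x_genes),
        "n_islands_per_chrom": int(n_islands_per_chrom),
        "expr_lognormal_params": [float(mu), float(sigma)],
        "assayable_fraction": float(assayable_fraction),
        "n_autosomes": int(n_autosomes),
        "island_near_tss_prob": float(island_near_tss_prob),
        "gene_spacing": int(gene_spacing),
        "gene_length": int(gene_length),
        "sites_per_island": [int(lo_n), int(hi_n)],
        "site_spacing": [int(lo_s), int(hi_s)],
        "p_meth_auto": float(p_meth_auto),
        "p_meth_xa": float(p_meth_xa),
        "p_meth_xi": float(p_meth_xi),
        "demeth_max": float(demeth_max),
        "demeth_e50": float(demeth_e50),
        "demeth_h": float(demeth_h),
        "hyper_fraction": float(hyper_fraction),
        "hyper_boost": float(hyper_boost),
    }
    fixture = GenomeFixture(chrom_lengths, genes, islands, sites,
                            methylome, params)
    fixture.validate()
    return fixture


def _build_methylome(genes, islands, sites, p_auto, p_xa, p_xi,
                     demeth_max, demeth_e50, demeth_h, hyper_boost) -> MethylomeState:
    n = len(sites)
    on_x = (sites["chrom"] == X_CHROM).to_numpy()
    auto = np.where(~on_x, p_auto, 0.0)
    xa = np.where(on_x, p_xa, 0.0)
    xi_neg = np.where(on_x, p_xi, 0.0)

    expr_by_gene = dict(zip(genes["gene_id"], genes["expr_rate"]))
    xi_factor = {}
    for row in islands.itertuples(index=False):
        if row.chrom != X_CHROM:
            continue
        if row.hyper:
            xi_factor[row.island_id] = (p_xi + hyper_boost * (1 - p_xi)) / p_xi
        elif row.host_gene_id:
            d = demeth_max * hill(expr_by_gene[row.host_gene_id], demeth_e50, demeth_h)
            xi_factor[row.island_id] = 1.0 - d
    factor = sites["island_id"].map(lambda i: xi_factor.get(i, 1.0)).to_numpy(float)
    xi_pos = np.clip(xi_neg * factor, 0.0, 1.0)

    probs = {
        CRE_NEG: {"auto": auto, "xa": xa, "xi": xi_neg},
        CRE_POS: {"auto": auto.copy(), "xa": xa.copy(), "xi": xi_pos},
    }
    state = MethylomeState(probs)
    state.validate()
    return state


# ---------------------------------------------------------------------------
# fixture IO: BED + TSV sidecars + JSON manifest, lossless round trip
# ---------------------------------------------------------------------------

_METH_COLS = [
    ("cre_neg", CRE_NEG, "auto"), ("cre_neg", CRE_NEG, "xa"), ("cre_neg", CRE_NEG, "xi"),
    ("cre_pos", CRE_POS, "auto"), ("cre_pos", CRE_POS, "xa"), ("cre_pos", CRE_POS, "xi"),
]


def write_fixture(fixture: GenomeFixture, out_dir) -> dict:
    """Write a fixture as BED + TSV sidecars + a JSON manifest.

    Genes go to BED6 (name = gene_id, score 0) with expression rates in a TSV
    sidecar; islands to BED4 with CpG site offsets, assayability and the
    methylome in TSV sidecars.  The files round-trip losslessly through
    :func:`read_fixture`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("genes_bed", "genes.bed"), ("expression", "gene_expression.tsv"),
        ("islands_bed", "islands.bed"), ("islands_meta", "islands_meta.tsv"),
        ("cpg_sites", "cpg_sites.tsv"), ("methylome", "methylome.tsv"),
        ("manifest", "fixture_manifest.json"),
    ]}

    bed6 = fixture.genes[["chrom", "start", "end", "gene_id"]].copy()
    bed6["score"] = 0
    bed6["strand"] = fixture.genes["strand"]
    bed6.to_csv(paths["genes_bed"], sep="\t", header=False, index=False)
    fixture.genes[["gene_id", "expr_rate"]].to_csv(
        paths["expression"], sep="\t", index=False, float_format="%.17g")

    fixture.islands[["chrom", "start", "end", "island_id"]].to_csv(
        paths["islands_bed"], sep="\t", header=False, index=False)
    fixture.islands[["island_id", "host_gene_id", "hyper"]].to_csv(
        paths["islands_meta"], sep="\t", index=False)

    start_by_island = dict(zip(fixture.islands["island_id"], fixture.islands["start"]))
    site_tab = fixture.sites.copy()
    site_tab["offset"] = site_tab["pos"] - site_tab["island_id"].map(start_by_island)
    site_tab[["island_id", "offset", "assayable"]].to_csv(
        paths["cpg_sites"], sep="\t", index=False)

    meth = site_tab[["island_id", "offset"]].copy()
    for col, cond, allele in _METH_COLS:
        meth[f"{col}_{allele}"] = fixture.methylome.probs[cond][allele]
    meth.to_csv(paths["methylome"], sep="\t", index=False, float_format="%.17g")

    manifest = {"chroms": list(fixture.chrom_lengths),
                "chrom_lengths": fixture.chrom_lengths, "params": fixture.params}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("fixture written to %s", out)
    return {k: str(v) for k, v in paths.items()}


def read_fixture(in_dir) -> GenomeFixture:
    """Reconstruct a :class:`GenomeFixture` written by :func:`write_fixture`."""
    d = Path(in_dir)
    manifest = json.loads((d / "fixture_manifest.json").read_text())
    order = manifest.get("chroms", list(manifest["chrom_lengths"]))
    chrom_lengths = {k: int(manifest["chrom_lengths"][k]) for k in order}

    genes = read_gene_bed(d / "genes.bed")
    expr = pd.read_csv(d / "gene_expression.tsv", sep="\t",
                       float_precision="round_trip")
    genes = genes.merge(expr, on="gene_id", how="left")
    genes = genes[["gene_id", "chrom", "strand", "start", "end", "tss", "expr_rate"]]

    islands = read_island_bed(d / "islands.bed")
    meta = pd.read_csv(d / "islands_meta.tsv", sep="\t",
                       dtype={"island_id": str, "host_gene_id": str})
    if len(meta):
        meta["host_gene_id"] = meta["host_gene_id"].fillna("")
        meta["hyper"] = meta["hyper"].astype(bool)
    else:
        meta = pd.DataFrame(columns=["island_id", "host_gene_id", "hyper"])
    islands = islands.merge(meta, on="island_id", how="left") if len(islands) else \
        pd.DataFrame(columns=["island_id", "chrom", "start", "end", "host_gene_id", "hyper"])
    if len(islands):
        islands = islands[["island_id", "chrom", "start", "end", "host_gene_id", "hyper"]]
        islands = islands.astype({"start": np.int64, "end": np.int64, "hyper": bool})
        islands["host_gene_id"] = islands["host_gene_id"].fillna("")

    site_tab = pd.read_csv(d / "cpg_sites.tsv", sep="\t")
    if len(site_tab):
        start_by_island = dict(zip(islands["island_id"], islands["start"]))
        chrom_by_island = dict(zip(islands["island_id"], islands["chrom"]))
        sites = pd.DataFrame({
            "island_id": site_tab["island_id"],
            "chrom": site_tab["island_id"].map(chrom_by_island),
            "pos": (site_tab["offset"] + site_tab["island_id"].map(start_by_island)).astype(np.int64),
            "assayable": site_tab["assayable"].astype(bool),
        })
    else:
        sites = pd.DataFrame(columns=["island_id", "chrom", "pos", "assayable"]).astype(
            {"pos": np.int64, "assayable": bool})

    meth_tab = pd.read_csv(d / "methylome.tsv", sep="\t",
                           float_precision="round_trip")
    probs = {CRE_NEG: {}, CRE_POS: {}}
    for col, cond, allele in _METH_COLS:
        key = f"{col}_{allele}"
        probs[cond][allele] = meth_tab[key].to_numpy(float) if len(meth_tab) else np.empty(0)
    methylome = MethylomeState(probs)

    return GenomeFixture(chrom_lengths, genes, islands, sites, methylome,
                         manifest["params"])


def read_gene_bed(path) -> pd.DataFrame:
    """Read a BED6 gene annotation; derives the TSS from the strand convention."""
    try:
        bed = pd.read_csv(path, sep="\t", header=None,
                          names=["chrom", "start", "end", "gene_id", "score", "strand"])
    except pd.errors.EmptyDataError:
        bed = pd.DataFrame(columns=["chrom", "start", "end", "gene_id", "score", "strand"])
    bed = bed.astype({"start": np.int64, "end": np.int64}) if len(bed) else bed
    tss = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1) if len(bed) else []
    out = bed[["gene_id", "chrom", "strand", "start", "end"]].copy()
    out["tss"] = np.asarray(tss, dtype=np.int64) if len(bed) else np.empty(0, np.int64)
    return out


def read_island_bed(path) -> pd.DataFrame:
    try:
        bed = pd.read_csv(path, sep="\t", header=None,
                          names=["chrom", "start", "end", "island_id"])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["island_id", "chrom", "start", "end"])
    bed = bed.astype({"start": np.int64, "end": np.int64})
    return bed[["island_id", "chrom", "start", "end"]]
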