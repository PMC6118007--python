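"""In-silico methylation-dependent restriction digestion (MeD-seq style).

The enzyme model places a blunt double-strand break a fixed number of
nucleotides downstream of each methylated cytosine on its own strand.  For a
CpG methylated on both strands (plus-strand C at position c) the two breaks
fall at the half-open boundaries ``c - cut_offset + 1`` and
``c + cut_offset + 1``, releasing a fragment of exactly ``2 * cut_offset``
bp — 32 bp at the default offset of 16.  Hemimethylated CpGs cut only one
strand and release no sized fragment; non-assayable sites (the enzyme
interrogates roughly half of all CpGs) never cut.

When methylated CpGs sit closer together than a fragment length, the breaks
interleave and the inter-cut pieces come out short; size selection then
removes them, so closely spaced sites need no special casing.  Fragments are
assigned to the CpG island containing their midpoint and tallied per island
per sample.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CRE_NEG, CRE_POS, X_CHROM, GenomeFixture

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DigestionModel:
    """Cut geometry, size-selection window and capture efficiency."""

    cut_offset: int = 16
    size_window: tuple = (27, 37)
    capture_efficiency: float = 1.0

    def __post_init__(self):
        if self.cut_offset < 1:
            raise ValueError("cut_offset must be >= 1")
        lo, hi = self.size_window
        if lo > hi:
            raise ValueError("size window min must be <= max")
        if not (0 <= self.capture_efficiency <= 1):
            raise ValueError("capture_efficiency must be a probability")


@dataclass(frozen=True)
class Fragment:
    """A digestion product, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("fragment length must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Lower-median position for even lengths."""
        return self.start + (self.length - 1) // 2


@dataclass
class IslandCountMatrix:
    """Per-island fragment counts (islands x samples) with sample metadata."""

    counts: pd.DataFrame
    samples: pd.DataFrame
    background: pd.Series = field(default_factory=lambda: pd.Series(dtype=np.int64))

    def condition_samples(self, condition: str) -> list:
        return list(self.samples.loc[self.samples["condition"] == condition, "sample_id"])


def _digest_core(gpos: np.ndarray, cut: int) -> tuple:
    """Fragments released around sorted methylated site positions.

    Returns (starts, ends) of the unique inter-break intervals that contain
    at least one methylated site; an isolated site yields exactly
    [c - cut + 1, c + cut + 1).
    """
    if len(gpos) == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e
    bounds = np.unique(np.concatenate([gpos - cut + 1, gpos + cut + 1]))
    j = np.searchsorted(bounds, gpos, side="right") - 1
    keep = np.ones(len(j), dtype=bool)
    keep[1:] = j[1:] != j[:-1]  # several close sites can share one piece
    j = j[keep]
    return bounds[j], bounds[j + 1]


def _chrom_offsets(chrom_lengths: dict, gap: int = 1_000) -> dict:
    offsets, acc = {}, 0
    for chrom, length in chrom_lengths.items():
        offsets[chrom] = acc
        acc += length + gap
    return offsets


def digest_methylome(
    fixture: GenomeFixture,
    realized_methylation: dict,
    model: DigestionModel | None = None,
) -> list:
    """Digest realized methylation states into fragments.

    ``realized_methylation`` maps an allele-copy label to binary states
    aligned with ``fixture.sites``: either a 1-D array of symmetric CpG
    methylation states, or a (n_sites, 2) array of per-strand states (a
    fragment requires methylation on both strands).  One fragment is emitted
    per symmetrically methylated, assayable CpG per allele copy; fragments
    that would extend past a chromosome end are dropped with a warning.
    """
    model = model or DigestionModel()
    sites = fixture.sites
    offsets = _chrom_offsets(fixture.chrom_lengths)
    off = sites["chrom"].map(offsets).to_numpy(np.int64)
    gpos = sites["pos"].to_numpy(np.int64) + off
    assayable = sites["assayable"].to_numpy(bool)

    chrom_names = list(fixture.chrom_lengths)
    chrom_starts = np.array([offsets[c] for c in chrom_names], dtype=np.int64)
    chrom_ends = chrom_starts + np.array(
        [fixture.chrom_lengths[c] for c in chrom_names], dtype=np.int64)

    fragments = []
    n_clipped = 0
    for label, states in realized_methylation.items():
        states = np.asarray(states)
        if states.ndim == 2:
            sym = states[:, 0].astype(bool) & states[:, 1].astype(bool)
        else:
            sym = states.astype(bool)
        if sym.shape[0] != len(sites):
            raise ValueError(f"states for {label!r} must cover every CpG site")
        meth_gpos = np.sort(gpos[sym & assayable])
        starts, ends = _digest_core(meth_gpos, model.cut_offset)
        ci = np.searchsorted(chrom_starts, starts, side="right") - 1
        ok = (starts >= chrom_starts[ci]) & (ends <= chrom_ends[ci])
        n_clipped += int((~ok).sum())
        for s, e, c in zip(starts[ok], ends[ok], ci[ok]):
            chrom = chrom_names[c]
            fragments.append(Fragment(chrom, int(s - offsets[chrom]),
                                      int(e - offsets[chrom])))
    if n_clipped:
        logger.warning("dropped %d fragments clipped at chromosome bounds", n_clipped)
    return fragments


def size_select(fragments, window=(27, 37)) -> list:
    """Keep fragments with window min <= length <= max, preserving order."""
    lo, hi = window
    return [f for f in fragments if lo <= f.length <= hi]


def count_island_fragments(fragments, islands: pd.DataFrame) -> tuple:
    """Tally fragments per island by midpoint containment.

    ``islands`` needs island_id, chrom, start, end and must be
    non-overlapping within each chromosome (validated).  Returns a
    (per-island count Series, background count) pair; a fragment whose
    midpoint lies in no island goes to the background tally.
    """
    _validate_non_overlapping(islands)
    counts = pd.Series(0, index=pd.Index(islands["island_id"]), dtype=np.int64)
    background = 0
    by_chrom = {
        chrom: sub.sort_values("start")
        for chrom, sub in islands.groupby("chrom", sort=False)
    }
    for frag in fragments:
        sub = by_chrom.get(frag.chrom)
        hit = None
        if sub is not None:
            starts = sub["start"].to_numpy()
            i = int(np.searchsorted(starts, frag.midpoint, side="right")) - 1
            if i >= 0 and frag.midpoint < int(sub["end"].iloc[i]):
                hit = sub["island_id"].iloc[i]
        if hit is None:
            background += 1
        else:
            counts[hit] += 1
    return counts, background


def _validate_non_overlapping(islands: pd.DataFrame) -> None:
    for chrom, sub in islands.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(sub) > 1 and np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping islands on {chrom}")


def simulate_medseq_samples(
    fixture: GenomeFixture,
    n_replicates_per_condition: int = 2,
    n_cells: int = 50,
    model: DigestionModel | None = None,
    depth_scale: float = 1.0,
    seed: int = 0,
) -> IslandCountMatrix:
    """Simulate MeD-seq island counts for Cre+ and Cre- replicates.

    Per sample, per cell and per allele copy (two autosomal copies, one Xa,
    one Xi), binary symmetric methylation is drawn i.i.d. from the fixture's
    methylome probabilities (Cre+ samples use the perturbed Xi values), the
    genome copy is digested, fragments are size-selected, thinned by
    ``capture_efficiency * depth_scale``, and tallied per island.  Expected
    island abundance is therefore proportional to the summed per-allele
    methylation probabilities over the island's assayable sites.
    """
    if n_replicates_per_condition < 1 or n_cells < 1:
        raise ValueError("replicate and cell counts must be >= 1")
    if depth_scale <= 0 or depth_scale > 1:
        raise ValueError("depth_scale must be in (0, 1]")
    model = model or DigestionModel()
    eff = model.capture_efficiency * depth_scale

    sites = fixture.sites
    offsets = _chrom_offsets(fixture.chrom_lengths)
    off = sites["chrom"].map(offsets).to_numpy(np.int64) if len(sites) else np.empty(0, np.int64)
    gpos_all = sites["pos"].to_numpy(np.int64) + off
    assayable = sites["assayable"].to_numpy(bool)
    on_x = (sites["chrom"] == X_CHROM).to_numpy()

    # only assayable sites can cut; restrict once
    auto_idx = np.flatnonzero(~on_x & assayable)
    x_idx = np.flatnonzero(on_x & assayable)
    gpos_auto, gpos_x = gpos_all[auto_idx], gpos_all[x_idx]

    islands = fixture.islands
    _validate_non_overlapping(islands)
    isl_starts = islands["start"].to_numpy(np.int64) + \
        islands["chrom"].map(offsets).to_numpy(np.int64)
    isl_ends = islands["end"].to_numpy(np.int64) + \
        islands["chrom"].map(offsets).to_numpy(np.int64)
    order = np.argsort(isl_starts)
    isl_starts, isl_ends = isl_starts[order], isl_ends[order]
    isl_pos_to_id = islands["island_id"].to_numpy()[order]

    probs = fixture.methylome.probs
    lo, hi = model.size_window
    cut = model.cut_offset

    rng = np.random.default_rng(seed)
    cols, meta, background = {}, [], {}
    for condition in (CRE_POS, CRE_NEG):
        p_auto = probs[condition]["auto"][auto_idx]
        p_xa = probs[condition]["xa"][x_idx]
        p_xi = probs[condition]["xi"][x_idx]
        for rep in range(1, n_replicates_per_condition + 1):
            sid = f"med_{'pos' if condition == CRE_POS else 'neg'}_{rep}"
            tally = np.zeros(len(islands), dtype=np.int64)
            bg = 0
            for gpos_class, p in ((gpos_auto, p_auto), (gpos_auto, p_auto),
                                  (gpos_x, p_xa), (gpos_x, p_xi)):
                if len(gpos_class) == 0 or not p.any():
                    continue
                meth = rng.random((n_cells, len(p))) < p
                for cell in range(n_cells):
                    mpos = gpos_class[meth[cell]]
                    if len(mpos) == 0:
                        continue
                    starts, ends = _digest_core(mpos, cut)
                    lengths = ends - starts
                    keep = (lengths >= lo) & (lengths <= hi)
                    starts, ends = starts[keep], ends[keep]
                    if eff < 1 and len(starts):
                        sel = rng.random(len(starts)) < eff
                        starts, ends = starts[sel], ends[sel]
                    if not len(starts):
                        continue
                    mids = starts + (ends - starts - 1) // 2
                    ii = np.searchsorted(isl_starts, mids, side="right") - 1
                    inside = (ii >= 0) & (mids < isl_ends[np.clip(ii, 0, None)])
                    bg += int((~inside).sum())
                    tally += np.bincount(ii[inside], minlength=len(islands))
            # map from start-sorted order back to fixture island order
            col = np.zeros(len(islands), dtype=np.int64)
            col[order] = tally
            cols[sid] = col
            background[sid] = bg
            meta.append((sid, condition, rep))

    counts = pd.DataFrame(cols, index=pd.Index(islands["island_id"]))
    samples = pd.DataFrame(meta, columns=["sample_id", "condition", "replicate"])
    return IslandCountMatrix(counts, samples, pd.Series(background, dtype=np.int64))
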