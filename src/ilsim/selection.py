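"""Selection regions, the selection index, and truncation selection.

Marker selection operates on *regions*: the genome is partitioned into 10
complete chromosomes, 20 chromosome halves, or 100 target segments.  The
selection index of an individual for a region is

    i = (donor dosage inside the region) + (1 - donor dosage outside it),

i.e. donor-genome proportion of the region plus recipient-genome
proportion of the genetic background, with equal unit weights.  The index
ranges over [0, 2]: the recipient scores 1.0 and a genotype homozygous
donor across the region with a clean recipient background scores 2.0.
The weights are exposed for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_model import GeneticMap, Genotype

__all__ = [
    "SelectionRegion",
    "region_partition",
    "selection_index",
    "selection_index_matrix",
    "select_per_region",
    "select_final_ils",
]

REGION_KINDS = ("chromosome", "half", "segment")


@dataclass(frozen=True, eq=False)  # identity equality: usable as dict key
class SelectionRegion:
    """A contiguous genome region used for truncation selection.

    ``marker_slice`` is the global marker-index slice of the region (marker
    order is chromosome-major, so chromosomes, halves and segments are all
    contiguous).  The background is the complement: every marker outside
    ``marker_slice`` genome-wide.
    """

    kind: str
    index: int
    chromosome: int
    start: float  # cM, within chromosome, half-open [start, end)
    end: float
    marker_slice: slice

    def contains(self, other: "SelectionRegion") -> bool:
        """True if ``other`` lies within this region (same chromosome)."""
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )

    def n_markers(self) -> int:
        return self.marker_slice.stop - self.marker_slice.start


def region_partition(gmap: GeneticMap, kind: str) -> list[SelectionRegion]:
    """Partition the genome into selection regions of the given kind.

    ``kind`` is one of ``"chromosome"`` (10 regions with the default map),
    ``"half"`` (20 regions, each chromosome split at chrom_length / 2) or
    ``"segment"`` (100 regions, the target segments).
    """
    if kind not in REGION_KINDS:
        raise ValueError(f"unknown region kind {kind!r}; expected one of {REGION_KINDS}")
    m = gmap.n_markers_per_chrom
    regions: list[SelectionRegion] = []
    if kind == "chromosome":
        for c in range(gmap.n_chromosomes):
            regions.append(
                SelectionRegion(kind, c, c, 0.0, gmap.chrom_length, gmap.chrom_slice(c))
            )
    elif kind == "half":
        half = m // 2
        for c in range(gmap.n_chromosomes):
            base = c * m
            regions.append(
                SelectionRegion(
                    kind, 2 * c, c, 0.0, gmap.chrom_length / 2, slice(base, base + half)
                )
            )
            regions.append(
                SelectionRegion(
                    kind,
                    2 * c + 1,
                    c,
                    gmap.chrom_length / 2,
                    gmap.chrom_length,
                    slice(base + half, base + m),
                )
            )
    else:  # segment
        for s in range(gmap.n_segments):
            c, lo, hi = gmap.segment_bounds(s)
            regions.append(SelectionRegion(kind, s, c, lo, hi, gmap.segment_slice(s)))
    return regions


def selection_index(
    g: Genotype,
    region: SelectionRegion,
    w_region: float = 1.0,
    w_background: float = 1.0,
) -> float:
    """Selection index of one individual for one region (range [0, 2])."""
    d = g.dosage()
    return float(
        _index_from_dosage(d[None, :], region, w_region, w_background)[0]
    )


def _index_from_dosage(
    dosage: np.ndarray,
    region: SelectionRegion,
    w_region: float = 1.0,
    w_background: float = 1.0,
) -> np.ndarray:
    """Vectorised index for a (N, M) dosage matrix."""
    M = dosage.shape[1]
    nr = region.n_markers()
    if nr == 0:
        raise ValueError(f"empty selection region {region}")
    if nr == M:
        # degenerate single-region partition: no background markers
        return w_region * dosage.mean(axis=1) + w_background
    reg = dosage[:, region.marker_slice].sum(axis=1)
    tot = dosage.sum(axis=1)
    return w_region * reg / nr + w_background * (1.0 - (tot - reg) / (M - nr))


def selection_index_matrix(
    dosage: np.ndarray, regions: Sequence[SelectionRegion]
) -> np.ndarray:
    """Index of every individual for every region: (N, n_regions) array."""
    return np.column_stack([_index_from_dosage(dosage, r) for r in regions])


def _top_m(scores: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of the m highest scores; exact ties broken by a seeded draw.

    Returned in decreasing score order.
    """
    if m > scores.size:
        raise ValueError(f"cannot select {m} from {scores.size} candidates")
    tie = rng.random(scores.size)
    order = np.lexsort((tie, scores))[::-1]
    return order[:m]


def select_per_region(
    pop: Sequence[Genotype],
    regions: Sequence[SelectionRegion],
    m_per_region: int,
    rng: np.random.Generator,
) -> dict[SelectionRegion, list[Genotype]]:
    """For each region independently, the m individuals with the highest
    selection index.  The same individual may be selected for several
    regions; exact ties are broken by a seeded uniform draw.
    """
    if len(pop) == 0:
        raise ValueError("empty population")
    dosage = np.stack([g.dosage() for g in pop])
    out: dict[SelectionRegion, list[Genotype]] = {}
    for r in regions:
        scores = _index_from_dosage(dosage, r)
        idx = _top_m(scores, m_per_region, rng)
        out[r] = [pop[i] for i in idx]
    return out


def select_final_ils(
    line_h0: np.ndarray,
    line_h1: np.ndarray,
    line_chains: Sequence[Sequence[SelectionRegion]],
    gmap: GeneticMap,
    rng: np.random.Generator,
):
    """Assign one line to each target segment by the segment index i_S.

    Parameters
    ----------
    line_h0, line_h1 : (n_lines, M) haplotype matrices of the candidate lines.
    line_chains : per-line sequence of ancestral selection regions
        The chain of regions the line's lineage was selected for over the
        backcross generations (empty when the scheme had no branching).

    For each target segment the candidate pool consists of the lines whose
    ancestral chain includes a region containing that segment — the
    sub-population that was developed for the genome region the segment
    belongs to.  If no line's lineage covers a segment the whole line set
    is used.  Segments are processed in genome order; each takes the
    not-yet-assigned line with the highest segment index (exact ties broken
    by a seeded draw), so the resulting library consists of distinct lines
    whenever the pools allow it.

    Returns
    -------
    (n_segments,) int array of selected line indices, one per segment.
    """
    n_lines = line_h0.shape[0]
    if n_lines == 0:
        raise ValueError("no candidate lines")
    dosage = (line_h0.astype(np.float64) + line_h1) / 2.0
    segments = region_partition(gmap, "segment")
    n_seg = len(segments)

    # unique ancestral regions (by identity), containment matrix vs segments
    uniq: list[SelectionRegion] = []
    key_of: dict[int, int] = {}
    for chain in line_chains:
        for r in chain:
            if r is not None and id(r) not in key_of:
                key_of[id(r)] = len(uniq)
                uniq.append(r)
    if uniq:
        member = np.zeros((n_lines, len(uniq)), dtype=bool)
        for i, chain in enumerate(line_chains):
            for r in chain:
                if r is not None:
                    member[i, key_of[id(r)]] = True
        cont = np.array(
            [[r.contains(seg) for seg in segments] for r in uniq], dtype=bool
        )
        in_pool = member @ cont  # (n_lines, n_seg)
    else:
        in_pool = np.zeros((n_lines, n_seg), dtype=bool)

    chosen = np.empty(n_seg, dtype=np.int64)
    used = np.zeros(n_lines, dtype=bool)
    for s, seg in enumerate(segments):
        pool = np.flatnonzero(in_pool[:, s])
        if pool.size == 0:
            pool = np.arange(n_lines)
        avail = pool[~used[pool]]
        if avail.size == 0:  # pool exhausted: fall back to re-using lines
            avail = pool
        scores = _index_from_dosage(dosage[avail], seg)
        pick = avail[_top_m(scores, 1, rng)[0]]
        chosen[s] = pick
        used[pick] = True
    return chosen
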