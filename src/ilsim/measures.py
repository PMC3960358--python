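"""Population measures for evaluating a final introgression-line set.

Nine measures characterise an IL population:

==========  ==============================================================
C_D         donor genome coverage, % of markers carried by >= 1 IL
depth       mean number of ILs carrying the donor allele, per marker
N_D         number of disjunct genome segments across the population
R           resolution in cM: total map length / N_D
S_D         mean number of donor segments per IL
L_D         mean donor-segment length per IL in cM
lambda_D    mean total donor genome proportion, %
Z_C         mean donor proportion of the carrier chromosome, %
Z_S         mean donor proportion of the assigned target segment, %
==========  ==============================================================

Carrier status (coverage, depth, donor segments) is presence-based: a
heterozygous marker counts as carrying the donor allele.  Donor
*proportions* (lambda_D, Z_C, Z_S) are allele-dosage based: a heterozygous
marker contributes 1/2.  N_D is the population-pattern partition count:
overlaying the donor/recipient state changes of every haplotype of every
IL on the marker grid, it counts the maximal intervals within which the
full population genotype pattern is constant (per chromosome, distinct
internal breakpoints + 1, summed over chromosomes), so R * N_D equals the
total map length exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .genome_model import GeneticMap, Genotype

__all__ = [
    "ILPopulation",
    "MeasureReport",
    "coverage",
    "depth",
    "disjunct_segments",
    "resolution",
    "segment_stats",
    "donor_proportions",
    "evaluate_population",
    "graphical_genotype",
]

MEASURE_COLUMNS = [
    "C_D",
    "depth",
    "N_D",
    "R",
    "S_D",
    "L_D",
    "lambda_D",
    "Z_C",
    "Z_S",
    "HT",
]


@dataclass
class ILPopulation:
    """A final introgression population: one IL per target segment.

    ``h0``/``h1`` are (n_ils, n_markers) haplotype matrices; IL ``i`` is
    assigned target segment ``assigned_segment[i]``.  The same source line
    may back more than one IL when it is the best candidate for several
    segments.
    """

    h0: np.ndarray
    h1: np.ndarray
    assigned_segment: np.ndarray
    gmap: GeneticMap
    line_method: str = "DH"
    source_line: np.ndarray | None = None

    def __post_init__(self):
        self.h0 = np.asarray(self.h0, dtype=np.uint8)
        self.h1 = np.asarray(self.h1, dtype=np.uint8)
        self.assigned_segment = np.asarray(self.assigned_segment, dtype=np.int64)
        if self.h0.shape != self.h1.shape:
            raise ValueError("haplotype matrices must have the same shape")
        if self.h0.shape[0] != self.assigned_segment.shape[0]:
            raise ValueError("one assigned segment per IL required")

    @property
    def n_ils(self) -> int:
        return self.h0.shape[0]

    def carrier(self) -> np.ndarray:
        """(n_ils, M) boolean: IL carries >= 1 donor allele at the marker."""
        return (self.h0 | self.h1).astype(bool)

    def dosage(self) -> np.ndarray:
        """(n_ils, M) donor allele dosage in {0, 0.5, 1}."""
        return (self.h0.astype(np.float64) + self.h1) / 2.0

    def genotypes(self) -> Iterator[Genotype]:
        for i in range(self.n_ils):
            yield Genotype(
                np.stack([self.h0[i], self.h1[i]]),
                id=f"IL-{i}",
                generation=self.line_method,
            )


@dataclass
class MeasureReport:
    """One evaluated IL population: the nine measures plus the HT count."""

    C_D: float
    depth: float
    N_D: int
    R: float
    S_D: float
    L_D: float
    lambda_D: float
    Z_C: float
    Z_S: float
    HT: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in MEASURE_COLUMNS}


def coverage(pop: ILPopulation) -> float:
    """Donor genome coverage C_D: % of markers carried by at least one IL."""
    return 100.0 * float(pop.carrier().any(axis=0).mean())


def depth(pop: ILPopulation, covered_only: bool = False) -> float:
    """Mean number of ILs carrying the donor allele per marker.

    With ``covered_only`` the mean is taken over donor-covered markers
    only instead of all markers (nearly identical when coverage ~ 100%).
    """
    per_marker = pop.carrier().sum(axis=0)
    if covered_only:
        per_marker = per_marker[per_marker > 0]
        if per_marker.size == 0:
            return 0.0
    return float(per_marker.mean())


def disjunct_segments(pop: ILPopulation, donor_only: bool = False) -> int:
    """Number of disjunct genome segments N_D across the population.

    Overlays the donor/recipient state changes of every haplotype of every
    IL; per chromosome N_D is the number of marker-grid intervals on which
    the population pattern is constant (distinct internal breakpoints + 1).
    With ``donor_only`` the count is restricted to intervals carried by at
    least one IL (an alternative reading of the measure, for comparison).
    """
    gmap = pop.gmap
    rows = np.vstack([pop.h0, pop.h1])
    any_carrier = pop.carrier().any(axis=0)
    total = 0
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        block = rows[:, sl]
        brk = (block[:, 1:] != block[:, :-1]).any(axis=0)
        if not donor_only:
            total += int(brk.sum()) + 1
        else:
            # walk the intervals, count those containing donor alleles
            cuts = np.flatnonzero(brk) + 1
            starts = np.concatenate(([0], cuts))
            ends = np.concatenate((cuts, [block.shape[1]]))
            cov = any_carrier[sl]
            total += int(sum(cov[s:e].any() for s, e in zip(starts, ends)))
    return total


def resolution(pop: ILPopulation, n_d: int | None = None) -> float:
    """Resolution R in cM: total map length divided by N_D."""
    if n_d is None:
        n_d = disjunct_segments(pop)
    return pop.gmap.total_length / n_d


def segment_stats(pop: ILPopulation) -> tuple[float, float]:
    """(S_D, L_D): mean donor-segment count and length per IL.

    A donor segment is a maximal run of consecutive markers (within one
    chromosome) at which the IL carries at least one donor allele; its
    length is run length x marker spacing.  S_D averages the run count
    over all ILs (zero-segment ILs contribute 0); L_D averages each IL's
    mean segment length over the ILs that have at least one segment.
    """
    gmap = pop.gmap
    car = pop.carrier()
    m = gmap.n_markers_per_chrom
    blocks = car.reshape(pop.n_ils, gmap.n_chromosomes, m)
    starts = blocks & ~np.pad(blocks, ((0, 0), (0, 0), (1, 0)))[:, :, :-1]
    runs_per_il = starts.sum(axis=(1, 2))
    carriers_per_il = car.sum(axis=1)
    s_d = float(runs_per_il.mean())
    has = runs_per_il > 0
    if not has.any():
        return s_d, float("nan")
    mean_len = carriers_per_il[has] / runs_per_il[has] * gmap.marker_spacing
    return s_d, float(mean_len.mean())


def donor_proportions(pop: ILPopulation) -> tuple[float, float, float]:
    """(lambda_D, Z_C, Z_S) in percent, dosage-based.

    lambda_D: mean genome-wide donor proportion over ILs; Z_C: mean donor
    proportion of each IL's carrier chromosome (the chromosome holding its
    assigned target segment); Z_S: mean donor proportion of the assigned
    target segment itself.
    """
    gmap = pop.gmap
    d = pop.dosage()
    lam = 100.0 * float(d.mean())
    zc = np.empty(pop.n_ils)
    zs = np.empty(pop.n_ils)
    per_chrom = gmap.n_segments_per_chrom
    for i, s in enumerate(pop.assigned_segment):
        zc[i] = d[i, gmap.chrom_slice(int(s) // per_chrom)].mean()
        zs[i] = d[i, gmap.segment_slice(int(s))].mean()
    return lam, 100.0 * float(zc.mean()), 100.0 * float(zs.mean())


def evaluate_population(pop: ILPopulation, ht: int = 0) -> MeasureReport:
    """Compute all nine measures for one IL population."""
    n_d = disjunct_segments(pop)
    s_d, l_d = segment_stats(pop)
    lam, zc, zs = donor_proportions(pop)
    return MeasureReport(
        C_D=coverage(pop),
        depth=depth(pop),
        N_D=n_d,
        R=resolution(pop, n_d),
        S_D=s_d,
        L_D=l_d,
        lambda_D=lam,
        Z_C=zc,
        Z_S=zs,
        HT=int(ht),
    )


def graphical_genotype(
    pop: ILPopulation,
    il_range: tuple[int, int] | None = None,
    chrom_range: tuple[int, int] | None = None,
    path: str | None = None,
):
    """Haplotype-resolved graphical genotype of (part of) the population.

    Returns the underlying matrix (two rows per IL over the selected
    marker columns; 1 = donor shown blue, 0 = recipient shown yellow).
    When ``path`` is given a PNG is also written.  ``il_range`` and
    ``chrom_range`` are half-open index ranges.
    """
    gmap = pop.gmap
    i0, i1 = il_range if il_range is not None else (0, pop.n_ils)
    c0, c1 = chrom_range if chrom_range is not None else (0, gmap.n_chromosomes)
    m = gmap.n_markers_per_chrom
    cols = slice(c0 * m, c1 * m)
    rows = np.empty((2 * (i1 - i0), cols.stop - cols.start), dtype=np.uint8)
    rows[0::2] = pop.h0[i0:i1, cols]
    rows[1::2] = pop.h1[i0:i1, cols]
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        fig, ax = plt.subplots(figsize=(10, max(2, (i1 - i0) * 0.12)))
        ax.imshow(
            rows,
            aspect="auto",
            interpolation="nearest",
            cmap=ListedColormap(["gold", "royalblue"]),
            vmin=0,
            vmax=1,
        )
        for c in range(c0 + 1, c1):
            ax.axvline((c - c0) * m - 0.5, color="black", lw=0.8)
        ax.set_xlabel("marker (chromosome-major)")
        ax.set_ylabel("haplotypes of ILs")
        ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return rows


def export_text_matrix(pop: ILPopulation, path: str) -> None:
    """Write the haplotype-resolved genotype matrix as tab-separated text."""
    rows = graphical_genotype(pop)
    np.savetxt(path, rows, fmt="%d", delimiter="\t")
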