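"""Genetic map construction and the stochastic machinery of meiosis.

The genome is a grid of biallelic markers (1 = donor allele, 0 = recipient
allele) on equally sized chromosomes.  Meiosis is simulated without
crossover interference: the number of crossovers per chromosome is Poisson
with mean equal to the map length in Morgans, crossover positions are
uniform on the chromosome, and the starting parental strand is chosen with
probability 1/2.  The recombination fraction between two markers d cM
apart therefore follows Haldane's mapping function
r = (1 - exp(-2 d / 100)) / 2.

Two APIs are provided: single-individual operations (`simulate_gamete`,
`cross`, `self_individual`, `make_dh`) working on :class:`Genotype`, and
vectorised batch equivalents (`meiosis_batch`, `cross_batch`, `self_batch`,
`dh_batch`) working on haplotype matrices, which the crossing-scheme engine
uses for speed.  Both draw from the same crossover process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneticMap",
    "Genotype",
    "build_map",
    "simulate_gamete",
    "cross",
    "self_individual",
    "make_dh",
    "donor_dosage",
    "meiosis_batch",
    "cross_batch",
    "self_batch",
    "dh_batch",
]


class MapConfigError(ValueError):
    """Raised when the requested map geometry is inconsistent."""


@dataclass(frozen=True)
class GeneticMap:
    """A multi-chromosome marker map with a tiling of target segments.

    Markers sit at segment-interior positions ``spacing/2, 3*spacing/2, ...``
    so that every target segment contains exactly
    ``segment_length / marker_spacing`` markers and no marker falls on a
    segment or chromosome-half boundary.

    Attributes
    ----------
    n_chromosomes : int
        Number of chromosomes (default 10).
    chrom_length : float
        Length of each chromosome in cM (default 200).
    marker_spacing : float
        Distance between adjacent markers in cM (default 1).
    segment_length : float
        Length of each target segment in cM (default 20).
    """

    n_chromosomes: int = 10
    chrom_length: float = 200.0
    marker_spacing: float = 1.0
    segment_length: float = 20.0
    # derived, filled in __post_init__
    chrom_positions: np.ndarray = field(default=None, repr=False, compare=False)
    n_markers_per_chrom: int = field(default=0, compare=False)
    n_markers: int = field(default=0, compare=False)

    def __post_init__(self):
        ratio_cs = self.chrom_length / self.segment_length
        if abs(ratio_cs - round(ratio_cs)) > 1e-9:
            raise MapConfigError(
                f"chrom_length ({self.chrom_length} cM) is not divisible by "
                f"segment_length ({self.segment_length} cM)"
            )
        ratio_sm = self.segment_length / self.marker_spacing
        if abs(ratio_sm - round(ratio_sm)) > 1e-9:
            raise MapConfigError(
                f"segment_length ({self.segment_length} cM) is not divisible "
                f"by marker_spacing ({self.marker_spacing} cM)"
            )
        m = int(round(self.chrom_length / self.marker_spacing))
        pos = (np.arange(m) + 0.5) * self.marker_spacing
        object.__setattr__(self, "chrom_positions", pos)
        object.__setattr__(self, "n_markers_per_chrom", m)
        object.__setattr__(self, "n_markers", m * self.n_chromosomes)

    # ---- geometry helpers -------------------------------------------------

    @property
    def total_length(self) -> float:
        """Total map length in cM."""
        return self.n_chromosomes * self.chrom_length

    @property
    def n_segments_per_chrom(self) -> int:
        return int(round(self.chrom_length / self.segment_length))

    @property
    def n_segments(self) -> int:
        return self.n_segments_per_chrom * self.n_chromosomes

    @property
    def markers_per_segment(self) -> int:
        return int(round(self.segment_length / self.marker_spacing))

    def chrom_slice(self, c: int) -> slice:
        """Global marker-index slice of chromosome ``c`` (0-based)."""
        m = self.n_markers_per_chrom
        return slice(c * m, (c + 1) * m)

    def segment_slice(self, s: int) -> slice:
        """Global marker-index slice of target segment ``s`` (0-based)."""
        k = self.markers_per_segment
        per = self.n_segments_per_chrom
        c, j = divmod(s, per)
        start = c * self.n_markers_per_chrom + j * k
        return slice(start, start + k)

    def segment_bounds(self, s: int) -> tuple[int, float, float]:
        """Return (chromosome, start cM, end cM) of segment ``s``, half-open."""
        per = self.n_segments_per_chrom
        c, j = divmod(s, per)
        return c, j * self.segment_length, (j + 1) * self.segment_length

    def segment_of_marker(self, global_idx: int) -> int:
        c, j = divmod(global_idx, self.n_markers_per_chrom)
        return c * self.n_segments_per_chrom + int(
            self.chrom_positions[j] // self.segment_length
        )

    @property
    def positions(self) -> np.ndarray:
        """Global array of within-chromosome cM positions (chromosome-major)."""
        return np.tile(self.chrom_positions, self.n_chromosomes)

    @property
    def chrom_index(self) -> np.ndarray:
        """Global array mapping marker index -> chromosome index."""
        return np.repeat(np.arange(self.n_chromosomes), self.n_markers_per_chrom)


def build_map(
    n_chromosomes: int = 10,
    chrom_length: float = 200.0,
    marker_spacing: float = 1.0,
    segment_length: float = 20.0,
) -> GeneticMap:
    """Build a :class:`GeneticMap`.

    The default call yields the maize model used throughout: 10 chromosomes
    of 200 cM, 2000 markers at 1 cM spacing (positions 0.5 ... 199.5 cM per
    chromosome) and 100 target segments of 20 cM tiling the genome.

    Raises
    ------
    MapConfigError
        If ``chrom_length`` is not a multiple of ``segment_length`` or
        ``segment_length`` is not a multiple of ``marker_spacing``.
    """
    return GeneticMap(n_chromosomes, chrom_length, marker_spacing, segment_length)


# ---------------------------------------------------------------------------
# Genotypes


@dataclass
class Genotype:
    """One individual: two haplotypes over the global marker grid.

    ``haplotypes`` has shape (2, n_markers) with values in {0, 1}
    (1 = donor allele).
    """

    haplotypes: np.ndarray
    id: str = ""
    generation: str = ""

    def __post_init__(self):
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 2 or h.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_markers)")
        if not np.isin(h, (0, 1)).all():
            raise ValueError("haplotype values must be 0 or 1")
        self.haplotypes = h

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def dosage(self) -> np.ndarray:
        """Per-marker donor allele dosage in {0, 0.5, 1}."""
        return self.haplotypes.mean(axis=0)

    def is_homozygous(self) -> bool:
        return bool((self.haplotypes[0] == self.haplotypes[1]).all())


def recipient_genotype(gmap: GeneticMap, id: str = "recipient") -> Genotype:
    """The fully homozygous recurrent parent (all-zero)."""
    return Genotype(np.zeros((2, gmap.n_markers), dtype=np.uint8), id=id, generation="P")


def donor_genotype(gmap: GeneticMap, id: str = "donor") -> Genotype:
    """The fully homozygous donor parent (all-one)."""
    return Genotype(np.ones((2, gmap.n_markers), dtype=np.uint8), id=id, generation="P")


def f1_genotype(gmap: GeneticMap, id: str = "F1") -> Genotype:
    """The F1 of donor x recipient: heterozygous at every marker."""
    h = np.zeros((2, gmap.n_markers), dtype=np.uint8)
    h[0] = 1
    return Genotype(h, id=id, generation="F1")


def donor_dosage(g: Genotype, markers=None) -> float:
    """Mean donor allele dosage of ``g`` over a marker index set.

    Heterozygous markers contribute 1/2.  ``markers`` may be a slice, an
    integer index array or a boolean mask; ``None`` means all markers.
    """
    h = g.haplotypes if markers is None else g.haplotypes[:, markers]
    if h.shape[1] == 0:
        raise ValueError("empty marker set")
    return float(h.mean())


# ---------------------------------------------------------------------------
# Meiosis — batch (vectorised) form


def meiosis_batch(
    h0: np.ndarray, h1: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one gamete for each of G parents.

    Parameters
    ----------
    h0, h1 : (G, n_markers) uint8 arrays
        The two haplotypes of each parent.
    rng : numpy Generator

    Returns
    -------
    (G, n_markers) uint8 array of gametes.

    Notes
    -----
    Per chromosome the crossover count is Poisson(chrom_length / 100) and
    crossover positions are i.i.d. uniform on (0, chrom_length); the
    starting strand is Bernoulli(1/2) and the active strand switches at
    every crossover.  At the marker grid this realises Haldane's
    no-interference model.
    """
    h0 = np.atleast_2d(h0)
    h1 = np.atleast_2d(h1)
    G, M = h0.shape
    m = gmap.n_markers_per_chrom
    L = gmap.chrom_length
    gamete = np.empty((G, M), dtype=np.uint8)
    mpos = gmap.chrom_positions
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        counts = rng.poisson(L / 100.0, G)
        total = int(counts.sum())
        pos = rng.uniform(0.0, L, total)
        owner = np.repeat(np.arange(G), counts)
        # interval index: crossover at p lies before markers j with mpos[j] > p
        bins = np.searchsorted(mpos, pos, side="left")
        cmat = np.bincount(owner * (m + 1) + bins, minlength=G * (m + 1)).reshape(
            G, m + 1
        )
        # crossovers strictly before marker j = cumsum over intervals 0..j
        parity = np.cumsum(cmat, axis=1)[:, :m] & 1
        start = rng.integers(0, 2, size=(G, 1))
        strand = (start + parity) & 1
        gamete[:, sl] = np.where(strand == 0, h0[:, sl], h1[:, sl])
    return gamete


def cross_batch(
    mh0, mh1, fh0, fh1, gmap: GeneticMap, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One offspring per (mother, father) pair: a gamete from each parent."""
    return meiosis_batch(mh0, mh1, gmap, rng), meiosis_batch(fh0, fh1, gmap, rng)


def backcross_batch(
    h0, h1, gmap: GeneticMap, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Backcross each parent to the fully homozygous recipient.

    Because the recipient is homozygous at every marker, its gamete is the
    all-zero vector and no meiosis needs to be simulated on the recipient
    side.
    """
    gam = meiosis_batch(h0, h1, gmap, rng)
    return gam, np.zeros_like(gam)


def self_batch(
    h0, h1, gmap: GeneticMap, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Self each parent: two independent gametes of the same individual."""
    return meiosis_batch(h0, h1, gmap, rng), meiosis_batch(h0, h1, gmap, rng)


def dh_batch(h0, h1, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """Doubled haploids: one gamete per parent, doubled.

    Returns the single haplotype array; the DH genotype has both haplotypes
    equal to it.  Exactly one DH line is derived per input individual.
    """
    return meiosis_batch(h0, h1, gmap, rng)


# ---------------------------------------------------------------------------
# Meiosis — single-individual form


def simulate_gamete(
    parent: Genotype, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Simulate a single gamete of ``parent``; returns a (n_markers,) vector."""
    return meiosis_batch(parent.haplotypes[0][None, :], parent.haplotypes[1][None, :], gmap, rng)[0]


def cross(
    mother: Genotype,
    father: Genotype,
    gmap: GeneticMap,
    rng: np.random.Generator,
    id: str = "",
    generation: str = "",
) -> Genotype:
    """Cross two individuals; offspring gets one gamete from each parent."""
    g0 = simulate_gamete(mother, gmap, rng)
    g1 = simulate_gamete(father, gmap, rng)
    return Genotype(np.stack([g0, g1]), id=id, generation=generation)


def self_individual(
    parent: Genotype,
    gmap: GeneticMap,
    rng: np.random.Generator,
    id: str = "",
    generation: str = "",
) -> Genotype:
    """Self an individual: offspring from two independent gametes of it."""
    g0 = simulate_gamete(parent, gmap, rng)
    g1 = simulate_gamete(parent, gmap, rng)
    return Genotype(np.stack([g0, g1]), id=id, generation=generation)


def make_dh(
    parent: Genotype,
    gmap: GeneticMap,
    rng: np.random.Generator,
    id: str = "",
) -> Genotype:
    """Derive one doubled-haploid line: a single gamete, doubled.

    The result is homozygous at every marker.
    """
    g = simulate_gamete(parent, gmap, rng)
    return Genotype(np.stack([g, g.copy()]), id=id, generation="DH")
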