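# Methods

This note documents the genetic model, the crossing-scheme engine, the
evaluation measures, and the design choices made where the underlying
study design was genuinely open.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Genetic model

The genome is a grid of biallelic markers, fully polymorphic between a
homozygous donor (allele 1) and a homozygous recipient (allele 0).  The
default map models maize: 10 chromosomes of 200 cM with markers every
1 cM and 100 target segments of 20 cM tiling the genome without gap or
overlap.  Markers sit at segment-interior positions 0.5, 1.5, …, 199.5 cM
(200 per chromosome).  The phase of the grid is a modelling choice: with
boundary markers (0, 1, …, 200 cM) each chromosome would carry 201 markers
and every segment boundary would be shared by two segments; the interior
grid gives every 20 cM segment exactly 20 markers and makes the
marker→segment, marker→half and marker→chromosome maps unambiguous.  Map
geometry is configurable (`build_map`) with the constraint that the
chromosome length is a multiple of the segment length and the segment
length a multiple of the marker spacing.

**Meiosis** assumes no crossover interference: per chromosome, the number
of crossovers in a gamete is Poisson with mean L/100 (the map length in
Morgans), crossover positions are i.i.d. uniform on (0, L), and the
starting parental strand is chosen with probability ½, switching at every
crossover.  There is no obligate chiasma and no four-strand bookkeeping —
for marker-grid genotypes this process is exactly Haldane's model, with
recombination fraction r(d) = (1 − e^(−2d/100))/2 between markers d cM
apart (verified empirically at 1–100 cM in the test suite).  Mutation,
genotyping error and marker failure are not modelled.  Backcrosses to the
recipient shortcut the recipient-side meiosis: a fully homozygous parent
can only produce one gamete (all-zero), so none is simulated.

Doubled haploids double a single gamete (homozygous at every marker), with
a success rate of exactly one DH line per backcross individual.  Selfing
draws two independent gametes from the same parent; heterozygosity halves
per selfing generation in expectation, so F₃ lines retain ≈ 25 % of the F₁
heterozygosity.

## Selection

Selection is truncation on the index
`i = D_region + (1 − D_background)` where `D` denotes donor allele
*dosage* (heterozygous markers count ½), the region is a complete
chromosome, a chromosome half, or a target segment, and the background is
every marker outside the region genome-wide.  Both terms are proportions
and carry equal unit weight; the weight pair is exposed as parameters for
sensitivity analysis.  An alternative reading — background excluding the
whole carrier chromosome rather than only the region — was evaluated and
rejected: it leaves the carrier-chromosome flanks unselected and inflates
the carrier-chromosome donor proportion of every scheme by 8–12
percentage points relative to the replicated reference populations.

Per generation, a fixed number m of individuals (default 1) is selected
for each region; candidates for a region are the offspring of the
branch(es) whose own selection region contains it — in BC₁, the entire
generation.  Ties in the index are broken by a seeded uniform draw, which
avoids index-order bias in small sub-populations while keeping runs
reproducible.  One individual may be selected for several regions in BC₁
(each region slot spawns its own branch).  DH schemes that select in the
final backcross generation spread a total quota (e.g. 360 retained lines)
as evenly as possible over the regions, remainders going to the
lowest-indexed regions.

**Final library assembly.**  For each of the 100 target segments the
candidate pool is every line whose ancestral branch-region chain contains
that segment (its own lineage); segments are processed in genome order and
each takes the highest-index *not-yet-used* line, so the library consists
of 100 distinct lines whenever the pools allow.  Distinctness is the
physically meaningful convention — an introgression library is a set of
distinct plants — and it is also empirically decisive: with re-use
permitted, one clean line can win several segments of its lineage, which
depresses the population's breakpoint diversity (N_D low by ~20 %) and
overstates target-segment retention for half-based strategies by 3–6
percentage points relative to the replicated reference values.  A global
candidate pool (ignoring lineage) was likewise evaluated and rejected: it
lets background drag from foreign lineages substitute for a segment's own
lineage and makes every scheme implausibly clean.

## Crossing schemes and cost accounting

Every scheme starts from one F₁ (donor × recipient), runs 2 or 3 backcross
generations with per-generation selection according to its strategy
letters, then develops lines: one DH per final backcross individual, or
one F₂ and one F₃ per family slot with only the F₃ genotyped.  When the
final backcross generation is unselected, every individual founds a line;
when it is selected, the F₂ family slots (F₃ schemes) or the DH quota (DH
schemes) are divided evenly over the selected founders, remainders to the
lowest-indexed.  One HT assay genotypes one individual at all markers;
generations are genotyped exactly when selection needs them plus the line
generation, and `ht_count` reproduces the ledger of a full simulation in
closed form.

The 32-scheme catalogue reconstructs four series: **basic** (N = 360 per
backcross generation, final backcross unselected), **high selection
intensity** (everything doubled to 720), **final-BC selection** (DH
variants double the final backcross to 720 to retain 360 DH lines; F₃
variants keep 360 throughout, which is why they need 360 fewer assays),
and **increasing sizes** (120/240/720).  The published table's numeric
layout is not machine-readable in our source; the sizes above are the
unique reconstruction consistent with its stated rules and every printed
HT total (720/1080/1440/1800/2160/1440) — except one scheme: the
increasing-size F₃ program with target-segment selection is printed with
1400 assays, 40 fewer than the profile implies.  Its composition is not
recoverable; it is implemented with the regular 120/240/720 + 360 profile
(1440 assays), and its carrier-chromosome and target-segment donor
proportions are the least certain numbers in the package (they run ~2–3
percentage points below the reference values; all other schemes reproduce
the reference measures within a few tenths).  All sizes remain
config-overridable.

## Measures

Carrier status is presence-based (a heterozygous marker counts as carrying
donor); donor *proportions* are dosage-based (heterozygous = ½).  This
reconciles the identity depth = N_IL × λ_D/100 on homozygous populations
with the larger depths of F₃ populations.  N_D is formalised as the
population-pattern partition count: overlay the state changes of every
haplotype of every IL on the marker grid; per chromosome, N_D is the
number of maximal intervals on which the whole population pattern is
constant (distinct internal breakpoints + 1).  This choice satisfies
R × N_D = total map length exactly, rises sharply with residual
heterozygosity, and is aware of breakpoint sharing between related lines;
a donor-only interval count is available as an option for comparison.
Depth averages over all loci by default (a donor-covered-only variant is a
flag).  Donor segments are maximal carrier runs; L_D averages each IL's
mean run length over ILs that have at least one run.  All measures are
verified against independent brute-force (plain-loop) oracles on random
small populations.

## Replication and reproducibility

Experiments run each scheme on independent substreams derived from
(master seed, CRC-32 of the scheme name, replicate index), so a single
replicate can be re-run in isolation and results are byte-identical for a
given configuration and seed, independent of which other schemes run.
Aggregates are arithmetic means with Monte-Carlo standard errors.  The
acceptance script uses 200 replicates per scheme: at that size the SEs of
the donor-proportion means are an order of magnitude below the one-decimal
reporting precision, while all 32 schemes finish in ~10 minutes on one
CPU.  The test suite uses the same replication for its table checks and
smaller sizes (10⁴–10⁵ gametes, toy maps) for distributional properties,
always at 3-SE tolerances.

## What the simulations do and do not show

The generator emulates an idealised breeding program: fully informative,
error-free markers at perfectly even spacing, equal chromosome lengths, no
interference, guaranteed DH induction, and no germination or phenotyping
losses.  Passing tests therefore demonstrate the comparative behaviour of
crossing schemes and selection strategies under the stated genetic model —
not absolute outcomes for a real program, where marker informativeness,
map inhomogeneity, interference and DH failure rates will shift the
absolute donor proportions.  QTL-detection power of the resulting
libraries is out of scope.
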