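"""Executable catalogue of crossing schemes and the scheme engine.

A crossing scheme starts from the cross of a homozygous donor and a
homozygous recipient (one F1), runs two or three generations of
backcrossing to the recipient with per-generation region-based marker
selection, develops lines either by doubled-haploid (DH) induction (one
viable DH per backcross individual) or by two generations of selfing
(F2 then F3), and finally assigns the best line to each target segment to
form the 100-IL introgression population.

Selection in the first backcross generation screens the whole generation
and spawns one branch per selection region (10 for complete chromosomes,
20 for chromosome halves); each branch is backcrossed independently and
later selection rounds pick the best individuals for each region from the
branch whose region contains it.  The final library is assembled from
*distinct* lines: target segments are processed in genome order and each
takes the best not-yet-used line of its lineage by the segment index.
Every genotyped individual consumes one high-throughput (HT) assay (one
individual scored at all markers); the ledger tracks these.

Four simulation series are built in:

* ``basic``      — constant N = 360 per backcross generation, no selection in
                   the final backcross generation.
* ``high``       — as basic with every population size doubled to 720.
* ``final``      — selection also in the final backcross generation; DH
                   variants double the final backcross to 720 so that 360
                   DH lines remain, F3 variants keep 360 throughout.
* ``incr``       — increasing sizes 120/240/720 over BC1/BC2/BC3 with
                   selection in every backcross generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genome_model as gm
from .genome_model import GeneticMap, build_map
from .measures import ILPopulation
from .selection import (
    SelectionRegion,
    _index_from_dosage,
    _top_m,
    region_partition,
    select_final_ils,
)

__all__ = [
    "GenerationPlan",
    "SchemeConfig",
    "HTLedger",
    "LineageRecord",
    "builtin_scheme",
    "list_schemes",
    "run_scheme",
    "ht_count",
    "scheme_from_dict",
]

_KIND = {"C": "chromosome", "H": "half", "S": "segment"}
_LETTER = {v: k for k, v in _KIND.items()}


class SchemeConfigError(ValueError):
    pass


class BranchStarvedError(RuntimeError):
    """A selection region had no candidates in any covering branch."""


@dataclass
class GenerationPlan:
    """One generation of a crossing scheme.

    ``m_per_region`` individuals are selected per selection region
    (default 1).  If ``m_total`` is set it overrides ``m_per_region``:
    ``m_total`` selections are distributed as evenly as possible over the
    regions, remainders going to the lowest-indexed regions (used by DH
    schemes that select in the final backcross generation to retain a
    fixed number of DH lines).
    """

    label: str
    total_size: int
    genotyped: bool = False
    selection_kind: str = "none"  # chromosome | half | segment | none
    m_per_region: int = 1
    m_total: int | None = None

    def __post_init__(self):
        if self.total_size < 1:
            raise SchemeConfigError(f"{self.label}: total_size must be >= 1")
        if self.selection_kind not in ("none", "chromosome", "half", "segment"):
            raise SchemeConfigError(
                f"{self.label}: unknown selection kind {self.selection_kind!r}"
            )
        if self.selection_kind != "none" and not self.genotyped:
            raise SchemeConfigError(
                f"{self.label}: selection requires the generation to be genotyped"
            )


@dataclass
class SchemeConfig:
    """A named crossing scheme: ordered generation plans plus metadata."""

    name: str
    line_method: str  # "DH" | "F3"
    plans: list[GenerationPlan]
    series: str = "custom"

    def __post_init__(self):
        if self.line_method not in ("DH", "F3"):
            raise SchemeConfigError(f"line_method must be DH or F3, got {self.line_method!r}")
        labels = [p.label for p in self.plans]
        if self.line_method == "DH" and "DH" not in labels:
            raise SchemeConfigError("DH scheme needs a DH generation plan")
        if self.line_method == "F3" and ("F2" not in labels or "F3" not in labels):
            raise SchemeConfigError("F3 scheme needs F2 and F3 generation plans")
        if not self.line_plan.genotyped:
            raise SchemeConfigError("the line generation must be genotyped")

    @property
    def bc_plans(self) -> list[GenerationPlan]:
        return [p for p in self.plans if p.label.startswith("BC")]

    @property
    def line_plan(self) -> GenerationPlan:
        label = "DH" if self.line_method == "DH" else "F3"
        return next(p for p in self.plans if p.label == label)

    @property
    def strategy(self) -> str:
        """Strategy letters, one per selected backcross generation."""
        return "".join(
            _LETTER[p.selection_kind] for p in self.bc_plans if p.selection_kind != "none"
        )

    @property
    def n_backcross_generations(self) -> int:
        return len(self.bc_plans)


@dataclass
class HTLedger:
    """Count of high-throughput genotyping assays per generation."""

    counts: dict = field(default_factory=dict)

    def add(self, label: str, n: int) -> None:
        self.counts[label] = self.counts.get(label, 0) + int(n)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class GenerationRecord:
    label: str
    size: int
    parent: np.ndarray  # index into the previous generation (or -1)
    branch: np.ndarray  # branch index (or -1 before branching)
    selected: np.ndarray  # indices of selected individuals (may be empty)
    region_of_selected: list  # SelectionRegion per selected individual


@dataclass
class LineageRecord:
    """Per-generation pedigree and selection bookkeeping of one scheme run."""

    generations: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.generations:
            sel = set(int(i) for i in g.selected)
            for i in range(g.size):
                rows.append(
                    {
                        "id": f"{g.label}-{i}",
                        "generation": g.label,
                        "branch": int(g.branch[i]),
                        "parent_id": (
                            "" if g.parent[i] < 0 else f"{_prev_label(self, g)}-{int(g.parent[i])}"
                        ),
                        "selected": i in sel,
                    }
                )
        return pd.DataFrame(rows)


def _prev_label(rec: LineageRecord, g: GenerationRecord) -> str:
    idx = rec.generations.index(g)
    return rec.generations[idx - 1].label if idx > 0 else "F1"


def _split(total: int, parts: int) -> np.ndarray:
    """Split ``total`` into ``parts`` integers as evenly as possible;
    remainders go to the lowest-indexed parts."""
    base, rem = divmod(int(total), int(parts))
    out = np.full(parts, base, dtype=np.int64)
    out[:rem] += 1
    return out


# ---------------------------------------------------------------------------
# Catalogue


def _build_config(
    series: str,
    method: str,
    strategy: str,
    bc_sizes: list[int],
    select_final_bc: bool,
    line_size: int,
    dh_final_m_total: int | None = None,
) -> SchemeConfig:
    n_bc = len(bc_sizes)
    letters = list(strategy)
    n_selected = n_bc if select_final_bc else n_bc - 1
    if len(letters) != n_selected:
        raise SchemeConfigError(
            f"strategy {strategy!r} has {len(letters)} letters but "
            f"{n_selected} backcross generations are selected"
        )
    plans: list[GenerationPlan] = []
    for t in range(n_bc):
        label = f"BC{t + 1}"
        if t < n_selected:
            kind = _KIND[letters[t]]
            is_final = t == n_bc - 1
            m_total = dh_final_m_total if (is_final and method == "DH") else None
            plans.append(
                GenerationPlan(label, bc_sizes[t], True, kind, m_total=m_total)
            )
        else:
            plans.append(GenerationPlan(label, bc_sizes[t], False, "none"))
    if method == "DH":
        plans.append(GenerationPlan("DH", line_size, True, "none"))
    else:
        plans.append(GenerationPlan("F2", line_size, False, "none"))
        plans.append(GenerationPlan("F3", line_size, True, "none"))
    name = f"{series}-bc{n_bc}-{method.lower()}-{strategy.lower()}"
    return SchemeConfig(name=name, line_method=method, plans=plans, series=series)


def _catalogue() -> dict[str, SchemeConfig]:
    cat: dict[str, SchemeConfig] = {}

    def add(cfg: SchemeConfig):
        cat[cfg.name] = cfg

    for method in ("DH", "F3"):
        # basic: constant 360, no selection in the final BC generation
        for strat in ("C", "H"):
            add(_build_config("basic", method, strat, [360, 360], False, 360))
        for strat in ("CC", "HH", "CH"):
            add(_build_config("basic", method, strat, [360, 360, 360], False, 360))
        # high selection intensity: everything doubled to 720
        for strat in ("CC", "HH", "CH"):
            add(_build_config("high", method, strat, [720, 720, 720], False, 720))
        # selection in the final BC generation
        for strat in ("CC", "HH", "CH"):
            if method == "DH":
                add(_build_config("final", method, strat, [360, 720], True, 360, 360))
            else:
                add(_build_config("final", method, strat, [360, 360], True, 360))
        for strat in ("CCC", "HHH", "CHH"):
            if method == "DH":
                add(
                    _build_config("final", method, strat, [360, 360, 720], True, 360, 360)
                )
            else:
                add(_build_config("final", method, strat, [360, 360, 360], True, 360))
        # increasing population sizes over the backcross generations
        for strat in ("HHH", "HHS"):
            if method == "DH":
                add(_build_config("incr", method, strat, [120, 240, 720], True, 360, 360))
            else:
                add(_build_config("incr", method, strat, [120, 240, 720], True, 360))
    return cat


_CATALOGUE = _catalogue()


def list_schemes() -> list[str]:
    """Names of all built-in crossing schemes."""
    return list(_CATALOGUE)


def builtin_scheme(name: str) -> SchemeConfig:
    """Look up a built-in scheme configuration by catalogue name.

    Names encode series, backcross depth, line method and strategy, e.g.
    ``basic-bc3-dh-cc`` or ``incr-bc3-f3-hhs``.
    """
    try:
        return _CATALOGUE[name]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name!r}; available: {', '.join(_CATALOGUE)}"
        ) from None


def scheme_from_dict(d: dict) -> SchemeConfig:
    """Build a scheme from a plain mapping (YAML/JSON config file form).

    Expected keys: ``name``, ``line_method``, ``generations`` (list of
    mappings with ``label``, ``size``, ``genotyped``, ``selection``,
    optional ``m`` and ``m_total``), optional ``series``.
    """
    plans = [
        GenerationPlan(
            label=g["label"],
            total_size=int(g["size"]),
            genotyped=bool(g.get("genotyped", g.get("selection", "none") != "none")),
            selection_kind=g.get("selection", "none"),
            m_per_region=int(g.get("m", 1)),
            m_total=g.get("m_total"),
        )
        for g in d["generations"]
    ]
    return SchemeConfig(
        name=d.get("name", "custom"),
        line_method=d["line_method"],
        plans=plans,
        series=d.get("series", "custom"),
    )


def ht_count(cfg: SchemeConfig) -> int:
    """Closed-form HT assay accounting: sum of genotyped generation sizes."""
    return int(sum(p.total_size for p in cfg.plans if p.genotyped))


# ---------------------------------------------------------------------------
# Engine


def _plan_m(plan: GenerationPlan, n_regions: int) -> np.ndarray:
    """Number of individuals to select for each region of a generation."""
    if plan.m_total is not None:
        return _split(plan.m_total, n_regions)
    return np.full(n_regions, plan.m_per_region, dtype=np.int64)


def run_scheme(
    cfg: SchemeConfig,
    gmap: GeneticMap | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Execute a crossing scheme from the F1 to the final IL population.

    Parameters
    ----------
    cfg : SchemeConfig
    gmap : GeneticMap, optional (default: the standard 10 x 200 cM map)
    rng : numpy Generator or integer seed

    Returns
    -------
    (ILPopulation, HTLedger, LineageRecord)

    Raises
    ------
    BranchStarvedError
        If a selection region has no candidate individuals in any covering
        branch (names the generation and region).
    """
    gmap = gmap or build_map()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ledger = HTLedger()
    lineage = LineageRecord()

    M = gmap.n_markers
    # F1 of donor x recipient: haplotype 0 all donor, haplotype 1 all recipient
    bp_h0 = np.ones((1, M), dtype=np.uint8)
    bp_h1 = np.zeros((1, M), dtype=np.uint8)
    # per-branch chain of ancestral selection regions (root: empty chain)
    branch_chains: list[tuple[SelectionRegion, ...]] = [()]

    founders_h0 = founders_h1 = None
    founder_chains: list[tuple[SelectionRegion, ...]] = []

    for plan in cfg.bc_plans:
        B = bp_h0.shape[0]
        if plan.total_size < B:
            raise SchemeConfigError(
                f"{cfg.name}: {plan.label} size {plan.total_size} is smaller "
                f"than the number of branches ({B})"
            )
        sizes = _split(plan.total_size, B)
        rep = np.repeat(np.arange(B), sizes)
        offsets = np.concatenate(([0], np.cumsum(sizes)))
        h0 = gm.meiosis_batch(bp_h0[rep], bp_h1[rep], gmap, rng)
        h1 = np.zeros_like(h0)  # recipient gamete: all-zero, no meiosis needed
        if plan.genotyped:
            ledger.add(plan.label, plan.total_size)
        if plan.selection_kind != "none":
            regions = region_partition(gmap, plan.selection_kind)
            m_by_region = _plan_m(plan, len(regions))
            # candidate pool of a region: offspring of every branch whose own
            # region contains it (BC1: the whole generation)
            pools: list[list[np.ndarray]] = [[] for _ in regions]
            for b, chain in enumerate(branch_chains):
                parent = chain[-1] if chain else None
                children = [
                    ri
                    for ri, r in enumerate(regions)
                    if parent is None or parent.contains(r)
                ]
                for ri in children:
                    pools[ri].append(np.arange(offsets[b], offsets[b + 1]))
            dosage = (h0.astype(np.float64) + h1) / 2.0
            sel_idx: list[int] = []
            sel_chains: list[tuple[SelectionRegion, ...]] = []
            sel_regions: list[SelectionRegion] = []
            for ri, r in enumerate(regions):
                pool = (
                    np.concatenate(pools[ri])
                    if pools[ri]
                    else np.arange(h0.shape[0])
                )
                if pool.size == 0:
                    raise BranchStarvedError(
                        f"{cfg.name}: no candidates for region "
                        f"{r.kind}#{r.index} in generation {plan.label}"
                    )
                if m_by_region[ri] > pool.size:
                    raise SchemeConfigError(
                        f"{cfg.name}: {plan.label} asks for {m_by_region[ri]} "
                        f"selections from a pool of {pool.size} "
                        f"({r.kind}#{r.index})"
                    )
                scores = _index_from_dosage(dosage[pool], r)
                top = pool[_top_m(scores, int(m_by_region[ri]), rng)]
                for i in top:
                    sel_idx.append(int(i))
                    sel_chains.append(branch_chains[rep[i]] + (r,))
                    sel_regions.append(r)
            sel = np.asarray(sel_idx, dtype=np.int64)
            lineage.generations.append(
                GenerationRecord(plan.label, plan.total_size, rep, rep, sel, sel_regions)
            )
            bp_h0, bp_h1 = h0[sel], h1[sel]
            branch_chains = sel_chains
            founders_h0, founders_h1 = bp_h0, bp_h1
            founder_chains = branch_chains
        else:
            lineage.generations.append(
                GenerationRecord(
                    plan.label,
                    plan.total_size,
                    rep,
                    rep,
                    np.empty(0, dtype=np.int64),
                    [],
                )
            )
            # unselected (final) backcross generation: all offspring go on
            bp_h0, bp_h1 = h0, h1
            founders_h0, founders_h1 = h0, h1
            founder_chains = [branch_chains[b] for b in rep]

    n_founders = founders_h0.shape[0]

    # ---- line development -------------------------------------------------
    if cfg.line_method == "DH":
        plan = cfg.line_plan
        if plan.total_size != n_founders:
            raise SchemeConfigError(
                f"{cfg.name}: DH plan size {plan.total_size} does not match "
                f"the {n_founders} backcross individuals (one DH each)"
            )
        gam = gm.dh_batch(founders_h0, founders_h1, gmap, rng)
        line_h0 = gam
        line_h1 = gam.copy()
        line_chains = list(founder_chains)
        parent = np.arange(n_founders)
        if plan.genotyped:
            ledger.add("DH", plan.total_size)
        lineage.generations.append(
            GenerationRecord(
                "DH",
                plan.total_size,
                parent,
                np.full(plan.total_size, -1, dtype=np.int64),
                np.empty(0, dtype=np.int64),
                [],
            )
        )
    else:
        f2_plan = next(p for p in cfg.plans if p.label == "F2")
        f3_plan = next(p for p in cfg.plans if p.label == "F3")
        if f3_plan.total_size != f2_plan.total_size:
            raise SchemeConfigError(
                f"{cfg.name}: one F3 line per F2 family requires equal sizes"
            )
        slots = _split(f2_plan.total_size, n_founders)
        rep = np.repeat(np.arange(n_founders), slots)
        f2_h0, f2_h1 = gm.self_batch(founders_h0[rep], founders_h1[rep], gmap, rng)
        if f2_plan.genotyped:
            ledger.add("F2", f2_plan.total_size)
        f3_h0, f3_h1 = gm.self_batch(f2_h0, f2_h1, gmap, rng)
        if f3_plan.genotyped:
            ledger.add("F3", f3_plan.total_size)
        line_h0, line_h1 = f3_h0, f3_h1
        line_chains = [founder_chains[b] for b in rep]
        lineage.generations.append(
            GenerationRecord(
                "F2",
                f2_plan.total_size,
                rep,
                np.full(len(rep), -1, dtype=np.int64),
                np.empty(0, dtype=np.int64),
                [],
            )
        )
        lineage.generations.append(
            GenerationRecord(
                "F3",
                f3_plan.total_size,
                np.arange(f3_plan.total_size),
                np.full(f3_plan.total_size, -1, dtype=np.int64),
                np.empty(0, dtype=np.int64),
                [],
            )
        )

    # ---- final IL assignment ----------------------------------------------
    chosen = select_final_ils(line_h0, line_h1, line_chains, gmap, rng)
    pop = ILPopulation(
        h0=line_h0[chosen],
        h1=line_h1[chosen],
        assigned_segment=np.arange(gmap.n_segments),
        gmap=gmap,
        line_method=cfg.line_method,
        source_line=chosen,
    )
    return pop, ledger, lineage
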