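"""Selection regions, the selection index, and truncation selection."""

import numpy as np
import pytest

from ilsim import build_map, region_partition, select_per_region, selection_index
from ilsim.genome_model import Genotype, f1_genotype, recipient_genotype
from ilsim.selection import SelectionRegion, _index_from_dosage, select_final_ils


def genotype_from_dosage(dose):
    """Build a genotype whose per-marker dosage is 0, 0.5 or 1."""
    dose = np.asarray(dose)
    h0 = (dose >= 0.5).astype(np.uint8)
    h1 = (dose == 1.0).astype(np.uint8)
    return Genotype(np.stack([h0, h1]))


class TestRegionPartition:
    @pytest.mark.parametrize(
        "kind, n_regions, markers_each",
        [("chromosome", 10, 200), ("half", 20, 100), ("segment", 100, 20)],
    )
    def test_default_map_partitions(self, gmap, kind, n_regions, markers_each):
        regions = region_partition(gmap, kind)
        assert len(regions) == n_regions
        assert all(r.n_markers() == markers_each for r in regions)
        covered = np.zeros(gmap.n_markers, dtype=int)
        for r in regions:
            covered[r.marker_slice] += 1
        assert (covered == 1).all()  # regions tile the genome

    def test_single_chromosome_toy(self):
        m = build_map(1, 20.0, 1.0, 20.0)
        (region,) = region_partition(m, "chromosome")
        assert region.marker_slice == slice(0, 20)

    def test_halves_split_at_midpoint(self, gmap):
        halves = region_partition(gmap, "half")
        assert halves[0].end == gmap.chrom_length / 2
        assert halves[1].start == gmap.chrom_length / 2

    def test_containment(self, gmap):
        chrom = region_partition(gmap, "chromosome")
        seg = region_partition(gmap, "segment")
        assert chrom[0].contains(seg[0])
        assert not chrom[0].contains(seg[10])  # other chromosome

    def test_unknown_kind(self, gmap):
        with pytest.raises(ValueError):
            region_partition(gmap, "arm")


class TestSelectionIndex:
    def test_het_region_recipient_background(self, gmap):
        region = region_partition(gmap, "chromosome")[0]
        dose = np.zeros(gmap.n_markers)
        dose[region.marker_slice] = 0.5
        g = genotype_from_dosage(dose)
        assert selection_index(g, region) == pytest.approx(1.5)

    def test_all_recipient_scores_one(self, gmap):
        region = region_partition(gmap, "half")[3]
        assert selection_index(recipient_genotype(gmap), region) == pytest.approx(1.0)

    def test_maximum_is_two(self, gmap):
        region = region_partition(gmap, "segment")[42]
        dose = np.zeros(gmap.n_markers)
        dose[region.marker_slice] = 1.0
        g = genotype_from_dosage(dose)
        assert selection_index(g, region) == pytest.approx(2.0)

    def test_matches_brute_force_on_random_genotypes(self, gmap, rng):
        regions = region_partition(gmap, "half")
        for _ in range(10):
            dose = rng.choice([0.0, 0.5, 1.0], size=gmap.n_markers)
            g = genotype_from_dosage(dose)
            r = regions[int(rng.integers(len(regions)))]
            mask = np.zeros(gmap.n_markers, dtype=bool)
            mask[r.marker_slice] = True
            expected = dose[mask].mean() + 1.0 - dose[~mask].mean()
            got = selection_index(g, r)
            assert got == pytest.approx(expected)
            assert 0.0 <= got <= 2.0


class TestSelectPerRegion:
    def _random_pop(self, gmap, rng, n):
        return [
            genotype_from_dosage(rng.choice([0, 0.5, 1.0], size=gmap.n_markers))
            for _ in range(n)
        ]

    @pytest.mark.parametrize("m", [1, 3])
    def test_equals_sort_and_take_oracle(self, gmap, rng, m):
        pop = self._random_pop(gmap, rng, 20)
        regions = region_partition(gmap, "chromosome")
        out = select_per_region(pop, regions, m, rng)
        for r in regions:
            scores = sorted((selection_index(g, r) for g in pop), reverse=True)
            got = sorted((selection_index(g, r) for g in out[r]), reverse=True)
            assert got == pytest.approx(scores[:m])

    def test_m_equal_population_returns_everyone(self, gmap, rng):
        pop = self._random_pop(gmap, rng, 5)
        regions = region_partition(gmap, "chromosome")[:2]
        out = select_per_region(pop, regions, 5, rng)
        for r in regions:
            assert len(out[r]) == 5

    def test_nesting_in_m(self, gmap, rng):
        """Raising m never removes a previously selected individual."""
        pop = self._random_pop(gmap, rng, 15)
        regions = region_partition(gmap, "chromosome")[:3]
        small = select_per_region(pop, regions, 2, np.random.default_rng(0))
        large = select_per_region(pop, regions, 4, np.random.default_rng(0))
        for r in regions:
            small_ids = {id(g) for g in small[r]}
            large_ids = {id(g) for g in large[r]}
            assert small_ids <= large_ids

    def test_tie_break_reproducible(self, gmap):
        pop = [recipient_genotype(gmap, id=f"g{i}") for i in range(4)]  # all tied
        regions = region_partition(gmap, "chromosome")[:1]
        picks = [
            select_per_region(pop, regions, 1, np.random.default_rng(99))[regions[0]][0].id
            for _ in range(3)
        ]
        assert len(set(picks)) == 1

    def test_empty_population_rejected(self, gmap, rng):
        with pytest.raises(ValueError):
            select_per_region([], region_partition(gmap, "chromosome"), 1, rng)

    def test_m_larger_than_population_rejected(self, gmap, rng):
        pop = self._random_pop(gmap, rng, 2)
        with pytest.raises(ValueError):
            select_per_region(pop, region_partition(gmap, "chromosome"), 3, rng)


class TestSelectFinalIls:
    def _ideal_lines(self, gmap):
        """One line per segment, homozygous donor exactly on that segment."""
        n = gmap.n_segments
        h = np.zeros((n, gmap.n_markers), dtype=np.uint8)
        for s in range(n):
            h[s, gmap.segment_slice(s)] = 1
        return h, h.copy()

    def test_ideal_library_is_recovered(self, gmap, rng):
        h0, h1 = self._ideal_lines(gmap)
        chains = [() for _ in range(gmap.n_segments)]
        chosen = select_final_ils(h0, h1, chains, gmap, rng)
        assert (chosen == np.arange(gmap.n_segments)).all()

    def test_all_recipient_still_assigns(self, gmap, rng):
        h0 = np.zeros((5, gmap.n_markers), dtype=np.uint8)
        chosen = select_final_ils(h0, h0.copy(), [()] * 5, gmap, rng)
        assert chosen.shape == (gmap.n_segments,)
        assert ((chosen >= 0) & (chosen < 5)).all()

    def test_index_trades_segment_against_background(self, gmap, rng):
        """Candidates (D_S, background-recipient) = (1.0,.95), (.5,.99),
        (1.0,.97): index 1.95 vs 1.49 vs 1.97 -> the third line wins."""
        seg = gmap.segment_slice(0)
        n_bg = gmap.n_markers - gmap.markers_per_segment
        specs = [(1.0, 0.95), (0.5, 0.99), (1.0, 0.97)]
        h0 = np.zeros((3, gmap.n_markers), dtype=np.uint8)
        h1 = np.zeros_like(h0)
        for i, (ds, bg_recip) in enumerate(specs):
            if ds == 1.0:
                h0[i, seg] = 1
                h1[i, seg] = 1
            else:  # heterozygous across the segment
                h0[i, seg] = 1
            n_donor = round((1 - bg_recip) * n_bg)
            cols = np.arange(gmap.markers_per_segment, gmap.markers_per_segment + n_donor)
            h0[i, cols] = 1
            h1[i, cols] = 1
        chosen = select_final_ils(h0, h1, [()] * 3, gmap, rng)
        assert chosen[0] == 2

    def test_lineage_pooling_restricts_candidates(self, gmap, rng):
        """A segment's pool is its covering lineage even if a foreign line
        scores higher."""
        halves = region_partition(gmap, "half")
        seg0 = gmap.segment_slice(0)  # inside half 0
        h0 = np.zeros((2, gmap.n_markers), dtype=np.uint8)
        h1 = np.zeros_like(h0)
        h0[0, seg0] = 1  # line 0: het on segment 0, lineage = half 1 (!)
        h0[1, gmap.segment_slice(1)] = 1  # line 1: lineage half 0, nothing on seg 0
        h1[1, gmap.segment_slice(1)] = 1
        chains = [(halves[1],), (halves[0],)]
        chosen = select_final_ils(h0, h1, chains, gmap, rng)
        assert chosen[0] == 1  # pooled by lineage, not by global score

    def test_distinct_lines_preferred(self, gmap, rng):
        """When one line dominates two segments the second segment takes the
        best remaining line."""
        chrom0 = region_partition(gmap, "chromosome")[0]
        h0 = np.zeros((2, gmap.n_markers), dtype=np.uint8)
        h0[0, gmap.segment_slice(0)] = 1
        h0[0, gmap.segment_slice(1)] = 1  # line 0 carries segments 0 and 1
        h0[1, gmap.segment_slice(1)] = 1  # line 1 carries only segment 1 (het)
        h1 = h0.copy()
        h1[1] = 0
        chains = [(chrom0,), (chrom0,)]
        chosen = select_final_ils(h0, h1, chains, gmap, rng)
        assert chosen[0] == 0
        assert chosen[1] == 1
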