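"""Genotype import/export.

The primary exchange format is a tab-delimited dosage matrix: one row per
marker with ``chrom`` (1-based) and ``pos_cM`` columns followed by one
column per individual holding the donor-allele dosage 0/1/2.  A minimal
VCF-style export with markers as pseudo-variants is provided for loading
simulated populations into standard variant tooling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import GeneticMap, build_map
from .measures import ILPopulation

__all__ = ["export_genotypes", "load_genotypes", "export_vcf"]


def export_genotypes(pop: ILPopulation, path: str) -> None:
    """Write the population as a marker x individual dosage matrix (TSV)."""
    gmap = pop.gmap
    data = {
        "chrom": gmap.chrom_index + 1,
        "pos_cM": gmap.positions,
    }
    dose = (pop.h0.astype(np.int64) + pop.h1).T  # (M, n_ils), values 0/1/2
    for i in range(pop.n_ils):
        data[f"IL-{i + 1}"] = dose[:, i]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def load_genotypes(
    path: str, gmap: GeneticMap | None = None, assigned_segment=None
) -> ILPopulation:
    """Read a dosage-matrix TSV back into an :class:`ILPopulation`.

    Dosage 1 is represented as a heterozygous marker.  When
    ``assigned_segment`` is omitted every IL is assigned the target
    segment in which its donor dosage is highest.
    """
    df = pd.read_csv(path, sep="\t")
    il_cols = [c for c in df.columns if c not in ("chrom", "pos_cM")]
    dose = df[il_cols].to_numpy().T  # (n_ils, M)
    if gmap is None:
        chroms = df["chrom"].nunique()
        per = (df["chrom"] == df["chrom"].iloc[0]).sum()
        spacing = float(np.diff(df["pos_cM"].to_numpy()[:2])[0]) if per > 1 else 1.0
        gmap = build_map(chroms, per * spacing, spacing, min(20.0, per * spacing))
    h0 = (dose >= 1).astype(np.uint8)
    h1 = (dose == 2).astype(np.uint8)
    n = h0.shape[0]
    if assigned_segment is None:
        d = (h0.astype(np.float64) + h1) / 2.0
        seg_dose = np.stack(
            [d[:, gmap.segment_slice(s)].mean(axis=1) for s in range(gmap.n_segments)],
            axis=1,
        )
        assigned_segment = seg_dose.argmax(axis=1)
    return ILPopulation(
        h0=h0,
        h1=h1,
        assigned_segment=np.asarray(assigned_segment),
        gmap=gmap,
        line_method="external",
    )


def export_vcf(pop: ILPopulation, path: str) -> None:
    """Minimal VCF-style export: markers as pseudo-variants (REF=recipient A,
    ALT=donor T), positions in 0.01-cM integer units."""
    gmap = pop.gmap
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CM,Number=1,Type=Float,Description="Map position in cM">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for c in range(gmap.n_chromosomes):
        lines.append(f"##contig=<ID=chr{c + 1}>")
    samples = "\t".join(f"IL-{i + 1}" for i in range(pop.n_ils))
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}")
    chrom_idx = gmap.chrom_index
    pos = gmap.positions
    for j in range(gmap.n_markers):
        gts = "\t".join(
            f"{pop.h0[i, j]}|{pop.h1[i, j]}" for i in range(pop.n_ils)
        )
        lines.append(
            f"chr{chrom_idx[j] + 1}\t{int(round(pos[j] * 100))}\tm{j + 1}\tA\tT\t.\t.\t"
            f"CM={pos[j]:g}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
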