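"""Growth rates, relative fitness, and the substitution heatmap.

For each variant v in a sample pair (t0, t1):

    growth rate g(v) = log2[(CFU_t1/CFU_t0) * (RPM_t1(v)/RPM_t0(v))] / hours

where RPM is reads per million over all counted classes (wild type plus
single-codon variants; discards excluded).  Relative fitness under
spectinomycin is g_+Spc / g_-Spc, computed within a replicate and then
averaged across replicates.  The heatmap reports mean relative fitness
per (residue 38-77, substituted amino acid incl. stop), masking variants
whose t0 read support falls below the read filter (default 8 reads) in
any contributing sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import AmpliconDesign, default_design
from .variant_calling import VariantCountTable, translate_codon

__all__ = [
    "SampleCounts",
    "FitnessResult",
    "rpm",
    "growth_rate",
    "relative_fitness",
    "aggregate",
    "heatmap_matrix",
    "AA_ROWS",
]

#: Heatmap row order: the 20 amino acids plus the amber stop.
AA_ROWS = tuple("ACDEFGHIKLMNPQRSTVWY") + ("*",)

WT_KEY = "WT"


@dataclass
class SampleCounts:
    """One replicate x condition: CFU pair, culture time, count tables."""

    replicate: int
    condition: str  # "spc" | "nospc"
    cfu_t0: int
    cfu_t1: int
    culture_hours: float
    counts_t0: VariantCountTable
    counts_t1: VariantCountTable

    def __post_init__(self) -> None:
        if self.cfu_t0 <= 0 or self.cfu_t1 <= 0:
            raise ValueError("CFU values must be positive")
        if self.culture_hours <= 0:
            raise ValueError("culture_hours must be positive")


def _class_counts(
    table: VariantCountTable, by_aa: bool, design: AmpliconDesign | None
) -> dict:
    if by_aa:
        counts = dict(table.by_amino_acid(design or default_design()))
    else:
        counts = dict(table.counts)
    counts[WT_KEY] = table.wt_count
    return counts


def rpm(
    table: VariantCountTable,
    by_aa: bool = False,
    design: AmpliconDesign | None = None,
) -> dict:
    """Reads per million for every counted class (incl. ``"WT"``).

    The denominator is wild type plus all single-codon variant counts;
    discarded reads are excluded.  With ``by_aa`` synonymous codons are
    summed per (residue, amino acid) before normalizing.
    """
    total = table.counted_reads
    if total <= 0:
        raise ValueError("count table is empty")
    counts = _class_counts(table, by_aa, design)
    return {k: 1e6 * c / total for k, c in counts.items()}


def growth_rate(
    variant,
    sample: SampleCounts,
    by_aa: bool = False,
    design: AmpliconDesign | None = None,
) -> float | None:
    """Per-variant growth rate (log2 units/hour), or None when the
    variant has zero reads at either timepoint (no pseudocounts)."""
    rpm_t0 = rpm(sample.counts_t0, by_aa=by_aa, design=design)
    rpm_t1 = rpm(sample.counts_t1, by_aa=by_aa, design=design)
    return _growth_rate_from_rpm(
        rpm_t0.get(variant, 0.0),
        rpm_t1.get(variant, 0.0),
        sample.cfu_t0,
        sample.cfu_t1,
        sample.culture_hours,
    )


def _growth_rate_from_rpm(
    rpm_t0: float, rpm_t1: float, cfu_t0: int, cfu_t1: int, hours: float
) -> float | None:
    if rpm_t0 <= 0 or rpm_t1 <= 0:
        return None
    return math.log2((cfu_t1 / cfu_t0) * (rpm_t1 / rpm_t0)) / hours


def relative_fitness(
    variant,
    spc_sample: SampleCounts,
    nospc_sample: SampleCounts,
    by_aa: bool = False,
    design: AmpliconDesign | None = None,
) -> float | None:
    """g_+Spc / g_-Spc within one replicate; None when either rate is
    undefined or the reference (-Spc) rate is non-positive."""
    g_spc = growth_rate(variant, spc_sample, by_aa=by_aa, design=design)
    g_nospc = growth_rate(variant, nospc_sample, by_aa=by_aa, design=design)
    if g_spc is None or g_nospc is None or g_nospc <= 0:
        return None
    return g_spc / g_nospc


@dataclass
class FitnessResult:
    """Long-format per-variant records plus the aggregated heatmap."""

    long: pd.DataFrame
    heatmap: pd.DataFrame

    def mean_fitness(self) -> dict[tuple[int, str], float]:
        out = {}
        for aa, row in self.heatmap.iterrows():
            for pos, v in row.items():
                if not pd.isna(v):
                    out[(int(pos), aa)] = float(v)
        return out


def aggregate(
    replicates: Sequence[tuple[SampleCounts, SampleCounts]],
    min_reads: int = 8,
    by_aa: bool = True,
    design: AmpliconDesign | None = None,
) -> FitnessResult:
    """Replicate-wise relative fitness, averaged, with read filtering.

    ``replicates`` pairs each +Spc sample with its -Spc counterpart.
    A variant passes the read filter only if its t0 count is at least
    ``min_reads`` in every contributing sample (both conditions of every
    replicate); variants failing it are masked in the heatmap, not
    zeroed.
    """
    if not replicates:
        raise ValueError("need at least one replicate pair")
    design = design or default_design()

    rows = []
    per_variant: dict = {}
    support_ok: dict = {}
    for spc, nospc in replicates:
        if spc.condition == nospc.condition:
            raise ValueError("replicate pair must span both conditions")
        if spc.condition != "spc":
            spc, nospc = nospc, spc
        t0_spc = _class_counts(spc.counts_t0, by_aa, design)
        t0_nospc = _class_counts(nospc.counts_t0, by_aa, design)
        rpm_maps = {
            ("spc", "t0"): rpm(spc.counts_t0, by_aa, design),
            ("spc", "t1"): rpm(spc.counts_t1, by_aa, design),
            ("nospc", "t0"): rpm(nospc.counts_t0, by_aa, design),
            ("nospc", "t1"): rpm(nospc.counts_t1, by_aa, design),
        }
        variants = (set(t0_spc) | set(t0_nospc)) - {WT_KEY}
        for v in sorted(variants):
            g_spc = _growth_rate_from_rpm(
                rpm_maps[("spc", "t0")].get(v, 0.0),
                rpm_maps[("spc", "t1")].get(v, 0.0),
                spc.cfu_t0, spc.cfu_t1, spc.culture_hours,
            )
            g_nospc = _growth_rate_from_rpm(
                rpm_maps[("nospc", "t0")].get(v, 0.0),
                rpm_maps[("nospc", "t1")].get(v, 0.0),
                nospc.cfu_t0, nospc.cfu_t1, nospc.culture_hours,
            )
            rf = (
                g_spc / g_nospc
                if g_spc is not None and g_nospc is not None and g_nospc > 0
                else None
            )
            n0_spc = t0_spc.get(v, 0)
            n0_nospc = t0_nospc.get(v, 0)
            passed = n0_spc >= min_reads and n0_nospc >= min_reads
            support_ok[v] = support_ok.get(v, True) and passed
            per_variant.setdefault(v, []).append(rf)
            pos, key2 = v
            rows.append(
                {
                    "position": pos,
                    ("aa" if by_aa else "codon"): key2,
                    "replicate": spc.replicate,
                    "t0_reads_spc": n0_spc,
                    "t0_reads_nospc": n0_nospc,
                    "growth_rate_spc": g_spc,
                    "growth_rate_nospc": g_nospc,
                    "relative_fitness": rf,
                    "pass_read_filter": passed,
                }
            )

    mean_rf: dict = {}
    for v, values in per_variant.items():
        defined = [x for x in values if x is not None]
        if support_ok[v] and defined:
            mean_rf[v] = float(np.mean(defined))

    long = pd.DataFrame(rows)
    if by_aa:
        hm = heatmap_matrix(mean_rf, design)
    else:
        aa_rf: dict = {}
        for (pos, codon), val in mean_rf.items():
            aa_rf.setdefault((pos, translate_codon(codon)), []).append(val)
        hm = heatmap_matrix(
            {k: float(np.mean(v)) for k, v in aa_rf.items()}, design
        )
    return FitnessResult(long=long, heatmap=hm)


def heatmap_matrix(
    mean_rf: Mapping[tuple[int, str], float],
    design: AmpliconDesign | None = None,
) -> pd.DataFrame:
    """Wide matrix: rows = substituted amino acid (incl. ``*``),
    columns = residues 38-77; missing entries are NaN (masked)."""
    design = design or default_design()
    positions = list(design.mutable_residues)
    hm = pd.DataFrame(
        np.nan, index=list(AA_ROWS), columns=positions, dtype=float
    )
    for (pos, aa), val in mean_rf.items():
        if aa in hm.index and pos in hm.columns:
            hm.loc[aa, pos] = val
    return hm
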