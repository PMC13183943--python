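"""Classify merged inserts against the library design and count variants.

A merged read is accepted only if it is exactly insert-length (any other
length is presumed to carry an indel) and carries the TAG/GGT anchors at
their fixed positions.  The 240-nt reporter is then compared codon-wise
to wild type: zero mismatched codons is wild type, exactly one mismatch
at a mutable position (residues 38-77) is a single-codon variant, and
everything else is discarded with a reason.  Hexamer spacers are ignored
entirely; the library was never deduplicated on them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .design import AmpliconDesign, NNK_CODONS
from .read_processing import MergedRead

__all__ = [
    "ReporterObservation",
    "Classification",
    "VariantCountTable",
    "parse_insert",
    "classify",
    "count_variants",
    "translate_codon",
]

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_NNK_SET = frozenset(NNK_CODONS)


def translate_codon(codon: str) -> str:
    """Standard genetic code; stop codons map to ``*``."""
    try:
        return _CODON_TO_AA[codon.upper()]
    except KeyError:
        raise ValueError(f"not a valid codon: {codon!r}") from None


class ParseReject(ValueError):
    """Insert rejected; ``reason`` is ``indel`` or ``anchor``."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


@dataclass
class ReporterObservation:
    """Extracted reporter with its codon-wise comparison to wild type."""

    reporter: str
    mismatched_codons: tuple[int, ...]  # 0-based reporter codon indices

    def n_mismatches(self) -> int:
        return len(self.mismatched_codons)


@dataclass(frozen=True)
class Classification:
    """Outcome of classifying one read."""

    kind: str  # "WT" | "single" | "discard"
    position: int | None = None  # protein residue number (38-77)
    codon: str | None = None
    aa: str | None = None
    reason: str | None = None  # for discards
    is_nnk: bool | None = None  # single variants: codon matches NNK?


def parse_insert(
    merged: MergedRead | str, design: AmpliconDesign
) -> ReporterObservation:
    """Check length and anchors, extract the reporter, diff codons."""
    seq = merged.sequence if isinstance(merged, MergedRead) else merged
    if len(seq) != design.insert_len:
        raise ParseReject(
            "indel", f"insert length {len(seq)} != {design.insert_len}"
        )
    h = design.hexamer_len
    a5 = seq[h : h + len(design.anchor5)]
    a3_start = design.insert_len - h - len(design.anchor3)
    a3 = seq[a3_start : a3_start + len(design.anchor3)]
    if a5 != design.anchor5 or a3 != design.anchor3:
        raise ParseReject("anchor", f"anchors {a5}/{a3} do not match")
    start = design.reporter_start
    reporter = seq[start : start + len(design.wt_reporter)]
    wt = design.wt_reporter
    mism = tuple(
        i
        for i in range(design.n_reporter_codons)
        if reporter[3 * i : 3 * i + 3] != wt[3 * i : 3 * i + 3]
    )
    return ReporterObservation(reporter=reporter, mismatched_codons=mism)


def classify(
    obs: ReporterObservation, design: AmpliconDesign
) -> Classification:
    """Wild type, single mutable-codon variant, or discard."""
    if obs.n_mismatches() == 0:
        return Classification(kind="WT")
    if obs.n_mismatches() > 1:
        return Classification(kind="discard", reason="multi")
    (idx,) = obs.mismatched_codons
    residue = design.residue_of_codon(idx)
    if residue is None:
        return Classification(kind="discard", reason="offsite")
    codon = obs.reporter[3 * idx : 3 * idx + 3]
    if set(codon) - set("ACGT"):
        return Classification(kind="discard", reason="ambiguous")
    return Classification(
        kind="single",
        position=residue,
        codon=codon,
        aa=translate_codon(codon),
        is_nnk=codon in _NNK_SET,
    )


@dataclass
class VariantCountTable:
    """Per-sample counts keyed by (residue, codon), plus WT and discards."""

    sample_id: str = ""
    counts: Counter = field(default_factory=Counter)  # (pos, codon) -> n
    wt_count: int = 0
    discards: Counter = field(default_factory=Counter)  # reason -> n
    non_nnk: Counter = field(default_factory=Counter)  # flagged singles

    @property
    def parsed_reads(self) -> int:
        return self.wt_count + sum(self.counts.values()) + sum(
            self.discards.values()
        )

    @property
    def counted_reads(self) -> int:
        """Denominator for RPM: wild type plus all single variants."""
        return self.wt_count + sum(self.counts.values())

    def add(self, cls: Classification) -> None:
        if cls.kind == "WT":
            self.wt_count += 1
        elif cls.kind == "single":
            key = (cls.position, cls.codon)
            self.counts[key] += 1
            if not cls.is_nnk:
                self.non_nnk[key] += 1
        else:
            self.discards[cls.reason] += 1

    def by_amino_acid(self, design: AmpliconDesign) -> Counter:
        """Sum synonymous codons per (residue, amino acid)."""
        agg: Counter = Counter()
        for (pos, codon), n in self.counts.items():
            agg[(pos, translate_codon(codon))] += n
        return agg

    # -- I/O ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id,
                "position": pos,
                "codon": codon,
                "aa": translate_codon(codon),
                "count": n,
            }
            for (pos, codon), n in sorted(self.counts.items())
        ]
        rows.append(
            {
                "sample_id": self.sample_id,
                "position": 0,
                "codon": "WT",
                "aa": "WT",
                "count": self.wt_count,
            }
        )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "VariantCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"codon": str})
        table = cls()
        for sample_id, pos, codon, n in zip(
            df["sample_id"], df["position"], df["codon"], df["count"]
        ):
            table.sample_id = sample_id
            if codon == "WT":
                table.wt_count = int(n)
            else:
                table.counts[(int(pos), codon)] = int(n)
        return table


def count_variants(
    merged_reads: Iterable[MergedRead | str],
    design: AmpliconDesign,
    sample_id: str = "",
) -> VariantCountTable:
    """Accumulate classifications over a stream of merged reads."""
    table = VariantCountTable(sample_id=sample_id)
    for read in merged_reads:
        try:
            obs = parse_insert(read, design)
        except ParseReject as err:
            table.discards[err.reason] += 1
            continue
        table.add(classify(obs, design))
    return table


def count_variants_matrix(
    seqs: np.ndarray, design: AmpliconDesign, sample_id: str = ""
) -> VariantCountTable:
    """Vectorized :func:`count_variants` over an (n, insert_len) uint8
    ASCII matrix of merged reads (reads of any other length must be
    tallied as ``indel`` discards by the caller)."""
    table = VariantCountTable(sample_id=sample_id)
    if seqs.size == 0:
        return table
    if seqs.shape[1] != design.insert_len:
        raise ValueError("matrix width must equal the insert length")
    h = design.hexamer_len
    a5 = np.frombuffer(design.anchor5.encode(), np.uint8)
    a3 = np.frombuffer(design.anchor3.encode(), np.uint8)
    a3_start = design.insert_len - h - len(design.anchor3)
    anchor_ok = (seqs[:, h : h + a5.size] == a5).all(axis=1) & (
        seqs[:, a3_start : a3_start + a3.size] == a3
    ).all(axis=1)
    table.discards["anchor"] += int(np.count_nonzero(~anchor_ok))

    start = design.reporter_start
    rep = seqs[anchor_ok, start : start + len(design.wt_reporter)]
    wt = np.frombuffer(design.wt_reporter.encode(), np.uint8)
    ncod = design.n_reporter_codons
    codon_mism = (
        (rep != wt).reshape(rep.shape[0], ncod, 3).any(axis=2)
    )
    n_mism = codon_mism.sum(axis=1)
    table.wt_count += int(np.count_nonzero(n_mism == 0))
    table.discards["multi"] += int(np.count_nonzero(n_mism > 1))

    single = n_mism == 1
    if single.any():
        idx = codon_mism[single].argmax(axis=1)
        first_codon = design.mutable_offset_nt // 3
        mutable = (idx >= first_codon) & (idx < first_codon + design.n_mutable)
        table.discards["offsite"] += int(np.count_nonzero(~mutable))
        rows = np.flatnonzero(single)[mutable]
        cods = idx[mutable]
        codon_bytes = rep[
            rows[:, None], (3 * cods)[:, None] + np.arange(3)[None, :]
        ]
        positions = design.first_mutable_residue + (cods - first_codon)
        for row_codon, pos in zip(codon_bytes, positions):
            codon = row_codon.tobytes().decode()
            if set(codon) - set("ACGT"):
                table.discards["ambiguous"] += 1
                continue
            key = (int(pos), codon)
            table.counts[key] += 1
            if codon not in _NNK_SET:
                table.non_nnk[key] += 1
    return table
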