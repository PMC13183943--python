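"""Toeprint fragment-length <-> stall-codon arithmetic.

A ribosome stalled with its P-site on codon *c* blocks reverse
transcription at a fixed distance downstream of the P-site, so the cDNA
fragment length is linear in the stall codon: advancing the ribosome by
one codon shortens the fragment by one codon's worth of nucleotides.
Absolute fragment lengths depend on the construct and primer, so the
model is anchored by a single calibration pair measured for the construct
at hand.  For the Cd CliM 77K construct, 0-site stalling (P-site codon
76) gives a 176-nt fragment; the model then predicts 179 nt for the -1
site (codon 75) and 173 nt for the +1 site (codon 77).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ToeprintCalibration",
    "PeakTable",
    "predict_length",
    "assign_peaks",
]


@dataclass(frozen=True)
class ToeprintCalibration:
    """One (P-site codon, fragment length) anchor plus the codon step."""

    anchor_codon: int
    anchor_length: int
    nt_per_codon: int = 3

    def __post_init__(self) -> None:
        if self.anchor_length <= 0:
            raise ValueError("anchor_length must be positive")
        if self.nt_per_codon < 1:
            raise ValueError("nt_per_codon must be >= 1")


@dataclass
class PeakTable:
    """Capillary-electrophoresis peaks: (fragment length nt, intensity)."""

    peaks: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for length, intensity in self.peaks:
            if int(length) != length or length <= 0:
                raise ValueError("fragment lengths must be positive integers")
            if intensity < 0:
                raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.peaks)

    def lengths(self) -> list[int]:
        return [int(l) for l, _ in self.peaks]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.peaks, columns=["length_nt", "intensity"])

    @classmethod
    def from_csv(cls, path) -> "PeakTable":
        df = pd.read_csv(path)
        return cls(list(zip(df["length_nt"].astype(int), df["intensity"])))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def predict_length(p_site_codon: int, calib: ToeprintCalibration) -> int:
    """Fragment length (nt) for stalling with the P-site on a codon.

    Downstream codons give shorter fragments; a non-positive prediction
    (ribosome past the primer) is rejected.
    """
    if p_site_codon < 1:
        raise ValueError("codon numbers are 1-based and positive")
    length = calib.anchor_length - calib.nt_per_codon * (
        p_site_codon - calib.anchor_codon
    )
    if length <= 0:
        raise ValueError(
            f"codon {p_site_codon} predicts a non-positive fragment length"
        )
    return length


def assign_peaks(
    peaks: PeakTable | Sequence[int],
    calib: ToeprintCalibration,
    candidate_codons: Iterable[int],
    tolerance_nt: int = 1,
) -> dict[int, int | None]:
    """Map each observed peak length to the stall codon that predicts it.

    Each peak is matched to the candidate codon whose predicted length
    lies within ``tolerance_nt``; ties break toward the smaller codon
    number; peaks with no prediction in range map to ``None``.
    """
    lengths = peaks.lengths() if isinstance(peaks, PeakTable) else list(peaks)
    candidates = sorted(set(candidate_codons))
    predicted = {c: predict_length(c, calib) for c in candidates}
    out: dict[int, int | None] = {}
    for obs in lengths:
        best: int | None = None
        best_err = None
        for c in candidates:  # ascending: ties go to the smaller codon
            err = abs(predicted[c] - obs)
            if err <= tolerance_nt and (best_err is None or err < best_err):
                best, best_err = c, err
        out[int(obs)] = best
    return out
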