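"""Amplicon architecture of the Cd CliM deep-mutational-scanning library.

The sequenced molecule is a fixed 258-nt insert flanked by Illumina adapters:

    adapter5 - NNNNNN - TAG - reporter (240 nt) - GGT - NNNNNN - adapter3

The two hexamers (``NNNNNN``) are randomized spacers, the trinucleotides
TAG (``bc5``) and GGT (``bc7``) are constant anchors bracketing the
reporter, and the reporter carries codons 38-76 of wild-type *C. difficile
cliM* plus an artificially introduced Lys77 codon, each of which was
saturated with NNK codons in the library.  With 150-bp paired-end reads the
forward and reverse mates overlap by 2*150 - 258 = 42 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

from Bio.Seq import Seq

__all__ = [
    "AmpliconDesign",
    "ADAPTER5",
    "ADAPTER3",
    "WT_REPORTER",
    "NNK_CODONS",
    "default_design",
    "build_reference_amplicon",
]

#: Illumina P5 side: P5 adapter, i5 index and read-1 primer binding site.
ADAPTER5 = (
    "AATGATACGGCGACCACCGAGATCTACACAGCGCTAGACACTCTTTCCCTACACGACGCTCTTCCGATCT"
)

#: Illumina P7 side: read-2 primer binding site, i7 index and P7 adapter.
ADAPTER3 = (
    "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACCCGCGGTTATCTCGTATGCCGTCTTCTGCTTG"
)

#: 240-nt reporter between bc5 and bc7: a GFP/linker tail, CliM codons
#: 30-37, the 40 mutagenized codons (CliM 38-76 + Lys77), and a FLAG tag.
WT_REPORTER = (
    "AGAGACCACATGGTCCTTCTTGAGTTTGTAACAGCTGCTGGGATTACACATGGCATGGATGAACTATAC"
    "AAAAAAGACCTCTTAAATCATAAAATTAAGTATGTTTTAATAAGAGACATATTTGTAAATAGAATTACA"
    "TATTCTGAAGAACGACTGCCTAAACAGTATATAGTTTTTCAGAAATATGATATTTGGCGGTATTGTAGT"
    "TTATTTAAAGACTATAAAGACGACGACGACAAA"
)

#: The 32 NNK codons (N = A/C/G/T, K = G/T): all 20 amino acids + amber.
NNK_CODONS = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "GT"
)

_FIRST_MUTABLE_RESIDUE = 38
_N_MUTABLE = 40
# codon 38 starts at 0-based reporter offset 96 (reporter codon index 32)
_MUTABLE_OFFSET_NT = 96

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class AmpliconDesign:
    """Fixed library architecture: adapters, anchors, reporter, geometry."""

    adapter5: str = ADAPTER5
    adapter3: str = ADAPTER3
    hexamer_len: int = 6
    anchor5: str = "TAG"  # bc5
    anchor3: str = "GGT"  # bc7
    wt_reporter: str = WT_REPORTER
    first_mutable_residue: int = _FIRST_MUTABLE_RESIDUE
    n_mutable: int = _N_MUTABLE
    mutable_offset_nt: int = _MUTABLE_OFFSET_NT
    read_len: int = 150

    def __post_init__(self) -> None:
        if len(self.wt_reporter) % 3 != 0:
            raise ValueError("reporter length must be a multiple of 3")
        if not set(self.wt_reporter) <= _VALID_BASES:
            raise ValueError("reporter contains non-ACGT characters")
        end = self.mutable_offset_nt + 3 * self.n_mutable
        if end > len(self.wt_reporter):
            raise ValueError("mutable window extends past the reporter")

    # -- geometry -----------------------------------------------------
    @property
    def insert_len(self) -> int:
        return (
            2 * self.hexamer_len
            + len(self.anchor5)
            + len(self.anchor3)
            + len(self.wt_reporter)
        )

    @property
    def pair_overlap(self) -> int:
        """Overlap (nt) of a forward/reverse read pair on the insert."""
        return 2 * self.read_len - self.insert_len

    @property
    def reporter_start(self) -> int:
        """0-based insert offset of the first reporter base."""
        return self.hexamer_len + len(self.anchor5)

    @property
    def n_reporter_codons(self) -> int:
        return len(self.wt_reporter) // 3

    # -- residue/codon coordinate maps --------------------------------
    @property
    def mutable_residues(self) -> tuple[int, ...]:
        """Protein residue numbers covered by the NNK scan (38..77)."""
        return tuple(
            range(
                self.first_mutable_residue,
                self.first_mutable_residue + self.n_mutable,
            )
        )

    def residue_of_codon(self, codon_index: int) -> int | None:
        """Protein residue for a 0-based reporter codon index, else None."""
        first = self.mutable_offset_nt // 3
        if first <= codon_index < first + self.n_mutable:
            return self.first_mutable_residue + (codon_index - first)
        return None

    def codon_index_of_residue(self, residue: int) -> int:
        if residue not in self.mutable_residues:
            raise ValueError(f"residue {residue} is not a mutable position")
        return self.mutable_offset_nt // 3 + (
            residue - self.first_mutable_residue
        )

    def wt_codon(self, residue: int) -> str:
        i = 3 * self.codon_index_of_residue(residue)
        return self.wt_reporter[i : i + 3]

    def wt_aa(self, residue: int) -> str:
        return str(Seq(self.wt_codon(residue)).translate())

    # -- serialization ------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AmpliconDesign":
        with open(path) as fh:
            return cls(**json.load(fh))


def default_design() -> AmpliconDesign:
    """The published Cd CliM DMS library design."""
    return AmpliconDesign()


def build_reference_amplicon(
    design: AmpliconDesign, hexamers: tuple[str, str]
) -> str:
    """Assemble the 258-nt insert for a given pair of hexamer spacers.

    Returns ``hexamer5 + anchor5 + wt_reporter + anchor3 + hexamer3``.
    """
    h5, h3 = hexamers
    for h in (h5, h3):
        if len(h) != design.hexamer_len:
            raise ValueError(
                f"hexamer {h!r} has length {len(h)}, "
                f"expected {design.hexamer_len}"
            )
        if not set(h) <= _VALID_BASES:
            raise ValueError(f"hexamer {h!r} contains non-ACGT characters")
    return h5 + design.anchor5 + design.wt_reporter + design.anchor3 + h3
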