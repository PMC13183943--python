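"""Synthetic fixtures for every pipeline stage.

Emulates the DMS selection experiment end to end: an NNK single-codon
library over residues 38-77 of the reporter, grown with or without
spectinomycin, where each variant's +Spc growth rate is its planted
relative fitness times the no-antibiotic rate.  Also generates toeprint
peak tables and simple coordinate fixtures (ideal helices, sphere sets)
for the geometry module.

The defaults are the study conditions: two biological replicates, both
antibiotic conditions, 150-bp paired reads over the 258-nt insert,
2x10^5 read pairs per sample, 0.1% per-base substitution error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._fastq import write_fastq_matrix
from .design import AmpliconDesign, NNK_CODONS, default_design
from .steric import AtomSet
from .toeprint import PeakTable, ToeprintCalibration, predict_length
from .variant_calling import translate_codon

__all__ = [
    "SimulationSpec",
    "TruthTable",
    "SimulatedLibrary",
    "random_fitness_map",
    "simulate_library",
    "simulate_toeprint_peaks",
    "make_helix_coords",
    "make_sphere_set",
]

_BASES = np.frombuffer(b"ACGT", np.uint8)

CONDITIONS = ("spc", "nospc")
TIMEPOINTS = ("t0", "t1")

METADATA_COLUMNS = [
    "sample_id", "replicate", "condition", "timepoint",
    "cfu", "culture_hours", "fastq1", "fastq2",
]


@dataclass
class SimulationSpec:
    """Planted truth and sampling parameters for one simulated screen."""

    true_relative_fitness: Mapping[tuple[int, str], float]
    wt_relative_fitness: float = 0.1
    base_growth_rate_nospc: float = 2.0  # doublings per hour
    culture_hours: float = 2.0
    depth_t0: int = 200_000
    depth_t1: int = 200_000
    cfu_t0: int = 1_000_000
    per_base_error: float = 0.001
    wt_fraction: float = 0.1  # un-mutagenized molecules at t0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error <= 1.0:
            raise ValueError("per_base_error must be a probability")
        if not 0.0 <= self.wt_fraction < 1.0:
            raise ValueError("wt_fraction must be in [0, 1)")
        if self.depth_t0 < 0 or self.depth_t1 < 0:
            raise ValueError("depths must be >= 0")
        if self.culture_hours <= 0:
            raise ValueError("culture_hours must be positive")
        if self.cfu_t0 <= 0:
            raise ValueError("cfu_t0 must be positive")
        for (pos, aa), r in self.true_relative_fitness.items():
            if r < 0:
                raise ValueError(
                    f"negative relative fitness for ({pos}, {aa})"
                )


def random_fitness_map(
    design: AmpliconDesign | None = None,
    seed: int = 0,
    low: float = 0.0,
    high: float = 1.2,
) -> dict[tuple[int, str], float]:
    """Planted relative fitness per (residue, amino acid incl. ``*``),
    drawn once uniformly; loss-of-arrest mutants sit near ``high``."""
    design = design or default_design()
    rng = np.random.default_rng(seed)
    amino_acids = sorted({translate_codon(c) for c in NNK_CODONS})
    out: dict[tuple[int, str], float] = {}
    for pos in design.mutable_residues:
        for aa in amino_acids:
            out[(pos, aa)] = float(rng.uniform(low, high))
    return out


@dataclass
class TruthTable:
    """Per-class planted truth: t0 frequency, growth rates, fitness."""

    frame: pd.DataFrame  # position, codon, aa, freq_t0, g_spc, g_nospc, rf

    def __post_init__(self) -> None:
        total = self.frame["freq_t0"].sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"t0 frequencies sum to {total}, not 1")

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"codon": str, "aa": str}))

    def fitness_by_aa(self) -> dict[tuple[int, str], float]:
        df = self.frame[self.frame["codon"] != "WT"]
        return {
            (int(p), a): float(r)
            for p, a, r in zip(df["position"], df["aa"], df["relative_fitness"])
        }


@dataclass
class SimulatedLibrary:
    """Paths and truth of one simulated screen."""

    out_dir: Path
    metadata: pd.DataFrame
    truth: TruthTable
    design: AmpliconDesign
    #: sample_id -> {(position, codon) or "WT": molecules drawn}
    drawn_counts: dict[str, dict] = field(default_factory=dict)

    @property
    def metadata_path(self) -> Path:
        return self.out_dir / "metadata.tsv"


def _build_classes(
    design: AmpliconDesign, spec: SimulationSpec
) -> tuple[list[tuple[int, str]], np.ndarray, np.ndarray, np.ndarray]:
    """Variant classes, t0 frequencies (incl. WT last), growth rates."""
    classes: list[tuple[int, str]] = []
    for pos in design.mutable_residues:
        wt_codon = design.wt_codon(pos)
        for codon in NNK_CODONS:
            if codon != wt_codon:
                classes.append((pos, codon))
    n_pos = design.n_mutable
    # uniform NNK sampling: 1/(n_pos * 32) per (position, codon) draw;
    # draws hitting the WT codon fold into the WT class
    per_class = (1.0 - spec.wt_fraction) / (n_pos * len(NNK_CODONS))
    freqs = np.full(len(classes) + 1, per_class)
    freqs[-1] = 1.0 - per_class * len(classes)  # WT absorbs the rest

    g0 = spec.base_growth_rate_nospc
    g_nospc = np.full(len(classes) + 1, g0)
    rel = np.empty(len(classes) + 1)
    for i, (pos, codon) in enumerate(classes):
        aa = translate_codon(codon)
        try:
            rel[i] = spec.true_relative_fitness[(pos, aa)]
        except KeyError:
            raise ValueError(
                f"true_relative_fitness missing ({pos}, {aa!r})"
            ) from None
    rel[-1] = spec.wt_relative_fitness
    g_spc = rel * g0
    return classes, freqs, g_spc, g_nospc


def _class_reporters(
    design: AmpliconDesign, classes: Sequence[tuple[int, str]]
) -> np.ndarray:
    wt = np.frombuffer(design.wt_reporter.encode(), np.uint8)
    reps = np.tile(wt, (len(classes) + 1, 1))
    for i, (pos, codon) in enumerate(classes):
        at = 3 * design.codon_index_of_residue(pos)
        reps[i, at : at + 3] = np.frombuffer(codon.encode(), np.uint8)
    return reps


def _apply_errors(reads: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0 or reads.size == 0:
        return reads
    mask = rng.random(reads.shape) < rate
    n_err = int(mask.sum())
    if n_err == 0:
        return reads
    idx = {b: i for i, b in enumerate(_BASES)}
    lut = np.zeros(256, np.uint8)
    for b, i in idx.items():
        lut[b] = i
    cur = lut[reads[mask]]
    shift = rng.integers(1, 4, size=n_err)
    reads[mask] = _BASES[(cur + shift) % 4]
    return reads


def _sample_reads(
    design: AmpliconDesign,
    reporters: np.ndarray,
    freqs: np.ndarray,
    depth: int,
    error: float,
    rng,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw reads for one sample; returns (class counts, R1, R2)."""
    L = design.read_len
    counts = rng.multinomial(depth, freqs)
    cls = rng.permutation(np.repeat(np.arange(freqs.size), counts))
    n = cls.size
    if n == 0:
        return counts, np.empty((0, L), np.uint8), np.empty((0, L), np.uint8)
    hex5 = _BASES[rng.integers(0, 4, size=(n, design.hexamer_len))]
    hex3 = _BASES[rng.integers(0, 4, size=(n, design.hexamer_len))]
    a5 = np.frombuffer(design.anchor5.encode(), np.uint8)
    a3 = np.frombuffer(design.anchor3.encode(), np.uint8)
    rep = reporters[cls]
    insert = np.concatenate(
        [
            hex5,
            np.tile(a5, (n, 1)),
            rep,
            np.tile(a3, (n, 1)),
            hex3,
        ],
        axis=1,
    )
    r1 = insert[:, :L].copy()
    # reverse read: reverse complement of the last L nt of the insert
    tail = insert[:, insert.shape[1] - L :]
    comp = np.zeros(256, np.uint8)
    for x, y in zip(b"ACGT", b"TGCA"):
        comp[x] = y
    r2 = comp[tail][:, ::-1].copy()
    r1 = _apply_errors(r1, error, rng)
    r2 = _apply_errors(r2, error, rng)
    return counts, r1, r2


def _phred_char(error: float) -> str:
    q = 40 if error <= 0 else int(round(-10.0 * np.log10(error)))
    return chr(min(q, 40) + 33)


def simulate_library(
    design: AmpliconDesign,
    spec: SimulationSpec,
    out_dir,
) -> SimulatedLibrary:
    """Write paired FASTQs for every (replicate, condition, timepoint),
    a metadata TSV, and the planted truth table.

    Deterministic: identical (design, spec) including the seed produce
    byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    classes, f0, g_spc, g_nospc = _build_classes(design, spec)
    reporters = _class_reporters(design, classes)
    h = spec.culture_hours
    growth = {"spc": g_spc, "nospc": g_nospc}
    qchar = _phred_char(spec.per_base_error)

    rows = []
    drawn_counts: dict[str, dict] = {}
    for rep in range(1, spec.n_replicates + 1):
        for cond in CONDITIONS:
            fold = 2.0 ** (growth[cond] * h)
            z = float(f0 @ fold)  # bulk fold-change of the culture
            f1 = f0 * fold / z
            cfu = {"t0": spec.cfu_t0, "t1": int(round(spec.cfu_t0 * z))}
            freqs = {"t0": f0, "t1": f1}
            depth = {"t0": spec.depth_t0, "t1": spec.depth_t1}
            for tp in TIMEPOINTS:
                sample = f"rep{rep}_{cond}_{tp}"
                counts, r1, r2 = _sample_reads(
                    design, reporters, freqs[tp], depth[tp],
                    spec.per_base_error, rng,
                )
                drawn = {
                    classes[i]: int(c)
                    for i, c in enumerate(counts[:-1])
                    if c > 0
                }
                drawn["WT"] = int(counts[-1])
                drawn_counts[sample] = drawn
                titles = [f"{sample}:{i}" for i in range(r1.shape[0])]
                f1_path = out_dir / f"{sample}_R1.fastq.gz"
                f2_path = out_dir / f"{sample}_R2.fastq.gz"
                write_fastq_matrix(f1_path, titles, r1, qchar)
                write_fastq_matrix(f2_path, titles, r2, qchar)
                rows.append(
                    {
                        "sample_id": sample,
                        "replicate": rep,
                        "condition": cond,
                        "timepoint": tp,
                        "cfu": cfu[tp],
                        "culture_hours": h,
                        "fastq1": f1_path.name,
                        "fastq2": f2_path.name,
                    }
                )

    metadata = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)

    truth_rows = [
        {
            "position": pos,
            "codon": codon,
            "aa": translate_codon(codon),
            "freq_t0": f0[i],
            "g_spc": g_spc[i],
            "g_nospc": g_nospc[i],
            "relative_fitness": g_spc[i] / g_nospc[i],
        }
        for i, (pos, codon) in enumerate(classes)
    ]
    truth_rows.append(
        {
            "position": 0,
            "codon": "WT",
            "aa": "WT",
            "freq_t0": f0[-1],
            "g_spc": g_spc[-1],
            "g_nospc": g_nospc[-1],
            "relative_fitness": g_spc[-1] / g_nospc[-1],
        }
    )
    truth = TruthTable(pd.DataFrame(truth_rows))
    truth.to_tsv(out_dir / "truth.tsv")
    with open(out_dir / "spec.json", "w") as fh:
        json.dump(
            {
                k: v
                for k, v in spec.__dict__.items()
                if k != "true_relative_fitness"
            },
            fh,
            indent=1,
        )
    count_rows = [
        {
            "sample_id": sid,
            "position": (0 if key == "WT" else key[0]),
            "codon": ("WT" if key == "WT" else key[1]),
            "count": n,
        }
        for sid, drawn in drawn_counts.items()
        for key, n in sorted(drawn.items(), key=str)
    ]
    pd.DataFrame(count_rows).to_csv(
        out_dir / "truth_counts.tsv", sep="\t", index=False
    )
    return SimulatedLibrary(
        out_dir=out_dir, metadata=metadata, truth=truth, design=design,
        drawn_counts=drawn_counts,
    )


# ---------------------------------------------------------------------
# Toeprint fixture
# ---------------------------------------------------------------------

def simulate_toeprint_peaks(
    stall_sites: Sequence[tuple[int, float]],
    calib: ToeprintCalibration,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> PeakTable:
    """Peaks at the predicted fragment length of each stall codon, with
    Gaussian-jittered intensities (clipped at 0)."""
    rng = np.random.default_rng(seed)
    peaks = []
    for codon, weight in stall_sites:
        if weight < 0:
            raise ValueError("stall-site weights must be >= 0")
        length = predict_length(codon, calib)
        intensity = max(0.0, weight + float(rng.normal(0.0, noise_sd)))
        peaks.append((length, intensity))
    return PeakTable(peaks)


# ---------------------------------------------------------------------
# Coordinate fixtures
# ---------------------------------------------------------------------

# ideal backbone internal coordinates (lengths Å, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
# dihedrals tuned so the built helix hits the canonical 1.5 A/residue
# rise and ~3 A (i, i+4) O...N separations with the bond geometry above
_PHI_HELIX, _PSI_HELIX, _OMEGA = -62.0, -45.0, 180.0


def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """Natural-extension position of atom d given chain a-b-c."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helix_coords(
    n_res: int,
    phi: float = _PHI_HELIX,
    psi: float = _PSI_HELIX,
    first_res_id: int = 1,
    chain: str = "A",
) -> AtomSet:
    """Ideal poly-alanine-like α-helix backbone (N, CA, C, O per residue).

    The default dihedrals give the canonical α-helix geometry: 1.5 Å
    rise per residue, ~100° turn per residue, and (i, i+4) O···N
    distances near 3 Å (all hydrogen-bondable).  Setting φ/ψ to extended
    values (−180/180) produces a fully extended chain instead.
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    # seed residue placed explicitly in a plane
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        Ni = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi)
        CAi = _place(CA[i - 1], C[i - 1], Ni, _B_N_CA, _A_C_N_CA, _OMEGA)
        Ci = _place(C[i - 1], Ni, CAi, _B_CA_C, _A_N_CA_C, phi)
        N.append(Ni)
        CA.append(CAi)
        C.append(Ci)
    O = [
        _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        for i in range(n_res)
    ]

    chains, rids, rnames, anames, xyz, rad, elem = ([] for _ in range(7))
    from .steric import vdw_radius

    for i in range(n_res):
        for name, pos, el in (
            ("N", N[i], "N"),
            ("CA", CA[i], "C"),
            ("C", C[i], "C"),
            ("O", O[i], "O"),
        ):
            chains.append(chain)
            rids.append(first_res_id + i)
            rnames.append("ALA")
            anames.append(name)
            xyz.append(pos)
            elem.append(el)
            rad.append(vdw_radius(el))
    return AtomSet(
        chain=np.array(chains, dtype=object),
        res_id=np.array(rids),
        res_name=np.array(rnames, dtype=object),
        atom_name=np.array(anames, dtype=object),
        coords=np.array(xyz),
        radius=np.array(rad),
        element=np.array(elem, dtype=object),
    )


def make_sphere_set(
    centers: Sequence[Sequence[float]], radii: Sequence[float]
) -> AtomSet:
    """Arbitrary labeled sphere set for volume-oracle fixtures."""
    return AtomSet.from_spheres(centers, radii)
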