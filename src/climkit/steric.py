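"""Geometry engine: van-der-Waals overlap volumes, sidechain truncation,
backbone hydrogen-bond census, rigid superposition, and functional-mode
analysis of conformational ensembles.

The central quantity is the *overlap volume* between two union-of-spheres
bodies (atoms dressed with van-der-Waals radii), estimated by Monte-Carlo
sampling: uniform points are drawn over the padded bounding box of the
smaller body, and the fraction landing inside at least one sphere of each
body scales the box volume.  This quantifies steric clash, e.g. between
the Leu75 sidechain of an arrest peptide and the GGQ loop of a release
factor poised for accommodation at the peptidyl transferase center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomSet",
    "Ensemble",
    "FunctionalModeResult",
    "BONDI_RADII",
    "mc_overlap_volume",
    "mutate_sidechain",
    "superpose",
    "count_i4_hbonds",
    "extended_length",
    "functional_mode",
]

#: Bondi van-der-Waals radii (Å) by element symbol; 1.70 Å fallback.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "NA": 2.27, "K": 2.75, "ZN": 1.39, "SE": 1.90,
}
_DEFAULT_RADIUS = 1.70

_BACKBONE = ("N", "CA", "C", "O")


def vdw_radius(element: str, overrides: dict[str, float] | None = None) -> float:
    el = element.upper()
    if overrides and el in overrides:
        return overrides[el]
    return BONDI_RADII.get(el, _DEFAULT_RADIUS)


@dataclass
class AtomSet:
    """Labeled 3-D coordinates with van-der-Waals radii (Å)."""

    chain: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    coords: np.ndarray
    radius: np.ndarray
    element: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        self.chain = np.asarray(self.chain, dtype=object)
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.radius = np.asarray(self.radius, dtype=float)
        self.element = np.asarray(self.element, dtype=object)
        for arr in (self.chain, self.res_id, self.res_name,
                    self.atom_name, self.radius, self.element):
            if arr.shape[0] != n:
                raise ValueError("field lengths disagree")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if (self.radius <= 0).any():
            raise ValueError("radii must be positive")

    def __len__(self) -> int:
        return self.coords.shape[0]

    # -- constructors -------------------------------------------------
    @classmethod
    def from_spheres(
        cls, centers: Sequence[Sequence[float]], radii: Sequence[float]
    ) -> "AtomSet":
        centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        radii = np.asarray(radii, dtype=float)
        n = centers.shape[0]
        return cls(
            chain=np.full(n, "X", dtype=object),
            res_id=np.arange(1, n + 1),
            res_name=np.full(n, "SPH", dtype=object),
            atom_name=np.full(n, "X", dtype=object),
            coords=centers,
            radius=radii,
            element=np.full(n, "X", dtype=object),
        )

    @classmethod
    def from_structure(
        cls,
        path,
        model_index: int = 0,
        radius_overrides: dict[str, float] | None = None,
    ) -> "AtomSet":
        """Load atoms from a PDB or mmCIF file (via gemmi)."""
        import gemmi

        st = gemmi.read_structure(str(path))
        st.setup_entities()
        model = st[model_index]
        chains, rids, rnames, anames, xyz, rad, elem = ([] for _ in range(7))
        for ch in model:
            for res in ch:
                for atom in res:
                    chains.append(ch.name)
                    rids.append(res.seqid.num)
                    rnames.append(res.name)
                    anames.append(atom.name)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    el = atom.element.name.upper()
                    elem.append(el)
                    rad.append(vdw_radius(el, radius_overrides))
        return cls(
            chain=np.array(chains, dtype=object),
            res_id=np.array(rids),
            res_name=np.array(rnames, dtype=object),
            atom_name=np.array(anames, dtype=object),
            coords=np.array(xyz, dtype=float),
            radius=np.array(rad, dtype=float),
            element=np.array(elem, dtype=object),
        )

    # -- selection ----------------------------------------------------
    def select(
        self,
        chain: str | None = None,
        res_ids: Sequence[int] | range | None = None,
        atom_names: Sequence[str] | None = None,
    ) -> "AtomSet":
        mask = np.ones(len(self), dtype=bool)
        if chain is not None:
            mask &= self.chain == chain
        if res_ids is not None:
            mask &= np.isin(self.res_id, np.asarray(list(res_ids)))
        if atom_names is not None:
            mask &= np.isin(self.atom_name, np.asarray(list(atom_names),
                                                       dtype=object))
        return self._mask(mask)

    def _mask(self, mask: np.ndarray) -> "AtomSet":
        return AtomSet(
            chain=self.chain[mask],
            res_id=self.res_id[mask],
            res_name=self.res_name[mask],
            atom_name=self.atom_name[mask],
            coords=self.coords[mask],
            radius=self.radius[mask],
            element=self.element[mask],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomSet":
        out = self._mask(np.ones(len(self), dtype=bool))
        out.coords = self.coords @ np.asarray(rotation).T + translation
        return out

    def bounding_box(self, pad: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        return self.coords.min(axis=0) - pad, self.coords.max(axis=0) + pad


# ---------------------------------------------------------------------
# Monte-Carlo overlap volume
# ---------------------------------------------------------------------

def _inside_any(points: np.ndarray, atoms: AtomSet) -> np.ndarray:
    d = cdist(points, atoms.coords)
    return (d <= atoms.radius[None, :]).any(axis=1)


def mc_overlap_volume(
    A: AtomSet,
    B: AtomSet,
    n_samples: int = 1_000_000,
    seed: int | None = None,
    chunk: int = 200_000,
) -> tuple[float, float]:
    """Overlap volume (Å³) of two union-of-spheres bodies, with its
    binomial Monte-Carlo standard error.

    Points are sampled uniformly over the axis-aligned bounding box of
    whichever set has the smaller padded box (pad = that set's largest
    radius); a point counts if it lies inside at least one sphere of A
    *and* at least one sphere of B.  Deterministic under ``seed``.
    """
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both atom sets must be non-empty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")

    boxes = []
    for s in (A, B):
        lo, hi = s.bounding_box(pad=float(s.radius.max()))
        boxes.append((lo, hi, float(np.prod(hi - lo))))
    lo, hi, box_vol = min(boxes, key=lambda t: t[2])

    rng = np.random.default_rng(seed)
    hits = 0
    remaining = int(n_samples)
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.uniform(lo, hi, size=(m, 3))
        inside = _inside_any(pts, A) & _inside_any(pts, B)
        hits += int(np.count_nonzero(inside))
        remaining -= m
    p = hits / n_samples
    volume = box_vol * p
    se = box_vol * float(np.sqrt(p * (1.0 - p) / n_samples))
    return volume, se


# ---------------------------------------------------------------------
# In-silico sidechain truncation
# ---------------------------------------------------------------------

def mutate_sidechain(
    model: AtomSet, chain: str, res_id: int, target: str
) -> AtomSet:
    """Truncate a residue's sidechain to alanine or glycine.

    ALA keeps N, CA, C, O, CB; GLY keeps N, CA, C, O.  The residue is
    renamed; all other atoms of the model are untouched.
    """
    target = target.upper()
    if target not in ("ALA", "GLY"):
        raise ValueError("target must be ALA or GLY")
    keep_names = {"N", "CA", "C", "O", "OXT"}
    if target == "ALA":
        keep_names.add("CB")
    in_res = (model.chain == chain) & (model.res_id == res_id)
    if not in_res.any():
        raise ValueError(f"residue {chain}/{res_id} not found")
    present = set(model.atom_name[in_res])
    missing = set(_BACKBONE) - present
    if missing:
        raise ValueError(
            f"residue {chain}/{res_id} lacks backbone atoms {sorted(missing)}"
        )
    keep = ~in_res | np.isin(model.atom_name,
                             np.asarray(sorted(keep_names), dtype=object))
    out = model._mask(keep)
    renamed = (out.chain == chain) & (out.res_id == res_id)
    out.res_name = out.res_name.copy()
    out.res_name[renamed] = target
    return out


# ---------------------------------------------------------------------
# Rigid superposition (Kabsch)
# ---------------------------------------------------------------------

def superpose(
    mobile: AtomSet | np.ndarray,
    reference: AtomSet | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired atoms.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to the
    reference.  Requires at least 3 non-collinear pairs.
    """
    P = mobile.coords if isinstance(mobile, AtomSet) else np.asarray(mobile, float)
    Q = reference.coords if isinstance(reference, AtomSet) else np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired coordinate arrays of shape (n, 3) required")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 paired atoms required")
    Pc, Qc = P - P.mean(axis=0), Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise ValueError("paired atoms are collinear")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - P.mean(axis=0) @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------
# Backbone i -> i+4 hydrogen-bond census
# ---------------------------------------------------------------------

def count_i4_hbonds(
    model: AtomSet,
    chain: str | None = None,
    residue_range: Sequence[int] | range | None = None,
    max_ON_dist: float = 3.5,
) -> tuple[int, list[tuple[int, int]]]:
    """Count helical (i, i+4) backbone hydrogen bonds.

    A pair counts when the carbonyl oxygen of residue i lies within
    ``max_ON_dist`` Å of the amide nitrogen of residue i+4.  Explicit
    hydrogens are not required; the criterion is the O...N distance.
    """
    sel = model if chain is None else model.select(chain=chain)
    residues = sorted(set(sel.res_id))
    if residue_range is not None:
        wanted = set(residue_range)
        residues = [r for r in residues if r in wanted]
    o_pos: dict[int, np.ndarray] = {}
    n_pos: dict[int, np.ndarray] = {}
    for r in residues:
        in_r = sel.res_id == r
        for name, store in (("O", o_pos), ("N", n_pos)):
            hit = in_r & (sel.atom_name == name)
            if hit.any():
                store[r] = sel.coords[hit][0]
    pairs: list[tuple[int, int]] = []
    for r in residues:
        partner = r + 4
        if partner not in residues:
            continue
        if r not in o_pos or partner not in n_pos:
            warnings.warn(
                f"skipping pair ({r}, {partner}): missing backbone O or N"
            )
            continue
        if np.linalg.norm(o_pos[r] - n_pos[partner]) <= max_ON_dist:
            pairs.append((r, partner))
    return len(pairs), pairs


def extended_length(n_residues: int, rise: float = 3.5) -> float:
    """Length (Å) of a fully extended chain at ``rise`` Å per residue."""
    if n_residues < 0:
        raise ValueError("n_residues must be >= 0")
    return n_residues * rise


# ---------------------------------------------------------------------
# Functional mode analysis
# ---------------------------------------------------------------------

@dataclass
class Ensemble:
    """Conformations over a fixed atom selection plus a scalar observable.

    ``coords`` is (n_frames, n_atoms, 3) or (n_frames, n_features);
    ``replica`` optionally labels each frame's source trajectory for
    replica-wise train/validation splitting.
    """

    coords: np.ndarray
    observable: np.ndarray
    replica: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim == 3:
            c = c.reshape(c.shape[0], -1)
        self.coords = c
        self.observable = np.asarray(self.observable, dtype=float)
        if self.observable.shape[0] != c.shape[0]:
            raise ValueError("observable length must equal frame count")
        if self.replica is not None:
            self.replica = np.asarray(self.replica)
            if self.replica.shape[0] != c.shape[0]:
                raise ValueError("replica labels must match frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def half_replica_split(self) -> np.ndarray:
        """Train mask using the first half of the replica labels."""
        if self.replica is None:
            raise ValueError("ensemble has no replica labels")
        reps = sorted(set(self.replica.tolist()))
        train_reps = set(reps[: len(reps) // 2])
        return np.isin(self.replica, list(train_reps))


@dataclass
class FunctionalModeResult:
    """Unit-norm mode vector with train/validation correlations."""

    mode: np.ndarray
    train_correlation: float
    validation_correlation: float
    projection: np.ndarray
    train_mask: np.ndarray = field(repr=False, default=None)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def functional_mode(
    ensemble: Ensemble,
    train: np.ndarray | str = "half_replicas",
) -> FunctionalModeResult:
    """Single-latent-mode partial least squares.

    Fits, on training frames only, the unit-norm linear combination of
    mean-centered coordinates whose projection has maximal covariance
    with the observable; reports Pearson correlations of the projection
    with the observable on the training and validation frames.
    """
    if isinstance(train, str):
        if train != "half_replicas":
            raise ValueError(f"unknown split spec {train!r}")
        train_mask = ensemble.half_replica_split()
    else:
        train_mask = np.asarray(train, dtype=bool)
        if train_mask.shape[0] != ensemble.n_frames:
            raise ValueError("train mask length must equal frame count")
    if train_mask.sum() < 2:
        raise ValueError("need at least 2 training conformations")

    X, y = ensemble.coords, ensemble.observable
    y_train = y[train_mask]
    if np.ptp(y_train) == 0:
        raise ValueError("observable is constant on the training set")
    x_mean = X[train_mask].mean(axis=0)
    y_mean = y_train.mean()
    Xc = X - x_mean
    w = Xc[train_mask].T @ (y_train - y_mean)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("coordinates carry no covariance with observable")
    w = w / norm
    proj = Xc @ w
    val_mask = ~train_mask
    return FunctionalModeResult(
        mode=w,
        train_correlation=_pearson(proj[train_mask], y_train),
        validation_correlation=_pearson(proj[val_mask], y[val_mask]),
        projection=proj,
        train_mask=train_mask,
    )
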