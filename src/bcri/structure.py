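"""Post-processing of coordinate ensembles around click-labeling sites.

Implements the trajectory analyses that link labeling efficiency to local
protein structure: superposed average structures, crystallographic-convention
B-factors of peptide-bond atoms, the "catchbox" census of atoms around the
strained-alkyne triple bond of BCNK, ring-normal orientation maps with
cross-validated kernel density estimates, and domain-wise Cα superposition
with anchor-centred RMSD profiles (RMSD_0..3).

Coordinates are in Å throughout. Static structures and trajectories are read
from (multi-model) PDB files via biotite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryEnsemble",
    "Catchbox",
    "RingOrientation",
    "RmsdProfile",
    "kabsch",
    "average_structure",
    "bfactors",
    "catchbox_hits",
    "ring_orientation",
    "angle_density_map",
    "CaChain",
    "ca_chain_from_pdb",
    "superpose_and_rmsd",
    "ce_structure_correlation",
    "load_sfe_table",
    "sfe_site_statistics",
    "mature_to_construct",
    "construct_to_mature",
]

#: The His-tagged expression construct shifts residue numbering by +6
#: relative to the mature wild-type sequence.
_CONSTRUCT_OFFSET = 6

#: Peptide-bond atom names; the BCNK pseudo-residue (BCN) renames its
#: backbone to N-C2-C3-O3.
BACKBONE_ATOMS = ("N", "CA", "C", "O")
BCN_BACKBONE_ALIASES = {"CA": "C2", "C": "C3", "O": "O3"}


def mature_to_construct(res_id: int) -> int:
    """Mature wild-type residue number → expression-construct number (+6)."""
    return res_id + _CONSTRUCT_OFFSET


def construct_to_mature(res_id: int) -> int:
    """Expression-construct residue number → mature wild-type number (−6)."""
    return res_id - _CONSTRUCT_OFFSET


@dataclass
class TrajectoryEnsemble:
    """A coordinate ensemble with a constant atom roster.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; atom metadata are
    parallel arrays over the atom axis.
    """

    atom_names: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chains: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n_atoms = self.coords.shape[1]
        for arr in (self.atom_names, self.res_names, self.res_ids, self.chains):
            if len(arr) != n_atoms:
                raise ValueError("atom metadata must match the atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, res_id: int, atom_name: str) -> int:
        hits = np.where((self.res_ids == res_id) & (self.atom_names == atom_name))[0]
        if hits.size == 0:
            raise KeyError(f"atom {atom_name} of residue {res_id} not found")
        return int(hits[0])

    @classmethod
    def from_pdb(cls, path: str) -> "TrajectoryEnsemble":
        """Read a (multi-model) PDB file as a trajectory, one frame per model."""
        import biotite.structure.io.pdb as pdb

        f = pdb.PDBFile.read(path)
        stack = pdb.get_structure(f, altloc="first")
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        return cls(
            atom_names=np.asarray(stack.atom_name),
            res_names=np.asarray(stack.res_name),
            res_ids=np.asarray(stack.res_id),
            chains=np.asarray(stack.chain_id),
            coords=coords,
        )

    def to_pdb(self, path: str) -> None:
        """Write the ensemble as a multi-model PDB file."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        arrays = []
        for i in range(self.n_frames):
            arr = struc.AtomArray(self.n_atoms)
            arr.atom_name = self.atom_names.astype("U6")
            arr.res_name = self.res_names.astype("U5")
            arr.res_id = self.res_ids.astype(int)
            arr.chain_id = self.chains.astype("U4")
            arr.element = np.array(
                [n.lstrip("0123456789")[:1] for n in self.atom_names], dtype="U2"
            )
            arr.coord = self.coords[i]
            arrays.append(arr)
        stack = struc.stack(arrays)
        f = pdb.PDBFile()
        pdb.set_structure(f, stack)
        f.write(path)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (R, t, rmsd) such that ``mobile @ R.T + t`` superposes onto the
    reference. Proper rotation enforced (no reflection).
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape or p.ndim != 2:
        raise ValueError("point sets must share shape (n, 3)")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = qc - r @ pc
    moved = p @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return r, t, rmsd


def _apply(coords: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ r.T + t


def superpose_frames(
    traj: TrajectoryEnsemble, reference: np.ndarray | None = None
) -> TrajectoryEnsemble:
    """Rigid-body superpose every frame onto a reference.

    Default reference is the iterated mean structure (see
    :func:`average_structure`), so the result does not depend on frame order.
    """
    if reference is None:
        reference = average_structure(traj)
    ref = np.asarray(reference, dtype=float)
    out = np.empty_like(traj.coords)
    for i in range(traj.n_frames):
        r, t, _ = kabsch(traj.coords[i], ref)
        out[i] = _apply(traj.coords[i], r, t)
    return TrajectoryEnsemble(
        atom_names=traj.atom_names, res_names=traj.res_names,
        res_ids=traj.res_ids, chains=traj.chains, coords=out,
    )


def _iterated_mean(coords: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Mean structure by iterated superposition onto the running mean.

    Starting from the raw arithmetic mean keeps the result invariant under
    frame permutation (a frame-0 reference would not be); a few fixed-point
    iterations remove the rigid-body spread between frames.
    """
    ref = coords.mean(axis=0)
    for _ in range(n_iter):
        acc = np.zeros_like(ref)
        for i in range(coords.shape[0]):
            r, t, _ = kabsch(coords[i], ref)
            acc += _apply(coords[i], r, t)
        ref = acc / coords.shape[0]
    return ref


def average_structure(
    traj: TrajectoryEnsemble, sub_ranges: int | list[tuple[int, int]] | None = None
) -> np.ndarray:
    """Per-atom mean coordinates after rigid-body superposition of all frames.

    Frames are superposed (least squares over all atoms) onto the running
    mean structure, iterated to a fixed point, so the average is independent
    of frame order. ``sub_ranges`` splits the trajectory into contiguous
    blocks and returns one average per block (an integer requests that many
    equal blocks, the convention used for sub-trajectory averages); all
    blocks are expressed in the global mean's frame.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    mean = _iterated_mean(traj.coords)
    if sub_ranges is None:
        return mean
    sup = superpose_frames(traj, reference=mean)
    if isinstance(sub_ranges, int):
        edges = np.linspace(0, traj.n_frames, sub_ranges + 1).astype(int)
        sub_ranges = [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
    return np.stack([sup.coords[a:b].mean(axis=0) for a, b in sub_ranges])


def bfactors(
    traj: TrajectoryEnsemble,
    residues: list[int],
    atom_names: tuple[str, ...] = BACKBONE_ATOMS,
) -> pd.DataFrame:
    """Crystallographic-convention B-factors of peptide-bond atoms per residue.

    Frames are superposed onto the trajectory average (computed after a first
    superposition pass); for each requested residue the mean-square
    fluctuation of its backbone atoms (N, CA, C, O; the BCN pseudo-residue
    aliases CA→C2, C→C3, O→O3) is converted to B = (8π²/3)·MSF in Å².
    Residues with no matching atoms are skipped with a warning.

    Returns a DataFrame with columns ``res_id, B, rmsf, n_atoms``.
    """
    avg = average_structure(traj)
    sup = superpose_frames(traj, reference=avg)
    rows = []
    for rid in residues:
        sel = np.zeros(traj.n_atoms, dtype=bool)
        for name in atom_names:
            res_here = traj.res_names[traj.res_ids == rid]
            alias = name
            if res_here.size and res_here[0] == "BCN":
                alias = BCN_BACKBONE_ALIASES.get(name, name)
            sel |= (traj.res_ids == rid) & (traj.atom_names == alias)
        if not sel.any():
            warnings.warn(f"residue {rid}: no backbone atoms found, skipped",
                          stacklevel=2)
            continue
        xyz = sup.coords[:, sel, :]
        mean = xyz.mean(axis=0)
        msf = float(np.mean(np.sum((xyz - mean) ** 2, axis=2)))
        rows.append({
            "res_id": rid,
            "B": 8.0 * np.pi**2 / 3.0 * msf,
            "rmsf": float(np.sqrt(msf)),
            "n_atoms": int(sel.sum()),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Catchbox:
    """Cuboid reaction-sampling volume tied to the BCNK triple-bond axis.

    The local x-axis runs along the C14→C15 bond; the box (default
    13.5 × 4.5 × 3.5 Å) is centred on the bond midpoint. The y-axis is the
    component of the vector from the ring centroid to the bond midpoint
    orthogonal to x (a deterministic, chemically meaningful in-plane
    direction), and z = x × y completes the right-handed frame.
    """

    dims: tuple[float, float, float] = (13.5, 4.5, 3.5)

    @property
    def half(self) -> np.ndarray:
        return np.asarray(self.dims, dtype=float) / 2.0


#: Ring-system carbons used to construct the local frame and ring normal.
_RING_ATOMS = ("C11", "C14", "C15", "C18")


def _bcn_frame(
    traj: TrajectoryEnsemble, bcn_residue: int, frame: int
) -> tuple[np.ndarray, np.ndarray]:
    """Local orthonormal axes (3×3, rows x/y/z) and origin for one snapshot."""
    c14 = traj.coords[frame, traj.atom_index(bcn_residue, "C14")]
    c15 = traj.coords[frame, traj.atom_index(bcn_residue, "C15")]
    x = c15 - c14
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("degenerate C14–C15 bond")
    x = x / nx
    origin = 0.5 * (c14 + c15)
    ring_sel = (traj.res_ids == bcn_residue) & np.char.startswith(
        traj.atom_names.astype(str), "C"
    )
    centroid = traj.coords[frame, ring_sel].mean(axis=0)
    y = origin - centroid
    y = y - np.dot(y, x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9:  # centroid on the bond axis: fall back to any orthogonal
        y = np.cross(x, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(y) < 1e-9:
            y = np.cross(x, np.array([0.0, 1.0, 0.0]))
        ny = np.linalg.norm(y)
    y = y / ny
    z = np.cross(x, y)
    return np.stack([x, y, z]), origin


def catchbox_hits(
    traj: TrajectoryEnsemble,
    bcn_residue: int,
    box: Catchbox | None = None,
) -> pd.DataFrame:
    """Census of non-BCNK atoms falling inside the catchbox per snapshot.

    For every frame the local frame is rebuilt from the ring atoms and each
    non-BCNK atom is tested against the centred cuboid (|ξ_i| ≤ dim_i/2 in
    local coordinates). Returns one row per atom that was ever inside, with
    its hit count, hit frequency, and the mean distance from the BCNK
    residue's Cα anchor over its hits.
    """
    box = box or Catchbox()
    for name in ("C14", "C15"):
        traj.atom_index(bcn_residue, name)  # raises if absent
    half = box.half
    non_bcn = traj.res_ids != bcn_residue
    idx_non = np.where(non_bcn)[0]
    try:
        anchor_idx = traj.atom_index(bcn_residue, "C2")  # BCN alias for CA
    except KeyError:
        anchor_idx = traj.atom_index(bcn_residue, "CA")
    hits = np.zeros(idx_non.size, dtype=int)
    dist_sum = np.zeros(idx_non.size)
    for f in range(traj.n_frames):
        axes, origin = _bcn_frame(traj, bcn_residue, f)
        local = (traj.coords[f, idx_non] - origin) @ axes.T
        inside = np.all(np.abs(local) <= half, axis=1)
        hits += inside
        if inside.any():
            anchor = traj.coords[f, anchor_idx]
            d = np.linalg.norm(traj.coords[f, idx_non[inside]] - anchor, axis=1)
            dist_sum[inside] += d
    ever = hits > 0
    return pd.DataFrame({
        "atom_index": idx_non[ever],
        "atom_name": traj.atom_names[idx_non[ever]],
        "res_name": traj.res_names[idx_non[ever]],
        "res_id": traj.res_ids[idx_non[ever]],
        "hit_count": hits[ever],
        "hit_frequency": hits[ever] / traj.n_frames,
        "mean_anchor_distance": dist_sum[ever] / np.maximum(hits[ever], 1),
    })


def point_in_catchbox(
    point: np.ndarray, axes: np.ndarray, origin: np.ndarray, box: Catchbox
) -> bool:
    """Membership test of a single lab-frame point against a posed catchbox."""
    local = axes @ (np.asarray(point, dtype=float) - origin)
    return bool(np.all(np.abs(local) <= box.half))


@dataclass
class RingOrientation:
    """Per-frame spherical angles of the BCNK ring normal (degrees)."""

    polar: np.ndarray  # [0, 180]
    azimuth: np.ndarray  # [-180, 180]
    excluded_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def ring_orientation(
    traj: TrajectoryEnsemble, bcn_residue: int, superpose: bool = True
) -> RingOrientation:
    """Orientation of the BCNK ring normal over the trajectory.

    Per frame, n = normalize((C15−C11) × (C14−C18)); the polar angle is
    arccos(n_z) and the azimuth atan2(n_y, n_x), both in degrees. By default
    frames are first superposed onto the trajectory average so the angles
    live in a consistent molecular frame. Frames with (near-)collinear ring
    vectors are excluded and reported.
    """
    idx = {name: traj.atom_index(bcn_residue, name) for name in _RING_ATOMS}
    work = traj
    if superpose and traj.n_frames > 1:
        avg = average_structure(traj)
        work = superpose_frames(traj, reference=avg)
    v1 = work.coords[:, idx["C15"]] - work.coords[:, idx["C11"]]
    v2 = work.coords[:, idx["C14"]] - work.coords[:, idx["C18"]]
    n = np.cross(v1, v2)
    norm = np.linalg.norm(n, axis=1)
    ok = norm >= 1e-9
    n_ok = n[ok] / norm[ok, None]
    polar = np.degrees(np.arccos(np.clip(n_ok[:, 2], -1.0, 1.0)))
    azimuth = np.degrees(np.arctan2(n_ok[:, 1], n_ok[:, 0]))
    # at the pole the azimuth is undefined; fix it to 0 by convention
    azimuth[np.isclose(polar % 180.0, 0.0)] = 0.0
    return RingOrientation(
        polar=polar, azimuth=azimuth, excluded_frames=np.where(~ok)[0]
    )


def angle_density_map(
    orient: RingOrientation,
    grid_step: float = 2.0,
    bandwidths: np.ndarray | None = None,
    n_levels: int = 8,
    floor: float = 10 ** -6.5,
) -> dict:
    """Gaussian KDE of the (azimuth, polar) angle pairs on a regular grid.

    The kernel bandwidth is chosen by leave-one-out cross-validated grid
    search over 100 logarithmically spaced values between 0.1 and 10 degrees.
    Angles are treated as Euclidean coordinates (no periodic wrap). Returns
    the density grid, its axes, the chosen bandwidth, and ``n_levels``
    log-spaced contour levels from ``floor`` to the density maximum.
    """
    from sklearn.model_selection import GridSearchCV, LeaveOneOut
    from sklearn.neighbors import KernelDensity

    pts = np.column_stack([orient.azimuth, orient.polar])
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 frames for a density map")
    if bandwidths is None:
        bandwidths = np.logspace(np.log10(0.1), np.log10(10.0), 100)
    if np.allclose(pts, pts[0]):
        bw = float(np.min(bandwidths))
    else:
        search = GridSearchCV(
            KernelDensity(kernel="gaussian"),
            {"bandwidth": bandwidths},
            cv=LeaveOneOut(),
        )
        search.fit(pts)
        bw = float(search.best_params_["bandwidth"])
    kde = KernelDensity(kernel="gaussian", bandwidth=bw).fit(pts)
    az_axis = np.arange(-180.0, 180.0 + grid_step, grid_step)
    pol_axis = np.arange(0.0, 180.0 + grid_step, grid_step)
    az_g, pol_g = np.meshgrid(az_axis, pol_axis)
    dens = np.exp(
        kde.score_samples(np.column_stack([az_g.ravel(), pol_g.ravel()]))
    ).reshape(az_g.shape)
    top = max(dens.max(), floor * 10)
    levels = np.logspace(np.log10(floor), np.log10(top), n_levels)
    return {
        "density": dens,
        "azimuth_axis": az_axis,
        "polar_axis": pol_axis,
        "bandwidth": bw,
        "levels": levels,
        "floor": floor,
    }


# ---------------------------------------------------------------------------
# Domain-wise superposition and anchor RMSD profiles


@dataclass
class CaChain:
    """Cα trace of one protein chain: residue ids, one-letter sequence, coords (Å)."""

    res_ids: np.ndarray
    sequence: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.sequence) != self.res_ids.size or self.coords.shape != (
            self.res_ids.size,
            3,
        ):
            raise ValueError("res_ids, sequence and coords must be congruent")


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "BCN": "K",  # BCNK replaces a lysine-like site
}


def ca_chain_from_pdb(path: str, chain_id: str, model: int = 1) -> CaChain:
    """Extract the Cα trace of one chain from a PDB file (first altloc)."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(path)
    arr = pdb.get_structure(f, model=model, altloc="first")
    sel = (arr.chain_id == chain_id) & (arr.atom_name == "CA")
    if not sel.any():
        raise ValueError(f"no Cα atoms for chain '{chain_id}' in {path}")
    res_ids = arr.res_id[sel]
    seq = "".join(_THREE_TO_ONE.get(rn, "X") for rn in arr.res_name[sel])
    return CaChain(res_ids=res_ids, sequence=seq, coords=arr.coord[sel])


def _align_pairs(mobile: CaChain, reference: CaChain) -> list[tuple[int, int]]:
    """Pair Cα indices by global sequence alignment (BLOSUM62)."""
    from biotite.sequence import ProteinSequence
    from biotite.sequence.align import SubstitutionMatrix, align_optimal

    sm = SubstitutionMatrix.std_protein_matrix()
    seq_m = ProteinSequence(mobile.sequence.replace("X", "A"))
    seq_r = ProteinSequence(reference.sequence.replace("X", "A"))
    aln = align_optimal(seq_m, seq_r, sm, gap_penalty=(-10, -1))[0]
    pairs = []
    for i, j in aln.trace:
        if i != -1 and j != -1:
            pairs.append((int(i), int(j)))
    return pairs


@dataclass
class RmsdProfile:
    """Anchor-centred RMSD values after one domain-wise superposition."""

    alignment_scheme: str
    superposition_rmsd: float
    n_pairs: int
    sites: dict  # site res_id (reference numbering) → {"RMSD_0": .., ...}


def superpose_and_rmsd(
    mobile: CaChain,
    reference: CaChain,
    region: tuple[int, int],
    anchors: list[int],
    scheme: str = "",
    outlier_cycles: int = 5,
    outlier_cutoff: float = 2.0,
) -> RmsdProfile:
    """Domain-wise superposition with anchor RMSD profiles RMSD_0..3.

    Residues inside ``region`` (inclusive reference residue-id range) are
    paired by sequence alignment, superposed by least squares with iterative
    outlier rejection (``outlier_cycles`` cycles, rejecting pairs farther than
    ``outlier_cutoff`` × current RMSD; pass ``outlier_cycles=0`` for a pure
    one-shot superposition). The resulting transform is then applied once and
    for each anchor the RMSD over the anchor Cα alone (RMSD_0) and including
    ±1, ±2, ±3 sequence neighbours (RMSD_1..3) is computed without refitting.
    """
    pairs = _align_pairs(mobile, reference)
    lo, hi = region
    in_region = [
        (i, j) for i, j in pairs if lo <= reference.res_ids[j] <= hi
    ]
    if len(in_region) < 10:
        raise ValueError(f"only {len(in_region)} paired Cα in region {region}")
    mi = np.array([i for i, _ in in_region])
    ri = np.array([j for _, j in in_region])
    p = mobile.coords[mi]
    q = reference.coords[ri]

    keep = np.ones(len(in_region), dtype=bool)
    r, t, rmsd = kabsch(p, q)
    for _ in range(outlier_cycles):
        moved = _apply(p[keep], r, t)
        dev = np.linalg.norm(moved - q[keep], axis=1)
        rmsd = float(np.sqrt(np.mean(dev**2)))
        new_keep = keep.copy()
        new_keep[np.where(keep)[0][dev > outlier_cutoff * rmsd]] = False
        if new_keep.sum() < 10 or new_keep.sum() == keep.sum():
            keep = new_keep if new_keep.sum() >= 10 else keep
            break
        keep = new_keep
        r, t, rmsd = kabsch(p[keep], q[keep])

    moved_all = _apply(mobile.coords, r, t)
    pair_of_ref = {int(reference.res_ids[j]): (i, j) for i, j in pairs}
    sites = {}
    for anchor in anchors:
        if anchor not in pair_of_ref:
            warnings.warn(f"anchor {anchor} not paired, skipped", stacklevel=2)
            continue
        profile = {}
        for k in range(4):
            offs = range(-k, k + 1)
            sel_m, sel_r = [], []
            for o in offs:
                rid = anchor + o
                if rid in pair_of_ref:
                    i, j = pair_of_ref[rid]
                    sel_m.append(i)
                    sel_r.append(j)
            d = moved_all[sel_m] - reference.coords[sel_r]
            profile[f"RMSD_{k}"] = float(np.sqrt(np.mean(np.sum(d**2, axis=1))))
        sites[anchor] = profile
    return RmsdProfile(
        alignment_scheme=scheme or f"{lo}-{hi}",
        superposition_rmsd=rmsd,
        n_pairs=int(keep.sum()),
        sites=sites,
    )


# ---------------------------------------------------------------------------
# Solvation-free-energy tables and CE–structure correlation


def sfe_site_statistics(values_per_site: dict, sd_cutoff: float = 3.0) -> pd.DataFrame:
    """Mean ± SEM of sub-trajectory solvation free energies per site.

    Values farther than ``sd_cutoff`` standard deviations from a site's mean
    are disregarded before the final statistics.
    """
    rows = []
    for site, vals in values_per_site.items():
        v = np.asarray(vals, dtype=float)
        if v.size > 1 and v.std(ddof=0) > 0:
            keep = np.abs(v - v.mean()) <= sd_cutoff * v.std(ddof=0)
            v = v[keep]
        rows.append({
            "site": site,
            "dG_solv": v.mean(),
            "sem": v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0,
            "n": v.size,
        })
    return pd.DataFrame(rows)


def load_sfe_table(path: str, check_sum: bool = True, atol: float = 0.05) -> pd.DataFrame:
    """Read a solvation-free-energy table CSV.

    Expected columns: site, dG_solv, dG_pol, dG_cav, dG_disp, sem (kcal/mol).
    The net value must equal the sum of its components within rounding.
    """
    df = pd.read_csv(path)
    required = {"site", "dG_solv", "dG_pol", "dG_cav", "dG_disp", "sem"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SFE table missing columns: {sorted(missing)}")
    if check_sum:
        total = df["dG_pol"] + df["dG_cav"] + df["dG_disp"]
        if not np.allclose(total, df["dG_solv"], atol=atol):
            raise ValueError("dG_solv does not equal the sum of its components")
    return df


def ce_structure_correlation(
    ce: dict,
    structural: dict,
    ce_sem: dict | None = None,
    structural_sem: dict | None = None,
    domains: dict | None = None,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Monte-Carlo Pearson correlation of CE-derived values with structure.

    ``ce`` and ``structural`` map site labels to values (e.g. |ΔCE| against
    RMSD_0, or CE against ΔG_solv). ``domains`` optionally maps site → domain
    label, producing one correlation per domain; otherwise a single global
    correlation. Uncertainties feed the Monte-Carlo resampling of
    :func:`bcri.binding.pearson_mc`.
    """
    from .binding import pearson_mc

    common = sorted(set(ce) & set(structural))
    if len(common) < 3:
        raise ValueError("need at least 3 matched sites")
    groups: dict[str, list] = {}
    for s in common:
        groups.setdefault(domains.get(s, "all") if domains else "all", []).append(s)
    out = {}
    for dom, sites in groups.items():
        if len(sites) < 3:
            warnings.warn(f"domain {dom}: fewer than 3 sites, skipped", stacklevel=2)
            continue
        x = np.array([ce[s] for s in sites])
        y = np.array([structural[s] for s in sites])
        sx = np.array([(ce_sem or {}).get(s, 0.0) for s in sites])
        sy = np.array([(structural_sem or {}).get(s, 0.0) for s in sites])
        out[dom] = pearson_mc(x, y, sx, sy, n_resamples=n_resamples, seed=seed)
        out[dom]["sites"] = sites
    return out
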