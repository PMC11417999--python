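"""Synthetic systems with planted ground truth.

Generates coarse two-chain proteins, composite trajectories with planted
ion-residue pockets, residue-material contacts and rigid motions, and
scored ion-site lists with controlled spacings — everything needed to test
each pipeline stage against known answers without running simulations.

The proteins are deliberately coarse (backbone plus a side-chain centroid):
the contact and pocket analyses depend only on heavy-atom positions and
residue bookkeeping, so these fixtures exercise the statistics exactly
while making no claim to physical realism.  Planted conditions are built
with margins of 1-2 Å around the contact cutoff so that moderate coordinate
noise (sigma up to ~0.5 Å) almost never flips them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import STANDARD_AMINO_ACIDS, Structure
from .ion_sites import IonSite, IonSiteSet, sites_to_structure
from .materials import MaterialSurface
from .traj_analysis import Trajectory


@dataclass
class PlantedPocket:
    """Ground truth for one ion's binding pocket.

    ``residues`` are (chain_id, res_id) pairs; the ion is placed within
    (cutoff - 1) Å of every listed residue in a seeded random subset of
    ceil(occupancy x n_analyzed_frames) analyzed frames, and parked far from
    the whole system otherwise.  ``include_last`` forces (or forbids) the
    last analyzed frame in that subset.
    """

    ion_id: int
    residues: list
    occupancy: float
    include_last: bool = True

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        self.residues = [("A", r) if isinstance(r, int) else (r[0], int(r[1]))
                         for r in self.residues]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic system.

    Defaults emulate the study protein: a two-chain dimer with 162 residues
    per chain, 100 frames of which the first 30 are equilibration.
    """

    n_chains: int = 2
    residues_per_chain: int = 162
    n_frames: int = 100
    equilibration_frames: int = 30
    planted_contacts: dict = field(default_factory=dict)
    planted_pockets: list = field(default_factory=list)
    rigid_motion: tuple | None = None  # (R 3x3, t 3-vector), per frame
    noise_sigma: float = 0.0
    seed: int = 0
    residue_names: dict = field(default_factory=dict)
    contact_cutoff: float = 5.0

    def __post_init__(self):
        for p in self.planted_pockets:
            if not 0.0 <= p.occupancy <= 1.0:
                raise ValueError("occupancy must lie in [0, 1]")
        if self.residues_per_chain < 1:
            raise ValueError("residues_per_chain must be >= 1")


CHAIN_LABELS = "ABCDEFGH"


def make_protein(spec: SyntheticSpec) -> Structure:
    """Coarse multi-chain protein: N, CA, C backbone plus a CB centroid.

    Residues follow a loose helix (Cα spacing ~3.8 Å); chains are laid side
    by side.  Residue names default to ALA and can be overridden per index
    through ``spec.residue_names`` (e.g. ``{129: "ASP"}``), so study-specific
    pockets such as D129/E131 can be named at the right positions.
    """
    names = {int(k): str(v).upper() for k, v in spec.residue_names.items()}
    for v in names.values():
        if v not in STANDARD_AMINO_ACIDS:
            raise ValueError(f"unknown residue name {v!r}")

    helix_radius = 12.0
    dtheta = 3.8 / helix_radius
    rise = 0.6

    atom_id, atom_name, element = [], [], []
    res_id, res_name, chain_id, coords, charge = [], [], [], [], []
    aid = 1
    for c in range(spec.n_chains):
        chain = CHAIN_LABELS[c]
        x_shift = c * 35.0
        for r in range(1, spec.residues_per_chain + 1):
            theta = r * dtheta
            ca = np.array([
                x_shift + helix_radius * math.cos(theta),
                helix_radius * math.sin(theta),
                r * rise,
            ])
            tangent = np.array([-math.sin(theta), math.cos(theta), 0.0])
            radial = np.array([math.cos(theta), math.sin(theta), 0.0])
            rname = names.get(r, "ALA")
            residue_atoms = [
                ("N", "N", ca - 1.25 * tangent, 0.0),
                ("CA", "C", ca, 0.0),
                ("C", "C", ca + 1.25 * tangent, 0.0),
            ]
            if rname != "GLY":
                q = {"ASP": -0.5, "GLU": -0.5,
                     "LYS": 0.5, "ARG": 0.5}.get(rname, 0.0)
                residue_atoms.append(("CB", "C", ca + 1.5 * radial, q))
            for name, el, pos, q in residue_atoms:
                atom_id.append(aid); aid += 1
                atom_name.append(name); element.append(el)
                res_id.append(r); res_name.append(rname)
                chain_id.append(chain); coords.append(pos); charge.append(q)

    return Structure(atom_id, atom_name, element, res_id, res_name,
                     chain_id, np.asarray(coords), charge, "protein")


def _sphere_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-spiral points on the sphere)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _choose_present_frames(rng, analyzed: np.ndarray, occupancy: float,
                           include_last: bool) -> np.ndarray:
    n = len(analyzed)
    m = math.ceil(occupancy * n)
    if m > n or (not include_last and m > n - 1):
        raise ValueError(
            "contradictory schedule: occupancy too high to exclude the "
            "last analyzed frame"
        )
    pool = analyzed[:-1] if not include_last else analyzed
    chosen: set[int] = set()
    if include_last and m > 0:
        chosen.add(int(analyzed[-1]))
    remaining = [f for f in pool if f not in chosen]
    extra = m - len(chosen)
    if extra > 0:
        chosen.update(int(f) for f in
                      rng.choice(remaining, size=extra, replace=False))
    return np.array(sorted(chosen), dtype=int)


def make_trajectory(protein: Structure,
                    material: MaterialSurface | None,
                    ions: IonSiteSet | Structure | None,
                    spec: SyntheticSpec) -> Trajectory:
    """Compose a trajectory with planted pockets, contacts and rigid motion.

    The composite system stacks the protein (chains A, B, ...), the material
    (chain M) below it, and one single-atom residue per ion (chain I).
    Planted pocket residues are relocated onto a small sphere (radius 3 Å)
    around a per-ion anchor well away from everything else; in pocket-present
    frames the ion sits at the anchor (within cutoff - 1 Å of every pocket
    residue) and otherwise it is parked at least cutoff + 2 Å from the whole
    system.  Gaussian noise of ``noise_sigma`` is added to all coordinates
    in every frame.
    """
    rng = np.random.default_rng(spec.seed)
    cutoff = spec.contact_cutoff

    ion_struct = None
    if ions is not None:
        ion_struct = (sites_to_structure(ions)
                      if isinstance(ions, IonSiteSet) else ions)

    prot = protein.copy()
    # keep the protein comfortably above the material so that only planted
    # contacts can reach it
    if material is not None:
        mat_zmax = material.structure.coords[:, 2].max()
        lift = (mat_zmax + cutoff + 5.0) - prot.coords[:, 2].min()
        prot = prot.translated([0.0, 0.0, lift])

    res_atoms: dict[tuple, np.ndarray] = {}
    for key, grp in _group_by_residue(prot):
        res_atoms[key] = grp

    # relocate planted pocket residues onto per-ion anchor spheres
    anchors: dict[int, np.ndarray] = {}
    zmax = prot.coords[:, 2].max()
    centroid = prot.centroid()
    for k, pocket in enumerate(spec.planted_pockets):
        anchor = np.array([centroid[0] + 40.0 * (k + 1),
                           centroid[1], zmax + 12.0])
        anchors[pocket.ion_id] = anchor
        dirs = _sphere_directions(max(len(pocket.residues), 4))
        for j, (chain, rid) in enumerate(pocket.residues):
            if (chain, rid) not in res_atoms:
                raise ValueError(
                    f"planted pocket residue {chain}:{rid} not in protein")
            idx = res_atoms[(chain, rid)]
            base = anchor + 3.0 * dirs[j]
            spread = _sphere_directions(len(idx)) * 0.3
            prot.coords[idx] = base + spread

    parts = [prot]
    offsets = {"protein": 0}
    if material is not None:
        offsets["material"] = parts[-1].n_atoms + offsets.get("protein", 0)
        parts.append(material.structure)
    if ion_struct is not None:
        offsets["ion"] = sum(p.n_atoms for p in parts)
        parts.append(ion_struct)

    base = _stack_parts(parts)
    n_atoms = base.n_atoms
    prot_slice = slice(0, prot.n_atoms)
    ion_offset = offsets.get("ion")

    # per-ion frame schedules
    analyzed = np.arange(spec.equilibration_frames, spec.n_frames)
    schedules: dict[int, set] = {}
    for pocket in spec.planted_pockets:
        present = _choose_present_frames(rng, analyzed, pocket.occupancy,
                                         pocket.include_last)
        schedules[pocket.ion_id] = set(present.tolist())

    # planted residue-material contact schedules
    contact_site = None
    if material is not None:
        mcoords = material.structure.coords
        top = mcoords[np.argmax(mcoords[:, 2])]
        contact_site = top + np.array([0.0, 0.0, cutoff - 1.0])
    contact_sched = {}
    for res, sched in spec.planted_contacts.items():
        key = ("A", res) if isinstance(res, int) else (res[0], int(res[1]))
        if key not in res_atoms:
            raise ValueError(f"planted contact residue {key} not in protein")
        contact_sched[key] = np.asarray(sched, dtype=bool)

    # cumulative rigid motion applied to the protein (and pocket anchors)
    R_step = t_step = None
    if spec.rigid_motion is not None:
        R_step = np.asarray(spec.rigid_motion[0], dtype=float).reshape(3, 3)
        t_step = np.asarray(spec.rigid_motion[1], dtype=float).reshape(3)

    frames = np.empty((spec.n_frames, n_atoms, 3))
    prot_coords = base.coords[prot_slice].copy()
    cum_shift = np.zeros(3)
    R_cum = np.eye(3)
    for f in range(spec.n_frames):
        coords = base.coords.copy()
        if R_step is not None and f > 0:
            R_cum = R_step @ R_cum
            cum_shift = R_step @ cum_shift + t_step
        center = prot_coords.mean(axis=0)
        coords[prot_slice] = ((prot_coords - center) @ R_cum.T + center
                              + cum_shift)
        for key, sched in contact_sched.items():
            if f < len(sched) and sched[f] and contact_site is not None:
                idx = res_atoms[key]
                spread = _sphere_directions(len(idx)) * 0.3
                coords[idx] = contact_site + spread
        if ion_offset is not None:
            for pocket in spec.planted_pockets:
                ion_atom = ion_offset + pocket.ion_id
                anchor = ((anchors[pocket.ion_id] - center) @ R_cum.T
                          + center + cum_shift)
                if f in schedules[pocket.ion_id]:
                    coords[ion_atom] = anchor
                else:
                    coords[ion_atom] = anchor + np.array(
                        [0.0, 0.0, 40.0 + 10.0 * pocket.ion_id])
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma,
                                         size=coords.shape)
        frames[f] = coords

    return Trajectory(structure=base, coords=frames,
                      frame_interval=1.0,
                      equilibration_frames=spec.equilibration_frames)


def _group_by_residue(structure: Structure):
    keys: dict[tuple, list[int]] = {}
    for i in range(structure.n_atoms):
        keys.setdefault((str(structure.chain_id[i]),
                         int(structure.res_id[i])), []).append(i)
    return [(k, np.asarray(v)) for k, v in keys.items()]


def _stack_parts(parts) -> Structure:
    out = Structure.concatenate(parts, entity_label="protein")
    out.atom_id = np.arange(1, out.n_atoms + 1)
    return out


def make_site_list(n: int, cluster_spacings, seed: int = 0,
                   species: str = "Cd") -> IonSiteSet:
    """Scored sites chained along a line with controlled consecutive gaps.

    Site ``i`` sits ``cluster_spacings[(i - 1) % len]`` Å after site
    ``i - 1`` along the x axis, so every pairwise distance is known by
    construction (non-consecutive distances are sums of gaps).  Scores
    decrease with index, with a tiny seeded jitter keeping them distinct.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spacings = list(np.atleast_1d(np.asarray(cluster_spacings, dtype=float)))
    rng = np.random.default_rng(seed)
    x = 0.0
    sites = []
    for i in range(n):
        if i > 0:
            x += spacings[(i - 1) % len(spacings)]
        score = float(n - i) + float(rng.uniform(0.0, 1e-6))
        sites.append(IonSite(position=np.array([x, 0.0, 0.0]),
                             score=score, species=species,
                             origin="predicted"))
    return IonSiteSet(sites)
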