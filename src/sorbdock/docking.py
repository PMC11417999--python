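"""Random-orientation rigid-body docking of a protein onto a material slab.

A docking campaign runs many independent rounds.  Each round translates the
protein above the material along +z, rotates it 90° about a random axis (a
uniform re-orientation), and settles it toward the surface by rigid-body
descent on the interaction energy.  Poses are scored twice — a 12-6
Lennard-Jones + Coulomb interaction energy and a distance-binned contact
potential — and the final pose is chosen by a top-k consensus over both
scorers.

The protein is exactly rigid throughout: settling moves it only as a whole,
so internal geometry is preserved to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Structure
from .geometry import random_unit_vector, rotation_about_axis
from .materials import MaterialSurface

logger = logging.getLogger(__name__)

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_CONST = 332.0636

#: Generic per-element Lennard-Jones parameters (epsilon kcal/mol, sigma Å).
#: These provide a consistent, configurable interaction field for pose
#: ranking; they are not force-field parameters.
DEFAULT_LJ = {
    "H": (0.030, 1.40), "C": (0.086, 3.40), "N": (0.170, 3.25),
    "O": (0.210, 2.96), "S": (0.250, 3.55), "P": (0.200, 3.70),
    "Mg": (0.060, 2.40), "Al": (0.100, 3.00), "Si": (0.150, 3.40),
    "Ca": (0.120, 2.90), "Cd": (0.200, 2.55), "Pb": (0.300, 3.10),
    "Cl": (0.150, 3.40), "Na": (0.047, 2.43),
}

#: Default distance-binned contact-potential table (edges Å, one weight per
#: bin); pairs beyond the last edge — or closer than the first — contribute 0.
DEFAULT_CONTACT_BINS = (
    np.array([2.0, 3.0, 4.0, 5.0, 6.0, 8.0]),
    np.array([-0.4, -1.0, -0.6, -0.3, -0.1]),
)

_PAIR_MATRIX_LIMIT = 5_000_000  # switch to KD-tree above this pair count


@dataclass
class Pose:
    """A rigid placement of the protein relative to a fixed material.

    The transform maps original protein coordinates x to ``R @ x + t``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    round_index: int = 0
    interaction_energy: float | None = None
    contact_potential: float | None = None
    initial_energy: float | None = None

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation matrix determinant must be +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class ScoredPoseSet:
    """A pose collection, optionally with a consensus-selected member."""

    poses: list[Pose]
    selected_index: int | None = None

    def __post_init__(self):
        if self.selected_index is not None and not (
                0 <= self.selected_index < len(self.poses)):
            raise ValueError("selected_index out of range")

    @property
    def selected(self) -> Pose:
        if self.selected_index is None:
            raise ValueError("no pose selected yet")
        return self.poses[self.selected_index]


def _material_structure(material) -> Structure:
    return material.structure if isinstance(material, MaterialSurface) else material


def _lj_arrays(elements: np.ndarray, lj_params: dict) -> tuple[np.ndarray, np.ndarray]:
    missing = sorted({str(e) for e in elements} - set(lj_params))
    if missing:
        raise ValueError(f"missing Lennard-Jones parameters for elements: "
                         f"{', '.join(missing)}")
    eps = np.array([lj_params[str(e)][0] for e in elements])
    sig = np.array([lj_params[str(e)][1] for e in elements])
    return eps, sig


class _PairField:
    """Precomputed protein-material pair interaction evaluator.

    The material is fixed, so its parameter arrays are cached; energies and
    rigid-translation gradients are evaluated for arbitrary protein
    coordinates.  Lorentz-Berthelot combination rules are used for the LJ
    cross terms.
    """

    def __init__(self, protein: Structure, material, lj_params=None,
                 cutoff: float = 12.0):
        lj_params = lj_params or DEFAULT_LJ
        mat = _material_structure(material)
        self.p_eps, self.p_sig = _lj_arrays(protein.element, lj_params)
        self.m_eps, self.m_sig = _lj_arrays(mat.element, lj_params)
        self.p_q = protein.charge
        self.m_q = mat.charge
        self.m_coords = mat.coords
        self.cutoff = float(cutoff)
        self._tree = (cKDTree(self.m_coords)
                      if protein.n_atoms * mat.n_atoms > _PAIR_MATRIX_LIMIT
                      else None)

    def _pairs(self, p_coords):
        if self._tree is None:
            diff = p_coords[:, None, :] - self.m_coords[None, :, :]
            r2 = np.einsum("ijk,ijk->ij", diff, diff)
            ii, jj = np.nonzero(r2 <= self.cutoff * self.cutoff)
            d = diff[ii, jj]
        else:
            pairs = cKDTree(p_coords).query_ball_tree(self._tree, self.cutoff)
            ii = np.repeat(np.arange(len(p_coords)),
                           [len(p) for p in pairs])
            jj = np.concatenate([np.asarray(p, dtype=int) for p in pairs]
                                ) if len(ii) else np.empty(0, dtype=int)
            d = p_coords[ii] - self.m_coords[jj]
        return ii, jj, d

    def energy(self, p_coords: np.ndarray) -> float:
        return self.energy_and_gradient(p_coords, gradient=False)[0]

    def energy_and_gradient(self, p_coords: np.ndarray, gradient: bool = True
                            ) -> tuple[float, np.ndarray]:
        ii, jj, d = self._pairs(p_coords)
        if len(ii) == 0:
            return 0.0, np.zeros(3)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        r = np.maximum(r, 1e-9)
        eps = np.sqrt(self.p_eps[ii] * self.m_eps[jj])
        sig = 0.5 * (self.p_sig[ii] + self.m_sig[jj])
        sr6 = (sig / r) ** 6
        qq = COULOMB_CONST * self.p_q[ii] * self.m_q[jj]
        energy = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6) + qq / r))
        if not gradient:
            return energy, np.zeros(3)
        # dE/dr per pair, projected on the pair direction and summed: the
        # gradient of the energy w.r.t. a rigid translation of the protein
        dEdr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r - qq / r ** 2
        grad = (dEdr / r)[:, None] * d
        return energy, grad.sum(axis=0)


def interaction_energy(entity_a: Structure, entity_b,
                       lj_params: dict | None = None,
                       cutoff: float = 12.0) -> float:
    """Pairwise 12-6 Lennard-Jones + Coulomb inter-entity energy (kcal/mol).

    Sums over all cross pairs within ``cutoff``; no intra-entity terms are
    included, so the energy is additive over disjoint sub-entities and
    symmetric in its two arguments.  Elements without LJ parameters raise an
    error naming them.
    """
    a = _material_structure(entity_a)
    field = _PairField(a, entity_b, lj_params, cutoff)
    return field.energy(a.coords)


def contact_potential(protein: Structure, material,
                      bins: tuple[np.ndarray, np.ndarray] | None = None
                      ) -> float:
    """Distance-binned heavy-atom pair potential (dimensionless).

    ``bins`` is ``(edges, weights)`` with strictly increasing edges and one
    weight per bin; each protein-material heavy-atom pair contributes the
    weight of the bin its distance falls in, and pairs outside the binned
    range contribute nothing.  This serves as the second, knowledge-based
    scorer in the docking consensus.
    """
    edges, weights = bins if bins is not None else DEFAULT_CONTACT_BINS
    edges = np.asarray(edges, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if len(weights) != len(edges) - 1:
        raise ValueError("need exactly one weight per bin")

    mat = _material_structure(material)
    p = protein.coords[protein.heavy_mask]
    m = mat.coords[mat.heavy_mask]
    if len(p) == 0 or len(m) == 0:
        return 0.0
    rmax = edges[-1]
    if len(p) * len(m) <= _PAIR_MATRIX_LIMIT:
        r = np.linalg.norm(p[:, None, :] - m[None, :, :], axis=-1).ravel()
        r = r[r <= rmax]
    else:
        tree = cKDTree(m)
        neighbours = tree.query_ball_point(p, rmax)
        r = np.concatenate([
            np.linalg.norm(p[i] - m[np.asarray(nb, dtype=int)], axis=1)
            for i, nb in enumerate(neighbours) if nb
        ]) if any(neighbours) else np.empty(0)
    idx = np.searchsorted(edges, r, side="right") - 1
    valid = (idx >= 0) & (idx < len(weights))
    return float(weights[idx[valid]].sum())


# ---------------------------------------------------------------------------
# Pose generation and settling


def generate_pose(protein: Structure, material, z_offset: float,
                  seed: int, round_index: int = 0) -> Pose:
    """Place the protein above the material and rotate it 90° about a random axis.

    The protein centroid is moved over the material's x-y centre at height
    ``z_offset`` above the material's z mid-plane, then the protein is
    rotated about its own centre by 90° around a seeded uniformly random
    unit axis.  ``z_offset`` must exceed the material half-thickness plus
    the protein bounding radius, or the bodies could overlap at the start.
    """
    mat = _material_structure(material)
    rng = np.random.default_rng(seed)
    cp = protein.centroid()
    mat_center = mat.coords.mean(axis=0)
    half_thickness = 0.5 * (mat.coords[:, 2].max() - mat.coords[:, 2].min())
    radius = float(np.linalg.norm(protein.coords - cp, axis=1).max())
    if z_offset < half_thickness + radius:
        raise ValueError(
            f"z_offset {z_offset:.2f} Å < material half-thickness "
            f"({half_thickness:.2f}) + protein radius ({radius:.2f}): "
            "bodies would overlap at the start"
        )
    target = np.array([mat_center[0], mat_center[1],
                       0.5 * (mat.coords[:, 2].max() + mat.coords[:, 2].min())
                       + z_offset])
    axis = random_unit_vector(rng)
    R = rotation_about_axis(axis, np.pi / 2.0)
    # translate centroid to target, then rotate about the (moved) centroid:
    # x -> R (x - cp) + target
    t = target - R @ cp
    return Pose(rotation=R, translation=t, round_index=round_index)


def default_z_offset(protein: Structure, material) -> float:
    """Material max-z extent plus protein bounding radius plus 5 Å."""
    mat = _material_structure(material)
    cp = protein.centroid()
    radius = float(np.linalg.norm(protein.coords - cp, axis=1).max())
    half_thickness = 0.5 * (mat.coords[:, 2].max() - mat.coords[:, 2].min())
    return half_thickness + radius + 5.0


def settle_pose(pose: Pose, protein: Structure, material,
                lj_params: dict | None = None, cutoff: float = 12.0,
                step: float = 0.5, max_steps: int = 200,
                min_step: float = 1e-3,
                field: "_PairField | None" = None) -> Pose:
    """Rigid-body descent of the posed protein toward lower interaction energy.

    The protein moves only by whole-body translation down the interaction
    energy gradient, with backtracking (step halving on any energy increase
    or non-finite energy) and modest step growth after accepted moves.  The
    material never moves, the protein's internal geometry is untouched, and
    the returned energy is never above the starting energy.
    """
    if field is None:
        field = _PairField(protein, material, lj_params, cutoff)
    coords = pose.apply(protein.coords)
    energy, grad = field.energy_and_gradient(coords)
    e0 = energy
    shift = np.zeros(3)
    step0 = step
    for _ in range(max_steps):
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-12:
            break  # at a stationary point; pose returned unchanged
        direction = -grad / gnorm
        trial_shift = direction * step
        e_trial, g_trial = field.energy_and_gradient(coords + trial_shift)
        if not np.isfinite(e_trial) or e_trial > energy:
            step *= 0.5
            if step < min_step:
                break
            continue
        coords = coords + trial_shift
        shift = shift + trial_shift
        energy, grad = e_trial, g_trial
        step = min(step * 1.2, 2.0 * step0)
    return Pose(
        rotation=pose.rotation, translation=pose.translation + shift,
        round_index=pose.round_index, interaction_energy=energy,
        contact_potential=pose.contact_potential, initial_energy=e0,
    )


# ---------------------------------------------------------------------------
# Consensus ranking


def _competition_rank(values, i) -> int:
    """1-based competition rank of value i (ties share the lowest rank)."""
    return 1 + sum(1 for v in values if v < values[i])


def consensus_rank(pose_set: ScoredPoseSet, k: int = 5) -> ScoredPoseSet:
    """Select a pose by summed rank over the two scorers' top-k lists.

    The k lowest interaction energies get ranks 1..k, likewise the k lowest
    contact potentials; tied scores share their (competition) rank.  A pose
    in both top lists scores the sum of its ranks; a pose in only one list
    scores its rank plus a ``k + 1`` penalty for the missing list.  The
    lowest total wins; ties fall to the lower interaction energy, then the
    lower round index.
    """
    poses = pose_set.poses
    if any(p.interaction_energy is None or p.contact_potential is None
           for p in poses):
        raise ValueError("all poses must carry both scores")
    n = len(poses)
    if n == 0:
        raise ValueError("empty pose set")
    if n < k:
        logger.warning("only %d poses; reducing consensus k from %d", n, k)
        k = n

    energies = [p.interaction_energy for p in poses]
    contacts = [p.contact_potential for p in poses]
    rank_e = {i: _competition_rank(energies, i) for i in range(n)}
    rank_c = {i: _competition_rank(contacts, i) for i in range(n)}
    rank_e = {i: r for i, r in rank_e.items() if r <= k}
    rank_c = {i: r for i, r in rank_c.items() if r <= k}

    candidates = sorted(set(rank_e) | set(rank_c))
    best = min(candidates, key=lambda i: (
        rank_e.get(i, k + 1) + rank_c.get(i, k + 1),
        poses[i].interaction_energy,
        poses[i].round_index,
    ))
    return ScoredPoseSet(poses=poses, selected_index=best)


# ---------------------------------------------------------------------------
# Campaign


def run_campaign(
    protein: Structure,
    material,
    n_rounds: int = 1000,
    seed: int = 0,
    z_offset: float | None = None,
    lj_params: dict | None = None,
    cutoff: float = 12.0,
    bins: tuple[np.ndarray, np.ndarray] | None = None,
    step: float = 0.5,
    max_steps: int = 200,
    k: int = 5,
) -> ScoredPoseSet:
    """Run a full docking campaign and pick the consensus pose.

    Every round is seeded from the single master seed, so the entire
    campaign — axes, settling paths and scores — is bit-reproducible.
    """
    if z_offset is None:
        z_offset = default_z_offset(protein, material)
    round_seeds = np.random.SeedSequence(seed).generate_state(n_rounds)
    field = _PairField(protein, material, lj_params, cutoff)
    poses = []
    for i in range(n_rounds):
        pose = generate_pose(protein, material, z_offset,
                             seed=int(round_seeds[i]), round_index=i)
        settled = settle_pose(pose, protein, material, step=step,
                              max_steps=max_steps, field=field)
        settled.contact_potential = contact_potential(
            protein.with_coords(settled.apply(protein.coords)),
            material, bins)
        poses.append(settled)
    return consensus_rank(ScoredPoseSet(poses), k=k)


def pose_to_complex(pose: Pose, protein: Structure, material) -> Structure:
    """Materialize a pose as a single protein+material structure."""
    mat = _material_structure(material)
    placed = protein.with_coords(pose.apply(protein.coords))
    mat_renumbered = mat.copy()
    mat_renumbered.atom_id = mat.atom_id + protein.n_atoms
    return Structure.concatenate([placed, mat_renumbered],
                                 entity_label="protein")


# ---------------------------------------------------------------------------
# Pose archive I/O


def write_pose_table(pose_set: ScoredPoseSet, path) -> None:
    """Write poses as a tab-separated table (round, quaternion, translation,
    scores, selection flag)."""
    import pandas as pd
    from scipy.spatial.transform import Rotation

    rows = []
    for i, p in enumerate(pose_set.poses):
        qx, qy, qz, qw = Rotation.from_matrix(p.rotation).as_quat()
        rows.append({
            "round": p.round_index,
            "qx": qx, "qy": qy, "qz": qz, "qw": qw,
            "tx": p.translation[0], "ty": p.translation[1],
            "tz": p.translation[2],
            "interaction_energy": p.interaction_energy,
            "contact_potential": p.contact_potential,
            "selected": int(i == pose_set.selected_index),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pose_table(path) -> ScoredPoseSet:
    import pandas as pd
    from scipy.spatial.transform import Rotation

    df = pd.read_csv(path, sep="\t")
    poses, selected = [], None
    for i, row in df.iterrows():
        R = Rotation.from_quat([row["qx"], row["qy"], row["qz"], row["qw"]]
                               ).as_matrix()
        poses.append(Pose(
            rotation=R,
            translation=np.array([row["tx"], row["ty"], row["tz"]]),
            round_index=int(row["round"]),
            interaction_energy=float(row["interaction_energy"]),
            contact_potential=float(row["contact_potential"]),
        ))
        if int(row["selected"]):
            selected = i
    return ScoredPoseSet(poses, selected_index=selected)
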