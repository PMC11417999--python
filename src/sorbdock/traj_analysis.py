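"""Trajectory analyses for protein-amended sorbent systems.

Implements the post-simulation workflow: heavy-atom contact criteria,
protein-material contact probability with a residue-type decomposition,
three RMSD modes, a consensus rule for selecting the best-formed trajectory,
per-frame ion binding-mode classification, and persistence-based mining of
metal-ion binding pockets with cross-system reporting.

All statistics run on the analyzed frames only: the first
``equilibration_frames`` snapshots of each trajectory are treated as an
extra equilibration stage and excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import THREE_TO_ONE, Structure, _atom_array_to_structure
from .geometry import kabsch, rmsd as _rmsd

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 5.0  # Å, inclusive heavy-atom contact criterion

BACKBONE_NAMES = ("N", "CA", "C")

#: Residue-type classes used for the contact decomposition.
RESIDUE_CLASSES = {
    "positive": {"ARG", "HIS", "LYS"},
    "negative": {"ASP", "GLU"},
    "polar": {"THR", "SER", "GLN", "ASN"},
    "other": {"CYS", "GLY", "PRO", "MET", "ALA", "VAL", "ILE", "LEU",
              "PHE", "TYR", "TRP"},
}

BINDING_MODES = ("protein_and_material", "protein_only", "material_only",
                 "unbound")


# ---------------------------------------------------------------------------
# Trajectory container and I/O


@dataclass
class Trajectory:
    """Frame sequence over a composite system (protein + material + ions).

    ``coords`` has shape (n_frames, n_atoms, 3) over the fixed atom order of
    ``structure``; ``frame_interval`` is in ns per frame.  The first
    ``equilibration_frames`` frames are excluded from every analysis.
    """

    structure: Structure
    coords: np.ndarray
    frame_interval: float = 1.0
    equilibration_frames: int = 0
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.structure.n_atoms:
            raise ValueError("frame atom count differs from the structure")
        if not 0 <= self.equilibration_frames < self.n_frames:
            raise ValueError("equilibration_frames must be < frame count")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def analyzed_indices(self, stride: int = 1) -> np.ndarray:
        return np.arange(self.equilibration_frames, self.n_frames, stride)


def _read_pdb_trajectory(path) -> tuple[Structure, np.ndarray]:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if stack.stack_depth() == 0:
        raise ValueError(f"{path}: no models found")
    template = _atom_array_to_structure(stack[0], "protein")
    return template, np.asarray(stack.coord, dtype=float)


#: Pluggable trajectory readers: format name -> callable(path) returning
#: (template Structure, coords array).  Binary formats can be registered
#: here without touching the analysis code.
TRAJECTORY_READERS = {"pdb": _read_pdb_trajectory}


def read_trajectory(path, format: str = "pdb", frame_interval: float = 1.0,
                    equilibration_frames: int = 0,
                    box=None) -> Trajectory:
    """Read a multi-frame trajectory (multi-model PDB by default)."""
    if format not in TRAJECTORY_READERS:
        raise ValueError(f"no trajectory reader registered for {format!r}")
    template, coords = TRAJECTORY_READERS[format](path)
    return Trajectory(structure=template, coords=coords,
                      frame_interval=frame_interval,
                      equilibration_frames=equilibration_frames, box=box)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB (MODEL/ENDMDL records)."""
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    from .core import _structure_to_atom_array

    template = _structure_to_atom_array(traj.structure)
    stack = bst.stack([template] * traj.n_frames)
    stack.coord = traj.coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selections


def select_chains(structure: Structure, chains) -> np.ndarray:
    """Boolean atom mask for a set of chain identifiers."""
    chains = {chains} if isinstance(chains, str) else set(chains)
    return np.isin(structure.chain_id, sorted(chains))


def backbone_mask(structure: Structure, within=None) -> np.ndarray:
    """Mask of protein backbone atoms (N, Cα, C), optionally restricted."""
    mask = np.isin(structure.atom_name, BACKBONE_NAMES)
    if within is not None:
        mask &= np.asarray(within, dtype=bool)
    return mask


# ---------------------------------------------------------------------------
# Contact criterion


def _min_distance(a: np.ndarray, b: np.ndarray,
                  box: np.ndarray | None = None) -> float:
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if box is None:
        if len(a) * len(b) <= 2_000_000:
            d = a[:, None, :] - b[None, :, :]
            return float(np.sqrt(np.einsum("ijk,ijk->ij", d, d).min()))
        return float(cKDTree(b).query(a)[0].min())
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)  # minimum image
    return float(np.sqrt(np.einsum("ijk,ijk->ij", d, d).min()))


def _heavy_coords(entity) -> np.ndarray:
    if isinstance(entity, Structure):
        return entity.coords[entity.heavy_mask]
    return np.atleast_2d(np.asarray(entity, dtype=float))


def in_contact(entity_a, entity_b, cutoff: float = DEFAULT_CONTACT_CUTOFF,
               box=None) -> bool:
    """Heavy-atom contact criterion between two entities.

    True iff any heavy-atom pair across the two entities is within
    ``cutoff`` (inclusive).  Entities may be :class:`Structure` objects
    (hydrogens are ignored) or raw coordinate arrays (assumed heavy).
    Minimum-image distances are used when a periodic ``box`` is supplied.
    """
    a = _heavy_coords(entity_a)
    b = _heavy_coords(entity_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("contact test requires non-empty heavy-atom sets")
    box = None if box is None else np.asarray(box, dtype=float)
    return _min_distance(a, b, box) <= cutoff


# ---------------------------------------------------------------------------
# Contact probability


@dataclass
class ContactTable:
    """Protein-material contact statistics over the analyzed frames."""

    per_residue: dict
    aggregate_percent: float
    residue_class_breakdown: dict
    per_chain_mean_bound: dict
    n_frames_analyzed: int = 0


def _residue_groups(structure: Structure, mask: np.ndarray
                    ) -> list[tuple[tuple, np.ndarray]]:
    """Heavy-atom index groups keyed by (chain, res_id, res_name)."""
    idx = np.where(mask & structure.heavy_mask)[0]
    groups: dict[tuple, list[int]] = {}
    for i in idx:
        key = (str(structure.chain_id[i]), int(structure.res_id[i]),
               str(structure.res_name[i]))
        groups.setdefault(key, []).append(int(i))
    return [(k, np.asarray(v)) for k, v in groups.items()]


def _per_frame_residue_contacts(traj: Trajectory, groups, other_idx,
                                cutoff: float, stride: int) -> np.ndarray:
    """Boolean (n_analyzed, n_residues) matrix of residue-entity contacts."""
    frames = traj.analyzed_indices(stride)
    atom_idx = np.concatenate([g for _, g in groups])
    bounds = np.cumsum([0] + [len(g) for _, g in groups])
    out = np.zeros((len(frames), len(groups)), dtype=bool)
    for fi, f in enumerate(frames):
        other = traj.coords[f, other_idx]
        pts = traj.coords[f, atom_idx]
        if traj.box is None:
            dmin = cKDTree(other).query(pts)[0]
        else:
            d = pts[:, None, :] - other[None, :, :]
            d -= traj.box * np.round(d / traj.box)
            dmin = np.sqrt(np.einsum("ijk,ijk->ij", d, d)).min(axis=1)
        per_res_min = np.minimum.reduceat(dmin, bounds[:-1])
        out[fi] = per_res_min <= cutoff
    return out


def contact_probability(traj: Trajectory, protein_mask, material_mask,
                        cutoff: float = DEFAULT_CONTACT_CUTOFF,
                        stride: int = 1) -> ContactTable:
    """Percent probability of protein residues contacting the material.

    For every protein residue and analyzed frame the heavy-atom contact
    criterion is evaluated against the material; the aggregate percent is
    normalized by the number of residues times the number of analyzed
    snapshots.  The per-chain mean number of simultaneously bound residues
    and a residue-type decomposition of the contact events are reported
    alongside.
    """
    protein_mask = np.asarray(protein_mask, dtype=bool)
    material_mask = np.asarray(material_mask, dtype=bool)
    groups = _residue_groups(traj.structure, protein_mask)
    other_idx = np.where(material_mask & traj.structure.heavy_mask)[0]
    if not groups or len(other_idx) == 0:
        raise ValueError("empty protein or material selection")

    contacts = _per_frame_residue_contacts(traj, groups, other_idx,
                                           cutoff, stride)
    n_frames, n_res = contacts.shape
    per_residue = {key: float(contacts[:, g].mean())
                   for g, (key, _) in enumerate(groups)}
    aggregate = 100.0 * contacts.sum() / (n_res * n_frames)

    chains = sorted({key[0] for key, _ in groups})
    per_chain = {}
    for c in chains:
        cols = [g for g, (key, _) in enumerate(groups) if key[0] == c]
        per_chain[c] = float(contacts[:, cols].sum(axis=1).mean())

    class_events = {cls: 0 for cls in RESIDUE_CLASSES}
    total_events = int(contacts.sum())
    for g, (key, _) in enumerate(groups):
        cls = classify_residue_type(key[2])
        class_events[cls] += int(contacts[:, g].sum())
    breakdown = {cls: (100.0 * n / total_events if total_events else 0.0)
                 for cls, n in class_events.items()}

    return ContactTable(
        per_residue=per_residue, aggregate_percent=float(aggregate),
        residue_class_breakdown=breakdown, per_chain_mean_bound=per_chain,
        n_frames_analyzed=n_frames,
    )


# ---------------------------------------------------------------------------
# Residue-type classification


def classify_residue_type(res_name: str) -> str:
    """Class of one residue: positive, negative, polar or other."""
    name = res_name.upper()
    for cls, members in RESIDUE_CLASSES.items():
        if name in members:
            return cls
    logger.warning("nonstandard residue %r classified as 'other'", res_name)
    return "other"


def classify_residue_types(residues) -> dict[str, str]:
    """Map residue names to their classes (total, disjoint partition)."""
    return {str(r): classify_residue_type(str(r)) for r in residues}


# ---------------------------------------------------------------------------
# RMSD suite


RMSD_MODES = ("align_wrt_initial", "no_alignment", "no_alignment_wrt_average")


@dataclass
class RMSDResult:
    mode: str
    series: np.ndarray
    mean: float
    sd: float


def rmsd_suite(traj: Trajectory, reference_mode: str,
               fit_selection=None, protein_mask=None,
               stride: int = 1) -> RMSDResult:
    """Per-frame backbone RMSD in one of three reference conventions.

    ``align_wrt_initial`` optimally superposes each frame's protein backbone
    (N, Cα, C) onto the initial frame before computing the RMSD — a measure
    of conformational change.  ``no_alignment`` computes the RMSD against
    the initial frame without protein superposition, capturing translation
    and rotation of the dimer as well; for materials that move freely
    (carbon sheets) a ``fit_selection`` of material atoms is first
    superposed frame-to-reference and the resulting transform applied to the
    whole frame, while restrained materials (clay) need none.
    ``no_alignment_wrt_average`` is the same but against the unaligned mean
    structure over the analyzed frames.
    """
    if reference_mode not in RMSD_MODES:
        raise ValueError(f"unknown RMSD mode {reference_mode!r}")
    bb = backbone_mask(traj.structure, within=protein_mask)
    if not bb.any():
        raise ValueError("backbone selection (N, CA, C) is empty")
    if fit_selection is not None:
        fit_selection = np.asarray(fit_selection)
        if fit_selection.dtype == bool:
            fit_idx = np.where(fit_selection)[0]
        else:
            fit_idx = fit_selection.astype(int)
        if len(fit_idx) == 0:
            raise ValueError("fit_selection is empty")
    else:
        fit_idx = None

    frames = traj.analyzed_indices(stride)
    bb_idx = np.where(bb)[0]
    ref_full = traj.coords[0]

    def material_fitted(frame_coords):
        if fit_idx is None:
            return frame_coords
        R, t = kabsch(frame_coords[fit_idx], ref_full[fit_idx])
        return frame_coords @ R.T + t

    if reference_mode == "no_alignment_wrt_average":
        fitted = np.stack([material_fitted(traj.coords[f])[bb_idx]
                           for f in frames])
        ref_bb = fitted.mean(axis=0)
        series = np.array([_rmsd(fc, ref_bb) for fc in fitted])
    elif reference_mode == "no_alignment":
        ref_bb = ref_full[bb_idx]
        series = np.array([
            _rmsd(material_fitted(traj.coords[f])[bb_idx], ref_bb)
            for f in frames
        ])
    else:  # align_wrt_initial
        ref_bb = ref_full[bb_idx]
        series = []
        for f in frames:
            mobile = traj.coords[f, bb_idx]
            R, t = kabsch(mobile, ref_bb)
            series.append(_rmsd(mobile @ R.T + t, ref_bb))
        series = np.array(series)

    return RMSDResult(mode=reference_mode, series=series,
                      mean=float(series.mean()),
                      sd=float(series.std(ddof=0)))


# ---------------------------------------------------------------------------
# Trajectory selection consensus


def select_trajectory(candidates) -> int:
    """Consensus pick of the best-formed trajectory.

    Each candidate is ``(trajectory, contact_table_or_percent, rmsd_mean)``.
    Candidates are ranked ascending by RMSD and descending by contact
    percent; the lowest summed rank wins, ties falling to the lower RMSD and
    then the lower index.
    """
    if len(candidates) == 0:
        raise ValueError("no candidates")
    rmsds, percents = [], []
    for cand in candidates:
        _, table, rmsd_mean = cand
        pct = (table.aggregate_percent if isinstance(table, ContactTable)
               else float(table))
        rmsds.append(float(rmsd_mean))
        percents.append(pct)
    n = len(candidates)
    # competition ranks: ties share the lowest rank
    rank_r = {i: 1 + sum(1 for v in rmsds if v < rmsds[i])
              for i in range(n)}
    rank_p = {i: 1 + sum(1 for v in percents if v > percents[i])
              for i in range(n)}
    return min(range(n), key=lambda i: (rank_r[i] + rank_p[i], rmsds[i], i))


# ---------------------------------------------------------------------------
# Ion binding modes


@dataclass
class BindingModeSeries:
    """Per-ion, per-analyzed-frame binding mode (exactly one per cell)."""

    modes: pd.DataFrame  # index: frame index, columns: ion id
    percentages: dict


def classify_ion_binding(traj: Trajectory, ion_indices, protein_mask,
                         material_mask,
                         cutoff: float = DEFAULT_CONTACT_CUTOFF,
                         stride: int = 1) -> BindingModeSeries:
    """Classify every ion in every analyzed frame into one binding mode.

    ``protein_and_material`` if the ion is in heavy-atom contact with both
    the material and at least one protein chain, ``protein_only`` /
    ``material_only`` for one-sided contact, else ``unbound``.  The returned
    percentages (over ions x frames) sum to 100 across the four modes.
    """
    ion_indices = np.asarray(ion_indices, dtype=int)
    if len(ion_indices) == 0:
        raise ValueError("no ions in selection")
    prot_idx = np.where(np.asarray(protein_mask, dtype=bool)
                        & traj.structure.heavy_mask)[0]
    mat_idx = np.where(np.asarray(material_mask, dtype=bool)
                       & traj.structure.heavy_mask)[0]
    frames = traj.analyzed_indices(stride)

    ion_ids = [int(traj.structure.atom_id[i]) for i in ion_indices]
    table = pd.DataFrame(index=frames, columns=ion_ids, dtype=object)
    for f in frames:
        prot = traj.coords[f, prot_idx]
        mat = traj.coords[f, mat_idx]
        for i, ion in enumerate(ion_indices):
            p = traj.coords[f, ion][None, :]
            near_p = _min_distance(p, prot, traj.box) <= cutoff
            near_m = (len(mat) > 0
                      and _min_distance(p, mat, traj.box) <= cutoff)
            if near_p and near_m:
                mode = "protein_and_material"
            elif near_p:
                mode = "protein_only"
            elif near_m:
                mode = "material_only"
            else:
                mode = "unbound"
            table.loc[f, ion_ids[i]] = mode

    total = table.size
    percentages = {m: 100.0 * (table.values == m).sum() / total
                   for m in BINDING_MODES}
    return BindingModeSeries(modes=table, percentages=percentages)


# ---------------------------------------------------------------------------
# Pocket identification


@dataclass
class PocketRecord:
    """A persistent metal-ion binding pocket.

    ``residues`` are (chain, residue index, residue name) triples;
    ``occupancy`` is the fraction of analyzed frames in which the ion had at
    least one protein residue in contact, and ``per_residue_membership`` the
    fraction of those pocket-present frames each reported residue was in
    contact.
    """

    ion_id: int
    residues: frozenset
    occupancy: float
    present_in_last_frame: bool
    per_residue_membership: dict
    species: str = ""


def identify_pockets(traj: Trajectory, ion_indices, protein_mask,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     pocket_threshold: float = 0.60,
                     residue_threshold: float = 0.50,
                     stride: int = 1) -> list[PocketRecord]:
    """Persistence-based binding-pocket mining, one candidate pocket per ion.

    A frame is pocket-present for an ion if at least one protein residue is
    within the heavy-atom cutoff.  A pocket is reported iff the present
    fraction over analyzed frames is at least ``pocket_threshold`` (60% by
    default, inclusive) and the pocket persists in the last analyzed frame;
    its residues are those in contact in at least ``residue_threshold``
    (50%) of the pocket-present frames.
    """
    ion_indices = np.asarray(ion_indices, dtype=int)
    protein_mask = np.asarray(protein_mask, dtype=bool)
    frames = traj.analyzed_indices(stride)
    if len(frames) < 10:
        logger.warning("only %d analyzed frames; pocket persistence "
                       "statistics are unreliable below 10", len(frames))
    groups = _residue_groups(traj.structure, protein_mask)
    if not groups:
        raise ValueError("empty protein selection")

    atom_idx = np.concatenate([g for _, g in groups])
    bounds = np.cumsum([0] + [len(g) for _, g in groups])

    records = []
    for ion in ion_indices:
        species = str(traj.structure.element[ion])
        ion_id = int(traj.structure.atom_id[ion])
        res_hits = np.zeros((len(frames), len(groups)), dtype=bool)
        for fi, f in enumerate(frames):
            d = traj.coords[f, atom_idx] - traj.coords[f, ion]
            if traj.box is not None:
                d -= traj.box * np.round(d / traj.box)
            dist = np.sqrt(np.einsum("ij,ij->i", d, d))
            res_hits[fi] = np.minimum.reduceat(dist, bounds[:-1]) <= cutoff
        present = res_hits.any(axis=1)
        n_present = int(present.sum())
        occupancy = n_present / len(frames)
        in_last = bool(present[-1])
        if occupancy < pocket_threshold or not in_last:
            continue
        membership = {}
        for g, (key, _) in enumerate(groups):
            frac = res_hits[present, g].sum() / n_present
            if frac >= residue_threshold:
                membership[key] = float(frac)
        if not membership:
            continue
        records.append(PocketRecord(
            ion_id=ion_id, residues=frozenset(membership),
            occupancy=float(occupancy), present_in_last_frame=in_last,
            per_residue_membership=membership, species=species,
        ))
    return records


# ---------------------------------------------------------------------------
# Cross-system pocket report


def residue_label(key: tuple) -> str:
    """One-letter label such as D129 for a (chain, res_id, res_name) triple."""
    _, rid, rname = key
    return f"{THREE_TO_ONE.get(rname.upper(), 'X')}{rid}"


def _set_label(residues) -> str:
    keys = sorted(residues, key=lambda k: (k[1], k[0]))
    return ", ".join(residue_label(k) for k in keys)


def pocket_occurrence_report(pockets_by_system: dict) -> pd.DataFrame:
    """Cross-tabulate pockets over systems and ion species.

    ``pockets_by_system`` maps ``(system_label, species)`` to a list of
    :class:`PocketRecord`.  Pockets with identical residue sets across
    systems merge into one row; a pocket whose residue set is a superset of
    another observed pocket joins that row with the extra residues shown in
    parentheses, attributed to its own system.  Cells hold "+" (exact
    match), "+ (K91)"-style annotations, or "" when absent.
    """
    observed: list[frozenset] = []
    for records in pockets_by_system.values():
        for rec in records:
            if rec.residues not in observed:
                observed.append(rec.residues)
    # core sets: observed sets that contain no other observed set strictly
    cores = [s for s in observed
             if not any(o < s for o in observed)]

    def core_for(residues: frozenset) -> frozenset:
        subsets = [c for c in cores if c <= residues]
        if not subsets:
            return residues
        return max(subsets, key=lambda c: (len(c), _set_label(c)))

    columns = sorted(pockets_by_system, key=lambda k: (str(k[0]), str(k[1])))
    rows: dict[frozenset, dict] = {}
    extras_union: dict[frozenset, set] = {}
    for col, records in pockets_by_system.items():
        for rec in records:
            core = core_for(rec.residues)
            cell_map = rows.setdefault(core, {})
            extras = rec.residues - core
            extras_union.setdefault(core, set()).update(extras)
            mark = "+" if not extras else f"+ ({_set_label(extras)})"
            # keep the richer annotation if the same cell is hit twice
            if col not in cell_map or len(mark) > len(cell_map[col]):
                cell_map[col] = mark

    def row_label(core: frozenset) -> str:
        label = _set_label(core)
        if extras_union.get(core):
            label += f" ({_set_label(extras_union[core])})"
        return label

    ordered = sorted(rows, key=lambda c: (min(k[1] for k in c), _set_label(c)))
    data = {
        row_label(core): {f"{sys}/{sp}": rows[core].get((sys, sp), "")
                          for sys, sp in columns}
        for core in ordered
    }
    df = pd.DataFrame.from_dict(data, orient="index")
    df = df.reindex(columns=[f"{sys}/{sp}" for sys, sp in columns],
                    fill_value="")
    df.index.name = "pocket"
    return df
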