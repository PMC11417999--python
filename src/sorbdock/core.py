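"""Core domain types shared by every pipeline stage.

Structures are stored column-wise (numpy arrays per field) in the style of
biotite's ``AtomArray``; :class:`Atom` is a lightweight per-row view used
where single-atom access reads better than indexing.  All coordinates are in
Ångström, energies in kcal/mol unless a unit is carried explicitly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Elements recognised when inferring from PDB atom names.  Two-letter symbols
#: are only accepted for non-amino-acid residues, where "CA" means calcium
#: rather than an alpha carbon.
_TWO_LETTER_ELEMENTS = {
    "MG", "AL", "CA", "CD", "PB", "CL", "NA", "FE", "ZN", "SI", "BR", "MN",
}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class FormatError(ValueError):
    """Raised when an input file does not parse as the declared format."""


@dataclass
class Atom:
    """A single atom with residue and chain bookkeeping.

    ``is_heavy`` is true for every non-hydrogen element; all contact criteria
    in the pipeline operate on heavy atoms only.
    """

    id: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    charge: float = 0.0

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


class Structure:
    """An ordered atom collection for one entity (protein, material or ion).

    Parameters are parallel arrays, one row per atom.  Residue indices must be
    non-decreasing within each chain (PDB convention); violating input raises.
    """

    def __init__(
        self,
        atom_id: Sequence[int],
        atom_name: Sequence[str],
        element: Sequence[str],
        res_id: Sequence[int],
        res_name: Sequence[str],
        chain_id: Sequence[str],
        coords: np.ndarray,
        charge: Sequence[float] | None = None,
        entity_label: str = "protein",
    ):
        n = len(atom_id)
        self.atom_id = np.asarray(atom_id, dtype=int)
        self.atom_name = np.asarray(atom_name, dtype="U6")
        self.element = np.asarray(element, dtype="U3")
        self.res_id = np.asarray(res_id, dtype=int)
        self.res_name = np.asarray(res_name, dtype="U5")
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.charge = (
            np.zeros(n) if charge is None else np.asarray(charge, dtype=float)
        )
        if entity_label not in {"protein", "material", "ion"}:
            raise ValueError(f"unknown entity label {entity_label!r}")
        self.entity_label = entity_label
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for cid in np.unique(self.chain_id):
            rid = self.res_id[self.chain_id == cid]
            if np.any(np.diff(rid) < 0):
                raise ValueError(
                    f"residue indices decrease within chain {cid!r}"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    def __len__(self) -> int:
        return self.n_atoms

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    @property
    def n_heavy(self) -> int:
        return int(self.heavy_mask.sum())

    def atoms(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(
                id=int(self.atom_id[i]),
                name=str(self.atom_name[i]),
                element=str(self.element[i]),
                residue_index=int(self.res_id[i]),
                residue_name=str(self.res_name[i]),
                chain_id=str(self.chain_id[i]),
                position=self.coords[i].copy(),
                charge=float(self.charge[i]),
            )

    def centroid(self, heavy_only: bool = False) -> np.ndarray:
        m = self.heavy_mask if heavy_only else slice(None)
        return self.coords[m].mean(axis=0)

    # -- construction ------------------------------------------------------

    def copy(self) -> "Structure":
        return self.select(np.ones(self.n_atoms, dtype=bool))

    def select(self, mask) -> "Structure":
        mask = np.asarray(mask)
        return Structure(
            self.atom_id[mask], self.atom_name[mask], self.element[mask],
            self.res_id[mask], self.res_name[mask], self.chain_id[mask],
            self.coords[mask], self.charge[mask], self.entity_label,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        return out

    def translated(self, shift) -> "Structure":
        return self.with_coords(self.coords + np.asarray(shift, dtype=float))

    @staticmethod
    def concatenate(parts: Sequence["Structure"],
                    entity_label: str | None = None) -> "Structure":
        label = entity_label or parts[0].entity_label
        out = Structure(
            np.concatenate([p.atom_id for p in parts]),
            np.concatenate([p.atom_name for p in parts]),
            np.concatenate([p.element for p in parts]),
            np.concatenate([p.res_id for p in parts]),
            np.concatenate([p.res_name for p in parts]),
            np.concatenate([p.chain_id for p in parts]),
            np.concatenate([p.coords for p in parts]),
            np.concatenate([p.charge for p in parts]),
            label,
        )
        return out

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique (chain_id, res_id, res_name) triples in atom order."""
        seen: dict[tuple[str, int], str] = {}
        for c, r, n in zip(self.chain_id, self.res_id, self.res_name):
            seen.setdefault((str(c), int(r)), str(n))
        return [(c, r, n) for (c, r), n in seen.items()]


# ---------------------------------------------------------------------------
# Element inference


def infer_element(atom_name: str, res_name: str) -> str:
    """Guess the element from a PDB atom-name column.

    Amino-acid atom names start with the element's single letter (possibly
    after a leading digit, as in ``1HB``); other residues may use two-letter
    ion/metal symbols such as ``MG`` or ``CD``.
    """
    name = re.sub(r"[\d'\"]", "", atom_name.strip()).upper()
    if not name:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if res_name.upper() not in STANDARD_AMINO_ACIDS:
        if name[:2] in _TWO_LETTER_ELEMENTS:
            return name[:2].capitalize()
    return name[0].capitalize()


def _normalize_elements(elements, atom_names, res_names) -> np.ndarray:
    out = []
    n_inferred = 0
    for el, an, rn in zip(elements, atom_names, res_names):
        el = str(el).strip()
        if el:
            out.append(el.capitalize())
        else:
            inferred = infer_element(str(an), str(rn))
            logger.warning(
                "element missing for atom %r (%s); inferred %s",
                str(an), str(rn), inferred,
            )
            n_inferred += 1
            out.append(inferred)
    if n_inferred:
        logger.warning("inferred element for %d atoms from atom names",
                       n_inferred)
    return np.asarray(out, dtype="U3")


# ---------------------------------------------------------------------------
# PDB I/O (delegated to biotite behind this surface)


def _validate_pdb_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError):
                    raise FormatError(
                        f"{path}: line {lineno}: unparseable coordinate "
                        f"fields in {line.rstrip()!r}"
                    ) from None


def _atom_array_to_structure(arr, entity_label: str) -> Structure:
    charge = (arr.charge.astype(float)
              if "charge" in arr.get_annotation_categories()
              else np.zeros(arr.array_length()))
    return Structure(
        atom_id=np.arange(1, arr.array_length() + 1),
        atom_name=arr.atom_name,
        element=_normalize_elements(arr.element, arr.atom_name, arr.res_name),
        res_id=arr.res_id,
        res_name=arr.res_name,
        chain_id=arr.chain_id,
        coords=arr.coord,
        charge=charge,
        entity_label=entity_label,
    )


def _structure_to_atom_array(structure: Structure):
    import biotite.structure as bst

    arr = bst.AtomArray(structure.n_atoms)
    arr.chain_id = structure.chain_id
    arr.res_id = structure.res_id
    arr.res_name = structure.res_name
    arr.atom_name = structure.atom_name
    arr.element = np.char.upper(structure.element)
    arr.hetero = np.full(structure.n_atoms,
                         structure.entity_label != "protein")
    arr.coord = structure.coords
    return arr


def read_structure(path, format: str = "pdb",
                   entity_label: str = "protein") -> Structure:
    """Read a structure file into a :class:`Structure`.

    Only the PDB format is currently supported.  Missing element columns are
    inferred from atom names with a logged warning; malformed coordinate
    records raise :class:`FormatError` naming the offending line.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # biotite error types vary by record
        raise FormatError(f"{path}: not parseable as PDB: {exc}") from exc
    return _atom_array_to_structure(arr, entity_label)


def write_structure(structure: Structure, path) -> None:
    """Write a :class:`Structure` as a single-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_structure_to_atom_array(structure))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Protonation


@dataclass
class ProtonationState:
    """Protonation of one titratable residue (ASP, GLU or HIS).

    Net charges follow the standard convention: protonated carboxylates are
    neutral (deprotonated −1); protonated histidine is +1 (neutral otherwise).
    """

    residue_index: int
    residue_name: str
    protonated: bool
    net_charge: int
    chain_id: str = ""


TITRATABLE = ("ASP", "GLU", "HIS")

#: Textbook side-chain pKa values; site-specific shifts can be supplied as
#: per-residue overrides.
DEFAULT_PKA = {"ASP": 3.9, "GLU": 4.1, "HIS": 6.0}


def _charge_for(res_name: str, protonated: bool) -> int:
    if res_name in ("ASP", "GLU"):
        return 0 if protonated else -1
    return 1 if protonated else 0


def assign_protonation(
    structure: Structure,
    pH: float,
    pKa_table: Mapping[str, float] | None = None,
    overrides: Mapping[int, float] | Mapping[tuple[str, int], float] | None = None,
) -> list[ProtonationState]:
    """Assign protonation states to all ASP/GLU/HIS residues at a given pH.

    A residue is protonated iff ``pH < pKa`` (strictly); at ``pH == pKa`` it
    is reported deprotonated.  ``pKa_table`` replaces the default per-type
    values; ``overrides`` maps a residue index (or ``(chain_id, res_id)``)
    to a residue-specific pKa and is rejected if the residue at that position
    is not titratable.
    """
    table = dict(DEFAULT_PKA)
    if pKa_table:
        for k, v in pKa_table.items():
            if k not in TITRATABLE:
                raise ValueError(f"pKa table entry for non-titratable {k!r}")
            table[k] = float(v)
    for res in TITRATABLE:
        if res not in table:
            raise ValueError(f"pKa table missing {res}")

    overrides = dict(overrides or {})
    states: list[ProtonationState] = []
    for chain, rid, rname in structure.residue_keys():
        if rname not in TITRATABLE:
            if rid in overrides or (chain, rid) in overrides:
                raise ValueError(
                    f"override given for residue {chain}:{rid} ({rname}); "
                    "only ASP, GLU and HIS are titratable"
                )
            continue
        pka = overrides.get((chain, rid), overrides.get(rid, table[rname]))
        prot = pH < pka
        states.append(ProtonationState(
            residue_index=rid, residue_name=rname, protonated=prot,
            net_charge=_charge_for(rname, prot), chain_id=chain,
        ))
    # overrides pointing at residues absent from the structure are suspicious
    covered = {(s.chain_id, s.residue_index) for s in states}
    covered |= {s.residue_index for s in states}
    for key in overrides:
        if key not in covered:
            raise ValueError(f"override for unknown residue {key!r}")
    return states


# ---------------------------------------------------------------------------
# Units


KCAL_PER_KJ = 1.0 / 4.184
A2_PER_NM2 = 100.0

_ENERGY_IN_KCAL = {"kcal/mol": 1.0, "kJ/mol": KCAL_PER_KJ}
_LENGTH_IN_A = {"Å": 1.0, "A": 1.0, "angstrom": 1.0, "nm": 10.0}


def _canonical_energy(unit: str) -> str:
    for u in _ENERGY_IN_KCAL:
        if u.lower() == unit.lower():
            return u
    raise ValueError(f"unknown energy unit {unit!r}")


def _canonical_length(unit: str) -> str:
    for u in _LENGTH_IN_A:
        if u.lower() == unit.lower():
            return u
    raise ValueError(f"unknown length unit {unit!r}")


@dataclass(frozen=True)
class ForceConstant:
    """A positive harmonic force constant with explicit units (energy/length²)."""

    value: float
    energy_unit: str = "kcal/mol"
    length_unit: str = "Å"

    def __post_init__(self):
        if not self.value > 0:
            raise ValueError("force constant must be positive")
        object.__setattr__(self, "energy_unit",
                           _canonical_energy(self.energy_unit))
        object.__setattr__(self, "length_unit",
                           _canonical_length(self.length_unit))


def convert_force_constant(k: ForceConstant, target_energy_unit: str,
                           target_length_unit: str) -> ForceConstant:
    """Convert a force constant between kcal/kJ per mol and Å/nm length units.

    Uses 1 kcal = 4.184 kJ and 1 nm² = 100 Å²; round-trip conversion is the
    identity to machine precision.
    """
    e_to = _canonical_energy(target_energy_unit)
    l_to = _canonical_length(target_length_unit)
    # value has units E / L^2
    in_kcal_per_A2 = (k.value * _ENERGY_IN_KCAL[k.energy_unit]
                      / _LENGTH_IN_A[k.length_unit] ** 2)
    value = in_kcal_per_A2 / _ENERGY_IN_KCAL[e_to] * _LENGTH_IN_A[l_to] ** 2
    return ForceConstant(value, e_to, l_to)
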