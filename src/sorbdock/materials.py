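"""Geometric builders for sorbent surface models.

Two material families are supported: a single-layer calcium-montmorillonite
clay slab (with pH-dependent edge chemistry) and a graphene-like carbon sheet
in which a controlled fraction of rings is non-hexagonal, emulating the
defect content of activated carbon.

These are geometric stand-ins for force-field-faithful mineral models: they
reproduce the features the docking and contact analyses depend on (a planar
slab in the x-y plane, element identities, a consistent electrostatic field
from per-element charges, a ring census) and nothing more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Structure

#: Default per-element partial charges (elementary charge units).  Clay
#: oxygens are negative, the octahedral metals positive, carbon neutral;
#: values are configurable constants, not force-field parameters.
DEFAULT_CLAY_CHARGES = {"O": -0.55, "H": 0.30, "Al": 1.05, "Mg": 0.90}

CC_BOND = 1.42  # graphene C-C bond length, Å


@dataclass
class MaterialSurface:
    """A material slab plus the bookkeeping the pipeline needs.

    ``fixed_atom_ids`` lists atoms held fixed during settling and simulation
    (the Mg/Al atoms for clay; empty for carbon, which moves freely).
    ``rings`` (carbon only) stores each ring as an array of 0-based atom
    indices, so the hexagonal/non-hexagonal census is exact.
    """

    structure: Structure
    box: np.ndarray
    fixed_atom_ids: frozenset
    family: str
    defect_fraction: float = 0.0
    pH_variant: str = "pH7"
    rings: list | None = field(default=None, repr=False)

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        if self.family not in {"clay", "carbon"}:
            raise ValueError(f"unknown material family {self.family!r}")
        if self.family == "clay" and self.defect_fraction != 0:
            raise ValueError("defect_fraction must be 0 for clay")
        if not 0 <= self.defect_fraction <= 1:
            raise ValueError("defect_fraction must lie in [0, 1]")
        ids = set(self.structure.atom_id.tolist())
        if not set(self.fixed_atom_ids) <= ids:
            raise ValueError("fixed_atom_ids not a subset of structure atoms")

    def ring_census(self) -> dict[int, int]:
        """Ring-size histogram (e.g. ``{6: 346, 5: 2, 7: 2}``)."""
        if self.rings is None:
            raise ValueError("no ring metadata on this surface")
        census: dict[int, int] = {}
        for ring in self.rings:
            census[len(ring)] = census.get(len(ring), 0) + 1
        return census

    def bond_degrees(self) -> np.ndarray:
        """Per-atom bonded-neighbour count derived from ring edges."""
        if self.rings is None:
            raise ValueError("no ring metadata on this surface")
        partners: list[set[int]] = [set() for _ in range(self.structure.n_atoms)]
        for ring in self.rings:
            m = len(ring)
            for i in range(m):
                a, b = int(ring[i]), int(ring[(i + 1) % m])
                partners[a].add(b)
                partners[b].add(a)
        return np.array([len(p) for p in partners])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Carbon sheet


def build_carbon_sheet(
    n_rings: int,
    defect_fraction: float,
    seed: int,
    bond_length: float = CC_BOND,
    curvature_amplitude: float = 0.0,
    curvature_wavelength: float = 25.0,
    charge: float = 0.0,
) -> MaterialSurface:
    """Build a planar carbon-ring sheet with a set fraction of defect rings.

    ``round(defect_fraction * n_rings)`` rings (half-up rounding) are drawn
    at seeded random lattice positions and converted from hexagons to 5- or
    7-membered rings occupying the same footprint.  An optional sinusoidal
    out-of-plane displacement approximates the curvature of highly defective
    activated carbon; the default sheet is flat.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    if not 0 <= defect_fraction <= 1:
        raise ValueError("defect_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a = bond_length
    pitch = math.sqrt(3.0) * a  # centre-to-centre distance of edge-sharing rings

    ncols = max(1, round(math.sqrt(n_rings)))
    nrows = math.ceil(n_rings / ncols)
    centers = []
    for row in range(nrows):
        for col in range(ncols):
            if len(centers) == n_rings:
                break
            x = col * pitch + (row % 2) * pitch / 2.0
            y = row * 1.5 * a
            centers.append((x, y))
    centers = np.asarray(centers)

    n_defects = _round_half_up(defect_fraction * n_rings)
    defect_idx = set(rng.choice(n_rings, size=n_defects, replace=False).tolist()
                     ) if n_defects else set()

    coords: list[np.ndarray] = []
    index_of: dict[tuple[int, int], int] = {}  # lattice-exact vertex -> atom
    rings: list[np.ndarray] = []

    def vertex_index(p: np.ndarray, shared: bool) -> int:
        if shared:
            key = (int(round(p[0] * 1000)), int(round(p[1] * 1000)))
            if key in index_of:
                return index_of[key]
            index_of[key] = len(coords)
        coords.append(p)
        return len(coords) - 1

    for ridx, (cx, cy) in enumerate(centers):
        if ridx in defect_idx:
            m = int(rng.choice([5, 7]))
            # circumradius preserving the C-C bond length along the new ring
            r_m = a / (2.0 * math.sin(math.pi / m))
            phase = rng.uniform(0.0, 2.0 * math.pi)
            ring = [
                vertex_index(np.array([cx + r_m * math.cos(phase + 2 * math.pi * k / m),
                                       cy + r_m * math.sin(phase + 2 * math.pi * k / m)]),
                             shared=False)
                for k in range(m)
            ]
        else:
            ring = [
                vertex_index(np.array([cx + a * math.cos(math.radians(30 + 60 * k)),
                                       cy + a * math.sin(math.radians(30 + 60 * k))]),
                             shared=True)
                for k in range(6)
            ]
        rings.append(np.asarray(ring, dtype=int))

    xy = np.asarray(coords)
    xy -= xy.min(axis=0) - 1.0  # margin inside the box
    z = np.zeros(len(xy))
    if curvature_amplitude > 0:
        z = curvature_amplitude * np.sin(2.0 * math.pi * xy[:, 0]
                                         / curvature_wavelength)
    pos = np.column_stack([xy, z])
    n = len(pos)

    structure = Structure(
        atom_id=np.arange(1, n + 1),
        atom_name=np.full(n, "C"),
        element=np.full(n, "C"),
        res_id=np.ones(n, dtype=int),
        res_name=np.full(n, "CAR"),
        chain_id=np.full(n, "M"),
        coords=pos,
        charge=np.full(n, float(charge)),
        entity_label="material",
    )
    box = np.array([xy[:, 0].max() + 1.0, xy[:, 1].max() + 1.0,
                    30.0 + 2.0 * curvature_amplitude])
    return MaterialSurface(
        structure=structure, box=box, fixed_atom_ids=frozenset(),
        family="carbon", defect_fraction=defect_fraction,
        pH_variant="pH7", rings=rings,
    )


# ---------------------------------------------------------------------------
# Clay slab


def build_clay_slab(
    x_len: float,
    y_len: float,
    pH_variant: str = "pH7",
    site_spacing: float = 3.0,
    mg_fraction: float = 0.33,
    seed: int = 0,
    charges: dict[str, float] | None = None,
) -> MaterialSurface:
    """Build a single-layer montmorillonite-like slab in the x-y plane.

    The slab is three sublayers: basal O/OH above and below an octahedral
    Al/Mg sheet in which ``round(mg_fraction * n_sites)`` sites carry the
    Mg-for-Al substitution (default 0.33, the Al1.67/Mg0.33 composition).
    Perimeter sites carry edge hydroxyls; at pH 7 part of the edge hydrogens
    and hydroxyl groups are removed (deprotonated edges), so the pH7 variant
    always has fewer atoms than the pH3 variant of the same dimensions.
    The Mg and Al atoms are recorded as the fixed (restrained) subset.
    """
    if x_len <= 0 or y_len <= 0:
        raise ValueError("slab dimensions must be positive")
    if pH_variant not in {"pH3", "pH7"}:
        raise ValueError(f"unknown pH variant {pH_variant!r}")
    q = dict(DEFAULT_CLAY_CHARGES)
    if charges:
        q.update(charges)
    rng = np.random.default_rng(seed)

    margin = 2.5  # keeps edge hydroxyls (which extend ~2 Å) inside the box
    nx = max(2, int((x_len - 2 * margin) / site_spacing) + 1)
    ny = max(2, int((y_len - 2 * margin) / site_spacing) + 1)
    xs = np.linspace(margin, x_len - margin, nx)
    ys = np.linspace(margin, y_len - margin, ny)

    names, elements, positions, charges_out = [], [], [], []

    def add(element: str, x: float, y: float, z: float):
        names.append(element)
        elements.append(element)
        positions.append((x, y, z))
        charges_out.append(q.get(element, 0.0))

    # octahedral Al/Mg sheet with seeded Mg substitutions
    n_sites = nx * ny
    n_mg = _round_half_up(mg_fraction * n_sites)
    mg_sites = set(rng.choice(n_sites, size=n_mg, replace=False).tolist())
    fixed_indices = []
    site = 0
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            fixed_indices.append(len(positions))
            add("Mg" if site in mg_sites else "Al", x, y, 0.0)
            site += 1

    # basal O/OH sublayers (checkerboard of bare O and hydroxyl O)
    for sign in (+1, -1):
        for j, y in enumerate(ys):
            for i, x in enumerate(xs):
                add("O", x, y, sign * 1.1)
                if (i + j) % 2 == 0:
                    add("H", x, y, sign * 2.06)

    # edge hydroxyls on perimeter octahedral sites; pH7 deprotonates and
    # strips alternating hydroxyl groups
    perimeter = [(i, j) for j in range(ny) for i in range(nx)
                 if i in (0, nx - 1) or j in (0, ny - 1)]
    for k, (i, j) in enumerate(perimeter):
        x, y = xs[i], ys[j]
        ex = -1.0 if i == 0 else (1.0 if i == nx - 1 else 0.0)
        ey = -1.0 if j == 0 else (1.0 if j == ny - 1 else 0.0)
        ev = np.array([ex, ey, 0.0])
        ev /= np.linalg.norm(ev)
        if pH_variant == "pH3" or k % 2 == 0:
            add("O", x + 1.0 * ev[0], y + 1.0 * ev[1], 0.0)
            if pH_variant == "pH3":
                add("H", x + 1.96 * ev[0], y + 1.96 * ev[1], 0.0)

    n = len(positions)
    structure = Structure(
        atom_id=np.arange(1, n + 1),
        atom_name=names,
        element=elements,
        res_id=np.ones(n, dtype=int),
        res_name=np.full(n, "CLA"),
        chain_id=np.full(n, "M"),
        coords=np.asarray(positions),
        charge=charges_out,
        entity_label="material",
    )
    fixed = frozenset(int(structure.atom_id[i]) for i in fixed_indices)
    return MaterialSurface(
        structure=structure, box=np.array([x_len, y_len, 30.0]),
        fixed_atom_ids=fixed, family="clay", defect_fraction=0.0,
        pH_variant=pH_variant, rings=None,
    )
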