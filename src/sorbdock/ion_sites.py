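"""Refinement and placement of heavy-metal ion sites.

Externally predicted candidate sites (tabular x, y, z, score, species) are
de-clustered with a greedy exclusion-radius filter, the Cd and Pb site lists
are harmonized so every Cd-only location also receives a Pb site, and
additional ions can be placed uniformly at random with a minimum gap from an
existing complex.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Structure

logger = logging.getLogger(__name__)

SPECIES = {"Cd", "Pb", "Ca"}
ORIGINS = {"predicted", "harmonized", "random"}

DEFAULT_EXCLUSION_RADIUS = 6.5  # Å, between kept candidate sites
DEFAULT_MIN_GAP = 3.0  # Å, no-overlap gap for randomly placed ions


@dataclass(frozen=True)
class IonSite:
    """One candidate metal-ion position; higher score means a better site."""

    position: np.ndarray
    score: float | None
    species: str = "Cd"
    origin: str = "predicted"

    def __post_init__(self):
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float).reshape(3))
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.origin == "predicted" and (
                self.score is None or not math.isfinite(self.score)):
            raise ValueError("predicted sites must carry a finite score")


@dataclass
class IonSiteSet:
    """An ordered collection of ion sites with its exclusion radius."""

    sites: list[IonSite]
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self) -> np.ndarray:
        if not self.sites:
            return np.empty((0, 3))
        return np.array([s.position for s in self.sites])

    def scores(self) -> np.ndarray:
        return np.array([math.nan if s.score is None else s.score
                         for s in self.sites])

    def min_pairwise_distance(self) -> float:
        pos = self.positions()
        if len(pos) < 2:
            return math.inf
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        return float(d[np.triu_indices(len(pos), k=1)].min())


def filter_sites(site_set: IonSiteSet,
                 radius: float = DEFAULT_EXCLUSION_RADIUS) -> IonSiteSet:
    """Greedy exclusion-radius filter keeping higher-scoring sites.

    Sites are visited in descending score order (ties broken by input order,
    logged); a site is kept iff it lies at least ``radius`` from every
    already-kept site.  The kept set therefore satisfies the pairwise
    distance invariant, and for distinct scores the result does not depend
    on input order.
    """
    sites = site_set.sites
    if any(s.score is None for s in sites):
        raise ValueError("all sites must be scored before filtering")
    scores = np.array([s.score for s in sites])
    if len(np.unique(scores)) < len(scores):
        logger.warning("tied site scores; breaking ties by input order")
    order = sorted(range(len(sites)), key=lambda i: (-scores[i], i))

    kept: list[int] = []
    kept_pos: list[np.ndarray] = []
    for i in order:
        p = sites[i].position
        if all(np.linalg.norm(p - kp) >= radius for kp in kept_pos):
            kept.append(i)
            kept_pos.append(p)
    kept.sort()
    return IonSiteSet([sites[i] for i in kept], exclusion_radius=radius)


def harmonize_species(cd_sites: IonSiteSet, pb_sites: IonSiteSet,
                      match_radius: float = DEFAULT_EXCLUSION_RADIUS
                      ) -> IonSiteSet:
    """Add a Pb site at every Cd location that has no nearby Pb site.

    A Cd site is considered covered if any Pb site (original or already
    added) lies within ``match_radius``.  Uncovered Cd positions receive a
    Pb site with origin ``harmonized`` carrying the Cd score.  The operation
    is idempotent and only grows the Pb set, by at most ``len(cd_sites)``.
    """
    out = list(pb_sites.sites)
    for cd in cd_sites.sites:
        covered = any(np.linalg.norm(cd.position - pb.position) <= match_radius
                      for pb in out)
        if not covered:
            out.append(IonSite(position=cd.position, score=cd.score,
                               species="Pb", origin="harmonized"))
    return IonSiteSet(out, exclusion_radius=pb_sites.exclusion_radius)


def random_place_ions(
    n: int,
    box: Sequence[float],
    excluded: Structure | None = None,
    min_gap: float = DEFAULT_MIN_GAP,
    species: str = "Cd",
    seed: int = 0,
    max_attempts: int = 200_000,
) -> IonSiteSet:
    """Place ``n`` ions uniformly in a box without overlap.

    Every placed ion lies at least ``min_gap`` from every heavy atom of
    ``excluded`` (the protein-material complex) and from every other placed
    ion.  Placement is rejection sampling with a seeded generator; if the box
    cannot accommodate all ions within ``max_attempts`` draws, an error
    reports the count achieved.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    box = np.asarray(box, dtype=float).reshape(3)
    rng = np.random.default_rng(seed)
    tree = None
    if excluded is not None and excluded.n_atoms:
        heavy = excluded.coords[excluded.heavy_mask]
        if len(heavy):
            tree = cKDTree(heavy)

    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} ions with min_gap={min_gap} Å; "
                f"achieved {len(placed)} after {max_attempts} attempts"
            )
        attempts += 1
        p = rng.uniform(0.0, 1.0, size=3) * box
        if tree is not None and tree.query(p)[0] < min_gap:
            continue
        if any(np.linalg.norm(p - q) < min_gap for q in placed):
            continue
        placed.append(p)
    sites = [IonSite(position=p, score=None, species=species, origin="random")
             for p in placed]
    return IonSiteSet(sites, exclusion_radius=min_gap)


# ---------------------------------------------------------------------------
# Tabular I/O (tab-separated: x, y, z, score, species, origin)


def write_site_table(site_set: IonSiteSet, path) -> None:
    rows = [{
        "x": s.position[0], "y": s.position[1], "z": s.position[2],
        "score": math.nan if s.score is None else s.score,
        "species": s.species, "origin": s.origin,
    } for s in site_set.sites]
    pd.DataFrame(rows, columns=["x", "y", "z", "score", "species", "origin"]
                 ).to_csv(path, sep="\t", index=False)


def read_site_table(path,
                    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS
                    ) -> IonSiteSet:
    df = pd.read_csv(path, sep="\t")
    sites = []
    for _, row in df.iterrows():
        score = None if pd.isna(row["score"]) else float(row["score"])
        sites.append(IonSite(
            position=np.array([row["x"], row["y"], row["z"]]),
            score=score, species=str(row["species"]),
            origin=str(row["origin"]),
        ))
    return IonSiteSet(sites, exclusion_radius=exclusion_radius)


def sites_to_structure(site_set: IonSiteSet) -> Structure:
    """Render ion sites as single-atom residues (one chain per set)."""
    n = len(site_set.sites)
    return Structure(
        atom_id=np.arange(1, n + 1),
        atom_name=[s.species.upper() for s in site_set.sites],
        element=[s.species for s in site_set.sites],
        res_id=np.arange(1, n + 1),
        res_name=[s.species.upper() for s in site_set.sites],
        chain_id=np.full(n, "I"),
        coords=site_set.positions().reshape(n, 3),
        charge=np.full(n, 2.0),  # divalent heavy metals / Ca(II)
        entity_label="ion",
    )
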