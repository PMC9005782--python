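"""Core domain types for active-site reconstruction and comparison.

Conventions used throughout the package:

* All coordinates are in Angstrom (Å), right-handed Cartesian axes.
* Residue numbers are author numbering as found in the source file
  (1-based); positions of residues *within* a site are 0-based ordinal
  slots against the family reference definition.
* A site is an ordered sequence of catalytic residues positionally
  aligned to the reference; a missing (non-aligned) residue is an
  explicit ``None`` slot, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "CatalyticResidue",
    "ActiveSite",
    "FamilyAnnotation",
    "SmallMolecule",
    "LigandRecord",
    "SanityVerdict",
    "PairComparison",
    "ParadigmCall",
    "FunctionLocation",
    "RoleCategory",
    "Experiment",
    "LigandClass",
    "Proximity",
    "Paradigm",
]


class FunctionLocation(str, Enum):
    """Where a catalytic residue performs its function."""

    MAIN_CHAIN = "main_chain"
    SIDE_CHAIN = "side_chain"
    POST_TRANSLATIONAL = "post_translational"


class RoleCategory(str, Enum):
    REACTANT = "reactant"
    INTERACTION = "interaction"
    SPECTATOR = "spectator"


class Experiment(str, Enum):
    XRAY = "xray"
    NMR = "nmr"
    EM = "em"
    SYNTHETIC = "synthetic"


class Proximity(str, Enum):
    ADJACENT = "adjacent"
    DISTAL = "distal"


class LigandClass(str, Enum):
    SUBSTRATE_LIKE = "substrate_like"
    COFACTOR = "cofactor"
    ARTEFACT = "artefact"
    UNCERTAIN = "uncertain"


class Paradigm(str, Enum):
    RIGID = "inherently_rigid"
    FLEXIBLE = "inherently_flexible"
    OPEN_CLOSED = "open_closed"
    EXTENSIVE = "extensively_variable"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class AtomRecord:
    """A single heavy atom: PDB-convention name, element, position in Å."""

    name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("AtomRecord.element must be non-empty")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class CatalyticResidue:
    """One annotated catalytic residue.

    ``equiv_group`` distinguishes otherwise identical residues that
    symmetric subunits contribute to a single interface site (e.g. the
    two catalytic aspartates of a retroviral protease dimer); it is 0
    for ordinary residues.
    """

    chain_id: str
    residue_name: str
    residue_number: int
    function_location: FunctionLocation = FunctionLocation.SIDE_CHAIN
    role: str = ""
    role_category: RoleCategory = RoleCategory.REACTANT
    equiv_group: int = 0
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.equiv_group < 0:
            raise ValueError("equiv_group must be >= 0")
        if isinstance(self.function_location, str):
            self.function_location = FunctionLocation(self.function_location)
        if isinstance(self.role_category, str):
            self.role_category = RoleCategory(self.role_category)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def center_of_mass(self) -> np.ndarray:
        """Unit-mass centroid over all heavy atoms."""
        if not self.atoms:
            raise ValueError(
                f"residue {self.residue_name}{self.residue_number} has no atoms"
            )
        return np.mean([a.xyz for a in self.atoms], axis=0)

    def coords(self, names: Iterable[str]) -> np.ndarray:
        out = []
        for n in names:
            a = self.atom(n)
            if a is None:
                raise KeyError(
                    f"atom {n!r} missing from {self.residue_name}{self.residue_number}"
                )
            out.append(a.xyz)
        return np.asarray(out)


@dataclass
class ActiveSite:
    """An ordered collection of catalytic residues from one assembly.

    ``residues`` is positionally aligned to the family reference; gaps
    are explicit ``None`` entries.
    """

    site_id: str
    structure_id: str
    residues: list[CatalyticResidue | None]
    is_reference: bool = False
    resolution: float | None = None
    experiment: Experiment = Experiment.XRAY
    sequence_accession: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.experiment, str):
            self.experiment = Experiment(self.experiment)
        if not any(r is not None for r in self.residues):
            raise ValueError(f"site {self.site_id} has no residues")

    @property
    def is_multichain(self) -> bool:
        chains = {r.chain_id for r in self.residues if r is not None}
        return len(chains) >= 2

    @property
    def has_gaps(self) -> bool:
        return any(r is None for r in self.residues)

    def filled(self) -> list[tuple[int, CatalyticResidue]]:
        """(slot, residue) pairs for non-gap slots."""
        return [(i, r) for i, r in enumerate(self.residues) if r is not None]

    def residue_coms(self) -> dict[int, np.ndarray]:
        return {i: r.center_of_mass() for i, r in self.filled()}

    def centroid(self) -> np.ndarray:
        coms = list(self.residue_coms().values())
        return np.mean(coms, axis=0)

    def mean_intra_residue_distance(self) -> float:
        """Mean pairwise distance between residue centers of mass."""
        coms = list(self.residue_coms().values())
        if len(coms) < 2:
            return 0.0
        d = [
            float(np.linalg.norm(coms[i] - coms[j]))
            for i in range(len(coms))
            for j in range(i + 1, len(coms))
        ]
        return float(np.mean(d))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ActiveSite":
        """Return a copy with every atom mapped through x -> R x + t."""
        new_res: list[CatalyticResidue | None] = []
        for r in self.residues:
            if r is None:
                new_res.append(None)
                continue
            atoms = [
                replace(a, position=tuple(rotation @ a.xyz + translation))
                for a in r.atoms
            ]
            new_res.append(replace(r, atoms=atoms))
        return replace(self, residues=new_res)


@dataclass
class FamilyAnnotation:
    """A reference site plus its positionally aligned homologues."""

    family_id: str
    reference_site: ActiveSite
    homolog_sites: list[ActiveSite] = field(default_factory=list)
    ec_number: str | None = None

    def __post_init__(self) -> None:
        if not self.reference_site.is_reference:
            raise ValueError("reference_site must have is_reference=True")
        n = len(self.reference_site.residues)
        for s in self.homolog_sites:
            if len(s.residues) != n:
                raise ValueError(
                    f"homolog {s.site_id} has {len(s.residues)} slots, reference has {n}"
                )

    @property
    def all_sites(self) -> list[ActiveSite]:
        return [self.reference_site, *self.homolog_sites]


@dataclass(frozen=True)
class SmallMolecule:
    """Minimal chemical graph: elements plus a bond list.

    ``atoms`` is a sequence of (element, index); ``bonds`` of
    (i, j, order). Bond orders are carried but ignored by the
    similarity score.
    """

    comp_id: str
    atoms: tuple[tuple[str, int], ...]
    bonds: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        idx = {i for _, i in self.atoms}
        for i, j, _ in self.bonds:
            if i == j:
                raise ValueError(f"self-loop bond on atom {i} in {self.comp_id}")
            if i not in idx or j not in idx:
                raise ValueError(f"bond ({i},{j}) references missing atom in {self.comp_id}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class LigandRecord:
    """A non-catalytic component found near an active site."""

    comp_id: str
    proximity: Proximity
    ligand_class: LigandClass = LigandClass.UNCERTAIN
    best_match: str | None = None
    similarity: float | None = None
    centrality: float | None = None
    chain_id: str | None = None
    residue_number: int | None = None
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if isinstance(self.proximity, str):
            self.proximity = Proximity(self.proximity)
        if isinstance(self.ligand_class, str):
            self.ligand_class = LigandClass(self.ligand_class)

    def center_of_mass(self) -> np.ndarray:
        return np.mean([a.xyz for a in self.atoms], axis=0)


@dataclass
class SanityVerdict:
    """Outcome of the geometric sanity check of one reconstructed site."""

    passed: bool
    failed_pairs: list[tuple[int, int, float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_pairs) == 0):
            raise ValueError("passed flag inconsistent with failed_pairs")


@dataclass
class PairComparison:
    """One superposed pair of homologous sites plus the metadata the
    dataset filters and groupings need."""

    site_a: str
    site_b: str
    family_id: str
    wrmsd: float
    max_residue_rmsd: float
    ca_rmsd: float | None = None
    per_residue: dict[int, float] = field(default_factory=dict)
    same_protein: bool = False
    conserved: bool = True
    ligand_state: str | None = None  # free_free | bound_bound | bound_free
    resolution: float | None = None
    is_nmr: bool = False
    ec_number: str | None = None
    has_gap: bool = False
    intra_distance_discrepancy: float | None = None


@dataclass
class ParadigmCall:
    """Family-level conformational-behaviour label with the distribution
    statistics that support it."""

    family_id: str
    label: Paradigm
    mean: float | None = None
    sd: float | None = None
    skewness: float | None = None
    delta_bic: float | None = None
    component_separation: float | None = None
    cluster_contrast: float | None = None
    minority_fraction: float | None = None
    n_pairs: int = 0
    n_sites: int = 0


def pairwise_com_distances(site: ActiveSite) -> dict[tuple[int, int], float]:
    """Distances between residue centers of mass, keyed by slot pair (i<j)."""
    coms = site.residue_coms()
    slots = sorted(coms)
    return {
        (i, j): float(np.linalg.norm(coms[i] - coms[j]))
        for ki, i in enumerate(slots)
        for j in slots[ki + 1:]
    }


def as_coords(atoms: Sequence[AtomRecord]) -> np.ndarray:
    return np.asarray([a.xyz for a in atoms], dtype=float)
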