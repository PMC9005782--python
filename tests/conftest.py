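"""Shared fixtures: idealized sites, perturbed copies, molecules."""

from __future__ import annotations

import numpy as np
import pytest

from sitevar.core import ActiveSite, AtomRecord, CatalyticResidue
from sitevar.synthetic import example_molecules, make_reference_site, make_residue


@pytest.fixture(scope="session")
def molecules():
    return example_molecules()


@pytest.fixture
def reference_site():
    return make_reference_site(n_residues=6)


def displace_site(
    site: ActiveSite,
    shifts: dict[int, np.ndarray] | None = None,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    site_id: str = "moved",
) -> ActiveSite:
    """Copy a site with per-slot displacements then a rigid motion."""
    from dataclasses import replace

    R = np.eye(3) if rotation is None else rotation
    t = np.zeros(3) if translation is None else np.asarray(translation)
    shifts = shifts or {}
    residues = []
    for slot, r in enumerate(site.residues):
        if r is None:
            residues.append(None)
            continue
        s = np.asarray(shifts.get(slot, np.zeros(3)))
        atoms = [
            AtomRecord(a.name, a.element, tuple(R @ (a.xyz + s) + t))
            for a in r.atoms
        ]
        residues.append(replace(r, atoms=atoms))
    return replace(site, residues=residues, site_id=site_id, is_reference=False)


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def swap_atoms(residue: CatalyticResidue, name_a: str, name_b: str) -> CatalyticResidue:
    """Exchange the coordinates of two atoms (symmetry flip fixture)."""
    from dataclasses import replace

    pos = {a.name: a.position for a in residue.atoms}
    pos[name_a], pos[name_b] = pos[name_b], pos[name_a]
    return replace(residue, atoms=[
        AtomRecord(a.name, a.element, pos[a.name]) for a in residue.atoms
    ])


@pytest.fixture
def simple_residue():
    return make_residue("SER", 10)


def displacement_field(P, delta, rng, orthogonal_to=None, iters=200):
    """Per-atom displacement field with |u_i| = delta for every atom,
    orthogonal to all six rigid-body motions of the point set (and
    optionally atomwise-orthogonal to another field).  Under such a
    field the identity transform stays optimal and every deviation
    equals delta, so planted RMSD values survive the reweighted fit."""
    n = len(P)
    Pc = P - P.mean(axis=0)
    basis = []
    for k in range(3):  # translations
        b = np.zeros((n, 3)); b[:, k] = 1.0
        basis.append(b.ravel())
    for k in range(3):  # infinitesimal rotations
        e = np.zeros(3); e[k] = 1.0
        basis.append(np.cross(np.broadcast_to(e, (n, 3)), Pc).ravel())
    B = np.linalg.qr(np.stack(basis, axis=1))[0]
    u = rng.normal(size=(n, 3))
    for _ in range(iters):
        if orthogonal_to is not None:
            dots = (u * orthogonal_to).sum(axis=1, keepdims=True)
            norms2 = (orthogonal_to**2).sum(axis=1, keepdims=True)
            u = u - dots / norms2 * orthogonal_to
        v = u.ravel() - B @ (B.T @ u.ravel())
        u = v.reshape(n, 3)
        u = delta * u / np.linalg.norm(u, axis=1, keepdims=True)
    return u


def plant_wrmsd_copy(site: ActiveSite, delta: float, rng, site_id: str) -> ActiveSite:
    """Copy of a (symmetry-free) site whose wRMSD to the original is
    ``delta`` by construction: an equal-magnitude rigid-free field on
    the functional triad atoms."""
    from dataclasses import replace
    from sitevar.superpose import functional_triad

    triads = [functional_triad(r).atom_names for r in site.residues]
    P = np.concatenate([r.coords(names) for r, names in zip(site.residues, triads)])
    f = displacement_field(P, delta, rng)
    out, k = [], 0
    for r, names in zip(site.residues, triads):
        shifts = {}
        for name in names:
            shifts[name] = f[k]
            k += 1
        atoms = [AtomRecord(a.name, a.element,
                            tuple(a.xyz + shifts.get(a.name, 0.0)))
                 for a in r.atoms]
        out.append(replace(r, atoms=atoms))
    return replace(site, residues=out, site_id=site_id, is_reference=False)


def asymmetric_reference_site():
    """A reference site built only from residue types without
    exchangeable atoms, so planted deviations cannot be absorbed by
    symmetry reassignment."""
    return make_reference_site(
        residue_names=("SER", "THR", "CYS", "ASN", "GLN", "TYR"))
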