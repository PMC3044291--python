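"""Synthetic binding sites with known composition and known perturbations.

These stand-in pockets make the whole pipeline testable without any
structure downloads: atoms are packed into a ball at protein-like spacing,
property vectors are drawn from pharmacophoric archetypes (donor-rich,
acceptor-rich, lipophilic, charged, aromatic) whose vectors mirror the
typing table used for real sites, and perturbed copies carry their exact
ground-truth rigid transform for recovery tests.  Fixture files round-trip
through the PDB reader, with a dummy HET group placed so that carving at
the default radius reproduces the site.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from ._seeds import stable_pair_seed
from .site_io import Atom, N_COMPONENTS, Site, property_vector
from .superpose import Pose

#: Property archetypes, mirroring the residue typing table so synthetic and
#: real sites share one energy model.
ARCHETYPES: dict[str, np.ndarray] = {
    "donor_rich": property_vector(donor=1.0, acceptor=0.2, size=0.9,
                                  electronegativity=0.49),
    "acceptor_rich": property_vector(acceptor=1.0, lipophilicity=-0.2,
                                     size=0.85, electronegativity=0.89),
    "lipophilic": property_vector(lipophilicity=1.0, size=1.0),
    "charged": property_vector(donor=0.5, acceptor=0.5, size=0.9,
                               electronegativity=0.49, charge=1.0),
    "aromatic": property_vector(lipophilicity=0.8, size=1.0, sp2=1.0),
}

_ARCHETYPE_ELEMENT = {
    "donor_rich": "N",
    "acceptor_rich": "O",
    "lipophilic": "C",
    "charged": "N",
    "aromatic": "C",
}

MIN_SEPARATION = 1.5  # A, protein-like heavy-atom packing limit


@dataclass
class FixtureSpec:
    """Recipe for one synthetic site.

    Defaults give a pocket-like cloud: ~30 heavy atoms inside a 7 A ball,
    roughly the atom count and extent of a small carved binding site.
    """

    n_atoms: int = 30
    composition: dict[str, float] = field(
        default_factory=lambda: {name: 1.0 for name in ARCHETYPES}
    )
    extent: float = 7.0  # A, bounding radius
    jitter: float = 0.0  # A, rms coordinate noise
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.extent <= 0:
            raise ValueError("extent must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        unknown = set(self.composition) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if sum(self.composition.values()) <= 0:
            raise ValueError("composition weights must sum to > 0")


def _place_atoms(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    coords: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * spec.n_atoms
    while len(coords) < spec.n_atoms:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_atoms} atoms at >= {MIN_SEPARATION} A "
                f"separation within extent {spec.extent} A; increase the extent"
            )
        attempts += 1
        p = rng.uniform(-spec.extent, spec.extent, 3)
        if np.linalg.norm(p) > spec.extent:
            continue
        if coords and np.min(
            np.linalg.norm(np.array(coords) - p, axis=1)
        ) < MIN_SEPARATION:
            continue
        coords.append(p)
    return np.array(coords)


def generate_site(spec: FixtureSpec) -> Site:
    """Deterministically generate a synthetic site from its spec."""
    rng = np.random.default_rng(spec.seed)
    coords = _place_atoms(spec, rng)
    if spec.jitter > 0:
        coords = coords + rng.normal(0.0, spec.jitter / np.sqrt(3.0),
                                     coords.shape)
    names = sorted(spec.composition)
    weights = np.array([spec.composition[n] for n in names], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(names), size=spec.n_atoms, p=weights)
    properties = np.zeros((spec.n_atoms, N_COMPONENTS))
    atoms: list[Atom] = []
    for i, pick in enumerate(picks):
        arch = names[pick]
        scale = rng.uniform(0.9, 1.1)  # mild per-atom property variation
        properties[i] = ARCHETYPES[arch] * scale
        atoms.append(
            Atom(
                element=_ARCHETYPE_ELEMENT[arch],
                name=f"{_ARCHETYPE_ELEMENT[arch]}{i + 1}",
                coords=coords[i],
                residue_name="SYN",
                residue_id=i + 1,
                chain="A",
            )
        )
    return Site(atoms=atoms, properties=properties, source_id=spec.label)


def perturb_site(
    site: Site,
    rotation_angle: float = 0.0,
    translation: float = 0.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[Site, Pose]:
    """Rigidly move a site (random axis/direction) and optionally add noise.

    Returns the moved copy and the exact ground-truth :class:`Pose` that
    maps the original coordinates onto the (noise-free) moved ones, so that
    recovery tests can compare against a known transform.
    """
    rng = np.random.default_rng(seed)

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    axis = unit(rng.normal(size=3))
    angles = Rotation.from_rotvec(rotation_angle * axis).as_euler("xyz")
    t_vec = translation * unit(rng.normal(size=3)) if translation else np.zeros(3)
    pose = Pose(translation=t_vec, angles=angles, center=site.centroid)
    coords = pose.apply(site.coords)
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter / np.sqrt(3.0), coords.shape)
    atoms = [replace(a, coords=c) for a, c in zip(site.atoms, coords)]
    moved = replace(site, atoms=atoms,
                    ligand_atoms=[replace(a, coords=pose.apply(a.coords)[0])
                                  for a in site.ligand_atoms])
    return moved, pose


def attach_dummy_ligand(site: Site, radius: float = 6.0) -> Site:
    """Attach a synthetic HET group covering the site within ``radius``.

    One atom sits at the centroid; extra atoms are added toward any site
    atom farther than the carve radius, so that re-carving the written
    fixture at that radius returns every site atom.
    """
    coords = site.coords
    centroid = site.centroid
    # >= 2 atoms so the group is never mistaken for a monoatomic ion
    ligand_pos = [centroid, centroid + np.array([0.75, 0.0, 0.0])]
    reach = radius - 0.5  # margin against format rounding
    for p in coords:
        if min(np.linalg.norm(p - q) for q in ligand_pos) > reach:
            d = np.linalg.norm(p - centroid)
            ligand_pos.append(centroid + (p - centroid) * max(d - reach + 1.0, 0)
                              / d)
    ligand = [
        Atom(
            element="C",
            name=f"C{i + 1}",
            coords=pos,
            residue_name="LIG",
            residue_id=900,
            chain="L",
            is_het=True,
        )
        for i, pos in enumerate(ligand_pos)
    ]
    return replace(site, ligand_atoms=ligand)


def write_fixture_pdb(site: Site, path: str | Path, radius: float = 6.0) -> None:
    """Write a synthetic site as a PDB complex (site + dummy ligand)."""
    from .site_io import write_site_pdb

    if not site.ligand_atoms:
        site = attach_dummy_ligand(site, radius)
    write_site_pdb(site, path)


def make_fixture_collection(
    out_dir: str | Path,
    n_sites: int = 6,
    n_families: int = 2,
    seed: int = 0,
    jitter: float = 0.3,
    **spec_kwargs,
) -> list[dict]:
    """Emit fixture PDB files in family structure plus a manifest TSV.

    Families are distinct parent sites (different composition emphasis and
    geometry seed); members are jittered, rigidly displaced copies.  The
    manifest records label, family, and the ground-truth transform.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    emphases = list(ARCHETYPES)
    manifest: list[dict] = []
    for idx in range(n_sites):
        family = idx % n_families
        member = idx // n_families
        emphasis = emphases[family % len(emphases)]
        composition = {name: 0.5 for name in ARCHETYPES}
        composition[emphasis] = 4.0
        parent = generate_site(
            FixtureSpec(
                composition=composition,
                seed=stable_pair_seed(seed, f"family{family}"),
                label=f"fam{family}_m{member}",
                **spec_kwargs,
            )
        )
        pseed = stable_pair_seed(seed, f"member{family}.{member}")
        rng = np.random.default_rng(pseed)
        site, pose = perturb_site(
            parent,
            rotation_angle=rng.uniform(0, np.pi),
            translation=rng.uniform(0, 5.0),
            jitter=jitter if member > 0 else 0.0,
            seed=pseed,
        )
        site = attach_dummy_ligand(site)
        path = out_dir / f"{site.source_id}.pdb"
        write_fixture_pdb(site, path)
        manifest.append(
            {
                "label": site.source_id,
                "family": f"fam{family}",
                "file": path.name,
                "translation": " ".join(f"{v:.6f}" for v in pose.translation),
                "angles_xyz": " ".join(f"{v:.6f}" for v in pose.angles),
            }
        )
    with open(out_dir / "manifest.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
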