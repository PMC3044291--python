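"""Reading protein-ligand complexes and carving ligand-defined binding sites.

A binding site is the set of receptor heavy atoms within a fixed radius
(default 6 A) of any atom of the bound ligand.  Each site atom carries a
7-component pharmacophoric property vector (hydrogen-bond donor, acceptor,
lipophilicity, size, electronegativity, charge, sp2/aromatic character)
assigned from a plain-text typing table keyed by residue and atom name,
with an element-based fallback.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Fixed order of the seven pharmacophoric components.
COMPONENTS = (
    "donor",
    "acceptor",
    "lipophilicity",
    "size",
    "electronegativity",
    "charge",
    "sp2",
)

N_COMPONENTS = len(COMPONENTS)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: Residue names of common monoatomic ions (excluded from ligand selection
#: and, by default, from the receptor side of the site).
ION_NAMES = frozenset(
    {"MG", "ZN", "CA", "NA", "K", "CL", "MN", "FE", "CU", "NI", "CO", "CD",
     "HG", "BR", "IOD", "F", "LI", "SR", "CS", "BA", "RB", "AL", "SM", "YB"}
)


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class LigandSelectionError(ValueError):
    """Raised when no suitable ligand can be identified."""


def property_vector(**kwargs: float) -> np.ndarray:
    """Build a 7-vector from named components; unnamed components are 0."""
    unknown = set(kwargs) - set(COMPONENTS)
    if unknown:
        raise KeyError(f"unknown property components: {sorted(unknown)}")
    return np.array([float(kwargs.get(c, 0.0)) for c in COMPONENTS])


@dataclass(frozen=True)
class Atom:
    """A heavy atom read from a PDB record."""

    element: str
    name: str
    coords: np.ndarray  # (3,) Angstrom
    residue_name: str
    residue_id: int
    icode: str = ""
    chain: str = ""
    is_het: bool = False
    is_water: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.residue_id, self.icode, self.residue_name)


@dataclass
class Site:
    """A carved binding site: receptor atoms plus their property vectors.

    ``ligand_atoms`` are retained only for validation (ligand RMSD after
    superposition); they never enter the property fields or the score.
    """

    atoms: list[Atom]
    properties: np.ndarray  # (n_atoms, 7)
    source_id: str = ""
    ligand_atoms: list[Atom] = field(default_factory=list)
    carve_radius: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("empty site")
        self.properties = np.asarray(self.properties, dtype=float)
        if self.properties.shape != (len(self.atoms), N_COMPONENTS):
            raise ValueError(
                f"properties shape {self.properties.shape} does not match "
                f"{len(self.atoms)} atoms x {N_COMPONENTS} components"
            )
        if not np.all(np.isfinite(self.properties)):
            raise ValueError("non-finite property values")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """Site atom coordinates as an (n, 3) array."""
        return np.array([a.coords for a in self.atoms])

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms]).reshape(-1, 3)


# ---------------------------------------------------------------------------
# parsing


def _validate_coordinate_columns(pdb_text: str) -> None:
    # gemmi zero-fills unparsable numbers; check the fixed columns up front so
    # corrupt records fail loudly with the offending line number.
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed coordinate field {line[lo:hi]!r}"
                ) from None


def parse_structure(pdb_text: str, *, keep_hydrogens: bool = False) -> list[Atom]:
    """Parse PDB-format text into a flat list of heavy atoms.

    Only the first model is read.  For alternate locations the
    highest-occupancy conformer is kept (first on tie).  Waters are flagged,
    not dropped.  Raises :class:`PDBParseError` on malformed coordinates or
    when no atoms are present.
    """
    _validate_coordinate_columns(pdb_text)
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise PDBParseError("no atoms found in structure")
    atoms: list[Atom] = []
    # (chain, resid, icode, resname, atom name) -> index of retained conformer
    best: dict[tuple, int] = {}
    model = structure[0]
    for chain in model:
        for residue in chain:
            is_het = residue.het_flag == "H"
            is_water = residue.name in WATER_NAMES
            for gatom in residue:
                if gatom.element.is_hydrogen and not keep_hydrogens:
                    continue
                atom = Atom(
                    element=gatom.element.name.upper(),
                    name=gatom.name,
                    coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    residue_name=residue.name,
                    residue_id=residue.seqid.num,
                    icode=residue.seqid.icode.strip(),
                    chain=chain.name,
                    is_het=is_het,
                    is_water=is_water,
                    occupancy=gatom.occ,
                    altloc=gatom.altloc.strip("\x00").strip(),
                )
                key = (chain.name, residue.seqid.num, atom.icode,
                       residue.name, gatom.name)
                if key in best:
                    if atom.occupancy > atoms[best[key]].occupancy:
                        atoms[best[key]] = atom
                else:
                    best[key] = len(atoms)
                    atoms.append(atom)
    if not atoms:
        raise PDBParseError("no atoms found in structure")
    return atoms


def read_structure(path: str | Path, **kwargs) -> list[Atom]:
    """Read a PDB file (optionally gzip-compressed) into atoms."""
    path = Path(path)
    if path.suffix == ".gz":
        text = gzip.open(path, "rt").read()
    else:
        text = path.read_text()
    return parse_structure(text, **kwargs)


# ---------------------------------------------------------------------------
# ligand selection and carving


def _het_groups(atoms: list[Atom]) -> dict[tuple, list[Atom]]:
    groups: dict[tuple, list[Atom]] = {}
    for atom in atoms:
        if atom.is_het and not atom.is_water:
            groups.setdefault(atom.residue_key, []).append(atom)
    return groups


def select_ligand(atoms: list[Atom], ligand_code: str | None = None) -> list[Atom]:
    """Pick the ligand residue from a parsed structure.

    An explicit 3-letter ``ligand_code`` wins; otherwise the largest
    non-water, non-ion HET group by heavy-atom count is chosen, breaking
    ties by lowest chain then lowest residue id.
    """
    if not atoms:
        raise LigandSelectionError("no atoms given")
    groups = _het_groups(atoms)
    if not groups:
        raise LigandSelectionError("no HET groups present in structure")
    if ligand_code is not None:
        code = ligand_code.upper()
        matches = {k: v for k, v in groups.items() if k[3].upper() == code}
        if not matches:
            available = sorted({k[3] for k in groups})
            raise LigandSelectionError(
                f"ligand code {code!r} not found; available HET codes: {available}"
            )
        key = min(matches, key=lambda k: (k[0], k[1], k[2]))
        return matches[key]
    candidates = {
        k: v
        for k, v in groups.items()
        if len(v) > 1 and k[3] not in ION_NAMES
    }
    if not candidates:
        available = sorted({k[3] for k in groups})
        raise LigandSelectionError(
            f"no multi-atom non-ion HET group found; HET codes present: {available}"
        )
    key = min(candidates, key=lambda k: (-len(candidates[k]), k[0], k[1], k[2]))
    return candidates[key]


def carve_site(
    atoms: list[Atom],
    ligand: list[Atom],
    radius: float = 6.0,
    *,
    include_metals: bool = False,
    source_id: str = "",
) -> Site:
    """Carve the binding site: receptor atoms within ``radius`` of the ligand.

    The cutoff is a union of spheres, one per ligand atom, inclusive at the
    boundary.  Waters are always excluded; monoatomic metal ions are excluded
    unless ``include_metals``.  Other HET groups (cofactors) count as
    receptor.  Properties are left zeroed; call :func:`assign_properties`.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not ligand:
        raise ValueError("ligand must be non-empty")
    ligand_keys = {a.residue_key for a in ligand}
    receptor = [
        a
        for a in atoms
        if a.residue_key not in ligand_keys
        and not a.is_water
        and (include_metals or not (a.is_het and a.residue_name in ION_NAMES))
    ]
    if receptor:
        tree = cKDTree(np.array([a.coords for a in ligand]))
        dmin, _ = tree.query(np.array([a.coords for a in receptor]))
        receptor = [a for a, d in zip(receptor, dmin) if d <= radius]
    if not receptor:
        raise ValueError(f"empty site: no receptor atoms within {radius} A of ligand")
    return Site(
        atoms=receptor,
        properties=np.zeros((len(receptor), N_COMPONENTS)),
        source_id=source_id,
        ligand_atoms=list(ligand),
        carve_radius=radius,
    )


# ---------------------------------------------------------------------------
# property typing


class TypingTable:
    """Maps (residue name, atom name, element) to a 7-component vector.

    Lookup order: exact ``(residue, atom)`` entry, wildcard ``('*', atom)``
    entry (backbone names), element fallback, then the all-default vector.
    """

    def __init__(
        self,
        exact: dict[tuple[str, str], np.ndarray],
        wildcard: dict[str, np.ndarray],
        by_element: dict[str, np.ndarray],
        default: np.ndarray,
    ) -> None:
        self.exact = exact
        self.wildcard = wildcard
        self.by_element = by_element
        self.default = default
        self._warned: set[str] = set()

    @classmethod
    def from_tsv(cls, text: str) -> "TypingTable":
        exact: dict[tuple[str, str], np.ndarray] = {}
        wildcard: dict[str, np.ndarray] = {}
        by_element: dict[str, np.ndarray] = {}
        default = np.zeros(N_COMPONENTS)
        default[COMPONENTS.index("size")] = 1.0
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 + N_COMPONENTS:
                raise ValueError(f"typing table line {lineno}: expected "
                                 f"{2 + N_COMPONENTS} fields, got {len(parts)}")
            res, atom = parts[0].upper(), parts[1].upper()
            vec = np.array([float(x) for x in parts[2:]])
            if res == "@ELEMENT":
                by_element[atom] = vec
            elif res == "@DEFAULT":
                default = vec
            elif res == "*":
                wildcard[atom] = vec
            else:
                exact[(res, atom)] = vec
        return cls(exact, wildcard, by_element, default)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "TypingTable":
        """Load from a TSV file, or the packaged default table."""
        if path is None:
            text = (
                resources.files("apfbss").joinpath("data/typing_table.tsv").read_text()
            )
        else:
            text = Path(path).read_text()
        return cls.from_tsv(text)

    def lookup(self, atom: Atom) -> np.ndarray:
        key = (atom.residue_name.upper(), atom.name.upper())
        if key in self.exact:
            return self.exact[key]
        if key[1] in self.wildcard:
            return self.wildcard[key[1]]
        element = atom.element.upper()
        if element in self.by_element:
            return self.by_element[element]
        if element not in self._warned:
            self._warned.add(element)
            logger.warning("no typing entry for element %r; using default", element)
        return self.default


_DEFAULT_TABLE: TypingTable | None = None


def default_typing_table() -> TypingTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = TypingTable.load()
    return _DEFAULT_TABLE


def assign_properties(site: Site, typing_table: TypingTable | None = None) -> Site:
    """Return a copy of ``site`` with property vectors from the typing table.

    Pure function of (residue name, atom name, element); idempotent and
    independent of atom order.
    """
    table = typing_table or default_typing_table()
    props = np.array([table.lookup(a) for a in site.atoms])
    return replace(site, properties=props)


def load_site(
    path: str | Path,
    ligand_code: str | None = None,
    radius: float = 6.0,
    typing_table: TypingTable | None = None,
    **carve_kwargs,
) -> Site:
    """Convenience pipeline: read, select ligand, carve, assign properties."""
    atoms = read_structure(path)
    ligand = select_ligand(atoms, ligand_code)
    site = carve_site(atoms, ligand, radius,
                      source_id=Path(path).stem, **carve_kwargs)
    return assign_properties(site, typing_table)


# ---------------------------------------------------------------------------
# writing


def write_site_pdb(site: Site, path: str | Path) -> None:
    """Write a carved site as a PDB fragment (site as ATOM, ligand as HETATM)."""
    structure = gemmi.Structure()
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def add(atom: Atom, het: bool) -> None:
        chain_name = atom.chain or "A"
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name)
        chain = chains[chain_name]
        residue = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if (last.name == atom.residue_name
                    and last.seqid.num == atom.residue_id):
                residue = last
        if residue is None:
            residue = gemmi.Residue()
            residue.name = atom.residue_name
            residue.seqid = gemmi.SeqId(atom.residue_id, atom.icode or " ")
            residue.het_flag = "H" if het else "A"
            chain.add_residue(residue)
            residue = chain[len(chain) - 1]
        gatom = gemmi.Atom()
        gatom.name = atom.name
        gatom.element = gemmi.Element(atom.element.capitalize())
        gatom.pos = gemmi.Position(*atom.coords)
        gatom.occ = atom.occupancy
        residue.add_atom(gatom)

    for atom in site.atoms:
        add(atom, het=False)
    for atom in site.ligand_atoms:
        add(atom, het=True)
    for chain in chains.values():
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    Path(path).write_text(structure.make_pdb_string())
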