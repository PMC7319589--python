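"""Structure I/O and mutant modelling.

Parses antibody–antigen complexes from PDB files into a light-weight
chain/residue/atom hierarchy, writes them back, models point mutants by
backbone-preserving side-chain template grafting, and provides the interface
and distance geometry the feature extractors build on.

Conventions: heavy atoms only (hydrogens are dropped on read), PDB author
numbering with insertion codes preserved verbatim, altloc resolved to the
highest-occupancy conformer (ties broken alphabetically), model 1 of
multi-model files.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "Residue",
    "Complex",
    "MutationSpec",
    "MultiMutation",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "parse_mutation_list",
    "format_mutation",
    "build_mutant",
    "interface_residues",
    "min_heavy_distance",
    "sidechain_template",
    "AA1_TO_3",
    "AA3_TO_1",
    "BACKBONE_ATOMS",
]

AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3_TO_1 = {v: k for k, v in AA1_TO_3.items()}
BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Raised on malformed structures, mutation specs or lookups."""


@dataclass
class Atom:
    """A single heavy atom with a PDB atom name and Cartesian position in Å."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element symbol")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str  # "" when absent
    name3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def aa1(self) -> str | None:
        return AA3_TO_1.get(self.name3)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.key} ({self.name3}) has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


class Complex:
    """A parsed structure with a declared antibody/antigen chain partition."""

    def __init__(
        self,
        residues: list[Residue],
        antibody_chains: set[str],
        antigen_chains: set[str],
    ):
        antibody_chains = frozenset(antibody_chains)
        antigen_chains = frozenset(antigen_chains)
        if not antibody_chains or not antigen_chains:
            raise StructureError("both antibody and antigen chain sets must be non-empty")
        if antibody_chains & antigen_chains:
            raise StructureError(
                f"chains {sorted(antibody_chains & antigen_chains)} assigned to both sides"
            )
        self.antibody_chains = antibody_chains
        self.antigen_chains = antigen_chains
        self.residues: list[Residue] = list(residues)
        if not self.residues:
            raise StructureError("complex has no residues")
        self._index: dict[tuple[str, int, str], Residue] = {}
        for r in self.residues:
            if r.key in self._index:
                raise StructureError(f"duplicate residue key {r.key}")
            self._index[r.key] = r
        declared = antibody_chains | antigen_chains
        present = {r.chain_id for r in self.residues}
        missing = declared - present
        if missing:
            raise StructureError(f"declared chains absent from structure: {sorted(missing)}")

    # -- lookups -----------------------------------------------------------

    def residue(self, key: tuple[str, int, str]) -> Residue:
        try:
            return self._index[key]
        except KeyError:
            raise StructureError(f"no residue with key {key}") from None

    def has_residue(self, key: tuple[str, int, str]) -> bool:
        return key in self._index

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def side_of(self, chain_id: str) -> str:
        if chain_id in self.antibody_chains:
            return "antibody"
        if chain_id in self.antigen_chains:
            return "antigen"
        raise StructureError(f"chain {chain_id!r} is in neither partition")

    def subset(self, chain_ids: set[str]) -> "Complex":
        """New Complex restricted to `chain_ids` (partition labels retained where possible)."""
        res = [r for r in self.residues if r.chain_id in chain_ids]
        ab = self.antibody_chains & chain_ids
        ag = self.antigen_chains & chain_ids
        if not ab or not ag:
            # single-side subset: degenerate partition used for SASA geometry only
            return _GeometryOnlyComplex(res)
        return Complex(res, set(ab), set(ag))

    def heavy_atoms(self) -> tuple[np.ndarray, list[tuple[tuple[str, int, str], str]]]:
        """All heavy-atom coordinates with (residue key, atom name) labels."""
        coords, labels = [], []
        for r in self.residues:
            for a in r.atoms:
                coords.append(a.position)
                labels.append((r.key, a.name))
        return np.array(coords, dtype=float), labels

    def copy(self) -> "Complex":
        res = [
            Residue(r.chain_id, r.number, r.icode, r.name3,
                    [Atom(a.name, a.element, a.position.copy()) for a in r.atoms])
            for r in self.residues
        ]
        return Complex(res, set(self.antibody_chains), set(self.antigen_chains))


class _GeometryOnlyComplex(Complex):
    """Single-partition view used for per-side SASA; bypasses partition checks."""

    def __init__(self, residues: list[Residue]):
        self.antibody_chains = frozenset({r.chain_id for r in residues})
        self.antigen_chains = frozenset()
        self.residues = list(residues)
        self._index = {r.key: r for r in self.residues}


@dataclass(frozen=True)
class MutationSpec:
    """One point mutation: chain, wild-type aa, author number+icode, mutant aa."""

    chain_id: str
    wt_aa: str
    number: int
    icode: str
    mt_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA1_TO_3 or self.mt_aa not in AA1_TO_3:
            raise StructureError(f"non-standard amino acid in {self}")
        if self.wt_aa == self.mt_aa:
            raise StructureError(f"{self}: wild-type and mutant are identical")

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)


@dataclass(frozen=True)
class MultiMutation:
    """Ordered, duplicate-site-free list of point mutations applied together."""

    specs: tuple[MutationSpec, ...]

    def __post_init__(self) -> None:
        if not self.specs:
            raise StructureError("empty multi-mutation")
        sites = [s.site for s in self.specs]
        if len(set(sites)) != len(sites):
            raise StructureError(f"duplicate mutation site in {self}")

    def __iter__(self):
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    @property
    def sites(self) -> list[tuple[str, int, str]]:
        return [s.site for s in self.specs]

    def __str__(self) -> str:
        return ";".join(format_mutation(s) for s in self.specs)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_pdb(
    path,
    antibody_chains: set[str] | str,
    antigen_chains: set[str] | str,
) -> Complex:
    """Parse a PDB file into a Complex.

    Keeps model 1 and ATOM records of the 20 standard residues; drops
    hydrogens, waters and HETATMs; resolves altlocs to the highest-occupancy
    conformer (alphabetical on ties).
    """
    if isinstance(antibody_chains, str):
        antibody_chains = {c.strip() for c in antibody_chains.split(",") if c.strip()}
    if isinstance(antigen_chains, str):
        antigen_chains = {c.strip() for c in antigen_chains.split(",") if c.strip()}

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("complex", path)
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise StructureError(f"{path}: no models found") from None

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, number, icode = res.id
            if hetflag.strip():
                continue  # HETATM / water
            if res.get_resname() not in AA3_TO_1:
                continue
            atoms: list[Atom] = []
            # resolve altlocs explicitly: group unpacked atoms by name
            by_name: dict[str, list] = {}
            for atom in res.get_unpacked_list():
                if atom.element == "H" or atom.get_name().startswith("H"):
                    continue
                by_name.setdefault(atom.get_name(), []).append(atom)
            for name, group in by_name.items():
                best = min(group, key=lambda a: (-(a.get_occupancy() or 1.0), a.get_altloc()))
                atoms.append(Atom(name, best.element or name[0], np.array(best.get_coord(), dtype=float)))
            if atoms:
                residues.append(Residue(chain.id, number, icode.strip(), res.get_resname(), atoms))
    if not residues:
        raise StructureError(f"{path}: no standard protein atoms found")
    return Complex(residues, antibody_chains, antigen_chains)


def write_pdb(complex_: Complex, path) -> None:
    """Write ATOM records (3-decimal coordinates), consecutive serials, TER between chains."""
    if not complex_.residues:
        raise StructureError("refusing to write an empty complex")
    serial = 0
    lines: list[str] = []
    last_chain = None
    last_res: Residue | None = None
    for res in complex_.residues:
        if last_chain is not None and res.chain_id != last_chain:
            serial += 1
            lines.append(_ter_line(serial, last_res))
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res.name3:>3s} {res.chain_id:1s}"
                f"{res.number:4d}{res.icode or ' ':1s}   "
                f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
            )
        last_chain = res.chain_id
        last_res = res
    serial += 1
    lines.append(_ter_line(serial, last_res))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _ter_line(serial: int, res: Residue) -> str:
    return (
        f"TER   {serial:5d}      {res.name3:>3s} {res.chain_id:1s}"
        f"{res.number:4d}{res.icode or ' ':1s}"
    )


# ---------------------------------------------------------------------------
# Mutation-list parsing
# ---------------------------------------------------------------------------

_MUT_RE = re.compile(r"^(?P<chain>\w)\.(?P<wt>[A-Z])(?P<num>\d+)(?P<icode>[A-Z]?)(?P<mt>[A-Z])$")


def parse_mutation_list(text: str) -> list[MultiMutation]:
    """Parse mutation-list text: one multi-mutation per line, sites separated
    by ``;``, each written ``CHAIN.WT<number><icode?>MT`` (e.g. ``H.Y33A`` or
    ``H.A100BY`` for antibody insertion-code site 100B)."""
    out: list[MultiMutation] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        specs = []
        for token in line.split(";"):
            token = token.strip()
            m = _MUT_RE.match(token)
            if m is None:
                raise StructureError(f"line {lineno}: malformed mutation token {token!r}")
            specs.append(
                MutationSpec(m["chain"], m["wt"], int(m["num"]), m["icode"], m["mt"])
            )
        try:
            out.append(MultiMutation(tuple(specs)))
        except StructureError as exc:
            raise StructureError(f"line {lineno}: {exc}") from None
    return out


def format_mutation(spec: MutationSpec) -> str:
    return f"{spec.chain_id}.{spec.wt_aa}{spec.number}{spec.icode}{spec.mt_aa}"


# ---------------------------------------------------------------------------
# Side-chain template grafting
# ---------------------------------------------------------------------------

_TEMPLATE_CACHE: dict[str, list[tuple[str, str, np.ndarray]]] = {}


def sidechain_template(name3: str) -> list[tuple[str, str, np.ndarray]]:
    """Idealized heavy-atom geometry of a residue, as (atom name, element,
    position) in the template frame. Sourced from the Chemical Component
    Dictionary bundled with biotite; hydrogens and the terminal OXT dropped."""
    if name3 not in _TEMPLATE_CACHE:
        import biotite.structure.info as bsinfo

        tmpl = bsinfo.residue(name3)
        atoms = [
            (str(n), str(e), np.array(c, dtype=float))
            for n, e, c in zip(tmpl.atom_name, tmpl.element, tmpl.coord)
            if e != "H" and n != "OXT"
        ]
        _TEMPLATE_CACHE[name3] = atoms
    return _TEMPLATE_CACHE[name3]


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||R P + t - Q||."""
    Pm, Qm = P.mean(axis=0), Q.mean(axis=0)
    H = (P - Pm).T @ (Q - Qm)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, Qm - R @ Pm


def graft_sidechain(residue: Residue, mt_name3: str) -> Residue:
    """Replace `residue`'s side chain with the idealized template of `mt_name3`.

    Backbone atoms (N, CA, C, O) keep their exact coordinates; the template is
    aligned on the backbone (N, CA, C) frame by least-squares superposition and
    contributes every atom beyond the backbone. No rotamer search, no
    minimization.
    """
    for bb in ("N", "CA", "C"):
        if not residue.has_atom(bb):
            raise StructureError(
                f"residue {residue.key} lacks backbone atom {bb}; cannot graft side chain"
            )
    tmpl = sidechain_template(mt_name3)
    tmpl_bb = {n: p for n, _, p in tmpl if n in ("N", "CA", "C")}
    P = np.array([tmpl_bb[n] for n in ("N", "CA", "C")])
    Q = np.array([residue.atom(n).position for n in ("N", "CA", "C")])
    R, t = _kabsch(P, Q)

    atoms = [
        Atom(a.name, a.element, a.position.copy())
        for a in residue.atoms
        if a.name in BACKBONE_ATOMS
    ]
    for name, element, pos in tmpl:
        if name in BACKBONE_ATOMS:
            continue
        atoms.append(Atom(name, element, R @ pos + t))
    return Residue(residue.chain_id, residue.number, residue.icode, mt_name3, atoms)


def build_mutant(complex_: Complex, mutation: MultiMutation) -> Complex:
    """Model the mutant complex, applying point mutations one at a time in
    list order. Wild-type identity is verified at every site."""
    mutant = complex_.copy()
    for spec in mutation:
        res = mutant.residue(spec.site)
        if res.aa1 != spec.wt_aa:
            raise StructureError(
                f"wild-type mismatch at {spec.site}: expected {spec.wt_aa}, "
                f"found {res.aa1 or res.name3}"
            )
        new = graft_sidechain(res, AA1_TO_3[spec.mt_aa])
        idx = mutant.residues.index(res)
        mutant.residues[idx] = new
        mutant._index[new.key] = new
    return mutant


# ---------------------------------------------------------------------------
# Interface geometry
# ---------------------------------------------------------------------------

def _partition_atoms(complex_: Complex, chains: frozenset[str]):
    coords, keys = [], []
    for r in complex_.residues:
        if r.chain_id in chains:
            for a in r.atoms:
                coords.append(a.position)
                keys.append(r.key)
    return np.array(coords, dtype=float), keys


def interface_residues(complex_: Complex, cutoff: float = 5.0) -> set[tuple[str, int, str]]:
    """Residues with any heavy atom within `cutoff` Å of the opposite partition."""
    if cutoff <= 0:
        raise StructureError("interface cutoff must be positive")
    ab_xyz, ab_keys = _partition_atoms(complex_, complex_.antibody_chains)
    ag_xyz, ag_keys = _partition_atoms(complex_, complex_.antigen_chains)
    if len(ab_xyz) == 0 or len(ag_xyz) == 0:
        return set()
    pairs = cKDTree(ab_xyz).query_ball_tree(cKDTree(ag_xyz), r=cutoff)
    out: set[tuple[str, int, str]] = set()
    for i, js in enumerate(pairs):
        if js:
            out.add(ab_keys[i])
            for j in js:
                out.add(ag_keys[j])
    return out


def min_heavy_distance(
    complex_: Complex,
    site_a: tuple[str, int, str],
    site_b: tuple[str, int, str],
) -> float:
    """Minimum heavy-atom distance between two residues (0 for a site with itself)."""
    ra, rb = complex_.residue(site_a), complex_.residue(site_b)
    if ra is rb:
        return 0.0
    return float(cdist(ra.coords(), rb.coords()).min())


def distance_to_partner(complex_: Complex, site: tuple[str, int, str]) -> float:
    """Minimum heavy-atom distance from a residue to the opposite partition."""
    res = complex_.residue(site)
    side = complex_.side_of(res.chain_id)
    other = complex_.antigen_chains if side == "antibody" else complex_.antibody_chains
    xyz, _ = _partition_atoms(complex_, other)
    if len(xyz) == 0:
        raise StructureError("opposite partition has no atoms")
    return float(cdist(res.coords(), xyz).min())
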