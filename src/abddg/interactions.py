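"""Non-covalent contact typing and solvent accessibility.

Contacts are typed with heavy-atom geometric rules (hydrogen positions are
never used): hydrogen bonds, ionic interactions, aromatic–aromatic and
cation–π ring contacts, hydrophobic carbon–carbon contacts, generic polar
contacts, and a residual van der Waals class for otherwise untyped pairs
within radius overlap. SASA uses Shrake–Rupley sphere sampling on a
deterministic golden-spiral point lattice, so results are exactly
reproducible and rotation-invariant to sampling tolerance.

Every threshold lives in `ContactConfig` / the `sasa` arguments and is
surfaced through the run configuration.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure_io import Complex, Residue, StructureError

__all__ = [
    "CONTACT_TYPES",
    "Contact",
    "ContactSummary",
    "ContactConfig",
    "SasaResult",
    "detect_contacts",
    "summarize_contacts",
    "delta_contacts",
    "sasa",
    "buried_area",
    "delta_sasa",
    "VDW_RADII",
]

CONTACT_TYPES = (
    "hydrogen_bond",
    "ionic",
    "aromatic",
    "cation_pi",
    "hydrophobic",
    "polar",
    "vdw",
)

#: element van der Waals radii, Å (Bondi-style single published table)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_VDW = 1.70

POSITIVE_ATOMS = {
    ("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
NEGATIVE_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}
# every residue may carry a C-terminal OXT
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


@dataclass(frozen=True)
class ContactConfig:
    """Distance windows (Å) for each contact type; all heavy-atom rules."""

    hbond_min: float = 2.5
    hbond_max: float = 3.5
    ionic_max: float = 4.0
    aromatic_max: float = 6.0       # ring-centroid to ring-centroid
    cation_pi_max: float = 6.0      # charged atom to ring centroid
    hydrophobic_max: float = 4.5    # apolar C to apolar C
    polar_max: float = 4.0          # donor/acceptor N,O,S pairs beyond H-bond range
    vdw_slack: float = 0.5          # r1 + r2 + slack
    bond_max: float = 1.9           # covalent bond inference (2.2 if S involved)
    bond_max_s: float = 2.2

    def window(self, contact_type: str) -> tuple[float, float]:
        return {
            "hydrogen_bond": (self.hbond_min, self.hbond_max),
            "ionic": (0.0, self.ionic_max),
            "aromatic": (0.0, self.aromatic_max),
            "cation_pi": (0.0, self.cation_pi_max),
            "hydrophobic": (0.0, self.hydrophobic_max),
            "polar": (0.0, self.polar_max),
            "vdw": (0.0, 2 * max(VDW_RADII.values()) + self.vdw_slack),
        }[contact_type]


@dataclass(frozen=True)
class Contact:
    """One typed contact between two atoms (or ring centroids, atom name 'ring')."""

    res_a: tuple[str, int, str]
    atom_a: str
    res_b: tuple[str, int, str]
    atom_b: str
    type: str
    distance: float
    interfacial: bool

    @property
    def pair(self) -> frozenset:
        return frozenset([(self.res_a, self.atom_a), (self.res_b, self.atom_b)])


@dataclass
class ContactSummary:
    """Per-type contact counts in three scopes: all, interfacial, and
    involving at least one mutated site."""

    all: dict[str, int] = field(default_factory=lambda: dict.fromkeys(CONTACT_TYPES, 0))
    interfacial: dict[str, int] = field(default_factory=lambda: dict.fromkeys(CONTACT_TYPES, 0))
    sites: dict[str, int] = field(default_factory=lambda: dict.fromkeys(CONTACT_TYPES, 0))


def _atom_table(complex_: Complex):
    """Flat arrays describing every heavy atom, plus per-residue ring centroids."""
    xyz, keys, names, elements, res_names, side = [], [], [], [], [], []
    for r in complex_.residues:
        s = r.chain_id in complex_.antibody_chains
        for a in r.atoms:
            xyz.append(a.position)
            keys.append(r.key)
            names.append(a.name)
            elements.append(a.element.upper())
            res_names.append(r.name3)
            side.append(s)
    return (np.array(xyz), keys, names, elements, res_names, np.array(side, dtype=bool))


def _bond_adjacency(xyz, elements, cfg: ContactConfig):
    """Distance-inferred covalent bonds between heavy atoms."""
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=cfg.bond_max_s, output_type="ndarray")
    adj: dict[int, set[int]] = defaultdict(set)
    for i, j in pairs:
        d = np.linalg.norm(xyz[i] - xyz[j])
        limit = cfg.bond_max_s if "S" in (elements[i], elements[j]) else cfg.bond_max
        if d <= limit:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def detect_contacts(
    complex_: Complex,
    config: ContactConfig | None = None,
) -> list[Contact]:
    """Type all non-covalent contacts in a complex.

    Covalently bonded atoms and 1-3 neighbours (sharing a bonded atom) are
    never contacts. A pair can carry several types (e.g. a salt bridge that
    also satisfies hydrogen-bond geometry); the van der Waals class is only
    assigned to pairs with no other type.
    """
    from .signatures import load_pharmacophore_table

    cfg = config or ContactConfig()
    table = load_pharmacophore_table()
    xyz, keys, names, elements, res_names, side = _atom_table(complex_)
    n = len(xyz)
    adj = _bond_adjacency(xyz, elements, cfg)

    def excluded(i: int, j: int) -> bool:
        if j in adj[i]:
            return True
        return bool(adj[i] & adj[j])  # 1-3 via a shared bonded atom

    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    hydrophob = np.zeros(n, dtype=bool)
    positive = np.zeros(n, dtype=bool)
    negative = np.zeros(n, dtype=bool)
    for i in range(n):
        cls = table.classes(res_names[i], names[i])
        donor[i] = "donor" in cls and elements[i] in ("N", "O", "S")
        acceptor[i] = "acceptor" in cls and elements[i] in ("N", "O")
        hydrophob[i] = "hydrophobic" in cls and elements[i] == "C"
        positive[i] = (res_names[i], names[i]) in POSITIVE_ATOMS
        negative[i] = (res_names[i], names[i]) in NEGATIVE_ATOMS or names[i] == "OXT"

    contacts: list[Contact] = []

    def add(i, j, ctype, d):
        contacts.append(
            Contact(keys[i], names[i], keys[j], names[j], ctype, float(d),
                    bool(side[i] != side[j]))
        )

    max_r = max(
        cfg.hbond_max, cfg.ionic_max, cfg.hydrophobic_max, cfg.polar_max,
        2 * max(VDW_RADII.values()) + cfg.vdw_slack,
    )
    tree = cKDTree(xyz)
    for i, j in tree.query_pairs(r=max_r, output_type="ndarray"):
        if keys[i] == keys[j] and names[i] == names[j]:
            continue
        if excluded(i, j):
            continue
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        typed = False
        if (donor[i] and acceptor[j]) or (donor[j] and acceptor[i]):
            if cfg.hbond_min <= d <= cfg.hbond_max:
                add(i, j, "hydrogen_bond", d)
                typed = True
            elif d <= cfg.polar_max:
                add(i, j, "polar", d)
                typed = True
        if ((positive[i] and negative[j]) or (positive[j] and negative[i])) and d <= cfg.ionic_max:
            add(i, j, "ionic", d)
            typed = True
        if hydrophob[i] and hydrophob[j] and d <= cfg.hydrophobic_max:
            add(i, j, "hydrophobic", d)
            typed = True
        if not typed:
            r_sum = (
                VDW_RADII.get(elements[i], DEFAULT_VDW)
                + VDW_RADII.get(elements[j], DEFAULT_VDW)
                + cfg.vdw_slack
            )
            if d <= r_sum:
                add(i, j, "vdw", d)

    # ring-based contacts: centroid geometry per aromatic residue
    rings = []
    for r in complex_.residues:
        ring_names = RING_ATOMS.get(r.name3)
        if ring_names and all(r.has_atom(a) for a in ring_names):
            centroid = np.mean([r.atom(a).position for a in ring_names], axis=0)
            rings.append((r.key, r.chain_id in complex_.antibody_chains, centroid))
    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            d = float(np.linalg.norm(rings[a][2] - rings[b][2]))
            if d <= cfg.aromatic_max:
                contacts.append(
                    Contact(rings[a][0], "ring", rings[b][0], "ring", "aromatic", d,
                            rings[a][1] != rings[b][1])
                )
    charged_idx = np.flatnonzero(positive | negative)
    for key, ring_side, centroid in rings:
        for i in charged_idx:
            if keys[i] == key:
                continue
            d = float(np.linalg.norm(xyz[i] - centroid))
            if d <= cfg.cation_pi_max:
                contacts.append(
                    Contact(keys[i], names[i], key, "ring", "cation_pi", d,
                            side[i] != ring_side)
                )
    return contacts


def summarize_contacts(
    contacts: list[Contact],
    sites: list[tuple[str, int, str]] | None = None,
) -> ContactSummary:
    sites_set = set(sites or [])
    summary = ContactSummary()
    for c in contacts:
        summary.all[c.type] += 1
        if c.interfacial:
            summary.interfacial[c.type] += 1
        if c.res_a in sites_set or c.res_b in sites_set:
            summary.sites[c.type] += 1
    return summary


def delta_contacts(
    wt: Complex,
    mt: Complex,
    sites: list[tuple[str, int, str]],
    config: ContactConfig | None = None,
    wt_contacts: list[Contact] | None = None,
) -> dict[str, dict[str, int]]:
    """Mutant − wild-type contact counts, per type, in all three scopes.

    `wt_contacts` may be supplied to reuse a cached wild-type contact list.
    """
    wt_keys = {r.key for r in wt.residues}
    mt_keys = {r.key for r in mt.residues}
    if wt_keys != mt_keys:
        raise StructureError("wild-type and mutant complexes have different residue keys")
    cw = summarize_contacts(
        wt_contacts if wt_contacts is not None else detect_contacts(wt, config), sites
    )
    cm = summarize_contacts(detect_contacts(mt, config), sites)
    return {
        scope: {t: getattr(cm, scope)[t] - getattr(cw, scope)[t] for t in CONTACT_TYPES}
        for scope in ("all", "interfacial", "sites")
    }


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

@dataclass
class SasaResult:
    per_residue: dict[tuple[str, int, str], float]
    total: float
    probe_radius: float
    n_points: int


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-angle spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    complex_: Complex,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Shrake–Rupley SASA with per-element van der Waals radii.

    Each atom's sphere of radius (r_vdw + probe) is sampled at `n_points`
    golden-spiral points; a point is accessible when outside every
    neighbouring atom's probe-expanded sphere.
    """
    if probe_radius <= 0:
        raise StructureError("probe_radius must be positive")
    if n_points < 60:
        raise StructureError("n_points must be at least 60")
    xyz, keys, names, elements, _, _ = _atom_table(complex_)
    radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]) + probe_radius
    sphere = _golden_spiral(n_points)
    tree = cKDTree(xyz)
    max_r = radii.max()
    per_res: dict[tuple[str, int, str], float] = defaultdict(float)
    for i in range(len(xyz)):
        neighbours = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_r)
                      if j != i and np.linalg.norm(xyz[j] - xyz[i]) < radii[i] + radii[j]]
        pts = xyz[i] + radii[i] * sphere
        if neighbours:
            d = cdist(pts, xyz[neighbours])
            accessible = np.all(d >= radii[neighbours][None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        per_res[keys[i]] += 4.0 * np.pi * radii[i] ** 2 * frac
    per_res = dict(per_res)
    return SasaResult(per_res, float(sum(per_res.values())), probe_radius, n_points)


def buried_area(
    complex_: Complex, probe_radius: float = 1.4, n_points: int = 960
) -> float:
    """Interface-buried area: sum of the two partitions' isolated SASAs minus
    the complex SASA."""
    ab = complex_.subset(set(complex_.antibody_chains))
    ag = complex_.subset(set(complex_.antigen_chains))
    return (
        sasa(ab, probe_radius, n_points).total
        + sasa(ag, probe_radius, n_points).total
        - sasa(complex_, probe_radius, n_points).total
    )


def delta_sasa(
    wt: Complex,
    mt: Complex,
    sites: list[tuple[str, int, str]],
    probe_radius: float = 1.4,
    n_points: int = 960,
    wt_sasa: SasaResult | None = None,
    wt_buried: float | None = None,
) -> tuple[float, float, float]:
    """(per-site Å² delta, complex-total Å² delta, interface-buried Å² delta),
    all mutant − wild-type. Cached wild-type results may be passed in."""
    wt_keys = {r.key for r in wt.residues}
    if wt_keys != {r.key for r in mt.residues}:
        raise StructureError("wild-type and mutant complexes have different residue keys")
    sw = wt_sasa if wt_sasa is not None else sasa(wt, probe_radius, n_points)
    sm = sasa(mt, probe_radius, n_points)
    site_delta = sum(
        sm.per_residue.get(k, 0.0) - sw.per_residue.get(k, 0.0) for k in sites
    )
    total_delta = sm.total - sw.total
    bw = wt_buried if wt_buried is not None else buried_area(wt, probe_radius, n_points)
    bm = buried_area(mt, probe_radius, n_points)
    return float(site_delta), float(total_delta), float(bm - bw)
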