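"""Graph-based structural signatures (cutoff scanning matrix).

The environment of the mutated site(s) is summarized as cumulative counts of
pharmacophore-class pairs over a grid of distance thresholds: for every pair
of heavy atoms in the environment and every distance edge d, the pair is
counted into each class-pair cell its two atoms' class sets induce whenever
the pair's separation is ≤ d. Together with per-class pharmacophore change
counts between wild-type and mutant residues, these vectors are the principal
feature family of the predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.distance import pdist

from .structure_io import AA1_TO_3, Complex, StructureError, sidechain_template

__all__ = [
    "PHARMACOPHORE_CLASSES",
    "PharmacophoreTable",
    "SignatureParams",
    "GraphSignature",
    "PharmacophoreChange",
    "load_pharmacophore_table",
    "atom_classes",
    "csm_signature",
    "pharmacophore_change",
]

logger = logging.getLogger(__name__)

PHARMACOPHORE_CLASSES = (
    "hydrophobic",
    "positive",
    "negative",
    "acceptor",
    "donor",
    "aromatic",
    "sulfur",
    "neutral",
)

#: unordered class pairs in a fixed, documented order
CLASS_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (a, b)
    for i, a in enumerate(PHARMACOPHORE_CLASSES)
    for b in PHARMACOPHORE_CLASSES[i:]
)
_PAIR_INDEX = {p: i for i, p in enumerate(CLASS_PAIRS)}


@dataclass(frozen=True)
class PharmacophoreTable:
    """Mapping (residue name3, atom name) -> frozenset of class labels."""

    assignments: dict[tuple[str, str], frozenset[str]]
    version: str = "1"

    def classes(self, name3: str, atom_name: str) -> frozenset[str]:
        return self.assignments.get((name3, atom_name), frozenset())


_TABLE_CACHE: PharmacophoreTable | None = None


def load_pharmacophore_table() -> PharmacophoreTable:
    """Load the versioned class table shipped with the package."""
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        assignments: dict[tuple[str, str], frozenset[str]] = {}
        text = resources.files("abddg.data").joinpath("pharmacophores.tsv").read_text()
        for line in text.splitlines():
            if not line or line.startswith("#") or line.startswith("residue\t"):
                continue
            res, atom, classes = line.split("\t")
            labels = frozenset(classes.split(","))
            unknown = labels - set(PHARMACOPHORE_CLASSES)
            if unknown:
                raise ValueError(f"unknown pharmacophore class {unknown} for {res}.{atom}")
            assignments[(res, atom)] = labels
        _TABLE_CACHE = PharmacophoreTable(assignments)
    return _TABLE_CACHE


def atom_classes(
    residue_name3: str, atom_name: str, table: PharmacophoreTable | None = None
) -> frozenset[str]:
    """Class set of one atom; unknown atoms yield an empty set and a warning."""
    table = table or load_pharmacophore_table()
    classes = table.classes(residue_name3, atom_name)
    if not classes:
        logger.warning("no pharmacophore classes for %s.%s", residue_name3, atom_name)
    return classes


@dataclass(frozen=True)
class SignatureParams:
    """Distance grid and environment radius of the cutoff scanning matrix.

    Edges run from d_min to d_max inclusive in steps of `step`; atoms within
    `environment_radius` Å of any heavy atom of a mutated site define the
    environment. All values in Å.
    """

    d_min: float = 1.0
    d_max: float = 10.0
    step: float = 1.5
    environment_radius: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max):
            raise ValueError("require 0 < d_min < d_max")
        if self.step <= 0:
            raise ValueError("step must be positive")
        n = (self.d_max - self.d_min) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(d_max - d_min) must be an integral multiple of step")
        if self.environment_radius <= 0:
            raise ValueError("environment_radius must be positive")

    @property
    def edges(self) -> np.ndarray:
        n = int(round((self.d_max - self.d_min) / self.step))
        return self.d_min + self.step * np.arange(n + 1)


@dataclass
class GraphSignature:
    """Cumulative class-pair counts: rows = unordered class pairs, columns =
    distance-bin upper edges."""

    counts: np.ndarray  # (n_class_pairs, n_edges) non-negative ints
    params: SignatureParams

    def row(self, class_a: str, class_b: str) -> np.ndarray:
        pair = (class_a, class_b) if (class_a, class_b) in _PAIR_INDEX else (class_b, class_a)
        return self.counts[_PAIR_INDEX[pair]]

    def flatten(self) -> np.ndarray:
        return self.counts.reshape(-1).astype(float)

    @staticmethod
    def feature_names(params: SignatureParams) -> list[str]:
        return [
            f"csm_{a}:{b}_le_{edge:g}A"
            for (a, b) in CLASS_PAIRS
            for edge in params.edges
        ]


def csm_signature(
    complex_: Complex,
    sites: list[tuple[str, int, str]],
    params: SignatureParams | None = None,
    table: PharmacophoreTable | None = None,
) -> GraphSignature:
    """Cutoff-scanning-matrix signature of the union environment of `sites`.

    The environment is every heavy atom within ``params.environment_radius``
    of any heavy atom of any site (site atoms included). Each unordered atom
    pair contributes one count to every distinct unordered class pair induced
    by the two atoms' class sets, accumulated over all edges ≥ its separation.
    """
    params = params or SignatureParams()
    table = table or load_pharmacophore_table()
    if not sites:
        raise StructureError("csm_signature requires at least one site")

    site_coords = []
    for key in sites:
        site_coords.append(complex_.residue(key).coords())
    site_xyz = np.vstack(site_coords)

    env_coords: list[np.ndarray] = []
    env_classes: list[frozenset[str]] = []
    r = params.environment_radius
    for res in complex_.residues:
        xyz = res.coords()
        d = np.linalg.norm(xyz[:, None, :] - site_xyz[None, :, :], axis=-1).min(axis=1)
        for a, dist in zip(res.atoms, d):
            if dist <= r:
                env_coords.append(a.position)
                env_classes.append(atom_classes(res.name3, a.name, table))
    if len(env_coords) == 0:
        raise StructureError("empty environment: degenerate structure or bad sites")

    xyz = np.array(env_coords)
    edges = params.edges
    counts = np.zeros((len(CLASS_PAIRS), len(edges)), dtype=int)
    if len(xyz) >= 2:
        dists = pdist(xyz)
        # first edge index whose threshold covers each pair; len(edges) = out of range
        start = np.searchsorted(edges, dists - 1e-9)
        idx = 0
        n = len(xyz)
        for i in range(n - 1):
            ci = env_classes[i]
            for j in range(i + 1, n):
                s = start[idx]
                idx += 1
                if s >= len(edges):
                    continue
                cells = {
                    (a, b) if (a, b) in _PAIR_INDEX else (b, a)
                    for a in ci
                    for b in env_classes[j]
                }
                for cell in cells:
                    counts[_PAIR_INDEX[cell], s:] += 1
    return GraphSignature(counts, params)


@dataclass
class PharmacophoreChange:
    """Per-class signed atom-count delta between mutant and wild-type residues."""

    deltas: dict[str, int]

    def as_array(self) -> np.ndarray:
        return np.array([self.deltas[c] for c in PHARMACOPHORE_CLASSES], dtype=float)

    @staticmethod
    def feature_names() -> list[str]:
        return [f"pharm_delta_{c}" for c in PHARMACOPHORE_CLASSES]

    def __add__(self, other: "PharmacophoreChange") -> "PharmacophoreChange":
        return PharmacophoreChange(
            {c: self.deltas[c] + other.deltas[c] for c in PHARMACOPHORE_CLASSES}
        )


def _residue_class_counts(name3: str, table: PharmacophoreTable) -> dict[str, int]:
    counts = dict.fromkeys(PHARMACOPHORE_CLASSES, 0)
    for atom_name, _, _ in sidechain_template(name3):
        for c in table.classes(name3, atom_name):
            counts[c] += 1
    return counts


def pharmacophore_change(
    wt_aa: str, mt_aa: str, table: PharmacophoreTable | None = None
) -> PharmacophoreChange:
    """Per-class (mutant − wild-type) atom-count delta over the idealized
    residues (backbone + side chain)."""
    table = table or load_pharmacophore_table()
    for aa in (wt_aa, mt_aa):
        if aa not in AA1_TO_3:
            raise StructureError(f"non-standard amino acid code {aa!r}")
    wt = _residue_class_counts(AA1_TO_3[wt_aa], table)
    mt = _residue_class_counts(AA1_TO_3[mt_aa], table)
    return PharmacophoreChange({c: mt[c] - wt[c] for c in PHARMACOPHORE_CLASSES})
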