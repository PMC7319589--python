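"""Synthetic complexes and affinity datasets with known ground truth.

`make_toy_complex` builds an ideal-geometry polypeptide (natural-extension
backbone construction at fixed φ/ψ, side chains grafted from idealized
templates) and places two chains at a requested minimum approach distance,
emulating an antibody–antigen interface. `make_synthetic_dataset` draws
mutations on such complexes and assigns each a true ΔΔG from a declared
linear-plus-interaction function of the *actually computed* features, plus
Gaussian noise; K_D pairs are back-computed from the planted ΔΔG at 298 K so
the full curation path (K_D → ΔG → ΔΔG) is exercised end-to-end. Planted
non-binders and additive/synergistic multi-point records let the
classification and labelling paths be tested with known answers.

Everything is fully determined by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dataset import (
    DEFAULT_TEMPERATURE_K,
    GAS_CONSTANT_KCAL,
    AffinityRecord,
    CuratedDataset,
)
from .model import FeatureConfig, Featurizer
from .structure_io import (
    AA1_TO_3,
    AA3_TO_1,
    Atom,
    Complex,
    MultiMutation,
    MutationSpec,
    Residue,
    StructureError,
    graft_sidechain,
    write_pdb,
)

__all__ = [
    "ToyComplexSpec",
    "SyntheticAffinitySpec",
    "make_toy_complex",
    "make_synthetic_dataset",
]

# idealized backbone internal coordinates (Å, degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.5


def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """Position a fourth atom from three predecessors and internal coordinates."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            bond * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a deterministic two-chain toy complex.

    `chains` maps chain id -> sequence; when a sequence is None it is drawn
    uniformly from the 20 standard residues at `chain_length`. The second
    chain is placed so the minimum heavy-atom approach to the first equals
    `approach_distance` within 0.1 Å.
    """

    chains: tuple[tuple[str, str | None], ...] = (("H", None), ("A", None))
    chain_length: int = 12
    approach_distance: float = 4.5
    phi: float = -140.0
    psi: float = 135.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.approach_distance < 2.0:
            raise StructureError("clashing placement request: approach distance < 2 Å")


def _build_chain(chain_id: str, sequence: str, phi: float, psi: float) -> list[Residue]:
    """Ideal-geometry extended chain with template side chains."""
    if len(sequence) < 5:
        raise StructureError("toy chain sequences must be at least 5 residues")
    n_xyz = [np.array([0.0, 0.0, 0.0])]
    ca_xyz = [np.array([_BOND_N_CA, 0.0, 0.0])]
    theta = math.radians(_ANGLE_N_CA_C)
    c0 = ca_xyz[0] + _BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])
    c_xyz = [c0]
    for _ in range(1, len(sequence)):
        n_next = _place(n_xyz[-1], ca_xyz[-1], c_xyz[-1], _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_next = _place(ca_xyz[-1], c_xyz[-1], n_next, _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        c_next = _place(c_xyz[-1], n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        n_xyz.append(n_next)
        ca_xyz.append(ca_next)
        c_xyz.append(c_next)

    residues = []
    for i, aa in enumerate(sequence):
        o = _place(n_xyz[i], ca_xyz[i], c_xyz[i], _BOND_C_O, _ANGLE_CA_C_O, psi - 180.0)
        backbone = Residue(
            chain_id,
            i + 1,
            "",
            AA1_TO_3[aa],
            [
                Atom("N", "N", n_xyz[i]),
                Atom("CA", "C", ca_xyz[i]),
                Atom("C", "C", c_xyz[i]),
                Atom("O", "O", o),
            ],
        )
        residues.append(graft_sidechain(backbone, AA1_TO_3[aa]))
    return residues


def make_toy_complex(spec: ToyComplexSpec, pdb_path=None) -> Complex:
    """Build the toy complex; optionally write it to a PDB file."""
    rng = np.random.default_rng(spec.seed)
    letters = sorted(AA1_TO_3)
    chains: list[tuple[str, str]] = []
    for cid, seq in spec.chains:
        if seq is None:
            seq = "".join(rng.choice(letters, size=spec.chain_length))
        chains.append((cid, seq))
    if len(chains) != 2:
        raise StructureError("toy complexes are two-chain by construction")

    (id_a, seq_a), (id_b, seq_b) = chains
    res_a = _build_chain(id_a, seq_a, spec.phi, spec.psi)
    res_b = _build_chain(id_b, seq_b, spec.phi, spec.psi)

    xyz_a = np.vstack([r.coords() for r in res_a])
    xyz_b0 = np.vstack([r.coords() for r in res_b])
    # flip the second chain so its face opposes the first, then slide along +y
    flip = np.diag([1.0, -1.0, -1.0])
    xyz_b0 = xyz_b0 @ flip.T

    def min_dist(t: float) -> float:
        shifted = xyz_b0 + np.array([0.0, t, 0.0])
        diff = xyz_a[:, None, :] - shifted[None, :, :]
        return float(np.sqrt((diff**2).sum(-1)).min())

    f = lambda v: min_dist(v) - spec.approach_distance
    t_low = float(xyz_a[:, 1].max() - xyz_b0[:, 1].min())  # bounding slabs touch
    t_high = t_low + spec.approach_distance + 30.0
    while f(t_low) > 0 and t_high - t_low < 200.0:  # walk down into clash range
        t_low -= 2.0
    t = brentq(f, t_low, t_high, xtol=1e-4)

    offset = np.array([0.0, t, 0.0])
    i = 0
    for r in res_b:
        for a in r.atoms:
            a.position = xyz_b0[i] + offset
            i += 1

    complex_ = Complex(res_a + res_b, {id_a}, {id_b})
    if pdb_path is not None:
        write_pdb(complex_, pdb_path)
    return complex_


# ---------------------------------------------------------------------------
# Synthetic affinity datasets
# ---------------------------------------------------------------------------

DEFAULT_EFFECT_COEFFS = {
    "pharm_delta_hydrophobic": 0.8,
    "evo_pam30_sum": 0.6,
    "dist_partner_min": 0.7,
    "sasa_delta_total": 0.5,
    "n_sites": 0.4,
}
DEFAULT_INTERACTION = ("pharm_delta_hydrophobic", "dist_partner_min", 0.4)


@dataclass(frozen=True)
class SyntheticAffinitySpec:
    """Study conditions for a synthetic affinity dataset.

    True ΔΔG is linear in z-scored computed features plus one pairwise
    interaction term, rescaled to `signal_std`, centred on `ddg_mean`
    (matching the skewed, destabilization-heavy character of experimental
    sets), with Gaussian noise of `noise_sigma` kcal/mol on top.
    """

    n_records: int = 500
    noise_sigma: float = 0.3
    fraction_multi: float = 0.3
    seed: int = 0
    ddg_mean: float = -1.0
    signal_std: float = 1.5
    effect_coeffs: tuple[tuple[str, float], ...] = tuple(DEFAULT_EFFECT_COEFFS.items())
    interaction: tuple[str, str, float] = DEFAULT_INTERACTION
    n_non_binders: int = 5
    n_planted_additive: int = 3
    n_planted_synergistic: int = 3

    def __post_init__(self) -> None:
        if self.n_records < 10:
            raise ValueError("n_records must be at least 10")


def _random_mutation(rng, complex_: Complex, n_sites: int) -> MultiMutation:
    candidates = [r for r in complex_.residues if r.aa1 is not None]
    idx = rng.choice(len(candidates), size=n_sites, replace=False)
    specs = []
    for i in sorted(idx):
        r = candidates[i]
        wt = r.aa1
        mt = rng.choice([aa for aa in sorted(AA1_TO_3) if aa != wt])
        specs.append(MutationSpec(r.chain_id, wt, r.number, r.icode, str(mt)))
    return MultiMutation(tuple(specs))


def _kd_pair_for_ddg(ddg: float, temperature: float = DEFAULT_TEMPERATURE_K):
    """Back-compute a (kd_wild, kd_mutant) pair whose ΔΔG equals `ddg`."""
    kd_wild = 1e-9
    rt = GAS_CONSTANT_KCAL * temperature
    dg_wild = rt * math.log(kd_wild)
    kd_mutant = math.exp((dg_wild - ddg) / rt)
    return kd_wild, kd_mutant


def make_synthetic_dataset(
    spec: SyntheticAffinitySpec,
    complexes: dict[str, Complex],
    featurizer: Featurizer | None = None,
) -> tuple[CuratedDataset, dict, pd.DataFrame]:
    """Generate a curated dataset with a ground-truth sidecar.

    Returns (dataset, sidecar, feature matrix). The feature matrix rows align
    with the regression records (train + blind partitions, in order); the
    sidecar stores the effect-model coefficients, the standardization
    constants and the noiseless true ΔΔG of every record.
    """
    if not complexes:
        raise ValueError("at least one toy complex is required")
    rng = np.random.default_rng(spec.seed)
    featurizer = featurizer or Featurizer(FeatureConfig())
    cx_ids = sorted(complexes)

    muts: list[tuple[str, MultiMutation]] = []
    seen: set[tuple] = set()
    while len(muts) < spec.n_records:
        cid = cx_ids[rng.integers(len(cx_ids))]
        n_sites = 1
        if rng.random() < spec.fraction_multi:
            n_sites = int(rng.integers(2, 4))
        m = _random_mutation(rng, complexes[cid], n_sites)
        key = (cid, str(m))
        if key in seen:
            continue
        seen.add(key)
        muts.append((cid, m))

    X = pd.DataFrame(
        np.vstack(
            [featurizer.featurize(complexes[cid], m).values for cid, m in muts]
        ),
        columns=featurizer.names,
    )

    coeffs = dict(spec.effect_coeffs)
    f1, f2, c_int = spec.interaction
    stats_used: dict[str, tuple[float, float]] = {}

    def zscore(col: str) -> np.ndarray:
        v = X[col].to_numpy(dtype=float)
        mu, sd = float(v.mean()), float(v.std())
        if sd == 0:
            sd = 1.0
        stats_used[col] = (mu, sd)
        return (v - mu) / sd

    raw = np.zeros(len(X))
    for col, coef in coeffs.items():
        raw = raw + coef * zscore(col)
    raw = raw + c_int * zscore(f1) * zscore(f2)
    raw_sd = raw.std() or 1.0
    signal = (raw - raw.mean()) / raw_sd * spec.signal_std + spec.ddg_mean
    noise = rng.normal(0.0, spec.noise_sigma, size=len(X))
    y = signal + noise

    records: list[AffinityRecord] = []
    truth_rows = []
    for (cid, m), true_ddg, noisy in zip(muts, signal, y):
        kd_w, kd_m = _kd_pair_for_ddg(float(noisy))
        partition = "train" if len(m) == 1 else "blind-multi"
        records.append(
            AffinityRecord(
                complex_id=cid,
                mutation=m,
                kd_wild=kd_w,
                kd_mutant=kd_m,
                temperature=DEFAULT_TEMPERATURE_K,
                source="synthetic",
                partition=partition,
            )
        )
        truth_rows.append(
            {"complex_id": cid, "mutations": str(m), "true_ddg_noiseless": float(true_ddg),
             "planted_ddg": float(noisy), "planted": None}
        )

    # planted non-binders: the most destabilizing of a pool of extra candidates
    nb_pool = []
    while len(nb_pool) < max(4 * spec.n_non_binders, 8):
        cid = cx_ids[rng.integers(len(cx_ids))]
        m = _random_mutation(rng, complexes[cid], int(rng.integers(2, 4)))
        if (cid, str(m)) in seen:
            continue
        seen.add((cid, str(m)))
        fv = featurizer.featurize(complexes[cid], m).values
        row = pd.Series(fv, index=featurizer.names)
        score = sum(
            coef * (row[col] - stats_used[col][0]) / stats_used[col][1]
            for col, coef in coeffs.items()
        )
        nb_pool.append((score, cid, m))
    nb_pool.sort(key=lambda e: e[0])
    for _, cid, m in nb_pool[: spec.n_non_binders]:
        records.append(
            AffinityRecord(
                complex_id=cid, mutation=m, is_non_binder=True,
                source="synthetic", partition="non-binder",
            )
        )
        truth_rows.append(
            {"complex_id": cid, "mutations": str(m), "true_ddg_noiseless": None,
             "planted_ddg": None, "planted": "non-binder"}
        )

    # planted additive / synergistic multi records built from existing singles
    singles_by_cx: dict[str, list[AffinityRecord]] = {}
    for r in records:
        if r.partition == "train" and len(r.mutation) == 1:
            singles_by_cx.setdefault(r.complex_id, []).append(r)
    planted = [("additive", spec.n_planted_additive), ("synergistic", spec.n_planted_synergistic)]
    from .dataset import ddg_of

    for label, count in planted:
        made = 0
        attempts = 0
        while made < count and attempts < 200:
            attempts += 1
            cid = cx_ids[rng.integers(len(cx_ids))]
            pool = singles_by_cx.get(cid, [])
            if len(pool) < 2:
                continue
            i, j = rng.choice(len(pool), size=2, replace=False)
            s1, s2 = pool[int(i)], pool[int(j)]
            (a,), (b,) = s1.mutation, s2.mutation
            if a.site == b.site:
                continue
            specs = tuple(sorted((a, b), key=lambda s: (s.chain_id, s.number, s.icode)))
            m = MultiMutation(specs)
            if (cid, str(m)) in seen:
                continue
            seen.add((cid, str(m)))
            total = ddg_of(s1) + ddg_of(s2)
            if label == "additive":
                ddg = total + float(rng.uniform(-0.5, 0.5))
            else:
                ddg = total + float(rng.choice([-1.0, 1.0])) * float(rng.uniform(1.5, 2.5))
            kd_w, kd_m = _kd_pair_for_ddg(ddg)
            records.append(
                AffinityRecord(
                    complex_id=cid, mutation=m, kd_wild=kd_w, kd_mutant=kd_m,
                    source="synthetic", partition="blind-multi",
                )
            )
            truth_rows.append(
                {"complex_id": cid, "mutations": str(m), "true_ddg_noiseless": None,
                 "planted_ddg": float(ddg), "planted": label}
            )
            made += 1

    sidecar = {
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
        "signal_std": spec.signal_std,
        "ddg_mean": spec.ddg_mean,
        "effect_coeffs": coeffs,
        "interaction": list(spec.interaction),
        "standardization": {k: list(v) for k, v in stats_used.items()},
        "records": truth_rows,
    }
    return CuratedDataset(records), sidecar, X
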