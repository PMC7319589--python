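"""Affinity-record curation.

Converts dissociation constants to binding free energies
(ΔG = RT·ln K_D, R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹) and expresses mutation
effects as ΔΔG = ΔG_wild − ΔG_mutant, so a positive value means the mutant
binds more tightly. Implements hypothetical-reverse-mutation augmentation
with its |ΔΔG| < 2 kcal/mol eligibility filter, additive/synergistic
labelling of multi-point mutations at a 1 kcal/mol tolerance, the
±0.5 kcal/mol increasing/decreasing classification, non-binder handling
(classification only, never regression training), and a documented CSV
schema for the whole record set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .structure_io import MultiMutation, MutationSpec, StructureError, parse_mutation_list

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "AffinityRecord",
    "CuratedDataset",
    "delta_g_from_kd",
    "ddg_of",
    "reverse_record",
    "augment_reverse",
    "label_additivity",
    "classify_ddg",
    "read_affinity_csv",
    "write_affinity_csv",
    "CSV_COLUMNS",
]

GAS_CONSTANT_KCAL = 1.987e-3  # kcal · mol⁻¹ · K⁻¹
DEFAULT_TEMPERATURE_K = 298.0


def delta_g_from_kd(kd: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Binding free energy ΔG = RT·ln(K_D), kcal/mol; K_D in molar."""
    if not kd > 0:
        raise ValueError(f"K_D must be positive, got {kd}")
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)


@dataclass
class AffinityRecord:
    """One experimental measurement of a mutation's effect on binding."""

    complex_id: str
    mutation: MultiMutation
    kd_wild: float | None = None
    kd_mutant: float | None = None
    temperature: float = DEFAULT_TEMPERATURE_K
    ddg: float | None = None          # kcal/mol, derived from K_D when absent
    is_reverse: bool = False
    is_non_binder: bool = False
    source: str = ""
    partition: str = "train"          # train | blind-multi | non-binder | validation

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.is_non_binder:
            if self.ddg is not None:
                raise ValueError("non-binder records carry no ΔΔG")
        elif self.ddg is None and (self.kd_wild is None or self.kd_mutant is None):
            raise ValueError(
                f"{self.complex_id} {self.mutation}: need either a K_D pair or a direct ΔΔG"
            )

    @property
    def n_sites(self) -> int:
        return len(self.mutation)

    @property
    def key(self) -> tuple[str, str]:
        return (self.complex_id, str(self.mutation))


def ddg_of(record: AffinityRecord) -> float:
    """ΔΔG = ΔG_wild − ΔG_mutant (kcal/mol); positive ⇒ mutant binds tighter."""
    if record.is_non_binder:
        raise ValueError("non-binder records have no measurable ΔΔG")
    if record.ddg is not None:
        return float(record.ddg)
    if record.kd_wild is None or record.kd_mutant is None:
        raise ValueError("record lacks both a direct ΔΔG and a K_D pair")
    return delta_g_from_kd(record.kd_wild, record.temperature) - delta_g_from_kd(
        record.kd_mutant, record.temperature
    )


def reverse_record(record: AffinityRecord) -> AffinityRecord:
    """The hypothetical reverse mutation: mutant structure becomes the
    wild-type context, letters swap, ΔΔG negates."""
    if len(record.mutation) != 1:
        raise ValueError("reverse augmentation is defined for single-point records")
    (spec,) = record.mutation
    rev_spec = MutationSpec(spec.chain_id, spec.mt_aa, spec.number, spec.icode, spec.wt_aa)
    return AffinityRecord(
        complex_id=record.complex_id,
        mutation=MultiMutation((rev_spec,)),
        kd_wild=record.kd_mutant,
        kd_mutant=record.kd_wild,
        temperature=record.temperature,
        ddg=-ddg_of(record),
        is_reverse=True,
        source=record.source,
        partition=record.partition,
    )


def augment_reverse(
    train: list[AffinityRecord],
    threshold_kcal: float = 2.0,
    signed: bool = False,
) -> list[AffinityRecord]:
    """Append hypothetical reverse mutations for eligible single-point records.

    A forward record qualifies when |ΔΔG| < threshold (strict); with
    ``signed=True`` the raw signed value is compared instead. Originals are
    always retained, reverses are flagged ``is_reverse``.
    """
    out = list(train)
    for rec in train:
        if rec.is_reverse or rec.is_non_binder:
            continue
        if len(rec.mutation) != 1:
            raise ValueError(
                f"{rec.complex_id} {rec.mutation}: augmentation expects single-point records"
            )
        value = ddg_of(rec) if signed else abs(ddg_of(rec))
        if value < threshold_kcal:
            out.append(reverse_record(rec))
    return out


def label_additivity(
    multi: AffinityRecord,
    singles: list[AffinityRecord],
    tol_kcal: float = 1.0,
) -> str:
    """'additive' when the multi-point ΔΔG is within `tol_kcal` of the sum of
    its constituent single-point ΔΔGs, 'synergistic' beyond it, 'unlabelable'
    when any constituent single is missing."""
    by_site: dict[tuple, float] = {}
    for s in singles:
        if len(s.mutation) == 1 and not s.is_non_binder and s.complex_id == multi.complex_id:
            (spec,) = s.mutation
            by_site[(spec.site, spec.wt_aa, spec.mt_aa)] = ddg_of(s)
    total = 0.0
    for spec in multi.mutation:
        k = (spec.site, spec.wt_aa, spec.mt_aa)
        if k not in by_site:
            return "unlabelable"
        total += by_site[k]
    return "additive" if abs(total - ddg_of(multi)) <= tol_kcal else "synergistic"


def classify_ddg(ddg: float, binarize_at_zero: bool = False) -> str:
    """'increasing' for ΔΔG > 0.5 kcal/mol, 'decreasing' for ΔΔG ≤ −0.5,
    otherwise 'neutral'. With ``binarize_at_zero`` the neutral band is split
    at 0 into the two outer classes."""
    if not math.isfinite(ddg):
        raise ValueError("ΔΔG must be finite")
    if ddg > 0.5:
        return "increasing"
    if ddg <= -0.5:
        return "decreasing"
    if binarize_at_zero:
        return "increasing" if ddg > 0 else "decreasing"
    return "neutral"


# ---------------------------------------------------------------------------
# Curated dataset container
# ---------------------------------------------------------------------------

@dataclass
class CuratedDataset:
    """Partitioned affinity records with a per-complex grouping index."""

    records: list[AffinityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple, str] = {}
        for r in self.records:
            k = r.key + (r.is_reverse,)
            if k in seen and seen[k] != r.partition:
                raise ValueError(f"record {k} appears in two partitions")
            seen[k] = r.partition
            if r.is_non_binder and r.partition == "train":
                raise ValueError(f"non-binder {r.key} must not be in the training partition")

    def partition(self, name: str) -> list[AffinityRecord]:
        return [r for r in self.records if r.partition == name]

    @property
    def train(self) -> list[AffinityRecord]:
        return self.partition("train")

    def by_complex(self) -> dict[str, list[AffinityRecord]]:
        out: dict[str, list[AffinityRecord]] = {}
        for r in self.records:
            out.setdefault(r.complex_id, []).append(r)
        return out


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "complex_id",
    "mutations",
    "kd_wt",
    "kd_mut",
    "temperature",
    "ddg",
    "is_reverse",
    "is_non_binder",
    "source",
    "partition",
]


def read_affinity_csv(path, ddg_consistency_tol: float = 1e-6) -> CuratedDataset:
    """Read the documented affinity CSV schema.

    A record may carry a K_D pair, a direct ΔΔG, or both; when both are given
    they must agree to `ddg_consistency_tol` kcal/mol.
    """
    df = pd.read_csv(path, dtype={"complex_id": str, "mutations": str, "source": str})
    missing = [c for c in ("complex_id", "mutations") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[AffinityRecord] = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            muts = parse_mutation_list(str(row["mutations"]))
            if len(muts) != 1:
                raise ValueError("expected exactly one multi-mutation per row")
            kd_wt = _opt_float(row.get("kd_wt"))
            kd_mut = _opt_float(row.get("kd_mut"))
            temperature = _opt_float(row.get("temperature")) or DEFAULT_TEMPERATURE_K
            ddg = _opt_float(row.get("ddg"))
            rec = AffinityRecord(
                complex_id=str(row["complex_id"]),
                mutation=muts[0],
                kd_wild=kd_wt,
                kd_mutant=kd_mut,
                temperature=temperature,
                ddg=ddg,
                is_reverse=_opt_bool(row.get("is_reverse")),
                is_non_binder=_opt_bool(row.get("is_non_binder")),
                source=str(row.get("source") or ""),
                partition=str(row.get("partition") or "train"),
            )
            if ddg is not None and kd_wt is not None and kd_mut is not None:
                derived = delta_g_from_kd(kd_wt, temperature) - delta_g_from_kd(
                    kd_mut, temperature
                )
                if abs(derived - ddg) > ddg_consistency_tol:
                    raise ValueError(
                        f"ΔΔG column ({ddg:.6f}) inconsistent with K_D pair ({derived:.6f})"
                    )
        except (ValueError, StructureError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
        records.append(rec)
    return CuratedDataset(records)


def write_affinity_csv(dataset: CuratedDataset, path) -> None:
    rows = []
    for r in dataset.records:
        rows.append(
            {
                "complex_id": r.complex_id,
                "mutations": str(r.mutation),
                "kd_wt": r.kd_wild,
                "kd_mut": r.kd_mutant,
                "temperature": r.temperature,
                "ddg": r.ddg,
                "is_reverse": r.is_reverse,
                "is_non_binder": r.is_non_binder,
                "source": r.source,
                "partition": r.partition,
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _opt_bool(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes")
    return bool(value)
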