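"""Evolutionary features: PAM30 substitution scores and PSI-BLAST PSSMs.

PSSMs are consumed, never computed: the package reads the ASCII profile
written by ``psiblast -out_ascii_pssm`` and maps its positions onto structure
residues by exact sequence match. When no profile is available the evolutionary
feature set degrades to PAM30 only, with the PSSM columns flagged missing and
imputed downstream from dataset medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import AA1_TO_3, Complex, MutationSpec, StructureError

__all__ = [
    "AA_ORDER",
    "SubstitutionMatrix",
    "PssmProfile",
    "load_pam30",
    "read_ncbi_matrix",
    "pam30_score",
    "read_ascii_pssm",
    "write_ascii_pssm",
    "map_profile_to_chain",
    "pssm_features",
]

#: PSI-BLAST ASCII PSSM column order
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class SubstitutionMatrix:
    """20×20 integer substitution-score lookup."""

    scores: dict[tuple[str, str], int]
    name: str

    def score(self, a: str, b: str) -> int:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise StructureError(f"no {self.name} score for pair ({a!r}, {b!r})") from None


_PAM30: SubstitutionMatrix | None = None


def load_pam30() -> SubstitutionMatrix:
    """PAM30 from Biopython's bundled NCBI matrices (standard residues only)."""
    global _PAM30
    if _PAM30 is None:
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("PAM30")
        scores = {
            (a, b): int(m[a, b]) for a in AA1_TO_3 for b in AA1_TO_3
        }
        _PAM30 = SubstitutionMatrix(scores, "PAM30")
    return _PAM30


def read_ncbi_matrix(path, name: str = "custom") -> SubstitutionMatrix:
    """Parse an NCBI-format substitution matrix text file (e.g. a PAM30 copy)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    lines = [ln for ln in lines if ln.strip()]
    header = lines[0].split()
    scores: dict[tuple[str, str], int] = {}
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        if len(parts) - 1 != len(header):
            raise StructureError(f"matrix row {row!r}: expected {len(header)} scores")
        for col, value in zip(header, parts[1:]):
            if row in AA1_TO_3 and col in AA1_TO_3:
                scores[(row, col)] = int(value)
    missing = [(a, b) for a in AA1_TO_3 for b in AA1_TO_3 if (a, b) not in scores]
    if missing:
        raise StructureError(f"matrix incomplete: missing {len(missing)} pairs")
    return SubstitutionMatrix(scores, name)


def pam30_score(
    wt_aa: str, mt_aa: str, matrix: SubstitutionMatrix | None = None
) -> int:
    matrix = matrix or load_pam30()
    if wt_aa not in AA1_TO_3 or mt_aa not in AA1_TO_3:
        raise StructureError(f"non-standard amino acid in ({wt_aa!r}, {mt_aa!r})")
    return matrix.score(wt_aa, mt_aa)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

@dataclass
class PssmProfile:
    """Ordered per-position log-odds from a PSI-BLAST ASCII PSSM."""

    letters: list[str]            # query residue letters, in order
    log_odds: np.ndarray          # (n_positions, 20) ints in AA_ORDER

    def __len__(self) -> int:
        return len(self.letters)

    @property
    def sequence(self) -> str:
        return "".join(self.letters)

    def score(self, position: int, aa: str) -> int:
        """Log-odds of `aa` at 0-based profile position."""
        return int(self.log_odds[position, AA_ORDER.index(aa)])


def read_ascii_pssm(path) -> PssmProfile:
    """Parse the `-out_ascii_pssm` dialect: a header naming the 20 columns,
    then one row per position: index, residue letter, 20 log-odds integers
    (any trailing weight/information columns are ignored)."""
    with open(path) as fh:
        lines = fh.readlines()
    header_idx = None
    for i, ln in enumerate(lines):
        cols = ln.split()
        if len(cols) >= 20 and "".join(cols[:20]) == AA_ORDER:
            header_idx = i
            break
    if header_idx is None:
        raise StructureError(f"{path}: no PSSM column header found")
    letters: list[str] = []
    rows: list[list[int]] = []
    for lineno, ln in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        cols = ln.split()
        if not cols:
            break  # blank line ends the log-odds block
        if not cols[0].isdigit():
            break  # footer (K, Lambda, ...)
        if len(cols) < 22:
            raise StructureError(f"{path}: line {lineno}: ragged PSSM row ({len(cols)} fields)")
        letters.append(cols[1])
        try:
            rows.append([int(v) for v in cols[2:22]])
        except ValueError:
            raise StructureError(f"{path}: line {lineno}: non-integer log-odds") from None
    if not rows:
        raise StructureError(f"{path}: empty PSSM body")
    return PssmProfile(letters, np.array(rows, dtype=int))


def write_ascii_pssm(profile: PssmProfile, path) -> None:
    """Write a profile back in the ASCII PSSM dialect (log-odds block only)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(AA_ORDER) + "\n")
        for i, (letter, row) in enumerate(zip(profile.letters, profile.log_odds), start=1):
            cells = " ".join(f"{v:3d}" for v in row)
            fh.write(f"{i:5d} {letter} {cells}\n")


def map_profile_to_chain(
    profile: PssmProfile, complex_: Complex, chain_id: str
) -> dict[tuple[str, int, str], int]:
    """Map profile positions onto a chain's residues by exact sequence match.

    The chain's ordered one-letter sequence must equal the profile sequence;
    any gap or mismatch is an error (never a silent shift).
    """
    residues = complex_.chain_residues(chain_id)
    seq = "".join(r.aa1 or "X" for r in residues)
    if seq != profile.sequence:
        raise StructureError(
            f"chain {chain_id} sequence does not match PSSM "
            f"(chain {len(seq)} aa vs profile {len(profile)} aa)"
        )
    return {r.key: i for i, r in enumerate(residues)}


def pssm_features(
    profile: PssmProfile | None,
    spec: MutationSpec,
    position_map: dict[tuple[str, int, str], int] | None = None,
) -> tuple[float, float, float]:
    """(wt log-odds, mt log-odds, wt − mt) at the mutated position.

    With no profile, returns NaNs: the feature assembly masks and imputes
    them (dataset median + missingness indicator).
    """
    if profile is None:
        return (float("nan"),) * 3
    if position_map is None:
        raise StructureError("a structure→profile position map is required")
    if spec.site not in position_map:
        raise StructureError(f"mutation site {spec.site} not mappable to the PSSM")
    pos = position_map[spec.site]
    if profile.letters[pos] != spec.wt_aa:
        raise StructureError(
            f"profile letter {profile.letters[pos]} at position {pos} does not "
            f"match wild-type {spec.wt_aa}"
        )
    wt = float(profile.score(pos, spec.wt_aa))
    mt = float(profile.score(pos, spec.mt_aa))
    return wt, mt, wt - mt
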