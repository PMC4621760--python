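"""Aux/IAA family identification by conserved-motif scanning.

Aux/IAA proteins carry four conserved motif blocks: motif I, an
N-terminal leucine-repeat repressor motif (LxLxLx); motif II, the degron
(core GWPPV) recognized by TIR1/AFB F-box proteins; and motifs III and IV,
which mediate homo-/hetero-dimerization.  Family members lacking an intact
degron cannot be targeted for auxin-mediated degradation and are called
*non-canonical*.

Membership here is a deterministic motif rule rather than a profile-HMM
search: by default a protein is a family member when at least two of
motifs {II, III, IV} are present, so degron-less members remain callable.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field

from .formats import FormatError, SeqRecord

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

#: Average residue masses (Da); peptide MW = sum of residues + one water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: EMBOSS-style pKa values; substitute ExPASy constants via the pKa argument.
DEFAULT_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}
_POSITIVE = ("Nterm", "K", "R", "H")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")


@dataclass(frozen=True)
class MotifModel:
    """A degenerate amino-acid pattern: fixed residues, 'x' wildcards and
    bracketed residue classes, e.g. ``GWPP[VI]``."""

    motif_id: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.motif_id}: empty pattern")
        stripped = re.sub(r"\[[A-Zx]+\]", "", self.pattern)
        if not set(stripped) <= AA20 | {"x"}:
            raise ValueError(
                f"motif {self.motif_id}: pattern {self.pattern!r} has letters "
                "outside the 20 amino acids / 'x' wildcard"
            )

    def to_regex(self) -> re.Pattern:
        out = []
        for token in re.findall(r"\[[A-Zx]+\]|.", self.pattern):
            if token.startswith("["):
                out.append(token)
            elif token == "x":
                out.append(".")
            else:
                out.append(re.escape(token))
        # lookahead so that overlapping start positions are all reported
        return re.compile("(?=(" + "".join(out) + "))")


@dataclass
class MotifCallResult:
    """Per-protein motif hits and the family / canonical verdicts."""

    protein_id: str
    hits: dict[str, list[int]]
    is_family_member: bool | None = None
    canonical_status: str | None = None


def default_motif_models() -> list[MotifModel]:
    """Packaged motif patterns for blocks I-IV (see data/motifs.tsv)."""
    return load_motif_models(
        importlib.resources.files("auxiaa.data") / "motifs.tsv"
    )


def load_motif_models(path) -> list[MotifModel]:
    models = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            motif_id, pattern = line.split("\t")[:2]
            models.append(MotifModel(motif_id, pattern))
    return models


def scan_motifs(protein: SeqRecord, models: list[MotifModel]) -> MotifCallResult:
    """Find every match start (1-based) of each motif in the protein."""
    seq = protein.sequence
    bad = set(seq) - AA20
    if bad:
        raise FormatError(
            f"protein {protein.id}: unknown residue letter(s) {sorted(bad)}"
        )
    hits = {
        m.motif_id: [mo.start() + 1 for mo in m.to_regex().finditer(seq)]
        for m in models
    }
    return MotifCallResult(protein_id=protein.id, hits=hits)


def membership_rule_default(hits: dict[str, list[int]]) -> bool:
    """Member iff at least two of motifs {II, III, IV} are present."""
    return sum(bool(hits.get(m)) for m in ("II", "III", "IV")) >= 2


def classify_family_member(result: MotifCallResult, rule=membership_rule_default) -> bool:
    result.is_family_member = bool(rule(result.hits))
    return result.is_family_member


def classify_canonical(result: MotifCallResult) -> str:
    """Canonical iff the degron (motif II) is present; member-only call."""
    if not result.is_family_member:
        raise ValueError(
            f"{result.protein_id}: canonical status is defined only for family members"
        )
    result.canonical_status = "canonical" if result.hits.get("II") else "non_canonical"
    return result.canonical_status


def call_family(proteins, models=None, rule=membership_rule_default):
    """Scan, classify membership and canonical status for a whole proteome."""
    models = models if models is not None else default_motif_models()
    results = []
    for p in proteins:
        r = scan_motifs(p, models)
        classify_family_member(r, rule)
        if r.is_family_member:
            classify_canonical(r)
        results.append(r)
    return results


# ---------------------------------------------------------------------------
# Physicochemical profile


@dataclass
class PhysicoChemProfile:
    length: int
    molecular_weight: float
    isoelectric_point: float
    pKa_table: dict[str, float] = field(default_factory=dict)


def net_charge(sequence: str, pH: float, pKa: dict[str, float] = DEFAULT_PKA) -> float:
    """Henderson-Hasselbalch net charge of the peptide at the given pH.

    Positive groups (N-terminus, K, R, H) contribute ``1/(1+10^(pH-pKa))``
    each; negative groups (C-terminus, D, E, C, Y) contribute
    ``-1/(1+10^(pKa-pH))``.  Strictly decreasing in pH.
    """
    counts = {g: 0 for g in pKa}
    counts["Nterm"] = counts["Cterm"] = 1
    for aa in sequence:
        if aa in counts:
            counts[aa] += 1
    charge = 0.0
    for g in _POSITIVE:
        charge += counts.get(g, 0) / (1.0 + 10.0 ** (pH - pKa[g]))
    for g in _NEGATIVE:
        charge -= counts.get(g, 0) / (1.0 + 10.0 ** (pKa[g] - pH))
    return charge


def isoelectric_point(
    sequence: str, pKa: dict[str, float] = DEFAULT_PKA, tol: float = 1e-4
) -> float:
    """pI by bisection on net charge; unique because charge is monotone."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(sequence, mid, pKa)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def molecular_weight(sequence: str) -> float:
    return sum(RESIDUE_MASS[a] for a in sequence) + WATER_MASS


def physicochemical_profile(
    protein: SeqRecord, pKa: dict[str, float] = DEFAULT_PKA
) -> PhysicoChemProfile:
    """Length, average MW and pI of a protein over the standard 20 residues."""
    bad = set(protein.sequence) - AA20
    if bad:
        raise FormatError(
            f"protein {protein.id}: nonstandard residue(s) {sorted(bad)}; "
            "no average-mass fallback is applied"
        )
    mw = molecular_weight(protein.sequence)
    pi = isoelectric_point(protein.sequence, pKa)
    if not (0.0 < pi < 14.0) or not math.isfinite(mw):
        raise ValueError(f"protein {protein.id}: degenerate profile")
    return PhysicoChemProfile(
        length=len(protein.sequence),
        molecular_weight=mw,
        isoelectric_point=pi,
        pKa_table=dict(pKa),
    )
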