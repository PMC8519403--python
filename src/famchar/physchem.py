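"""ProtParam-style physicochemical panel computed from sequence alone.

Conventions match the ExPASy tool: average (not monoisotopic) residue masses,
the Bjellqvist pKa set for the isoelectric point, Kyte-Doolittle hydropathy
for GRAVY, the Guruprasad DIWV dipeptide table for the instability index
(stable iff II < 40), and His excluded from the charged-residue counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.SeqUtils import molecular_weight as _bio_molecular_weight
from Bio.SeqUtils.ProtParamData import DIWV as _DIWV
from Bio.SeqUtils.ProtParamData import kd as _KD

from famchar._util import CANONICAL_AA
from famchar.seq_model import ProteinRecord

__all__ = [
    "PhysicoChemProfile",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "gravy",
    "instability_index",
    "aliphatic_index",
    "charged_counts",
    "physchem_profile",
    "write_panel_tsv",
    "BJELLQVIST_PKA",
]

#: Bjellqvist pKa values as used by ExPASy's pI tool.
BJELLQVIST_PKA = {
    "Nterm": 7.5,
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
    "H": 5.98,
    "K": 10.0,
    "R": 12.0,
}

_POSITIVE = ("H", "K", "R")
_NEGATIVE = ("D", "E", "C", "Y")


def _check_canonical(p: ProteinRecord) -> str:
    bad = set(p.sequence) - CANONICAL_AA
    if bad:
        raise ValueError(
            f"protein {p.id!r}: non-canonical residue(s) {sorted(bad)}; "
            "physicochemical formulas are defined on canonical letters only"
        )
    return p.sequence


def molecular_weight(p: ProteinRecord) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    seq = _check_canonical(p)
    return _bio_molecular_weight(seq, seq_type="protein", monoisotopic=False) / 1000.0


def net_charge(p: ProteinRecord, ph: float, pka: dict | None = None) -> float:
    """Net charge at a given pH under the Henderson-Hasselbalch model with
    N-/C-termini and D, E, C, Y, H, K, R side chains."""
    seq = _check_canonical(p)
    pka = pka or BJELLQVIST_PKA
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in _POSITIVE:
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in _NEGATIVE:
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge


def isoelectric_point(p: ProteinRecord, pka: dict | None = None) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Iterates well past the contract tolerance (1e-3) so the residual charge
    at the returned pH is negligible even for long sequences.
    """
    lo, hi = 0.0, 14.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if net_charge(p, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gravy(p: ProteinRecord) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value."""
    seq = _check_canonical(p)
    return sum(_KD[a] for a in seq) / len(seq)


def instability_index(p: ProteinRecord) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV dipeptide weights."""
    seq = _check_canonical(p)
    if len(seq) < 2:
        raise ValueError(f"protein {p.id!r}: instability index needs length >= 2")
    total = sum(_DIWV[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return (10.0 / len(seq)) * total


def is_stable(ii: float) -> bool:
    """Stable iff instability index < 40 (strict)."""
    return ii < 40.0


def aliphatic_index(p: ProteinRecord) -> float:
    """AI = X_Ala + 2.9 * X_Val + 3.9 * (X_Ile + X_Leu), X in mole percent."""
    seq = _check_canonical(p)
    n = len(seq)
    x = {a: 100.0 * seq.count(a) / n for a in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def charged_counts(p: ProteinRecord) -> tuple[int, int]:
    """(n_negative, n_positive) = (#Asp + #Glu, #Arg + #Lys); His excluded."""
    seq = p.sequence
    return seq.count("D") + seq.count("E"), seq.count("R") + seq.count("K")


@dataclass(frozen=True)
class PhysicoChemProfile:
    protein_id: str
    length_aa: int
    mw_kda: float
    pi: float
    gravy: float
    instability_index: float
    stability: str  # "stable" | "unstable"
    aliphatic_index: float
    n_neg: int
    n_pos: int
    cds_length: int | None = None

    def __post_init__(self) -> None:
        if self.length_aa < 1 or self.mw_kda <= 0 or not (0 < self.pi < 14):
            raise ValueError("inconsistent physicochemical profile")
        expected = "stable" if is_stable(self.instability_index) else "unstable"
        if self.stability != expected:
            raise ValueError("stability label inconsistent with instability index")


def physchem_profile(
    p: ProteinRecord, cds_length: int | None = None
) -> PhysicoChemProfile:
    ii = instability_index(p)
    n_neg, n_pos = charged_counts(p)
    return PhysicoChemProfile(
        protein_id=p.id,
        length_aa=len(p),
        mw_kda=molecular_weight(p),
        pi=isoelectric_point(p),
        gravy=gravy(p),
        instability_index=ii,
        stability="stable" if is_stable(ii) else "unstable",
        aliphatic_index=aliphatic_index(p),
        n_neg=n_neg,
        n_pos=n_pos,
        cds_length=cds_length,
    )


def write_panel_tsv(profiles: Iterable[PhysicoChemProfile], path: str | Path) -> None:
    """Panel TSV column-compatible with typical family-survey supplements."""
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tcds_length\tlength_aa\tmw_kda\tpi\tn_neg\tn_pos\t"
            "gravy\tinstability_index\tstability\taliphatic_index\n"
        )
        for pr in profiles:
            cds = "" if pr.cds_length is None else str(pr.cds_length)
            fh.write(
                f"{pr.protein_id}\t{cds}\t{pr.length_aa}\t{pr.mw_kda:.4f}\t"
                f"{pr.pi:.3f}\t{pr.n_neg}\t{pr.n_pos}\t{pr.gravy:.4f}\t"
                f"{pr.instability_index:.2f}\t{pr.stability}\t"
                f"{pr.aliphatic_index:.2f}\n"
            )
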