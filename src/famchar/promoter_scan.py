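"""Exact IUPAC motif scanning over promoter sequences.

This is literal degenerate-pattern matching (no weight matrices, no database
lookups). Motif definitions are user-supplied; the bundled table
(``data/motifs.tsv``) carries literature citations per motif and is meant to
be edited or replaced.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MotifDef",
    "MotifHit",
    "IUPAC",
    "reverse_complement",
    "scan_promoter",
    "scan_promoters",
    "hit_count_matrix",
    "load_motifs",
    "default_motifs",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_CATEGORIES = {"stress", "light", "development", "hormone", "other"}


def reverse_complement(pattern: str) -> str:
    """Reverse complement of a nucleotide / IUPAC string."""
    return pattern.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str
    category: str = "other"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.name!r}: empty pattern")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"motif {self.name!r}: illegal IUPAC code(s) {sorted(bad)}"
            )
        if self.category not in _CATEGORIES:
            raise ValueError(f"motif {self.name!r}: unknown category")

    def regex(self, reverse: bool = False) -> re.Pattern:
        pattern = reverse_complement(self.pattern) if reverse else self.pattern
        # N in the PROMOTER matches nothing: classes contain ACGT only.
        body = "".join(f"[{IUPAC[c]}]" for c in pattern.upper())
        return re.compile(f"(?=({body}))")  # lookahead -> overlapping hits


@dataclass(frozen=True)
class MotifHit:
    gene: str
    motif: str
    position: int  # 1-based, forward-strand coordinates of the match window
    strand: str  # "+" | "-"


def scan_promoter(
    gene: str,
    promoter: str,
    motifs: Sequence[MotifDef],
    both_strands: bool = True,
) -> list[MotifHit]:
    """All (overlapping) IUPAC matches of each motif in one promoter.

    Minus-strand hits are matches of the motif's reverse complement on the
    forward sequence; their positions are forward-strand coordinates of the
    matched window.
    """
    seq = promoter.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"promoter {gene!r}: illegal base(s) {sorted(bad)}")
    hits: list[MotifHit] = []
    for motif in motifs:
        for m in motif.regex().finditer(seq):
            hits.append(MotifHit(gene, motif.name, m.start() + 1, "+"))
        if both_strands:
            for m in motif.regex(reverse=True).finditer(seq):
                hits.append(MotifHit(gene, motif.name, m.start() + 1, "-"))
    hits.sort(key=lambda h: (h.motif, h.position, h.strand))
    return hits


def scan_promoters(
    promoters: Mapping[str, str],
    motifs: Sequence[MotifDef],
    both_strands: bool = True,
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for gene in promoters:
        hits.extend(scan_promoter(gene, promoters[gene], motifs, both_strands))
    return hits


def hit_count_matrix(
    hits: Iterable[MotifHit],
    genes: Sequence[str] | None = None,
    motifs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene x motif hit-count matrix (both strands pooled)."""
    rows = [(h.gene, h.motif) for h in hits]
    df = pd.DataFrame(rows, columns=["gene", "motif"])
    counts = df.groupby(["gene", "motif"]).size().unstack(fill_value=0)
    if genes is not None:
        counts = counts.reindex(genes, fill_value=0)
    if motifs is not None:
        counts = counts.reindex(columns=motifs, fill_value=0)
    return counts.astype(int)


def load_motifs(path: str | Path) -> list[MotifDef]:
    """Read motif definitions from a TSV with columns name/pattern/category
    (extra columns such as citations are ignored)."""
    motifs: list[MotifDef] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_name = header.index("name")
            i_pat = header.index("pattern")
            i_cat = header.index("category")
        except ValueError as exc:
            raise ValueError(f"{path}: need columns name, pattern, category") from exc
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            motifs.append(MotifDef(cols[i_name], cols[i_pat], cols[i_cat]))
    if not motifs:
        raise ValueError(f"{path}: no motifs defined")
    return motifs


def default_motifs() -> list[MotifDef]:
    """The bundled motif table."""
    with resources.as_file(
        resources.files("famchar").joinpath("data/motifs.tsv")
    ) as p:
        return load_motifs(p)
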