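"""Core sequence/gene records and readers for the formats the pipeline consumes.

Coordinates are 1-based inclusive everywhere (GFF3 convention). Strand is
carried as metadata only; no computation in this package uses it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from famchar._util import AMBIGUOUS_SENTINEL, CANONICAL_AA, DNA_LETTERS

__all__ = [
    "ProteinRecord",
    "GeneModel",
    "CodingSequence",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
    "translate_cds",
]

_STOP_CODONS = {"TAA", "TAG", "TGA"}

# Standard (NCBI table 1) genetic code; stops as '*'.
_CODE_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_BASES = "TCAG"
GENETIC_CODE = {
    a + b + c: _CODE_STRING[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


class FastaError(ValueError):
    """Malformed FASTA input (message carries the offending line number)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 canonical letters (plus the sentinel
    ``X`` when produced by a permissive reader)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - CANONICAL_AA - {AMBIGUOUS_SENTINEL}
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding sequence over {A,C,G,T}.

    The final codon may be a stop; internal stops are rejected.
    """

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("coding sequence requires a non-empty gene id")
        seq = self.sequence
        if len(seq) < 3:
            raise ValueError(f"CDS {self.gene_id!r}: length < 3")
        if len(seq) % 3:
            raise ValueError(
                f"CDS {self.gene_id!r}: length {len(seq)} not divisible by 3"
            )
        bad = set(seq) - DNA_LETTERS
        if bad:
            raise ValueError(f"CDS {self.gene_id!r}: illegal base(s) {sorted(bad)}")
        for i in range(0, len(seq) - 3, 3):
            if seq[i : i + 3] in _STOP_CODONS:
                raise ValueError(
                    f"CDS {self.gene_id!r}: internal stop codon at nt {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codons(self) -> list[str]:
        return [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]


def translate_cds(cds: CodingSequence) -> str:
    """Translate a CDS with the standard code, dropping a trailing stop."""
    aa = [GENETIC_CODE[c] for c in cds.codons]
    if aa and aa[-1] == "*":
        aa.pop()
    if not aa:
        raise ValueError(f"CDS {cds.gene_id!r}: translates to an empty protein")
    return "".join(aa)


@dataclass(frozen=True)
class GeneModel:
    """A gene placed on a chromosome; ``rank`` is the 1-based ordinal of the
    gene along its chromosome by ascending start."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id!r}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")


def assign_ranks(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Return genes with per-chromosome ranks assigned by ascending start.

    Input order is preserved.
    """
    order: dict[str, list[GeneModel]] = {}
    for g in genes:
        order.setdefault(g.chromosome, []).append(g)
    rank_of: dict[str, int] = {}
    for chrom_genes in order.values():
        for i, g in enumerate(sorted(chrom_genes, key=lambda g: (g.start, g.gene_id))):
            rank_of[g.gene_id] = i + 1
    return [replace(g, rank=rank_of[g.gene_id]) for g in genes]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _iter_fasta(path: Path) -> Iterable[tuple[str, str, int]]:
    """Yield (id, sequence, header_line_no). Hand-rolled so that errors can
    carry the source line number, which library parsers discard."""
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks), header_line
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunks.append(line.upper())
        if header is not None:
            yield header, "".join(chunks), header_line


def read_fasta(
    path: str | Path,
    kind: Literal["protein", "cds"] = "protein",
    permissive: bool = False,
) -> list[ProteinRecord] | list[CodingSequence]:
    """Read a FASTA file into validated records.

    Sequences are upper-cased; duplicate ids are rejected. With
    ``permissive=True`` protein ambiguity codes (X, B, Z, J, U, O) are mapped
    to the sentinel ``X``; otherwise they are rejected with the line number.
    """
    path = Path(path)
    records: list = []
    seen: set[str] = set()
    n = 0
    for rid, seq, lineno in _iter_fasta(path):
        n += 1
        if rid in seen:
            raise FastaError(f"{path}:{lineno}: duplicate id {rid!r}")
        seen.add(rid)
        if kind == "protein":
            ambiguous = set(seq) & set("XBZJUO")
            if ambiguous and not permissive:
                raise FastaError(
                    f"{path}:{lineno}: record {rid!r} contains ambiguity "
                    f"code(s) {sorted(ambiguous)} (use permissive mode)"
                )
            if ambiguous:
                seq = re.sub("[XBZJUO]", AMBIGUOUS_SENTINEL, seq)
            bad = set(seq) - CANONICAL_AA - {AMBIGUOUS_SENTINEL}
            if bad:
                raise FastaError(
                    f"{path}:{lineno}: record {rid!r} contains illegal "
                    f"character(s) {sorted(bad)}"
                )
            records.append(ProteinRecord(rid, seq))
        elif kind == "cds":
            bad = set(seq) - DNA_LETTERS
            if bad:
                raise FastaError(
                    f"{path}:{lineno}: record {rid!r} contains illegal "
                    f"base(s) {sorted(bad)}"
                )
            records.append(CodingSequence(rid, seq))
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown kind {kind!r}")
    if n == 0:
        raise FastaError(f"{path}: empty FASTA file")
    return records


def write_fasta(
    records: Iterable[ProteinRecord | CodingSequence],
    path: str | Path,
    width: int = 70,
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid = rec.id if isinstance(rec, ProteinRecord) else rec.gene_id
            fh.write(f">{rid}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3 or simple TSV)
# ---------------------------------------------------------------------------

_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def _parse_gff3(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if cols[2] != "gene":
                continue
            m = _GFF_ID_RE.search(cols[8])
            if not m:
                raise ValueError(f"{path}:{lineno}: gene feature without ID=")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = cols[6] if cols[6] in {"+", "-"} else "+"
            try:
                genes.append(GeneModel(m.group(1), cols[0], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _parse_gene_tsv(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0].lower() in {"gene_id", "gene", "id"}:
                continue  # header row
            if len(cols) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >=4 columns "
                    "(gene_id, chromosome, start, end[, strand])"
                )
            try:
                start, end = int(cols[2]), int(cols[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = cols[4] if len(cols) > 4 and cols[4] in {"+", "-"} else "+"
            try:
                genes.append(GeneModel(cols[0], cols[1], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (``gene`` features) or a 4+-column TSV and
    assign per-chromosome ranks by ascending start."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    is_gff = first.startswith("##gff-version") or (
        len(first.split("\t")) == 9 and not first.startswith("#")
    )
    genes = _parse_gff3(path) if is_gff else _parse_gene_tsv(path)
    if not genes:
        raise ValueError(f"{path}: no gene models found")
    ids = [g.gene_id for g in genes]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"{path}: duplicate gene id(s) {sorted(dup)}")
    return assign_ranks(genes)


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\n")
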