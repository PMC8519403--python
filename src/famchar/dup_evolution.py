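"""Tandem-duplicate detection, Nei-Gojobori (1986) Ka/Ks estimation on codon
alignments, selection labelling, and divergence dating.

NG86 conventions used here:

* Site counting enumerates the nine single-base mutations of each codon;
  every mutation carries weight 1/3. Synonymous mutations accrue to S sites,
  nonsynonymous non-stop mutations to N sites, and mutations creating a stop
  codon accrue to neither (so N + S = 3 - stops/3 per codon). Site totals are
  averaged over the two sequences.
* Differences between two codons are averaged over all minimal mutational
  pathways (orderings of the differing positions), excluding pathways that
  pass through a stop codon; if every pathway is blocked, all pathways are
  used unrestricted.
* Proportions are Jukes-Cantor corrected: d = -(3/4) ln(1 - (4/3) p).
  p >= 3/4 leaves the corresponding rate undefined (None), mirroring
  saturated pairs that retain only a Ka value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Iterable, Sequence

from famchar._util import GAP, percent
from famchar.seq_model import (
    GENETIC_CODE,
    CodingSequence,
    GeneModel,
    translate_cds,
)

__all__ = [
    "TandemCriteria",
    "EvolutionParams",
    "DuplicatePair",
    "NGResult",
    "find_tandem_pairs",
    "codon_align",
    "nei_gojobori",
    "jukes_cantor",
    "selection_label",
    "divergence_time",
    "analyze_pair",
    "chromosome_distribution",
    "write_pairs_tsv",
]

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Tandem detection & chromosome tabulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TandemCriteria:
    max_intervening_genes: int = 1
    max_distance_bp: int = 100_000
    require_same_chromosome: bool = True

    def __post_init__(self) -> None:
        if self.max_intervening_genes < 0 or self.max_distance_bp < 0:
            raise ValueError("tandem criteria bounds must be >= 0")


def find_tandem_pairs(
    genes: Sequence[GeneModel],
    family_ids: Iterable[str],
    criteria: TandemCriteria | None = None,
) -> list[tuple[str, str]]:
    """Family-member pairs that are tandem under the criteria.

    Genes must carry per-chromosome ranks (see ``read_gene_models``). Pairs
    are reported once, each in lexicographic id order, list sorted.
    """
    criteria = criteria or TandemCriteria()
    family = set(family_ids)
    by_id = {g.gene_id: g for g in genes}
    missing = family - set(by_id)
    if missing:
        raise ValueError(f"family id(s) absent from gene set: {sorted(missing)}")
    members = [by_id[i] for i in sorted(family)]
    pairs: set[tuple[str, str]] = set()
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if criteria.require_same_chromosome and a.chromosome != b.chromosome:
                continue
            if a.chromosome == b.chromosome:
                if abs(a.rank - b.rank) - 1 > criteria.max_intervening_genes:
                    continue
            if abs(a.start - b.start) > criteria.max_distance_bp:
                continue
            pairs.add(tuple(sorted((a.gene_id, b.gene_id))))
    return sorted(pairs)


def chromosome_distribution(
    genes: Sequence[GeneModel], family_ids: Iterable[str] | None = None
) -> list[tuple[str, int, float]]:
    """(chromosome, gene count, percent of family) rows, sorted by name.

    Percentages are over all counted genes, rounded half-away-from-zero to
    two decimals.
    """
    family = set(family_ids) if family_ids is not None else None
    counts: dict[str, int] = {}
    total = 0
    for g in genes:
        if family is not None and g.gene_id not in family:
            continue
        counts[g.chromosome] = counts.get(g.chromosome, 0) + 1
        total += 1
    if total == 0:
        raise ValueError("no genes to tabulate")
    return [(c, n, percent(n, total)) for c, n in sorted(counts.items())]


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

def codon_align(
    cds_a: CodingSequence,
    cds_b: CodingSequence,
    protein_alignment: tuple[str, str],
) -> tuple[str, str]:
    """Expand a pairwise protein alignment to a codon alignment.

    Each protein column becomes a codon column; protein gaps become codon
    gaps. The ungapped rows must equal the CDS translations (trailing stop
    codons are ignored).
    """
    row_a, row_b = protein_alignment
    if len(row_a) != len(row_b):
        raise ValueError("protein alignment rows must have equal length")
    out = []
    for cds, row in ((cds_a, row_a), (cds_b, row_b)):
        prot = translate_cds(cds)
        if row.replace(GAP, "") != prot:
            for k, (x, y) in enumerate(zip(row.replace(GAP, ""), prot)):
                if x != y:
                    raise ValueError(
                        f"{cds.gene_id}: protein alignment row disagrees with "
                        f"CDS translation at residue {k + 1} ({x!r} vs {y!r})"
                    )
            raise ValueError(
                f"{cds.gene_id}: protein alignment row length "
                f"{len(row.replace(GAP, ''))} != translation length {len(prot)}"
            )
        codons = iter(
            cds.sequence[i : i + 3] for i in range(0, 3 * len(prot), 3)
        )
        out.append(
            "".join("---" if c == GAP else next(codons) for c in row)
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def _is_stop(codon: str) -> bool:
    return GENETIC_CODE[codon] == "*"


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; each of the nine
    single-base mutations weighs 1/3, stop-creating mutations excluded."""
    aa = GENETIC_CODE[codon]
    s = n = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _is_stop(mutant):
                continue
            if GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over minimal mutational pathways avoiding stop codons."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(exclude_stops: bool) -> list[tuple[int, int]]:
        results = []
        for order in permutations(diff_pos):
            cur = c1
            sd = nd = 0
            ok = True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if exclude_stops and _is_stop(nxt):
                    ok = False
                    break
                if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                results.append((sd, nd))
        return results

    paths = walk(exclude_stops=True)
    if not paths:
        paths = walk(exclude_stops=False)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """d = -(3/4) ln(1 - (4/3) p); None when p >= 3/4 (saturation)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass(frozen=True)
class NGResult:
    ka: float | None
    ks: float | None
    pn: float
    ps: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons: int

    @property
    def ka_ks(self) -> float | None:
        if self.ka is None or self.ks is None or self.ks <= 0.0:
            return None
        return self.ka / self.ks


def nei_gojobori(seq_a: str, seq_b: str) -> NGResult:
    """NG86 Ka/Ks on an aligned codon pair (equal-length nt strings, length a
    multiple of 3). Codon columns containing a gap are skipped; remaining
    codons must be canonical and non-stop."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned codon sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("aligned length must be a multiple of 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    s_sites = n_sites = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if GAP in ca or GAP in cb:
            continue
        for c in (ca, cb):
            if any(b not in _BASES for b in c):
                raise ValueError(f"non-canonical codon {c!r} at nt {i + 1}")
            if _is_stop(c):
                raise ValueError(f"stop codon {c!r} at nt {i + 1}")
        n_codons += 1
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        d_s, d_n = _pathway_diffs(ca, cb)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise ValueError("no comparable (gap-free) codon columns")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return NGResult(
        ka=jukes_cantor(pn),
        ks=jukes_cantor(ps),
        pn=pn,
        ps=ps,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        n_codons=n_codons,
    )


# ---------------------------------------------------------------------------
# Selection label & dating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionParams:
    """Clock rate in substitutions/site/year (default: the dicot rate)."""

    lambda_rate: float = 1.5e-8

    def __post_init__(self) -> None:
        if self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be positive")


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    ka: float | None
    ks: float | None
    ka_ks: float | None
    divergence_time_mya: float | None
    selection_label: str

    def __post_init__(self) -> None:
        if (self.ka_ks is not None) != (
            self.ka is not None and self.ks is not None and self.ks > 0
        ):
            raise ValueError("ka_ks defined iff ka and ks defined and ks > 0")
        if (self.divergence_time_mya is not None) != (self.ks is not None):
            raise ValueError("divergence time defined iff ks defined")


def selection_label(
    ka_ks: float | None, neutral_band: tuple[float, float] = (0.95, 1.05)
) -> str:
    """purifying / neutral / positive by the neutral band; undetermined when
    the ratio is undefined."""
    low, high = neutral_band
    if low >= high:
        raise ValueError("neutral band must satisfy low < high")
    if ka_ks is None:
        return "undetermined"
    if ka_ks < low:
        return "purifying"
    if ka_ks > high:
        return "positive"
    return "neutral"


def divergence_time(ks: float, params: EvolutionParams | None = None) -> float:
    """T = ks / (2 * lambda) / 1e6 Mya (ks = 0.03 -> 1.0 Mya at the default
    dicot rate)."""
    if ks < 0:
        raise ValueError("ks must be non-negative")
    params = params or EvolutionParams()
    return ks / (2.0 * params.lambda_rate) / 1.0e6


def analyze_pair(
    gene_a: str,
    gene_b: str,
    aligned_codons: tuple[str, str],
    params: EvolutionParams | None = None,
    neutral_band: tuple[float, float] = (0.95, 1.05),
) -> DuplicatePair:
    """Full per-pair record: NG86 rates, selection label, divergence time."""
    ng = nei_gojobori(*aligned_codons)
    ratio = ng.ka_ks
    return DuplicatePair(
        gene_a=gene_a,
        gene_b=gene_b,
        ka=ng.ka,
        ks=ng.ks,
        ka_ks=ratio,
        divergence_time_mya=(
            divergence_time(ng.ks, params) if ng.ks is not None else None
        ),
        selection_label=selection_label(ratio, neutral_band),
    )


def write_pairs_tsv(pairs: Iterable[DuplicatePair], path: str | Path) -> None:
    def fmt(x: float | None, nd: int = 4) -> str:
        return "NA" if x is None else f"{x:.{nd}f}"

    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tka\tks\tka_ks\tdivergence_time_mya\tselection\n")
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{fmt(p.ka)}\t{fmt(p.ks)}\t"
                f"{fmt(p.ka_ks)}\t{fmt(p.divergence_time_mya, 2)}\t"
                f"{p.selection_label}\n"
            )
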