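"""Synthetic inputs with planted ground truth for every pipeline stage.

Everything is generated from a single integer seed and is byte-identical
across runs: protein families carrying one planted 61-residue domain each
(satisfying an assigned DNA-binding category's residue rules), back-translated
coding sequences, chromosome maps with planted tandem clusters, FPKM matrices
realizing planted tissue/treatment archetypes, and promoters with planted
motif occurrences (incidental matches are scrubbed so planted counts are
exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from famchar._util import GAP
from famchar.binding_rules import BindingCategory
from famchar.promoter_scan import IUPAC, MotifDef, reverse_complement
from famchar.residue_frame import AlignedDomain, ReferenceFrame, default_frame
from famchar.seq_model import (
    GENETIC_CODE,
    CodingSequence,
    GeneModel,
    ProteinRecord,
    assign_ranks,
    write_fasta,
    write_gene_models,
)

__all__ = [
    "CONSENSUS_DOMAIN",
    "FamilySpec",
    "FamilyBundle",
    "default_family_spec",
    "default_seed_alignment",
    "generate_family",
    "evolve_codon_pair",
    "domains_with_column_counts",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: 61-residue domain consensus used as the planting scaffold. The 23
#: family-conserved residues sit at their frame positions (H8, A11, E12, R13,
#: R15, R16; I19, N20, R22, L26, L29, V30, P31; K44, D45; A48, S49, L51, A54,
#: I55, Y57, K59, L61) and the basic region carries exactly six R/K/H.
CONSENSUS_DOMAIN = (
    "ANQRKSTHNMAERLRRE"  # basic      1-17
    "IINDRIKELQELVP"     # helix1    18-31
    "GSDQTNGASEGSKD"     # loop      32-45
    "INASELFEAIEYIKFL"   # helix2    46-61
)

# Frame positions (1-based) where random substitutions never touch the
# classification rules (outside the basic region) nor the 23 consensus
# residues.
_NOISE_POSITIONS = (
    18, 21, 23, 24, 25, 27, 28,
    32, 33, 34, 35, 36, 37, 38, 39, 40, 41, 42, 43,
    46, 47, 50, 52, 53, 56, 58, 60,
)

# Residue edits (frame position -> letter) planting each category.
_CATEGORY_EDITS: dict[BindingCategory, dict[int, str]] = {
    BindingCategory.G_BOX: {},
    # Break the G-box position 8 while restoring the sixth basic residue at
    # a rule-free basic-region position.
    BindingCategory.E_BOX_NON_G: {8: "S", 6: "K"},
    BindingCategory.NON_E_BOX: {12: "A"},
    # Strip the basic region down to two basic residues (R15, R16).
    BindingCategory.NON_DNA: {4: "T", 5: "S", 8: "L", 13: "M"},
}

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in GENETIC_CODE.items():
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()

_TISSUES = ("bud", "fruit", "leaf", "stem", "root")
_TREATMENT_CONDITIONS = ("control_25C", "chill_4C_8h", "chill_4C_5d", "freeze_5C_1h")


@dataclass(frozen=True)
class FamilySpec:
    """Shape of a synthetic family cohort."""

    n_genes: int = 95
    category_counts: Mapping[BindingCategory, int] = field(
        default_factory=lambda: {
            BindingCategory.G_BOX: 24,
            BindingCategory.E_BOX_NON_G: 13,
            BindingCategory.NON_E_BOX: 3,
            BindingCategory.NON_DNA: 55,
        }
    )
    domain_frame: ReferenceFrame = field(default_factory=default_frame)
    n_chromosomes: int = 8
    n_scaffolds: int = 6
    n_tandem_clusters: int = 9
    chrom_counts: Mapping[str, int] | None = None
    tissue_counts: Mapping[str, int] | None = None
    n_screen_up: int = 6
    n_screen_down: int = 4
    n_effective: int = 62
    noise_sigma: float = 0.2
    treatment_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.category_counts.values()) != self.n_genes:
            raise ValueError("category counts must sum to n_genes")
        if any(v < 0 for v in self.category_counts.values()):
            raise ValueError("category counts must be non-negative")
        if 2 * self.n_tandem_clusters > self.n_genes:
            raise ValueError("more tandem-cluster genes than genes")
        if self.n_screen_up + self.n_screen_down > self.n_effective:
            raise ValueError("screen genes must be a subset of effective genes")
        if self.n_effective > self.n_genes:
            raise ValueError("n_effective exceeds n_genes")


def default_family_spec(seed: int = 0) -> FamilySpec:
    return FamilySpec(seed=seed)


# Paper-shaped defaults for the 95-gene cohort: 78 genes on 8 chromosomes
# (max 18 on chr2, min 2 on chr3) and 17 on scaffolds.
_CHROM_COUNTS_95 = {
    "chr1": 12, "chr2": 18, "chr3": 2, "chr4": 10,
    "chr5": 11, "chr6": 10, "chr7": 8, "chr8": 7,
    "scaffold_1": 3, "scaffold_2": 3, "scaffold_3": 3,
    "scaffold_4": 3, "scaffold_5": 3, "scaffold_6": 2,
}
# Tandem clusters per sequence for the default map (paper: chromosomes 1, 5,
# 6, 7 and scaffolds, most on chromosome 6).
_TANDEM_PLACEMENT_95 = {"chr1": 1, "chr5": 2, "chr6": 3, "chr7": 2, "scaffold_1": 1}

_TISSUE_COUNTS_95 = {"all": 53, "none": 2, "single:fruit": 2, "single:root": 7}


def _resolved_chrom_counts(spec: FamilySpec) -> dict[str, int]:
    if spec.chrom_counts is not None:
        counts = dict(spec.chrom_counts)
    elif spec.n_genes == 95 and spec.n_chromosomes == 8 and spec.n_scaffolds == 6:
        counts = dict(_CHROM_COUNTS_95)
    else:
        names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)] + [
            f"scaffold_{i + 1}" for i in range(spec.n_scaffolds)
        ]
        counts = {name: 0 for name in names}
        for i in range(spec.n_genes):
            counts[names[i % len(names)]] += 1
        counts = {k: v for k, v in counts.items() if v > 0}
    if sum(counts.values()) != spec.n_genes:
        raise ValueError("chromosome counts must sum to n_genes")
    return counts


def _resolved_tandem_placement(
    spec: FamilySpec, chrom_counts: dict[str, int]
) -> dict[str, int]:
    if spec.n_genes == 95 and chrom_counts == _CHROM_COUNTS_95 and (
        spec.n_tandem_clusters == 9
    ):
        return dict(_TANDEM_PLACEMENT_95)
    placement: dict[str, int] = {}
    remaining = spec.n_tandem_clusters
    capacity = {c: n // 2 for c, n in chrom_counts.items()}
    for chrom in sorted(chrom_counts):
        if remaining == 0:
            break
        take = min(capacity[chrom], remaining)
        if take:
            placement[chrom] = take
            remaining -= take
    if remaining:
        raise ValueError("cannot place all tandem clusters on the map")
    return placement


def _resolved_tissue_counts(spec: FamilySpec) -> dict[str, int]:
    if spec.tissue_counts is not None:
        counts = dict(spec.tissue_counts)
    elif spec.n_genes == 95:
        counts = dict(_TISSUE_COUNTS_95)
    else:
        n = spec.n_genes
        counts = {
            "all": max(1, round(n * 53 / 95)),
            "none": min(2, max(0, n - 2)),
            "single:fruit": 2 if n >= 20 else 0,
            "single:root": 7 if n >= 20 else 0,
        }
    fixed = sum(counts.values())
    if fixed > spec.n_genes:
        raise ValueError("tissue counts exceed n_genes")
    return counts


# ---------------------------------------------------------------------------
# Proteins / CDS
# ---------------------------------------------------------------------------

def _planted_domain(category: BindingCategory, rng: np.random.Generator) -> str:
    residues = list(CONSENSUS_DOMAIN)
    for pos, letter in _CATEGORY_EDITS[category].items():
        residues[pos - 1] = letter
    if category is BindingCategory.G_BOX and rng.random() < 0.5:
        residues[7] = "K"  # His/Lys-8 are equally valid G-box residues
    for pos in _NOISE_POSITIONS:
        if rng.random() < 0.15:
            residues[pos - 1] = ALPHABET[rng.integers(20)]
    return "".join(residues)


def _random_residues(n: int, rng: np.random.Generator) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=n))


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein
    ]
    codons.append("TAA")
    return "".join(codons)


def default_seed_alignment(
    n_rows: int = 30, mutation_rate: float = 0.1, seed: int = 0
) -> list[str]:
    """Gapless seed alignment for PSSM construction: the consensus scaffold
    with independent random substitutions."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_rows):
        chars = list(CONSENSUS_DOMAIN)
        for i in range(len(chars)):
            if rng.random() < mutation_rate:
                chars[i] = ALPHABET[rng.integers(20)]
        rows.append("".join(chars))
    return rows


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def _naive_matches(seq: str, pattern: str) -> list[int]:
    """0-based positions where the IUPAC pattern matches (independent of the
    scanner module's regex machinery)."""
    out = []
    for p in range(len(seq) - len(pattern) + 1):
        if all(seq[p + i] in IUPAC[c] for i, c in enumerate(pattern.upper())):
            out.append(p)
    return out


def _plant_promoter(
    length: int,
    plants: Sequence[tuple[MotifDef, int]],  # (motif, 0-based position)
    motifs: Sequence[MotifDef],
    rng: np.random.Generator,
) -> str:
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    planted_windows: list[tuple[int, int]] = []
    allowed: set[tuple[str, str, int]] = set()
    for motif, pos in plants:
        instance = "".join(
            c if c in "ACGT" else IUPAC[c][rng.integers(len(IUPAC[c]))]
            for c in motif.pattern.upper()
        )
        seq[pos : pos + len(instance)] = list(instance)
        planted_windows.append((pos, pos + len(instance)))
        allowed.add((motif.name, "+", pos))
        rc = reverse_complement(motif.pattern)
        # A planted instance of a palindromic pattern also matches the
        # reverse strand at the same window.
        if all(instance[i] in IUPAC[c] for i, c in enumerate(rc)):
            allowed.add((motif.name, "-", pos))

    def extra_hits() -> list[tuple[str, str, int, str]]:
        s = "".join(seq)
        found = []
        for motif in motifs:
            for strand, pat in (
                ("+", motif.pattern.upper()),
                ("-", reverse_complement(motif.pattern.upper())),
            ):
                for p in _naive_matches(s, pat):
                    if (motif.name, strand, p) not in allowed:
                        found.append((motif.name, strand, p, pat))
        return found

    for _ in range(400):
        extras = extra_hits()
        if not extras:
            break
        _, _, p, pat = extras[0]
        # Mutate a fixed-letter offset of the match lying outside every
        # planted window, to a base excluded by the pattern there.
        for offset, c in enumerate(pat):
            pos = p + offset
            if len(IUPAC[c]) == 4:
                continue
            if any(a <= pos < b for a, b in planted_windows):
                continue
            choices = [b for b in "ACGT" if b not in IUPAC[c]]
            seq[pos] = choices[rng.integers(len(choices))]
            break
        else:  # pragma: no cover - cannot happen with >=12 bp plant spacing
            raise RuntimeError("could not scrub incidental motif match")
    else:  # pragma: no cover
        raise RuntimeError("promoter scrubbing did not converge")
    return "".join(seq)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class FamilyBundle:
    spec: FamilySpec
    proteins: list[ProteinRecord]
    cds: list[CodingSequence]
    gene_models: list[GeneModel]
    seed_alignment: list[str]
    tissue_fpkm: pd.DataFrame
    treatment_fpkm: pd.DataFrame
    promoters: dict[str, str]
    motifs: list[MotifDef]
    truth: dict[str, pd.DataFrame]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.fa")
        write_fasta(self.cds, outdir / "cds.fa")
        write_gene_models(self.gene_models, outdir / "genes.tsv")
        with open(outdir / "seed_alignment.afa", "w") as fh:
            for i, row in enumerate(self.seed_alignment, start=1):
                fh.write(f">seed{i:02d}\n{row}\n")
        self.tissue_fpkm.to_csv(outdir / "fpkm_tissues.tsv", sep="\t",
                                index_label="gene_id")
        self.treatment_fpkm.to_csv(outdir / "fpkm_treatment.tsv", sep="\t",
                                   index_label="gene_id")
        with open(outdir / "promoters.fa", "w") as fh:
            for gid, seq in self.promoters.items():
                fh.write(f">{gid}\n{seq}\n")
        with open(outdir / "motifs.tsv", "w") as fh:
            fh.write("name\tpattern\tcategory\n")
            for m in self.motifs:
                fh.write(f"{m.name}\t{m.pattern}\t{m.category}\n")
        for name, df in self.truth.items():
            df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


def generate_family(spec: FamilySpec | None = None) -> FamilyBundle:
    """Generate the full synthetic cohort with its truth tables."""
    spec = spec or FamilySpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    gene_ids = [f"G{i + 1:03d}" for i in range(n)]

    # --- categories & proteins ------------------------------------------
    categories: list[BindingCategory] = []
    for cat in (
        BindingCategory.G_BOX,
        BindingCategory.E_BOX_NON_G,
        BindingCategory.NON_E_BOX,
        BindingCategory.NON_DNA,
    ):
        categories.extend([cat] * spec.category_counts.get(cat, 0))
    perm = rng.permutation(n)
    categories = [categories[i] for i in perm]

    proteins: list[ProteinRecord] = []
    cds_records: list[CodingSequence] = []
    cat_rows = []
    frame_len = spec.domain_frame.length
    for gid, cat in zip(gene_ids, categories):
        domain = _planted_domain(cat, rng)
        total_len = int(rng.integers(150, 351))
        max_start = total_len - frame_len
        start0 = int(rng.integers(0, max_start + 1))
        seq = (
            _random_residues(start0, rng)
            + domain
            + _random_residues(total_len - frame_len - start0, rng)
        )
        proteins.append(ProteinRecord(gid, seq))
        cds_records.append(CodingSequence(gid, _back_translate(seq, rng)))
        cat_rows.append(
            {
                "gene_id": gid,
                "category": cat.value,
                "domain_start": start0 + 1,
                "domain_end": start0 + frame_len,
                "domain_sequence": domain,
            }
        )
    truth_categories = pd.DataFrame(cat_rows)

    # --- gene map with planted tandem clusters --------------------------
    chrom_counts = _resolved_chrom_counts(spec)
    placement = _resolved_tandem_placement(spec, chrom_counts)
    models: list[GeneModel] = []
    pair_rows = []
    cursor = 0
    for chrom in sorted(chrom_counts):
        k = chrom_counts[chrom]
        ids_here = gene_ids[cursor : cursor + k]
        cursor += k
        n_pairs = placement.get(chrom, 0)
        pos = 150_000 + int(rng.integers(0, 50_000))
        i = 0
        while i < k:
            gid = ids_here[i]
            length = int(rng.integers(1_500, 3_001))
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(GeneModel(gid, chrom, pos, pos + length, strand))
            in_cluster = i % 2 == 0 and (i // 2) < n_pairs and i + 1 < k
            if in_cluster:
                partner = ids_here[i + 1]
                ppos = pos + length + int(rng.integers(5_000, 20_000))
                plen = int(rng.integers(1_500, 3_001))
                pstrand = "+" if rng.random() < 0.5 else "-"
                models.append(GeneModel(partner, chrom, ppos, ppos + plen, pstrand))
                pair_rows.append(
                    {"gene_a": gid, "gene_b": partner, "chromosome": chrom}
                )
                pos = ppos + plen + 800_000 + int(rng.integers(0, 100_000))
                i += 2
            else:
                pos = pos + length + 800_000 + int(rng.integers(0, 100_000))
                i += 1
    models = assign_ranks(models)
    truth_pairs = pd.DataFrame(
        pair_rows, columns=["gene_a", "gene_b", "chromosome"]
    )

    # --- tissue FPKM matrix ---------------------------------------------
    tissue_counts = _resolved_tissue_counts(spec)
    roles: list[str] = []
    for role, count in tissue_counts.items():
        roles.extend([role] * count)
    roles.extend(["partial"] * (n - len(roles)))
    roles = [roles[i] for i in rng.permutation(n)]

    def _noisy(mean: float, sigma: float) -> float:
        return float(mean * np.exp(sigma * rng.standard_normal()))

    tissue_rows = []
    tissue_truth_rows = []
    for gid, role in zip(gene_ids, roles):
        if role == "all":
            on = set(_TISSUES)
        elif role == "none":
            on = set()
        elif role.startswith("single:"):
            on = {role.split(":", 1)[1]}
        else:
            k_on = int(rng.integers(3, 5))
            on = set(rng.choice(_TISSUES, size=k_on, replace=False))
            role = "partial"
        row = {}
        for t in _TISSUES:
            mean = float(rng.uniform(8.0, 40.0)) if t in on else 0.1
            row[t] = _noisy(mean, spec.noise_sigma)
        tissue_rows.append(row)
        tissue_truth_rows.append(
            {
                "gene_id": gid,
                "role": role,
                "n_tissues": len(on),
                "tissues": ",".join(sorted(on)),
            }
        )
    tissue_fpkm = pd.DataFrame(tissue_rows, index=gene_ids)[list(_TISSUES)]
    truth_tissue = pd.DataFrame(tissue_truth_rows)

    # --- treatment FPKM matrix with planted screen ----------------------
    screen_roles = (
        ["up"] * spec.n_screen_up
        + ["down"] * spec.n_screen_down
        + ["flat"] * (spec.n_effective - spec.n_screen_up - spec.n_screen_down)
        + ["silent"] * (n - spec.n_effective)
    )
    screen_roles = [screen_roles[i] for i in rng.permutation(n)]
    chill = [c for c in _TREATMENT_CONDITIONS if c.startswith("chill")]
    sig = spec.treatment_sigma
    treat_rows = []
    screen_rows = []
    for gid, role in zip(gene_ids, screen_roles):
        row = {}
        if role == "silent":
            for c in _TREATMENT_CONDITIONS:
                row[c] = _noisy(0.05, sig)
        elif role == "flat":
            base = float(rng.uniform(5.0, 30.0))
            for c in _TREATMENT_CONDITIONS:
                row[c] = _noisy(base, sig)
        elif role == "up":
            base = float(rng.uniform(3.0, 6.0))
            fold = float(rng.uniform(2.8, 4.2))
            for c in _TREATMENT_CONDITIONS:
                mean = base * fold if c in chill else base
                row[c] = _noisy(mean, sig)
        else:  # down
            base = float(rng.uniform(10.0, 30.0))
            fold = float(rng.uniform(2.8, 4.2))
            for c in _TREATMENT_CONDITIONS:
                mean = base / fold if c in chill else base
                row[c] = _noisy(mean, sig)
        treat_rows.append(row)
        screen_rows.append({"gene_id": gid, "role": role})
    treatment_fpkm = pd.DataFrame(treat_rows, index=gene_ids)[
        list(_TREATMENT_CONDITIONS)
    ]
    truth_screen = pd.DataFrame(screen_rows)

    # --- promoters with planted motifs ----------------------------------
    motifs = [
        MotifDef("E-box", "CANNTG", "other"),
        MotifDef("LTR", "CCGAAA", "stress"),
    ]
    promoter_len = 1500
    slots = np.arange(0, promoter_len - 10, 15)
    promoters: dict[str, str] = {}
    motif_rows = []
    for gid in gene_ids:
        n_ebox = int(rng.integers(0, 4))
        n_ltr = int(rng.integers(0, 3))
        chosen = rng.choice(slots, size=n_ebox + n_ltr, replace=False)
        plants = [(motifs[0], int(p)) for p in chosen[:n_ebox]] + [
            (motifs[1], int(p)) for p in chosen[n_ebox:]
        ]
        promoters[gid] = _plant_promoter(promoter_len, plants, motifs, rng)
        motif_rows.append(
            {
                "gene_id": gid,
                "E-box_plus": n_ebox,
                "E-box_minus": n_ebox,  # palindromic pattern
                "LTR_plus": n_ltr,
                "LTR_minus": 0,
                "positions_ebox": ",".join(
                    str(int(p) + 1) for p in sorted(chosen[:n_ebox])
                ),
                "positions_ltr": ",".join(
                    str(int(p) + 1) for p in sorted(chosen[n_ebox:])
                ),
            }
        )
    truth_motifs = pd.DataFrame(motif_rows)

    return FamilyBundle(
        spec=spec,
        proteins=proteins,
        cds=cds_records,
        gene_models=models,
        seed_alignment=default_seed_alignment(seed=spec.seed),
        tissue_fpkm=tissue_fpkm,
        treatment_fpkm=treatment_fpkm,
        promoters=promoters,
        motifs=motifs,
        truth={
            "categories": truth_categories,
            "tandem_pairs": truth_pairs,
            "tissue": truth_tissue,
            "screen": truth_screen,
            "motifs": truth_motifs,
        },
    )


# ---------------------------------------------------------------------------
# Codon-pair evolution
# ---------------------------------------------------------------------------

def evolve_codon_pair(
    n_codons: int,
    t_sub: float,
    omega: float,
    seed: int,
    gene_a: str = "anc",
    gene_b: str = "der",
) -> tuple[CodingSequence, CodingSequence, dict]:
    """Simulate a codon-sequence pair diverged at a planted dN/dS.

    An ancestor is drawn codon-wise over the 61 sense codons; a Poisson
    number of substitutions (expectation ``t_sub`` per nucleotide site) is
    applied to one lineage. Proposals are uniform single-base changes;
    stop-creating changes are rejected outright, synonymous changes accepted
    at relative rate min(1, 1/omega) and nonsynonymous at min(1, omega).
    Truth records the realized accepted counts.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if omega <= 0 or t_sub < 0:
        raise ValueError("omega must be > 0 and t_sub >= 0")
    rng = np.random.default_rng(seed)
    codons = [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    ]
    ancestor = "".join(codons)
    n_events = int(rng.poisson(t_sub * 3 * n_codons))
    seq = list(ancestor)
    p_syn = min(1.0, 1.0 / omega)
    p_non = min(1.0, omega)
    n_syn = n_nonsyn = 0
    accepted = 0
    while accepted < n_events:
        site = int(rng.integers(0, 3 * n_codons))
        ci = site // 3
        offset = site % 3
        old_codon = "".join(seq[3 * ci : 3 * ci + 3])
        base = seq[site]
        new_base = "ACGT".replace(base, "")[rng.integers(3)]
        new_codon = (
            old_codon[:offset] + new_base + old_codon[offset + 1 :]
        )
        if new_codon in _STOP_CODONS:
            continue
        synonymous = GENETIC_CODE[new_codon] == GENETIC_CODE[old_codon]
        p_accept = p_syn if synonymous else p_non
        if p_accept < 1.0 and rng.random() >= p_accept:
            continue
        seq[site] = new_base
        accepted += 1
        if synonymous:
            n_syn += 1
        else:
            n_nonsyn += 1
    truth = {
        "n_codons": n_codons,
        "t_sub": t_sub,
        "omega": omega,
        "n_events": n_events,
        "n_syn": n_syn,
        "n_nonsyn": n_nonsyn,
    }
    return (
        CodingSequence(gene_a, ancestor),
        CodingSequence(gene_b, "".join(seq)),
        truth,
    )


# ---------------------------------------------------------------------------
# Consensus-profile planting helper
# ---------------------------------------------------------------------------

def domains_with_column_counts(
    column_counts: Sequence[Mapping[str, int]],
    protein_prefix: str = "D",
) -> list[AlignedDomain]:
    """Build aligned domains whose per-column residue counts are exactly as
    specified (every column mapping must sum to the same row count; use the
    key ``"-"`` for gaps)."""
    totals = {sum(c.values()) for c in column_counts}
    if len(totals) != 1:
        raise ValueError("all columns must sum to the same number of rows")
    n_rows = totals.pop()
    columns = []
    for counts in column_counts:
        col = []
        for letter in sorted(counts):
            col.extend([letter] * counts[letter])
        columns.append(col)
    return [
        AlignedDomain(
            f"{protein_prefix}{r + 1:03d}",
            "".join(col[r] for col in columns),
        )
        for r in range(n_rows)
    ]
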