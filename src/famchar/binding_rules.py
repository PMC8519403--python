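"""Residue-rule classification of aligned domains into DNA-binding categories
and category summary tables.

Decision tree (positions are frame coordinates):

1. fewer than ``min_basic_count`` basic residues (R/K/H by default) in the
   basic region -> NON_DNA;
2. else any E-box-required position failing its residue set -> NON_E_BOX;
3. else all G-box-required positions passing -> G_BOX;
4. else -> E_BOX_NON_G.

A gap at a rule position counts as failing that rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from famchar._util import GAP, percent
from famchar.residue_frame import AlignedDomain, ReferenceFrame, default_frame

__all__ = [
    "BindingCategory",
    "RuleConfig",
    "CategorySummary",
    "classify_binding",
    "classification_details",
    "summarize_categories",
    "write_summary_tsv",
]


class BindingCategory(str, Enum):
    G_BOX = "G-box"
    E_BOX_NON_G = "Non-G-box"
    NON_E_BOX = "Non-E-box"
    NON_DNA = "Non-DNA-binding"

    @property
    def binds_dna(self) -> bool:
        return self is not BindingCategory.NON_DNA


@dataclass(frozen=True)
class RuleConfig:
    """Configurable residue rules; defaults follow the published convention
    for plant bHLH basic regions."""

    basic_region: str = "basic"
    basic_letters: frozenset[str] = frozenset({"R", "K", "H"})
    min_basic_count: int = 6
    ebox_required: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: {12: frozenset({"E"}), 15: frozenset({"R"})}
    )
    gbox_required: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: {
            8: frozenset({"H", "K"}),
            12: frozenset({"E"}),
            16: frozenset({"R"}),
        }
    )

    def __post_init__(self) -> None:
        if self.min_basic_count < 1:
            raise ValueError("min_basic_count must be >= 1")
        if not self.basic_letters:
            raise ValueError("basic_letters must be non-empty")

    def validate_against(self, frame: ReferenceFrame) -> None:
        for pos in list(self.ebox_required) + list(self.gbox_required):
            if not (1 <= pos <= frame.length):
                raise ValueError(f"rule position {pos} outside frame 1..{frame.length}")
        frame.region_span(self.basic_region)


def _basic_count(
    domain: AlignedDomain, rules: RuleConfig, frame: ReferenceFrame
) -> int:
    return sum(
        1
        for pos in frame.positions(rules.basic_region)
        if domain.residue_at(pos) in rules.basic_letters
    )


def _passes(domain: AlignedDomain, required: Mapping[int, frozenset[str]]) -> bool:
    for pos, allowed in required.items():
        res = domain.residue_at(pos)
        if res == GAP or res not in allowed:
            return False
    return True


def classify_binding(
    domain: AlignedDomain,
    rules: RuleConfig | None = None,
    frame: ReferenceFrame | None = None,
) -> BindingCategory:
    """Assign exactly one DNA-binding category to an aligned domain."""
    rules = rules or RuleConfig()
    frame = frame or default_frame()
    rules.validate_against(frame)
    if len(domain) != frame.length:
        raise ValueError(
            f"domain length {len(domain)} does not match frame length {frame.length}"
        )
    if _basic_count(domain, rules, frame) < rules.min_basic_count:
        return BindingCategory.NON_DNA
    if not _passes(domain, rules.ebox_required):
        return BindingCategory.NON_E_BOX
    if _passes(domain, rules.gbox_required):
        return BindingCategory.G_BOX
    return BindingCategory.E_BOX_NON_G


def classification_details(
    domain: AlignedDomain,
    rules: RuleConfig | None = None,
    frame: ReferenceFrame | None = None,
) -> dict:
    """Per-domain rule outcomes for export alongside the category."""
    rules = rules or RuleConfig()
    frame = frame or default_frame()
    return {
        "protein_id": domain.protein_id,
        "basic_count": _basic_count(domain, rules, frame),
        "ebox_ok": _passes(domain, rules.ebox_required),
        "gbox_ok": _passes(domain, rules.gbox_required),
        "category": classify_binding(domain, rules, frame).value,
    }


@dataclass(frozen=True)
class CategorySummary:
    """Counts and percentages per category plus the DNA-binding total."""

    counts: dict[BindingCategory, int]
    percentages: dict[BindingCategory, float]
    dna_binding_count: int
    dna_binding_percentage: float
    n_total: int


def summarize_categories(
    labels: Sequence[BindingCategory] | Mapping[BindingCategory, int],
) -> CategorySummary:
    """Tabulate counts and percentages (2 decimals, half-away-from-zero).

    Accepts either a sequence of labels or a precomputed count mapping.
    """
    if isinstance(labels, Mapping):
        counts = {cat: int(labels.get(cat, 0)) for cat in BindingCategory}
        if any(v < 0 for v in counts.values()):
            raise ValueError("category counts must be non-negative")
    else:
        tally = Counter(labels)
        counts = {cat: tally.get(cat, 0) for cat in BindingCategory}
    n_total = sum(counts.values())
    if n_total == 0:
        raise ValueError("cannot summarize an empty label collection")
    percentages = {cat: percent(c, n_total) for cat, c in counts.items()}
    dna_count = sum(c for cat, c in counts.items() if cat.binds_dna)
    return CategorySummary(
        counts=counts,
        percentages=percentages,
        dna_binding_count=dna_count,
        dna_binding_percentage=percent(dna_count, n_total),
        n_total=n_total,
    )


def write_summary_tsv(summary: CategorySummary, path: str | Path) -> None:
    rows = [
        ("G-box", summary.counts[BindingCategory.G_BOX],
         summary.percentages[BindingCategory.G_BOX]),
        ("Non-G-box", summary.counts[BindingCategory.E_BOX_NON_G],
         summary.percentages[BindingCategory.E_BOX_NON_G]),
        ("Non-E-box", summary.counts[BindingCategory.NON_E_BOX],
         summary.percentages[BindingCategory.NON_E_BOX]),
        ("DNA-binding total", summary.dna_binding_count,
         summary.dna_binding_percentage),
        ("Non-DNA-binding", summary.counts[BindingCategory.NON_DNA],
         summary.percentages[BindingCategory.NON_DNA]),
    ]
    with open(path, "w") as fh:
        fh.write("category\tcount\tpercentage\n")
        for name, count, pct in rows:
            fh.write(f"{name}\t{count}\t{pct:.2f}\n")
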