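"""Map located domains onto a fixed 61-position reference frame and compute
per-position consensus statistics.

The frame is partitioned into four contiguous regions (basic / helix1 / loop /
helix2). Length variation between a domain hit and the frame is absorbed
entirely inside the loop region: shorter hits receive gaps there, longer hits
have loop residues trimmed. Placement of gaps/trims is the best-scoring fit
against an anchor profile (exhaustive over loop placements), with
lexicographically-first tie-breaking for determinism.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from famchar._util import CANONICAL_AA, GAP
from famchar.domain_locator import DomainHit, Pssm

__all__ = [
    "ReferenceFrame",
    "AlignedDomain",
    "ConsensusProfile",
    "default_frame",
    "align_to_frame",
    "consensus",
    "conserved_calls",
    "write_aligned_fasta",
    "write_consensus_tsv",
]

_REGION_NAMES = ("basic", "helix1", "loop", "helix2")


@dataclass(frozen=True)
class ReferenceFrame:
    """A fixed-length coordinate frame partitioned into the four domain
    regions. Positions are 1-based inclusive."""

    length: int = 61
    regions: tuple[tuple[str, int, int], ...] = (
        ("basic", 1, 17),
        ("helix1", 18, 31),
        ("loop", 32, 45),
        ("helix2", 46, 61),
    )

    def __post_init__(self) -> None:
        names = tuple(name for name, _, _ in self.regions)
        if names != _REGION_NAMES:
            raise ValueError(f"regions must be exactly {_REGION_NAMES} in order")
        expected = 1
        for name, start, end in self.regions:
            if start != expected or end < start:
                raise ValueError(
                    f"region {name!r} [{start}, {end}] breaks contiguous cover"
                )
            expected = end + 1
        if expected != self.length + 1:
            raise ValueError("regions must cover 1..length exactly once")

    def region_of(self, position: int) -> str:
        for name, start, end in self.regions:
            if start <= position <= end:
                return name
        raise ValueError(f"position {position} outside frame 1..{self.length}")

    def region_span(self, name: str) -> tuple[int, int]:
        for rname, start, end in self.regions:
            if rname == name:
                return start, end
        raise ValueError(f"unknown region {name!r}")

    def positions(self, name: str) -> range:
        start, end = self.region_span(name)
        return range(start, end + 1)


def default_frame() -> ReferenceFrame:
    return ReferenceFrame()


@dataclass(frozen=True)
class AlignedDomain:
    """A domain laid out on the reference frame; ``residues`` has exactly the
    frame length, gaps as ``-``."""

    protein_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("aligned domain must be non-empty")
        bad = set(self.residues) - CANONICAL_AA - {GAP, "X"}
        if bad:
            raise ValueError(f"illegal residue(s) {sorted(bad)} in aligned domain")
        if set(self.residues) <= {GAP}:
            raise ValueError("aligned domain must contain at least one residue")

    def residue_at(self, position: int) -> str:
        """Residue at 1-based frame position."""
        return self.residues[position - 1]

    def __len__(self) -> int:
        return len(self.residues)


def align_to_frame(
    hit: DomainHit,
    frame: ReferenceFrame | None = None,
    anchor_profile: Pssm | None = None,
    loop_slack: int = 6,
) -> AlignedDomain:
    """Fit a domain hit to the reference frame.

    Non-loop residues map position-to-position; the hit's central segment is
    placed into the loop columns, padded with gaps (shorter) or with surplus
    residues dropped (longer). Among all order-preserving placements the one
    maximizing the anchor-profile score of the loop columns is chosen.
    """
    frame = frame or default_frame()
    loop_start, loop_end = frame.region_span("loop")
    n_loop = loop_end - loop_start + 1
    n_prefix = loop_start - 1
    n_suffix = frame.length - loop_end
    seq = hit.domain_sequence

    delta = len(seq) - frame.length
    if abs(delta) > loop_slack:
        raise ValueError(
            f"hit length {len(seq)} outside frame length {frame.length} "
            f"± {loop_slack}"
        )
    if anchor_profile is not None and anchor_profile.length != frame.length:
        raise ValueError("anchor profile length must equal frame length")

    prefix = seq[:n_prefix]
    suffix = seq[len(seq) - n_suffix :]
    middle = seq[n_prefix : len(seq) - n_suffix]
    m = len(middle)

    def loop_score(layout: str) -> float:
        if anchor_profile is None:
            return 0.0
        return sum(
            anchor_profile.score(loop_start + i, c) for i, c in enumerate(layout)
        )

    if m == n_loop:
        loop = middle
    elif m < n_loop:
        # Choose which loop columns carry residues; the rest are gaps.
        best_layout = None
        best_score = -float("inf")
        for cols in combinations(range(n_loop), m):
            layout_chars = [GAP] * n_loop
            for c, res in zip(cols, middle):
                layout_chars[c] = res
            layout = "".join(layout_chars)
            s = loop_score(layout)
            if s > best_score:
                best_score, best_layout = s, layout
        loop = best_layout if best_layout is not None else GAP * n_loop
    else:
        # Choose which residues to keep, order preserved.
        best_layout = None
        best_score = -float("inf")
        for keep in combinations(range(m), n_loop):
            layout = "".join(middle[i] for i in keep)
            s = loop_score(layout)
            if s > best_score:
                best_score, best_layout = s, layout
        loop = best_layout  # type: ignore[assignment]

    return AlignedDomain(protein_id=hit.protein_id, residues=prefix + loop + suffix)


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-position modal residue and consensus ratio over a domain set."""

    modal: tuple[str, ...]
    ratio: tuple[float, ...]
    n_sequences: int
    frame: ReferenceFrame = field(default_factory=default_frame)

    def __post_init__(self) -> None:
        if len(self.modal) != len(self.ratio):
            raise ValueError("modal and ratio must have equal length")
        if any(not (0.0 <= r <= 1.0) for r in self.ratio):
            raise ValueError("consensus ratios must lie in [0, 1]")

    @property
    def length(self) -> int:
        return len(self.modal)


def consensus(domains: Sequence[AlignedDomain]) -> ConsensusProfile:
    """Column-wise modal residue and consensus ratio over non-gap residues.

    Ties in the modal residue are broken alphabetically.
    """
    if not domains:
        raise ValueError("consensus of an empty domain collection")
    width = len(domains[0])
    if any(len(d) != width for d in domains):
        raise ValueError("all aligned domains must have the frame length")
    modal: list[str] = []
    ratio: list[float] = []
    for pos in range(width):
        counts = Counter(
            d.residues[pos] for d in domains if d.residues[pos] != GAP
        )
        counts.pop("X", None)
        if not counts:
            modal.append(GAP)
            ratio.append(0.0)
            continue
        top = max(counts.values())
        letter = min(a for a, c in counts.items() if c == top)
        modal.append(letter)
        ratio.append(top / sum(counts.values()))
    return ConsensusProfile(
        modal=tuple(modal), ratio=tuple(ratio), n_sequences=len(domains)
    )


def conserved_calls(
    profile: ConsensusProfile,
    conserved_threshold: float = 0.5,
    highly_threshold: float = 0.9,
) -> list[str]:
    """Per-position labels: ``highly_conserved`` if ratio > highly_threshold,
    ``conserved`` if ratio > conserved_threshold, else ``none``.

    Inequalities are strict (the ">50%" / ">90%" convention).
    """
    if not (0.0 < conserved_threshold <= 1.0 and 0.0 < highly_threshold <= 1.0):
        raise ValueError("thresholds must lie in (0, 1]")
    if conserved_threshold >= highly_threshold:
        raise ValueError("conserved_threshold must be below highly_threshold")
    labels = []
    for r in profile.ratio:
        if r > highly_threshold:
            labels.append("highly_conserved")
        elif r > conserved_threshold:
            labels.append("conserved")
        else:
            labels.append("none")
    return labels


def write_aligned_fasta(domains: Iterable[AlignedDomain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f">{d.protein_id}\n{d.residues}\n")


def write_consensus_tsv(
    profile: ConsensusProfile,
    path: str | Path,
    conserved_threshold: float = 0.5,
    highly_threshold: float = 0.9,
) -> None:
    labels = conserved_calls(profile, conserved_threshold, highly_threshold)
    with open(path, "w") as fh:
        fh.write("position\tregion\tmodal\tratio\tlabel\n")
        for i, (m, r, lab) in enumerate(zip(profile.modal, profile.ratio, labels)):
            pos = i + 1
            fh.write(f"{pos}\t{profile.frame.region_of(pos)}\t{m}\t{r:.4f}\t{lab}\n")
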