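"""MedDRA preferred-term groups and drug-event pair counting.

A Standardized-MedDRA-Query-like group is a named, ordered set of preferred
terms (PTs) representing one medical condition; the bundled default is a
ten-PT osteoporosis group.  :func:`count_pt_pairs` extracts, from a
deduplicated report collection, the sufficient statistics for every PT-level
2x2 contingency table of one drug, and :func:`aggregate_smq` rolls those up
to the group level.

Two group-level counting conventions exist.  The default is the PT-row sum
(a report contributing k member PTs counts k times), which matches how the
group total equals the column sum of its PT rows in published signal tables.
MedDRA-standard unique-case counting is available via ``unique_reports=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .ingest import IcsrReport, normalize_drug_name, normalize_pt

__all__ = [
    "SmqDefinition",
    "PairCounts",
    "SmqCounts",
    "load_smq",
    "default_osteoporosis_smq",
    "count_pt_pairs",
    "aggregate_smq",
]


@dataclass(frozen=True)
class SmqDefinition:
    """A named PT group; member PTs are normalized to lowercase, order kept."""

    name: str
    member_pts: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_pts:
            raise ValueError("SMQ definition must contain at least one PT")
        normalized = [normalize_pt(p) for p in self.member_pts]
        if len(set(normalized)) != len(normalized):
            dupes = sorted({p for p in normalized if normalized.count(p) > 1})
            raise ValueError(f"duplicate PTs after normalization: {dupes}")
        object.__setattr__(self, "member_pts", tuple(normalized))

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.member_pts)

    def __len__(self) -> int:
        return len(self.member_pts)


def load_smq(definition_file: str | Path, name: str | None = None) -> SmqDefinition:
    """Load a PT group from a plain-text file (one PT per line) or JSON array.

    An empty list is a fatal configuration error; PTs that collide after
    case normalization are rejected.
    """
    path = Path(definition_file)
    text = path.read_text(encoding="utf-8").strip()
    if path.suffix.lower() == ".json" or text.startswith("["):
        pts = json.loads(text)
        if not isinstance(pts, list):
            raise ValueError(f"{path}: JSON SMQ definition must be an array")
    else:
        pts = [line.strip() for line in text.splitlines()]
        pts = [p for p in pts if p and not p.startswith("#")]
    if not pts:
        raise ValueError(f"{path}: empty SMQ definition")
    return SmqDefinition(name=name or path.stem, member_pts=tuple(pts))


def default_osteoporosis_smq() -> SmqDefinition:
    """The bundled ten-PT osteoporosis group."""
    ref = resources.files("faersig").joinpath("data/osteoporosis_smq.txt")
    with resources.as_file(ref) as path:
        return load_smq(path, name="osteoporosis")


@dataclass(frozen=True)
class PairCounts:
    """Sufficient statistics for every member-PT 2x2 table of one drug.

    ``pt_a`` maps each member PT to a = number of reports with the drug as
    primary suspect and the PT among reactions.  ``event_totals`` counts the
    PT over all reports regardless of drug.  ``smq_a_unique`` /
    ``smq_event_total_unique`` are unique-report union counts for the
    MedDRA-standard group convention.
    """

    drug: str
    pt_a: Mapping[str, int]
    drug_total: int
    event_totals: Mapping[str, int]
    grand_total: int
    smq_a_unique: int = 0
    smq_event_total_unique: int = 0


@dataclass(frozen=True)
class SmqCounts:
    """Group-level counts, consistent with one of the two conventions."""

    drug: str
    a: int
    drug_total: int
    event_total: int
    grand_total: int


def count_pt_pairs(
    reports: Iterable[IcsrReport], drug_name: str, smq: SmqDefinition
) -> PairCounts:
    """Count drug-event pairs for each member PT over deduplicated reports.

    Counts are invariant to report ordering.
    """
    target = normalize_drug_name(drug_name)
    members = smq.member_set
    pt_a = {pt: 0 for pt in smq.member_pts}
    event_totals = {pt: 0 for pt in smq.member_pts}
    drug_total = 0
    grand_total = 0
    smq_a_unique = 0
    smq_event_unique = 0
    for r in reports:
        grand_total += 1
        hit_pts = r.reactions & members
        if hit_pts:
            smq_event_unique += 1
            for pt in hit_pts:
                event_totals[pt] += 1
        if r.has_primary_suspect(target):
            drug_total += 1
            if hit_pts:
                smq_a_unique += 1
                for pt in hit_pts:
                    pt_a[pt] += 1
    return PairCounts(
        drug=target,
        pt_a=pt_a,
        drug_total=drug_total,
        event_totals=event_totals,
        grand_total=grand_total,
        smq_a_unique=smq_a_unique,
        smq_event_total_unique=smq_event_unique,
    )


def aggregate_smq(pt_results: PairCounts, unique_reports: bool = False) -> SmqCounts:
    """Aggregate member-PT counts to the group level.

    Default is the PT-row-sum convention: group a equals the sum of member-PT
    a values (a report carrying k member PTs contributes k), with the
    background event total summed consistently.  ``unique_reports=True``
    switches to unique-case counting.
    """
    if unique_reports:
        a = pt_results.smq_a_unique
        event_total = pt_results.smq_event_total_unique
    else:
        a = sum(pt_results.pt_a.values())
        event_total = sum(pt_results.event_totals.values())
    return SmqCounts(
        drug=pt_results.drug,
        a=a,
        drug_total=pt_results.drug_total,
        event_total=event_total,
        grand_total=pt_results.grand_total,
    )
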