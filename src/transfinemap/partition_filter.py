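"""Index-SNP selection, LD-cluster partitioning and trans-ethnic filtering.

The "partition" half mirrors standard LD clumping: significant SNPs are
sorted by p-value and greedily accepted as index SNPs when they are in low
LD (r^2 below the independence threshold, default 0.9) with every index
accepted so far; every significant SNP is then binned with the index it is
in strongest LD with. The "filter" half builds, per ancestry group, the
union of proxy sets (r^2 above a per-group threshold, default 0.9 for
array/HapMap-density panels and 0.95 for sequencing-density panels) around
the retained index SNPs, and intersects them across groups: the intersection
is the fine-mapped candidate list, reported with Venn-style overlap counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ld_core
from .association import AssocResult
from .errors import DegenerateError, InputError
from .geno_io import GenotypeMatrix

__all__ = [
    "ClusterAssignment",
    "CandidateSet",
    "select_index_snps",
    "assign_clusters",
    "drop_clusters",
    "transethnic_filter",
]


@dataclass
class ClusterAssignment:
    """Mapping of significant SNPs to index-SNP LD clusters."""

    index_snps: list[str]
    assignment: dict[str, str]
    r2_to_index: dict[str, float]
    unassigned: list[str]

    def __post_init__(self) -> None:
        for idx in self.index_snps:
            if self.assignment.get(idx) != idx:
                raise InputError(f"index SNP {idx} must map to itself")
        bad = [s for s, i in self.assignment.items() if i not in self.index_snps]
        if bad:
            raise InputError(f"SNPs assigned to unknown index: {bad}")

    def bins(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {i: [] for i in self.index_snps}
        for s, i in sorted(self.assignment.items()):
            out[i].append(s)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"snp_id": s, "index": i, "r2": self.r2_to_index.get(s, np.nan)}
            for s, i in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows, columns=["snp_id", "index", "r2"])


@dataclass
class CandidateSet:
    """Per-group proxy sets, their intersection and Venn overlap counts."""

    per_group_sets: dict[str, set[str]]
    intersection: set[str]
    venn_counts: dict[str, int]

    def __post_init__(self) -> None:
        for g, s in self.per_group_sets.items():
            if not self.intersection <= s:
                raise InputError(f"intersection is not a subset of group {g}")
        union = set().union(*self.per_group_sets.values()) if self.per_group_sets else set()
        if sum(self.venn_counts.values()) != len(union):
            raise InputError("venn counts do not sum to the union size")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"membership": k, "count": v} for k, v in sorted(self.venn_counts.items())
        ]
        return pd.DataFrame(rows, columns=["membership", "count"])


def _r2_lookup(ld: pd.DataFrame, a: str, b: str) -> float:
    if a == b:
        return 1.0
    try:
        val = ld.at[a, b]
    except KeyError as exc:
        raise InputError(f"missing LD entry for pair ({a}, {b})") from exc
    if pd.isna(val):
        raise InputError(f"missing LD entry for pair ({a}, {b})")
    return float(val)


def select_index_snps(
    results: list[AssocResult],
    ld: pd.DataFrame,
    p_threshold: float = 0.05,
    r2_independence: float = 0.9,
    positions: dict[str, int] | None = None,
) -> list[str]:
    """Greedy LD clumping of association results into index SNPs.

    SNPs passing ``p_threshold`` are visited in order of ascending p (ties
    broken by smaller position, then lexicographic id); a SNP becomes a new
    index iff its r^2 to every accepted index is below ``r2_independence``.
    Returns an empty list (with a warning) when nothing is significant.
    """
    if not results:
        raise InputError("no association results supplied")
    positions = positions or {}
    candidates = sorted(
        (r for r in results if r.p < p_threshold),
        key=lambda r: (r.p, positions.get(r.snp_id, np.inf), r.snp_id),
    )
    if not candidates:
        warnings.warn(f"no SNP passes p < {p_threshold}; no index SNPs selected")
        return []
    indices: list[str] = []
    for r in candidates:
        if all(_r2_lookup(ld, r.snp_id, i) < r2_independence for i in indices):
            indices.append(r.snp_id)
    return indices


def assign_clusters(
    significant_snps: list[str],
    index_snps: list[str],
    ld: pd.DataFrame,
    r2_floor: float = 0.1,
    positions: dict[str, int] | None = None,
) -> ClusterAssignment:
    """Bin each significant SNP with the index it is in strongest LD with.

    Ties go to the physically nearer index (when positions are given), then
    the lexicographically smaller one. SNPs whose best r^2 falls below
    ``r2_floor`` are listed as unassigned.
    """
    if not index_snps:
        raise InputError("index SNP list is empty")
    positions = positions or {}
    assignment: dict[str, str] = {i: i for i in index_snps}
    r2_to_index: dict[str, float] = {i: 1.0 for i in index_snps}
    unassigned: list[str] = []
    for s in significant_snps:
        if s in assignment:
            continue
        scored = []
        for i in index_snps:
            r2 = _r2_lookup(ld, s, i)
            dist = (
                abs(positions[s] - positions[i])
                if s in positions and i in positions
                else np.inf
            )
            scored.append((-r2, dist, i))
        neg_r2, _, best = min(scored)
        if -neg_r2 < r2_floor:
            unassigned.append(s)
        else:
            assignment[s] = best
            r2_to_index[s] = -neg_r2
    return ClusterAssignment(
        index_snps=list(index_snps),
        assignment=assignment,
        r2_to_index=r2_to_index,
        unassigned=unassigned,
    )


def drop_clusters(
    assignment: ClusterAssignment, evidence: dict[str, str]
) -> ClusterAssignment:
    """Remove whole LD clusters whose index failed downstream screening.

    ``evidence`` maps an index SNP to the reason it is excluded (e.g. a
    non-significant marginal association, or losing the conditional screen);
    the index and its entire bin are removed. Unknown indices raise
    ``KeyError``.
    """
    for idx in evidence:
        if idx not in assignment.index_snps:
            raise KeyError(f"unknown index SNP {idx!r}")
    for idx, reason in sorted(evidence.items()):
        warnings.warn(f"LD cluster of {idx} dropped: {reason}")
    keep = [i for i in assignment.index_snps if i not in evidence]
    new_assign = {s: i for s, i in assignment.assignment.items() if i not in evidence}
    return ClusterAssignment(
        index_snps=keep,
        assignment=new_assign,
        r2_to_index={s: assignment.r2_to_index[s] for s in new_assign},
        unassigned=list(assignment.unassigned),
    )


def transethnic_filter(
    retained_indices: list[str],
    panels: dict[str, GenotypeMatrix],
    thresholds: dict[str, float] | float = 0.9,
) -> CandidateSet:
    """Cross-population proxy-set intersection around the retained indices.

    Per ancestry group g, P_g is the union over retained indices of
    ``proxy_set(index, panel_g, thresholds[g])``. The candidate list is the
    intersection of the P_g; Venn counts tabulate every group-membership
    pattern over the union (patterns are sorted group names joined by '&',
    so counts are invariant to group ordering).
    """
    if not retained_indices:
        raise InputError("no retained index SNPs")
    if not panels:
        raise InputError("no panels supplied")
    if isinstance(thresholds, (int, float)):
        thresholds = {g: float(thresholds) for g in panels}
    missing = [g for g in panels if g not in thresholds]
    if missing:
        raise InputError(f"no r^2 threshold for groups: {missing}")

    per_group: dict[str, set[str]] = {}
    for g in sorted(panels):
        panel = panels[g]
        proxies: set[str] = set()
        for idx in retained_indices:
            if idx not in panel.snp_ids:
                warnings.warn(f"{g}: index {idx} absent from panel; skipped")
                continue
            try:
                proxies |= ld_core.proxy_set(idx, panel, thresholds[g])
            except DegenerateError:
                warnings.warn(f"{g}: index {idx} monomorphic; skipped")
        per_group[g] = proxies

    groups = sorted(per_group)
    intersection = set.intersection(*(per_group[g] for g in groups))
    union = set().union(*per_group.values())
    venn: dict[str, int] = {}
    for snp in union:
        pattern = "&".join(g for g in groups if snp in per_group[g])
        venn[pattern] = venn.get(pattern, 0) + 1
    return CandidateSet(
        per_group_sets=per_group, intersection=intersection, venn_counts=venn
    )
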