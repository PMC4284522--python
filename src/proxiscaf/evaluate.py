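"""Reconstruction quality metrics against a reference structure.

The headline metric is the oriented-adjacency error: the fraction of the
reference's oriented bin adjacencies that the assembly fails to reproduce,
counting an adjacency (a, o_a) -> (b, o_b) as recovered when present either
directly or as its reverse complement (b, -o_b) -> (a, -o_a).  It is zero
iff assembly and reference agree up to scaffold naming, scaffold order and
whole-scaffold reversal, and it accounts for both the order and the
orientation of the bins.  Duplicated bins are handled as adjacency
multisets, which implements an optimal pairing of copies.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, asdict

import numpy as np

from .genome import GenomeStructure

__all__ = [
    "AssemblyReport",
    "reconstruction_error",
    "chromosome_assignment_accuracy",
    "ordering_and_rank",
    "evaluate",
]


@dataclass(frozen=True)
class AssemblyReport:
    """Flat bundle of assembly-vs-reference quality metrics."""

    error: float
    n_contigs: int
    chrom_assignment_pct: float
    ordered_pct: float
    rank_error_mean: float
    rank_error_median: float
    iqr_contigs: float = math.nan

    def __post_init__(self) -> None:
        if not 0 <= self.error <= 1:
            raise ValueError("error must lie in [0, 1]")
        for pct in (self.chrom_assignment_pct, self.ordered_pct):
            if not 0 <= pct <= 100:
                raise ValueError("percentages must lie in [0, 100]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_text(self) -> str:
        return "\n".join(f"{k}\t{v}" for k, v in asdict(self).items())


def _check_universe(assembly: GenomeStructure, reference: GenomeStructure) -> None:
    a = {b.bin_id for b in assembly.bins}
    r = {b.bin_id for b in reference.bins}
    if a != r:
        raise ValueError("assembly and reference have disjoint/differing bin universes")


def _adjacency_multiset(structure: GenomeStructure) -> Counter:
    """Canonical oriented adjacencies; each edge keyed identically to its
    reverse complement so whole-scaffold reversal is a symmetry."""
    edges: Counter = Counter()
    for sc in structure.scaffolds:
        for p, q in zip(sc.placed, sc.placed[1:]):
            fwd = (p.bin_id, p.orientation, q.bin_id, q.orientation)
            rev = (q.bin_id, -q.orientation, p.bin_id, -p.orientation)
            edges[min(fwd, rev)] += 1
    return edges


def reconstruction_error(
    assembly: GenomeStructure, reference: GenomeStructure
) -> float:
    """1 - (recovered oriented adjacencies) / (reference adjacencies).

    Orientations of non-orientable (single-fragment) bins are fixed forward
    on both sides, so they never contribute orientation mismatches.
    """
    _check_universe(assembly, reference)
    ref = _adjacency_multiset(reference)
    asm = _adjacency_multiset(assembly)
    total = sum(ref.values())
    if total == 0:
        return 0.0
    matched = sum(min(c, asm[e]) for e, c in ref.items())
    return 1.0 - matched / total


def _majority_map(assembly: GenomeStructure, reference: GenomeStructure) -> dict[str, str]:
    """Assembly scaffold -> reference chromosome contributing most length."""
    ref_chrom: dict[int, str] = {}
    for sc in reference.scaffolds:
        for p in sc.placed:
            ref_chrom[p.bin_id] = sc.name
    out = {}
    for sc in assembly.scaffolds:
        weight: Counter = Counter()
        for p in sc.placed:
            weight[ref_chrom.get(p.bin_id, "?")] += assembly.bins[p.bin_id].length_bp
        out[sc.name] = weight.most_common(1)[0][0]
    return out


def chromosome_assignment_accuracy(
    assembly: GenomeStructure, reference: GenomeStructure
) -> float:
    """% of bins whose scaffold maps (majority length rule) to their true chromosome."""
    _check_universe(assembly, reference)
    ref_chrom: dict[int, str] = {}
    for sc in reference.scaffolds:
        for p in sc.placed:
            ref_chrom[p.bin_id] = sc.name
    mapping = _majority_map(assembly, reference)
    good = total = 0
    for sc in assembly.scaffolds:
        for p in sc.placed:
            if p.bin_id not in ref_chrom:
                continue
            total += 1
            if mapping[sc.name] == ref_chrom[p.bin_id]:
                good += 1
    return 100.0 * good / total if total else 0.0


def _neighbor_sets(structure: GenomeStructure) -> dict[int, set[frozenset]]:
    """bin -> set of unordered neighbour id pairs over all its placements."""
    out: dict[int, set] = {}
    for sc in structure.scaffolds:
        ids = [p.bin_id for p in sc.placed]
        for i, b in enumerate(ids):
            nb = frozenset(
                ids[j] for j in (i - 1, i + 1) if 0 <= j < len(ids)
            )
            out.setdefault(b, set()).add(nb)
    return out


def ordering_and_rank(
    assembly: GenomeStructure, reference: GenomeStructure
) -> tuple[float, dict[str, float]]:
    """Neighbourhood accuracy and per-bin rank errors.

    A bin counts as accurately ordered when its set of immediate neighbours
    (unordered, orientation ignored) equals the reference's.  Rank errors are
    |position in assembly scaffold - position in reference chromosome| for
    bins whose scaffold maps to their true chromosome, with each assembly
    scaffold read in the direction minimising its total rank error (so a
    reversed scaffold scores zero).
    """
    _check_universe(assembly, reference)
    ref_nb = _neighbor_sets(reference)
    asm_nb = _neighbor_sets(assembly)
    all_bins = [b.bin_id for b in reference.bins]
    ordered = sum(
        1 for b in all_bins if asm_nb.get(b, {frozenset()}) == ref_nb.get(b, {frozenset()})
    )
    ordered_pct = 100.0 * ordered / len(all_bins)

    ref_chrom: dict[int, str] = {}
    ref_rank: dict[int, int] = {}
    for sc in reference.scaffolds:
        for r, p in enumerate(sc.placed):
            ref_chrom[p.bin_id] = sc.name
            ref_rank[p.bin_id] = r
    mapping = _majority_map(assembly, reference)
    errors: list[float] = []
    for sc in assembly.scaffolds:
        chrom = mapping[sc.name]
        ids = [p.bin_id for p in sc.placed]
        fwd = [
            abs(i - ref_rank[b])
            for i, b in enumerate(ids)
            if ref_chrom.get(b) == chrom
        ]
        n = len(ids)
        rev = [
            abs((n - 1 - i) - ref_rank[b])
            for i, b in enumerate(ids)
            if ref_chrom.get(b) == chrom
        ]
        errors.extend(fwd if sum(fwd) <= sum(rev) else rev)
    stats = {
        "mean": float(np.mean(errors)) if errors else math.nan,
        "median": float(np.median(errors)) if errors else math.nan,
    }
    return ordered_pct, stats


def evaluate(
    assembly: GenomeStructure,
    reference: GenomeStructure,
    iqr_contigs: float = math.nan,
) -> AssemblyReport:
    """All metrics in one report."""
    ordered_pct, rank = ordering_and_rank(assembly, reference)
    return AssemblyReport(
        error=reconstruction_error(assembly, reference),
        n_contigs=len(assembly.scaffolds),
        chrom_assignment_pct=chromosome_assignment_accuracy(assembly, reference),
        ordered_pct=ordered_pct,
        rank_error_mean=rank["mean"],
        rank_error_median=rank["median"],
        iqr_contigs=iqr_contigs,
    )
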