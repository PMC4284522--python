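"""Build bin-level contact matrices from restriction maps and contact pairs.

The pipeline mirrors standard 3C-seq processing of pre-mapped read pairs:
keep pairs whose two mates map with quality strictly above the threshold,
assign each mate to its restriction fragment, discard same-fragment pairs
(undigested or self-religated molecules), collapse exact PCR duplicates, and
accumulate counts between the sub-bin segments containing the two mates.
Read mapping itself is out of scope: records arrive as tab-separated
``seq1 pos1 strand1 mapq1 seq2 pos2 strand2 mapq2`` lines.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
import pandas as pd

from .genome import Bin
from .model import ContactMatrix

__all__ = [
    "RestrictionMap",
    "ContactPairRecord",
    "FilterStats",
    "digest",
    "make_bins",
    "build_matrix",
    "read_pairs",
    "write_matrix",
    "read_matrix",
    "write_bin_table",
    "read_bin_table",
    "write_restriction_map",
    "read_restriction_map",
]

_VALID_NT = set("ACGT")


@dataclass(frozen=True)
class RestrictionMap:
    """Per-sequence fragment intervals (0-based half-open) tiling each sequence."""

    fragments: dict[str, tuple[tuple[int, int], ...]]

    def __post_init__(self) -> None:
        for name, frags in self.fragments.items():
            if not frags:
                raise ValueError(f"{name}: empty fragment list")
            pos = 0
            for a, b in frags:
                if a != pos or b <= a:
                    raise ValueError(f"{name}: fragments do not tile the sequence")
                pos = b

    def sequence_length(self, name: str) -> int:
        return self.fragments[name][-1][1]

    def fragment_index(self, name: str, pos: int) -> int:
        frags = self.fragments[name]
        if not 0 <= pos < frags[-1][1]:
            raise IndexError(f"position {pos} outside {name}")
        starts = [f[0] for f in frags]
        return bisect.bisect_right(starts, pos) - 1


@dataclass(frozen=True)
class ContactPairRecord:
    seq1: str
    pos1: int
    strand1: str
    mapq1: int
    seq2: str
    pos2: int
    strand2: str
    mapq2: int


@dataclass
class FilterStats:
    """Pair accounting; retained + all drop classes equals the input count."""

    retained: int = 0
    dropped_mapq: int = 0
    dropped_same_fragment: int = 0
    dropped_duplicate: int = 0
    dropped_unknown: int = 0

    @property
    def total(self) -> int:
        return (
            self.retained
            + self.dropped_mapq
            + self.dropped_same_fragment
            + self.dropped_duplicate
            + self.dropped_unknown
        )


def digest(sequences: dict[str, str] | Iterable[tuple[str, str]], site: str) -> RestrictionMap:
    """Cut every sequence before each occurrence of the recognition motif.

    Only plain ACGT motifs are supported; ambiguity codes raise.  A sequence
    without any site yields a single fragment spanning it.
    """
    site = site.upper()
    if not site:
        raise ValueError("empty recognition site")
    if not set(site) <= _VALID_NT:
        raise ValueError(f"unsupported characters in site {site!r} (ACGT only)")
    items = sequences.items() if isinstance(sequences, dict) else sequences
    fragments: dict[str, tuple[tuple[int, int], ...]] = {}
    for name, seq in items:
        seq = seq.upper()
        cuts = [0]
        start = seq.find(site)
        while start != -1:
            if start > 0:
                cuts.append(start)
            start = seq.find(site, start + 1)
        cuts.append(len(seq))
        fragments[name] = tuple(zip(cuts[:-1], cuts[1:]))
    return RestrictionMap(fragments)


def make_bins(
    rmap: RestrictionMap,
    min_rf: int = 2,
    target_bp: int | None = None,
) -> list[Bin]:
    """Greedy left-to-right grouping of consecutive fragments into bins.

    A bin closes as soon as it holds at least ``min_rf`` fragments and (when
    ``target_bp`` is given) at least that many base pairs.  A trailing group
    below ``min_rf`` is merged into its left neighbour.  Bins never span
    sequences; a sequence with fewer than ``min_rf`` fragments in total
    becomes a single non-orientable bin.  With ``min_rf >= 2`` every regular
    bin is orientable and its internal split sits on the fragment boundary
    nearest the bin midpoint.
    """
    if min_rf < 1:
        raise ValueError("min_rf must be >= 1")
    bins: list[Bin] = []
    for name, frags in rmap.fragments.items():
        groups: list[list[tuple[int, int]]] = []
        current: list[tuple[int, int]] = []
        for frag in frags:
            current.append(frag)
            long_enough = target_bp is None or (current[-1][1] - current[0][0]) >= target_bp
            if len(current) >= min_rf and long_enough:
                groups.append(current)
                current = []
        if current:
            if len(current) >= min_rf or not groups:
                groups.append(current)
            else:
                groups[-1].extend(current)
        for grp in groups:
            start, end = grp[0][0], grp[-1][1]
            n_rf = len(grp)
            split = -1
            if n_rf >= 2:
                mid = (end - start) / 2
                boundaries = [f[1] - start for f in grp[:-1]]
                split = min(boundaries, key=lambda x: abs(x - mid))
            bins.append(
                Bin(
                    bin_id=len(bins),
                    length_bp=end - start,
                    n_rf=n_rf,
                    source_name=name,
                    source_start=start,
                    source_end=end,
                    split_bp=split,
                )
            )
    return bins


def read_pairs(handle: TextIO) -> Iterator[ContactPairRecord]:
    """Parse tab-separated contact pair records, skipping comments."""
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        yield ContactPairRecord(
            f[0], int(f[1]), f[2], int(f[3]), f[4], int(f[5]), f[6], int(f[7])
        )


def _segment_lookup(bins: Sequence[Bin]) -> dict[str, list[tuple[int, int, int]]]:
    """Per source sequence: sorted (start, end, first_seg_index) per segment."""
    seg_index = 0
    table: dict[str, list[tuple[int, int, int]]] = {}
    for b in bins:
        start = b.source_start
        for L in b.segment_lengths:
            table.setdefault(b.source_name, []).append((start, start + L, seg_index))
            seg_index += 1
            start += L
    for rows in table.values():
        rows.sort()
    return table


def build_matrix(
    pairs: Iterable[ContactPairRecord],
    rmap: RestrictionMap,
    bins: Sequence[Bin],
    mapq_min: int = 30,
) -> tuple[ContactMatrix, FilterStats]:
    """Filter pairs and accumulate the symmetric segment-level count matrix.

    Retention requires both mates strictly above ``mapq_min`` (the default
    reproduces the classic "mapping quality above 30" rule), mates on known
    sequences, distinct restriction fragments, and a previously unseen
    (coordinates, strands) pair key.  Filters are applied in the order mapq,
    fragment assignment, same-fragment, duplicate.
    """
    n_segs = sum(len(b.segment_lengths) for b in bins)
    counts = np.zeros((n_segs, n_segs))
    lookup = _segment_lookup(bins)
    stats = FilterStats()
    seen: set[tuple] = set()

    def seg_at(seq: str, pos: int) -> int | None:
        rows = lookup.get(seq)
        if rows is None:
            return None
        i = bisect.bisect_right(rows, (pos, float("inf"), -1)) - 1
        if i < 0 or not rows[i][0] <= pos < rows[i][1]:
            return None
        return rows[i][2]

    for rec in pairs:
        if rec.seq1 not in rmap.fragments or rec.seq2 not in rmap.fragments:
            stats.dropped_unknown += 1
            continue
        if not (rec.mapq1 > mapq_min and rec.mapq2 > mapq_min):
            stats.dropped_mapq += 1
            continue
        try:
            f1 = rmap.fragment_index(rec.seq1, rec.pos1)
            f2 = rmap.fragment_index(rec.seq2, rec.pos2)
        except IndexError:
            stats.dropped_unknown += 1
            continue
        if rec.seq1 == rec.seq2 and f1 == f2:
            stats.dropped_same_fragment += 1
            continue
        key = tuple(
            sorted(
                [(rec.seq1, rec.pos1, rec.strand1), (rec.seq2, rec.pos2, rec.strand2)]
            )
        )
        if key in seen:
            stats.dropped_duplicate += 1
            continue
        seen.add(key)
        s1 = seg_at(rec.seq1, rec.pos1)
        s2 = seg_at(rec.seq2, rec.pos2)
        if s1 is None or s2 is None:
            stats.dropped_unknown += 1
            continue
        stats.retained += 1
        counts[s1, s2] += 1
        if s1 != s2:
            counts[s2, s1] += 1
    return ContactMatrix(bins, counts), stats


# -------------------------------------------------------------------- file IO


def write_bin_table(bins: Sequence[Bin], path) -> None:
    """Companion bin table, one row per sub-bin segment (bin_id repeats for
    the two rows of an orientable bin)."""
    with open(path, "w") as fh:
        fh.write("#bin_id\tsource_name\tstart\tend\tn_rf\tlength_bp\n")
        for b in bins:
            start = b.source_start
            rf_left = b.n_rf
            for k, L in enumerate(b.segment_lengths):
                n_rf = (
                    rf_left
                    if k == len(b.segment_lengths) - 1
                    else max(1, round(b.n_rf * L / b.length_bp))
                )
                rf_left -= n_rf
                fh.write(f"{b.bin_id}\t{b.source_name}\t{start}\t{start + L}\t{n_rf}\t{L}\n")
                start += L


def read_bin_table(path) -> list[Bin]:
    """Rebuild the bin universe from a bin table written by :func:`write_bin_table`."""
    tab = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["bin_id", "source_name", "start", "end", "n_rf", "length_bp"],
    )
    bins: list[Bin] = []
    for bin_id, grp in tab.groupby("bin_id", sort=True):
        grp = grp.sort_values("start")
        length = int(grp["length_bp"].sum())
        n_rf = int(grp["n_rf"].sum())
        split = int(grp["length_bp"].iloc[0]) if len(grp) == 2 else -1
        bins.append(
            Bin(
                bin_id=int(bin_id),
                length_bp=length,
                n_rf=max(n_rf, 2 if len(grp) == 2 else 1),
                source_name=str(grp["source_name"].iloc[0]),
                source_start=int(grp["start"].min()),
                source_end=int(grp["end"].max()),
                split_bp=split,
            )
        )
    return bins


def write_matrix(data: ContactMatrix, matrix_path, bins_path) -> None:
    """Sparse text triplets (upper triangle) plus the companion bin table.

    Both files are row-per-segment: two-segment (orientable) bins occupy two
    consecutive rows sharing a bin_id, which the reader regroups.
    """
    write_bin_table(data.bins, bins_path)
    K = data.seg_counts
    with open(matrix_path, "w") as fh:
        fh.write(f"#n_rows\t{data.n_segs}\n")
        ii, jj = np.nonzero(np.triu(K))
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{int(K[i, j])}\n")


def read_matrix(matrix_path, bins_path) -> ContactMatrix:
    """Read the triplet matrix + bin table written by :func:`write_matrix`.

    Either triangle of the triplet file is accepted.
    """
    bins = read_bin_table(bins_path)
    n_rows = sum(len(b.segment_lengths) for b in bins)
    counts = np.zeros((n_rows, n_rows))
    with open(matrix_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j, c = line.split("\t")
            i, j, c = int(i), int(j), float(c)
            counts[i, j] += c
            if i != j:
                counts[j, i] += c
    return ContactMatrix(bins, counts)


def write_restriction_map(rmap: RestrictionMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#sequence\tstart\tend\n")
        for name, frags in rmap.fragments.items():
            for a, b in frags:
                fh.write(f"{name}\t{a}\t{b}\n")


def read_restriction_map(path) -> RestrictionMap:
    frags: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, a, b = line.split("\t")
            frags.setdefault(name, []).append((int(a), int(b)))
    return RestrictionMap({k: tuple(v) for k, v in frags.items()})
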