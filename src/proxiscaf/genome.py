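"""One-dimensional genome structures and the catalogue of virtual rearrangements.

A genome structure is an ordered, oriented arrangement of *bins* (groups of
consecutive restriction fragments) into scaffolds, plus a pool of unplaced
bins and a multiplicity map allowing duplicated placements.  The sampler
explores this space with 14 typed moves: 4 transpositions, 4 reciprocal
translocations, a deletion, 4 duplications and an ejection into a fresh
scaffold.  In-place inversions arise as transpositions next to a bin's own
neighbour with flipped orientation, and as the segment-inversion degenerate
form of a same-scaffold translocation.

Structures are immutable: every move returns a new object sharing the bin
universe with its parent.  Copy indices of duplicated placements are assigned
monotonically and never reused, so traces are replayable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "Bin",
    "PlacedBin",
    "Scaffold",
    "GenomeStructure",
    "Mutation",
    "MutationKind",
    "MUTATION_KINDS",
    "apply_mutation",
    "enumerate_candidates",
    "genomic_distance",
    "n_contigs",
    "validate",
    "PairGeometry",
    "read_layout",
    "write_layout",
]


@dataclass(frozen=True)
class Bin:
    """Atomic repositionable unit: a run of ``n_rf`` restriction fragments.

    A bin is orientable only if it contains at least two restriction
    fragments; ``split_bp`` records the internal fragment boundary (offset
    from the bin start) at which the bin divides into its two sub-bin
    segments.  Non-orientable bins consist of a single segment.
    """

    bin_id: int
    length_bp: int
    n_rf: int
    source_name: str = ""
    source_start: int = 0
    source_end: int = -1
    split_bp: int = -1

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"bin {self.bin_id}: length_bp must be > 0")
        if self.n_rf < 1:
            raise ValueError(f"bin {self.bin_id}: n_rf must be >= 1")
        if self.source_end < 0:
            object.__setattr__(self, "source_end", self.source_start + self.length_bp)
        if self.split_bp < 0 and self.n_rf >= 2:
            object.__setattr__(self, "split_bp", self.length_bp // 2)
        if self.n_rf < 2:
            object.__setattr__(self, "split_bp", -1)
        if self.n_rf >= 2 and not (0 < self.split_bp < self.length_bp):
            raise ValueError(f"bin {self.bin_id}: split_bp outside bin")

    @property
    def orientable(self) -> bool:
        return self.n_rf >= 2

    @property
    def segment_lengths(self) -> tuple[int, ...]:
        if not self.orientable:
            return (self.length_bp,)
        return (self.split_bp, self.length_bp - self.split_bp)


@dataclass(frozen=True)
class PlacedBin:
    """One placement of a bin: orientation is +1 (forward) or -1 (reverse)."""

    bin_id: int
    orientation: int = 1
    copy_index: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in (1, -1):
            raise ValueError("orientation must be +1 or -1")


@dataclass(frozen=True)
class Scaffold:
    """Non-empty ordered chain of placed bins; order defines 1D coordinates."""

    name: str
    placed: tuple[PlacedBin, ...]

    def __post_init__(self) -> None:
        if not self.placed:
            raise ValueError("scaffolds must be non-empty")


@dataclass(frozen=True)
class PairGeometry:
    """Geometry of one placement pair: cis distance in bp, or a trans flag.

    ``s_floor`` is the small-distance floor (half the smaller bin length,
    at least 1 bp) applied before evaluating the contact-probability law.
    """

    s: float
    is_trans: bool
    s_floor: float = 1.0


class MutationKind(enum.Enum):
    """The 14 virtual rearrangement moves on a (bin, partner) pair.

    Transpositions remove the bin and reinsert it before/after the partner,
    keeping (FWD) or flipping (REV) its orientation.  Translocations cut the
    bin's scaffold and the partner's scaffold and rejoin the four arms; the
    name encodes which side of each cut is joined: EXCHANGE swaps the right
    arms (cuts fall before bin and partner), HEAD_HEAD joins the two cut
    starts, TAIL_HEAD joins the bin's end to the partner's start (cut after
    the bin), and TAIL_TAIL joins the two ends.  On a single scaffold these
    degenerate to, respectively: a split, a double split, an excision of the
    spanned segment into its own scaffold, and an in-place inversion of the
    spanned segment.  Duplications insert an extra copy, the original
    staying in place.
    """

    TRANSPOSE_BEFORE_FWD = "transpose_before_fwd"
    TRANSPOSE_BEFORE_REV = "transpose_before_rev"
    TRANSPOSE_AFTER_FWD = "transpose_after_fwd"
    TRANSPOSE_AFTER_REV = "transpose_after_rev"
    TRANSLOC_EXCHANGE = "transloc_exchange"
    TRANSLOC_HEAD_HEAD = "transloc_head_head"
    TRANSLOC_TAIL_HEAD = "transloc_tail_head"
    TRANSLOC_TAIL_TAIL = "transloc_tail_tail"
    DELETE = "delete"
    DUP_BEFORE_FWD = "dup_before_fwd"
    DUP_BEFORE_REV = "dup_before_rev"
    DUP_AFTER_FWD = "dup_after_fwd"
    DUP_AFTER_REV = "dup_after_rev"
    EJECT = "eject"


MUTATION_KINDS: tuple[MutationKind, ...] = tuple(MutationKind)

_TRANSPOSES = {
    MutationKind.TRANSPOSE_BEFORE_FWD: (0, 1),
    MutationKind.TRANSPOSE_BEFORE_REV: (0, -1),
    MutationKind.TRANSPOSE_AFTER_FWD: (1, 1),
    MutationKind.TRANSPOSE_AFTER_REV: (1, -1),
}
_DUPS = {
    MutationKind.DUP_BEFORE_FWD: (0, 1),
    MutationKind.DUP_BEFORE_REV: (0, -1),
    MutationKind.DUP_AFTER_FWD: (1, 1),
    MutationKind.DUP_AFTER_REV: (1, -1),
}
_TRANSLOCS = {
    MutationKind.TRANSLOC_EXCHANGE: "exchange",
    MutationKind.TRANSLOC_HEAD_HEAD: "head_head",
    MutationKind.TRANSLOC_TAIL_HEAD: "tail_head",
    MutationKind.TRANSLOC_TAIL_TAIL: "tail_tail",
}


@dataclass(frozen=True)
class Mutation:
    """A typed move on a (bin, partner) placement pair.

    ``bin`` and ``partner`` are ``(bin_id, copy_index)`` tuples.  A bin that
    is currently unplaced is addressed with ``copy_index=None``; moves that
    cannot apply to an unplaced bin (delete, translocations) are emitted as
    identity candidates so the candidate count stays exactly 14 per partner.
    """

    kind: MutationKind
    bin: tuple[int, int | None]
    partner: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.partner is not None and self.bin[0] == self.partner[0] and self.bin[1] == self.partner[1]:
            raise ValueError("bin and partner must differ")


class GenomeStructure:
    """Ordered, oriented bins partitioned into scaffolds plus an unplaced pool.

    Parameters
    ----------
    bins:
        The immutable bin universe; ``bins[i].bin_id == i`` is required.
    scaffolds:
        Tuple of :class:`Scaffold`.
    unplaced:
        Bin ids with zero placements.
    """

    __slots__ = (
        "bins",
        "scaffolds",
        "unplaced",
        "_next_copy",
        "_next_name",
        "_index",
        "_scafs_of",
        "_mult",
    )

    def __init__(
        self,
        bins: Sequence[Bin],
        scaffolds: Iterable[Scaffold],
        unplaced: Iterable[int] = (),
        _next_copy: tuple[int, ...] | None = None,
        _next_name: int | None = None,
    ) -> None:
        self.bins = tuple(bins)
        for i, b in enumerate(self.bins):
            if b.bin_id != i:
                raise ValueError("bins must be indexed by bin_id")
        self.scaffolds = tuple(scaffolds)
        self.unplaced = frozenset(unplaced)
        if _next_copy is None:
            nxt = [0] * len(self.bins)
            for sc in self.scaffolds:
                for p in sc.placed:
                    nxt[p.bin_id] = max(nxt[p.bin_id], p.copy_index + 1)
            _next_copy = tuple(nxt)
        self._next_copy = _next_copy
        if _next_name is None:
            _next_name = len(self.scaffolds)
        self._next_name = _next_name
        self._index: dict[tuple[int, int], tuple[int, int]] | None = None
        self._scafs_of: list[list[tuple[int, int]]] | None = None
        self._mult: list[int] | None = None

    # ---------------------------------------------------------------- builders

    @classmethod
    def from_bins(cls, bins: Sequence[Bin], layout: str = "separate") -> "GenomeStructure":
        """Initial structure: ``"separate"`` puts each bin in its own scaffold,
        ``"single"`` chains all bins into one scaffold in bin_id order."""
        placed = [PlacedBin(b.bin_id, 1, 0) for b in bins]
        if layout == "separate":
            scaffolds = [Scaffold(f"s{i}", (p,)) for i, p in enumerate(placed)]
        elif layout == "single":
            scaffolds = [Scaffold("s0", tuple(placed))]
        else:
            raise ValueError(f"unknown layout {layout!r}")
        return cls(bins, scaffolds)

    @classmethod
    def from_arrangement(
        cls,
        bins: Sequence[Bin],
        arrangement: Sequence[Sequence[tuple[int, int]]],
        names: Sequence[str] | None = None,
    ) -> "GenomeStructure":
        """Build from explicit per-scaffold ``(bin_id, orientation)`` lists."""
        counters = [0] * len(bins)
        scaffolds = []
        for k, chain in enumerate(arrangement):
            row = []
            for bin_id, ori in chain:
                if not bins[bin_id].orientable:
                    ori = 1
                row.append(PlacedBin(bin_id, ori, counters[bin_id]))
                counters[bin_id] += 1
            name = names[k] if names is not None else f"s{k}"
            scaffolds.append(Scaffold(name, tuple(row)))
        placed_ids = {p.bin_id for sc in scaffolds for p in sc.placed}
        unplaced = set(range(len(bins))) - placed_ids
        return cls(bins, scaffolds, unplaced)

    # ---------------------------------------------------------------- indices

    def _build_index(self) -> None:
        idx: dict[tuple[int, int], tuple[int, int]] = {}
        scafs: list[list[tuple[int, int]]] = [[] for _ in self.bins]
        mult = [0] * len(self.bins)
        for si, sc in enumerate(self.scaffolds):
            for pi, p in enumerate(sc.placed):
                idx[(p.bin_id, p.copy_index)] = (si, pi)
                scafs[p.bin_id].append((si, pi))
                mult[p.bin_id] += 1
        self._index = idx
        self._scafs_of = scafs
        self._mult = mult

    @property
    def placement_index(self) -> dict[tuple[int, int], tuple[int, int]]:
        if self._index is None:
            self._build_index()
        return self._index  # type: ignore[return-value]

    def placements_of(self, bin_id: int) -> list[tuple[int, int]]:
        """(scaffold_index, position) of every copy of ``bin_id``."""
        if self._scafs_of is None:
            self._build_index()
        return self._scafs_of[bin_id]  # type: ignore[index]

    @property
    def multiplicity(self) -> list[int]:
        if self._mult is None:
            self._build_index()
        return self._mult  # type: ignore[return-value]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def locate(self, placement: tuple[int, int | None]) -> tuple[int, int]:
        bin_id, copy_index = placement
        if copy_index is None:
            raise KeyError(f"bin {bin_id} addressed as unplaced")
        try:
            return self.placement_index[(bin_id, copy_index)]
        except KeyError:
            raise KeyError(f"no placement ({bin_id}, {copy_index}) in structure") from None

    # ---------------------------------------------------------------- queries

    def scaffold_of(self, placement: tuple[int, int]) -> int:
        return self.locate(placement)[0]

    def canonical(self) -> tuple:
        """Canonical form invariant under scaffold order/naming, whole-scaffold
        reversal and copy-index relabelling; used for structure equivalence."""
        chains = []
        for sc in self.scaffolds:
            fwd = tuple((p.bin_id, p.orientation) for p in sc.placed)
            rev = tuple(
                (p.bin_id, -p.orientation if self.bins[p.bin_id].orientable else 1)
                for p in reversed(sc.placed)
            )
            chains.append(min(fwd, rev))
        return (tuple(sorted(chains)), self.unplaced)

    def equivalent(self, other: "GenomeStructure") -> bool:
        return self.canonical() == other.canonical()

    # ---------------------------------------------------------------- editing

    def _fresh_name(self, k: int = 0) -> str:
        return f"s{self._next_name + k}"

    def _rebuild(
        self,
        scaffolds: list[Scaffold],
        unplaced: Iterable[int],
        next_copy: tuple[int, ...] | None = None,
        names_used: int = 0,
    ) -> "GenomeStructure":
        return GenomeStructure(
            self.bins,
            tuple(sc for sc in scaffolds if sc.placed),
            unplaced,
            _next_copy=next_copy if next_copy is not None else self._next_copy,
            _next_name=self._next_name + names_used,
        )


def n_contigs(structure: GenomeStructure) -> int:
    """Number of scaffolds (the unplaced pool is not counted)."""
    return len(structure.scaffolds)


def _oriented(bins: Sequence[Bin], bin_id: int, orientation: int, copy_index: int) -> PlacedBin:
    if not bins[bin_id].orientable:
        orientation = 1
    return PlacedBin(bin_id, orientation, copy_index)


def _rc(bins: Sequence[Bin], chain: tuple[PlacedBin, ...]) -> tuple[PlacedBin, ...]:
    """Reverse-complement a chain: reverse order, flip orientable bins."""
    return tuple(
        _oriented(bins, p.bin_id, -p.orientation, p.copy_index) for p in reversed(chain)
    )


def _with_chain(sc: Scaffold, chain: tuple[PlacedBin, ...]) -> Scaffold | None:
    return Scaffold(sc.name, chain) if chain else None


def apply_mutation(structure: GenomeStructure, move: Mutation) -> GenomeStructure:
    """Apply one virtual rearrangement, returning a new structure.

    The input structure is left untouched.  Moves referencing placements that
    do not exist raise ``KeyError``.  Deleting the last copy of a bin is
    legal: the bin joins the unplaced pool and can later be re-inserted by
    addressing it with ``copy_index=None``.
    """
    bins = structure.bins
    a_bin, a_copy = move.bin
    if not 0 <= a_bin < len(bins):
        raise KeyError(f"unknown bin {a_bin}")
    a_placed = a_copy is not None
    if a_placed:
        sa, ia = structure.locate((a_bin, a_copy))
    elif a_bin not in structure.unplaced:
        raise KeyError(f"bin {a_bin} addressed as unplaced but has placements")

    kind = move.kind
    needs_partner = kind is not MutationKind.DELETE and kind is not MutationKind.EJECT
    if needs_partner:
        if move.partner is None:
            raise KeyError(f"move {kind.value} requires a partner")
        sb, ib = structure.locate(move.partner)

    scaffolds = list(structure.scaffolds)
    unplaced = set(structure.unplaced)
    next_copy = structure._next_copy
    names_used = 0

    if kind in _TRANSPOSES:
        after, ori_sign = _TRANSPOSES[kind]
        if a_placed:
            src = scaffolds[sa].placed
            moved = src[ia]
            new_p = _oriented(bins, a_bin, ori_sign * moved.orientation, moved.copy_index)
            scaffolds[sa] = _with_chain(scaffolds[sa], src[:ia] + src[ia + 1 :])
            if sb == sa and ib > ia:
                ib -= 1
        else:
            new_p = _oriented(bins, a_bin, ori_sign, next_copy[a_bin])
            next_copy = tuple(
                c + 1 if i == a_bin else c for i, c in enumerate(next_copy)
            )
            unplaced.discard(a_bin)
        tgt = scaffolds[sb]
        if tgt is None:  # partner scaffold emptied: degenerate, re-create
            scaffolds[sb] = Scaffold(structure.scaffolds[sb].name, (new_p,))
        else:
            pos = ib + after
            scaffolds[sb] = Scaffold(tgt.name, tgt.placed[:pos] + (new_p,) + tgt.placed[pos:])

    elif kind in _DUPS:
        after, ori_sign = _DUPS[kind]
        base_ori = scaffolds[sa].placed[ia].orientation if a_placed else 1
        new_p = _oriented(bins, a_bin, ori_sign * base_ori, next_copy[a_bin])
        next_copy = tuple(c + 1 if i == a_bin else c for i, c in enumerate(next_copy))
        unplaced.discard(a_bin)
        tgt = scaffolds[sb]
        pos = ib + after
        scaffolds[sb] = Scaffold(tgt.name, tgt.placed[:pos] + (new_p,) + tgt.placed[pos:])

    elif kind is MutationKind.DELETE:
        if a_placed:
            src = scaffolds[sa].placed
            scaffolds[sa] = _with_chain(scaffolds[sa], src[:ia] + src[ia + 1 :])
            if structure.multiplicity[a_bin] == 1:
                unplaced.add(a_bin)
        # deleting an unplaced bin is the identity

    elif kind is MutationKind.EJECT:
        if a_placed:
            src = scaffolds[sa].placed
            moved = src[ia]
            scaffolds[sa] = _with_chain(scaffolds[sa], src[:ia] + src[ia + 1 :])
        else:
            moved = _oriented(bins, a_bin, 1, next_copy[a_bin])
            next_copy = tuple(c + 1 if i == a_bin else c for i, c in enumerate(next_copy))
            unplaced.discard(a_bin)
        scaffolds.append(Scaffold(structure._fresh_name(names_used), (moved,)))
        names_used += 1

    elif kind in _TRANSLOCS:
        variant = _TRANSLOCS[kind]
        if not a_placed:
            pass  # identity: cannot cut at an unplaced bin
        elif sa != sb:
            A, B = scaffolds[sa].placed, scaffolds[sb].placed
            if variant == "exchange":  # cuts before bin and partner; swap right arms
                chains = (A[:ia] + B[ib:], B[:ib] + A[ia:])
            elif variant == "head_head":  # join the two cut starts
                chains = (A[:ia] + _rc(bins, B[:ib]), _rc(bins, A[ia:]) + B[ib:])
            elif variant == "tail_head":  # bin's end joined to partner's start
                chains = (A[: ia + 1] + B[ib:], B[:ib] + A[ia + 1 :])
            else:  # tail_tail: join the two cut ends
                chains = (
                    A[: ia + 1] + _rc(bins, B[: ib + 1]),
                    _rc(bins, A[ia + 1 :]) + B[ib + 1 :],
                )
            scaffolds[sa] = _with_chain(scaffolds[sa], chains[0])
            scaffolds[sb] = _with_chain(scaffolds[sb], chains[1])
        else:
            # degenerate same-scaffold forms
            S = scaffolds[sa].placed
            if variant == "exchange":  # split before the first cut
                i = min(ia, ib)
                scaffolds[sa] = _with_chain(scaffolds[sa], S[i:])
                if S[:i]:
                    scaffolds.append(Scaffold(structure._fresh_name(names_used), S[:i]))
                    names_used += 1
            elif variant == "head_head":  # both splits
                i, j = sorted((ia, ib))
                parts = [p for p in (S[:i], S[i:j], S[j:]) if p]
                scaffolds[sa] = _with_chain(scaffolds[sa], parts[0])
                for part in parts[1:]:
                    scaffolds.append(Scaffold(structure._fresh_name(names_used), part))
                    names_used += 1
            else:
                lo, hi = sorted((ia + 1, ib))
                seg = S[lo:hi]
                if variant == "tail_head":  # excise the spanned segment
                    if seg and (S[:lo] + S[hi:]):
                        scaffolds[sa] = _with_chain(scaffolds[sa], S[:lo] + S[hi:])
                        scaffolds.append(
                            Scaffold(structure._fresh_name(names_used), seg)
                        )
                        names_used += 1
                else:  # tail_tail: invert the spanned segment in place
                    scaffolds[sa] = _with_chain(
                        scaffolds[sa], S[:lo] + _rc(bins, seg) + S[hi:]
                    )
    else:  # pragma: no cover
        raise ValueError(f"unhandled mutation kind {kind}")

    scaffolds = [sc for sc in scaffolds if sc is not None]
    return structure._rebuild(scaffolds, unplaced, next_copy, names_used)


def enumerate_candidates(
    structure: GenomeStructure,
    bin_placement: tuple[int, int | None],
    partners: Sequence[tuple[int, int]],
) -> list[tuple[Mutation, GenomeStructure]]:
    """All 14 moves against each of the m partners: exactly ``14*m`` candidates.

    Candidates that coincide with the current structure (for example a
    transposition to a bin's own position, or degenerate cuts at scaffold
    ends) are still emitted.
    """
    if not partners:
        raise ValueError("partner list must be non-empty")
    out: list[tuple[Mutation, GenomeStructure]] = []
    for partner in partners:
        if partner[0] == bin_placement[0] and partner[1] == bin_placement[1]:
            raise ValueError("partner must differ from the selected bin")
        for kind in MUTATION_KINDS:
            mv = Mutation(kind, bin_placement, partner)
            out.append((mv, apply_mutation(structure, mv)))
    return out


def _midpoints(structure: GenomeStructure, si: int) -> list[float]:
    pos, out = 0.0, []
    for p in structure.scaffolds[si].placed:
        L = structure.bins[p.bin_id].length_bp
        out.append(pos + L / 2.0)
        pos += L
    return out


def genomic_distance(
    structure: GenomeStructure,
    a: tuple[int, int],
    b: tuple[int, int],
) -> PairGeometry:
    """Midpoint-to-midpoint separation in bp for cis pairs; trans otherwise."""
    sa, ia = structure.locate(a)
    sb, ib = structure.locate(b)
    la = structure.bins[a[0]].length_bp
    lb = structure.bins[b[0]].length_bp
    floor = max(1.0, 0.5 * min(la, lb))
    if sa != sb:
        return PairGeometry(s=float("nan"), is_trans=True, s_floor=floor)
    mids = _midpoints(structure, sa)
    return PairGeometry(s=abs(mids[ia] - mids[ib]), is_trans=False, s_floor=floor)


def validate(structure: GenomeStructure) -> list[str]:
    """Check the structure invariants; returns a list of violation messages."""
    issues: list[str] = []
    seen: set[tuple[int, int]] = set()
    counts = [0] * len(structure.bins)
    for sc in structure.scaffolds:
        if not sc.placed:
            issues.append(f"scaffold {sc.name}: empty")
        for p in sc.placed:
            if not 0 <= p.bin_id < len(structure.bins):
                issues.append(f"scaffold {sc.name}: unknown bin {p.bin_id}")
                continue
            key = (p.bin_id, p.copy_index)
            if key in seen:
                issues.append(f"duplicate placement key {key}")
            seen.add(key)
            counts[p.bin_id] += 1
            if not structure.bins[p.bin_id].orientable and p.orientation != 1:
                issues.append(f"bin {p.bin_id}: non-orientable bin carries orientation")
    for b in structure.bins:
        placed = counts[b.bin_id]
        if placed == 0 and b.bin_id not in structure.unplaced:
            issues.append(f"bin {b.bin_id}: neither placed nor in unplaced pool")
        if placed > 0 and b.bin_id in structure.unplaced:
            issues.append(f"bin {b.bin_id}: placed but marked unplaced")
    names = [sc.name for sc in structure.scaffolds]
    if len(names) != len(set(names)):
        issues.append("scaffold names not unique")
    return issues


# -------------------------------------------------------------------- layout IO

_ORI_CHAR = {1: "+", -1: "-"}
_CHAR_ORI = {"+": 1, "-": -1}


def write_layout(structure: GenomeStructure, path) -> None:
    """Tab-separated layout: scaffold_name, rank, bin_id, orientation, copy_index.

    Unplaced bins are written with scaffold name ``*``.  Round-trips losslessly
    through :func:`read_layout`.
    """
    with open(path, "w") as fh:
        fh.write("#scaffold\trank\tbin_id\torientation\tcopy_index\n")
        for sc in structure.scaffolds:
            for rank, p in enumerate(sc.placed):
                fh.write(
                    f"{sc.name}\t{rank}\t{p.bin_id}\t{_ORI_CHAR[p.orientation]}\t{p.copy_index}\n"
                )
        for rank, bin_id in enumerate(sorted(structure.unplaced)):
            fh.write(f"*\t{rank}\t{bin_id}\t+\t0\n")


def read_layout(path, bins: Sequence[Bin]) -> GenomeStructure:
    chains: dict[str, list[tuple[int, PlacedBin]]] = {}
    order: list[str] = []
    unplaced: set[int] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, rank, bin_id, ori, copy_index = line.split("\t")
            if name == "*":
                unplaced.add(int(bin_id))
                continue
            if name not in chains:
                chains[name] = []
                order.append(name)
            chains[name].append(
                (int(rank), PlacedBin(int(bin_id), _CHAR_ORI[ori], int(copy_index)))
            )
    scaffolds = []
    for name in order:
        placed = tuple(p for _, p in sorted(chains[name], key=lambda t: t[0]))
        scaffolds.append(Scaffold(name, placed))
    return GenomeStructure(bins, scaffolds, unplaced)
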