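"""Poisson contact model: expected intensities and structure log-likelihood.

The model scores a genome structure G against an observed contact matrix D
under three nuisance parameters xi = (b, s0, Pt):

* cis pairs at genomic distance s <= s0 contact with probability
  ``Pt * (s / s0) ** b`` per bp^2 (power law, b < 0),
* cis pairs beyond s0 and all trans pairs contact with the uniform
  probability Pt per bp^2 (the plateau),
* observed counts are independent Poisson draws around
  ``lambda = exposure * L_i * L_j * intensity``.

Counts are kept at sub-bin *segment* resolution (orientable bins carry two
segments split at a restriction-fragment boundary): flipping a bin reverses
its segments inside the bin span, which is what makes bin orientation
identifiable from contact data at all, and why orientability requires at
least two restriction fragments per bin.  Bin-level quantities are the
aggregates over segment pairs.

Unplaced (deleted) bins keep a floor intensity (factor ``UNPLACED_EPS`` of
Pt), so observed contacts of a deleted bin actively penalise the deletion.
Duplicated bins keep their observed counts on the single collapsed row while
the model sums lambda over all copy pairs — a collapsed two-copy bin is
expected to show twice the contacts of an ordinary bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genome import Bin, GenomeStructure, Mutation, PairGeometry, apply_mutation

__all__ = [
    "NuisanceParams",
    "ContactMatrix",
    "LikelihoodState",
    "contact_probability",
    "expected_count",
    "log_likelihood",
    "delta_log_likelihood",
    "fit_exposure",
    "UNPLACED_EPS",
]

UNPLACED_EPS = 1e-3


@dataclass(frozen=True)
class NuisanceParams:
    """xi = (b, s0, Pt): power-law exponent, plateau onset (bp), trans level (/bp^2)."""

    b: float
    s0: float
    pt: float

    def __post_init__(self) -> None:
        if not self.b < 0:
            raise ValueError("power-law exponent b must be negative")
        if not self.s0 > 0:
            raise ValueError("plateau onset s0 must be positive")
        if not self.pt > 0:
            raise ValueError("trans intensity Pt must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.b, self.s0, self.pt)


def contact_probability(geom: PairGeometry, params: NuisanceParams) -> float:
    """Contact intensity per bp^2 for one placement pair.

    Continuous at s0 by construction: ``Pc(s0) == Pt``.
    """
    if geom.is_trans:
        return params.pt
    s = max(geom.s, geom.s_floor, 1.0)
    if s >= params.s0:
        return params.pt
    return params.pt * (s / params.s0) ** params.b


class ContactMatrix:
    """Symmetric observed contact counts over sub-bin segments.

    Parameters
    ----------
    bins:
        Bin universe (``bins[i].bin_id == i``); each bin contributes one or
        two segments (see :attr:`Bin.segment_lengths`).
    seg_counts:
        Dense symmetric non-negative ``(n_segs, n_segs)`` count matrix.
        The diagonal holds within-segment self contacts.
    """

    def __init__(self, bins, seg_counts: np.ndarray) -> None:
        self.bins: tuple[Bin, ...] = tuple(bins)
        seg_bin: list[int] = []
        seg_len: list[float] = []
        seg_mid: list[float] = []
        offsets: list[int] = []
        for b in self.bins:
            offsets.append(len(seg_bin))
            start = 0
            for L in b.segment_lengths:
                seg_bin.append(b.bin_id)
                seg_len.append(float(L))
                seg_mid.append(start + L / 2.0)
                start += L
        self.seg_bin = np.asarray(seg_bin, dtype=np.intp)
        self.seg_len = np.asarray(seg_len)
        self.seg_mid_in_bin = np.asarray(seg_mid)
        self.bin_offset = np.asarray(offsets, dtype=np.intp)
        self.bin_nseg = np.asarray(
            [len(b.segment_lengths) for b in self.bins], dtype=np.intp
        )

        K = np.asarray(seg_counts, dtype=np.float64)
        if K.shape != (self.n_segs, self.n_segs):
            raise ValueError(
                f"seg_counts shape {K.shape} does not match {self.n_segs} segments"
            )
        if not np.allclose(K, K.T):
            raise ValueError("contact matrix must be symmetric")
        if (K < 0).any():
            raise ValueError("contact counts must be non-negative")
        self.seg_counts = K
        self._lgam = gammaln(K + 1.0)
        self._L2 = np.outer(self.seg_len, self.seg_len)
        self._floor = np.maximum(1.0, 0.5 * np.minimum.outer(self.seg_len, self.seg_len))
        self._bin_counts: np.ndarray | None = None

    # ------------------------------------------------------------- properties

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_segs(self) -> int:
        return int(self.seg_bin.shape[0])

    @property
    def total_contacts(self) -> float:
        K = self.seg_counts
        return float((K.sum() + np.trace(K)) / 2.0)

    @property
    def bin_counts(self) -> np.ndarray:
        """Dense bin-level count matrix k (segment counts aggregated)."""
        if self._bin_counts is None:
            n = self.n_bins
            bc = np.zeros((n, n))
            np.add.at(bc, (self.seg_bin[:, None], self.seg_bin[None, :]), self.seg_counts)
            self._bin_counts = bc
        return self._bin_counts

    @property
    def k(self):
        """Bin-level counts as a scipy sparse matrix (upper storage dense-backed)."""
        from scipy import sparse

        return sparse.csr_matrix(self.bin_counts)

    def bin_marginals(self) -> np.ndarray:
        """Per-bin total contact counts (row sums of the bin-level matrix)."""
        bc = self.bin_counts
        return bc.sum(axis=1) - np.diag(bc) / 2.0

    @classmethod
    def empty(cls, bins) -> "ContactMatrix":
        n = sum(len(b.segment_lengths) for b in bins)
        return cls(bins, np.zeros((n, n)))

    def segs_of_bin(self, bin_id: int) -> np.ndarray:
        o = self.bin_offset[bin_id]
        return np.arange(o, o + self.bin_nseg[bin_id], dtype=np.intp)

    def downsample(self, fraction: float, rng: np.random.Generator) -> "ContactMatrix":
        """Binomially thin every pair count, keeping ``fraction`` of contacts."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        upper = np.triu(self.seg_counts)
        thin = rng.binomial(upper.astype(np.int64), fraction).astype(np.float64)
        out = thin + np.triu(thin, 1).T
        return ContactMatrix(self.bins, out)


# ----------------------------------------------------------------- geometry


def _scaffold_positions(structure: GenomeStructure, data: ContactMatrix, si: int):
    """Segment indices, positions and owning bins along one scaffold."""
    idx: list[int] = []
    pos: list[float] = []
    owner: list[int] = []
    x = 0.0
    for p in structure.scaffolds[si].placed:
        b = p.bin_id
        L = data.seg_len[data.segs_of_bin(b)].sum()
        o = data.bin_offset[b]
        for j in range(data.bin_nseg[b]):
            s = o + j
            mid = data.seg_mid_in_bin[s]
            if p.orientation < 0:
                mid = L - mid
            idx.append(int(s))
            pos.append(x + mid)
            owner.append(b)
        x += L
    return np.asarray(idx, dtype=np.intp), np.asarray(pos), owner


def _pc_correction(D: np.ndarray, F: np.ndarray, params: NuisanceParams) -> np.ndarray:
    """Pc(s) - Pt with the small-s floor applied; zero beyond the plateau.

    Uses the identity Pc(s)/Pt = min(s, s0)/s0 ** b (b < 0), so the plateau
    region evaluates to exactly zero without boolean indexing.
    """
    r = np.maximum(D, F)
    r /= params.s0
    np.clip(r, None, 1.0, out=r)
    return params.pt * (r**params.b - 1.0)


def _t_seg(data: ContactMatrix, structure: GenomeStructure) -> np.ndarray:
    """Per-segment trans weight: copy count for placed bins, floor otherwise."""
    mult = np.asarray(structure.multiplicity, dtype=np.float64)
    t = np.where(mult > 0, mult, UNPLACED_EPS)
    return t[data.seg_bin]


def _intensity_full(
    data: ContactMatrix, structure: GenomeStructure, params: NuisanceParams
) -> np.ndarray:
    t = _t_seg(data, structure)
    I = params.pt * np.outer(t, t)
    for si in range(len(structure.scaffolds)):
        idx, pos, _ = _scaffold_positions(structure, data, si)
        D = np.abs(pos[:, None] - pos[None, :])
        F = data._floor[np.ix_(idx, idx)]
        C = _pc_correction(D, F, params)
        if len(set(idx.tolist())) == len(idx):
            I[np.ix_(idx, idx)] += C
        else:  # duplicated bin placed twice in one scaffold
            np.add.at(I, (idx[:, None], idx[None, :]), C)
    return I


def _check_universe(data: ContactMatrix, structure: GenomeStructure) -> None:
    if len(structure.bins) != data.n_bins:
        raise ValueError(
            f"structure has {len(structure.bins)} bins, matrix has {data.n_bins}"
        )


def log_likelihood(
    data: ContactMatrix,
    structure: GenomeStructure,
    params: NuisanceParams,
    exposure: float = 1.0,
) -> float:
    """Poisson log-likelihood sum_{i<=j} [k ln lam - lam - ln k!] over segment pairs."""
    _check_universe(data, structure)
    lam = exposure * data._L2 * _intensity_full(data, structure, params)
    T = data.seg_counts * np.log(lam) - lam - data._lgam
    return float((T.sum() + np.trace(T)) / 2.0)


def fit_exposure(
    data: ContactMatrix, structure: GenomeStructure, params: NuisanceParams
) -> float:
    """Depth-matching scale: exposure such that sum(lambda) equals observed total."""
    _check_universe(data, structure)
    total = data.total_contacts
    if total <= 0:
        raise ValueError("cannot fit exposure on an all-zero matrix")
    raw = data._L2 * _intensity_full(data, structure, params)
    denom = (raw.sum() + np.trace(raw)) / 2.0
    return float(total / denom)


def expected_count(
    data: ContactMatrix,
    structure: GenomeStructure,
    i: int,
    j: int,
    params: NuisanceParams,
    exposure: float = 1.0,
) -> float:
    """Expected bin-level count lambda_ij, summed over copy and segment pairs."""
    _check_universe(data, structure)
    lam = exposure * data._L2 * _intensity_full(data, structure, params)
    si, sj = data.segs_of_bin(i), data.segs_of_bin(j)
    block = lam[np.ix_(si, sj)]
    if i != j:
        return float(block.sum())
    return float((block.sum() + np.trace(block)) / 2.0)


# ------------------------------------------------------------ incremental state


class LikelihoodState:
    """Likelihood bookkeeping for the sampler.

    Holds the current structure, parameters, exposure and total
    log-likelihood, and scores candidate moves by recomputing only the pairs
    whose geometry can have changed: the bins of the scaffolds replaced by
    the move, plus the whole row of the moved bin when its copy number
    changes.  Scaffold geometry (segment positions, pairwise distances) is
    cached per scaffold object; candidate structures share all untouched
    scaffold objects with their parent, so the cache carries over.
    """

    def __init__(
        self,
        data: ContactMatrix,
        structure: GenomeStructure,
        params: NuisanceParams,
        exposure: float,
    ) -> None:
        _check_universe(data, structure)
        self.data = data
        self.structure = structure
        self.params = params
        self.exposure = exposure
        self._geom: dict[int, tuple] = {}
        self._t_bin = self._make_t(structure)
        self.loglik = self._full_loglik()

    @staticmethod
    def _make_t(structure: GenomeStructure) -> np.ndarray:
        mult = np.asarray(structure.multiplicity, dtype=np.float64)
        return np.where(mult > 0, mult, UNPLACED_EPS)

    # ---------------------------------------------------------------- geometry

    def _entry(self, sc) -> tuple:
        """(idx, pos, D, F, owners, has_dup) for one scaffold, cached by object."""
        e = self._geom.get(id(sc))
        if e is not None and e[0] is sc:
            return e
        data = self.data
        idx_l: list[int] = []
        pos_l: list[float] = []
        owner: list[int] = []
        x = 0.0
        for p in sc.placed:
            b = p.bin_id
            o = data.bin_offset[b]
            nseg = data.bin_nseg[b]
            L = 0.0
            for j in range(nseg):
                L += data.seg_len[o + j]
            for j in range(nseg):
                s = o + j
                mid = data.seg_mid_in_bin[s]
                if p.orientation < 0:
                    mid = L - mid
                idx_l.append(s)
                pos_l.append(x + mid)
                owner.append(b)
            x += L
        idx = np.asarray(idx_l, dtype=np.intp)
        pos = np.asarray(pos_l)
        D = np.abs(pos[:, None] - pos[None, :])
        F = data._floor[idx[:, None], idx]
        has_dup = len(set(idx_l)) != len(idx_l)
        e = (sc, idx, pos, D, F, np.asarray(owner, dtype=np.intp), has_dup)
        self._geom[id(sc)] = e
        return e

    def _prune_cache(self) -> None:
        live = {id(sc) for sc in self.structure.scaffolds}
        if len(self._geom) > 4 * len(live) + 64:
            self._geom = {k: v for k, v in self._geom.items() if k in live}

    # ----------------------------------------------------------- scoring cores

    def _full_loglik(
        self,
        params: NuisanceParams | None = None,
        structure: GenomeStructure | None = None,
        t_bin: np.ndarray | None = None,
    ) -> float:
        params = params or self.params
        structure = structure if structure is not None else self.structure
        t_bin = t_bin if t_bin is not None else self._t_bin
        data = self.data
        t = t_bin[data.seg_bin]
        I = params.pt * np.outer(t, t)
        for sc in structure.scaffolds:
            _, idx, _, D, F, _, has_dup = self._entry(sc)
            C = _pc_correction(D, F, params)
            if has_dup:
                np.add.at(I, (idx[:, None], idx[None, :]), C)
            else:
                I[idx[:, None], idx] += C
        lam = self.exposure * data._L2 * I
        T = data.seg_counts * np.log(lam) - lam - data._lgam
        return float((T.sum() + np.trace(T)) / 2.0)

    def _score_block(
        self,
        segs: np.ndarray,
        t_bin: np.ndarray,
        scaffold_objs,
        u_set: set[int],
        params: NuisanceParams,
    ) -> float:
        """sum over pairs within the segment set of [k ln lam - lam] (the ln k!
        term cancels in every difference this is used for)."""
        data = self.data
        t_sub = t_bin[data.seg_bin[segs]]
        I = params.pt * np.outer(t_sub, t_sub)
        for sc in scaffold_objs:
            _, idx, pos, D, F, owner, _ = self._entry(sc)
            sel = np.asarray([b in u_set for b in owner], dtype=bool)
            if not sel.any():
                continue
            gi = idx[sel]
            C = _pc_correction(D[sel][:, sel], F[sel][:, sel], params)
            li = np.searchsorted(segs, gi)
            if len(set(gi.tolist())) == len(gi):
                I[li[:, None], li] += C
            else:
                np.add.at(I, (li[:, None], li[None, :]), C)
        l = data.seg_len[segs]
        lam = self.exposure * np.outer(l, l) * I
        T = data.seg_counts[segs[:, None], segs] * np.log(lam) - lam
        return float((T.sum() + np.trace(T)) / 2.0)

    def _score_row(
        self,
        a_bin: int,
        rest: np.ndarray,
        t_bin: np.ndarray,
        scaffold_objs,
        u_set: set[int],
        params: NuisanceParams,
    ) -> float:
        """Terms for pairs (a_bin, q) with q outside the affected set — needed
        when a_bin's copy number changes, which rescales its whole row."""
        data = self.data
        a_segs = data.segs_of_bin(a_bin)
        if rest.size == 0:
            return 0.0
        I = (
            params.pt
            * t_bin[a_bin]
            * t_bin[data.seg_bin[rest]][None, :]
            * np.ones((a_segs.size, 1))
        )
        for sc in scaffold_objs:
            _, idx, pos, _, _, owner, _ = self._entry(sc)
            a_rows = np.nonzero(owner == a_bin)[0]
            if a_rows.size == 0:
                continue
            q_cols = np.asarray(
                [i for i, b in enumerate(owner) if b not in u_set], dtype=np.intp
            )
            if q_cols.size == 0:
                continue
            gq = idx[q_cols]
            cols = np.searchsorted(rest, gq)
            for ar in a_rows:
                ga = int(idx[ar])
                arow = int(ga - data.bin_offset[a_bin])
                D = np.abs(pos[q_cols] - pos[ar])
                F = data._floor[ga, gq]
                C = _pc_correction(D, F, params)
                np.add.at(I[arow], cols, C)
        lam = (
            self.exposure
            * np.outer(data.seg_len[a_segs], data.seg_len[rest])
            * I
        )
        T = data.seg_counts[a_segs[:, None], rest] * np.log(lam) - lam
        return float(T.sum())

    # ------------------------------------------------------------ move scoring

    def affected_bins(self, move: Mutation) -> list[int]:
        """Bins of the scaffolds touched by the move, plus the moved bin."""
        st = self.structure
        bins = {move.bin[0]}
        for placement in (move.bin, move.partner):
            if placement is None or placement[1] is None:
                continue
            si, _ = st.locate(placement)  # raises on stale placements
            for p in st.scaffolds[si].placed:
                bins.add(p.bin_id)
        return sorted(bins)

    def propose(
        self, move: Mutation, _iter_cache: dict | None = None
    ) -> tuple[GenomeStructure, float]:
        """Candidate structure and its log-likelihood change for one move.

        ``_iter_cache`` (optional) memoises before-move block/row scores
        across the candidates of one sampler iteration.
        """
        new_structure = apply_mutation(self.structure, move)
        delta = self._delta(move, new_structure, _iter_cache)
        return new_structure, delta

    def _delta(
        self,
        move: Mutation,
        new_structure: GenomeStructure,
        _iter_cache: dict | None = None,
    ) -> float:
        old_sc = self.structure.scaffolds
        new_ids = {id(sc) for sc in new_structure.scaffolds}
        old_ids = {id(sc) for sc in old_sc}
        changed = [sc for sc in old_sc if id(sc) not in new_ids]
        added = [sc for sc in new_structure.scaffolds if id(sc) not in old_ids]

        a_bin = move.bin[0]
        u_set = {a_bin}
        for sc in changed:
            for p in sc.placed:
                u_set.add(p.bin_id)
        data = self.data
        key = (tuple(sorted(id(sc) for sc in changed)), a_bin)
        cached = _iter_cache.get(key) if _iter_cache is not None else None
        if cached is None:
            segs = np.concatenate([data.segs_of_bin(b) for b in sorted(u_set)])
            segs.sort()
            before_objs = []
            seen: set[int] = set()
            for b in u_set:
                for si, _ in self.structure.placements_of(b):
                    if si not in seen:
                        seen.add(si)
                        before_objs.append(old_sc[si])
            before = self._score_block(segs, self._t_bin, before_objs, u_set, self.params)
            cached = (segs, before_objs, before, {})
            if _iter_cache is not None:
                _iter_cache[key] = cached
        segs, before_objs, before, row_cache = cached

        after_objs = [sc for sc in before_objs if id(sc) in new_ids] + added
        # copy-number change of the moved bin, from placement counts alone
        old_copies = sum(1 for sc in changed for p in sc.placed if p.bin_id == a_bin)
        new_copies = sum(1 for sc in added for p in sc.placed if p.bin_id == a_bin)
        d_mult = new_copies - old_copies
        if d_mult == 0:
            t_after = self._t_bin
        else:
            t_after = self._t_bin.copy()
            total = self.structure.multiplicity[a_bin] + d_mult
            t_after[a_bin] = total if total > 0 else UNPLACED_EPS

        after = self._score_block(segs, t_after, after_objs, u_set, self.params)
        delta = after - before
        if d_mult != 0:
            if "row" not in row_cache:
                rest = np.nonzero(~np.isin(data.seg_bin, list(u_set)))[0]
                row_cache["row"] = (
                    rest,
                    self._score_row(
                        a_bin, rest, self._t_bin, before_objs, u_set, self.params
                    ),
                )
            rest, row_before = row_cache["row"]
            a_objs_after = [
                sc
                for sc in after_objs
                if any(p.bin_id == a_bin for p in sc.placed)
            ]
            delta += (
                self._score_row(a_bin, rest, t_after, a_objs_after, u_set, self.params)
                - row_before
            )
        return delta

    # ------------------------------------------------------------- transitions

    def advance(self, new_structure: GenomeStructure, delta: float) -> None:
        self.structure = new_structure
        self.loglik += delta
        self._t_bin = self._make_t(new_structure)
        self._prune_cache()

    def set_params(self, params: NuisanceParams, loglik: float | None = None) -> None:
        self.params = params
        self.loglik = loglik if loglik is not None else self._full_loglik(params)

    def refit_exposure(self) -> None:
        self.exposure = fit_exposure(self.data, self.structure, self.params)
        self.resync()

    def resync(self) -> None:
        """Full recomputation of the cached log-likelihood (drift control)."""
        self._t_bin = self._make_t(self.structure)
        self.loglik = self._full_loglik()


def delta_log_likelihood(
    state: LikelihoodState,
    data: ContactMatrix,
    structure: GenomeStructure,
    move: Mutation,
    params: NuisanceParams,
) -> float:
    """Log-likelihood change of applying ``move``, touching only changed pairs.

    ``structure`` and ``params`` must match the state's current ones (a stale
    state raises ``ValueError``); agreement with full recomputation is within
    1e-6 relative tolerance.
    """
    if structure is not state.structure or data is not state.data:
        raise ValueError("stale likelihood state: structure/data mismatch")
    if params != state.params:
        raise ValueError("stale likelihood state: params mismatch")
    _, delta = state.propose(move)
    return delta
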