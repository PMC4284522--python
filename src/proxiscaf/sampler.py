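"""Multiple-try sampling over genome rearrangements.

Each cycle visits every bin exactly once in a random order.  For the visited
bin, m partner bins are drawn with probabilities proportional to their
measured contacts with it; the 14 moves against each partner define
``14*m`` candidate structures which compete — together with the unchanged
current structure — in a softmax over their log-likelihoods.  The winner is
systematically accepted (no Metropolis rejection on the structure chain).
The nuisance parameters xi = (b, s0, Pt) are updated in alternation by a
classic component-wise Metropolis step with a flat prior inside box bounds.
Each new cycle restarts from the highest-likelihood structure seen during
the previous cycle.

All randomness flows through a single seeded generator in a fixed order
(cycle permutation; copy choice; partner draws; candidate selection;
parameter proposals), so runs are exactly replayable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .genome import GenomeStructure, Mutation, MUTATION_KINDS, apply_mutation, n_contigs
from .model import ContactMatrix, LikelihoodState, NuisanceParams, fit_exposure

__all__ = [
    "SamplerConfig",
    "SampleTrace",
    "TraceRecord",
    "choose_partners",
    "structure_step",
    "nuisance_step",
    "run",
    "dispersion",
    "estimate_params",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Knobs of the sampler.

    ``m`` is the user-defined partner count; ``n_cycles`` times the bin count
    gives the iteration budget; ``burn_in_cycles`` are discarded before any
    posterior summary.  ``selection_temperature`` scales the softmax over
    candidate log-likelihoods (T -> 0 is greedy argmax; T = 1 uses the
    likelihoods as-is).  ``xi_bounds`` boxes (b, s0, Pt); ``proposal_scales``
    are random-walk steps (linear in b, log-scale for s0 and Pt).
    """

    m: int = 3
    n_cycles: int = 20
    burn_in_cycles: int = 2
    seed: int = 0
    selection_temperature: float = 1.0
    partner_pseudocount: float = 0.01
    xi_bounds: tuple[tuple[float, float], ...] = (
        (-4.0, -0.05),
        (1.0e3, 1.0e8),
        (1.0e-16, 1.0e-2),
    )
    proposal_scales: tuple[float, float, float] = (0.02, 0.03, 0.008)
    initial_params: NuisanceParams | None = None
    update_params: bool = True
    refit_exposure_each_cycle: bool = True
    thin: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0 <= self.burn_in_cycles < self.n_cycles:
            raise ValueError("burn_in_cycles must be in [0, n_cycles)")


class TraceRecord(NamedTuple):
    iteration: int
    loglik: float
    n_contigs: int
    b: float
    s0: float
    pt: float
    move_kind: str


@dataclass
class SampleTrace:
    """Per-iteration records plus thinned post-burn-in structures."""

    records: list[TraceRecord]
    retained: list[tuple[int, GenomeStructure]]
    burn_in_iterations: int
    best_structure: GenomeStructure
    best_loglik: float
    final_params: NuisanceParams
    final_exposure: float
    config: SamplerConfig

    def frame(self):
        """Trace as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(self.records, columns=TraceRecord._fields)

    def n_contigs_series(self, from_iteration: int = 0) -> np.ndarray:
        return np.asarray(
            [r.n_contigs for r in self.records if r.iteration >= from_iteration]
        )

    def write(self, path) -> None:
        """Tab-separated trace, one line per iteration."""
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(TraceRecord._fields) + "\n")
            for r in self.records:
                fh.write(
                    f"{r.iteration}\t{r.loglik:.6f}\t{r.n_contigs}\t"
                    f"{r.b:.6g}\t{r.s0:.6g}\t{r.pt:.6g}\t{r.move_kind}\n"
                )

    def write_retained(self, directory) -> None:
        """One layout file per retained (thinned, post-burn-in) structure."""
        from pathlib import Path

        from .genome import write_layout

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for iteration, structure in self.retained:
            write_layout(structure, directory / f"structure_{iteration:07d}.tsv")

    def summary(self, reference: GenomeStructure | None = None) -> dict:
        post = self.n_contigs_series(self.burn_in_iterations)
        out = {
            "median_n_contigs": float(np.median(post)) if post.size else math.nan,
            "iqr_n_contigs": dispersion(self, self.burn_in_iterations),
            "n_iterations": len(self.records),
        }
        if reference is not None:
            from .evaluate import reconstruction_error

            errs = [
                reconstruction_error(s, reference)
                for it, s in self.retained
                if it >= self.burn_in_iterations
            ]
            out["median_error"] = float(np.median(errs)) if errs else math.nan
        return out


def dispersion(trace: SampleTrace, from_iteration: int = 0) -> float:
    """Interquartile range (Q3 - Q1, linear interpolation) of the contig count."""
    values = trace.n_contigs_series(from_iteration)
    if values.size == 0:
        raise ValueError("from_iteration beyond end of trace")
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def choose_partners(
    data: ContactMatrix,
    bin_id: int,
    m: int,
    rng: np.random.Generator,
    structure: GenomeStructure,
    pseudocount: float = 0.01,
) -> list[tuple[int, int]]:
    """Draw m partner placements without replacement.

    Partner bins are drawn with probability proportional to their measured
    contacts with ``bin_id`` plus a pseudocount (so zero-contact partners stay
    reachable); a partner with several copies contributes one copy chosen
    uniformly.  If fewer than m partners are available, all are returned.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    w = data.bin_counts[bin_id].astype(np.float64) + pseudocount
    w[bin_id] = 0.0
    placed = np.asarray([mu > 0 for mu in structure.multiplicity])
    w[~placed] = 0.0
    avail = int(np.count_nonzero(w))
    if avail == 0:
        return []
    take = min(m, avail)
    chosen = rng.choice(data.n_bins, size=take, replace=False, p=w / w.sum())
    partners = []
    for j in chosen:
        copies = structure.placements_of(int(j))
        si, pi = copies[int(rng.integers(len(copies)))]
        partners.append(
            (int(j), structure.scaffolds[si].placed[pi].copy_index)
        )
    return partners


def _softmax_choice(
    logliks: Sequence[float], temperature: float, rng: np.random.Generator
) -> int:
    """Index drawn with probability ~ exp(loglik / T); T <= 0 is greedy argmax
    (ties broken uniformly)."""
    ll = np.asarray(logliks, dtype=np.float64)
    if temperature <= 0:
        best = np.flatnonzero(ll == ll.max())
        return int(best[rng.integers(best.size)])
    z = (ll - ll.max()) / temperature
    p = np.exp(z)
    p /= p.sum()
    return int(rng.choice(ll.size, p=p))


def _bin_placement(
    structure: GenomeStructure, bin_id: int, rng: np.random.Generator
) -> tuple[int, int | None]:
    copies = structure.placements_of(bin_id)
    if not copies:
        return (bin_id, None)
    si, pi = copies[int(rng.integers(len(copies)))]
    return (bin_id, structure.scaffolds[si].placed[pi].copy_index)


def _structure_step_engine(
    state: LikelihoodState,
    bin_placement: tuple[int, int | None],
    partners: list[tuple[int, int]],
    temperature: float,
    rng: np.random.Generator,
) -> tuple[Mutation | None, float]:
    """Score 14*m candidates plus the null candidate and accept the winner."""
    candidates: list[tuple[Mutation | None, GenomeStructure | None, float]] = [
        (None, None, 0.0)
    ]
    iter_cache: dict = {}
    for partner in partners:
        for kind in MUTATION_KINDS:
            move = Mutation(kind, bin_placement, partner)
            new_structure, delta = state.propose(move, iter_cache)
            candidates.append((move, new_structure, delta))
    deltas = [c[2] for c in candidates]
    pick = _softmax_choice(deltas, temperature, rng)
    move, new_structure, delta = candidates[pick]
    if move is not None:
        state.advance(new_structure, delta)
    return move, delta


def structure_step(
    structure: GenomeStructure,
    data: ContactMatrix,
    params: NuisanceParams,
    bin_id: int,
    config: SamplerConfig,
    rng: np.random.Generator,
    exposure: float | None = None,
) -> tuple[GenomeStructure, Mutation | None, float]:
    """One multiple-try update of the visited bin (standalone convenience form).

    Returns the systematically accepted structure, the chosen move (``None``
    when the null candidate won) and its log-likelihood change.
    """
    if exposure is None:
        exposure = fit_exposure(data, structure, params)
    state = LikelihoodState(data, structure, params, exposure)
    placement = _bin_placement(structure, bin_id, rng)
    partners = choose_partners(
        data, bin_id, config.m, rng, structure, config.partner_pseudocount
    )
    move, delta = _structure_step_engine(
        state, placement, partners, config.selection_temperature, rng
    )
    return state.structure, move, delta


def _metropolis_params(
    state: LikelihoodState, config: SamplerConfig, rng: np.random.Generator
) -> None:
    """Component-wise Metropolis on (b, s0, Pt) with a flat prior in the box."""
    scales = config.proposal_scales
    for comp in range(3):
        noise = rng.normal()
        u = rng.random()
        b, s0, pt = state.params.as_tuple()
        if comp == 0:
            prop = (b + scales[0] * noise, s0, pt)
        elif comp == 1:
            prop = (b, s0 * math.exp(scales[1] * noise), pt)
        else:
            prop = (b, s0, pt * math.exp(scales[2] * noise))
        lo_hi = config.xi_bounds[comp]
        if not lo_hi[0] <= prop[comp] <= lo_hi[1]:
            continue
        new_params = NuisanceParams(*prop)
        new_ll = state._full_loglik(new_params)
        if math.log(u) < new_ll - state.loglik:
            state.set_params(new_params, new_ll)


def nuisance_step(
    params: NuisanceParams,
    structure: GenomeStructure,
    data: ContactMatrix,
    config: SamplerConfig,
    rng: np.random.Generator,
    exposure: float | None = None,
) -> NuisanceParams:
    """Standalone Metropolis sweep over the three nuisance parameters."""
    if exposure is None:
        exposure = fit_exposure(data, structure, params)
    state = LikelihoodState(data, structure, params, exposure)
    _metropolis_params(state, config, rng)
    return state.params


def estimate_params(
    data: ContactMatrix,
    structure: GenomeStructure,
    bounds: tuple[tuple[float, float], ...] = SamplerConfig.xi_bounds,
) -> NuisanceParams:
    """Initial xi from the structure's own contact-versus-distance curve.

    Fits the power-law exponent by least squares on log-binned cis rates, the
    trans level from the mean trans rate, and s0 from where the fitted law
    crosses that level.  Falls back to mild defaults when the initial
    structure exposes too few informative cis pairs (e.g. every bin its own
    scaffold, or a fully scrambled arrangement with a flat curve).
    """
    from .model import _scaffold_positions

    rate_all = data.seg_counts / data._L2
    n = data.n_segs
    cis_mask = np.zeros((n, n), dtype=bool)
    s_cis: list[np.ndarray] = []
    r_cis: list[np.ndarray] = []
    for si in range(len(structure.scaffolds)):
        idx, pos, _ = _scaffold_positions(structure, data, si)
        if idx.size < 2:
            continue
        ii, jj = np.triu_indices(idx.size, k=1)
        gi, gj = idx[ii], idx[jj]
        cis_mask[gi, gj] = True
        cis_mask[gj, gi] = True
        d = np.abs(pos[ii] - pos[jj])
        d = np.maximum(d, data._floor[gi, gj])
        s_cis.append(d)
        r_cis.append(rate_all[gi, gj])
    trans = ~cis_mask
    np.fill_diagonal(trans, False)
    if trans.any():
        pt = float(data.seg_counts[trans].sum() / data._L2[trans].sum())
    else:
        pt = float(data.total_contacts / ((data._L2.sum() + np.trace(data._L2)) / 2))
    pt = float(np.clip(pt, bounds[2][0], bounds[2][1]))

    b_hat, s0_hat = -1.0, 20.0 * float(np.median(data.seg_len))
    if s_cis:
        s = np.concatenate(s_cis)
        r = np.concatenate(r_cis)
        edges = np.geomspace(s.min(), s.max() + 1, 16)
        which = np.digitize(s, edges) - 1
        xs, ys = [], []
        for k in range(len(edges) - 1):
            sel = which == k
            if sel.sum() >= 3:
                mean_rate = r[sel].mean()
                if mean_rate > 1.5 * pt:
                    xs.append(np.log(np.median(s[sel])))
                    ys.append(np.log(mean_rate))
        if len(xs) >= 3:
            slope, intercept = np.polyfit(xs, ys, 1)
            if slope < 0:
                b_hat = float(slope)
                # Pc(s0) = pt  =>  log s0 = (log pt - intercept) / slope
                s0_hat = float(np.exp((np.log(pt) - intercept) / slope))
    b_hat = float(np.clip(b_hat, bounds[0][0], bounds[0][1]))
    s0_hat = float(np.clip(s0_hat, bounds[1][0], bounds[1][1]))
    return NuisanceParams(b=b_hat, s0=s0_hat, pt=pt)


def run(
    data: ContactMatrix,
    initial: GenomeStructure,
    config: SamplerConfig,
) -> SampleTrace:
    """Full sampling run: ``n_cycles`` cycles over random bin permutations.

    Each iteration performs one multiple-try structure update followed by a
    Metropolis sweep of the nuisance parameters; each new cycle restarts from
    the best structure of the previous cycle, and the exposure constant is
    refit at cycle starts.  Deterministic given ``config.seed``.
    """
    if data.total_contacts <= 0:
        raise ValueError("empty contact matrix")
    if len(initial.bins) != data.n_bins:
        raise ValueError("structure/matrix dimension mismatch")
    rng = np.random.default_rng(config.seed)
    n_bins = data.n_bins
    thin = config.thin if config.thin is not None else max(1, n_bins // 10)
    burn_in_iterations = config.burn_in_cycles * n_bins

    params = config.initial_params or estimate_params(data, initial, config.xi_bounds)
    exposure = fit_exposure(data, initial, params)
    state = LikelihoodState(data, initial, params, exposure)

    records: list[TraceRecord] = []
    retained: list[tuple[int, GenomeStructure]] = []
    best_structure, best_ll = state.structure, state.loglik
    iteration = 0

    for cycle in range(config.n_cycles):
        if cycle > 0:
            state.structure = cycle_best[1]
            state.resync()
        if config.refit_exposure_each_cycle:
            state.refit_exposure()
        cycle_best = (state.loglik, state.structure)

        for bin_id in rng.permutation(n_bins):
            placement = _bin_placement(state.structure, int(bin_id), rng)
            partners = choose_partners(
                data, int(bin_id), config.m, rng, state.structure,
                config.partner_pseudocount,
            )
            move, _ = _structure_step_engine(
                state, placement, partners, config.selection_temperature, rng
            )
            if config.update_params:
                _metropolis_params(state, config, rng)

            if state.loglik > cycle_best[0]:
                cycle_best = (state.loglik, state.structure)
            if state.loglik > best_ll:
                best_structure, best_ll = state.structure, state.loglik

            records.append(
                TraceRecord(
                    iteration,
                    state.loglik,
                    n_contigs(state.structure),
                    state.params.b,
                    state.params.s0,
                    state.params.pt,
                    move.kind.value if move is not None else "none",
                )
            )
            if iteration >= burn_in_iterations and iteration % thin == 0:
                retained.append((iteration, state.structure))
            iteration += 1

    return SampleTrace(
        records=records,
        retained=retained,
        burn_in_iterations=burn_in_iterations,
        best_structure=best_structure,
        best_loglik=best_ll,
        final_params=state.params,
        final_exposure=state.exposure,
        config=config,
    )
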