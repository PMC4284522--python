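"""Contact model: intensities, Poisson likelihood, incremental deltas.

The reference oracle is a plain-Python scalar loop over all segment pairs,
independent of the vectorized implementation it checks.
"""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from proxiscaf.genome import (
    Bin,
    GenomeStructure,
    Mutation,
    MutationKind,
    MUTATION_KINDS,
    PairGeometry,
    apply_mutation,
)
from proxiscaf.model import (
    ContactMatrix,
    LikelihoodState,
    NuisanceParams,
    UNPLACED_EPS,
    contact_probability,
    delta_log_likelihood,
    expected_count,
    fit_exposure,
    log_likelihood,
)
from proxiscaf.simulate import SimulationSpec, scramble, simulate_contacts, yeast_like_genome

from conftest import PARAMS, random_placed_pair


# ------------------------------------------------------------------ oracle


def oracle_loglik(data, structure, params, exposure):
    """Scalar-loop Poisson log-likelihood over all segment pairs."""
    # segment placements: (scaffold_id or None, position) per copy
    placements = {s: [] for s in range(data.n_segs)}
    for si, sc in enumerate(structure.scaffolds):
        x = 0.0
        for p in sc.placed:
            segs = list(data.segs_of_bin(p.bin_id))
            L = sum(data.seg_len[s] for s in segs)
            for s in segs:
                mid = data.seg_mid_in_bin[s]
                if p.orientation < 0:
                    mid = L - mid
                placements[s].append((si, x + mid))
            x += L

    def intensity(p_seg, q_seg):
        tp = len(placements[p_seg]) or UNPLACED_EPS
        tq = len(placements[q_seg]) or UNPLACED_EPS
        total = params.pt * tp * tq
        floor = max(1.0, 0.5 * min(data.seg_len[p_seg], data.seg_len[q_seg]))
        for sp, xp in placements[p_seg]:
            for sq, xq in placements[q_seg]:
                if sp == sq:
                    s = max(abs(xp - xq), floor)
                    if s < params.s0:
                        total += params.pt * ((s / params.s0) ** params.b - 1.0)
        return total

    ll = 0.0
    for p in range(data.n_segs):
        for q in range(p, data.n_segs):
            lam = exposure * data.seg_len[p] * data.seg_len[q] * intensity(p, q)
            k = data.seg_counts[p, q]
            ll += k * math.log(lam) - lam - gammaln(k + 1.0)
    return ll


# --------------------------------------------------------------- unit tests


class TestContactProbability:
    def test_continuity_at_plateau_onset(self):
        g = PairGeometry(s=PARAMS.s0, is_trans=False)
        assert contact_probability(g, PARAMS) == pytest.approx(PARAMS.pt)

    def test_trans_is_flat_in_b(self):
        g = PairGeometry(s=float("nan"), is_trans=True)
        for b in (-0.5, -1.0, -3.0):
            p = NuisanceParams(b, PARAMS.s0, PARAMS.pt)
            assert contact_probability(g, p) == PARAMS.pt

    def test_power_law_hand_value(self):
        p = NuisanceParams(-1.0, 1.0e5, 2.0e-9)
        g = PairGeometry(s=p.s0 / 2, is_trans=False)
        assert contact_probability(g, p) == pytest.approx(2 * p.pt)

    def test_monotone_decay(self):
        ss = np.linspace(1e3, 5e5, 200)
        vals = [
            contact_probability(PairGeometry(s=s, is_trans=False), PARAMS) for s in ss
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NuisanceParams(-1.5, -1.0, 1e-9)
        with pytest.raises(ValueError):
            NuisanceParams(-1.5, 1e5, 0.0)
        with pytest.raises(ValueError):
            NuisanceParams(0.5, 1e5, 1e-9)


class TestExpectedCount:
    @pytest.fixture
    def setup(self, toy_bins, toy_structure):
        data = ContactMatrix.empty(toy_bins)
        return data, toy_structure

    def test_trans_pair_definition(self, setup):
        data, st = setup
        lam = expected_count(data, st, 0, 3, PARAMS, exposure=2.0)
        assert lam == pytest.approx(2.0 * PARAMS.pt * 1e4 * 1e4)

    def test_symmetry(self, setup):
        data, st = setup
        assert expected_count(data, st, 1, 2, PARAMS) == pytest.approx(
            expected_count(data, st, 2, 1, PARAMS)
        )

    def test_duplicated_bin_doubles_trans_lambda(self, toy_bins, toy_structure):
        data = ContactMatrix.empty(toy_bins)
        dup = apply_mutation(
            toy_structure, Mutation(MutationKind.DUP_AFTER_FWD, (0, 0), (1, 0))
        )
        base = expected_count(data, toy_structure, 0, 3, PARAMS)
        doubled = expected_count(data, dup, 0, 3, PARAMS)
        assert doubled == pytest.approx(2 * base)


class TestLogLikelihood:
    def test_matches_oracle_on_toy(self, small_genome, small_data):
        st = scramble(small_genome, 4)
        expo = fit_exposure(small_data, st, PARAMS)
        fast = log_likelihood(small_data, st, PARAMS, expo)
        slow = oracle_loglik(small_data, st, PARAMS, expo)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_oracle_with_duplication_and_deletion(self, small_genome, small_data):
        st = apply_mutation(
            small_genome, Mutation(MutationKind.DUP_AFTER_FWD, (3, 0), (8, 0))
        )
        st = apply_mutation(st, Mutation(MutationKind.DELETE, (12, 0)))
        expo = fit_exposure(small_data, st, PARAMS)
        assert log_likelihood(small_data, st, PARAMS, expo) == pytest.approx(
            oracle_loglik(small_data, st, PARAMS, expo), rel=1e-10
        )

    def test_scrambling_decreases_likelihood(self, small_genome, small_data):
        expo = fit_exposure(small_data, small_genome, PARAMS)
        ll_truth = log_likelihood(small_data, small_genome, PARAMS, expo)
        for seed in range(50):
            sc = scramble(small_genome, seed)
            if sc.equivalent(small_genome):
                continue
            assert log_likelihood(small_data, sc, PARAMS, expo) < ll_truth

    def test_dimension_mismatch_rejected(self, small_genome, toy_bins):
        other = ContactMatrix.empty(toy_bins)
        with pytest.raises(ValueError):
            log_likelihood(other, small_genome, PARAMS)

    def test_poisson_normalization(self):
        # sum_k p(k | lam) = 1 for the pmf implied by the likelihood terms
        for lam in (0.5, 5.0, 50.0):
            ks = np.arange(0, 201)
            logp = ks * np.log(lam) - lam - gammaln(ks + 1.0)
            assert np.exp(logp).sum() == pytest.approx(1.0, abs=1e-9)

    def test_truth_beats_single_move_neighbors(self, medium_genome):
        data = simulate_contacts(
            SimulationSpec(medium_genome, PARAMS, 1_000_000, seed=3)
        )
        expo = fit_exposure(data, medium_genome, PARAMS)
        ll_truth = log_likelihood(data, medium_genome, PARAMS, expo)
        rng = np.random.default_rng(0)
        state = LikelihoodState(data, medium_genome, PARAMS, expo)
        for _ in range(100):
            a, b = random_placed_pair(medium_genome, rng)
            kind = MUTATION_KINDS[rng.integers(14)]
            new_s, delta = state.propose(Mutation(kind, a, b))
            if new_s.equivalent(medium_genome):
                continue
            assert delta < 1e-6, f"{kind} improved on truth"


class TestDelta:
    def test_identity_move_is_zero(self, small_genome, small_data):
        expo = fit_exposure(small_data, small_genome, PARAMS)
        state = LikelihoodState(small_data, small_genome, PARAMS, expo)
        # re-delete an unplaced bin: structurally the identity
        gone = apply_mutation(small_genome, Mutation(MutationKind.DELETE, (0, 0)))
        state = LikelihoodState(small_data, gone, PARAMS, expo)
        d = delta_log_likelihood(
            state, small_data, gone, Mutation(MutationKind.DELETE, (0, None)), PARAMS
        )
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_full_recomputation(self, small_genome, small_data):
        """>=200 random moves: delta equals full recomputation to 1e-6 rel."""
        rng = np.random.default_rng(1)
        st = scramble(small_genome, 9)
        expo = fit_exposure(small_data, st, PARAMS)
        state = LikelihoodState(small_data, st, PARAMS, expo)
        for trial in range(220):
            a, b = random_placed_pair(state.structure, rng)
            kind = MUTATION_KINDS[rng.integers(14)]
            new_s, delta = state.propose(Mutation(kind, a, b))
            full = log_likelihood(small_data, new_s, PARAMS, expo) - log_likelihood(
                small_data, state.structure, PARAMS, expo
            )
            assert delta == pytest.approx(full, rel=1e-6, abs=1e-6)
            if trial % 4 == 0:
                state.advance(new_s, delta)

    def test_delete_then_reinsert_round_trip(self, small_genome, small_data):
        expo = fit_exposure(small_data, small_genome, PARAMS)
        state = LikelihoodState(small_data, small_genome, PARAMS, expo)
        si, pi = small_genome.placements_of(5)[0]
        neighbor = small_genome.scaffolds[si].placed[pi - 1]
        gone, d1 = state.propose(Mutation(MutationKind.DELETE, (5, 0)))
        state.advance(gone, d1)
        back, d2 = state.propose(
            Mutation(
                MutationKind.TRANSPOSE_AFTER_FWD,
                (5, None),
                (neighbor.bin_id, neighbor.copy_index),
            )
        )
        assert back.equivalent(small_genome)
        assert d1 + d2 == pytest.approx(0.0, abs=1e-6)

    def test_stale_state_rejected(self, small_genome, small_data):
        expo = fit_exposure(small_data, small_genome, PARAMS)
        state = LikelihoodState(small_data, small_genome, PARAMS, expo)
        other = scramble(small_genome, 2)
        with pytest.raises(ValueError):
            delta_log_likelihood(
                state,
                small_data,
                other,
                Mutation(MutationKind.DELETE, (0, 0)),
                PARAMS,
            )


class TestExposure:
    def test_linearity(self, small_genome, small_data):
        e1 = fit_exposure(small_data, small_genome, PARAMS)
        doubled = ContactMatrix(small_data.bins, small_data.seg_counts * 2)
        e2 = fit_exposure(doubled, small_genome, PARAMS)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)
        assert e1 > 0

    def test_simulation_exposure_recovered(self, small_genome):
        from proxiscaf.model import _intensity_full

        n = 2_000_000
        data = simulate_contacts(SimulationSpec(small_genome, PARAMS, n, seed=5))
        # the exposure the simulator used to hit the requested total
        raw = data._L2 * _intensity_full(data, small_genome, PARAMS)
        exposure_sim = n / ((raw.sum() + np.trace(raw)) / 2.0)
        exposure_fit = fit_exposure(data, small_genome, PARAMS)
        assert exposure_fit == pytest.approx(exposure_sim, rel=0.01)

    def test_all_zero_matrix_rejected(self, toy_bins, toy_structure):
        empty = ContactMatrix.empty(toy_bins)
        with pytest.raises(ValueError):
            fit_exposure(empty, toy_structure, PARAMS)


class TestDuplicationSignature:
    def test_lambda_adds_over_copies(self, toy_bins, toy_structure):
        """lambda_ij with two copies equals the sum of the single-copy rows."""
        data = ContactMatrix.empty(toy_bins)
        both = apply_mutation(
            toy_structure, Mutation(MutationKind.DUP_AFTER_FWD, (0, 0), (4, 0))
        )
        other = apply_mutation(
            toy_structure, Mutation(MutationKind.TRANSPOSE_AFTER_FWD, (0, 0), (4, 0))
        )
        for j in range(1, 6):
            lam_two = expected_count(data, both, 0, j, PARAMS)
            lam_a = expected_count(data, toy_structure, 0, j, PARAMS)
            lam_b = expected_count(data, other, 0, j, PARAMS)
            assert lam_two == pytest.approx(lam_a + lam_b, rel=1e-9)

    def test_collapsing_halves_trans_row(self, toy_bins):
        """A bin trans to both copies sees exactly twice the single-copy rate."""
        st3 = GenomeStructure.from_arrangement(
            toy_bins, [[(0, 1), (1, 1)], [(2, 1), (3, 1)], [(4, 1), (5, 1)]]
        )
        data = ContactMatrix.empty(toy_bins)
        dup = apply_mutation(
            st3, Mutation(MutationKind.DUP_AFTER_FWD, (0, 0), (2, 0))
        )
        # bin 4 is trans to both copies of bin 0
        assert expected_count(data, dup, 0, 4, PARAMS) == pytest.approx(
            2 * expected_count(data, st3, 0, 4, PARAMS), rel=1e-12
        )
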