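"""Configuration enumeration, master-equation steady state, boundary chain."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppdkrp import (
    DomainError,
    ReducibleChainError,
    binary_event_probability,
    boundary_chain_distribution,
    build_master_model,
    canonical_form,
    enumerate_configurations,
    gillespie_simulate,
    master_steady_state,
)

# Figure-5-scale parameters: Vk = Vp = 0.2 koff -> mu/eta = 1/6, eta ~ 1
MU = binary_event_probability(0.2, 0.2, 1.0, 1.0)
TWO_STATE_RATES = {"mu": MU, "eta1": 1.0, "eta2": 1.0}


class TestEnumeration:
    @pytest.mark.parametrize(
        "n,k,expected",
        [(4, 3, 21), (4, 2, 6), (4, 1, 1), (2, 3, 6), (3, 3, 10), (6, 2, 13)],
    )
    def test_class_counts(self, n, k, expected):
        # counts cross-checked by Burnside's lemma on the dihedral group
        assert len(enumerate_configurations(n, k)) == expected

    def test_multiplicities_partition_raw_assignments(self):
        configs = enumerate_configurations(4, 3)
        assert sum(c.multiplicity for c in configs) == 3**4

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=8))
    def test_canonicalization_idempotent(self, states):
        c = canonical_form(states)
        assert canonical_form(c) == c

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=8),
           st.integers(0, 15))
    def test_canonical_form_is_symmetry_invariant(self, states, k):
        n = len(states)
        rot = tuple(states[k % n:] + states[: k % n])
        assert canonical_form(rot) == canonical_form(states)
        assert canonical_form(rot[::-1]) == canonical_form(states)


class TestMasterModel:
    def test_columns_sum_to_zero(self):
        model = build_master_model(4, TWO_STATE_RATES, "two_state")
        assert np.abs(model.W.sum(axis=0)).max() < 1e-12

    def test_pure_classes_have_no_ternary_events(self):
        model = build_master_model(4, TWO_STATE_RATES, "two_state")
        i_all1 = model.index[(1, 1, 1, 1)]
        kinds = {k for (i, j, r, k) in model.edges if i == i_all1}
        assert kinds == {"binary"}

    def test_checkerboard_ternary_outflow(self):
        """(1,2,1,2) has 4 mixed adjacent pairs: ternary outflow 4(eta1+eta2)."""
        rates = {"mu": 0.1, "eta1": 0.7, "eta2": 0.3}
        model = build_master_model(4, rates, "two_state")
        i_cb = model.index[canonical_form((1, 2, 1, 2))]
        ternary = sum(r for (i, j, r, k) in model.edges
                      if i == i_cb and k == "ternary")
        assert ternary == pytest.approx(4 * (0.7 + 0.3))

    def test_missing_rates_rejected(self):
        with pytest.raises(DomainError):
            build_master_model(4, {"mu": 0.1}, "two_state")
        with pytest.raises(DomainError):
            build_master_model(4, TWO_STATE_RATES, "three_state")


class TestSteadyState:
    def test_swap_symmetry(self):
        dist = master_steady_state(
            build_master_model(4, TWO_STATE_RATES, "two_state"))
        assert dist.prob([1, 1, 1, 1]) == pytest.approx(dist.prob([2, 2, 2, 2]),
                                                        rel=1e-10)
        assert sum(dist.probabilities.values()) == pytest.approx(1.0, abs=1e-10)

    def test_bimodality_and_checkerboard_rarity(self):
        """All-S1/all-S2 dominate; the checkerboard is the rarest class."""
        model = build_master_model(4, TWO_STATE_RATES, "two_state")
        dist = master_steady_state(model)
        p = dist.probabilities
        pure = {(1, 1, 1, 1), (2, 2, 2, 2)}
        p_mixed_max = max(v for c, v in p.items() if c not in pure)
        assert p[(1, 1, 1, 1)] > p_mixed_max
        assert p[(2, 2, 2, 2)] > p_mixed_max
        cb = canonical_form((1, 2, 1, 2))
        assert p[cb] == min(p.values())

    def test_clustering_beats_fragmentation(self):
        """One contiguous S1 domain outweighs the split same-composition class."""
        dist = master_steady_state(
            build_master_model(4, TWO_STATE_RATES, "two_state"))
        assert dist.prob([1, 1, 2, 2]) > dist.prob([1, 2, 1, 2])

    def test_fast_binary_limit_is_binomial(self):
        """mu >> eta: subunits decouple and classes follow multiplicity/2^n."""
        model = build_master_model(4, {"mu": 1e4, "eta1": 1.0, "eta2": 1.0},
                                   "two_state")
        dist = master_steady_state(model)
        for c in model.configs:
            assert dist.probabilities[c.states] == pytest.approx(
                c.multiplicity / 16.0, rel=1e-3)

    def test_reducible_without_binary_events(self):
        model = build_master_model(4, {"mu": 0.0, "eta1": 1.0, "eta2": 1.0},
                                   "two_state")
        with pytest.raises(ReducibleChainError):
            master_steady_state(model)

    def test_lumping_matches_full_chain(self):
        """Class-level steady state equals the raw 2^4-state chain aggregated."""
        rates = {"mu": 0.21, "eta1": 0.9, "eta2": 0.6}
        model = build_master_model(4, rates, "two_state")
        dist = master_steady_state(model)

        # independent brute-force chain over all 16 raw configurations
        raw_states = list(product((1, 2), repeat=4))
        idx = {s: i for i, s in enumerate(raw_states)}
        W = np.zeros((16, 16))
        for s in raw_states:
            for pos in range(4):
                flip = s[:pos] + (3 - s[pos],) + s[pos + 1:]
                W[idx[flip], idx[s]] += rates["mu"]
            for pos in range(4):
                a, b = s[pos], s[(pos + 1) % 4]
                if {a, b} == {1, 2}:
                    i1 = pos if a == 1 else (pos + 1) % 4
                    i2 = pos if a == 2 else (pos + 1) % 4
                    up = s[:i1] + (2,) + s[i1 + 1:]
                    dn = s[:i2] + (1,) + s[i2 + 1:]
                    W[idx[up], idx[s]] += rates["eta1"]
                    W[idx[dn], idx[s]] += rates["eta2"]
        np.fill_diagonal(W, W.diagonal() - W.sum(axis=0))
        A = np.vstack([W[:-1], np.ones(16)])
        b = np.zeros(16)
        b[-1] = 1.0
        p_raw, *_ = np.linalg.lstsq(A, b, rcond=None)
        for c in model.configs:
            agg = sum(p_raw[idx[s]] for s in raw_states
                      if canonical_form(s) == c.states)
            assert dist.probabilities[c.states] == pytest.approx(agg, abs=1e-10)

    def test_three_state_s0_mass_shrinks_with_delta_ratio(self):
        """delta1 > delta2 drains PPDK0, pushing mass into the S1/S2 cycle."""
        def s0_mass(ratio):
            rates = {"mu": MU, "eta1": 1.0, "eta2": 1.0,
                     "delta1": 0.01 * ratio, "delta2": 0.01}
            dist = master_steady_state(
                build_master_model(4, rates, "three_state"))
            return sum(p for c, p in dist.probabilities.items() if 0 in c)

        masses = [s0_mass(r) for r in (1.0, 1.5, 2.5)]
        assert masses[0] > masses[1] > masses[2]


class TestBinaryEventProbability:
    def test_arithmetic_and_limits(self):
        assert binary_event_probability(0.2, 0.2, 1.0, 1.0) == pytest.approx(1 / 6)
        assert binary_event_probability(1e-4, 1e-4, 1.0, 1.0) == pytest.approx(
            1e-4, rel=1e-3)
        assert binary_event_probability(1e6, 1e6, 1.0, 1.0) == pytest.approx(
            1.0, rel=1e-5)


class TestGillespie:
    def test_seed_determinism(self):
        model = build_master_model(4, TWO_STATE_RATES, "two_state")
        d1, t1 = gillespie_simulate(model, 20_000, seed=11)
        d2, t2 = gillespie_simulate(model, 20_000, seed=11)
        assert t1 == t2
        assert d1.probabilities == d2.probabilities

    def test_converges_to_analytic_distribution(self):
        model = build_master_model(4, TWO_STATE_RATES, "two_state")
        analytic = master_steady_state(model)
        emp, _ = gillespie_simulate(model, 200_000, seed=5)
        tv = 0.5 * sum(abs(emp.probabilities[c.states]
                           - analytic.probabilities[c.states])
                       for c in model.configs)
        assert tv < 0.02

    def test_ternary_share_grows_with_eta(self):
        tallies = {}
        for mu in (0.5, 0.05, 0.005):
            model = build_master_model(
                4, {"mu": mu, "eta1": 1.0, "eta2": 1.0}, "two_state")
            _, t = gillespie_simulate(model, 50_000, seed=2)
            tallies[mu] = t["ternary"] / max(t["binary"], 1)
        assert tallies[0.005] > tallies[0.05] > tallies[0.5]


class TestBoundaryChain:
    def test_symmetric_closed_form(self):
        """eps = eta, n = 4: N(0) = N(4) = 1/8, interior 1/4 (to 1e-12)."""
        occ = boundary_chain_distribution(4, 1.0, 1.0, 1.0, 1.0)
        assert occ == pytest.approx([0.125, 0.25, 0.25, 0.25, 0.125], abs=1e-12)

    @pytest.mark.parametrize("ratio", [0.01, 0.3, 1.0])
    def test_tetramer_closed_form_for_symmetric_rates(self, ratio):
        """n = 4: N(0) = N(4) = eta/(2(n-1)eps + 2 eta), N(i) = eps/((n-1)eps + eta)."""
        n, eps, eta = 4, ratio, 1.0
        occ = boundary_chain_distribution(n, eps, eps, eta, eta)
        n0 = eta / (2 * (n - 1) * eps + 2 * eta)
        ni = eps / ((n - 1) * eps + eta)
        expect = [n0] + [ni] * (n - 1) + [n0]
        assert occ == pytest.approx(expect, abs=1e-12)
        assert occ.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4, 6, 10])
    @pytest.mark.parametrize("ratio", [0.01, 0.3, 1.0])
    def test_general_n_closed_form_for_symmetric_rates(self, n, ratio):
        """By hand from the balance equations: the boundary condition
        n*eps*N(0) = 2*eta*N(1) forces all interior states to the common value
        (n*eps/2*eta) * N(0); normalization fixes N(0)."""
        eps, eta = ratio, 1.0
        occ = boundary_chain_distribution(n, eps, eps, eta, eta)
        n0 = 2 * eta / (4 * eta + n * (n - 1) * eps)
        ni = n * eps / (2 * eta) * n0
        expect = [n0] + [ni] * (n - 1) + [n0]
        assert occ == pytest.approx(expect, abs=1e-12)

    def test_rare_binary_limit_pins_boundaries(self):
        occ = boundary_chain_distribution(4, 1e-9, 1e-9, 1.0, 1.0)
        assert occ[0] == pytest.approx(0.5, abs=1e-6)
        assert occ[-1] == pytest.approx(0.5, abs=1e-6)
        assert occ[1:-1].max() < 1e-6

    def test_bulk_boundary_ratio_scales_as_eps_over_eta(self):
        eps, eta = 0.01, 1.0
        occ = boundary_chain_distribution(5, eps, eps, eta, eta)
        ratio = occ[1] / occ[0]
        assert ratio == pytest.approx(5 * eps / (2 * eta), rel=1e-9)
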