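import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from conftest import dimer_stationary_mean, toy_network
from moblue.engine import (
    CompiledNetwork,
    RateParams,
    SimState,
    effective_rate_constant,
    propensity,
    run,
    run_ensemble,
    step,
)
from moblue.network import Reaction, Species, default_network


class TestEffectiveRateConstant:
    def test_template_presence_gives_exact_factor(self):
        species = [Species("A", 1), Species("B", 1), Species("C", 2, "corner_dimer_path", 10)]
        rx = Reaction("synthesis", ("A", "B"), ("C",), base_k=1.0, template_id="A")
        net = toy_network(species, [rx])
        p = RateParams(k_nano=0.0)
        k_absent = effective_rate_constant(rx, net, p, {"A": 0})
        k_present = effective_rate_constant(rx, net, p, {"A": 3})
        assert k_present / k_absent == pytest.approx(10.0)

    def test_zero_knano_disables_completion_bias(self):
        species = [Species("A", 1), Species("B", 1), Species("C", 2, "edge_dimer_path", 3)]
        rx = Reaction("synthesis", ("A", "B"), ("C",), base_k=2.0)
        net = toy_network(species, [rx])
        k0 = effective_rate_constant(rx, net, RateParams(k_nano=0.0))
        k1 = effective_rate_constant(rx, net, RateParams(k_nano=8.0))
        assert k1 / k0 == pytest.approx(1 + 8.0 / (1 + 3))
        # reduced-mass prefactor for two unit masses: sqrt(T/0.5)
        assert k0 == pytest.approx(2.0 * math.sqrt(2.0))

    def test_reduced_mass_scaling_sqrt2(self):
        # monomer+monomer (mu=1/2) vs dimer+dimer (mu=1): ratio sqrt(2)
        species = [
            Species("M", 1), Species("D", 2), Species("P2", 2), Species("P4", 4),
        ]
        rx_m = Reaction("synthesis", ("M", "M"), ("P2",), base_k=1.0)
        rx_d = Reaction("synthesis", ("D", "D"), ("P4",), base_k=1.0)
        net = toy_network(species, [rx_m, rx_d])
        p = RateParams(k_nano=0.0)
        ratio = effective_rate_constant(rx_m, net, p) / effective_rate_constant(rx_d, net, p)
        assert ratio == pytest.approx(math.sqrt(2.0))

    def test_degradation_returns_base_k(self):
        species = [Species("A", 1), Species("B", 1), Species("C", 2)]
        rx = Reaction("degradation", ("C",), ("A", "B"), base_k=0.37)
        net = toy_network(species, [rx])
        assert effective_rate_constant(rx, net, RateParams()) == 0.37


class TestPropensity:
    @pytest.mark.parametrize(
        "kind, reactants, counts, k, expected",
        [
            ("degradation", ("C",), {"C": 5}, 1.0, 5.0),
            ("synthesis", ("A", "B"), {"A": 3, "B": 4}, 2.0, 24.0),
            ("synthesis", ("A", "A"), {"A": 4}, 1.0, 6.0),
        ],
    )
    def test_mass_action_forms(self, kind, reactants, counts, k, expected):
        species = [Species("A", 1), Species("B", 1), Species("C", 2)]
        products = ("C",) if kind == "synthesis" else ("A", "B")
        rx = Reaction(kind, reactants, products, base_k=k, plain_rate=True)
        net = toy_network(species, [rx])
        assert propensity(rx, counts, net, RateParams()) == pytest.approx(expected)


class TestStep:
    def test_waiting_time_matches_exponential_rate(self, params):
        species = [Species("A", 2), Species("B", 1), Species("C", 1)]
        rx = Reaction("degradation", ("A",), ("B", "C"), base_k=1.0)
        compiled = CompiledNetwork(toy_network(species, [rx]), params)
        rng = np.random.default_rng(0)
        waits = []
        for _ in range(3000):
            state = SimState(0.0, compiled.counts_vector({"A": 1000}))
            new, fired = step(state, compiled, rng=rng)
            assert fired == 0
            waits.append(new.time)
        mean = np.mean(waits)
        assert mean == pytest.approx(1 / 1000, rel=0.1)

    def test_zero_counts_fire_nothing(self, params):
        species = [Species("A", 2), Species("B", 1), Species("C", 1)]
        rx = Reaction("degradation", ("A",), ("B", "C"), base_k=1.0)
        compiled = CompiledNetwork(toy_network(species, [rx]), params)
        state = SimState(0.0, compiled.counts_vector({}))
        new, fired = step(state, compiled, rng=np.random.default_rng(1), horizon=7.0)
        assert fired is None and new.time == 7.0

    def test_selection_frequencies_proportional_to_propensity(self, params):
        # two degradation channels with propensities 3 : 1
        species = [Species("A", 2), Species("B", 1), Species("C", 1)]
        rxs = [
            Reaction("degradation", ("A",), ("B", "C"), base_k=3.0),
            Reaction("degradation", ("A",), ("C", "B"), base_k=1.0),
        ]
        compiled = CompiledNetwork(toy_network(species, rxs), params)
        rng = np.random.default_rng(2)
        state = SimState(0.0, compiled.counts_vector({"A": 50}))
        first = 0
        trials = 10_000
        for _ in range(trials):
            _, fired = step(state, compiled, rng=rng)
            first += fired == 0
        freq = first / trials
        assert freq == pytest.approx(0.75, abs=3 * math.sqrt(0.75 * 0.25 / trials))


class TestRun:
    def test_isomerization_equilibrates_at_half(self, params):
        # A <-> B with equal constants: time-averaged N_A -> N/2
        species = [Species("A", 1), Species("B", 1)]
        rxs = [
            Reaction("degradation", ("A",), ("B",), base_k=1.0),
            Reaction("degradation", ("B",), ("A",), base_k=1.0),
        ]
        net = toy_network(species, rxs)
        traj = run(net, params, {"A": 100}, horizon=60.0, grid=601, seed=3)
        half = traj.counts.shape[1] // 4
        assert traj.series("A")[half:].mean() == pytest.approx(50.0, abs=3.0)

    def test_same_seed_is_bit_identical(self, params, dimerization_network):
        net = dimerization_network()
        kw = dict(init_counts={"A": 200}, horizon=2.0, seed=11)
        for backend in ("numba", "python"):
            t1 = run(net, params, backend=backend, **kw)
            t2 = run(net, params, backend=backend, **kw)
            assert np.array_equal(t1.counts, t2.counts)
            assert t1.events == t2.events

    def test_mass_conserved_on_default_network(self):
        p = RateParams()
        net = default_network(p)
        traj = run(net, p, {"Mo1": 500}, horizon=2.0, seed=9)
        nuc = np.array([sp.nuclearity for sp in net.species])
        masses = traj.mass(nuc)
        assert (masses == 500).all()

    def test_nonpositive_horizon_rejected(self, params, dimerization_network):
        with pytest.raises(ValueError):
            run(dimerization_network(), params, {"A": 10}, horizon=0.0, seed=0)

    def test_dimer_stationary_mean_matches_master_equation(self, params):
        # small system: exact stationary mean by state enumeration
        net_build = toy_network(
            [Species("A", 1), Species("A2", 2)],
            [
                Reaction("synthesis", ("A", "A"), ("A2",), base_k=0.1, plain_rate=True),
                Reaction("degradation", ("A2",), ("A", "A"), base_k=1.0, plain_rate=True),
            ],
        )
        exact = dimer_stationary_mean(20, 0.1, 1.0)
        traj = run(net_build, params, {"A": 20}, horizon=400.0, grid=4001, seed=17)
        burn = traj.counts.shape[1] // 4
        observed = traj.series("A2")[burn:].mean()
        assert observed == pytest.approx(exact, rel=0.1)

    def test_backends_agree_statistically(self, params, dimerization_network):
        net = dimerization_network(k_f=0.05, k_r=1.0)
        means = {}
        for backend in ("numba", "python"):
            ens = run_ensemble(
                net, params, {"A": 60}, horizon=4.0, n_reps=40,
                seed_base=100, backend=backend,
            )
            means[backend] = ens.time_averaged_abundance["A2"]
        assert means["numba"] == pytest.approx(means["python"], rel=0.15)


class TestEnsemble:
    def test_single_replicate_mean_equals_trajectory(self, params, dimerization_network):
        net = dimerization_network()
        traj = run(net, params, {"A": 100}, horizon=1.0, grid=51, seed=21)
        ens = run_ensemble(net, params, {"A": 100}, horizon=1.0, grid=51,
                           n_reps=1, seed_base=21)
        assert np.array_equal(ens.mean, traj.counts.astype(float))

    def test_irreversible_decay_absorbs_everything(self, params):
        species = [Species("A", 2), Species("B", 1), Species("C", 1)]
        rx = Reaction("degradation", ("A",), ("B", "C"), base_k=1.0)
        net = toy_network(species, [rx])
        ens = run_ensemble(net, params, {"A": 100}, horizon=40.0, n_reps=5, seed_base=0)
        assert ens.mean_series("B")[-1] == pytest.approx(100.0)
        assert ens.mean_series("A")[-1] == 0.0

    def test_ensemble_mean_matches_ode_within_monte_carlo_error(self, params):
        # A + B -> C irreversible, exact (plain) constant
        k = 0.002
        species = [Species("A", 1), Species("B", 1), Species("C", 2)]
        rx = Reaction("synthesis", ("A", "B"), ("C",), base_k=k, plain_rate=True)
        net = toy_network(species, [rx])
        n0 = 1000
        ens = run_ensemble(
            net, params, {"A": n0, "B": n0}, horizon=2.0, grid=21,
            n_reps=40, seed_base=7,
        )

        def rhs(_, y):
            a, b, c = y
            return [-k * a * b, -k * a * b, k * a * b]

        sol = solve_ivp(rhs, (0, 2.0), [n0, n0, 0], t_eval=ens.grid, rtol=1e-8)
        mean_c = ens.mean_series("C")
        sem = np.sqrt(ens.var[ens.species_ids.index("C")] / ens.n_replicates)
        diff = np.abs(mean_c - sol.y[2])
        assert (diff <= 3 * sem + 3.0).all()

    def test_replicate_seeds_are_sequential(self, params, dimerization_network):
        ens = run_ensemble(
            dimerization_network(), params, {"A": 10}, horizon=0.5,
            n_reps=3, seed_base=41,
        )
        assert ens.seeds == [41, 42, 43]

    def test_invalid_replicate_count(self, params, dimerization_network):
        with pytest.raises(ValueError):
            run_ensemble(dimerization_network(), params, {"A": 10}, n_reps=0)
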