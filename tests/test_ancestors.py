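"""Contribution shares, pruning paths, stopping rules, kernel ladder, bootstrap."""

import numpy as np
import pytest

import chd
from chd.ancestors import (
    PruneStep,
    PruneTrace,
    bootstrap_null,
    choose_kernel,
    contributions,
    prune_path,
    select_inflection,
    select_threshold,
    z_score,
)
from chd.data import DataMatrix, normalize
from chd.kernels import GramFactory, KernelSpec
from chd.regression import fit


def make_trace(noise_ratios, start_size=None):
    """Build a synthetic trace with the given noise-ratio path."""
    n = len(noise_ratios)
    start_size = start_size or n
    names = [f"c{i}" for i in range(start_size)]
    steps = []
    for t, ratio in enumerate(noise_ratios):
        steps.append(
            PruneStep(
                ancestors=tuple(names[: start_size - t]),
                removed=None if t == 0 else names[start_size - t],
                v_signal=1 - ratio,
                v_noise=ratio,
                noise_ratio=ratio,
            )
        )
    return PruneTrace(target="y", kernel_family="linear", steps=tuple(steps))


def noise_dataset(rng, n, d):
    cols = rng.standard_normal((n, d))
    return normalize(DataMatrix(cols, tuple(f"n{i}" for i in range(d))))


class TestContributions:
    def test_zero_coefficients_give_zero_shares(self, rng):
        comps = {"a": np.eye(4), "b": np.eye(4)}
        shares = contributions(np.zeros(4), comps, np.eye(4))
        assert shares == {"a": 0.0, "b": 0.0}

    def test_decomposition_identity(self, rng):
        """z'K1z + z'K2z = z'Kz for every candidate split."""
        rows = rng.standard_normal((40, 4))
        spec = KernelSpec("nonlinear", ("a", "b", "c", "d"))
        factory = GramFactory(rows, spec)
        z = rng.standard_normal(40)
        total = z @ factory.total @ z
        for var in spec.active_variables:
            parts = z @ factory.k1(var) @ z + z @ factory.k2(var) @ z
            assert parts == pytest.approx(total, rel=1e-8)

    def test_true_ancestor_dominates_shares(self):
        """A target equal to one candidate concentrates the signal share."""
        rng = np.random.default_rng(7)
        w = rng.standard_normal((500, 4))
        names = ("w1", "n1", "n2", "n3")
        data = normalize(
            DataMatrix(np.column_stack([w, w[:, 0]]), names + ("y",))
        )
        cols = names
        spec = KernelSpec("linear", cols)
        factory = GramFactory(data.matrix(cols), spec)
        res = fit(factory.total, data.column("y"), 1e-3)
        comps = {n: factory.k2(n) for n in cols}
        shares = contributions(res.coefficients, comps, factory.total)
        assert shares["w1"] > 0.9
        assert all(shares[n] < 0.05 for n in ("n1", "n2", "n3"))


class TestPrunePath:
    def test_single_candidate_single_step(self, rng):
        data = noise_dataset(rng, 50, 2)
        trace = prune_path(data, "n0", ["n1"], "linear")
        assert len(trace.steps) == 1
        assert trace.steps[0].removed is None
        assert trace.steps[0].ancestors == ("n1",)

    def test_true_ancestor_survives_to_the_end(self):
        rng = np.random.default_rng(11)
        w = rng.standard_normal((500, 4))
        data = normalize(
            DataMatrix(
                np.column_stack([w[:, 0], w[:, 1:], ]),
                ("w1", "n1", "n2", "n3"),
            )
        )
        vals = np.column_stack([data.values, data.column("w1")])
        data = DataMatrix(vals, ("w1", "n1", "n2", "n3", "y"))
        trace = prune_path(data, "y", ["w1", "n1", "n2", "n3"], "linear")
        assert trace.steps[-1].ancestors == ("w1",)
        assert all(s.removed != "w1" for s in trace.steps)

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            prune_path(noise_dataset(rng, 20, 2), "n0", [], "linear")

    def test_target_among_candidates_rejected(self, rng):
        with pytest.raises(ValueError, match="target"):
            prune_path(noise_dataset(rng, 20, 2), "n0", ["n0", "n1"], "linear")

    def test_small_sample_warns(self, rng):
        data = noise_dataset(rng, 3, 4)
        with pytest.warns(UserWarning, match="N > d"):
            prune_path(data, "n0", ["n1", "n2", "n3"], "linear")

    def test_conservation_along_path(self, rng):
        data = noise_dataset(rng, 80, 5)
        trace = prune_path(data, "n0", ["n1", "n2", "n3", "n4"], "quadratic")
        for step in trace.steps:
            assert 0.0 <= step.noise_ratio <= 1.0
        sizes = [len(s.ancestors) for s in trace.steps]
        assert sizes == [4, 3, 2, 1]


class TestStoppingRules:
    def test_threshold_stops_before_first_crossing(self):
        trace = make_trace([0.1, 0.15, 0.2, 0.8])
        assert len(select_threshold(trace)) == 2

    def test_threshold_all_above(self):
        assert select_threshold(make_trace([0.7, 0.8, 0.9])) == ()

    def test_threshold_all_below_keeps_final_singleton(self):
        final = select_threshold(make_trace([0.1, 0.2, 0.3]))
        assert len(final) == 1

    def test_threshold_is_sequential_not_global(self):
        """A late re-dip below 0.5 does not override the first crossing."""
        trace = make_trace([0.1, 0.15, 0.6, 0.4])
        assert len(select_threshold(trace)) == 3

    def test_inflection_surge_example(self):
        trace = make_trace([0.10, 0.12, 0.25, 0.99], start_size=5)
        assert len(select_inflection(trace)) == 3

    def test_inflection_flat_path_returns_singleton(self):
        """With no surge, the virtual terminal removal dominates and the
        final singleton is kept."""
        final = select_inflection(make_trace([0.1, 0.1, 0.1, 0.1]))
        assert len(final) == 1

    def test_inflection_single_step(self):
        trace = make_trace([0.3])
        assert select_inflection(trace) == trace.steps[0].ancestors

    def test_inflection_real_surge_beats_virtual_step(self):
        # surge 0.03 -> 0.70 dominates the virtual terminal increment
        # (0.35); the set before that removal (size 3) is kept
        trace = make_trace([0.02, 0.03, 0.70, 0.65])
        assert len(select_inflection(trace)) == 3


class TestChooseKernel:
    def test_linear_target_selects_linear(self):
        ds = chd.generate_algebraic(1, N=600, seed=5)
        data = normalize(ds.data)
        fam, res = choose_kernel(
            data, "x1", [n for n in data.names if n != "x1"]
        )
        assert fam == "linear"
        assert res.ratio > 0.5

    def test_quadratic_target_selects_quadratic(self):
        ds = chd.generate_algebraic(2, N=600, seed=5)
        data = normalize(ds.data)
        fam, _ = choose_kernel(data, "x2", [n for n in data.names if n != "x2"])
        assert fam == "quadratic"

    def test_nonlinear_target_selects_nonlinear(self):
        ds = chd.generate_algebraic(3, N=600, seed=5)
        data = normalize(ds.data)
        fam, _ = choose_kernel(data, "x2", [n for n in data.names if n != "x2"])
        assert fam == "nonlinear"

    def test_pure_noise_yields_none(self, rng):
        data = noise_dataset(rng, 1000, 6)
        fam, res = choose_kernel(data, "n0", [f"n{i}" for i in range(1, 6)])
        assert fam is None
        assert res.ratio < 0.5

    def test_pure_noise_gate_is_reliable_across_seeds(self):
        """choose_kernel returns none for >= 90% of noise-only datasets."""
        hits = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(3000 + seed)
            data = noise_dataset(rng, 1000, 6)
            fam, _ = choose_kernel(data, "n0", [f"n{i}" for i in range(1, 6)])
            hits += fam is None
        assert hits >= 0.9 * reps


class TestBootstrap:
    def test_z_score_zero_at_mean(self, rng):
        gram = np.eye(30) * 2.0
        null = bootstrap_null(gram, 1.0, n_boot=50, seed=3)
        assert z_score(null.mean, null) == pytest.approx(0.0)

    def test_quantile_ordering(self, rng):
        gram = GramFactory(
            rng.standard_normal((60, 3)), KernelSpec("nonlinear", ("a", "b", "c"))
        ).total
        null = bootstrap_null(gram, 0.01, n_boot=80, seed=1)
        assert null.q05 <= null.mean <= null.q95

    def test_zero_spread_warns(self):
        # gamma >> gram makes every draw's ratio 1 up to rounding; force
        # the degenerate branch directly instead
        null = chd.NullDistribution(mean=0.5, sd=0.0, q05=0.5, q95=0.5)
        with pytest.warns(UserWarning, match="zero spread"):
            assert np.isinf(z_score(0.7, null))

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            bootstrap_null(np.eye(5), 1.0, n_boot=1, seed=0)

    def test_seeded_reproducibility(self, rng):
        gram = np.eye(40) + 0.1
        a = bootstrap_null(gram, 0.5, n_boot=30, seed=9)
        b = bootstrap_null(gram, 0.5, n_boot=30, seed=9)
        assert a.ratios == b.ratios
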