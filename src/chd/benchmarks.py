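"""Seeded generators for the three self-contained benchmark systems.

Each generator returns a :class:`BenchmarkDataset`: a raw (unnormalized)
sample table, the ground-truth edge list of the generative structure,
and metadata including any discovery hints (restricted target or
candidate sets) that define the benchmark's standard protocol.

* :func:`simulate_fput` — the Fermi-Pasta-Ulam-Tsingou chain of M
  masses with quadratic nonlinearity and fixed boundaries; snapshots of
  positions, velocities and accelerations pooled over several
  trajectories.  Accelerations are evaluated from the equation of
  motion at the recorded positions, never finite-differenced, so the
  functional dependence holds exactly in the data.
* :func:`generate_algebraic` — four small algebraic systems driven by
  i.i.d. standard-normal sources, exercising the linear, quadratic and
  nonlinear kernel families.
* :func:`simulate_reactions` — mass-action kinetics of ethylene
  hydrogenation (H2 <-> 2H, H + C2H4 <-> C2H5, C2H5 + H -> C2H6);
  observed variables are four concentrations and their time
  derivatives, the latter evaluated from the rate laws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataMatrix

__all__ = [
    "BenchmarkDataset",
    "simulate_fput",
    "generate_algebraic",
    "simulate_reactions",
]


@dataclass(frozen=True)
class BenchmarkDataset:
    """A generated benchmark: raw samples plus ground truth.

    ``targets`` and ``candidates`` describe the benchmark's standard
    discovery protocol (``None`` means the default all-vs-all run);
    ``expected_families`` records which kernel family each functionally
    generated node calls for.
    """

    data: DataMatrix
    truth: tuple[tuple[str, str], ...]
    meta: dict = field(default_factory=dict)
    targets: tuple[str, ...] | None = None
    candidates: dict[str, tuple[str, ...]] | None = None
    expected_families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = set(self.data.names)
        for src, dst in self.truth:
            if src not in names or dst not in names:
                raise ValueError(f"truth edge ({src}, {dst}) off the table")


# ---------------------------------------------------------------------------
# FPUT chain


def _fput_acceleration(x: np.ndarray, c: float, h: float) -> np.ndarray:
    """Right-hand side of the chain: masses j = 0..M-1, ends clamped.

    a_j = (c/h)^2 (x_{j+1} + x_{j-1} - 2 x_j) (1 + (x_{j+1} - x_{j-1})^2)
    with virtual boundary masses x_{-1} = x_M = 0.  The nonlinearity can
    be switched off (alpha = 0) to recover the linear wave chain.
    """
    xp = np.concatenate([x[..., 1:], np.zeros_like(x[..., :1])], axis=-1)
    xm = np.concatenate([np.zeros_like(x[..., :1]), x[..., :-1]], axis=-1)
    lap = xp + xm - 2.0 * x
    return (c / h) ** 2 * lap * (1.0 + (xp - xm) ** 2)


def _fput_acceleration_linear(x: np.ndarray, c: float, h: float) -> np.ndarray:
    xp = np.concatenate([x[..., 1:], np.zeros_like(x[..., :1])], axis=-1)
    xm = np.concatenate([np.zeros_like(x[..., :1]), x[..., :-1]], axis=-1)
    return (c / h) ** 2 * (xp + xm - 2.0 * x)


def simulate_fput(
    M: int = 10,
    c: float = 1.0,
    n_snapshots: int = 1000,
    n_trajectories: int = 50,
    seed: int = 0,
    dt: float = 2e-3,
    subsample: int = 125,
    burn_in: float = 1.0,
    alpha: str = "quadratic",
) -> BenchmarkDataset:
    """Simulate the FPUT chain and pool snapshots over trajectories.

    Observed variables are positions ``x0..x{M-1}``, velocities
    ``v0..``, and accelerations ``a0..``; accelerations are the exact
    equation-of-motion values at the recorded positions.  Initial
    conditions are random combinations of the first three standing-wave
    modes, rescaled so the peak displacement lies in [0.5, 1.5], with
    zero initial velocity.  Pooling many trajectories with independent
    mode mixtures matters more than trajectory length here: each
    acceleration is also expressible through its neighbours'
    accelerations (invert one equation of motion for the missing
    position), and only a diverse ensemble makes that composite
    representation harder to fit than the direct three-position one, so
    that pruning resolves the sparse neighbour set.  A short ``burn_in``
    lets the velocities leave the measure-zero v=0 initial slice before
    recording.  Integration is fixed-step classical Runge-Kutta with
    step ``dt`` (the quadratic stiffening destabilizes larger steps);
    one snapshot is recorded every ``subsample`` steps (0.25 time units
    at the defaults).  A trajectory whose displacement exceeds 1e3 is
    discarded and resampled.

    ``alpha="none"`` switches the spring nonlinearity off, giving the
    linear wave chain limit.
    """
    if M < 3:
        raise ValueError("need at least 3 masses")
    if n_snapshots % n_trajectories:
        raise ValueError("n_snapshots must divide across trajectories")
    if alpha not in ("quadratic", "none"):
        raise ValueError(f"unknown nonlinearity {alpha!r}")
    accel = _fput_acceleration if alpha == "quadratic" else _fput_acceleration_linear
    h = 1.0 / M
    per_traj = n_snapshots // n_trajectories
    rng = np.random.default_rng(seed)
    rows = []

    def rhs(state: np.ndarray) -> np.ndarray:
        x, v = state
        return np.stack([v, accel(x, c, h)])

    j = np.arange(M)
    mode_shapes = np.stack(
        [np.sin(np.pi * m * (j + 1) / (M + 1)) for m in (1, 2, 3)]
    )
    n_burn = int(round(burn_in / dt))

    def draw_ic() -> np.ndarray:
        profile = rng.standard_normal(3) @ mode_shapes
        amplitude = rng.uniform(0.5, 1.5)
        return amplitude * profile / np.abs(profile).max()

    def integrate_batch(x0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """RK4 for a (T, M) batch of trajectories; returns snapshots
        (T, per_traj, 3M) and a per-trajectory validity mask."""
        state = np.stack([x0, np.zeros_like(x0)])  # (2, T, M)
        t_count = x0.shape[0]
        good = np.ones(t_count, dtype=bool)
        snaps = np.empty((t_count, per_traj, 3 * M))
        snap_idx = 0
        for k in range(n_burn + per_traj * subsample):
            k1 = rhs(state)
            k2 = rhs(state + 0.5 * dt * k1)
            k3 = rhs(state + 0.5 * dt * k2)
            k4 = rhs(state + dt * k3)
            state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            with np.errstate(invalid="ignore"):
                good &= np.nanmax(np.abs(state[0]), axis=-1) <= 1e3
            state[:, ~good, :] = 0.0  # freeze diverged trajectories
            if k >= n_burn and (k + 1 - n_burn) % subsample == 0:
                x, v = state
                snaps[:, snap_idx, :] = np.concatenate(
                    [x, v, accel(x, c, h)], axis=-1
                )
                snap_idx += 1
        return snaps, good

    collected: list[np.ndarray] = []
    pending = n_trajectories
    guard = 0
    while pending > 0:
        guard += 1
        if guard > 20:
            raise RuntimeError("too many diverging trajectories")
        x0 = np.stack([draw_ic() for _ in range(pending)])
        snaps, good = integrate_batch(x0)
        collected.extend(snaps[i] for i in range(pending) if good[i])
        pending -= int(good.sum())
    rows = [row for traj_snaps in collected for row in traj_snaps]

    names = (
        [f"x{j}" for j in range(M)]
        + [f"v{j}" for j in range(M)]
        + [f"a{j}" for j in range(M)]
    )
    data = DataMatrix(np.asarray(rows), tuple(names))
    truth = []
    for j in range(M):
        parents = [p for p in (j - 1, j, j + 1) if 0 <= p < M]
        truth.extend((f"x{p}", f"a{j}") for p in parents)
    families = {f"a{j}": ("linear" if alpha == "none" else "nonlinear") for j in range(M)}
    return BenchmarkDataset(
        data=data,
        truth=tuple(truth),
        meta={
            "name": "fput",
            "M": M,
            "c": c,
            "h": h,
            "alpha": alpha,
            "dt": dt,
            "subsample": subsample,
            "burn_in": burn_in,
            "n_snapshots": n_snapshots,
            "n_trajectories": n_trajectories,
            "seed": seed,
        },
        expected_families=families,
    )


# ---------------------------------------------------------------------------
# algebraic systems


def generate_algebraic(example_id: int, N: int = 1000, seed: int = 0) -> BenchmarkDataset:
    """One of the four printed algebraic systems.

    Sources ``w1..w4`` are i.i.d. standard normal; the ``x`` variables
    are deterministic (or small-noise) functions of them:

    1. d=6:  x1 = w1,  x2 = w2                          (linear)
    2. d=7:  x1 = w1,  x2 = x1^2 + 1 + 0.1 w2,  x3 = w3 (quadratic)
    3. d=6:  x1 = w1 w2,  x2 = w2 sin(w4)               (nonlinear)
    4. d=7:  x1 = w1,  x2 = x1^3 + 1 + 0.1 w2,
             x3 = (x1 + 2)^3 + 0.1 w3                   (quadratic)

    The cubic system 4 hides quadratic structure: eliminating x1^3
    between the two equations leaves each of x2, x3 an exact quadratic
    function of {x1, the other one, w2, w3}.
    """
    rng = np.random.default_rng(seed)
    if N < 10:
        raise ValueError("need at least 10 samples")
    w = rng.standard_normal((N, 4))
    w1, w2, w3, w4 = w.T
    if example_id == 1:
        cols = {"w1": w1, "w2": w2, "w3": w3, "w4": w4, "x1": w1.copy(), "x2": w2.copy()}
        truth = (("w1", "x1"), ("w2", "x2"))
        families = {"x1": "linear", "x2": "linear"}
    elif example_id == 2:
        x1 = w1.copy()
        x2 = x1**2 + 1.0 + 0.1 * w2
        x3 = w3.copy()
        cols = {"w1": w1, "w2": w2, "w3": w3, "w4": w4, "x1": x1, "x2": x2, "x3": x3}
        truth = (("w1", "x1"), ("x1", "x2"), ("w2", "x2"), ("w3", "x3"))
        families = {"x1": "linear", "x2": "quadratic", "x3": "linear"}
    elif example_id == 3:
        x1 = w1 * w2
        x2 = w2 * np.sin(w4)
        cols = {"w1": w1, "w2": w2, "w3": w3, "w4": w4, "x1": x1, "x2": x2}
        truth = (("w1", "x1"), ("w2", "x1"), ("w2", "x2"), ("w4", "x2"))
        families = {"x1": "quadratic", "x2": "nonlinear"}
    elif example_id == 4:
        x1 = w1.copy()
        x2 = x1**3 + 1.0 + 0.1 * w2
        x3 = (x1 + 2.0) ** 3 + 0.1 * w3
        cols = {"w1": w1, "w2": w2, "w3": w3, "w4": w4, "x1": x1, "x2": x2, "x3": x3}
        truth = (
            ("w1", "x1"),
            ("x1", "x2"),
            ("w2", "x2"),
            ("x1", "x3"),
            ("w3", "x3"),
        )
        families = {"x1": "linear", "x2": "quadratic", "x3": "quadratic"}
    else:
        raise ValueError(f"unknown example_id {example_id}; expected 1-4")
    data = DataMatrix(
        np.column_stack(list(cols.values())), tuple(cols)
    )
    return BenchmarkDataset(
        data=data,
        truth=truth,
        meta={"name": f"algebraic-{example_id}", "N": N, "seed": seed},
        expected_families=families,
    )


# ---------------------------------------------------------------------------
# reaction network


#: default mass-action rate constants (k1f, k1r, k2f, k2r, k3)
DEFAULT_RATES = (0.7, 0.2, 1.0, 0.3, 0.5)

_SPECIES = ("H2", "H", "C2H4", "C2H5", "C2H6")


def _reaction_rhs(state: np.ndarray, rates: tuple[float, ...]) -> np.ndarray:
    """Mass-action rates for H2 <-> 2H, H + C2H4 <-> C2H5, C2H5 + H -> C2H6."""
    k1f, k1r, k2f, k2r, k3 = rates
    h2, h, c2h4, c2h5 = state[..., 0], state[..., 1], state[..., 2], state[..., 3]
    r1 = k1f * h2 - k1r * h * h
    r2 = k2f * h * c2h4 - k2r * c2h5
    r3 = k3 * c2h5 * h
    return np.stack(
        [-r1, 2.0 * r1 - r2 - r3, -r2, r2 - r3, r3], axis=-1
    )


def _integrate_reactions(
    y0: np.ndarray,
    rates: tuple[float, ...],
    t_max: float,
    dt: float,
    n_keep: int,
) -> np.ndarray:
    """Fixed-step RK4 trajectory; returns ``n_keep`` evenly spaced states
    (including t=0).  Halves the step and retries once if a concentration
    goes negative; rejects after that."""
    steps = int(round(t_max / dt))
    keep_at = set(
        int(round(i * steps / (n_keep - 1))) for i in range(n_keep)
    ) if n_keep > 1 else {0}
    for attempt in range(2):
        states = []
        y = y0.copy()
        if 0 in keep_at:
            states.append(y.copy())
        bad = False
        for k in range(1, steps + 1):
            k1 = _reaction_rhs(y, rates)
            k2 = _reaction_rhs(y + 0.5 * dt * k1, rates)
            k3 = _reaction_rhs(y + 0.5 * dt * k2, rates)
            k4 = _reaction_rhs(y + dt * k3, rates)
            y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if np.any(y < 0):
                bad = True
                break
            if k in keep_at:
                states.append(y.copy())
        if not bad:
            return np.asarray(states)
        dt *= 0.5
        steps *= 2
        keep_at = set(
            int(round(i * steps / (n_keep - 1))) for i in range(n_keep)
        ) if n_keep > 1 else {0}
    raise RuntimeError("reaction trajectory produced negative concentrations")


def simulate_reactions(
    rates: tuple[float, ...] = DEFAULT_RATES,
    n_snapshots: int = 1000,
    seed: int = 0,
    n_trajectories: int = 25,
    t_max: float = 4.0,
    dt: float = 2e-3,
) -> BenchmarkDataset:
    """Mass-action snapshots of the ethylene-hydrogenation network.

    Observed variables are the concentrations ``H2, H, C2H4, C2H5`` and
    their time derivatives ``dH2, dH, dC2H4, dC2H5`` (the product C2H6
    never feeds back, so it is integrated but not observed).  Initial
    concentrations are drawn uniformly in [0.5, 1.5] per species and
    trajectory, so pooled snapshots explore the full 4-dimensional state
    space and no spurious cross-concentration constraint survives.

    The benchmark's standard discovery protocol, recorded in the
    returned dataset, regresses each derivative on the four
    concentrations — the system-identification question "which states
    drive each rate".  The stoichiometry makes any one derivative an
    exact *linear* combination of the other three (atom bookkeeping), so
    admitting derivatives as candidates of derivatives can only recover
    that accounting identity, not the reaction structure.
    """
    if any(k <= 0 for k in rates) or len(rates) != 5:
        raise ValueError("need 5 positive rate constants")
    if n_snapshots % n_trajectories:
        raise ValueError("n_snapshots must divide across trajectories")
    per_traj = n_snapshots // n_trajectories
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_trajectories):
        y0 = np.concatenate([rng.uniform(0.5, 1.5, size=4), [0.0]])
        states = _integrate_reactions(y0, rates, t_max, dt, per_traj)
        derivs = _reaction_rhs(states, rates)
        rows.append(np.concatenate([states[:, :4], derivs[:, :4]], axis=1))
    table = np.concatenate(rows, axis=0)
    conc = list(_SPECIES[:4])
    deriv = [f"d{s}" for s in conc]
    data = DataMatrix(table, tuple(conc + deriv))
    truth = (
        ("H2", "dH2"), ("H", "dH2"),
        ("H2", "dH"), ("H", "dH"), ("C2H4", "dH"), ("C2H5", "dH"),
        ("H", "dC2H4"), ("C2H4", "dC2H4"), ("C2H5", "dC2H4"),
        ("H", "dC2H5"), ("C2H4", "dC2H5"), ("C2H5", "dC2H5"),
    )
    return BenchmarkDataset(
        data=data,
        truth=truth,
        meta={
            "name": "reactions",
            "rates": tuple(rates),
            "n_snapshots": n_snapshots,
            "n_trajectories": n_trajectories,
            "t_max": t_max,
            "dt": dt,
            "seed": seed,
        },
        targets=tuple(deriv),
        candidates={d: tuple(conc) for d in deriv},
        expected_families={d: "quadratic" for d in deriv},
    )
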