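"""Ancestor detection and pruning for a single node.

For a target variable the engine (i) walks a kernel ladder — linear,
then quadratic, then fully nonlinear — and keeps the first family whose
signal-to-noise ratio exceeds 0.5, concluding "no ancestors" if none
does; (ii) attributes the fitted signal variance to each candidate node
through the additive split Ks = K1 + K2 (the share of node j is
z'K2_j z / z'Ks z); (iii) prunes candidates one at a time, always
removing the smallest contributor and refitting, which yields a
noise-to-signal ratio as a function of the number of retained
candidates; and (iv) stops either at the 0.5 threshold or at the
largest surge (inflection) of that ratio.  A bootstrap over white-noise
targets on the same Gram provides a null band and a Z-score for the
observed ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import DataMatrix
from .kernels import FAMILIES, GramFactory, KernelSpec
from .regression import RegressionResult, fit, resolve_gamma

__all__ = [
    "PruneStep",
    "PruneTrace",
    "AncestorReport",
    "NullDistribution",
    "contributions",
    "prune_path",
    "select_threshold",
    "select_inflection",
    "choose_kernel",
    "bootstrap_null",
    "z_score",
]

#: numerically-negative contribution shares smaller than this are clamped to 0
_SHARE_CLAMP = 1e-10


@dataclass(frozen=True)
class PruneStep:
    """One state along the pruning path.

    ``removed`` is the node whose deletion produced this state (``None``
    for the initial full-candidate fit).
    """

    ancestors: tuple[str, ...]
    removed: str | None
    v_signal: float
    v_noise: float
    noise_ratio: float


@dataclass(frozen=True)
class PruneTrace:
    """Ordered record of the pruning path for one target node."""

    target: str
    kernel_family: str
    steps: tuple[PruneStep, ...]

    def __post_init__(self) -> None:
        sizes = [len(s.ancestors) for s in self.steps]
        if any(b - a != -1 for a, b in zip(sizes, sizes[1:])):
            raise ValueError("ancestor sets must shrink by exactly 1 per step")

    @property
    def increments(self) -> tuple[float, ...]:
        """Noise-ratio differences between consecutive steps."""
        ratios = [s.noise_ratio for s in self.steps]
        return tuple(b - a for a, b in zip(ratios, ratios[1:]))

    @property
    def noise_ratios(self) -> tuple[float, ...]:
        return tuple(s.noise_ratio for s in self.steps)


@dataclass(frozen=True)
class NullDistribution:
    """Bootstrap distribution of the noise ratio under white-noise targets."""

    mean: float
    sd: float
    q05: float
    q95: float
    ratios: tuple[float, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class AncestorReport:
    """Final verdict for one target node."""

    target: str
    has_ancestors: bool
    kernel_family: str | None
    final_ancestors: tuple[str, ...]
    final_ratio: float
    z_score: float
    null_band: tuple[float, float] | None = None
    trace: PruneTrace | None = None

    def __post_init__(self) -> None:
        if self.has_ancestors != bool(self.final_ancestors):
            raise ValueError(
                "has_ancestors must match emptiness of final_ancestors"
            )


# ---------------------------------------------------------------------------
# contributions


def contributions(
    z: np.ndarray,
    gram_components: dict[str, np.ndarray],
    gram_total: np.ndarray,
) -> dict[str, float]:
    """Share of the signal variance carried by each candidate node.

    ``gram_components`` maps node -> Gram of K2 = Ks - K1 for that node.
    The share of node j is z'K2_j z / z'Ks z; both quadratic forms are
    nonnegative because K1 and K2 are PSD, so each share lies in [0, 1]
    up to rounding (tiny negative values are clamped).  Shares need not
    sum to 1: interaction terms are counted in every participating
    node's component.  The all-zero coefficient vector yields all-zero
    shares by convention.
    """
    z = np.asarray(z, dtype=float).ravel()
    total = float(z @ gram_total @ z)
    if total <= 0:
        return {name: 0.0 for name in gram_components}
    shares = {}
    for name, k2 in gram_components.items():
        val = float(z @ k2 @ z) / total
        if val < 0:
            if val < -_SHARE_CLAMP:
                warnings.warn(
                    f"contribution of {name!r} is {val:.3e} < 0 beyond "
                    "rounding; clamping to 0",
                    stacklevel=2,
                )
            val = 0.0
        shares[name] = val
    return shares


def _node_columns(data: DataMatrix, nodes: list[str]) -> tuple[str, ...]:
    cols: list[str] = []
    for node in nodes:
        cols.extend(data.columns_of(node))
    return tuple(cols)


def _fit_on(
    data: DataMatrix,
    target: str,
    nodes: list[str],
    family: str,
    gamma: float | str,
    beta1: float,
    beta2: float,
    beta3: float,
    base_kernel: str,
) -> tuple[RegressionResult, GramFactory]:
    cols = _node_columns(data, nodes)
    spec = KernelSpec(
        family, cols, beta1=beta1, beta2=beta2, beta3=beta3, base_kernel=base_kernel
    )
    factory = GramFactory(data.matrix(cols), spec)
    y = _target_vector(data, target)
    res = fit(factory.total, y, gamma, kernel=spec, target_name=target)
    return res, factory


def _target_vector(data: DataMatrix, target: str) -> np.ndarray:
    members = data.columns_of(target)
    if len(members) != 1:
        raise ValueError(
            f"target node {target!r} is a cluster of {len(members)} "
            "variables; regress its members individually"
        )
    return data.column(members[0])


# ---------------------------------------------------------------------------
# pruning


def prune_path(
    data: DataMatrix,
    target: str,
    candidates: set[str] | list[str] | tuple[str, ...],
    spec: KernelSpec | str,
    gamma: float | str = 0.01,
    beta1: float = 0.1,
    beta2: float = 0.1,
    beta3: float = 0.1,
    base_kernel: str = "gaussian",
) -> PruneTrace:
    """Iteratively remove the least-contributing candidate and refit.

    Step 0 fits the target on all candidate nodes; each subsequent step
    deletes the node with the smallest contribution share (ties broken
    by name order), refits, and records the new noise-to-signal ratio.
    The path continues down to a single candidate.  Contribution shares
    are recomputed from the current fit after every removal.

    ``spec`` may be a full :class:`KernelSpec` (its family and weights
    are used; its active set is ignored in favour of ``candidates``) or
    just a family name.
    """
    if isinstance(spec, KernelSpec):
        family = spec.family
        beta1, beta2, beta3 = spec.beta1, spec.beta2, spec.beta3
        base_kernel = spec.base_kernel
    else:
        family = spec
        if family not in FAMILIES:
            raise ValueError(f"unknown kernel family {family!r}")
    nodes = sorted(set(candidates))
    if not nodes:
        raise ValueError("candidate set is empty")
    if target in nodes:
        raise ValueError("target must not be among its candidates")
    if data.n_samples <= len(_node_columns(data, nodes)):
        warnings.warn(
            f"N={data.n_samples} samples for {len(nodes)} candidate "
            "node(s); statistical accuracy requires N > d",
            stacklevel=2,
        )

    steps: list[PruneStep] = []
    removed: str | None = None
    while True:
        res, factory = _fit_on(
            data, target, nodes, family, gamma, beta1, beta2, beta3, base_kernel
        )
        steps.append(
            PruneStep(
                ancestors=tuple(nodes),
                removed=removed,
                v_signal=res.v_signal,
                v_noise=res.v_noise,
                noise_ratio=res.noise_ratio,
            )
        )
        if len(nodes) == 1:
            break
        comps = {
            node: factory.k2(data.columns_of(node)) for node in nodes
        }
        shares = contributions(res.coefficients, comps, factory.total)
        removed = min(nodes, key=lambda n: (shares[n], n))
        nodes = [n for n in nodes if n != removed]
    return PruneTrace(target=target, kernel_family=family, steps=tuple(steps))


def select_threshold(
    trace: PruneTrace, threshold: float = 0.5
) -> tuple[str, ...]:
    """Stop pruning just before the signal ratio first drops below 0.5.

    Walks the path in pruning order and keeps the last ancestor set
    before the noise ratio first reaches the threshold — a removal that
    pushes the ratio over the line is not performed.  Returns the empty
    tuple when even the full candidate set is below the signal
    threshold, and the final singleton when no removal ever crosses it.
    """
    if not trace.steps:
        raise ValueError("empty pruning trace")
    final: tuple[str, ...] = ()
    for step in trace.steps:
        if step.noise_ratio >= threshold:
            break
        final = step.ancestors
    return final


def select_inflection(trace: PruneTrace) -> tuple[str, ...]:
    """Ancestor set preceding the largest surge in the noise ratio.

    The path ends at a single candidate, so the (never-performed)
    removal of that last node is scored as a virtual terminal increment
    of ``1 - final noise ratio``: an empty ancestor set is pure noise.
    Without it, a target explained by exactly one ancestor would show a
    flat path and the surge rule could not recover the singleton.  Ties
    are broken toward the earliest maximal increment.
    """
    if not trace.steps:
        raise ValueError("empty pruning trace")
    if len(trace.steps) == 1:
        return trace.steps[0].ancestors
    increments = list(trace.increments)
    increments.append(1.0 - trace.steps[-1].noise_ratio)
    best = int(np.argmax(increments))  # argmax keeps the earliest tie
    return trace.steps[best].ancestors


# ---------------------------------------------------------------------------
# kernel ladder


def choose_kernel(
    data: DataMatrix,
    target: str,
    candidates: set[str] | list[str] | tuple[str, ...],
    gamma: float | str = 0.01,
    ladder: tuple[str, ...] = FAMILIES,
    threshold: float = 0.5,
    beta1: float = 0.1,
    beta2: float = 0.1,
    beta3: float = 0.1,
    base_kernel: str = "gaussian",
) -> tuple[str | None, RegressionResult]:
    """Walk the kernel ladder on the full candidate set.

    Returns the first family whose signal-to-noise ratio exceeds the
    threshold together with its fit, or ``(None, last fit)`` when no
    family reaches it (the target is deemed ancestor-free).
    """
    nodes = sorted(set(candidates))
    if not nodes:
        raise ValueError("candidate set is empty")
    if target in nodes:
        raise ValueError("target must not be among its candidates")
    res = None
    for family in ladder:
        res, _ = _fit_on(
            data, target, nodes, family, gamma, beta1, beta2, beta3, base_kernel
        )
        if res.ratio > threshold:
            return family, res
    assert res is not None
    return None, res


# ---------------------------------------------------------------------------
# bootstrap null


def bootstrap_null(
    gram: np.ndarray,
    gamma: float | str,
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
) -> NullDistribution:
    """Noise-ratio distribution under i.i.d. standard-normal targets.

    White-noise targets are the natural null for standardized variables:
    under the null the observed noise ratio should fall inside the
    [q05, q95] band with probability ~0.9.  The Gram is factorized once
    and reused across draws.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap draws")
    gram = np.asarray(gram, dtype=float)
    gamma = resolve_gamma(gram, gamma)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = gram.shape[0]
    factor = cho_factor(gram + gamma * np.eye(n), lower=True)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        y = rng.standard_normal(n)
        z = cho_solve(factor, y)
        v_noise = gamma * z @ z
        total = z @ y
        ratios[b] = v_noise / total if total > 0 else 1.0
    q05, q95 = np.quantile(ratios, [0.05, 0.95])
    return NullDistribution(
        mean=float(ratios.mean()),
        sd=float(ratios.std()),
        q05=float(q05),
        q95=float(q95),
        ratios=tuple(ratios),
    )


def z_score(observed_ratio: float, null: NullDistribution) -> float:
    """Standardized distance of the observed noise ratio from the null."""
    if null.sd == 0:
        warnings.warn(
            "null distribution has zero spread; Z-score is infinite",
            stacklevel=2,
        )
        if observed_ratio == null.mean:
            return 0.0
        return float(np.sign(observed_ratio - null.mean) * np.inf)
    return (observed_ratio - null.mean) / null.sd
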