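"""Additive signal kernels and their per-variable splits.

The signal kernel on m standardized variables is the additive family

    Ks(x, x') = 1 + b1 * sum_i x_i x'_i                        (linear)
              + b2 * sum_{i<=j} x_i x_j x'_i x'_j              (quadratic)
              + b3 * prod_i (1 + k(x_i, x'_i))                 (nonlinear)

truncated after the first, second, or third block depending on the
family.  ``k`` is a universal base kernel (Gaussian or Matern 5/2) with
all shape parameters fixed to 1, and the block weights default to 0.1.

For ancestor scoring the kernel is split per variable as Ks = K1 + K2,
where K1 is the same family evaluated on the active variables minus the
candidate (K1 is independent of it) and K2 = Ks - K1 carries every term
the candidate participates in.  Both parts are positive semidefinite,
so the split induces an ANOVA-style decomposition of the fitted
function's RKHS norm.

The linear and quadratic families have exact finite-dimensional feature
maps (:func:`feature_map`), which the regression layer uses to replace
N x N solves by p x p solves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property
from typing import Iterable

import numpy as np

__all__ = [
    "FAMILIES",
    "KernelSpec",
    "KernelSplit",
    "kernel_matrix",
    "kernel_split",
    "feature_map",
    "GramFactory",
]

FAMILIES = ("linear", "quadratic", "nonlinear")
BASE_KERNELS = ("gaussian", "matern")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family, block weights, and the ordered active variables.

    ``beta2`` is ignored by the linear family and ``beta3`` by the
    linear and quadratic families.  Base-kernel shape parameters are
    fixed to 1 (unit Gaussian bandwidth; Matern smoothness 5/2, unit
    scale).
    """

    family: str
    active_variables: tuple[str, ...]
    beta1: float = 0.1
    beta2: float = 0.1
    beta3: float = 0.1
    base_kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.base_kernel not in BASE_KERNELS:
            raise ValueError(f"unknown base kernel {self.base_kernel!r}")
        object.__setattr__(
            self, "active_variables", tuple(self.active_variables)
        )
        if len(set(self.active_variables)) != len(self.active_variables):
            raise ValueError("active_variables must be unique")
        for b in (self.beta1, self.beta2, self.beta3):
            if b < 0:
                raise ValueError("kernel weights must be nonnegative")

    @property
    def n_variables(self) -> int:
        return len(self.active_variables)

    def restrict(self, variables: tuple[str, ...]) -> "KernelSpec":
        """Same family and weights on a subset of the active variables."""
        unknown = set(variables) - set(self.active_variables)
        if unknown:
            raise ValueError(f"unknown variable(s): {sorted(unknown)}")
        return replace(self, active_variables=tuple(variables))


def _base_cross(u: np.ndarray, v: np.ndarray, kind: str) -> np.ndarray:
    """1-D base kernel k(u_i, v_j) with unit parameters."""
    diff = u[:, None] - v[None, :]
    if kind == "gaussian":
        return np.exp(-0.5 * diff * diff)
    r = np.abs(diff)
    sr = np.sqrt(5.0) * r
    return (1.0 + sr + sr * sr / 3.0) * np.exp(-sr)


def _check_rows(rows: np.ndarray, spec: KernelSpec, name: str) -> np.ndarray:
    rows = np.asarray(rows, dtype=float)
    if rows.ndim == 1:
        rows = rows[None, :]
    if rows.ndim != 2 or rows.shape[1] != spec.n_variables:
        raise ValueError(
            f"{name} has shape {rows.shape}; spec expects "
            f"{spec.n_variables} variable column(s)"
        )
    if not np.all(np.isfinite(rows)):
        raise ValueError(f"{name} contains non-finite entries")
    return rows


def kernel_matrix(
    rows_a: np.ndarray, rows_b: np.ndarray, spec: KernelSpec
) -> np.ndarray:
    """Gram matrix of the additive signal kernel between two row sets.

    Rows must order their columns as ``spec.active_variables``.  The
    result is symmetric positive semidefinite when ``rows_a is rows_b``.
    """
    a = _check_rows(rows_a, spec, "rows_a")
    b = _check_rows(rows_b, spec, "rows_b")
    lin = a @ b.T
    gram = 1.0 + spec.beta1 * lin
    if spec.family in ("quadratic", "nonlinear"):
        sq = (a * a) @ (b * b).T
        gram += spec.beta2 * 0.5 * (lin * lin + sq)
    if spec.family == "nonlinear":
        prod = np.ones_like(lin)
        for i in range(spec.n_variables):
            prod *= 1.0 + _base_cross(a[:, i], b[:, i], spec.base_kernel)
        gram += spec.beta3 * prod
    return gram


@dataclass(frozen=True)
class KernelSplit:
    """Additive split Ks = K1 + K2 around one excluded node.

    ``excluded`` may hold several variable names when the node is a
    cluster; K1 is then independent of every member jointly.
    """

    spec: KernelSpec
    excluded: tuple[str, ...]

    @cached_property
    def k1_spec(self) -> KernelSpec:
        remaining = tuple(
            v for v in self.spec.active_variables if v not in self.excluded
        )
        return self.spec.restrict(remaining)

    def _restrict_rows(self, rows: np.ndarray) -> np.ndarray:
        rows = _check_rows(rows, self.spec, "rows")
        keep = [
            i
            for i, v in enumerate(self.spec.active_variables)
            if v not in self.excluded
        ]
        return rows[:, keep]

    def k1_matrix(self, rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
        """Gram of the component blind to the excluded node.

        Rows are given on the full active variable set; the excluded
        columns are ignored.
        """
        return kernel_matrix(
            self._restrict_rows(rows_a), self._restrict_rows(rows_b), self.k1_spec
        )

    def k2_matrix(self, rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
        """Gram of K2 = Ks - K1, the part carried by the excluded node."""
        return kernel_matrix(rows_a, rows_b, self.spec) - self.k1_matrix(
            rows_a, rows_b
        )


def kernel_split(spec: KernelSpec, variables: str | Iterable[str]) -> KernelSplit:
    """Split the kernel around one candidate node.

    ``variables`` is a single name or, for a cluster node, an iterable
    of member names; each must be active in ``spec``.
    """
    if isinstance(variables, str):
        excluded = (variables,)
    else:
        excluded = tuple(variables)
    if not excluded:
        raise ValueError("must exclude at least one variable")
    unknown = set(excluded) - set(spec.active_variables)
    if unknown:
        raise ValueError(f"unknown variable(s): {sorted(unknown)}")
    return KernelSplit(spec, excluded)


def feature_map(rows: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Exact finite feature map of the linear or quadratic family.

    Feature ordering is fixed so coefficient vectors are comparable
    across runs: the constant 1, then the m linear features in variable
    order, then (quadratic only) the m squares in variable order, then
    the m(m-1)/2 cross-terms in lexicographic index order.  The feature
    inner products reproduce :func:`kernel_matrix` exactly; p = 1 + m
    (linear) or 1 + m + m(m+1)/2 (quadratic).
    """
    if spec.family == "nonlinear":
        raise ValueError(
            "the nonlinear family has no finite exact feature map; "
            "use the full Gram path instead"
        )
    rows = _check_rows(rows, spec, "rows")
    n, m = rows.shape
    blocks = [np.ones((n, 1)), np.sqrt(spec.beta1) * rows]
    if spec.family == "quadratic":
        blocks.append(np.sqrt(spec.beta2) * rows * rows)
        cross = [
            np.sqrt(spec.beta2) * rows[:, i] * rows[:, j]
            for i in range(m)
            for j in range(i + 1, m)
        ]
        if cross:
            blocks.append(np.stack(cross, axis=1))
    return np.concatenate(blocks, axis=1)


class GramFactory:
    """Cached Gram evaluator for one training row set.

    Precomputes the shared building blocks (linear inner products,
    squared inner products, the nonlinear product term) so that the
    leave-one-node-out Grams K1 needed during pruning cost O(N^2) each
    instead of a full re-evaluation.  K1 obtained here agrees with a
    direct :func:`kernel_matrix` call on the restricted columns to
    rounding error.
    """

    def __init__(self, rows: np.ndarray, spec: KernelSpec):
        self.spec = spec
        self.rows = _check_rows(rows, spec, "rows")
        self._lin = self.rows @ self.rows.T
        self._sq = None
        self._prod = None
        if spec.family in ("quadratic", "nonlinear"):
            r2 = self.rows * self.rows
            self._sq = r2 @ r2.T
        if spec.family == "nonlinear":
            prod = np.ones_like(self._lin)
            for i in range(spec.n_variables):
                prod *= 1.0 + self._factor(i)
            self._prod = prod

    def _factor(self, i: int) -> np.ndarray:
        col = self.rows[:, i]
        return _base_cross(col, col, self.spec.base_kernel)

    @cached_property
    def total(self) -> np.ndarray:
        gram = 1.0 + self.spec.beta1 * self._lin
        if self._sq is not None:
            gram = gram + self.spec.beta2 * 0.5 * (self._lin * self._lin + self._sq)
        if self._prod is not None:
            gram = gram + self.spec.beta3 * self._prod
        return gram

    def k1(self, excluded: str | Iterable[str]) -> np.ndarray:
        """Gram of the kernel restricted to the variables not excluded."""
        if isinstance(excluded, str):
            excluded = (excluded,)
        idx = [self.spec.active_variables.index(v) for v in excluded]
        sub = self.rows[:, idx]
        lin1 = self._lin - sub @ sub.T
        gram = 1.0 + self.spec.beta1 * lin1
        if self._sq is not None:
            s2 = sub * sub
            sq1 = self._sq - s2 @ s2.T
            gram = gram + self.spec.beta2 * 0.5 * (lin1 * lin1 + sq1)
        if self._prod is not None:
            # factors are >= 1 everywhere, so dividing them out is stable
            prod1 = self._prod.copy()
            for i in idx:
                prod1 /= 1.0 + self._factor(i)
            gram = gram + self.spec.beta3 * prod1
        return gram

    def k2(self, excluded: str | Iterable[str]) -> np.ndarray:
        """Gram of K2 = Ks - K1 for one candidate node."""
        return self.total - self.k1(excluded)
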