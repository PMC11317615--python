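"""Closed-form kernel ridge regression and the signal/noise variance split.

A target vector Y is regressed on the candidate variables by minimizing

    ||f||_Ks^2 + (1/gamma) * ||f(X) - Y||^2   over f in the RKHS of Ks,

equivalently by modelling Y as the sum of a smooth signal GP with
covariance Ks and a white-noise GP with variance gamma.  The representer
coefficients solve (K + gamma*I) z = Y and the explained data variance
splits exactly into

    V_signal = z' K z          (RKHS norm of the fitted function)
    V_noise  = gamma * ||z||^2 (equal to (1/gamma)*||f(X) - Y||^2,
                                because the residual is exactly gamma*z)

with V_signal + V_noise = Y'z.  The signal-to-noise ratio
V_signal / (V_signal + V_noise) lies in [0, 1] and is the statistic the
discovery layer thresholds: values above 0.5 mean the smooth component
explains more of the data variance than white noise does.

The regularizer ``gamma`` is the white-noise variance floor: on
standardized (unit-variance) targets, a residual carrying a fraction
rho of the data variance contributes roughly rho*N/gamma to V_noise, so
gamma sets the smallest departure from an exact functional dependence
that still counts as signal.  The package default of 0.01 treats up to
about one percent of a variable's variance as measurement noise, which
resolves weak exact dependencies (a term with coefficient 0.1 on a unit
source carries 1 percent of the variance) while leaving structureless
targets far above the 0.5 noise threshold.  ``gamma="auto"`` is a
scale-adaptive alternative placing gamma at the mean Gram eigenvalue
trace(K)/N, useful when kernels of very different sizes must be
compared on one footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .kernels import KernelSpec, kernel_matrix

__all__ = [
    "RegressionResult",
    "fit",
    "low_rank_fit",
    "predict",
    "signal_to_noise",
    "resolve_gamma",
]


def resolve_gamma(gram: np.ndarray, gamma: float | str) -> float:
    """Turn a gamma setting into a positive number.

    ``"auto"`` places gamma at the mean eigenvalue of the Gram,
    trace(K)/N; ``"auto:<eps>"`` (e.g. ``"auto:0.005"``) at that
    fraction of the mean eigenvalue, making the regularization
    scale-free across kernels of very different sizes.  Numeric values
    are passed through (and validated).
    """
    if isinstance(gamma, str):
        if gamma == "auto":
            scale = 1.0
        elif gamma.startswith("auto:"):
            scale = float(gamma.split(":", 1)[1])
            if not scale > 0:
                raise ValueError(f"gamma scale must be positive, got {scale}")
        else:
            raise ValueError(f"unknown gamma setting {gamma!r}")
        return scale * float(np.trace(gram)) / gram.shape[0]
    gamma = float(gamma)
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return gamma


def signal_to_noise(v_signal: float, v_noise: float) -> float:
    """V_signal / (V_signal + V_noise), with 0/0 -> 0 ("no signal")."""
    if v_signal < 0 or v_noise < 0:
        raise ValueError("variance components must be nonnegative")
    total = v_signal + v_noise
    if total == 0:
        return 0.0
    return v_signal / total


@dataclass(frozen=True)
class RegressionResult:
    """Representer solution of one ridge regression.

    ``ratio`` is the signal-to-noise ratio V_s / (V_s + V_n);
    ``1 - ratio`` is the noise-to-signal ratio used along pruning paths.
    """

    coefficients: np.ndarray
    gamma: float
    v_signal: float
    v_noise: float
    ratio: float
    kernel: KernelSpec | None = None
    target: str | None = None

    @property
    def noise_ratio(self) -> float:
        return 1.0 - self.ratio


def _variance_split(
    z: np.ndarray, y: np.ndarray, gamma: float
) -> tuple[float, float]:
    # V_noise as gamma*||z||^2 avoids the cancellation-prone form
    # (1/gamma)*||K z - Y||^2; V_signal via z'Y - V_noise keeps the
    # conservation identity V_s + V_n = Y'z exact.
    v_noise = float(gamma * z @ z)
    v_signal = float(z @ y - v_noise)
    return max(v_signal, 0.0), max(v_noise, 0.0)


def fit(
    gram: np.ndarray,
    targets: np.ndarray,
    gamma: float | str,
    kernel: KernelSpec | None = None,
    target_name: str | None = None,
) -> RegressionResult:
    """Solve (K + gamma*I) z = Y and split the explained variance.

    ``gram`` must be the symmetric PSD Gram of the signal kernel on the
    training rows.  The ridge objective is minimized exactly by the
    representer solution; no iterative solver is involved.
    """
    gram = np.asarray(gram, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if gram.ndim != 2 or gram.shape[0] != gram.shape[1]:
        raise ValueError(f"gram must be square, got shape {gram.shape}")
    if gram.shape[0] != y.shape[0]:
        raise ValueError("gram and targets sizes differ")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets contain non-finite entries")
    if not np.allclose(gram, gram.T, rtol=0, atol=1e-8 * max(1.0, np.abs(gram).max())):
        raise ValueError("gram matrix is not symmetric")
    gamma = resolve_gamma(gram, gamma)
    try:
        factor = cho_factor(gram + gamma * np.eye(gram.shape[0]), lower=True)
    except LinAlgError as exc:
        raise ValueError(
            "gram + gamma*I is not positive definite; the Gram matrix "
            "is not PSD"
        ) from exc
    z = cho_solve(factor, y)
    v_signal, v_noise = _variance_split(z, y, gamma)
    return RegressionResult(
        coefficients=z,
        gamma=gamma,
        v_signal=v_signal,
        v_noise=v_noise,
        ratio=signal_to_noise(v_signal, v_noise),
        kernel=kernel,
        target=target_name,
    )


def low_rank_fit(
    features: np.ndarray,
    targets: np.ndarray,
    gamma: float | str,
    kernel: KernelSpec | None = None,
    target_name: str | None = None,
) -> RegressionResult:
    """Ridge fit through an explicit feature map (linear/quadratic).

    Produces the same representer coefficients and variance split as
    :func:`fit` on the full Gram Phi Phi', but through a p x p solve
    (Woodbury identity), reducing O(N^3) to O(N p^2).  When p >= N there
    is no saving, but the result is still exact.
    """
    phi = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if phi.ndim != 2 or phi.shape[0] != y.shape[0]:
        raise ValueError("features must be N x p with N matching targets")
    if isinstance(gamma, str):
        if gamma != "auto":
            raise ValueError(f"unknown gamma setting {gamma!r}")
        gamma = float(np.sum(phi * phi)) / phi.shape[0]  # trace(Phi Phi')/N
    gamma = float(gamma)
    if not gamma > 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    p = phi.shape[1]
    small = phi.T @ phi + gamma * np.eye(p)
    w = np.linalg.solve(small, phi.T @ y)
    z = (y - phi @ w) / gamma
    v_noise = float(gamma * z @ z)
    v_signal = float(np.sum((phi.T @ z) ** 2))
    return RegressionResult(
        coefficients=z,
        gamma=gamma,
        v_signal=max(v_signal, 0.0),
        v_noise=v_noise,
        ratio=signal_to_noise(max(v_signal, 0.0), v_noise),
        kernel=kernel,
        target=target_name,
    )


def predict(
    result: RegressionResult,
    train_rows: np.ndarray,
    new_rows: np.ndarray,
) -> np.ndarray:
    """Evaluate the fitted function at new rows: Ks(new, X) z.

    On the training rows this equals Y - gamma*z exactly (the ridge
    residual identity).  ``result`` must carry its kernel spec, and the
    row sets must share its variable ordering.
    """
    if result.kernel is None:
        raise ValueError("result carries no kernel spec; cannot predict")
    cross = kernel_matrix(new_rows, train_rows, result.kernel)
    if cross.shape[1] != result.coefficients.shape[0]:
        raise ValueError("train_rows do not match the fitted coefficients")
    return cross @ result.coefficients
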