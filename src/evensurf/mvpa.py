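"""MVPA benchmarking: time-point classification, RSA-ISC, and reliability curves.

Between-participant classification predicts which time point a left-out
participant was experiencing: the prediction for each time point is the mean
response pattern of the training participants, and a test pattern is
correct iff it correlates highest with its own predicted pattern among all
T predictions (chance 1/T).  Representational geometry is summarized by
correlation-distance RDMs; its reliability across participants (RSA-ISC,
the correlation of one participant's RDM with the average of the others')
extrapolates over sample size through Cronbach's alpha and the
Spearman-Brown prediction formula r_n = n r_1 / (1 + (n-1) r_1).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .synthetic import ResponseCohort

__all__ = [
    "compute_rdm",
    "rdm_vector",
    "rsa_isc",
    "fisher_mean",
    "timepoint_classification",
    "subsample_accuracy_curve",
    "cronbach_alpha",
    "spearman_brown",
    "spearman_brown_inverse",
    "equivalent_n",
]


def _as_matrices(responses) -> list[np.ndarray]:
    if isinstance(responses, ResponseCohort):
        return responses.data
    return [np.asarray(m, dtype=np.float64) for m in responses]


def _normalize_rows(x: np.ndarray, what: str) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    bad = np.flatnonzero(norms.ravel() == 0)
    if len(bad):
        raise ValueError(f"constant {what} row(s): {bad[:5].tolist()}")
    return x / norms


def compute_rdm(responses: np.ndarray) -> np.ndarray:
    """Time-point-by-time-point RDM of correlation distances (1 - Pearson r)."""
    x = np.asarray(responses, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("responses must be a (time x vertex) matrix, at least 2x2")
    z = _normalize_rows(x, "time-point pattern")
    rdm = 1.0 - z @ z.T
    np.fill_diagonal(rdm, 0.0)
    return np.clip(rdm, 0.0, 2.0)


def rdm_vector(rdm: np.ndarray) -> np.ndarray:
    """Strict upper triangle of an RDM as a vector."""
    iu = np.triu_indices(rdm.shape[0], k=1)
    return rdm[iu]


def rsa_isc(rdms: list[np.ndarray]) -> np.ndarray:
    """Per-participant correlation of each RDM with the mean of the others'."""
    rdms = [np.asarray(r, dtype=np.float64) for r in rdms]
    if len(rdms) < 3:
        raise ValueError("need at least 3 participants")
    vecs = np.stack([rdm_vector(r) for r in rdms])
    if np.any(vecs.std(axis=1) == 0):
        raise ValueError("constant RDM")
    total = vecs.sum(axis=0)
    out = np.empty(len(rdms))
    for i, v in enumerate(vecs):
        others = (total - v) / (len(rdms) - 1)
        out[i] = np.corrcoef(v, others)[0, 1]
    return out


def fisher_mean(correlations) -> float:
    """Mean correlation through the Fisher z transform: tanh(mean(atanh(r)))."""
    r = np.asarray(correlations, dtype=np.float64)
    if np.any(np.abs(r) >= 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    return float(np.tanh(np.arctanh(r).mean()))


def identity_alignment(data: list[np.ndarray]) -> list[np.ndarray]:
    """Default (no-op) functional alignment; hyperalignment plugs in here."""
    return data


def timepoint_classification(
    responses,
    return_mean: bool = False,
    segment_length: int = 1,
    preprocess=None,
    align=identity_alignment,
):
    """Leave-one-participant-out nearest-neighbor time-point classification.

    For each left-out participant the predicted patterns are the training
    participants' mean; accuracy is the fraction of time points whose
    measured pattern correlates highest with its own prediction among all T
    predicted patterns (computed through the T x T correlation Gram matrix).
    Returns per-participant accuracies.

    ``segment_length`` classifies averages of that many consecutive time
    points instead of single ones; ``preprocess`` (e.g. a fitted PCA
    projection) is applied to each participant's matrix; ``align`` is the
    functional-alignment hook (identity by default).
    """
    data = _as_matrices(responses)
    data = align(data)
    if preprocess is not None:
        data = [np.asarray(preprocess(x), dtype=np.float64) for x in data]
    if segment_length > 1:
        t = data[0].shape[0] // segment_length * segment_length
        data = [
            x[:t].reshape(-1, segment_length, x.shape[1]).mean(axis=1) for x in data
        ]
    if len(data) < 3:
        raise ValueError("need at least 3 participants")
    stack = np.stack(data)  # (P, T, V)
    total = stack.sum(axis=0)
    t = stack.shape[1]
    acc = np.empty(len(data))
    for i, x in enumerate(stack):
        predicted = (total - x) / (len(data) - 1)
        gram = _normalize_rows(x, "measured pattern") @ _normalize_rows(
            predicted, "predicted pattern"
        ).T
        acc[i] = np.mean(gram.argmax(axis=1) == np.arange(t))
    return float(acc.mean()) if return_mean else acc


def subsample_accuracy_curve(
    responses, n_grid, n_draws: int = 100, seed: int = 0
) -> np.ndarray:
    """Mean classification accuracy at each participant count in ``n_grid``.

    For each n, ``n_draws`` random subsets of participants are drawn and the
    leave-one-out accuracies averaged (one draw suffices when n equals the
    full cohort).
    """
    data = _as_matrices(responses)
    n_total = len(data)
    rng = np.random.default_rng(seed)
    out = np.empty(len(n_grid))
    for g, n in enumerate(n_grid):
        if not 3 <= n <= n_total:
            raise ValueError(f"subset size {n} outside [3, {n_total}]")
        draws = 1 if n == n_total else n_draws
        accs = []
        for _ in range(draws):
            subset = rng.choice(n_total, size=n, replace=False)
            accs.append(timepoint_classification([data[j] for j in subset]).mean())
        out[g] = np.mean(accs)
    return out


def cronbach_alpha(units: np.ndarray) -> float:
    """Cronbach's alpha with items as rows and observations as columns."""
    x = np.asarray(units, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (k x m) matrix with k >= 2 item rows")
    k = x.shape[0]
    total_var = np.var(x.sum(axis=0), ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    item_var = np.var(x, axis=1, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def spearman_brown(r1: float, n: float) -> float:
    """Reliability of an average of n parallel measurements: n r1 / (1 + (n-1) r1)."""
    if not 0 <= r1 < 1:
        raise ValueError("r1 must be in [0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * r1 / (1.0 + (n - 1) * r1)


def spearman_brown_inverse(rn: float, n: float) -> float:
    """Single-measurement reliability r1 from the reliability of an n-average."""
    if not 0 <= rn < 1:
        raise ValueError("rn must be in [0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    return rn / (n - (n - 1) * rn)


def equivalent_n(
    n_grid, values, target: float, method: str = "spline"
) -> float:
    """Fractional sample size at which a performance curve reaches ``target``.

    ``method="spline"`` (accuracy curves) interpolates the monotone curve
    with a cubic spline and solves for the target; ``method="spearman-brown"``
    (ISC curves) fits the single-unit reliability r1 to the curve and
    inverts the prediction formula in closed form.
    """
    n_grid = np.asarray(n_grid, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if len(n_grid) != len(values) or len(n_grid) < 2:
        raise ValueError("need matching n_grid and values with at least 2 points")
    if not (np.all(np.diff(n_grid) > 0) and np.all(np.diff(values) > 0)):
        raise ValueError("curve must be strictly increasing over the grid")
    if not values.min() <= target <= values.max():
        raise ValueError(f"target {target} outside curve range "
                         f"[{values.min():.4g}, {values.max():.4g}]")
    exact = np.flatnonzero(values == target)
    if len(exact):
        return float(n_grid[exact[0]])
    if method == "spline":
        spline = CubicSpline(n_grid, values)
        return float(brentq(lambda n: spline(n) - target, n_grid[0], n_grid[-1]))
    if method == "spearman-brown":
        r1 = float(np.mean([spearman_brown_inverse(v, n) for v, n in zip(values, n_grid)]))
        return float(target * (1.0 - r1) / (r1 * (1.0 - target)))
    raise ValueError(f"unknown method {method!r}")
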