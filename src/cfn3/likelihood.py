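"""Direct log-likelihood evaluation and an independent numerical maximizer.

The log-likelihood of edge parameters ``theta`` given split counts ``sbar`` is

    l(theta) = sum_alpha sbar_alpha * log(pbar_alpha(theta)) - N log 2,

an extended-real-valued function on the closed cube [0,1]^3: it is -inf
exactly when some split class with positive count has probability zero (which
happens only when two of the theta's equal 1 and a mismatch was observed).

The numerical oracle is deliberately independent of the closed-form solver: a
dense grid scan over the cube (boundary faces included, since maxima are
frequently on the boundary) followed by bounded L-BFGS-B refinement with the
analytic gradient, from the best grid points plus seeded random restarts.  It
exists to validate the closed form, and as the fallback for non-generic data
where the closed form's hypotheses fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import SPLIT_SIGNS, _as_theta
from .stats import SiteFrequencyVector, SplitFrequencyVector, split_collapse

__all__ = ["loglik", "loglik_grad", "numeric_oracle", "OracleResult"]

_LOG2 = np.log(2.0)


def _as_sbar(counts) -> SplitFrequencyVector:
    if isinstance(counts, SplitFrequencyVector):
        return counts
    if isinstance(counts, SiteFrequencyVector):
        return split_collapse(counts)
    return SplitFrequencyVector(tuple(int(c) for c in counts))


def _pbar_many(theta: np.ndarray) -> np.ndarray:
    """Split probabilities for an (m, 3) array of parameter points: (m, 4)."""
    prods = np.stack(
        [
            theta[:, 0] * theta[:, 1],
            theta[:, 0] * theta[:, 2],
            theta[:, 1] * theta[:, 2],
        ],
        axis=1,
    )
    return np.clip(0.25 * (1.0 + prods @ SPLIT_SIGNS.T), 0.0, 1.0)


def loglik(theta, counts) -> float:
    """Log-likelihood l(theta | sbar); returns -inf where the data forbid theta."""
    theta = _as_theta(theta)
    sbar = _as_sbar(counts).as_array()
    pbar = _pbar_many(theta[None, :])[0]
    n = int(sbar.sum())
    value = -n * _LOG2
    for c, p in zip(sbar, pbar):
        if c == 0:
            continue
        if p <= 0.0:
            return float("-inf")
        value += c * np.log(p)
    return float(value)


def loglik_grad(theta, counts) -> np.ndarray:
    """Analytic gradient of :func:`loglik` (finite region only).

    d pbar_alpha / d theta_1 = (1/4)(e12 theta_2 + e13 theta_3), etc., with
    e the split-sign matrix.
    """
    theta = _as_theta(theta)
    sbar = _as_sbar(counts).as_array().astype(float)
    pbar = _pbar_many(theta[None, :])[0]
    # d(pair products)/d(theta): rows = (t1t2, t1t3, t2t3), cols = theta index
    dprod = np.array(
        [
            [theta[1], theta[0], 0.0],
            [theta[2], 0.0, theta[0]],
            [0.0, theta[2], theta[1]],
        ]
    )
    dpbar = 0.25 * SPLIT_SIGNS @ dprod  # (4, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        weights = np.where(sbar > 0, sbar / np.where(pbar > 0, pbar, 1.0), 0.0)
    return weights @ dpbar


@dataclass
class OracleResult:
    """Outcome of the grid-then-refine likelihood maximization."""

    best_theta: np.ndarray
    best_loglik: float
    grid_resolution: int
    trace: list[dict] = field(default_factory=list)

    def to_dict(self, include_trace: bool = True) -> dict:
        out = {
            "best_theta": [float(t) for t in self.best_theta],
            "best_loglik": float(self.best_loglik),
            "grid_resolution": self.grid_resolution,
        }
        if include_trace:
            out["trace"] = self.trace
        return out


def numeric_oracle(
    counts,
    grid_n: int = 11,
    restarts: int = 5,
    seed: int = 0,
) -> OracleResult:
    """Maximize the log-likelihood over [0,1]^3 numerically.

    A ``grid_n``^3 scan (grid includes both boundary values 0 and 1) picks the
    most promising starts; bounded quasi-Newton refinement is run from the top
    grid points and from ``restarts`` seeded uniform draws.  Deterministic for
    a fixed seed.  The returned value is the best point ever evaluated, so it
    is always >= the best grid value.
    """
    if grid_n < 11:
        raise ValueError(f"grid_n must be >= 11, got {grid_n}")
    if restarts < 5:
        raise ValueError(f"restarts must be >= 5, got {restarts}")
    sbar = _as_sbar(counts)
    sarr = sbar.as_array().astype(float)
    n = float(sbar.N)

    axis = np.linspace(0.0, 1.0, grid_n)
    g1, g2, g3 = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([g1.ravel(), g2.ravel(), g3.ravel()], axis=1)
    pbar = _pbar_many(pts)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(pbar > 0.0, np.log(np.where(pbar > 0.0, pbar, 1.0)), -np.inf)
    contrib = np.where(sarr[None, :] > 0, sarr[None, :] * logp, 0.0)
    grid_ll = contrib.sum(axis=1) - n * _LOG2

    order = np.argsort(grid_ll)[::-1]
    n_top = min(4, len(order))
    rng = np.random.default_rng(seed)
    starts = [pts[i] for i in order[:n_top]]
    # the surface can have distinct local maxima on different boundary faces;
    # seed one refinement from the best grid point of every face of the cube
    for axis_idx in range(3):
        for bound in (0.0, 1.0):
            mask = pts[:, axis_idx] == bound
            finite = np.where(mask & np.isfinite(grid_ll))[0]
            if finite.size:
                starts.append(pts[finite[np.argmax(grid_ll[finite])]])
    starts += [rng.uniform(0.0, 1.0, size=3) for _ in range(restarts)]

    tiny = 1e-12

    def neg_ll(x):
        pb = np.clip(_pbar_many(x[None, :])[0], tiny, 1.0)
        return -(float(sarr @ np.log(pb)) - n * _LOG2)

    def neg_grad(x):
        return -loglik_grad(np.clip(x, 0.0, 1.0), sbar)

    best_idx = int(order[0])
    best_theta = pts[best_idx].copy()
    best_ll = float(grid_ll[best_idx])
    trace = []
    for x0 in starts:
        res = minimize(
            neg_ll,
            x0,
            jac=neg_grad,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * 3,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        cand = np.clip(res.x, 0.0, 1.0)
        cand_ll = loglik(cand, sbar)
        trace.append(
            {
                "start": [float(v) for v in x0],
                "converged": [float(v) for v in cand],
                "value": float(cand_ll),
            }
        )
        if cand_ll > best_ll:
            best_ll = cand_ll
            best_theta = cand
    return OracleResult(
        best_theta=best_theta,
        best_loglik=float(best_ll),
        grid_resolution=grid_n,
        trace=trace,
    )
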