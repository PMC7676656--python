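"""Treatment response functions Psi(T) and their calibration.

Psi(T) is the probability that a patient whose tumor truly carries T mut/Mb
responds to checkpoint-inhibitor treatment.  Three shapes are supported:

``step``
    A perfect predictor: respond iff ``T >= tau_resp``.
``two_level``
    Respond with probability ``p_high`` above the threshold, ``p_low`` below
    (e.g. 80% vs 20% ORR).
``gamma``
    The mechanistic dose-response: if immune activation requires the
    presentation of ``n`` neoepitopes and neoepitopes accrue with TMB as a
    Poisson process of rate ``r``, the waiting "time" (in TMB) to the n-th
    neoepitope is Gamma(n, r), so the response probability is the
    regularized lower incomplete gamma function P(n, r*T).  Shape 1 — a
    single immunodominant neoepitope — reduces to ``1 - exp(-r*T)``.

The gamma rate can either be fit to observed (TMB, response) pairs by
ordinary least squares over an integer shape grid, or calibrated so that a
chosen TMB quantile (e.g. the top-20% cutoff of a histology) yields a chosen
response probability (e.g. 50%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .cohort_io import Cohort
from .distributions import HistologyDistribution, quantile_threshold
from .errors import DegenerateDataError, InsufficientDataError, SolverError, ValidationError

__all__ = [
    "ResponseFunction",
    "evaluate_response",
    "fit_gamma_response",
    "calibrate_gamma_rate",
]


@dataclass(frozen=True)
class ResponseFunction:
    """A response curve; use the classmethod constructors."""

    kind: str
    tau_resp: float = 0.0
    p_high: float = 1.0
    p_low: float = 0.0
    shape_n: int = 1
    rate_r: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "two_level", "gamma"):
            raise ValidationError(f"unknown response kind {self.kind!r}")
        if not (0 <= self.p_low <= self.p_high <= 1):
            raise ValidationError("need 0 <= p_low <= p_high <= 1")
        if self.kind == "gamma":
            if self.shape_n < 1 or int(self.shape_n) != self.shape_n:
                raise ValidationError(f"shape_n must be a positive integer, got {self.shape_n}")
            if self.rate_r <= 0:
                raise ValidationError(f"rate_r must be > 0, got {self.rate_r}")
        elif self.tau_resp < 0:
            raise ValidationError(f"tau_resp must be >= 0, got {self.tau_resp}")

    @classmethod
    def step(cls, tau_resp: float) -> "ResponseFunction":
        return cls(kind="step", tau_resp=tau_resp)

    @classmethod
    def two_level(cls, tau_resp: float, p_high: float, p_low: float) -> "ResponseFunction":
        return cls(kind="two_level", tau_resp=tau_resp, p_high=p_high, p_low=p_low)

    @classmethod
    def gamma(cls, shape_n: int, rate_r: float) -> "ResponseFunction":
        return cls(kind="gamma", shape_n=int(shape_n), rate_r=rate_r)

    def __call__(self, T):
        return evaluate_response(self, T)

    def to_dict(self) -> dict:
        if self.kind == "step":
            return {"kind": "step", "tau_resp": self.tau_resp}
        if self.kind == "two_level":
            return {"kind": "two_level", "tau_resp": self.tau_resp,
                    "p_high": self.p_high, "p_low": self.p_low}
        return {"kind": "gamma", "shape_n": self.shape_n, "rate_r": self.rate_r}

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseFunction":
        return cls(**d)


def evaluate_response(psi: ResponseFunction, T):
    """Psi(T) for scalar or array T >= 0; always in [0, 1]."""
    arr = np.asarray(T, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any(arr < 0):
        raise ValidationError("T must be >= 0")
    if psi.kind == "step":
        out = (arr >= psi.tau_resp).astype(float)
    elif psi.kind == "two_level":
        out = np.where(arr >= psi.tau_resp, psi.p_high, psi.p_low)
    else:
        out = special.gammainc(psi.shape_n, psi.rate_r * arr)
    return float(out[0]) if scalar else out


def fit_gamma_response(
    data: Cohort,
    shape_grid=(1, 2, 3),
    rate_bounds: tuple[float, float] = (1e-4, 10.0),
) -> tuple[int, float, float]:
    """OLS fit of the gamma response to binary (tmb_wes, response) pairs.

    For each integer shape on the grid, the rate minimizing
    ``sum_i (response_i - Psi(T_i))**2`` is found by bounded scalar
    minimization (tolerance 1e-8); the (shape, rate) pair with the smallest
    error wins.  Returns ``(shape_n, rate_r, ols_error)``.
    """
    frame = data.frame
    mask = frame["tmb_wes"].notna() & frame["response"].notna()
    T = frame.loc[mask, "tmb_wes"].to_numpy(float)
    y = frame.loc[mask, "response"].to_numpy(float)
    if T.size < 10:
        raise InsufficientDataError(
            f"need >= 10 records with tmb_wes and response, got {T.size}"
        )
    if y.min() == y.max():
        raise DegenerateDataError(
            "responses are all identical; the response curve is unidentifiable"
        )
    shapes = [int(s) for s in shape_grid]
    if not shapes or min(shapes) < 1:
        raise ValidationError("shape_grid must contain positive integers")
    lo, hi = float(rate_bounds[0]), float(rate_bounds[1])
    if not (0 < lo < hi):
        raise ValidationError(f"bad rate bounds {rate_bounds}")

    best: tuple[int, float, float] | None = None
    for n in shapes:
        def err(rate: float, n=n) -> float:
            return float(np.sum((y - special.gammainc(n, rate * T)) ** 2))

        res = optimize.minimize_scalar(err, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        if best is None or res.fun < best[2]:
            best = (n, float(res.x), float(res.fun))
    assert best is not None
    return best


def calibrate_gamma_rate(
    dist: HistologyDistribution,
    shape_n: int,
    top_fraction: float,
    target_orr: float,
) -> float:
    """Rate such that Psi hits ``target_orr`` at the histology's top-fraction cutoff.

    Solves ``P(shape_n, rate * tau) = target_orr`` with
    ``tau = quantile_threshold(dist, top_fraction)``; since the regularized
    incomplete gamma is strictly increasing in the rate this inverts in
    closed form via ``gammaincinv``.
    """
    if not (0 < top_fraction < 1):
        raise ValidationError(f"top_fraction must be in (0, 1), got {top_fraction}")
    if not (0 < target_orr < 1):
        raise ValidationError(f"target_orr must be in (0, 1), got {target_orr}")
    if shape_n < 1 or int(shape_n) != shape_n:
        raise ValidationError(f"shape_n must be a positive integer, got {shape_n}")
    tau = quantile_threshold(dist, top_fraction)
    if tau <= 0:
        raise SolverError(
            f"top-fraction cutoff is {tau}; no finite rate reaches {target_orr} at 0"
        )
    rate = float(special.gammaincinv(shape_n, target_orr) / tau)
    achieved = float(special.gammainc(shape_n, rate * tau))
    if abs(achieved - target_orr) > 1e-6:
        raise SolverError(
            f"rate calibration round-trip failed: {achieved} vs {target_orr}"
        )
    return rate
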