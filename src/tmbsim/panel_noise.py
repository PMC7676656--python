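"""The panel measurement model Theta(T, tau, sigma).

A targeted panel of size ``L`` Mbp observes only a fraction ``K = L / L0`` of
the exome-wide mutation count ``t = T * L0`` (``L0`` ~ 35.6 Mbp).  The
recorded count is modelled as

    t_obs = K * t + Normal(0, sigma) + Poisson(lambda_driver),
    sigma = C0 + sqrt(K * t),

rounded to the nearest integer and clamped at zero; the reported panel TMB is
``t_obs / L``.  ``sqrt(K t)`` is the binomial sampling noise of reading a
Poisson-thin subset of the exome; ``C0`` is a panel-size-independent noise
floor (germline-subtraction residue and similar); ``lambda_driver`` is the
mean count of driver/hotspot mutations that panels are enriched for
regardless of size.  ``C0`` and ``lambda_driver`` are tissue-invariant.

``selection_probability`` is the chance that such a readout exceeds a
threshold ``tau`` (mut/Mb) — the biomarker's per-patient operating
characteristic.  The analytic path convolves the rounded, clamped Gaussian
with the Poisson mass; a Monte-Carlo path serves as an independent check.

Because the recorded count is an integer, the exceedance probability is a
step function of ``tau`` with jumps at multiples of ``1/L``.  Threshold
solvers need a threshold-continuous objective, so a panel can be built with
``discretize=False``, which skips rounding/clamping and makes the readout
(and everything downstream) smooth in ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort_io import Cohort
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "PanelModel",
    "ClassifierSpec",
    "panel_sigma",
    "simulate_panel_tmb",
    "simulate_cohort_readouts",
    "attach_panel_readouts",
    "selection_probability",
    "fit_noise_params",
    "DEFAULT_EXOME_SIZE",
    "DEFAULT_C0",
    "DEFAULT_LAMBDA",
]

DEFAULT_EXOME_SIZE = 35.6  # Mbp, human exome territory
DEFAULT_C0 = 0.5           # fitted panel-size-independent noise constant
DEFAULT_LAMBDA = 1.0       # fitted mean driver/germline bias count

#: Poisson mass beyond this cumulative tail is dropped in the convolution
POISSON_TAIL = 1e-12


@dataclass(frozen=True)
class PanelModel:
    """Noise parameters of one TMB assay.

    Attributes
    ----------
    panel_size : float
        Targeted territory L in Mbp; must satisfy ``0 < L <= exome_size``.
    exome_size : float
        Exome territory L0 in Mbp (default 35.6).
    c0 : float
        Panel-size-independent Gaussian noise constant (counts).
    lambda_driver : float
        Poisson rate of driver/germline bias counts.
    exact : bool
        An idealized noiseless device: reports T itself and classifies by
        ``T >= tau``.  Models "WES as gold standard" with zero noise.
    discretize : bool
        Round readout counts to integers and clamp at zero (the physical
        model).  ``False`` keeps the readout continuous in ``tau`` for
        threshold solving.
    """

    panel_size: float
    exome_size: float = DEFAULT_EXOME_SIZE
    c0: float = DEFAULT_C0
    lambda_driver: float = DEFAULT_LAMBDA
    exact: bool = False
    discretize: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.panel_size <= self.exome_size):
            raise ValidationError(
                f"panel_size must be in (0, {self.exome_size}], got {self.panel_size}"
            )
        if self.c0 < 0 or self.lambda_driver < 0:
            raise ValidationError("c0 and lambda_driver must be >= 0")

    @property
    def K(self) -> float:
        """Territory ratio L / L0 in (0, 1]."""
        return self.panel_size / self.exome_size

    @classmethod
    def noiseless(cls, exome_size: float = DEFAULT_EXOME_SIZE) -> "PanelModel":
        """The idealized zero-noise whole-exome device."""
        return cls(panel_size=exome_size, exome_size=exome_size,
                   c0=0.0, lambda_driver=0.0, exact=True)

    def continuous(self) -> "PanelModel":
        return replace(self, discretize=False)


@dataclass(frozen=True)
class ClassifierSpec:
    """A TMB-high decision rule: readout above ``threshold_tau`` (mut/Mb)."""

    threshold_tau: float

    def __post_init__(self) -> None:
        if self.threshold_tau < 0:
            raise ValidationError(f"threshold_tau must be >= 0, got {self.threshold_tau}")


def panel_sigma(panel: PanelModel, expected_panel_count) -> np.ndarray | float:
    """Gaussian noise scale ``sigma = C0 + sqrt(K t)`` in counts.

    ``expected_panel_count`` is ``K * t = T * L``, the mean number of
    mutations the panel should record.
    """
    kt = np.asarray(expected_panel_count, dtype=float)
    if np.any(kt < 0):
        raise ValidationError("expected panel count must be >= 0")
    out = panel.c0 + np.sqrt(kt)
    return float(out) if out.ndim == 0 else out


def _readout_counts(panel: PanelModel, kt: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    sigma = panel.c0 + np.sqrt(kt)
    x = kt + rng.normal(0.0, 1.0, size=kt.shape) * sigma
    if panel.lambda_driver > 0:
        x = x + rng.poisson(panel.lambda_driver, size=kt.shape)
    if panel.discretize:
        x = np.maximum(np.rint(x), 0.0)
    return x


def simulate_panel_tmb(panel: PanelModel, true_tmb: float, n_reps: int, seed) -> np.ndarray:
    """``n_reps`` panel TMB readouts (mut/Mb) for one true burden.

    Discretizing panels return nonnegative multiples of ``1/L``; the exact
    device returns ``true_tmb`` unchanged.
    """
    if true_tmb < 0:
        raise ValidationError(f"true_tmb must be >= 0, got {true_tmb}")
    if n_reps < 0:
        raise ValidationError(f"n_reps must be >= 0, got {n_reps}")
    if panel.exact:
        return np.full(int(n_reps), float(true_tmb))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kt = np.full(int(n_reps), float(true_tmb) * panel.panel_size)
    return _readout_counts(panel, kt, rng) / panel.panel_size


def simulate_cohort_readouts(panel: PanelModel, true_tmb_values, seed) -> np.ndarray:
    """One panel readout (mut/Mb) per true TMB value; the paired-cohort front end."""
    T = np.asarray(true_tmb_values, dtype=float)
    if np.any(T < 0):
        raise ValidationError("true TMB values must be >= 0")
    if panel.exact:
        return T.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _readout_counts(panel, T * panel.panel_size, rng) / panel.panel_size


def attach_panel_readouts(cohort: Cohort, panel: PanelModel, seed) -> Cohort:
    """Return a copy of the cohort with ``tmb_panel`` filled by simulation."""
    frame = cohort.frame.copy()
    frame["tmb_panel"] = simulate_cohort_readouts(panel, frame["tmb_wes"].to_numpy(float), seed)
    return Cohort(frame, provenance=cohort.provenance + f"+panel(L={panel.panel_size})")


def _poisson_support(lam: float) -> tuple[np.ndarray, np.ndarray]:
    if lam == 0:
        return np.array([0]), np.array([1.0])
    jmax = int(stats.poisson.isf(POISSON_TAIL, lam)) + 1
    j = np.arange(jmax + 1)
    w = stats.poisson.pmf(j, lam)
    return j, w / w.sum()


def selection_probability(
    panel: PanelModel,
    spec: ClassifierSpec,
    true_tmb,
    method: str = "analytic",
    n_mc: int = 1_000_000,
    seed=None,
):
    """P(panel readout > tau) for a patient with true burden T.

    The analytic path sums the Poisson driver mass against the Gaussian
    survival function with the half-integer continuity correction implied by
    rounding; Monte Carlo replays ``simulate_panel_tmb`` and counts
    exceedances.  The exact (noiseless) device is the step ``1{T >= tau}``.
    Accepts scalar or array T; returns matching shape.
    """
    T = np.asarray(true_tmb, dtype=float)
    scalar = T.ndim == 0
    T = np.atleast_1d(T)
    if np.any(T < 0):
        raise ValidationError("true TMB must be >= 0")

    if panel.exact:
        out = (T >= spec.threshold_tau).astype(float)
        return float(out[0]) if scalar else out

    if method == "monte_carlo":
        if n_mc <= 0:
            raise ValidationError("monte_carlo requires n_mc >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out = np.empty(T.shape)
        for i, t in enumerate(T):
            draws = simulate_panel_tmb(panel, float(t), n_mc, rng)
            out[i] = np.mean(draws > spec.threshold_tau)
        return float(out[0]) if scalar else out
    if method != "analytic":
        raise ValidationError(f"unknown method {method!r}")

    L = panel.panel_size
    kt = T * L
    sigma = panel.c0 + np.sqrt(kt)
    tau_counts = spec.threshold_tau * L
    if panel.discretize:
        # smallest integer count m with m / L > tau, then P(round(x) >= m)
        edge = np.floor(tau_counts) + 1.0 - 0.5
    else:
        edge = tau_counts

    j, w = _poisson_support(panel.lambda_driver)
    # z[i, j] = (kt_i + j - edge) / sigma_i ; P = sum_j w_j Phi(z)
    shift = kt[:, None] + j[None, :] - edge
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = shift / sigma[:, None]
    prob = np.where(sigma[:, None] > 0, special.ndtr(z), (shift >= 0).astype(float))
    out = np.clip(prob @ w, 0.0, 1.0)
    return float(out[0]) if scalar else out


def fit_noise_params(
    paired: Cohort,
    panel_size: float,
    grid_c0,
    grid_lambda,
    concordance: str = "energy_distance",
    seed: int = 0,
    exome_size: float = DEFAULT_EXOME_SIZE,
    n_sim_reps: int = 8,
) -> tuple[float, float, pd.DataFrame]:
    """Grid search for the tissue-invariant noise constants (C0, lambda).

    For every grid point, ``n_sim_reps`` panel readouts are simulated from
    each record's ``tmb_wes`` (common random numbers across grid points,
    replicates suppressing simulation noise) and the pooled sample is scored
    against the observed ``tmb_panel`` by either the RMSE between matched
    quantiles (``quantile_rmse``) or the two-sample energy distance
    (``energy_distance``).  Returns the minimizing ``(c0, lambda)`` and the
    full score table.
    """
    grid_c0 = [float(c) for c in grid_c0]
    grid_lambda = [float(l) for l in grid_lambda]
    if not grid_c0 or not grid_lambda:
        raise ValidationError("parameter grids must be non-empty")
    if min(grid_c0) < 0 or min(grid_lambda) < 0:
        raise ValidationError("grid values must be >= 0")
    if concordance not in ("quantile_rmse", "energy_distance"):
        raise ValidationError(f"unknown concordance objective {concordance!r}")

    wes, observed = paired.paired_values()
    if wes.size < 20:
        raise InsufficientDataError(
            f"need >= 20 paired (tmb_wes, tmb_panel) records, got {wes.size}"
        )
    if n_sim_reps < 1:
        raise ValidationError(f"n_sim_reps must be >= 1, got {n_sim_reps}")
    observed_sorted = np.sort(observed)
    # order-statistic probability points of the observed sample
    probs = (np.arange(1, observed.size + 1) - 0.5) / observed.size
    wes_tiled = np.tile(wes, n_sim_reps)

    rows = []
    for c0 in grid_c0:
        for lam in grid_lambda:
            panel = PanelModel(panel_size=panel_size, exome_size=exome_size,
                               c0=c0, lambda_driver=lam)
            sim = simulate_cohort_readouts(panel, wes_tiled, np.random.default_rng(seed))
            if concordance == "quantile_rmse":
                sim_q = np.quantile(sim, probs)
                score = float(np.sqrt(np.mean((sim_q - observed_sorted) ** 2)))
            else:
                score = float(stats.energy_distance(sim, observed))
            rows.append({"c0": c0, "lambda_driver": lam, "score": score})
    table = pd.DataFrame(rows).sort_values("score", kind="stable").reset_index(drop=True)
    best = table.iloc[0]
    return float(best["c0"]), float(best["lambda_driver"]), table
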