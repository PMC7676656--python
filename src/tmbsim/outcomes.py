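"""Observable consequences of noisy TMB stratification.

Everything a trialist cares about follows from three ingredients — the
histology's true-TMB density Pi(T), the assay's selection characteristic
Theta(T, tau, sigma), and the response curve Psi(T):

* treated fraction ("market size")   Z = integral Pi * Theta dT
* expected overall response rate     ORR = integral Pi * Psi * Theta dT / Z
* agreement of the noisy panel call with the noiseless whole-exome call
  (PPA/NPA/OPA and PPV/NPV), estimated by Monte Carlo because rounding and
  clamping leave the joint (truth, call) law without a usable closed form.

Z and ORR are evaluated by trapezoidal quadrature on the distribution's own
grid, so identities like "Psi constant c implies ORR = c" hold to machine
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .distributions import HistologyDistribution, quantile_threshold, sample_tmb
from .errors import ValidationError, ZeroSelectionError
from .panel_noise import ClassifierSpec, PanelModel, selection_probability, simulate_cohort_readouts
from .response import ResponseFunction, evaluate_response

__all__ = [
    "OutcomeSummary",
    "ClassificationMetrics",
    "treated_fraction",
    "expected_orr",
    "classification_metrics",
    "outcome_grid",
]


@dataclass(frozen=True)
class ClassificationMetrics:
    """Agreement of the panel call with noiseless truth; NaN marks an
    undefined metric (empty stratum), never coerced to 0 or 1."""

    ppa: float
    npa: float
    opa: float
    ppv: float
    npv: float


@dataclass(frozen=True)
class OutcomeSummary:
    """One (histology, panel size, threshold) cell of the outcome grid."""

    histology: str
    panel_size: float
    threshold_tau: float
    orr: float
    treated_fraction: float
    ppa: float
    npa: float
    opa: float
    ppv: float
    npv: float


def _grid_with_breaks(
    dist: HistologyDistribution, breaks
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution grid with nodes straddling each integrand jump.

    The noiseless device, the step/two-level response curves, and the truth
    indicator are discontinuous in T; trapezoidal quadrature across the
    straddled cell would smear the jump, so a node pair is inserted just
    below and at each breakpoint.  Returns (grid, density-at-grid).
    """
    grid = dist.grid
    inner = [b for b in breaks if grid[0] < b < grid[-1]]
    if inner:
        eps = 1e-9 * max(1.0, grid[-1])
        extra = np.concatenate([[b - eps, b] for b in inner])
        grid = np.union1d(grid, extra)
    return grid, dist.pdf(grid)


def _quadrature_grid(
    dist: HistologyDistribution,
    panel: PanelModel,
    spec: ClassifierSpec,
    psi: ResponseFunction | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    breaks = []
    if panel.exact:
        breaks.append(spec.threshold_tau)
    if psi is not None and psi.kind in ("step", "two_level"):
        breaks.append(psi.tau_resp)
    return _grid_with_breaks(dist, breaks)


def treated_fraction(
    dist: HistologyDistribution, panel: PanelModel, spec: ClassifierSpec
) -> float:
    """Fraction of the population the assay would select, Z in [0, 1]."""
    grid, density = _quadrature_grid(dist, panel, spec)
    theta = selection_probability(panel, spec, grid)
    z = float(np.trapezoid(density * theta, grid))
    return min(max(z, 0.0), 1.0)


def expected_orr(
    dist: HistologyDistribution,
    psi: ResponseFunction,
    panel: PanelModel,
    spec: ClassifierSpec,
) -> float:
    """Expected response rate of the selected group (Bayes ratio of quadratures)."""
    grid, density = _quadrature_grid(dist, panel, spec, psi)
    theta = selection_probability(panel, spec, grid)
    weight = density * theta
    z = float(np.trapezoid(weight, grid))
    if z <= 0.0:
        raise ZeroSelectionError(
            f"no patient selected at tau={spec.threshold_tau}; ORR undefined"
        )
    num = float(np.trapezoid(weight * evaluate_response(psi, grid), grid))
    return num / z


def _agreement(truth: np.ndarray, call: np.ndarray) -> ClassificationMetrics:
    tp = int(np.sum(truth & call))
    fn = int(np.sum(truth & ~call))
    fp = int(np.sum(~truth & call))
    tn = int(np.sum(~truth & ~call))

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return ClassificationMetrics(
        ppa=ratio(tp, tp + fn),
        npa=ratio(tn, tn + fp),
        opa=ratio(tp + tn, tp + fn + fp + tn),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


def classification_metrics(
    dist: HistologyDistribution,
    panel: PanelModel,
    spec_panel: ClassifierSpec,
    spec_truth: ClassifierSpec | None = None,
    n_mc: int = 100_000,
    seed=0,
    method: str = "monte_carlo",
) -> ClassificationMetrics:
    """2x2 agreement of the panel call against noiseless truth.

    Truth is the zero-noise whole-exome call ``T >= spec_truth.tau``;
    the test call is a simulated panel readout exceeding ``spec_panel.tau``.
    ``spec_truth`` defaults to ``spec_panel`` (same intended threshold), but
    the two stay distinct so harmonized thresholds can be scored against the
    original clinical cutoff.

    ``method="monte_carlo"`` replays the full simulation; ``"quadrature"``
    exploits that truth is a deterministic function of T, so the expected
    confusion-table cells are integrals of ``Pi * Theta`` over the two truth
    strata and carry no sampling error.
    """
    if spec_truth is None:
        spec_truth = spec_panel
    if method == "quadrature":
        grid, density = _grid_with_breaks(dist, [spec_truth.threshold_tau])
        theta = selection_probability(panel, spec_panel, grid)
        high = grid >= spec_truth.threshold_tau
        tp = float(np.trapezoid(density * theta * high, grid))
        fp = float(np.trapezoid(density * theta * ~high, grid))
        fn = float(np.trapezoid(density * (1 - theta) * high, grid))
        tn = float(np.trapezoid(density * (1 - theta) * ~high, grid))

        def ratio(num: float, den: float) -> float:
            return num / den if den > 0 else math.nan

        return ClassificationMetrics(
            ppa=ratio(tp, tp + fn),
            npa=ratio(tn, tn + fp),
            opa=ratio(tp + tn, tp + fp + fn + tn),
            ppv=ratio(tp, tp + fp),
            npv=ratio(tn, tn + fn),
        )
    if method != "monte_carlo":
        raise ValidationError(f"unknown method {method!r}")
    if n_mc < 1000:
        raise ValidationError(f"n_mc must be >= 1000 for stable metrics, got {n_mc}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = sample_tmb(dist, n_mc, rng)
    truth = T >= spec_truth.threshold_tau
    readout = simulate_cohort_readouts(panel, T, rng)
    call = readout > spec_panel.threshold_tau if not panel.exact else T >= spec_panel.threshold_tau
    return _agreement(truth, call)


def outcome_grid(
    dists,
    psi: ResponseFunction,
    panel_sizes,
    thresholds,
    n_mc: int = 50_000,
    seed: int = 0,
    c0: float | None = None,
    lambda_driver: float | None = None,
    exome_size: float | None = None,
) -> pd.DataFrame:
    """Outcome summaries over histologies x panel sizes x thresholds.

    ``thresholds`` entries are either fixed cutoffs (floats, mut/Mb) or
    ``{"top_fraction": q}`` dicts resolved per histology through the
    quantile operation.  Cell failures (e.g. nobody selected) are recorded
    in an ``error`` column instead of aborting the grid.  Deterministic for
    a given seed: each cell draws from its own spawned substream.
    """
    dists = list(dists)
    panel_sizes = [float(x) for x in panel_sizes]
    thresholds = list(thresholds)
    if not dists or not panel_sizes or not thresholds:
        raise ValidationError("grids must be non-empty")

    panel_kwargs = {}
    if c0 is not None:
        panel_kwargs["c0"] = c0
    if lambda_driver is not None:
        panel_kwargs["lambda_driver"] = lambda_driver
    if exome_size is not None:
        panel_kwargs["exome_size"] = exome_size

    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(dists) * len(panel_sizes) * len(thresholds))
    rows = []
    cell = 0
    for dist in dists:
        for L in panel_sizes:
            panel = PanelModel(panel_size=L, **panel_kwargs)
            for thr in thresholds:
                rng = np.random.default_rng(streams[cell])
                cell += 1
                if isinstance(thr, dict):
                    tau = quantile_threshold(dist, float(thr["top_fraction"]))
                else:
                    tau = float(thr)
                spec = ClassifierSpec(tau)
                row = {"histology": dist.histology, "panel_size": L, "threshold_tau": tau}
                try:
                    row["treated_fraction"] = treated_fraction(dist, panel, spec)
                    row["orr"] = expected_orr(dist, psi, panel, spec)
                    metrics = classification_metrics(dist, panel, spec, spec, n_mc=n_mc, seed=rng)
                    row.update(asdict(metrics))
                    row["error"] = ""
                except Exception as exc:  # recorded per cell, grid continues
                    for key in ("treated_fraction", "orr", "ppa", "npa", "opa", "ppv", "npv"):
                        row.setdefault(key, math.nan)
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    cols = ["histology", "panel_size", "threshold_tau", "orr", "treated_fraction",
            "ppa", "npa", "opa", "ppv", "npv", "error"]
    return pd.DataFrame(rows)[cols]
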