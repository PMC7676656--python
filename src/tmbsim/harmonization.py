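"""Cross-assay harmonization: regression mapping, threshold solvers, and the
fraction-vs-ORR trade-off.

The field's default way to map panel TMB onto exome TMB is ordinary linear
regression of paired measurements.  This module provides that regression and
a bootstrap scan showing why it misleads: even when the generative map is
histology-agnostic by construction (panel counts are just a thinned copy of
exome counts), the fitted slopes and offsets vary with histology, because
low-TMB cohorts live where the count noise is discrete, skewed, and bounded
below by zero.

It also provides the two threshold solvers a harmonizer actually needs —
match the treated fraction, or match the expected ORR — plus the trade-off
report demonstrating that for assays with different noise no single
threshold satisfies both, and a two-sample Cramér (energy-type) concordance
test with permutation p-values for comparing readout distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort
from .distributions import HistologyDistribution, sample_tmb
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    SolverError,
    ValidationError,
    ZeroSelectionError,
)
from .outcomes import expected_orr, treated_fraction
from .panel_noise import ClassifierSpec, PanelModel, simulate_cohort_readouts
from .response import ResponseFunction

__all__ = [
    "RegressionFit",
    "regress_panel_vs_wes",
    "regression_variability_scan",
    "threshold_for_fraction",
    "threshold_for_orr",
    "harmonization_tradeoff",
    "cramer_concordance",
    "select_top_fraction",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS of panel TMB on exome TMB (both mut/Mb) for one histology."""

    histology: str
    slope: float
    intercept: float
    r_squared: float
    n_pairs: int


def regress_panel_vs_wes(paired: Cohort, histology: str | None = None) -> RegressionFit:
    """Ordinary least squares of ``tmb_panel`` on ``tmb_wes``."""
    wes, panel = paired.paired_values(histology)
    if wes.size < 2:
        raise InsufficientDataError(
            f"need >= 2 paired records, got {wes.size}"
        )
    if np.ptp(wes) == 0:
        raise DegenerateDataError("tmb_wes has zero variance; slope undefined")
    res = stats.linregress(wes, panel)
    return RegressionFit(
        histology=histology or "all",
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_pairs=int(wes.size),
    )


def _bootstrap_slopes(
    wes: np.ndarray, panel: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    n = wes.size
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        x, y = wes[idx], panel[idx]
        if np.ptp(x) == 0:
            slopes[b] = np.nan
            continue
        xm, ym = x.mean(), y.mean()
        slopes[b] = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    return slopes


def regression_variability_scan(
    dists,
    panel: PanelModel,
    n_per_cohort: int = 500,
    n_boot: int = 200,
    seed: int = 0,
    method: str = "model",
) -> pd.DataFrame:
    """Bootstrap slope dispersion of the panel-vs-exome regression per histology.

    For each histology a paired cohort is simulated (true TMB from the
    density; panel readout either from the full noise model or from pure
    binomial thinning of exome counts, ``method="binomial"``), the OLS slope
    is bootstrapped, and its interquartile range is reported.  Rows are
    sorted by ascending median TMB.
    """
    dists = list(dists)
    if len(dists) < 2:
        raise InsufficientDataError("need >= 2 histologies to compare variability")
    if n_boot < 50:
        raise ValidationError(f"n_boot must be >= 50, got {n_boot}")
    if method not in ("model", "binomial"):
        raise ValidationError(f"unknown method {method!r}")

    root = np.random.SeedSequence(seed)
    rows = []
    for dist, stream in zip(dists, root.spawn(len(dists))):
        rng = np.random.default_rng(stream)
        T = sample_tmb(dist, n_per_cohort, rng)
        if method == "model":
            readout = simulate_cohort_readouts(panel, T, rng)
        else:
            counts = rng.binomial(np.rint(T * panel.exome_size).astype(int), panel.K)
            readout = counts / panel.panel_size
        slopes = _bootstrap_slopes(T, readout, n_boot, rng)
        q25, q50, q75 = np.nanpercentile(slopes, [25, 50, 75])
        rows.append(
            {
                "histology": dist.histology,
                "median_tmb": dist.median,
                "slope_median": float(q50),
                "slope_iqr": float(q75 - q25),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("median_tmb", kind="stable")
        .reset_index(drop=True)
    )


def _bisect_threshold(objective, lo: float, hi: float, target: float,
                      increasing: bool, tol: float) -> float:
    """Leftmost tau in [lo, hi] whose monotone objective meets the target."""
    f_lo, f_hi = objective(lo), objective(hi)
    lo_val, hi_val = (f_lo, f_hi) if increasing else (f_hi, f_lo)
    if not (min(lo_val, hi_val) - tol <= target <= max(lo_val, hi_val) + tol):
        raise SolverError(
            f"target {target} outside attainable range "
            f"[{min(f_lo, f_hi):.6f}, {max(f_lo, f_hi):.6f}] on tau in [{lo}, {hi}]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = objective(mid)
        reached = val >= target if increasing else val <= target
        if reached:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-12 * max(1.0, hi):
            break
    return hi


def threshold_for_fraction(
    dist: HistologyDistribution,
    panel: PanelModel,
    target_fraction: float,
    tol: float = 1e-3,
) -> float:
    """Threshold tau with ``treated_fraction == target_fraction`` (± tol).

    Uses bisection on the nonincreasing map tau -> Z.  A discretizing panel
    makes Z a step function of tau that may jump over the target; build the
    panel with ``discretize=False`` when an exact match is required.
    """
    if not (0 < target_fraction < 1):
        raise ValidationError(f"target_fraction must be in (0, 1), got {target_fraction}")
    hi = dist.support_max + 10.0 * (panel.c0 + 1.0 + panel.lambda_driver) / panel.panel_size
    tau = _bisect_threshold(
        lambda t: treated_fraction(dist, panel, ClassifierSpec(t)),
        0.0, hi, target_fraction, increasing=False, tol=tol,
    )
    achieved = treated_fraction(dist, panel, ClassifierSpec(tau))
    if abs(achieved - target_fraction) > tol:
        raise SolverError(
            f"treated fraction jumps over {target_fraction}: closest {achieved:.4f} "
            f"at tau={tau:.4f} (discrete readout; try panel.continuous())"
        )
    return float(tau)


def threshold_for_orr(
    dist: HistologyDistribution,
    panel: PanelModel,
    psi: ResponseFunction,
    target_orr: float,
    tol: float = 1e-3,
) -> float:
    """Smallest threshold tau with ``expected_orr == target_orr`` (± tol).

    ORR is nondecreasing in tau for a nondecreasing response function, so the
    leftmost satisfying tau is found by bisection; plateaus (e.g. a perfect
    step response on a noiseless device) resolve to their left edge.
    """
    hi = dist.support_max + 10.0 * (panel.c0 + 1.0 + panel.lambda_driver) / panel.panel_size

    def orr_at(tau: float) -> float:
        try:
            return expected_orr(dist, psi, panel, ClassifierSpec(tau))
        except ZeroSelectionError:
            # nobody left below tau: the selected group degenerates to the
            # extreme upper tail, where the response is Psi(support max)
            return float(psi(dist.support_max))

    tau = _bisect_threshold(orr_at, 0.0, hi, target_orr, increasing=True, tol=tol)
    achieved = orr_at(tau)
    if abs(achieved - target_orr) > tol:
        raise SolverError(
            f"expected ORR cannot reach {target_orr} within {tol}: closest "
            f"{achieved:.4f} at tau={tau:.4f}"
        )
    return float(tau)


def harmonization_tradeoff(
    dist: HistologyDistribution,
    panel_a: PanelModel,
    panel_b: PanelModel,
    psi: ResponseFunction,
    target_fraction: float = 0.2,
    target_orr: float = 0.5,
    tol: float = 0.01,
) -> dict:
    """Cross-evaluate fraction-matched and ORR-matched thresholds on two assays.

    Harmonizing two assays means choosing a threshold per assay.  Pinning the
    treated fraction at ``target_fraction`` on both fixes both thresholds —
    the expected ORRs then generally differ; pinning the ORR at
    ``target_orr`` on both fixes a different threshold pair — the treated
    fractions then differ.  The report carries both threshold pairs, the
    off-criterion values they achieve, and the cross-assay gaps;
    ``harmonizable_in_both`` is true only when one threshold pair meets both
    criteria within ``tol`` (identical devices), which assays with different
    noise cannot do.
    """
    report: dict = {
        "target_fraction": target_fraction,
        "target_orr": target_orr,
        "tolerance": tol,
        "panels": {},
    }
    for name, panel in (("panel_a", panel_a), ("panel_b", panel_b)):
        tau_frac = threshold_for_fraction(dist, panel, target_fraction)
        tau_orr = threshold_for_orr(dist, panel, psi, target_orr)
        report["panels"][name] = {
            "panel_size": panel.panel_size,
            "tau_fraction": tau_frac,
            "tau_orr": tau_orr,
            "orr_at_tau_fraction": expected_orr(dist, psi, panel, ClassifierSpec(tau_frac)),
            "fraction_at_tau_orr": treated_fraction(dist, panel, ClassifierSpec(tau_orr)),
        }
    a, b = report["panels"]["panel_a"], report["panels"]["panel_b"]
    report["orr_gap_at_matched_fraction"] = (
        a["orr_at_tau_fraction"] - b["orr_at_tau_fraction"]
    )
    report["fraction_gap_at_matched_orr"] = (
        a["fraction_at_tau_orr"] - b["fraction_at_tau_orr"]
    )
    report["tau_gap_fraction_vs_orr"] = {
        "panel_a": a["tau_fraction"] - a["tau_orr"],
        "panel_b": b["tau_fraction"] - b["tau_orr"],
    }
    report["harmonizable_in_both"] = bool(
        abs(report["orr_gap_at_matched_fraction"]) <= tol
        and abs(report["fraction_gap_at_matched_orr"]) <= tol
    )
    return report


def select_top_fraction(values, top_fraction: float) -> np.ndarray:
    """Boolean mask of the top ``top_fraction`` of readouts by empirical quantile.

    Quantile selection is invariant under strictly increasing affine
    transforms of the readouts, which is why linear rescaling cannot
    harmonize assays: it never changes who is selected.
    """
    values = np.asarray(values, dtype=float)
    if not (0 < top_fraction <= 1):
        raise ValidationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    cutoff = np.quantile(values, 1.0 - top_fraction)
    return values >= cutoff


def _cramer_statistic(a: np.ndarray, b: np.ndarray) -> float:
    n, m = a.size, b.size
    ab = np.abs(a[:, None] - b[None, :]).mean()
    aa = np.abs(a[:, None] - a[None, :]).mean()
    bb = np.abs(b[:, None] - b[None, :]).mean()
    return n * m / (n + m) * (ab - 0.5 * aa - 0.5 * bb)


def cramer_concordance(
    sample_a, sample_b, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Two-sample Cramér (energy-type) test with a permutation null.

    The statistic is ``nm/(n+m) * (mean|a-b| - mean|a-a'|/2 - mean|b-b'|/2)``,
    zero iff the empirical distributions coincide.  The p-value is the
    permutation tail ``(1 + #{perm >= observed}) / (n_perm + 1)``, in (0, 1].
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
    observed = _cramer_statistic(a, b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _cramer_statistic(perm[: a.size], perm[a.size :]) >= observed:
            count += 1
    return float(observed), (1 + count) / (n_perm + 1)
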