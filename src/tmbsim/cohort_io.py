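"""Cohort tables: reading, validation, synthesis, and binomial thinning.

The canonical cohort table is a CSV/TSV file with a mandatory header and the
columns ``sample_id``, ``histology``, ``tmb_wes`` and, optionally,
``tmb_panel`` and ``response``.  TMB values are in mutations per megabase
(mut/Mb).  ``tmb_wes`` holds the whole-exome ("true") burden T; ``tmb_panel``
holds a paired panel readout when one exists; ``response`` is a 0/1 treatment
response indicator.

Synthetic cohorts emulate the shapes of real histology TMB distributions:
a heavy-tailed lung-adenocarcinoma-like mixture, a high-median
squamous-like lognormal, a low-burden breast/prostate-like lognormal, and a
uniform preset for analytic tests.  ``thin_to_panel`` implements the
read-subsampling view of panel measurement — each exome mutation falls on the
panel territory independently with probability ``panel size / exome size`` —
and serves as the brute-force oracle for the Gaussian noise approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError

__all__ = [
    "TMBRecord",
    "Cohort",
    "PRESETS",
    "SyntheticPreset",
    "read_tmb_table",
    "read_tmb_xlsx",
    "write_tmb_table",
    "generate_synthetic_cohort",
    "thin_to_panel",
]

MANDATORY_COLUMNS = ("sample_id", "histology", "tmb_wes")
OPTIONAL_COLUMNS = ("tmb_panel", "response")


@dataclass(frozen=True)
class TMBRecord:
    """One patient's TMB measurements.

    Attributes
    ----------
    sample_id : str
        Opaque unique identifier.
    histology : str
        Cancer-type code (e.g. ``LUAD``, ``LUSC``, ``BRCA``, ``PRAD``).
    tmb_wes : float
        Whole-exome TMB in mut/Mb; the proxy for the true burden T.
    tmb_panel : float or None
        Paired panel TMB in mut/Mb, if measured.
    response : int or None
        Binary treatment response (1 = responder), if observed.
    """

    sample_id: str
    histology: str
    tmb_wes: float
    tmb_panel: float | None = None
    response: int | None = None

    def __post_init__(self) -> None:
        if not self.histology:
            raise ValidationError("histology must be non-empty")
        if not (self.tmb_wes >= 0):
            raise ValidationError(f"tmb_wes must be >= 0, got {self.tmb_wes}")
        if self.tmb_panel is not None and not (self.tmb_panel >= 0):
            raise ValidationError(f"tmb_panel must be >= 0, got {self.tmb_panel}")
        if self.response is not None and self.response not in (0, 1):
            raise ValidationError(f"response must be 0/1, got {self.response}")


@dataclass
class Cohort:
    """An ordered collection of :class:`TMBRecord` backed by a DataFrame."""

    frame: pd.DataFrame
    provenance: str = ""

    @classmethod
    def from_records(cls, records: Sequence[TMBRecord], provenance: str = "") -> "Cohort":
        frame = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in records],
                "histology": [r.histology for r in records],
                "tmb_wes": [r.tmb_wes for r in records],
                "tmb_panel": [r.tmb_panel for r in records],
                "response": [r.response for r in records],
            }
        )
        return cls(frame, provenance)

    def __post_init__(self) -> None:
        for col in MANDATORY_COLUMNS:
            if col not in self.frame.columns:
                raise SchemaError(f"cohort frame missing mandatory column {col!r}")
        for col in OPTIONAL_COLUMNS:
            if col not in self.frame.columns:
                self.frame[col] = np.nan
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[TMBRecord]:
        for row in self.frame.itertuples(index=False):
            yield TMBRecord(
                sample_id=str(row.sample_id),
                histology=str(row.histology),
                tmb_wes=float(row.tmb_wes),
                tmb_panel=None if pd.isna(row.tmb_panel) else float(row.tmb_panel),
                response=None if pd.isna(row.response) else int(row.response),
            )

    @property
    def histologies(self) -> list[str]:
        return sorted(self.frame["histology"].unique().tolist())

    def subset(self, histology: str) -> "Cohort":
        sub = self.frame[self.frame["histology"] == histology].reset_index(drop=True)
        return Cohort(sub.copy(), provenance=self.provenance)

    def filter_min_count(self, min_count: int = 100) -> "Cohort":
        """Keep only histologies with at least ``min_count`` samples."""
        counts = self.frame["histology"].value_counts()
        keep = counts[counts >= min_count].index
        sub = self.frame[self.frame["histology"].isin(keep)].reset_index(drop=True)
        return Cohort(sub.copy(), provenance=self.provenance)

    def wes_values(self, histology: str | None = None) -> np.ndarray:
        frame = self.frame if histology is None else self.frame[self.frame["histology"] == histology]
        vals = frame["tmb_wes"].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]

    def paired_values(self, histology: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(tmb_wes, tmb_panel) for rows where both are present."""
        frame = self.frame if histology is None else self.frame[self.frame["histology"] == histology]
        mask = frame["tmb_wes"].notna() & frame["tmb_panel"].notna()
        sub = frame[mask]
        return (
            sub["tmb_wes"].to_numpy(dtype=float),
            sub["tmb_panel"].to_numpy(dtype=float),
        )


def _validate_frame(frame: pd.DataFrame, source: str) -> pd.DataFrame:
    problems: list[str] = []
    for col in MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"{source}: missing mandatory column {col!r}")
    for col in OPTIONAL_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan

    for col in ("tmb_wes", "tmb_panel", "response"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")

    # row numbers reported are 1-based data rows (header = row 0)
    for idx, row in frame.iterrows():
        rowno = int(idx) + 1
        if pd.isna(row["sample_id"]) or str(row["sample_id"]) == "":
            problems.append(f"row {rowno}: empty sample_id")
        if pd.isna(row["histology"]) or str(row["histology"]) == "":
            problems.append(f"row {rowno}: empty histology")
        if pd.isna(row["tmb_wes"]):
            problems.append(f"row {rowno}: tmb_wes missing or non-numeric")
        elif row["tmb_wes"] < 0:
            problems.append(f"row {rowno}: negative tmb_wes ({row['tmb_wes']})")
        if not pd.isna(row["tmb_panel"]) and row["tmb_panel"] < 0:
            problems.append(f"row {rowno}: negative tmb_panel ({row['tmb_panel']})")
        if not pd.isna(row["response"]) and row["response"] not in (0, 1):
            problems.append(f"row {rowno}: response not binary ({row['response']})")
    dup = frame["sample_id"].astype(str).duplicated()
    for idx in frame.index[dup]:
        problems.append(f"row {int(idx) + 1}: duplicate sample_id {frame.loc[idx, 'sample_id']!r}")
    if problems:
        raise ValidationError(f"{source}: " + "; ".join(problems))
    frame["sample_id"] = frame["sample_id"].astype(str)
    frame["histology"] = frame["histology"].astype(str)
    return frame


def read_tmb_table(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a cohort table from CSV or TSV.

    Parameters
    ----------
    path : path
        File with a header containing at least sample_id, histology, tmb_wes.
    format : {"csv", "tsv"}, optional
        Defaults to the file extension (``.tsv``/``.tab`` means tab-separated).
    column_map : mapping, optional
        ``{source_column: canonical_column}`` renames applied before
        validation, for ingesting externally-named spreadsheets.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if format not in ("csv", "tsv"):
        raise ConfigurationError(f"unknown table format {format!r}")
    sep = "\t" if format == "tsv" else ","
    frame = pd.read_csv(path, sep=sep)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    frame = _validate_frame(frame, str(path))
    return Cohort(frame, provenance=str(path))


def read_tmb_xlsx(
    path: str | Path,
    sheet: int | str = 0,
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a cohort from a spreadsheet (thin conversion to the CSV schema)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = pd.read_excel(path, sheet_name=sheet)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    frame = _validate_frame(frame, str(path))
    return Cohort(frame, provenance=str(path))


def write_tmb_table(cohort: Cohort, path: str | Path, format: str | None = None) -> None:
    """Write a cohort in the canonical schema; inverse of :func:`read_tmb_table`."""
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = "\t" if format == "tsv" else ","
    cols = list(MANDATORY_COLUMNS + OPTIONAL_COLUMNS)
    cohort.frame.to_csv(path, sep=sep, index=False, columns=cols, float_format="%.10g")


@dataclass(frozen=True)
class SyntheticPreset:
    """A documented synthetic TMB distribution for one histology archetype."""

    name: str
    histology: str
    description: str
    sampler: Callable[[np.random.Generator, int], np.ndarray]
    median_band: tuple[float, float]
    params: dict = field(default_factory=dict)


def _lognormal_mixture(
    weights: Sequence[float], medians: Sequence[float], sigmas: Sequence[float]
) -> Callable[[np.random.Generator, int], np.ndarray]:
    weights = np.asarray(weights, dtype=float)
    mus = np.log(np.asarray(medians, dtype=float))
    sigmas = np.asarray(sigmas, dtype=float)

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
        return rng.lognormal(mean=mus[comp], sigma=sigmas[comp])

    return sample


# Preset parameters are calibration stand-ins chosen to reflect the shapes of
# TCGA histology TMB distributions (medians in mut/Mb): a heavy right tail for
# lung adenocarcinoma, a higher median with a tighter body for squamous lung
# tumors, and a low-burden profile for breast/prostate.  See docs/methods.md.
PRESETS: dict[str, SyntheticPreset] = {
    "luad_like": SyntheticPreset(
        name="luad_like",
        histology="LUAD",
        description=(
            "Lognormal mixture 0.7*LogN(median 4, sigma 0.9) + "
            "0.3*LogN(median 12, sigma 0.8); long right tail"
        ),
        sampler=_lognormal_mixture([0.7, 0.3], [4.0, 12.0], [0.9, 0.8]),
        median_band=(4.8, 6.4),
        params={"weights": [0.7, 0.3], "medians": [4.0, 12.0], "sigmas": [0.9, 0.8]},
    ),
    "lusc_like": SyntheticPreset(
        name="lusc_like",
        histology="LUSC",
        description="LogN(median 8.5, sigma 0.55); high median, moderate tail",
        sampler=_lognormal_mixture([1.0], [8.5], [0.55]),
        median_band=(7.8, 9.2),
        params={"weights": [1.0], "medians": [8.5], "sigmas": [0.55]},
    ),
    "low_tmb_like": SyntheticPreset(
        name="low_tmb_like",
        histology="BRCA",
        description="LogN(median 1.2, sigma 0.7); low-burden breast/prostate profile",
        sampler=_lognormal_mixture([1.0], [1.2], [0.7]),
        median_band=(1.0, 1.4),
        params={"weights": [1.0], "medians": [1.2], "sigmas": [0.7]},
    ),
    "uniform": SyntheticPreset(
        name="uniform",
        histology="UNIF",
        description="Uniform on [0, 20]; analytic-test preset",
        sampler=lambda rng, n: rng.uniform(0.0, 20.0, size=n),
        median_band=(9.5, 10.5),
        params={"low": 0.0, "high": 20.0},
    ),
}


def generate_synthetic_cohort(preset: str, n: int, seed: int) -> Cohort:
    """Draw ``n`` samples from a named preset distribution.

    Fully reproducible from ``seed``; sample ids are ``{preset}-{i:05d}``.
    """
    if preset not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        )
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n}")
    spec = PRESETS[preset]
    rng = np.random.default_rng(seed)
    values = spec.sampler(rng, int(n))
    frame = pd.DataFrame(
        {
            "sample_id": [f"{preset}-{i:05d}" for i in range(int(n))],
            "histology": spec.histology,
            "tmb_wes": values,
            "tmb_panel": np.nan,
            "response": np.nan,
        }
    )
    return Cohort(frame, provenance=f"synthetic:{preset}:seed={seed}")


def preset_median(preset: str) -> float:
    """Exact median of a preset's distribution (root of the mixture CDF)."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    spec = PRESETS[preset]
    if preset == "uniform":
        return 0.5 * (spec.params["low"] + spec.params["high"])
    w = np.asarray(spec.params["weights"], dtype=float)
    w = w / w.sum()
    mu = np.log(np.asarray(spec.params["medians"], dtype=float))
    sg = np.asarray(spec.params["sigmas"], dtype=float)

    def cdf(x: float) -> float:
        return float(np.sum(w * norm.cdf((math.log(x) - mu) / sg)))

    return float(brentq(lambda x: cdf(x) - 0.5, 1e-6, 1e4))


def thin_to_panel(
    exome_count: int, size_ratio: float, seed: int, replicates: int
) -> np.ndarray:
    """Binomial subsampling of exome mutation counts onto a panel territory.

    Each of the ``exome_count`` mutations lands on the panel independently
    with probability ``size_ratio`` (panel size over exome size), mirroring
    the in-silico construction of panel TMB by intersecting exome calls with
    panel targets.  Returns ``replicates`` integer panel counts.
    """
    if exome_count < 0:
        raise ValidationError(f"exome_count must be >= 0, got {exome_count}")
    if not (0 < size_ratio <= 1):
        raise ValidationError(f"size_ratio must be in (0, 1], got {size_ratio}")
    rng = np.random.default_rng(seed)
    return rng.binomial(int(exome_count), float(size_ratio), size=int(replicates))
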