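"""Single-cell proteomics preprocessing.

Fluorescence-microscopy studies report, per protein and per timepoint, a
gamma distribution (shape ``k``, scale ``theta``) fitted to the single-cell
fluorescence signal. Automated deconvolution of weak GFP signal from
autofluorescence produces pathological, near-degenerate "spike"
distributions that must be censored before sampling. This module
implements the multi-step censoring pipeline, the power-law calibration
that maps fluorescence (A.U.) to absolute protein copy numbers, and the
media-ratio rescaling applied when simulating growth in a medium other
than the one the proteomics were measured in.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceDistribution",
    "CensorConfig",
    "CensorReport",
    "ProteinMarginal",
    "CalibrationModel",
    "RescaleTable",
    "censor_distributions",
    "fit_calibration",
    "fluorescence_to_count",
    "rescale_counts",
    "read_distributions_tsv",
    "read_calibration_tsv",
]

#: Censoring pipeline stage names, in application order.
CENSOR_STEPS = (
    "missing_timepoints",
    "sd_floor",
    "iqr_outlier",
    "too_few_survivors",
    "cv_too_high",
    "low_fluorescence",
)


@dataclass(frozen=True)
class FluorescenceDistribution:
    """Gamma-distributed single-cell fluorescence of one protein at one timepoint.

    Parameters
    ----------
    protein_id : str
        Systematic gene/protein identifier.
    timepoint : int
        Index of the measurement timepoint.
    shape : float
        Gamma shape parameter ``k`` (dimensionless, > 0).
    scale : float
        Gamma scale parameter ``theta`` (fluorescence A.U., > 0).
    """

    protein_id: str
    timepoint: int
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError(
                f"protein {self.protein_id!r} timepoint {self.timepoint}: "
                f"gamma parameters must be positive "
                f"(shape={self.shape}, scale={self.scale})"
            )

    @property
    def mean(self) -> float:
        """Distribution mean ``k * theta`` (A.U.)."""
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        """Distribution standard deviation ``sqrt(k) * theta`` (A.U.)."""
        return math.sqrt(self.shape) * self.scale


@dataclass(frozen=True)
class CensorConfig:
    """Thresholds for the fluorescence-distribution censoring pipeline.

    Attributes
    ----------
    sd_floor : float
        Minimum credible standard deviation (A.U.); narrower distributions
        are deconvolution artifacts ("spikes").
    iqr_factor : float
        Tukey fence multiplier for the per-protein outlier step.
    min_timepoints : int
        Minimum surviving timepoints for a protein to be kept.
    cv_max : float
        Upper bound (exclusive) on the CV of per-timepoint means and on the
        CV of per-timepoint standard deviations.
    fluor_floor : float
        Minimum pooled mean fluorescence (A.U.) for a reliable signal.
    required_timepoints : int
        Number of timepoints a protein must have in the raw data.
    """

    sd_floor: float = 0.1
    iqr_factor: float = 1.5
    min_timepoints: int = 3
    cv_max: float = 0.5
    fluor_floor: float = 7.98
    required_timepoints: int = 18

    def __post_init__(self) -> None:
        for name in ("sd_floor", "iqr_factor", "min_timepoints", "cv_max",
                     "fluor_floor", "required_timepoints"):
            if not getattr(self, name) > 0:
                raise ValueError(f"CensorConfig.{name} must be strictly positive")


@dataclass(frozen=True)
class ProteinMarginal:
    """Per-protein gamma marginal used for population sampling."""

    protein_id: str
    shape: float
    scale: float
    n_retained: int

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError(
                f"protein {self.protein_id!r}: marginal gamma parameters must "
                f"be positive (shape={self.shape}, scale={self.scale})"
            )

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass
class CensorReport:
    """Bookkeeping for one censoring run.

    ``distributions_removed`` / ``proteins_removed`` count removals per
    pipeline stage (keys from :data:`CENSOR_STEPS`); ``retained`` holds the
    surviving per-timepoint distributions before aggregation.
    """

    n_input_distributions: int = 0
    n_input_proteins: int = 0
    distributions_removed: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in CENSOR_STEPS})
    proteins_removed: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in CENSOR_STEPS})
    retained: list[FluorescenceDistribution] = field(default_factory=list)

    @property
    def n_retained_distributions(self) -> int:
        return len(self.retained)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input_distributions": self.n_input_distributions,
                "n_input_proteins": self.n_input_proteins,
                "n_retained_distributions": self.n_retained_distributions,
                "distributions_removed": self.distributions_removed,
                "proteins_removed": self.proteins_removed,
            },
            indent=2,
        )


def _tukey_fences(values: np.ndarray, factor: float) -> tuple[float, float]:
    # Type-7 (linear interpolation) quantiles, the numpy default.
    q25, q75 = np.quantile(values, [0.25, 0.75])
    iqr = q75 - q25
    return q25 - factor * iqr, q75 + factor * iqr


def censor_distributions(
    distros: Iterable[FluorescenceDistribution],
    cfg: CensorConfig | None = None,
) -> tuple[list[ProteinMarginal], CensorReport]:
    """Censor unreliable fluorescence distributions and pool the survivors.

    The pipeline applies, in order: (1) drop proteins missing any of the
    ``required_timepoints`` measurements; (2) drop individual distributions
    with ``sd < sd_floor``; (3) per protein, drop distributions whose mean
    or sd falls outside the Tukey fences (``iqr_factor`` times the IQR
    beyond the quartiles) of that protein's remaining values; (4) drop
    proteins with fewer than ``min_timepoints`` survivors; (5) drop
    proteins whose CV-of-means or CV-of-sds is not below ``cv_max``;
    (6) drop proteins whose pooled mean fluorescence is below
    ``fluor_floor``.

    Survivors are pooled into one :class:`ProteinMarginal` per protein by
    averaging the per-timepoint means and variances and refitting a gamma
    by method of moments (``shape = mean^2/var``, ``scale = var/mean``),
    preserving the two moments the pipeline quality-controls.

    Returns
    -------
    (marginals, report)
        Retained per-protein marginals and a :class:`CensorReport` whose
        per-step distribution counts sum exactly to the number of
        distributions removed overall.
    """
    cfg = cfg or CensorConfig()
    distros = list(distros)
    if not distros:
        raise ValueError("censor_distributions: empty input")

    by_protein: dict[str, list[FluorescenceDistribution]] = defaultdict(list)
    for d in distros:
        by_protein[d.protein_id].append(d)
    for pid, ds in by_protein.items():
        tps = [d.timepoint for d in ds]
        if len(set(tps)) != len(tps):
            raise ValueError(f"protein {pid!r} has duplicate timepoints")

    report = CensorReport(
        n_input_distributions=len(distros),
        n_input_proteins=len(by_protein),
    )

    def drop_protein(step: str, pid: str) -> None:
        report.proteins_removed[step] += 1
        report.distributions_removed[step] += len(by_protein[pid])
        del by_protein[pid]

    # 1. completeness of the time series
    for pid in [p for p, ds in by_protein.items()
                if len(ds) < cfg.required_timepoints]:
        drop_protein("missing_timepoints", pid)

    # 2. spike removal by sd floor
    for pid in list(by_protein):
        kept = [d for d in by_protein[pid] if d.sd >= cfg.sd_floor]
        report.distributions_removed["sd_floor"] += len(by_protein[pid]) - len(kept)
        if kept:
            by_protein[pid] = kept
        else:
            report.proteins_removed["sd_floor"] += 1
            del by_protein[pid]

    # 3. per-protein Tukey-fence outlier removal on means and sds
    for pid in list(by_protein):
        ds = by_protein[pid]
        means = np.array([d.mean for d in ds])
        sds = np.array([d.sd for d in ds])
        mlo, mhi = _tukey_fences(means, cfg.iqr_factor)
        slo, shi = _tukey_fences(sds, cfg.iqr_factor)
        kept = [d for d, m, s in zip(ds, means, sds)
                if mlo <= m <= mhi and slo <= s <= shi]
        report.distributions_removed["iqr_outlier"] += len(ds) - len(kept)
        if kept:
            by_protein[pid] = kept
        else:
            report.proteins_removed["iqr_outlier"] += 1
            del by_protein[pid]

    # 4. minimum number of surviving timepoints
    for pid in [p for p, ds in by_protein.items()
                if len(ds) < cfg.min_timepoints]:
        drop_protein("too_few_survivors", pid)

    # 5. reproducibility across timepoints: CV of means and CV of sds
    for pid in list(by_protein):
        means = np.array([d.mean for d in by_protein[pid]])
        sds = np.array([d.sd for d in by_protein[pid]])
        cv_means = means.std(ddof=0) / means.mean()
        cv_sds = sds.std(ddof=0) / sds.mean()
        if not (cv_means < cfg.cv_max and cv_sds < cfg.cv_max):
            drop_protein("cv_too_high", pid)

    # 6. unreliable low-fluorescence proteins
    for pid in list(by_protein):
        pooled_mean = float(np.mean([d.mean for d in by_protein[pid]]))
        if pooled_mean < cfg.fluor_floor:
            drop_protein("low_fluorescence", pid)

    marginals = []
    for pid in sorted(by_protein):
        ds = by_protein[pid]
        report.retained.extend(ds)
        mean = float(np.mean([d.mean for d in ds]))
        var = float(np.mean([d.sd ** 2 for d in ds]))
        marginals.append(ProteinMarginal(
            protein_id=pid,
            shape=mean * mean / var,
            scale=var / mean,
            n_retained=len(ds),
        ))
    return marginals, report


@dataclass(frozen=True)
class CalibrationModel:
    """Power-law map from fluorescence (A.U.) to protein copies.

    ``copies = max(a * f**b, floor)``. The floor equals the coefficient
    ``a`` by default: fluorescence below 1 A.U. is unreliable, so no
    sampled copy number is allowed below the count predicted at f = 1.
    """

    a: float
    b: float
    floor: float | None = None

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("calibration coefficient and exponent must be positive")
        if self.floor is None:
            object.__setattr__(self, "floor", self.a)
        if not self.floor > 0:
            raise ValueError("calibration floor must be positive")

    def convert(self, f):
        """Vectorized fluorescence -> copies conversion with floor."""
        return fluorescence_to_count(f, self)


def fit_calibration(
    rows: Iterable[tuple[float, float, float]] | pd.DataFrame,
) -> CalibrationModel:
    """Fit the fluorescence -> copy-number power law by log-log OLS.

    Each row pairs the mean protein copy number measured in rich medium,
    the mean fluorescence of the same protein, and the expression ratio
    between the simulated medium and the rich medium. Ordinary least
    squares of ``ln(count * ratio)`` on ``ln(fluorescence)`` gives the
    exponent ``b`` (slope) and coefficient ``a`` (exp of intercept).
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows[["mean_count", "mean_fluorescence", "ratio"]].itertuples(index=False)
    rows = [tuple(map(float, r)) for r in rows]
    if len(rows) < 2:
        raise ValueError("fit_calibration requires at least 2 rows")
    arr = np.asarray(rows, dtype=float)
    if not (arr > 0).all():
        raise ValueError("fit_calibration: all counts, fluorescences and ratios "
                         "must be strictly positive")
    counts, fluor, ratio = arr.T
    slope, intercept = np.polyfit(np.log(fluor), np.log(counts * ratio), 1)
    a = float(np.exp(intercept))
    return CalibrationModel(a=a, b=float(slope), floor=a)


def fluorescence_to_count(f, cal: CalibrationModel):
    """Convert fluorescence to protein copies: ``max(a * f**b, floor)``.

    Accepts scalars or arrays; negative fluorescence is an error.
    """
    f = np.asarray(f, dtype=float)
    if not np.isfinite(f).all():
        raise ValueError("fluorescence values must be finite")
    if (f < 0).any():
        raise ValueError("fluorescence values must be non-negative")
    counts = np.maximum(cal.a * np.power(f, cal.b), cal.floor)
    return float(counts) if counts.ndim == 0 else counts


class RescaleTable(dict):
    """Per-protein multiplicative expression ratios between media.

    Maps ``protein_id -> ratio``; proteins absent from the table keep
    ratio 1.0.
    """

    def __init__(self, ratios: Mapping[str, float] | None = None):
        super().__init__(ratios or {})
        for pid, r in self.items():
            if not r > 0:
                raise ValueError(f"rescale ratio for {pid!r} must be positive, got {r}")

    def ratio(self, protein_id: str) -> float:
        return self.get(protein_id, 1.0)


def rescale_counts(
    counts: Mapping[str, float] | pd.Series,
    table: RescaleTable,
    cal: CalibrationModel | None = None,
) -> dict[str, float]:
    """Rescale copy numbers by media-expression ratios, then re-floor.

    The calibration floor is re-applied after scaling so no downstream
    count falls below the minimum credible copy number.
    """
    floor = cal.floor if cal is not None else 0.0
    out = {}
    for pid, c in dict(counts).items():
        out[pid] = max(float(c) * table.ratio(pid), floor)
    return out


# ---------------------------------------------------------------------------
# TSV plumbing

def read_distributions_tsv(path) -> list[FluorescenceDistribution]:
    """Read per-protein, per-timepoint gamma parameters.

    Expects columns ``protein_id, timepoint, shape, scale``.
    """
    df = pd.read_csv(path, sep="\t")
    return [
        FluorescenceDistribution(str(r.protein_id), int(r.timepoint),
                                 float(r.shape), float(r.scale))
        for r in df.itertuples(index=False)
    ]


def read_calibration_tsv(path) -> pd.DataFrame:
    """Read a calibration table with columns ``gene, mean_count, mean_fluorescence, ratio``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"mean_count", "mean_fluorescence", "ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"calibration table missing columns: {sorted(missing)}")
    return df


def write_marginals_tsv(marginals: Sequence[ProteinMarginal], path) -> None:
    pd.DataFrame(
        [(m.protein_id, m.shape, m.scale, m.n_retained) for m in marginals],
        columns=["protein_id", "shape", "scale", "n_retained"],
    ).to_csv(path, sep="\t", index=False)
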