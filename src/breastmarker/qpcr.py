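"""CT-level preprocessing for SYBR and OpenArray quantitative PCR.

Raw cycle-threshold (CT) values are logarithmic: each PCR cycle multiplies the
product by the amplification efficiency, so a difference of one cycle is one
efficiency-fold difference in template.  This module converts CT values to
linear relative expression via a dilution-standard curve (SYBR platform) or
the fixed OpenArray transform, averages replicate wells, normalizes by
housekeeping genes, centers genes on the log2 scale, and quantifies
cross-platform concordance as a per-gene coefficient of variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "RawPlateData",
    "ReplicateSummary",
    "fit_standard_curve",
    "ct_to_linear",
    "openarray_linear",
    "average_replicates",
    "normalize_housekeeping",
    "median_center",
    "cross_platform_cv",
]

#: OpenArray linearization constants: linear value = 1.735 ** (32 - CT).
OPENARRAY_EFFICIENCY = 1.735
OPENARRAY_REFERENCE_CT = 32.0


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares fit of CT against log concentration of a dilution series.

    Attributes
    ----------
    slope : float
        Cycles per natural-log unit of concentration (negative: more template
        amplifies earlier).
    intercept : float
        Fitted CT of the undiluted standard (log concentration 0); the anchor
        that maps to linear value 1.
    efficiency : float
        Fold amplification per cycle, ``exp(-1 / slope)``; 2.0 is perfect
        doubling.
    r_squared : float
        Coefficient of determination of the fit.
    """

    slope: float
    intercept: float
    efficiency: float
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency < 4.0):
            raise ValueError(
                f"amplification efficiency {self.efficiency:.3f} outside (1, 4); "
                "check the dilution series"
            )


@dataclass
class RawPlateData:
    """Long-format CT records from one plate.

    ``wells`` has columns ``gene``, ``tissue``, ``replicate``, ``ct``;
    ``standard`` has columns ``dilution``, ``ct`` (the dilution series of the
    reference cDNA amplified with the standard's primers); ``housekeeping``
    lists the reference gene symbols present among the wells.
    """

    wells: pd.DataFrame
    standard: pd.DataFrame
    housekeeping: tuple[str, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        required = {"gene", "tissue", "replicate", "ct"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"wells table missing columns: {sorted(missing)}")
        ct = self.wells["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise ValueError("CT values must be finite and positive")


@dataclass
class ReplicateSummary:
    """Replicate-averaged linear expression plus per-well concordance.

    ``matrix`` is the gene x tissue mean of linearized replicates;
    ``cv_percent`` the per-(gene, tissue) replicate %CV (NaN when a well has a
    single replicate); ``discordant`` the (gene, tissue) pairs whose %CV
    exceeded the re-run flag threshold.
    """

    matrix: pd.DataFrame
    cv_percent: pd.DataFrame
    discordant: list[tuple[str, str]]


def fit_standard_curve(series) -> StandardCurve:
    """Fit a standard curve from ``(dilution factor, CT)`` pairs.

    Parameters
    ----------
    series
        Iterable of ``(dilution, ct)`` pairs or a DataFrame with ``dilution``
        and ``ct`` columns.  Dilution 1 is the undiluted standard.

    Returns
    -------
    StandardCurve
        CT regressed on the natural log of the dilution factor; efficiency is
        ``exp(-1 / slope)``.

    Raises
    ------
    ValueError
        Fewer than 3 distinct dilutions, or zero slope (identical CTs).
    """
    if isinstance(series, pd.DataFrame):
        dil = series["dilution"].to_numpy(dtype=float)
        ct = series["ct"].to_numpy(dtype=float)
    else:
        pairs = list(series)
        dil = np.array([p[0] for p in pairs], dtype=float)
        ct = np.array([p[1] for p in pairs], dtype=float)
    if np.any(dil <= 0):
        raise ValueError("dilution factors must be positive")
    if len(np.unique(dil)) < 3:
        raise ValueError("standard curve needs >=3 distinct dilutions")

    # Aggregate replicate standard wells at the same dilution before checking
    # monotonicity; the regression itself uses every well.
    order = np.argsort(-dil)  # undiluted first
    mean_ct = pd.Series(ct).groupby(pd.Series(dil)).mean()
    if not np.all(np.diff(mean_ct.sort_index(ascending=False).to_numpy()) > 0):
        warnings.warn(
            "standard series CT not monotone in dilution; fitting anyway",
            stacklevel=2,
        )

    res = stats.linregress(np.log(dil[order]), ct[order])
    if res.slope == 0 or not np.isfinite(res.slope):
        raise ValueError("degenerate standard series: zero slope")
    efficiency = float(np.exp(-1.0 / res.slope))
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=efficiency,
        r_squared=float(res.rvalue**2),
    )


def ct_to_linear(ct, curve: StandardCurve):
    """Convert CT values to linear expression anchored at the undiluted standard.

    Returns ``efficiency ** (intercept - ct)``, so a CT equal to the undiluted
    standard's fitted CT maps to 1.0 and each cycle earlier is one
    efficiency-fold more template.  Accepts scalars or arrays.
    """
    return curve.efficiency ** (curve.intercept - np.asarray(ct, dtype=float))


def openarray_linear(ct):
    """OpenArray linearization: ``1.735 ** (32 - CT)``; strictly decreasing in CT."""
    return OPENARRAY_EFFICIENCY ** (OPENARRAY_REFERENCE_CT - np.asarray(ct, dtype=float))


def average_replicates(
    raw: RawPlateData,
    curve: StandardCurve | None = None,
    discordance_cv_percent: float = 50.0,
) -> ReplicateSummary:
    """Linearize replicate CT wells and average them per (gene, tissue).

    The standard curve is fitted from ``raw.standard`` when not supplied.
    Replicate concordance is reported as %CV of the linearized values
    (ddof=1); wells above ``discordance_cv_percent`` are flagged for re-run.
    Single-replicate wells keep their value with an undefined (NaN) CV.
    """
    raw.validate()
    if curve is None:
        curve = fit_standard_curve(raw.standard)
    wells = raw.wells.copy()
    wells["linear"] = ct_to_linear(wells["ct"].to_numpy(), curve)

    grouped = wells.groupby(["gene", "tissue"])["linear"]
    mean = grouped.mean().unstack("tissue")
    sd = grouped.std(ddof=1).unstack("tissue")
    cv = 100.0 * sd / mean

    discordant = [
        (g, t)
        for (g, t), v in cv.stack().items()
        if np.isfinite(v) and v > discordance_cv_percent
    ]
    return ReplicateSummary(matrix=mean, cv_percent=cv, discordant=discordant)


def normalize_housekeeping(m: pd.DataFrame, hk: list[str]) -> pd.DataFrame:
    """Divide each tissue column by the mean of its housekeeping-gene values.

    Housekeeping rows stay in the output (each becomes its value divided by
    the shared per-tissue mean).  The result is invariant to rescaling any
    tissue column, which is the point: per-sample template load cancels.

    Raises
    ------
    KeyError
        A housekeeping gene is absent from the matrix.
    ValueError
        A housekeeping value is missing, zero or negative in some tissue (the
        offending tissue is named).
    """
    hk = list(hk)
    missing = [g for g in hk if g not in m.index]
    if missing:
        raise KeyError(f"housekeeping genes not in matrix: {missing}")
    hk_mean = m.loc[hk].mean(axis=0)
    bad = hk_mean.index[~(hk_mean > 0) | hk_mean.isna()]
    if len(bad):
        raise ValueError(
            f"housekeeping mean non-positive or missing in tissue(s): {list(bad)}"
        )
    return m.div(hk_mean, axis=1)


def median_center(
    m: pd.DataFrame, center: str = "median", base: float = 2.0
) -> pd.DataFrame:
    """Log-transform and center each gene by its median (or mean).

    Positive linear values are taken to ``log2`` (or ``base``) and each gene
    row is centered on its median across tissues; with ``center="mean"`` the
    row mean is used (the convention for clustering input).  Zeros are below
    the platform's detection range and become missing in log space (with a
    warning); NaNs stay NaN.  On median-centered data a gene's standard
    deviation doubles as a scale-free dispersion measure.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    values = m.to_numpy(dtype=float)
    if np.any(values[np.isfinite(values)] < 0):
        raise ValueError("expression values must be non-negative")
    if np.any(values == 0):
        warnings.warn("zero expression values become missing in log space", stacklevel=2)
    with np.errstate(divide="ignore"):
        logged = np.log(values) / np.log(base)
    logged[~np.isfinite(logged)] = np.nan
    out = pd.DataFrame(logged, index=m.index, columns=m.columns)
    loc = out.median(axis=1) if center == "median" else out.mean(axis=1)
    return out.sub(loc, axis=0)


def cross_platform_cv(a: pd.DataFrame, b: pd.DataFrame, mean_normalize: bool = True):
    """Concordance between two platforms as a per-gene averaged %CV.

    Both matrices are first mean-normalized per gene over the shared tissues
    (removing platform scale; disable with ``mean_normalize=False`` when the
    inputs are already on a common scale), then for every shared
    (gene, tissue) the CV of the measurement pair is computed (sd with ddof=1
    over the two values, divided by their mean) and averaged across tissues.

    Returns
    -------
    (pandas.Series, dict)
        Per-gene %CV, and a summary with keys ``mean``, ``min``, ``max``
        across genes.
    """
    genes = a.index.intersection(b.index)
    tissues = a.columns.intersection(b.columns)
    if genes.empty or tissues.empty:
        raise ValueError("matrices share no genes or no tissues")
    aa = a.loc[genes, tissues]
    bb = b.loc[genes, tissues]
    if mean_normalize:
        aa = aa.div(aa.mean(axis=1), axis=0)
        bb = bb.div(bb.mean(axis=1), axis=0)

    pair_mean = (aa + bb) / 2.0
    # sd of two values with ddof=1 is |x - y| / sqrt(2)
    pair_sd = (aa - bb).abs() / np.sqrt(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * pair_sd / pair_mean
    per_gene = cv.mean(axis=1)
    summary = {
        "mean": float(per_gene.mean()),
        "min": float(per_gene.min()),
        "max": float(per_gene.max()),
    }
    return per_gene, summary
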