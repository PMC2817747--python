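"""Nested variance-component decomposition of normal-tissue expression.

The sampling design is three-level nested: women, breasts within woman, and
tissue slices within breast.  For each gene the observed (median-centered
log2) expression is modelled as

    y[w, b, s] = mu + W[w] + B[w, b] + E[w, b, s]

with independent zero-mean components of variance sigma_w^2 (between women),
sigma_b^2 (between breasts of the same woman) and sigma_s^2 (between slices
of one breast).  Components are estimated by method-of-moments from the
nested-ANOVA mean squares with unbalanced-design coefficients (Searle's
expected mean squares); negative estimates are truncated at zero.  An
optional REML estimator (direct covariance-matrix likelihood) is provided as
a cross-check.

Component *shares* are reported on the standard-deviation scale:
``sigma_component / (sigma_w + sigma_b + sigma_s)``, the only convention
under which the three shares sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "VarianceDecomposition",
    "nested_varcomp",
    "summarize_varcomp",
    "high_variability_flag",
]

_REQUIRED = ("woman", "breast", "slice", "value")


@dataclass
class VarianceDecomposition:
    """Per-gene variance decomposition of a nested normal-tissue design.

    ``overall_sd`` is the plain sample SD of all the gene's values (the
    scale-free dispersion on median-centered log2 data).  ``share_*`` are
    component-SD shares in [0, 1] summing to 1, or NaN when the gene is
    degenerate (no variability at all; then ``degenerate`` is True).
    """

    gene: str
    overall_sd: float
    sigma2_woman: float
    sigma2_breast: float
    sigma2_slice: float
    share_women: float
    share_breast: float
    share_slice: float
    degenerate: bool = False

    @property
    def shares(self) -> tuple[float, float, float]:
        return (self.share_women, self.share_breast, self.share_slice)


def _check_design(df: pd.DataFrame) -> None:
    women = df["woman"].unique()
    if len(women) < 2:
        raise ValueError("non-estimable design: need >=2 women")
    breasts = df.groupby("woman")["breast"].nunique()
    if (breasts < 2).all():
        raise ValueError(
            "non-estimable design: no woman contributes 2 breasts "
            "(between-breast stratum missing)"
        )
    slices = df.groupby(["woman", "breast"])["slice"].nunique()
    if (slices < 2).all():
        raise ValueError(
            "non-estimable design: no breast contributes 2 slices "
            "(within-breast stratum missing)"
        )


def _anova_sums(df: pd.DataFrame):
    """Nested sums of squares and unbalanced expected-mean-square coefficients."""
    y = df["value"].to_numpy(dtype=float)
    n_total = len(y)
    grand = y.mean()

    by_breast = df.groupby(["woman", "breast"])["value"]
    by_woman = df.groupby("woman")["value"]
    n_wb = by_breast.size()          # slices per (woman, breast)
    n_w = by_woman.size()            # observations per woman
    mean_wb = by_breast.mean()
    mean_w = by_woman.mean()

    a = len(n_w)                     # women
    b_total = len(n_wb)              # breasts

    ss_women = float((n_w * (mean_w - grand) ** 2).sum())
    woman_of_breast = n_wb.index.get_level_values("woman")
    ss_breast = float(
        (n_wb * (mean_wb - mean_w.loc[woman_of_breast].to_numpy()) ** 2).sum()
    )
    breast_mean_per_obs = mean_wb.loc[
        pd.MultiIndex.from_frame(df[["woman", "breast"]])
    ].to_numpy()
    ss_slice = float(((y - breast_mean_per_obs) ** 2).sum())

    df_women = a - 1
    df_breast = b_total - a
    df_slice = n_total - b_total

    # Searle's coefficients for the two-fold nested unbalanced classification.
    sum_n2_within_w = (n_wb**2).groupby("woman").sum() / n_w
    k1 = (n_total - float(sum_n2_within_w.sum())) / df_breast if df_breast else np.nan
    k2 = (float(sum_n2_within_w.sum()) - float((n_wb**2).sum()) / n_total) / df_women
    k3 = (n_total - float((n_w**2).sum()) / n_total) / df_women

    return {
        "ms_women": ss_women / df_women,
        "ms_breast": ss_breast / df_breast if df_breast else np.nan,
        "ms_slice": ss_slice / df_slice if df_slice else np.nan,
        "df": (df_women, df_breast, df_slice),
        "k": (k1, k2, k3),
    }


def _mom_estimates(df: pd.DataFrame) -> tuple[float, float, float]:
    s = _anova_sums(df)
    k1, k2, k3 = s["k"]
    sigma2_slice = max(s["ms_slice"], 0.0)
    sigma2_breast = max((s["ms_breast"] - s["ms_slice"]) / k1, 0.0)
    sigma2_woman = max(
        (s["ms_women"] - s["ms_slice"] - k2 * sigma2_breast) / k3, 0.0
    )
    return sigma2_woman, sigma2_breast, sigma2_slice


def _reml_estimates(df: pd.DataFrame) -> tuple[float, float, float]:
    """REML fit by direct maximization over the 3 variance parameters.

    Builds the marginal covariance V = s2w Zw Zw' + s2b Zb Zb' + s2s I for the
    gene's (small) observation vector and maximizes the restricted
    log-likelihood with the intercept profiled out.  Used as a cross-check on
    the method-of-moments estimator, not as the default.
    """
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    woman = pd.factorize(df["woman"])[0]
    breast = pd.factorize(df["woman"].astype(str) + "|" + df["breast"].astype(str))[0]
    zw = (woman[:, None] == np.arange(woman.max() + 1)[None, :]).astype(float)
    zb = (breast[:, None] == np.arange(breast.max() + 1)[None, :]).astype(float)
    gw = zw @ zw.T
    gb = zb @ zb.T
    x = np.ones((n, 1))
    total_var = max(y.var(ddof=1), 1e-8)

    def neg_restricted_loglik(log_params):
        s2w, s2b, s2s = np.exp(log_params)
        v = s2w * gw + s2b * gb + s2s * np.eye(n)
        try:
            cho = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return 1e10
        logdet_v = 2.0 * np.log(np.diag(cho)).sum()
        vinv_y = np.linalg.solve(v, y)
        vinv_x = np.linalg.solve(v, x)
        xtvx = x.T @ vinv_x
        beta = (x.T @ vinv_y) / xtvx
        resid = y - x[:, 0] * beta[0, 0]
        quad = resid @ np.linalg.solve(v, resid)
        return 0.5 * (logdet_v + np.log(xtvx[0, 0]) + quad)

    start = np.log(np.full(3, total_var / 3.0))
    best = optimize.minimize(
        neg_restricted_loglik, start, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    s2w, s2b, s2s = np.exp(best.x)
    return float(s2w), float(s2b), float(s2s)


def nested_varcomp(
    data: pd.DataFrame,
    gene: str | None = None,
    method: str = "mom",
    share_scale: str = "sd",
) -> VarianceDecomposition:
    """Decompose one gene's variability into nested components.

    Parameters
    ----------
    data
        Long-format records with columns ``woman``, ``breast``, ``slice``,
        ``value`` and, when ``gene`` is given, a ``gene`` column to filter on.
    gene
        Gene to analyse; omit when ``data`` already holds a single gene.
    method
        ``"mom"`` (default): method-of-moments from nested-ANOVA mean squares
        with unbalanced-design coefficients, negatives truncated at 0.
        ``"reml"``: restricted maximum likelihood (cross-check mode).
    share_scale
        ``"sd"`` (default): shares are component SDs over the summed SDs (the
        convention in which shares add to 100%).  ``"variance"``: shares of
        summed variances.

    Raises
    ------
    ValueError
        Non-estimable layout (fewer than 2 women, or no stratum with
        replication), identifying the missing stratum.
    """
    if gene is not None:
        data = data.loc[data["gene"] == gene]
        if data.empty:
            raise ValueError(f"no records for gene {gene!r}")
    else:
        gene = str(data["gene"].iloc[0]) if "gene" in data.columns else "gene"
    missing = [c for c in _REQUIRED if c not in data.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    values = data["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    _check_design(data)

    overall_sd = float(np.std(values, ddof=1))
    if overall_sd == 0.0:
        return VarianceDecomposition(
            gene=gene, overall_sd=0.0,
            sigma2_woman=0.0, sigma2_breast=0.0, sigma2_slice=0.0,
            share_women=float("nan"), share_breast=float("nan"),
            share_slice=float("nan"), degenerate=True,
        )

    if method == "mom":
        s2w, s2b, s2s = _mom_estimates(data)
    elif method == "reml":
        s2w, s2b, s2s = _reml_estimates(data)
    else:
        raise ValueError("method must be 'mom' or 'reml'")

    if share_scale == "sd":
        comps = np.sqrt([s2w, s2b, s2s])
    elif share_scale == "variance":
        comps = np.array([s2w, s2b, s2s])
    else:
        raise ValueError("share_scale must be 'sd' or 'variance'")
    total = comps.sum()
    shares = comps / total if total > 0 else np.full(3, np.nan)

    return VarianceDecomposition(
        gene=gene,
        overall_sd=overall_sd,
        sigma2_woman=float(s2w),
        sigma2_breast=float(s2b),
        sigma2_slice=float(s2s),
        share_women=float(shares[0]),
        share_breast=float(shares[1]),
        share_slice=float(shares[2]),
        degenerate=bool(total == 0),
    )


def _as_frame(decomps) -> pd.DataFrame:
    if isinstance(decomps, pd.DataFrame):
        return decomps
    rows = [
        {
            "gene": d.gene,
            "overall_sd": d.overall_sd,
            "share_women": d.share_women,
            "share_breast": d.share_breast,
            "share_slice": d.share_slice,
        }
        for d in decomps
    ]
    return pd.DataFrame(rows)


def summarize_varcomp(decomps, digits: int = 0) -> dict:
    """Across-gene summary of component shares: mean and SD, in percent.

    Accepts a list of :class:`VarianceDecomposition` or an equivalent
    DataFrame with ``share_women`` / ``share_breast`` / ``share_slice`` (as
    fractions) and ``overall_sd`` columns.  Degenerate genes (NaN shares) are
    excluded from share means.
    """
    frame = _as_frame(decomps)
    if frame.empty:
        raise ValueError("no decompositions to summarize")
    out: dict[str, float] = {}
    for comp in ("women", "breast", "slice"):
        pct = 100.0 * frame[f"share_{comp}"].dropna()
        out[f"mean_share_{comp}_pct"] = round(float(pct.mean()), digits)
        out[f"sd_share_{comp}_pct"] = round(float(pct.std(ddof=1)), digits) if len(pct) > 1 else 0.0
    if "overall_sd" in frame:
        out["mean_overall_sd"] = float(frame["overall_sd"].mean())
    return out


def high_variability_flag(decomps, threshold_sd: float = 1.0) -> list[str]:
    """Genes whose overall SD strictly exceeds ``threshold_sd``.

    On median-centered log2 data the overall SD is a surrogate for the
    population CV, so this flags genes with unusually dispersed expression in
    normal tissue (candidates for spotty, cell-type-restricted expression).
    """
    if threshold_sd < 0:
        raise ValueError("threshold must be >= 0")
    frame = _as_frame(decomps)
    return frame.loc[frame["overall_sd"] > threshold_sd, "gene"].tolist()
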