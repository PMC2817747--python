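"""Control-referenced threshold differential-expression calling.

Instead of a test statistic, a gene is called differentially expressed when
enough cancers exceed a cutoff derived purely from the healthy-control
(reduction-mammaplasty) distribution:

* over-expression cutoff: control mean + 3 x control SD (ddof=1);
* under-expression cutoff: the control minimum.

A gene is called when at least ``min_cancer_frac`` (default 20%) of cancers
and at most ``max_control_frac`` (default 5%) of controls lie strictly beyond
the cutoff.  For the under direction no control can lie strictly below the
control minimum, so the control condition is automatic there.

`ratio_filter` is the single-replicate (OpenArray) variant with stricter
filtering: a tumor counts as differential when its value exceeds
control-mean x ratio or falls below control-mean / ratio, and a gene passes
when more than ``min_frac`` of tumors are differential in its majority
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DECall",
    "compute_thresholds",
    "call_de",
    "calls_to_frame",
    "called_genes",
    "ratio_filter",
]


@dataclass
class DECall:
    """Per-gene thresholds, exceedance fractions and the call verdict."""

    gene: str
    over_threshold: float
    under_threshold: float
    frac_cancers_over: float
    frac_controls_over: float
    frac_cancers_under: float
    frac_controls_under: float
    verdict: str  # "over" | "under" | "none"
    evaluable: bool = True


def compute_thresholds(control_values) -> tuple[float, float]:
    """Control-derived cutoffs: (mean + 3*SD, minimum of controls).

    Raises
    ------
    ValueError
        Fewer than 2 non-missing control values (SD undefined).
    """
    vals = np.asarray(control_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need >=2 control values to set thresholds")
    over = float(vals.mean() + 3.0 * vals.std(ddof=1))
    under = float(vals.min())
    return over, under


def _frac_beyond(values: np.ndarray, threshold: float, direction: str) -> float:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    if direction == "over":
        return float(np.mean(values > threshold))
    return float(np.mean(values < threshold))


def call_de(
    m: pd.DataFrame,
    cancer_ids,
    control_ids,
    min_cancer_frac: float = 0.20,
    max_control_frac: float = 0.05,
) -> list[DECall]:
    """Call differential expression per gene against control-derived cutoffs.

    Parameters
    ----------
    m
        Gene x tissue matrix (any per-gene monotone scale; cutoffs are derived
        from the same data, so verdicts are invariant to per-gene affine
        transforms).  NaN marks missing measurements.
    cancer_ids, control_ids
        Disjoint tissue-column groups; controls define the thresholds.

    Returns
    -------
    list of DECall
        One entry per gene.  Genes with fewer than 2 control or 1 cancer
        measurement are marked non-evaluable with verdict ``"none"``.

    Notes
    -----
    Exceedance is strict: a cancer counts only when *above* the
    over-threshold or *below* the control minimum.  When both directions
    qualify, the direction with the larger cancer fraction wins; ties go to
    over-expression.
    """
    cancer_ids = list(cancer_ids)
    control_ids = list(control_ids)
    overlap = set(cancer_ids) & set(control_ids)
    if overlap:
        raise ValueError(f"tissues in both groups: {sorted(overlap)}")
    for tid in cancer_ids + control_ids:
        if tid not in m.columns:
            raise KeyError(f"tissue {tid!r} not in matrix")

    calls: list[DECall] = []
    for gene in m.index:
        cancers = m.loc[gene, cancer_ids].to_numpy(dtype=float)
        controls = m.loc[gene, control_ids].to_numpy(dtype=float)
        controls = controls[np.isfinite(controls)]
        cancers = cancers[np.isfinite(cancers)]
        if controls.size < 2 or cancers.size < 1:
            calls.append(DECall(
                gene=str(gene), over_threshold=float("nan"),
                under_threshold=float("nan"),
                frac_cancers_over=float("nan"), frac_controls_over=float("nan"),
                frac_cancers_under=float("nan"), frac_controls_under=float("nan"),
                verdict="none", evaluable=False,
            ))
            continue
        over_thr, under_thr = compute_thresholds(controls)
        fc_over = _frac_beyond(cancers, over_thr, "over")
        fn_over = _frac_beyond(controls, over_thr, "over")
        fc_under = _frac_beyond(cancers, under_thr, "under")
        fn_under = _frac_beyond(controls, under_thr, "under")

        over_ok = fc_over >= min_cancer_frac and fn_over <= max_control_frac
        under_ok = fc_under >= min_cancer_frac and fn_under <= max_control_frac
        if over_ok and under_ok:
            verdict = "under" if fc_under > fc_over else "over"
        elif over_ok:
            verdict = "over"
        elif under_ok:
            verdict = "under"
        else:
            verdict = "none"
        calls.append(DECall(
            gene=str(gene), over_threshold=over_thr, under_threshold=under_thr,
            frac_cancers_over=fc_over, frac_controls_over=fn_over,
            frac_cancers_under=fc_under, frac_controls_under=fn_under,
            verdict=verdict,
        ))
    return calls


def calls_to_frame(calls: list[DECall]) -> pd.DataFrame:
    """Tabulate DE calls (one row per gene)."""
    return pd.DataFrame([vars(c) for c in calls])


def called_genes(calls: list[DECall]) -> list[str]:
    """Genes with an over or under verdict."""
    return [c.gene for c in calls if c.verdict != "none"]


def ratio_filter(
    m: pd.DataFrame,
    tumor_ids,
    control_ids,
    ratio: float = 1.2,
    min_frac: float = 0.30,
) -> pd.DataFrame:
    """Ratio-based differential-expression filter for single-replicate data.

    Operates on linear (positive) expression.  Per gene, a tumor is
    differential when its value is above ``control_mean * ratio`` (over) or
    below ``control_mean / ratio`` (under).  The gene's direction is the
    majority direction among its differential tumors; it passes when the
    majority-direction fraction exceeds ``min_frac``.

    Returns a DataFrame with per-gene ``frac_differential`` (majority
    direction), ``direction``, ``passes`` and ``signed_percent`` — the
    printed-style integer percentage, negative for under-expression.
    """
    tumor_ids, control_ids = list(tumor_ids), list(control_ids)
    if not tumor_ids or not control_ids:
        raise ValueError("both tissue groups must be non-empty")
    rows = []
    for gene in m.index:
        tumors = m.loc[gene, tumor_ids].to_numpy(dtype=float)
        tumors = tumors[np.isfinite(tumors)]
        ctrl = m.loc[gene, control_ids].to_numpy(dtype=float)
        ctrl = ctrl[np.isfinite(ctrl)]
        if tumors.size == 0 or ctrl.size == 0:
            rows.append({"gene": str(gene), "frac_differential": float("nan"),
                         "direction": "none", "passes": False,
                         "signed_percent": float("nan")})
            continue
        center = float(ctrl.mean())
        n_over = int(np.sum(tumors > center * ratio))
        n_under = int(np.sum(tumors < center / ratio))
        if n_under > n_over:
            direction, n_diff = "under", n_under
        else:
            direction, n_diff = "over", n_over
        frac = n_diff / tumors.size
        passes = frac > min_frac
        pct = int(round(100.0 * frac))
        rows.append({
            "gene": str(gene),
            "frac_differential": frac,
            "direction": direction,
            "passes": passes,
            "signed_percent": -pct if direction == "under" else pct,
        })
    return pd.DataFrame(rows)
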