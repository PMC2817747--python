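"""Candidate-marker reduction cascade over a discretized expression database.

A serum biomarker must reach the blood (secreted or membrane-shed protein),
must not be swamped by baseline production in large, well-perfused organs,
and must be low in normal tissues so tumor-derived excess is detectable.  The
cascade encodes those requirements as successive filters over per-gene
database records carrying subcellular localization, housekeeping status and
discretized expression levels (absent / low / medium / high, with boundaries
at 1x, 3x and 10x the median expression across tissues).

Each filter is a pointwise predicate on a record, so filters are idempotent
and commute; the cascade order only determines how the removal counts are
attributed in the trace.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneDBRecord",
    "CascadeTrace",
    "LEVELS",
    "LOCALIZATIONS",
    "HIGH_OUTPUT_ORGANS",
    "encode_levels",
    "filter_localization",
    "filter_housekeeping",
    "filter_high_organ_expression",
    "retain_low_normal_expression",
    "select_secreted_membrane",
    "run_cascade",
]

log = logging.getLogger(__name__)

LEVELS = ("absent", "low", "medium", "high")
_LEVEL_RANK = {lvl: i for i, lvl in enumerate(LEVELS)}

LOCALIZATIONS = frozenset(
    {"nuclear", "mitochondrial", "ribosomal", "secreted", "membrane",
     "cytoplasmic", "unknown"}
)
_INTRACELLULAR_CONFINED = frozenset({"nuclear", "mitochondrial", "ribosomal"})
_BLOOD_ACCESSIBLE = frozenset({"secreted", "membrane"})

#: Organs with high cardiac output whose baseline expression would raise the
#: background blood level of a candidate protein.
HIGH_OUTPUT_ORGANS = (
    "bone", "brain", "heart", "kidney", "lung", "liver",
    "skeletal muscle", "pancreas",
)


@dataclass(frozen=True)
class GeneDBRecord:
    """One gene's database entry: annotation plus discretized expression."""

    gene: str
    localization: frozenset = frozenset({"unknown"})
    housekeeping: bool = False
    organ_levels: dict = field(default_factory=dict)
    normal_tissue_levels: dict = field(default_factory=dict)
    breast_cancer_presence: bool = True
    tn_ratio_over_2: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "localization", frozenset(self.localization))
        bad = self.localization - LOCALIZATIONS
        if bad:
            raise ValueError(f"{self.gene}: unknown localization labels {sorted(bad)}")
        for m in (self.organ_levels, self.normal_tissue_levels):
            for key, lvl in m.items():
                if lvl not in _LEVEL_RANK:
                    raise ValueError(f"{self.gene}: invalid level {lvl!r} for {key!r}")


def encode_levels(values, below_median_level: str = "low") -> list[str]:
    """Discretize expression values against the median across tissues.

    With m the median of ``values``: ratio >= 10 -> ``high``; [3, 10) ->
    ``medium``; [1, 3) -> ``low`` (boundaries closed on the left).  Positive
    values below the median map to ``below_median_level`` (``"low"`` by
    default, ``"absent"`` for a stricter reading); exact zeros are always
    ``absent``.

    Raises
    ------
    ValueError
        All-zero input (no median to define the scale).
    """
    if below_median_level not in ("low", "absent"):
        raise ValueError("below_median_level must be 'low' or 'absent'")
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0 or np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValueError("need finite non-negative values")
    med = float(np.median(vals))
    if med <= 0:
        raise ValueError("median expression is zero; levels undefined")
    out = []
    for v in vals:
        r = v / med
        if v == 0:
            out.append("absent")
        elif r >= 10:
            out.append("high")
        elif r >= 3:
            out.append("medium")
        elif r >= 1:
            out.append("low")
        else:
            out.append(below_median_level)
    return out


def filter_localization(db):
    """Drop genes confined to nucleus, mitochondrion or ribosome.

    A record is removed only when its localization contains a confirmed
    intracellular-confined label (nuclear / mitochondrial / ribosomal) and no
    blood-accessible label (secreted / membrane): a secreted isoform defeats
    the rationale for exclusion.  ``unknown`` localization passes — only
    confirmed localizations disqualify.
    """
    return [
        r for r in db
        if not (r.localization & _INTRACELLULAR_CONFINED)
        or (r.localization & _BLOOD_ACCESSIBLE)
    ]


def filter_housekeeping(db):
    """Drop genes flagged as housekeeping (uninformative, uniformly expressed)."""
    return [r for r in db if not r.housekeeping]


def filter_high_organ_expression(db, organs=HIGH_OUTPUT_ORGANS, level: str = "high"):
    """Drop genes expressed at >= ``level`` in any listed high-output organ.

    Missing organ entries pass the filter (the database is sparse by design);
    a debug log line records each pass-through so sparsity is auditable.
    """
    cutoff = _LEVEL_RANK[level]
    kept = []
    for r in db:
        missing = [o for o in organs if o not in r.organ_levels]
        if missing:
            log.debug("%s: no data for organ(s) %s; passing filter", r.gene, missing)
        if any(_LEVEL_RANK[r.organ_levels[o]] >= cutoff
               for o in organs if o in r.organ_levels):
            continue
        kept.append(r)
    return kept


def retain_low_normal_expression(db):
    """Keep genes whose level in every normal-tissue dataset is at most ``low``.

    Records with an empty normal-tissue map are kept with a warning: absence
    of evidence of expression is not evidence of expression, but the gap is
    worth surfacing.
    """
    kept = []
    for r in db:
        if not r.normal_tissue_levels:
            warnings.warn(
                f"{r.gene}: no normal-tissue data; retained unfiltered", stacklevel=2
            )
            kept.append(r)
        elif all(_LEVEL_RANK[lvl] <= _LEVEL_RANK["low"]
                 for lvl in r.normal_tissue_levels.values()):
            kept.append(r)
    return kept


def select_secreted_membrane(db):
    """Partition survivors by blood accessibility; nothing is removed.

    Returns ``(flagged, unflagged)`` where flagged records carry a secreted
    or membrane localization — the prime serum-marker candidates.
    """
    flagged = [r for r in db if r.localization & _BLOOD_ACCESSIBLE]
    unflagged = [r for r in db if not (r.localization & _BLOOD_ACCESSIBLE)]
    return flagged, unflagged


@dataclass
class CascadeTrace:
    """Per-step accounting of the reduction cascade."""

    steps: list = field(default_factory=list)  # (name, n_in, n_out, removed ids)

    def record(self, name: str, before, after) -> None:
        removed = sorted({r.gene for r in before} - {r.gene for r in after})
        self.steps.append((name, len(before), len(after), removed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(n, i, o, ";".join(rm)) for n, i, o, rm in self.steps],
            columns=["step", "genes_in", "genes_out", "removed"],
        )

    def counts(self) -> list[int]:
        """Gene counts entering each step plus the final count."""
        if not self.steps:
            return []
        return [self.steps[0][1]] + [s[2] for s in self.steps]


def run_cascade(db, breast_cancer_gene_universe=None, literature_additions=()):
    """Run the full candidate-reduction cascade and return the candidate list.

    Steps, in order: restriction to the breast-cancer gene universe,
    localization filter, housekeeping filter, high-output-organ filter,
    low-normal-expression retention, secreted/membrane prioritization; the
    literature additions are then unioned in (case-insensitive dedup).

    Returns
    -------
    (pandas.DataFrame, CascadeTrace)
        Candidates with columns ``gene``, ``secreted_or_membrane`` (priority
        flag), ``from_literature``; and the step-by-step trace.

    Raises
    ------
    ValueError
        Duplicate gene ids in the database.
    """
    db = list(db)
    ids = [r.gene for r in db]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids in database: {dupes}")

    trace = CascadeTrace()

    if breast_cancer_gene_universe is not None:
        universe = {g.upper() for g in breast_cancer_gene_universe}
        current = [r for r in db if r.gene.upper() in universe]
    else:
        current = [r for r in db if r.breast_cancer_presence]
    trace.record("breast_cancer_universe", db, current)

    for name, fn in (
        ("localization", filter_localization),
        ("housekeeping", filter_housekeeping),
        ("high_organ_expression", filter_high_organ_expression),
        ("low_normal_expression", retain_low_normal_expression),
    ):
        nxt = fn(current)
        trace.record(name, current, nxt)
        current = nxt

    flagged, unflagged = select_secreted_membrane(current)
    trace.record("secreted_membrane_priority", current, current)  # nothing removed

    flagged_ids = {r.gene.upper() for r in flagged}
    survivor_ids = {r.gene.upper() for r in current}
    rows = [
        {"gene": r.gene, "secreted_or_membrane": r.gene.upper() in flagged_ids,
         "from_literature": False}
        for r in current
    ]
    for g in literature_additions:
        if g.upper() in survivor_ids:
            continue
        survivor_ids.add(g.upper())
        rows.append({"gene": g, "secreted_or_membrane": False, "from_literature": True})
    candidates = pd.DataFrame(rows, columns=["gene", "secreted_or_membrane", "from_literature"])
    trace.steps.append(
        ("literature_augmentation", len(current), len(candidates),
         sorted(r["gene"] for r in rows if r["from_literature"]))
    )
    return candidates, trace
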