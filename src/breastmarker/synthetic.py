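"""Synthetic generators emulating the marker-discovery study design.

Four generators cover every input the pipeline consumes:

* `gen_nested_normal` — the bilateral reduction-mammaplasty design: women,
  both breasts, several tissue slices per breast, with Gaussian variance
  components on the log2 scale at each level of nesting.
* `gen_cohort` — the validation cohort: invasive cancers, ipsilateral and
  contralateral normals, and mammaplasty controls, with planted differential
  expression, molecular subtypes among cancers, and a configurable fraction
  of "cancer-like" histologically normal tissues that carry the cancer
  profile.
* `gen_ct_plates` — raw CT-level qPCR plates for a known truth matrix,
  including the dilution-standard series and housekeeping wells.
* `gen_toy_genedb` — a toy annotation/expression database in which a planted
  subset survives the full mining cascade by construction.

All randomness flows through explicit seeds in the configs: the same config
yields bit-identical output.  Components are Gaussian on the log2 scale (the
scale the analysis centers and clusters on); values are exponentiated only
where linear measurements are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from breastmarker.mining import HIGH_OUTPUT_ORGANS, GeneDBRecord
from breastmarker.qpcr import RawPlateData

__all__ = [
    "NestedDesignConfig",
    "CohortConfig",
    "PlateConfig",
    "gen_nested_normal",
    "gen_cohort",
    "gen_ct_plates",
    "gen_toy_genedb",
    "study_cohort_config",
]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:03d}" for i in range(n)]


@dataclass
class NestedDesignConfig:
    """Design of the nested normal-tissue study.

    SDs may be scalars (shared by all genes) or arrays of length ``n_genes``.
    ``mean_slices_per_breast`` is achieved by drawing floor/ceil slice counts
    with the matching probability (3 or 4 for the default 3.5).
    """

    n_women: int = 10
    breasts_per_woman: int = 2
    mean_slices_per_breast: float = 3.5
    n_genes: int = 18
    sigma_woman: float | np.ndarray = 0.64
    sigma_breast: float | np.ndarray = 0.06
    sigma_slice: float | np.ndarray = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n_women < 2:
            raise ValueError("need >=2 women (between-woman stratum)")
        if self.breasts_per_woman < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        if self.mean_slices_per_breast < 1:
            raise ValueError("mean slices per breast must be >=1")
        for name in ("sigma_woman", "sigma_breast", "sigma_slice"):
            s = np.asarray(getattr(self, name), dtype=float)
            if np.any(s < 0):
                raise ValueError(f"{name} must be >= 0")
        if self.mean_slices_per_breast == 1:
            raise ValueError(
                "non-estimable design: exactly 1 slice everywhere leaves the "
                "within-breast stratum empty"
            )


@dataclass
class CohortConfig:
    """The cancer / ipsilateral / contralateral / mammaplasty cohort.

    ``de_genes`` lists planted effects as ``(gene index, direction, effect)``
    with direction ``"over"``/``"under"`` and effect in log2 units.
    ``frac_cancerlike_ipsi`` of the ipsilateral normals (and
    ``n_cancerlike_contra`` of the contralateral normals) receive the full
    cancer expression profile — the molecular-predisposition signal the
    clustering stage is meant to recover.  ``n_inconclusive`` genes are
    emitted as all-missing, emulating assays that fail repeatedly.
    """

    n_cancer: int = 24
    n_ipsi: int = 38
    n_contra: int = 3
    n_mamm: int = 28
    n_genes: int = 134
    de_genes: tuple = ()
    frac_cancerlike_ipsi: float = 0.0
    n_cancerlike_contra: int = 0
    n_subtype_groups: int = 2
    subtype_effect: float = 2.0
    noise_sd: float = 1.0
    n_inconclusive: int = 0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cancer, self.n_ipsi, self.n_contra, self.n_mamm) < 0:
            raise ValueError("tissue counts must be >= 0")
        if not 0.0 <= self.frac_cancerlike_ipsi <= 1.0:
            raise ValueError("frac_cancerlike_ipsi must lie in [0, 1]")
        if not 0 <= self.n_cancerlike_contra <= self.n_contra:
            raise ValueError("n_cancerlike_contra out of range")
        if len(self.de_genes) > self.n_genes:
            raise ValueError("more de_genes than genes")
        for idx, direction, effect in self.de_genes:
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"de gene index {idx} out of range")
            if direction not in ("over", "under"):
                raise ValueError("direction must be 'over' or 'under'")
            if not np.isfinite(effect):
                raise ValueError("effect sizes must be finite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.n_inconclusive <= self.n_genes - len(self.de_genes):
            raise ValueError("n_inconclusive out of range")


@dataclass
class PlateConfig:
    """CT-level plate simulation: dilution standard, housekeeping, replicates."""

    dilution_factors: tuple = (1.0, 1 / 3, 1 / 9, 1 / 27, 1 / 81)
    amplification_efficiency: float = 2.0
    housekeeping_genes: tuple = ("ACTB", "B2M", "TMED10")
    replicate_count: int = 2
    ct_noise_sd: float = 0.0
    standard_ct: float = 22.0  # CT of the undiluted standard
    seed: int = 0

    def validate(self) -> None:
        d = np.asarray(self.dilution_factors, dtype=float)
        if len(d) < 3 or np.any(d <= 0) or np.any(np.diff(d) >= 0):
            raise ValueError("dilutions must be >=3 strictly decreasing positives")
        if not 1.0 < self.amplification_efficiency <= 2.0:
            raise ValueError("efficiency must lie in (1, 2]")
        if self.replicate_count < 1 or self.ct_noise_sd < 0:
            raise ValueError("invalid replicate count or noise SD")


def gen_nested_normal(cfg: NestedDesignConfig) -> pd.DataFrame:
    """Simulate the nested normal-tissue dataset in long format.

    value(g, w, b, s) = W[g, w] + B[g, w, b] + S[g, w, b, s], each component
    independent zero-mean Gaussian with the configured SD (per-gene SDs when
    vectors are given).  Columns: ``gene``, ``woman``, ``breast``, ``slice``,
    ``value``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    sw = np.broadcast_to(np.asarray(cfg.sigma_woman, dtype=float), (cfg.n_genes,))
    sb = np.broadcast_to(np.asarray(cfg.sigma_breast, dtype=float), (cfg.n_genes,))
    ss = np.broadcast_to(np.asarray(cfg.sigma_slice, dtype=float), (cfg.n_genes,))

    lo = int(np.floor(cfg.mean_slices_per_breast))
    p_hi = cfg.mean_slices_per_breast - lo
    breast_names = (
        ["L", "R"] if cfg.breasts_per_woman == 2
        else [f"B{k + 1}" for k in range(cfg.breasts_per_woman)]
    )

    records = []
    for w in range(cfg.n_women):
        woman = f"W{w + 1:02d}"
        w_eff = rng.normal(0.0, 1.0, cfg.n_genes) * sw
        for breast in breast_names:
            b_eff = rng.normal(0.0, 1.0, cfg.n_genes) * sb
            n_slices = lo + int(rng.random() < p_hi)
            for s in range(n_slices):
                s_eff = rng.normal(0.0, 1.0, cfg.n_genes) * ss
                vals = w_eff + b_eff + s_eff
                for g, v in zip(genes, vals):
                    records.append((g, woman, breast, f"S{s + 1}", float(v)))
    df = pd.DataFrame(records, columns=["gene", "woman", "breast", "slice", "value"])

    slices_per_breast = df.groupby(["woman", "breast"])["slice"].nunique()
    if (slices_per_breast < 2).all():
        raise ValueError(
            "non-estimable design: every breast has a single slice; "
            "increase mean_slices_per_breast"
        )
    return df


def study_cohort_config(seed: int = 0) -> CohortConfig:
    """The validation-cohort configuration at the study's conditions.

    24 cancers, 38 ipsilateral and 3 contralateral normals, 28 mammaplasty
    controls; 134 genes of which 8 are inconclusive (assay failure) and 67 of
    the 126 evaluable carry differential expression (34 over, 33 under, 3
    log2 units); 7/38 ipsilateral and 1/3 contralateral normals are
    cancer-like.
    """
    n_genes, n_inconclusive, n_de = 134, 8, 67
    n_over = 34
    evaluable = n_genes - n_inconclusive  # inconclusive genes occupy the tail
    step = evaluable / n_de
    idx = [int(round(i * step)) for i in range(n_de)]
    de = tuple(
        (g, "over" if i < n_over else "under", 3.0) for i, g in enumerate(idx)
    )
    return CohortConfig(
        n_genes=n_genes,
        de_genes=de,
        frac_cancerlike_ipsi=7 / 38,
        n_cancerlike_contra=1,
        n_inconclusive=n_inconclusive,
        noise_sd=1.0,
        seed=seed,
    )


def gen_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the validation cohort.

    Returns ``(matrix, annotations)``: a gene x tissue matrix of *linear*
    relative expression (NaN for inconclusive genes) and per-tissue
    annotations with columns ``tissue``, ``tissue_class``, ``cancer_like``,
    ``subtype``, ``outcome`` and ``patient``.

    Mammaplasty, contralateral and non-cancer-like ipsilateral tissues share
    the baseline (zero log2) profile; cancers shift the planted ``de_genes``
    by their effects; cancer-like normals receive the same cancer profile.
    Cancers are split among ``n_subtype_groups`` molecular subtypes whose
    marker genes (a split of the over-expressed de genes) are pushed up by
    ``subtype_effect`` in their own group and down in the others; outcome
    events concentrate in the last (basal-like) group.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)

    tissues, classes, patients = [], [], []
    for prefix, n, cls in (
        ("CA", cfg.n_cancer, "cancer"),
        ("NI", cfg.n_ipsi, "ipsilateral"),
        ("NC", cfg.n_contra, "contralateral"),
        ("NM", cfg.n_mamm, "mammaplasty"),
    ):
        for k in range(n):
            tissues.append(f"{prefix}{k + 1:02d}")
            classes.append(cls)
            patients.append(f"P_{prefix}{k + 1:02d}")

    n_tissues = len(tissues)
    effect = np.zeros(cfg.n_genes)
    for idx, direction, eff in cfg.de_genes:
        effect[idx] = eff if direction == "over" else -eff

    # cancer-like normals
    ipsi_idx = [i for i, c in enumerate(classes) if c == "ipsilateral"]
    n_cl = int(round(cfg.frac_cancerlike_ipsi * len(ipsi_idx)))
    cancerlike = set(rng.choice(ipsi_idx, size=n_cl, replace=False)) if n_cl else set()
    contra_idx = [i for i, c in enumerate(classes) if c == "contralateral"]
    if cfg.n_cancerlike_contra:
        cancerlike |= set(
            rng.choice(contra_idx, size=cfg.n_cancerlike_contra, replace=False)
        )

    # subtypes among cancers; markers = split of the over-expressed de genes
    cancer_idx = [i for i, c in enumerate(classes) if c == "cancer"]
    subtype_names = (
        ["luminal", "basal"] if cfg.n_subtype_groups == 2
        else [f"subtype{k + 1}" for k in range(cfg.n_subtype_groups)]
    )
    subtype_of = {}
    for pos, i in enumerate(cancer_idx):
        subtype_of[i] = subtype_names[pos % cfg.n_subtype_groups]
    over_genes = [idx for idx, d, _ in cfg.de_genes if d == "over"]
    marker_sets: dict[str, list[int]] = {s: [] for s in subtype_names}
    for pos, g in enumerate(over_genes):
        marker_sets[subtype_names[pos % max(cfg.n_subtype_groups, 1)]].append(g)

    log2 = np.zeros((cfg.n_genes, n_tissues))
    for t in range(n_tissues):
        carries_cancer_profile = classes[t] == "cancer" or t in cancerlike
        if carries_cancer_profile:
            log2[:, t] += effect
        if classes[t] == "cancer" and cfg.n_subtype_groups > 1:
            own = subtype_of[t]
            for s, markers in marker_sets.items():
                delta = cfg.subtype_effect if s == own else -cfg.subtype_effect
                log2[markers, t] += delta
    log2 += rng.normal(0.0, cfg.noise_sd, size=log2.shape)

    matrix = pd.DataFrame(np.exp2(log2), index=genes, columns=tissues)
    if cfg.n_inconclusive:
        de_set = {idx for idx, _, _ in cfg.de_genes}
        eligible = [i for i in range(cfg.n_genes) if i not in de_set]
        inconclusive = eligible[-cfg.n_inconclusive:]
        matrix.iloc[inconclusive, :] = np.nan

    outcome = []
    for i in range(n_tissues):
        if classes[i] != "cancer":
            outcome.append(None)
        else:
            p_event = 0.6 if subtype_of[i] == subtype_names[-1] else 0.05
            outcome.append("event" if rng.random() < p_event else "censored")
    ann = pd.DataFrame({
        "tissue": tissues,
        "tissue_class": classes,
        "cancer_like": [i in cancerlike for i in range(n_tissues)],
        "subtype": [subtype_of.get(i) for i in range(n_tissues)],
        "outcome": outcome,
        "patient": patients,
    })
    return matrix, ann


def gen_ct_plates(cfg: PlateConfig, truth: pd.DataFrame) -> RawPlateData:
    """Simulate raw CT wells for a known linear truth matrix.

    CT(g, t) = standard_ct - log(truth[g, t]) / log(efficiency) + noise, with
    ``replicate_count`` wells per (gene, tissue), a duplicated
    dilution-standard series, and housekeeping rows (constant truth 1) added
    when absent from ``truth``.

    Raises
    ------
    ValueError
        Non-positive truth values (no CT exists for zero template).
    """
    cfg.validate()
    vals = truth.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("truth matrix must be strictly positive and finite")
    rng = np.random.default_rng(cfg.seed)
    log_eff = np.log(cfg.amplification_efficiency)

    full = truth.copy()
    for hk in cfg.housekeeping_genes:
        if hk not in full.index:
            full.loc[hk] = 1.0

    wells = []
    for gene in full.index:
        for tissue in full.columns:
            base_ct = cfg.standard_ct - np.log(full.loc[gene, tissue]) / log_eff
            for rep in range(cfg.replicate_count):
                ct = base_ct + rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd else base_ct
                wells.append((gene, tissue, rep + 1, float(ct)))
    standard = []
    for dil in cfg.dilution_factors:
        base_ct = cfg.standard_ct - np.log(dil) / log_eff
        for _ in range(2):  # the standard series runs in duplicate
            ct = base_ct + rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd else base_ct
            standard.append((float(dil), float(ct)))

    return RawPlateData(
        wells=pd.DataFrame(wells, columns=["gene", "tissue", "replicate", "ct"]),
        standard=pd.DataFrame(standard, columns=["dilution", "ct"]),
        housekeeping=tuple(cfg.housekeeping_genes),
    )


def gen_toy_genedb(n_genes: int, truth_flags, seed: int = 0) -> list[GeneDBRecord]:
    """Toy annotation database where the flagged subset survives the cascade.

    ``truth_flags`` is a boolean sequence of length ``n_genes``; flagged
    genes are constructed to pass every filter (secreted/membrane, not
    housekeeping, no high-output-organ expression above medium, all normal
    tissues at most low).  Every unflagged gene violates exactly one filter,
    chosen pseudo-randomly, so the cascade's survivors equal the planted set
    by construction.
    """
    if n_genes < 1:
        raise ValueError("need n_genes >= 1")
    truth_flags = list(truth_flags)
    if len(truth_flags) != n_genes:
        raise ValueError("truth_flags length must equal n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    normal_sets = ("epithelial_a", "epithelial_b", "breast_adjacent")

    records = []
    for g, flag in zip(genes, truth_flags):
        organ_levels = {
            o: str(rng.choice(["absent", "low", "medium"])) for o in HIGH_OUTPUT_ORGANS
        }
        normal_levels = {
            s: str(rng.choice(["absent", "low"])) for s in normal_sets
        }
        if flag:
            loc = frozenset({str(rng.choice(["secreted", "membrane"])), "cytoplasmic"})
            rec = GeneDBRecord(
                gene=g, localization=loc, housekeeping=False,
                organ_levels=organ_levels, normal_tissue_levels=normal_levels,
                breast_cancer_presence=True, tn_ratio_over_2=True,
            )
        else:
            violation = int(rng.integers(0, 4))
            loc = frozenset({"cytoplasmic"})
            hk = False
            if violation == 0:
                loc = frozenset({str(rng.choice(["nuclear", "mitochondrial", "ribosomal"]))})
            elif violation == 1:
                hk = True
            elif violation == 2:
                organ = str(rng.choice(HIGH_OUTPUT_ORGANS))
                organ_levels[organ] = "high"
            else:
                ds = str(rng.choice(normal_sets))
                normal_levels[ds] = str(rng.choice(["medium", "high"]))
            rec = GeneDBRecord(
                gene=g, localization=loc, housekeeping=hk,
                organ_levels=organ_levels, normal_tissue_levels=normal_levels,
                breast_cancer_presence=True, tn_ratio_over_2=bool(rng.random() < 0.5),
            )
        records.append(rec)
    return records
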