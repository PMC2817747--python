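"""CSV / JSON-lines readers and writers for the pipeline's file formats.

Expression matrices travel as CSV with the gene symbol in the first column
and one column per tissue; raw plate data as long-format CSV
(gene, tissue, replicate, ct); nested normal-tissue data as long-format CSV
(gene, woman, breast, slice, value); gene-database records as JSON lines.
Configs are YAML mappings whose sections mirror the dataclass fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from breastmarker.mining import GeneDBRecord
from breastmarker.qpcr import RawPlateData
from breastmarker.synthetic import CohortConfig, NestedDesignConfig, PlateConfig

__all__ = [
    "read_expression_csv",
    "write_expression_csv",
    "read_long_csv",
    "read_plate_csv",
    "read_genedb_jsonl",
    "write_genedb_jsonl",
    "load_config",
]


def read_expression_csv(path) -> pd.DataFrame:
    """Read a gene x tissue expression matrix (first column = gene symbol)."""
    df = pd.read_csv(path)
    return df.set_index(df.columns[0]).astype(float)


def write_expression_csv(m: pd.DataFrame, path) -> None:
    m.rename_axis("gene").to_csv(path)


def read_long_csv(path) -> pd.DataFrame:
    """Read long-format records (nested dataset or annotations) as-is."""
    return pd.read_csv(path)


def read_plate_csv(wells_path, standard_path, housekeeping=()) -> RawPlateData:
    """Assemble RawPlateData from a wells CSV and a standard-series CSV."""
    return RawPlateData(
        wells=pd.read_csv(wells_path),
        standard=pd.read_csv(standard_path),
        housekeeping=tuple(housekeeping),
    )


def read_genedb_jsonl(path) -> list[GeneDBRecord]:
    """Read gene-database records from JSON lines (one record per line)."""
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        records.append(GeneDBRecord(
            gene=d["gene"],
            localization=frozenset(d.get("localization", ["unknown"])),
            housekeeping=bool(d.get("housekeeping", False)),
            organ_levels=d.get("organ_levels", {}),
            normal_tissue_levels=d.get("normal_tissue_levels", {}),
            breast_cancer_presence=bool(d.get("breast_cancer_presence", True)),
            tn_ratio_over_2=bool(d.get("tn_ratio_over_2", False)),
        ))
    return records


def write_genedb_jsonl(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            d = dataclasses.asdict(r)
            d["localization"] = sorted(d["localization"])
            fh.write(json.dumps(d) + "\n")


_CONFIG_SECTIONS = {
    "nested_design": NestedDesignConfig,
    "cohort": CohortConfig,
    "plate": PlateConfig,
}


def load_config(path) -> dict:
    """Load simulation configs from a YAML file.

    Recognized top-level sections: ``nested_design``, ``cohort``, ``plate``;
    each maps onto the corresponding config dataclass (tuple-valued fields
    accept YAML lists).  Returns a dict of section name to config instance.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for section, cls in _CONFIG_SECTIONS.items():
        if section not in raw:
            continue
        kwargs = dict(raw[section])
        for f in dataclasses.fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], list):
                value = kwargs[f.name]
                kwargs[f.name] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in value
                )
        cfg = cls(**kwargs)
        cfg.validate()
        out[section] = cfg
    return out
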