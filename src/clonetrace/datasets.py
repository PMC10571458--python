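"""Bundled example case data: two multisample prostate cancer patients.

The package ships curated cluster-level summaries for two high-risk
prostate cancer cases (GP5 and GP12), each with a reconstructed clone
tree (per-cluster per-sample CCFs and branch mutation counts), sample
anatomy, cluster-assigned driver events, and shared driver-gene /
drug-gene tables. GP5 carries a CDK12-driven tandem-duplicator
phenotype and seeded its pelvic lymph nodes from the apex; GP12 grew
from the left mid-apex over the midline into both seminal vesicles and
seeded strictly side-to-side. The tables are desk-scale curated
summaries intended for worked examples and regression tests; the
drug-gene table is a small synthetic snapshot, not a database export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .drivers import map_drivers
from .errors import DataError
from .trees import Clone, CloneTree

__all__ = ["CaseStudy", "load_case", "available_cases"]


@dataclass
class CaseStudy:
    """One bundled patient: tree, anatomy, drivers and catalogs."""

    name: str
    age_rp: float
    index_samples: list[str]
    tree: CloneTree
    anatomy: pd.DataFrame
    driver_events: pd.DataFrame  # cluster-assigned, catalog-annotated
    driver_catalog: pd.DataFrame
    drug_table: pd.DataFrame


def available_cases() -> list[str]:
    return ["GP5", "GP12"]


def _data_root():
    return resources.files("clonetrace") / "data"


def load_case(name: str) -> CaseStudy:
    """Load a bundled case study by name (``"GP5"`` or ``"GP12"``)."""
    key = name.lower()
    if name.upper() not in available_cases():
        raise DataError(f"unknown case {name!r}; available: {available_cases()}")
    root = _data_root()
    case_dir = root / key
    with (case_dir / "patient.json").open() as fh:
        meta = json.load(fh)
    clusters = pd.read_csv((case_dir / "clusters.tsv").open(), sep="\t")
    anatomy = pd.read_csv((case_dir / "anatomy.tsv").open(), sep="\t")
    events = pd.read_csv((case_dir / "drivers.tsv").open(), sep="\t")
    catalog = pd.read_csv((root / "shared" / "driver_catalog.tsv").open(), sep="\t")
    drugs = pd.read_csv((root / "shared" / "drug_gene.tsv").open(), sep="\t")

    samples = [c[4:] for c in clusters.columns if c.startswith("ccf_")]
    clones = [
        Clone(
            id=str(row["cluster"]),
            parent=None if pd.isna(row["parent"]) or row["parent"] == "" else str(row["parent"]),
            ccf={s: float(row[f"ccf_{s}"]) for s in samples},
            n_snv=int(row["n_snv"]),
            n_sbs1=int(row["n_sbs1"]),
            n_td=int(row["n_td"]),
        )
        for _, row in clusters.iterrows()
    ]
    tree = CloneTree(clones, samples=samples)
    tree.validate()
    return CaseStudy(
        name=meta["patient_id"],
        age_rp=float(meta["age_rp"]),
        index_samples=list(meta["index_samples"]),
        tree=tree,
        anatomy=anatomy,
        driver_events=map_drivers(events, catalog, tree),
        driver_catalog=catalog,
        drug_table=drugs,
    )
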