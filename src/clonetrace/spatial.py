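"""Anatomic tracing: origin inference, metastatic capability, seeding.

Anatomy metadata assign each sequenced sample a site class (prostate,
seminal_vesicle, lymph_node), a laterality (L, R, midline) and a free
text region. Samples outside the prostate are extraprostatic; every
subclonal (non-truncal) cell population found in them is considered
metastatic, and its intraprostatic occurrences mark seeder regions.

Two related but distinct cluster sets are computed:

* the **metastatic-capable set** — non-truncal clusters whose
  (cumulative) CCF reaches the presence threshold in any extraprostatic
  sample; ancestors of metastatic subclones belong to it because their
  mutations are carried by the metastatic cells.
* the **seeding set** — non-truncal clusters with a *resident
  population* (jawbreaker surface >= threshold) in a metastatic
  sample. Each such population must have migrated out of the primary
  at least once, so the size of this set is the minimum number of
  seeding events; an ancestor whose presence in the metastases is fully
  explained by its descendants does not imply an extra migration.

Because the abstract-level "prostate to lymph node" tally and the
broader all-extraprostatic tally can differ when seminal vesicles are
invaded, :class:`TraceReport` carries both.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import pandas as pd

from .errors import DataError
from .trees import CloneTree

__all__ = [
    "TraceReport",
    "classify_metastatic",
    "seeding_clusters",
    "count_seeding_events",
    "infer_origin",
    "trace_routes",
    "trace_report",
    "descent_closure_report",
]

logger = logging.getLogger(__name__)

PRESENCE_THRESHOLD = 0.01
EXTRAPROSTATIC = ("seminal_vesicle", "lymph_node")


def _check_anatomy(anatomy: pd.DataFrame, tree: CloneTree) -> pd.DataFrame:
    required = {"sample", "site_class", "laterality"}
    missing = required - set(anatomy.columns)
    if missing:
        raise DataError(f"anatomy table lacks columns {sorted(missing)}")
    unknown = set(tree.samples) - set(anatomy["sample"])
    if unknown:
        raise DataError(f"samples without anatomy record: {sorted(unknown)}")
    return anatomy.set_index("sample", drop=False)


def classify_metastatic(
    tree: CloneTree,
    anatomy: pd.DataFrame,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Metastatic-capable clusters and their intraprostatic seeders.

    A non-truncal cluster is metastatic-capable iff its CCF reaches
    ``presence_threshold`` in at least one extraprostatic sample.
    Returns one row per capable cluster with the extraprostatic samples
    where it is found and the primary (prostate) samples that could
    have seeded it. With no extraprostatic samples the result is empty
    (with a logged warning).
    """
    ana = _check_anatomy(anatomy, tree)
    extra = [s for s in tree.samples if ana.loc[s, "site_class"] in EXTRAPROSTATIC]
    if not extra:
        logger.warning("no extraprostatic samples: metastatic-capable set is empty")
        return pd.DataFrame(columns=["cluster", "met_samples", "seeder_samples"])
    primary = [s for s in tree.samples if ana.loc[s, "site_class"] == "prostate"]
    rows = []
    for cid in tree.preorder():
        if cid == tree.root:
            continue
        mets = [s for s in extra if tree.present_in(cid, s, presence_threshold)]
        if not mets:
            continue
        seeders = [s for s in primary if tree.present_in(cid, s, presence_threshold)]
        rows.append({"cluster": cid, "met_samples": mets, "seeder_samples": seeders})
    return pd.DataFrame(rows, columns=["cluster", "met_samples", "seeder_samples"])


def seeding_clusters(
    tree: CloneTree,
    anatomy: pd.DataFrame,
    presence_threshold: float = PRESENCE_THRESHOLD,
    sites: tuple[str, ...] = EXTRAPROSTATIC,
) -> set[str]:
    """Non-truncal clusters with a resident population in a met sample."""
    ana = _check_anatomy(anatomy, tree)
    met_samples = [s for s in tree.samples if ana.loc[s, "site_class"] in sites]
    found: set[str] = set()
    for cid in tree.clones:
        if cid == tree.root:
            continue
        if any(tree.surface(cid, s) >= presence_threshold for s in met_samples):
            found.add(cid)
    return found


def count_seeding_events(
    tree: CloneTree,
    anatomy: pd.DataFrame,
    presence_threshold: float = PRESENCE_THRESHOLD,
    sites: tuple[str, ...] = EXTRAPROSTATIC,
) -> int:
    """Minimum number of seeding events into the given site classes.

    Each evolutionarily distinct population resident in a metastatic
    sample migrated out of the primary at least once, so the count is
    the number of such populations (see :func:`seeding_clusters`).
    """
    return len(seeding_clusters(tree, anatomy, presence_threshold, sites))


def infer_origin(
    tree: CloneTree,
    anatomy: pd.DataFrame,
    tie_window: float = 0.02,
) -> tuple[list[str], pd.DataFrame]:
    """Rank primary samples by their truncal-only cell fraction.

    The sample(s) with the largest fraction of cells carrying solely
    truncal mutations (the root's jawbreaker surface) mark the
    putative anatomic site of origin. Samples within ``tie_window`` of
    the top fraction are reported jointly.
    """
    ana = _check_anatomy(anatomy, tree)
    primary = [s for s in tree.samples if ana.loc[s, "site_class"] == "prostate"]
    if not primary:
        primary = list(tree.samples)
    table = pd.DataFrame(
        {
            "sample": primary,
            "truncal_fraction": [tree.surface(tree.root, s) for s in primary],
        }
    ).sort_values(["truncal_fraction", "sample"], ascending=[False, True]).reset_index(drop=True)
    top = table["truncal_fraction"].iloc[0]
    origin = table.loc[table["truncal_fraction"] >= top - tie_window, "sample"].tolist()
    return origin, table


_SOURCE_SITES = {
    "lymph_node": ("prostate", "seminal_vesicle"),
    "seminal_vesicle": ("prostate",),
}


def trace_routes(
    tree: CloneTree,
    anatomy: pd.DataFrame,
    presence_threshold: float = PRESENCE_THRESHOLD,
    sites: tuple[str, ...] = EXTRAPROSTATIC,
) -> pd.DataFrame:
    """Candidate sources and laterality verdict per metastatic route.

    One row per (cluster, metastatic sample) where the cluster has a
    resident population. Candidate sources are upstream-compartment
    samples (prostate and, for lymph nodes, seminal vesicles)
    containing the cluster. The verdict is ``ipsilateral`` when all
    sources share the metastasis' laterality, ``contralateral`` when
    none does, ``ambiguous-bilateral`` when both sides qualify. A
    cluster with no source anywhere is flagged ``met-private`` and its
    nearest sourced ancestor supplies the route.
    """
    ana = _check_anatomy(anatomy, tree)
    met_samples = [s for s in tree.samples if ana.loc[s, "site_class"] in sites]
    rows = []
    for met in met_samples:
        met_lat = ana.loc[met, "laterality"]
        source_sites = _SOURCE_SITES.get(ana.loc[met, "site_class"], ("prostate",))
        upstream = [s for s in tree.samples if ana.loc[s, "site_class"] in source_sites]
        for cid in tree.preorder():
            if cid == tree.root or tree.surface(cid, met) < presence_threshold:
                continue
            node, flag = cid, ""
            sources = [s for s in upstream if tree.present_in(node, s, presence_threshold)]
            while not sources and tree.clones[node].parent is not None:
                node = tree.clones[node].parent  # type: ignore[assignment]
                flag = "met-private"
                if node == tree.root:
                    break
                sources = [s for s in upstream if tree.present_in(node, s, presence_threshold)]
            lats = {ana.loc[s, "laterality"] for s in sources}
            if not sources:
                verdict = "unsourced"
            elif lats == {met_lat}:
                verdict = "ipsilateral"
            elif met_lat in lats:
                verdict = "ambiguous-bilateral"
            elif lats == {"midline"}:
                verdict = "midline"
            else:
                verdict = "contralateral"
            rows.append(
                {
                    "cluster": cid,
                    "met_sample": met,
                    "met_laterality": met_lat,
                    "source_cluster": node,
                    "sources": sources,
                    "verdict": verdict,
                    "flag": flag,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "met_sample",
            "met_laterality",
            "source_cluster",
            "sources",
            "verdict",
            "flag",
        ],
    )


def descent_closure_report(
    tree: CloneTree,
    anatomy: pd.DataFrame,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Are all descendants of seeding clusters present in metastases?

    Empirically, every detectable descendant of a cluster with proven
    metastatic capability (a resident population in a metastatic
    sample) tends to reach the metastases as well — seeding is an
    ongoing process. This reports, for each detectable descendant of
    each seeding cluster, whether it is present in any extraprostatic
    sample; it never raises.
    """
    ana = _check_anatomy(anatomy, tree)
    extra = [s for s in tree.samples if ana.loc[s, "site_class"] in EXTRAPROSTATIC]
    capable = seeding_clusters(tree, anatomy, presence_threshold)
    rows = []
    for cid in sorted(capable):
        for desc in tree.descendants(cid):
            detected = any(
                tree.present_in(desc, s, presence_threshold) for s in tree.samples
            )
            if not detected:
                continue
            in_mets = any(tree.present_in(desc, s, presence_threshold) for s in extra)
            rows.append({"cluster": cid, "descendant": desc, "in_metastases": in_mets})
    return pd.DataFrame(rows, columns=["cluster", "descendant", "in_metastases"])


@dataclass
class TraceReport:
    """Combined anatomic tracing summary for one patient."""

    origin: list[str]
    origin_table: pd.DataFrame
    capable: pd.DataFrame
    routes: pd.DataFrame
    seeding_events_extraprostatic: int
    seeding_events_lymph_node: int
    seeding_clusters_extraprostatic: list[str]
    seeding_clusters_lymph_node: list[str]

    def to_dict(self) -> dict:
        return {
            "origin": self.origin,
            "origin_ranking": self.origin_table.to_dict(orient="records"),
            "metastatic_capable": self.capable.to_dict(orient="records"),
            "routes": self.routes.to_dict(orient="records"),
            "seeding_events": {
                "extraprostatic": self.seeding_events_extraprostatic,
                "lymph_node_only": self.seeding_events_lymph_node,
            },
            "seeding_clusters": {
                "extraprostatic": self.seeding_clusters_extraprostatic,
                "lymph_node_only": self.seeding_clusters_lymph_node,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def trace_report(
    tree: CloneTree,
    anatomy: pd.DataFrame,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> TraceReport:
    """Run the full anatomic tracing and bundle the results."""
    origin, origin_table = infer_origin(tree, anatomy)
    capable = classify_metastatic(tree, anatomy, presence_threshold)
    routes = trace_routes(tree, anatomy, presence_threshold)
    seeds_all = seeding_clusters(tree, anatomy, presence_threshold, EXTRAPROSTATIC)
    seeds_ln = seeding_clusters(tree, anatomy, presence_threshold, ("lymph_node",))
    return TraceReport(
        origin=origin,
        origin_table=origin_table,
        capable=capable,
        routes=routes,
        seeding_events_extraprostatic=len(seeds_all),
        seeding_events_lymph_node=len(seeds_ln),
        seeding_clusters_extraprostatic=sorted(seeds_all),
        seeding_clusters_lymph_node=sorted(seeds_ln),
    )
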