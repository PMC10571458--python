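"""Driver mapping, index-lesion coverage and druggability tiers.

Driver events (SNVs, CNAs, SVs) already assigned to tree clusters are
matched against a driver-gene catalog; an event counts as *putatively
oncogenic* when the catalog knows the gene's oncogenic direction and
the observed effect is consistent with it (a loss in a tumor
suppressor, a gain in an oncogene). Events in catalog genes without a
known direction are mapped but excluded from coverage denominators.

Index-lesion coverage quantifies how much of the driver landscape a
conventional "index lesion" (the largest tumor focus) captures: the
fraction of putatively oncogenic events whose cluster is detectable in
the index samples. Druggability prioritisation orders targets by
evolutionary status — truncal druggable events first (present in all
cancer cells, hence most likely to yield durable responses), then
druggable events in metastatic-capable subclones, then the remaining
subclonal ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import DataError
from .trees import CloneTree

__all__ = [
    "load_catalog",
    "map_drivers",
    "index_lesion_coverage",
    "druggability_report",
    "cna_burden_compare",
    "CnaBurdenResult",
]

logger = logging.getLogger(__name__)

PRESENCE_THRESHOLD = 0.01

#: Variant classes eligible for drug targeting; TP53 additionally
#: qualifies through loss of heterozygosity.
_DRUGGABLE_CLASSES = {"protein_altering", "copy_gain", "homozygous_loss"}
_LOH_EXCEPTION_GENES = {"TP53"}


def load_catalog(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a driver catalog (gene, evidence, direction)."""
    required = {"gene", "evidence", "direction"}
    if missing := required - set(frame.columns):
        raise DataError(f"driver catalog lacks columns {sorted(missing)}")
    if frame["gene"].duplicated().any():
        dupes = frame.loc[frame["gene"].duplicated(), "gene"].tolist()
        raise DataError(f"driver catalog has duplicate gene symbols: {dupes}")
    return frame.reset_index(drop=True)


def map_drivers(
    events: pd.DataFrame,
    catalog: pd.DataFrame,
    tree: CloneTree,
) -> pd.DataFrame:
    """Annotate cluster-assigned events with catalog and tree status.

    Adds ``truncal`` (cluster is the root), ``in_catalog``,
    ``evidence``, ``catalog_direction`` and ``putatively_oncogenic``
    columns. Events whose gene is absent from the catalog pass through
    unannotated (``in_catalog`` False). Events must carry ``gene``,
    ``effect`` and ``cluster`` columns; unknown clusters raise.
    """
    catalog = load_catalog(catalog)
    out = events.reset_index(drop=True).copy()
    unknown = set(out["cluster"].dropna()) - set(tree.clones)
    if unknown:
        raise DataError(f"events assigned to unknown clusters: {sorted(unknown)}")
    cat = catalog.set_index("gene")
    out["truncal"] = out["cluster"] == tree.root
    out["in_catalog"] = out["gene"].isin(cat.index)
    out["evidence"] = [
        cat.loc[g, "evidence"] if g in cat.index else None for g in out["gene"]
    ]
    out["catalog_direction"] = [
        cat.loc[g, "direction"] if g in cat.index else None for g in out["gene"]
    ]
    consistent = {
        ("gain-of-function", "gain"): True,
        ("loss-of-function", "loss"): True,
    }
    out["putatively_oncogenic"] = [
        bool(consistent.get((eff, direction), False))
        for eff, direction in zip(out["effect"], out["catalog_direction"])
    ]
    return out


def index_lesion_coverage(
    tree: CloneTree,
    drivers: pd.DataFrame,
    index_samples: list[str],
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> tuple[int, int, float]:
    """Fraction of oncogenic driver events detectable in index samples.

    Numerator: putatively oncogenic events whose cluster has CCF >=
    threshold in at least one index sample. Denominator: all mapped
    putatively oncogenic events. Returns ``(numerator, denominator,
    fraction)``.
    """
    if not index_samples:
        raise DataError("index sample set is empty")
    if unknown := set(index_samples) - set(tree.samples):
        raise DataError(f"index samples not in tree: {sorted(unknown)}")
    onco = drivers[drivers["putatively_oncogenic"]]
    denominator = len(onco)
    numerator = sum(
        any(tree.present_in(c, s, presence_threshold) for s in index_samples)
        for c in onco["cluster"]
    )
    fraction = numerator / denominator if denominator else float("nan")
    return int(numerator), int(denominator), fraction


def druggability_report(
    tree: CloneTree,
    drivers: pd.DataFrame,
    drug_table: pd.DataFrame,
    capable_clusters: set[str] | None = None,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Prioritised druggable targets by evolutionary status.

    Tier 1: truncal druggable events; tier 2: druggable events in
    metastatic-capable subclones; tier 3: other subclonal druggable
    events. Eligibility requires a protein-altering variant, copy
    gain or homozygous loss (TP53 additionally qualifies through LOH)
    plus at least one drug interaction for the gene. Every event
    appears exactly once, with ineligible ones carrying a reason.
    """
    capable_clusters = capable_clusters or set()
    drugs_by_gene = (
        drug_table.groupby("gene")["drug"].apply(lambda d: sorted(set(d))).to_dict()
    )
    rows = []
    for _, ev in drivers.iterrows():
        var_class = str(ev.get("variant_class", "other"))
        eligible_class = var_class in _DRUGGABLE_CLASSES or (
            ev["gene"] in _LOH_EXCEPTION_GENES and var_class == "loh"
        )
        drug_list = drugs_by_gene.get(ev["gene"], [])
        max_ccf = max(
            (tree.ccf(ev["cluster"], s) for s in tree.samples), default=float("nan")
        )
        if not eligible_class:
            tier, reason = None, f"variant class {var_class!r} not druggable-eligible"
        elif not drug_list:
            tier, reason = None, "no drug interaction recorded for gene"
        elif ev["cluster"] == tree.root:
            tier, reason = 1, "truncal"
        elif ev["cluster"] in capable_clusters:
            tier, reason = 2, "metastatic-capable subclone"
        else:
            tier, reason = 3, "subclonal"
        rows.append(
            {
                "gene": ev["gene"],
                "cluster": ev["cluster"],
                "kind": ev.get("kind"),
                "variant_class": var_class,
                "truncal": ev["cluster"] == tree.root,
                "tier": tier,
                "max_ccf": float(max_ccf),
                "drugs": ";".join(drug_list),
                "reason": reason,
            }
        )
    report = pd.DataFrame(rows)
    return report.sort_values(
        ["tier", "max_ccf", "gene"],
        ascending=[True, False, True],
        na_position="last",
    ).reset_index(drop=True)


@dataclass
class CnaBurdenResult:
    """Per-sample CNA burden and a rank test between two groups."""

    burden: pd.Series  # sample -> fraction of genome at non-baseline CN
    pvalue: float | None
    groups: dict[str, str]


def cna_burden_compare(
    segments: pd.DataFrame,
    ploidy: dict[str, float],
    groups: dict[str, str],
) -> CnaBurdenResult:
    """Compare copy-number burden between two sample groups.

    ``segments`` is long-format (sample, chrom, start, end, total_cn;
    1-based inclusive). Burden per sample = fraction of the autosomal
    length covered by segments whose total copy number differs from
    the sample's rounded ploidy. Groups with at least 3 samples each
    are compared by a two-sided Mann-Whitney U test; otherwise the
    test is skipped with a warning.
    """
    required = {"sample", "chrom", "start", "end", "total_cn"}
    if missing := required - set(segments.columns):
        raise DataError(f"segment table lacks columns {sorted(missing)}")
    seg = segments.copy()
    if (seg["end"] < seg["start"]).any() or (seg[["start", "end"]] <= 0).any().any():
        raise DataError("segment coordinates must be 1-based with end >= start")
    autosomal = ~seg["chrom"].astype(str).str.replace("chr", "", regex=False).isin(["X", "Y"])
    seg = seg[autosomal]
    seg["length"] = seg["end"] - seg["start"] + 1

    burden = {}
    for sample, sub in seg.groupby("sample"):
        baseline = round(float(ploidy[sample]))
        altered = sub.loc[sub["total_cn"] != baseline, "length"].sum()
        burden[sample] = float(altered / sub["length"].sum())
    burden_series = pd.Series(burden, name="cna_burden").sort_index()

    labels = sorted(set(groups.values()))
    values = {
        lab: [burden_series[s] for s in burden_series.index if groups.get(s) == lab]
        for lab in labels
    }
    if len(labels) == 2 and all(len(v) >= 3 for v in values.values()):
        pvalue = float(
            stats.mannwhitneyu(values[labels[0]], values[labels[1]], alternative="two-sided").pvalue
        )
    else:
        logger.warning("a group has fewer than 3 samples; rank test skipped")
        pvalue = None
    return CnaBurdenResult(burden=burden_series, pvalue=pvalue, groups=dict(groups))
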