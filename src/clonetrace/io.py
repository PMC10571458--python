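"""Readers, writers and pipeline orchestration.

Formats follow the field's conventions: multi-sample VCF 4.x with
per-sample allelic depths (``AD``) for SNVs, tab-separated tables with
header rows for copy-number segments (1-based inclusive coordinates),
purity/ploidy, SV breakpoints (BEDPE-like) and sample anatomy, Newick
for cladogram export, JSON for trees/reports, YAML for configuration.
Readers validate coordinate conventions loudly: 0 or negative
positions and ``end < start`` segments are errors, never silently
fixed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .chronology import ClockModel, td_onset_age, td_sbs1_regression, time_clusters
from .clustering import (
    cluster_mutations,
    count_sbs1,
    flag_artifact_clusters,
)
from .drivers import druggability_report, index_lesion_coverage, map_drivers
from .errors import ConfigurationError, DataError
from .observations import MutationTable
from .phylogeny import (
    assign_event_to_cluster,
    build_tree,
    classify_tandem_duplications,
    drop_low_ccf_clusters,
    merge_close_clusters,
)
from .signatures import artifact_like_spectrum
from .spatial import classify_metastatic, trace_report
from .synthetic import SyntheticDataset
from .trees import CloneTree

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_purity",
    "read_cn_segments",
    "read_sv_table",
    "read_anatomy",
    "build_mutation_table",
    "write_synthetic_bundle",
    "tree_to_newick",
    "PipelineConfig",
    "run_pipeline",
    "case_report",
]

_CONTIGS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, keep_filtered: bool = False):
    """Read a multi-sample VCF into variant records and depth matrices.

    Returns ``(variants, alt, depth, samples)``. Multiallelic records
    are split into one observation per ALT; records with a non-PASS
    filter are excluded unless ``keep_filtered``. Each sample must
    carry an ``AD`` (allelic depth) FORMAT field; a missing field is an
    error naming the sample.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    rows, alt_rows, depth_rows = [], [], []
    for rec in vcf:
        if not keep_filtered and rec.filter.keys() not in ([], ["PASS"]):
            continue
        if rec.pos < 1:
            raise DataError(f"VCF position {rec.pos} violates 1-based convention")
        alts = rec.alts or ()
        for ai, alt_allele in enumerate(alts):
            alt_counts, depths = [], []
            for s in samples:
                fmt = rec.samples[s]
                if "AD" not in fmt or fmt["AD"] is None or fmt["AD"][0] is None:
                    raise DataError(f"sample {s!r} lacks the AD field at {rec.chrom}:{rec.pos}")
                ad = fmt["AD"]
                alt_counts.append(int(ad[ai + 1]))
                depths.append(int(sum(a for a in ad if a is not None)))
            def _info(key):
                try:  # undeclared INFO keys raise instead of defaulting
                    return rec.info.get(key, None)
                except (KeyError, ValueError):
                    return None

            mult = _info("MULT")
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": int(rec.pos),
                    "ref": rec.ref,
                    "alt": alt_allele,
                    "context": _info("TNC"),
                    "cluster": _info("CLUSTER"),
                    "multiplicity": int(mult) if mult is not None else None,
                }
            )
            alt_rows.append(alt_counts)
            depth_rows.append(depths)
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "context", "cluster", "multiplicity"]
    )
    return (
        variants,
        np.array(alt_rows, dtype=int).reshape(len(variants), len(samples)),
        np.array(depth_rows, dtype=int).reshape(len(variants), len(samples)),
        samples,
    )


def write_vcf(table: MutationTable, path) -> None:
    """Write a :class:`MutationTable` as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    for contig in _CONTIGS:
        header.contigs.add(contig, length=260_000_000)
    header.add_meta(
        "INFO", items=[("ID", "TNC"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Trinucleotide context of the reference base")]
    )
    header.add_meta(
        "INFO", items=[("ID", "CLUSTER"), ("Number", "1"), ("Type", "String"),
                       ("Description", "Evolutionary cluster assignment")]
    )
    header.add_meta(
        "INFO", items=[("ID", "MULT"), ("Number", "1"), ("Type", "Integer"),
                       ("Description", "Mutation copy number (multiplicity)")]
    )
    header.add_meta(
        "FORMAT", items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
                         ("Description", "Allelic depths (ref, alt)")]
    )
    header.add_meta(
        "FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                         ("Description", "Total read depth")]
    )
    for s in table.samples:
        header.add_sample(s)
    order = np.lexsort((table.variants["pos"], table.variants["chrom"]))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in order:
            row = table.variants.iloc[i]
            rec = out.new_record(
                contig=row["chrom"],
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(row["ref"], row["alt"]),
            )
            if row.get("context") is not None:
                rec.info["TNC"] = str(row["context"])
            if row.get("cluster") is not None:
                rec.info["CLUSTER"] = str(row["cluster"])
            rec.info["MULT"] = int(table.multiplicity[i].max())
            for j, s in enumerate(table.samples):
                ref_depth = int(table.depth[i, j] - table.alt[i, j])
                rec.samples[s]["AD"] = (ref_depth, int(table.alt[i, j]))
                rec.samples[s]["DP"] = int(table.depth[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# TSV readers
# ---------------------------------------------------------------------------

def read_purity(path) -> pd.DataFrame:
    """Purity/ploidy table: sample, purity, ploidy."""
    frame = pd.read_csv(path, sep="\t")
    if missing := {"sample", "purity"} - set(frame.columns):
        raise DataError(f"purity table lacks columns {sorted(missing)}")
    bad = frame[(frame["purity"] <= 0) | (frame["purity"] > 1)]
    if len(bad):
        raise DataError(f"purity outside (0, 1] for samples {bad['sample'].tolist()}")
    return frame


def read_cn_segments(path) -> pd.DataFrame:
    """Copy-number segments: sample, chrom, start, end, major_cn, minor_cn.

    Coordinates are 1-based inclusive; ``end < start`` or
    non-positive positions are rejected.
    """
    frame = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end", "major_cn", "minor_cn"}
    if missing := required - set(frame.columns):
        raise DataError(f"copy-number table lacks columns {sorted(missing)}")
    if (frame["start"] < 1).any() or (frame["end"] < frame["start"]).any():
        raise DataError("copy-number segments violate 1-based inclusive coordinates")
    frame["total_cn"] = frame["major_cn"] + frame["minor_cn"]
    return frame


def read_sv_table(path) -> pd.DataFrame:
    """BEDPE-like SV table: chrom1, pos1, chrom2, pos2, svtype [, ccf_*]."""
    frame = pd.read_csv(path, sep="\t")
    required = {"chrom1", "pos1", "chrom2", "pos2", "svtype"}
    if missing := required - set(frame.columns):
        raise DataError(f"SV table lacks columns {sorted(missing)}")
    if (frame[["pos1", "pos2"]] < 1).any().any():
        raise DataError("SV breakpoints violate 1-based coordinates")
    return frame


def read_anatomy(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if missing := {"sample", "site_class", "laterality"} - set(frame.columns):
        raise DataError(f"anatomy table lacks columns {sorted(missing)}")
    return frame


def build_mutation_table(vcf_path, purity_path, cn_path=None) -> MutationTable:
    """Assemble a :class:`MutationTable` from VCF + purity + CN inputs."""
    variants, alt, depth, samples = read_vcf(vcf_path)
    purity_frame = read_purity(purity_path).set_index("sample")
    missing = [s for s in samples if s not in purity_frame.index]
    if missing:
        raise DataError(f"samples without purity values: {missing}")
    purity = {s: float(purity_frame.loc[s, "purity"]) for s in samples}

    n, m = alt.shape
    tumor_cn = np.full((n, m), 2, dtype=int)
    if cn_path is not None:
        segments = read_cn_segments(cn_path)
        for j, s in enumerate(samples):
            sub = segments[segments["sample"] == s]
            for chrom, chrom_seg in sub.groupby("chrom"):
                sel = variants["chrom"] == chrom
                if not sel.any():
                    continue
                starts = chrom_seg["start"].to_numpy()
                order = np.argsort(starts)
                starts = starts[order]
                ends = chrom_seg["end"].to_numpy()[order]
                totals = chrom_seg["total_cn"].to_numpy()[order]
                pos = variants.loc[sel, "pos"].to_numpy()
                idx = np.searchsorted(starts, pos, side="right") - 1
                ok = (idx >= 0) & (pos <= ends[np.clip(idx, 0, len(ends) - 1)])
                values = np.where(ok, totals[np.clip(idx, 0, len(totals) - 1)], 2)
                tumor_cn[sel.to_numpy(), j] = values

    if variants["multiplicity"].notna().all():
        multiplicity = np.repeat(
            variants["multiplicity"].to_numpy(dtype=int)[:, None], m, axis=1
        )
    else:
        # pool samples per variant: multiplicity is a property of the
        # mutated locus, and per-sample rounding is far too noisy
        pur = np.array([purity[s] for s in samples])[None, :]
        conv = pur / (pur * tumor_cn + (1 - pur) * 2)  # VAF per mutated copy
        pooled = alt.sum(axis=1) / np.maximum((depth * conv).sum(axis=1), 1e-9)
        mult = np.clip(np.round(pooled), 1, np.maximum(tumor_cn.max(axis=1), 1))
        multiplicity = np.repeat(mult.astype(int)[:, None], m, axis=1)
    return MutationTable(
        variants=variants.drop(columns=["multiplicity"]),
        alt=alt,
        depth=depth,
        tumor_cn=tumor_cn,
        multiplicity=multiplicity,
        samples=samples,
        purity=purity,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_synthetic_bundle(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write a simulated dataset in the formats the pipeline reads.

    Emits VCF, purity TSV, copy-number TSV, anatomy TSV, ground-truth
    JSON and the config as YAML; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = dataset.mutations
    paths = {k: str(outdir / v) for k, v in {
        "vcf": "somatic.vcf",
        "purity": "purity.tsv",
        "cn": "copy_number.tsv",
        "anatomy": "anatomy.tsv",
        "truth": "ground_truth.json",
        "config": "config.yaml",
    }.items()}
    write_vcf(table, paths["vcf"])
    pd.DataFrame(
        {
            "sample": table.samples,
            "purity": [table.purity[s] for s in table.samples],
            "ploidy": [2.0] * len(table.samples),
        }
    ).to_csv(paths["purity"], sep="\t", index=False)
    seg_rows = []
    for j, s in enumerate(table.samples):
        for i in range(len(table)):
            seg_rows.append(
                {
                    "sample": s,
                    "chrom": table.variants.at[i, "chrom"],
                    "start": int(table.variants.at[i, "pos"]),
                    "end": int(table.variants.at[i, "pos"]),
                    "major_cn": int(table.tumor_cn[i, j]) - 1,
                    "minor_cn": 1,
                }
            )
    pd.DataFrame(seg_rows).to_csv(paths["cn"], sep="\t", index=False)
    dataset.truth.anatomy.to_csv(paths["anatomy"], sep="\t", index=False)
    truth = dataset.truth
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "tree": truth.tree.to_dict(),
                "emergence_age": truth.emergence_age,
                "anchor_leaf": truth.anchor_leaf,
                "anchor_total": truth.anchor_total,
                "td_onset_age": truth.td_onset_age,
                "purity": truth.purity,
                "artifact_clusters": truth.artifact_clusters,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    cfg = asdict(dataset.config)
    cfg["metastatic_clusters"] = (
        sorted(cfg["metastatic_clusters"]) if cfg["metastatic_clusters"] else None
    )
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


def tree_to_newick(tree: CloneTree, path=None) -> str:
    """Cladogram as Newick, branch lengths = branch SNV counts."""
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    nodes = {}
    for cid in tree.preorder():
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(cid)
        node.edge.length = tree.clones[cid].n_snv
        nodes[cid] = node
        parent = tree.clones[cid].parent
        if parent is None:
            dtree.seed_node.add_child(node)
        else:
            nodes[parent].add_child(node)
    newick = dtree.as_string(schema="newick", suppress_rooting=True).strip()
    if path is not None:
        Path(path).write_text(newick + "\n", encoding="utf-8")
    return newick


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All inputs, thresholds and clock parameters of one run."""

    vcf: str
    purity_tsv: str
    anatomy_tsv: str
    age_rp: float
    outdir: str
    cn_tsv: str | None = None
    sv_tsv: str | None = None
    driver_events_tsv: str | None = None
    driver_catalog_tsv: str | None = None
    drug_gene_tsv: str | None = None
    index_samples: list[str] = field(default_factory=list)
    seed: int = 0
    presence_threshold: float = 0.01
    tolerance: float = 0.1
    merge_distance: float = 0.2
    td_max_span: float = 5e6
    low_ccf_median: float = 0.5
    accel_factor: float = 5.0
    window_years: float = 15.0
    n_draws: int = 10_000
    max_clusters: int = 8

    def validate(self) -> None:
        if not 0 <= self.presence_threshold <= 0.5:
            raise ConfigurationError("presence_threshold must lie in [0, 0.5]")
        if not 0 < self.tolerance <= 0.5:
            raise ConfigurationError("tolerance must lie in (0, 0.5]")
        if self.td_max_span <= 0:
            raise ConfigurationError("td_max_span must be positive")
        if not 0 <= self.low_ccf_median <= 1:
            raise ConfigurationError("low_ccf_median must lie in [0, 1]")
        if self.accel_factor < 1:
            raise ConfigurationError("accel_factor >= 1 violated")
        if not 0 < self.window_years < self.age_rp:
            raise ConfigurationError("window_years must lie in (0, age_rp)")
        if self.n_draws < 1:
            raise ConfigurationError("n_draws >= 1 violated")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute cluster -> tree -> events -> time -> trace -> drivers.

    Every stage's outputs are written under ``config.outdir``; a
    manifest JSON records the package version, seed, thresholds and
    per-stage status. A stage failure aborts the run with the stage
    name and cause, retaining the outputs of earlier stages.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "presence_threshold": config.presence_threshold,
            "tolerance": config.tolerance,
            "merge_distance": config.merge_distance,
            "td_max_span": config.td_max_span,
            "low_ccf_median": config.low_ccf_median,
            "accel_factor": config.accel_factor,
            "window_years": config.window_years,
            "n_draws": config.n_draws,
        },
        "stages": [],
    }
    report: dict = {}

    def _finish_stage(name: str, outputs: list[str]) -> None:
        manifest["stages"].append({"name": name, "status": "completed", "outputs": outputs})
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    def _fail(name: str, exc: Exception) -> None:
        manifest["stages"].append({"name": name, "status": "failed", "error": str(exc)})
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise DataError(f"pipeline stage {name!r} failed: {exc}") from exc

    # stage 1: cluster
    try:
        table = build_mutation_table(config.vcf, config.purity_tsv, config.cn_tsv)
        anatomy = read_anatomy(config.anatomy_tsv)
        solution = cluster_mutations(table, max_clusters=config.max_clusters, seed=config.seed)
        if table.variants["context"].notna().all():
            solution = flag_artifact_clusters(solution, table, [artifact_like_spectrum()])
        clusters = solution.to_frame()
        sbs1, td = [], []
        for label in clusters["cluster"]:
            members = table.variants[solution.assignments == label]
            sbs1.append(count_sbs1(members) if members["context"].notna().all() else 0)
            td.append(0)
        clusters["n_sbs1"] = sbs1
        clusters["n_td"] = td
        # EM components split by noise alone are statistically
        # indistinguishable; fold them back together before phylogeny
        real = clusters[~clusters["artifact"]].drop(columns=["artifact"])
        merged = merge_close_clusters(
            real, ccf_distance=config.merge_distance, max_discordant_samples=0
        )
        merged["artifact"] = False
        artifacts = clusters[clusters["artifact"]]
        clusters = pd.concat([merged, artifacts], ignore_index=True)
        clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        report["clusters"] = clusters
        _finish_stage("cluster", ["clusters.tsv"])
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail("cluster", exc)

    # stage 2: tree
    try:
        retained = clusters[~clusters["artifact"]].reset_index(drop=True)
        tree = build_tree(retained, tolerance=config.tolerance)
        tree.to_json(outdir / "tree.json")
        tree_to_newick(tree, outdir / "tree.nwk")
        report["tree"] = tree
        _finish_stage("tree", ["tree.json", "tree.nwk"])
    except Exception as exc:  # noqa: BLE001
        _fail("tree", exc)

    # stage 3: assign events (tandem duplications from the SV table)
    try:
        assignments = []
        if config.sv_tsv:
            svs = read_sv_table(config.sv_tsv)
            tds = classify_tandem_duplications(svs, max_span=config.td_max_span)
            ccf_cols = [c for c in tds.columns if c.startswith("ccf_")]
            for _, row in tds.iterrows():
                ev_ccf = {c[4:]: row[c] for c in ccf_cols}
                cluster, distance = assign_event_to_cluster(ev_ccf, tree)
                assignments.append(
                    {
                        "chrom1": row["chrom1"],
                        "pos1": row["pos1"],
                        "chrom2": row["chrom2"],
                        "pos2": row["pos2"],
                        "svtype": row["svtype"],
                        "cluster": cluster,
                        "distance": distance,
                    }
                )
                if cluster is not None:
                    tree.clones[cluster].n_td += 1
        events_frame = pd.DataFrame(
            assignments,
            columns=["chrom1", "pos1", "chrom2", "pos2", "svtype", "cluster", "distance"],
        )
        events_frame.to_csv(outdir / "event_assignments.tsv", sep="\t", index=False)
        report["events"] = events_frame
        _finish_stage("events", ["event_assignments.tsv"])
    except Exception as exc:  # noqa: BLE001
        _fail("events", exc)

    # stage 4: time
    try:
        clock = ClockModel(
            age_rp=config.age_rp,
            accel_factor=config.accel_factor,
            window_years=config.window_years,
            n_draws=config.n_draws,
            seed=config.seed,
            presence_threshold=config.presence_threshold,
        )
        timing = time_clusters(tree, clock)
        timing.table.to_csv(outdir / "timing.tsv", sep="\t", index=False)
        timeline = {
            "age_rp": config.age_rp,
            "anchor": timing.anchor,
            "anchor_total_sbs1": timing.anchor_total,
            "accepted_draws": timing.n_accepted,
            "clusters": timing.table.to_dict(orient="records"),
        }
        scope, dropped = drop_low_ccf_clusters(
            report["clusters"][~report["clusters"]["artifact"]], config.low_ccf_median
        )
        timeline["td_scope_dropped"] = dropped
        if (sum(tree.clones[c].n_td for c in tree.clones) > 0
                and len(scope) >= 3):
            in_scope = [c for c in scope["cluster"] if c in tree.clones]
            x = [tree.cumulative(c, "n_sbs1") for c in in_scope]
            y = [tree.cumulative(c, "n_td") for c in in_scope]
            fit = td_sbs1_regression(x, y)
            timeline["td_regression"] = asdict(fit)
            if fit.slope > 0 and tree.clones[tree.root].n_sbs1 > 0:
                onset = td_onset_age(tree, timing, fit.slope, clock)
                timeline["td_onset"] = asdict(onset)
        with open(outdir / "timeline.json", "w", encoding="utf-8") as fh:
            json.dump(timeline, fh, indent=1, sort_keys=True)
        report["timing"] = timing
        _finish_stage("time", ["timing.tsv", "timeline.json"])
    except Exception as exc:  # noqa: BLE001
        _fail("time", exc)

    # stage 5: trace
    try:
        trace = trace_report(tree, anatomy, config.presence_threshold)
        trace.to_json(outdir / "trace.json")
        trace.routes.to_csv(outdir / "routes.tsv", sep="\t", index=False)
        report["trace"] = trace
        _finish_stage("trace", ["trace.json", "routes.tsv"])
    except Exception as exc:  # noqa: BLE001
        _fail("trace", exc)

    # stage 6: drivers
    try:
        driver_out: dict = {"n_events": 0}
        if config.driver_events_tsv and config.driver_catalog_tsv:
            events = pd.read_csv(config.driver_events_tsv, sep="\t")
            catalog = pd.read_csv(config.driver_catalog_tsv, sep="\t")
            if "cluster" not in events.columns:
                ccf_cols = [c for c in events.columns if c.startswith("ccf_")]
                events["cluster"] = [
                    assign_event_to_cluster({c[4:]: row[c] for c in ccf_cols}, tree)[0]
                    for _, row in events.iterrows()
                ]
            mapped = map_drivers(events, catalog, tree)
            mapped.to_csv(outdir / "drivers.tsv", sep="\t", index=False)
            driver_out["n_events"] = len(mapped)
            if config.index_samples:
                num, den, frac = index_lesion_coverage(
                    tree, mapped, config.index_samples, config.presence_threshold
                )
                driver_out["index_coverage"] = {
                    "numerator": num, "denominator": den, "fraction": frac,
                }
            if config.drug_gene_tsv:
                drug_table = pd.read_csv(config.drug_gene_tsv, sep="\t")
                capable = set(
                    classify_metastatic(tree, anatomy, config.presence_threshold)["cluster"]
                )
                prioritized = druggability_report(tree, mapped, drug_table, capable)
                prioritized.to_csv(outdir / "druggability.tsv", sep="\t", index=False)
        with open(outdir / "driver_summary.json", "w", encoding="utf-8") as fh:
            json.dump(driver_out, fh, indent=1, sort_keys=True)
        report["drivers"] = driver_out
        _finish_stage("drivers", ["driver_summary.json"])
    except Exception as exc:  # noqa: BLE001
        _fail("drivers", exc)

    report["manifest"] = manifest
    return report


def case_report(case, n_draws: int = 10_000, seed: int = 0) -> dict:
    """Full evolution-aware summary of a bundled case study.

    Combines anatomic tracing, index-lesion driver coverage,
    molecular-clock timing and (when the patient carries tandem
    duplications) TD-phenotype dating into one JSON-serialisable dict.
    """
    tree, anatomy = case.tree, case.anatomy
    trace = trace_report(tree, anatomy)
    num, den, frac = index_lesion_coverage(tree, case.driver_events, case.index_samples)
    clock = ClockModel(age_rp=case.age_rp, n_draws=n_draws, seed=seed)
    timing = time_clusters(tree, clock)
    capable = set(classify_metastatic(tree, anatomy)["cluster"])
    onco = case.driver_events[case.driver_events["putatively_oncogenic"]]
    branch_counts = {
        "truncal": int((onco["cluster"] == tree.root).sum()),
        "metastatic_capable": int(onco["cluster"].isin(capable).sum()),
        "other_subclonal": int(
            (~onco["cluster"].isin(capable | {tree.root})).sum()
        ),
    }
    out = {
        "patient": case.name,
        "age_rp": case.age_rp,
        "origin": trace.origin,
        "seeding_events": {
            "extraprostatic": trace.seeding_events_extraprostatic,
            "lymph_node_only": trace.seeding_events_lymph_node,
        },
        "index_coverage": {
            "index_samples": case.index_samples,
            "numerator": num,
            "denominator": den,
            "percent": round(100.0 * frac, 1),
        },
        "driver_branch_counts": branch_counts,
        "timing": timing.table.to_dict(orient="records"),
        "druggability": druggability_report(
            tree, case.driver_events, case.drug_table, capable
        ).to_dict(orient="records"),
    }
    total_td = sum(tree.clones[c].n_td for c in tree.clones)
    if total_td > 0:
        frame = pd.DataFrame(
            {
                "cluster": list(tree.clones),
                "n_mutations": [tree.clones[c].n_snv for c in tree.clones],
            }
            | {
                f"ccf_{s}": [tree.ccf(c, s) for c in tree.clones]
                for s in tree.samples
            }
        )
        scope, dropped = drop_low_ccf_clusters(frame)
        in_scope = scope["cluster"].tolist()
        fit = td_sbs1_regression(
            [tree.cumulative(c, "n_sbs1") for c in in_scope],
            [tree.cumulative(c, "n_td") for c in in_scope],
        )
        onset = td_onset_age(tree, timing, fit.slope, clock)
        out["td_phenotype"] = {
            "slope": fit.slope,
            "pvalue": fit.pvalue,
            "scope_dropped": dropped,
            "onset_age": onset.median_age,
            "onset_ci": [onset.ci_low, onset.ci_high],
            "fraction_truncal_before_onset": onset.fraction_truncal,
        }
    return out
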