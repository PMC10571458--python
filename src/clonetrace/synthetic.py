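"""Ground-truthed synthetic clonal-evolution datasets.

The generator emulates the statistical structure that the downstream
analysis assumes about a multisample tumor genome study:

* a rooted clone tree with a truncal (MRCA) cluster at CCF 1.0 in every
  tumor sample and subclone CCFs obeying the pigeonhole sum rule by
  construction (stick-breaking under each parent);
* clock-like CpG>TpG ("SBS1") mutations accumulating as a piecewise-
  constant Poisson process from birth (age 0), with a ``accel_factor``-
  fold rate increase after a change-point age;
* tandem duplications accruing in proportion to clock mutations
  (``td_per_sbs1`` expected TDs per SBS1 mutation) once an onset point
  is passed, mimicking a duplicator phenotype switching on mid-way
  through the truncal branch;
* anatomically lateralised samples, with metastatic samples containing
  only a restricted subset of lineages;
* binomial read-count noise around purity- and copy-number-scaled VAFs,
  with a small sequencing error floor so "absent" mutations are absent
  statistically rather than literally.

Every draw flows from a single :class:`numpy.random.Generator` seeded
from the config, so all outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .observations import MutationTable
from .signatures import CHANNELS_96
from .trees import Clone, CloneTree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_clone_tree",
    "simulate_sample_reads",
    "simulate_dataset",
    "inject_artifact_cluster",
]

_CLOCK_CHANNELS = [i for i, c in enumerate(CHANNELS_96) if c.endswith("[C>T]G")]
_NON_CLOCK_CHANNELS = [i for i in range(96) if i not in _CLOCK_CHANNELS]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated patient.

    Defaults describe a realistic high-risk prostate tumor study:
    a patient in his early sixties whose tumor accelerated its mutation
    rate fivefold in the last years before prostatectomy, sequenced at
    ~70x over a handful of anatomically annotated regions.
    """

    seed: int = 0
    n_samples: int = 6
    n_clusters: int = 6
    age_rp: float = 60.0  # age at prostatectomy (years)
    accel_age: float = 50.0  # true change-point age (years)
    accel_factor: float = 5.0
    base_rate: float = 4.0  # SBS1 mutations / year before the change point
    td_per_sbs1: float = 2.0
    td_onset_fraction: float = 0.75  # truncal SBS1 fraction preceding TD onset
    purity_range: tuple[float, float] = (0.5, 0.9)
    mean_depth: float = 70.0
    ccf_noise_sd: float = 0.02
    metastatic_clusters: frozenset[str] | None = None  # None -> auto (one root branch)
    laterality_map: dict[str, str] | None = None  # cluster -> {L,R,both}
    n_metastatic_samples: int | None = None  # None -> n_samples // 4
    snv_per_sbs1: float = 3.0  # non-clock SNVs per clock SNV on a branch
    seq_error: float = 1e-3
    presence_prob: float = 0.7  # chance a subclone persists into a sample

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigurationError("n_clusters >= 1 violated")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples >= 1 violated")
        if not self.accel_age < self.age_rp:
            raise ConfigurationError("accel_age < age_rp violated")
        if self.accel_factor < 1:
            raise ConfigurationError("accel_factor >= 1 violated")
        if not 0 <= self.td_onset_fraction <= 1:
            raise ConfigurationError("td_onset_fraction in [0, 1] violated")
        lo, hi = self.purity_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("purity_range must be an interval within [0, 1]")
        if self.base_rate <= 0:
            raise ConfigurationError("base_rate must be positive")
        if self.ccf_noise_sd < 0:
            raise ConfigurationError("ccf_noise_sd must be non-negative")
        if self.laterality_map is not None:
            bad = {v for v in self.laterality_map.values()} - {"L", "R", "both"}
            if bad:
                raise ConfigurationError(f"laterality_map values must be L/R/both, got {bad}")


@dataclass
class GroundTruth:
    """Truth channel for recovery tests.

    ``tree`` repeats the simulated topology with true CCFs and true
    branch counts; ``emergence_age`` dates each cluster at the end of
    its branch (all branch mutations accrued).
    """

    tree: CloneTree
    emergence_age: dict[str, float]
    anchor_leaf: str
    anchor_total: int
    td_onset_age: float | None
    anatomy: pd.DataFrame  # sample, site_class, laterality, region
    purity: dict[str, float]
    artifact_clusters: list[str] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    """Simulated reads plus the truth that generated them."""

    mutations: MutationTable
    tree: CloneTree
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# clock helpers
# ---------------------------------------------------------------------------

def _expected_sbs1(a0: float, a1: float, cfg: SimulationConfig) -> float:
    """Integral of the piecewise-constant clock rate over [a0, a1]."""
    ta, k, r = cfg.accel_age, cfg.accel_factor, cfg.base_rate
    before = max(0.0, min(a1, ta) - min(a0, ta))
    after = max(0.0, max(a1, ta) - max(a0, ta))
    return r * before + k * r * after


def _age_at_fraction(frac: float, a1: float, cfg: SimulationConfig) -> float:
    """Age by which ``frac`` of the expected [0, a1] clock mass accrued."""
    target = frac * _expected_sbs1(0.0, a1, cfg)
    ta, k, r = cfg.accel_age, cfg.accel_factor, cfg.base_rate
    if target <= r * min(a1, ta):
        return target / r
    return ta + (target - r * ta) / (k * r)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_clone_tree(config: SimulationConfig) -> tuple[CloneTree, GroundTruth]:
    """Draw a ground-truthed clone tree under the piecewise clock.

    Topology is sampled by sequential uniform parent attachment;
    emergence ages strictly increase from root to leaves, with the
    deepest leaf anchored to ``age_rp``; branch SBS1 counts are Poisson
    with the piecewise-constant clock intensity, tandem duplications
    switch on after ``td_onset_fraction`` of the truncal clock mass.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    ids = ["T"] + [f"S{i}" for i in range(1, config.n_clusters)]
    parent: dict[str, str | None] = {"T": None}
    for i, cid in enumerate(ids[1:], start=1):
        parent[cid] = ids[int(rng.integers(0, i))]
    children: dict[str, list[str]] = {cid: [] for cid in ids}
    for cid, p in parent.items():
        if p is not None:
            children[p].append(cid)

    # emergence ages: strictly increasing root -> leaf, deepest leaf at T
    depth = {"T": 0}
    for cid in ids[1:]:
        depth[cid] = depth[parent[cid]] + 1
    anchor_leaf = max((cid for cid in ids if not children[cid]), key=lambda c: (depth[c], c))
    age: dict[str, float] = {}
    if config.n_clusters == 1:
        age["T"] = 0.0
    else:
        # the MRCA completes (first clonal expansion) after the rate
        # acceleration sets in: subclonal expansions are a phenomenon of
        # the accelerated era, so every subclonal branch lies beyond the
        # change point
        span = config.age_rp - config.accel_age
        age["T"] = config.accel_age + span * rng.uniform(0.25, 0.55)
        for cid in ids[1:]:  # ids are in attachment order, parents precede children
            a_par = age[parent[cid]]
            age[cid] = a_par + (config.age_rp - a_par) * rng.uniform(0.35, 0.75)
        # the deepest leaf anchors the path to the age at sampling
        age[anchor_leaf] = config.age_rp

    # branch mutation counts under the piecewise clock
    n_sbs1: dict[str, int] = {}
    n_snv: dict[str, int] = {}
    n_td: dict[str, int] = {}
    td_onset = (
        _age_at_fraction(config.td_onset_fraction, age["T"], config)
        if config.n_clusters > 1
        else _age_at_fraction(config.td_onset_fraction, config.age_rp, config)
    )
    for cid in ids:
        a0 = 0.0 if parent[cid] is None else age[parent[cid]]
        a1 = age[cid] if config.n_clusters > 1 else config.age_rp
        lam = _expected_sbs1(a0, a1, config)
        n_sbs1[cid] = int(rng.poisson(lam))
        n_snv[cid] = n_sbs1[cid] + int(rng.poisson(config.snv_per_sbs1 * lam))
        lam_td_window = _expected_sbs1(max(a0, td_onset), max(a1, td_onset), config)
        frac_after = lam_td_window / lam if lam > 0 else 0.0
        n_td[cid] = int(rng.poisson(config.td_per_sbs1 * n_sbs1[cid] * frac_after))

    anatomy = _draw_anatomy(config)
    met_samples = list(anatomy.loc[anatomy.site_class != "prostate", "sample"])
    met_set = _resolve_metastatic_set(config, ids, parent, children, met_samples)
    presence = _draw_presence(config, rng, ids, parent, children, anatomy, met_set)
    ccf = _stick_break_ccfs(rng, ids, children, anatomy["sample"].tolist(), presence)

    clones = [
        Clone(
            id=cid,
            parent=parent[cid],
            ccf={s: ccf[(cid, s)] for s in anatomy["sample"] if (cid, s) in ccf},
            n_snv=n_snv[cid],
            n_sbs1=n_sbs1[cid],
            n_td=n_td[cid],
        )
        for cid in ids
    ]
    tree = CloneTree(clones, samples=anatomy["sample"].tolist())

    anchor_total = max(tree.cumulative(leaf, "n_sbs1") for leaf in tree.leaves())
    purity = {
        s: float(rng.uniform(*config.purity_range)) for s in anatomy["sample"]
    }
    truth = GroundTruth(
        tree=tree,
        emergence_age=dict(age),
        anchor_leaf=anchor_leaf,
        anchor_total=anchor_total,
        td_onset_age=td_onset,
        anatomy=anatomy,
        purity=purity,
    )
    return tree, truth


def _draw_anatomy(config: SimulationConfig) -> pd.DataFrame:
    n_met = config.n_metastatic_samples
    if n_met is None:
        n_met = config.n_samples // 4
    if n_met >= config.n_samples:
        raise ConfigurationError("need at least one primary (prostate) sample")
    rows = []
    n_primary = config.n_samples - n_met
    for i in range(n_primary):
        side = "L" if i % 2 == 0 else "R"
        rows.append((f"P{i + 1}", "prostate", side, f"{side.lower()}-region-{i + 1}"))
    for j in range(n_met):
        side = "L" if j % 2 == 0 else "R"
        rows.append((f"M{j + 1}", "lymph_node", side, f"{side.lower()}-pelvic-ln-{j + 1}"))
    return pd.DataFrame(rows, columns=["sample", "site_class", "laterality", "region"])


def _resolve_metastatic_set(
    config: SimulationConfig,
    ids: list[str],
    parent: dict[str, str | None],
    children: dict[str, list[str]],
    met_samples: list[str],
) -> frozenset[str]:
    def closure(seed_ids) -> frozenset[str]:
        out = set()
        stack = list(seed_ids)
        while stack:
            cid = stack.pop()
            if cid not in out:
                out.add(cid)
                stack.extend(children[cid])
        return frozenset(out)

    if config.metastatic_clusters is not None:
        met = frozenset(config.metastatic_clusters)
        unknown = met - set(ids)
        if unknown:
            raise ConfigurationError(f"metastatic_clusters not in tree: {sorted(unknown)}")
        if met != closure(met):
            raise ConfigurationError(
                "metastatic_clusters must be closed under descent: missing "
                f"{sorted(closure(met) - met)}"
            )
        return met
    if not met_samples:
        return frozenset()
    # auto: the lexically first branch off the root, with all its descendants
    root_kids = children["T"]
    return closure([root_kids[0]]) if root_kids else frozenset()


def _draw_presence(
    config: SimulationConfig,
    rng: np.random.Generator,
    ids: list[str],
    parent: dict[str, str | None],
    children: dict[str, list[str]],
    anatomy: pd.DataFrame,
    met_set: frozenset[str],
) -> dict[tuple[str, str], bool]:
    lat = config.laterality_map or {}
    met_and_ancestors = set(met_set)
    for cid in met_set:
        p = parent[cid]
        while p is not None:
            met_and_ancestors.add(p)
            p = parent[p]

    presence: dict[tuple[str, str], bool] = {}
    for _, row in anatomy.iterrows():
        s, is_met, side = row["sample"], row.site_class != "prostate", row.laterality
        for cid in ids:  # attachment order: parents precede children
            if cid == "T":
                presence[(cid, s)] = True
                continue
            ok = presence[(parent[cid], s)]
            allowed = lat.get(cid, "both")
            if allowed != "both" and allowed != side:
                ok = False
            if is_met and cid not in met_and_ancestors:
                ok = False
            p_keep = 0.9 if is_met else config.presence_prob
            presence[(cid, s)] = bool(ok and rng.uniform() < p_keep)
    # every cluster must be observable somewhere; force into one legal sample
    for cid in ids[1:]:
        if any(presence[(cid, s)] for s in anatomy["sample"]):
            continue
        allowed = lat.get(cid, "both")
        legal = anatomy[
            (anatomy.site_class == "prostate")
            & ((anatomy.laterality == allowed) if allowed != "both" else True)
        ]["sample"].tolist()
        if not legal:
            raise ConfigurationError(
                f"cluster {cid} has no sample compatible with laterality {allowed!r}"
            )
        target = legal[int(rng.integers(0, len(legal)))]
        for node in _root_path(cid, parent):
            lat_node = lat.get(node, "both")
            if lat_node not in ("both", anatomy.set_index("sample").loc[target, "laterality"]):
                raise ConfigurationError(
                    f"laterality_map makes cluster {cid} unplaceable (ancestor {node})"
                )
            presence[(node, target)] = True
    return presence


def _root_path(cid: str, parent: dict[str, str | None]) -> list[str]:
    path = [cid]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])  # type: ignore[arg-type]
    return path


def _stick_break_ccfs(
    rng: np.random.Generator,
    ids: list[str],
    children: dict[str, list[str]],
    samples: list[str],
    presence: dict[tuple[str, str], bool],
) -> dict[tuple[str, str], float]:
    """Exact sum-rule CCFs: children split a stick under their parent."""
    ccf: dict[tuple[str, str], float] = {}
    for s in samples:
        ccf[("T", s)] = 1.0
        stack = ["T"]
        while stack:
            cid = stack.pop()
            kids = [k for k in children[cid] if presence[(k, s)]]
            if not kids:
                continue
            w_parent = rng.uniform(0.1, 1.0)
            w_kids = rng.uniform(0.2, 1.0, size=len(kids))
            total = w_parent + w_kids.sum()
            for k, w in zip(kids, w_kids):
                ccf[(k, s)] = ccf[(cid, s)] * w / total
            stack.extend(kids)
    return ccf


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _channel_to_mutation(channel: str) -> tuple[str, str, str]:
    """Channel label -> (ref, alt, trinucleotide context)."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, five + ref + three


def simulate_sample_reads(
    tree: CloneTree,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Draw per-mutation, per-sample read counts for a simulated tree.

    Each branch contributes its SBS1 mutations (CpG>TpG contexts) and
    non-clock SNVs (contexts drawn uniformly from the remaining
    channels). The alt count of mutation i in sample s is binomial
    around the purity- and copy-number-scaled VAF of the mutation's
    cluster CCF (jittered by ``ccf_noise_sd``), with a sequencing-error
    floor of ``seq_error``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    samples = tree.samples
    purity = truth.purity

    rows = []
    for cid in tree.preorder():
        clone = tree.clones[cid]
        for j in range(clone.n_snv):
            if j < clone.n_sbs1:
                five = "ACGT"[int(rng.integers(0, 4))]
                ref, alt_base, context = "C", "T", five + "CG"
            else:
                channel = CHANNELS_96[_NON_CLOCK_CHANNELS[int(rng.integers(0, 92))]]
                ref, alt_base, context = _channel_to_mutation(channel)
            rows.append(
                (
                    f"chr{int(rng.integers(1, 23))}",
                    int(rng.integers(1_000_000, 100_000_000)),
                    ref,
                    alt_base,
                    context,
                    cid,
                )
            )
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "context", "cluster"])
    variants = variants.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    n = len(variants)
    m = len(samples)

    # clonal copy-number context: mostly diploid, a minority of gained loci
    cn_gain = rng.uniform(size=n) < 0.1
    tumor_cn = np.where(cn_gain, 3, 2)[:, None].repeat(m, axis=1)
    multiplicity = np.ones((n, m), dtype=int)

    cluster_ccf = np.zeros((n, m))
    for si, s in enumerate(samples):
        col = np.array([tree.ccf(c, s) for c in variants["cluster"]])
        cluster_ccf[:, si] = col
    if config.ccf_noise_sd > 0:
        noise = rng.normal(0.0, config.ccf_noise_sd, size=(n, m))
        noisy = np.clip(cluster_ccf + noise, 0.0, 1.0)
        # keep truly absent mutations absent: noise only where the clone exists
        cluster_ccf = np.where(cluster_ccf > 0, noisy, 0.0)

    pur = np.array([purity[s] for s in samples])[None, :]
    vaf = pur * cluster_ccf * multiplicity / (pur * tumor_cn + (1 - pur) * 2)
    p_eff = vaf + (1 - vaf) * config.seq_error
    depth = rng.poisson(config.mean_depth, size=(n, m))
    alt = rng.binomial(depth, np.clip(p_eff, 0.0, 1.0))

    table = MutationTable(
        variants=variants,
        alt=alt.astype(int),
        depth=depth.astype(int),
        tumor_cn=tumor_cn.astype(int),
        multiplicity=multiplicity,
        samples=list(samples),
        purity=dict(purity),
    )
    return SyntheticDataset(mutations=table, tree=tree, truth=truth, config=config)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Convenience wrapper: tree + reads in one call."""
    tree, truth = simulate_clone_tree(config)
    return simulate_sample_reads(tree, truth, config)


def inject_artifact_cluster(
    dataset: SyntheticDataset,
    spectrum: np.ndarray,
    ccf_range: tuple[float, float] = (0.02, 0.17),
    n_mutations: int = 100,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Add an artifact mutation set present at low CCF in every sample.

    Per-sample CCFs are drawn independently from ``ccf_range`` (the
    low-and-inconsistent pattern of a sequencing artifact, incompatible
    with any single clone), trinucleotide contexts from ``spectrum``.
    ``n_mutations == 0`` returns the dataset unchanged.
    """
    lo, hi = ccf_range
    if not (0 < lo <= hi <= 0.2):
        raise ConfigurationError("artifact ccf_range must lie within (0, 0.2]")
    if n_mutations == 0:
        return dataset
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([dataset.config.seed, 2]))
    spectrum = np.asarray(spectrum, dtype=float)
    spectrum = spectrum / spectrum.sum()
    cfg = dataset.config
    samples = dataset.mutations.samples
    m = len(samples)

    channels = rng.choice(96, size=n_mutations, p=spectrum)
    rows = []
    for ch in channels:
        ref, alt_base, context = _channel_to_mutation(CHANNELS_96[int(ch)])
        rows.append(
            (
                f"chr{int(rng.integers(1, 23))}",
                int(rng.integers(1_000_000, 100_000_000)),
                ref,
                alt_base,
                context,
                "ARTIFACT",
            )
        )
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "context", "cluster"])
    n = len(variants)
    ccf = rng.uniform(lo, hi, size=(n, m))
    tumor_cn = np.full((n, m), 2, dtype=int)
    multiplicity = np.ones((n, m), dtype=int)
    pur = np.array([dataset.mutations.purity[s] for s in samples])[None, :]
    vaf = pur * ccf / (pur * tumor_cn + (1 - pur) * 2)
    p_eff = vaf + (1 - vaf) * cfg.seq_error
    depth = rng.poisson(cfg.mean_depth, size=(n, m))
    alt = rng.binomial(depth, np.clip(p_eff, 0.0, 1.0))

    extra = MutationTable(
        variants=variants,
        alt=alt.astype(int),
        depth=depth.astype(int),
        tumor_cn=tumor_cn,
        multiplicity=multiplicity,
        samples=list(samples),
        purity=dict(dataset.mutations.purity),
    )
    truth = replace(
        dataset.truth, artifact_clusters=dataset.truth.artifact_clusters + ["ARTIFACT"]
    )
    return SyntheticDataset(
        mutations=dataset.mutations.concat(extra),
        tree=dataset.tree,
        truth=truth,
        config=cfg,
    )
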