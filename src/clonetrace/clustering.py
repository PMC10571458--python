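"""Multi-sample CCF clustering and artifact-cluster filtering.

Mutations are grouped into evolutionary clusters by a finite binomial
mixture over the joint CCF space of all samples, fitted by
expectation-maximisation with BIC model selection — a deterministic,
desk-scale stand-in for MCMC Dirichlet-process clustering. Each
cluster k has a latent CCF vector theta_k (one entry per sample); the
alt count of mutation i in sample s is binomial with success
probability theta_k scaled by the locus' purity/copy-number VAF
conversion factor. The interface leaves room for an alternative
sampler: anything returning a :class:`ClusterSolution` can feed the
downstream phylogeny.

Artifact filtering implements a conjunction rule: a cluster is flagged
only when its CCFs are low everywhere (below ``ccf_ceiling`` in every
sample) *and* its trinucleotide spectrum matches a known artifact
profile (cosine >= ``cos_threshold``). Flagged clusters are excluded
from phylogeny reconstruction, not deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import KMeans

from .errors import DataError
from .observations import MutationTable, compute_ccf, estimate_multiplicity
from .signatures import CHANNELS_96, channel_index

__all__ = [
    "ClusterSolution",
    "cluster_mutations",
    "trinucleotide_spectrum",
    "cosine_similarity",
    "flag_artifact_clusters",
    "count_sbs1",
    "compute_ccf",
    "estimate_multiplicity",
]

#: A cluster counts as present in a sample at or above this median CCF.
PRESENCE_THRESHOLD = 0.01

#: CCF values may overshoot 1 through noise; the model caps them here.
CCF_CEILING = 1.2


@dataclass
class ClusterSolution:
    """Result of clustering mutations across samples.

    ``assignments`` maps each retained mutation (row order of the input
    table) to a cluster label; ``clusters`` holds one row per cluster
    with its mutation count and per-sample median CCF (columns
    ``ccf_<sample>``); ``artifact_flags`` marks clusters excluded from
    phylogeny reconstruction.
    """

    assignments: np.ndarray  # cluster label per mutation
    clusters: pd.DataFrame  # cluster, n_mutations, ccf_<sample>...
    samples: list[str]
    artifact_flags: dict[str, bool] = field(default_factory=dict)
    log_likelihood: float = float("nan")
    bic: float = float("nan")

    def ccf_vector(self, label: str) -> np.ndarray:
        row = self.clusters.set_index("cluster").loc[label]
        return row[[f"ccf_{s}" for s in self.samples]].to_numpy(dtype=float)

    def retained_labels(self) -> list[str]:
        return [
            c for c in self.clusters["cluster"] if not self.artifact_flags.get(c, False)
        ]

    def to_frame(self) -> pd.DataFrame:
        out = self.clusters.copy()
        out["artifact"] = [bool(self.artifact_flags.get(c, False)) for c in out["cluster"]]
        return out


def _vaf_conversion(table: MutationTable) -> np.ndarray:
    """Expected VAF per unit CCF for each mutation/sample."""
    pur = np.array([table.purity[s] for s in table.samples])[None, :]
    return pur * table.multiplicity / (pur * table.tumor_cn + (1 - pur) * table.normal_cn)


def _component_loglik(alt, depth, p, overdispersion):
    """Per-mutation beta-binomial log likelihood for one component.

    ``overdispersion`` is the beta precision tau: the success
    probability of each read draw is Beta(p*tau, (1-p)*tau), which
    inflates the binomial variance by ~(depth-1)/(tau+1) and keeps
    noise-level CCF wobble from being mistaken for subclonal
    structure. Large tau recovers the plain binomial.
    """
    a = p * overdispersion
    b = (1.0 - p) * overdispersion
    return np.sum(
        gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
        + gammaln(alt + a) + gammaln(depth - alt + b) - gammaln(depth + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b),
        axis=1,
    )


def _binomial_em(
    alt: np.ndarray,
    depth: np.ndarray,
    conv: np.ndarray,
    k: int,
    init_theta: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    overdispersion: float = 500.0,
    error_rate: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """EM for a k-component beta-binomial mixture over CCF space.

    Returns ``(pi, theta, resp, ll)``. The expected VAF of component j
    in sample s is ``theta[j, s] * conv`` floored at the sequencing
    error rate; the M-step uses the moment estimator
    ``theta = sum(resp * alt) / sum(resp * depth * conv)`` (exact for
    the binomial mean, and the beta-binomial mean is identical).
    """
    eps = 1e-9
    n, m = alt.shape
    theta = np.clip(init_theta.copy(), 0.0, CCF_CEILING)
    pi = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        # E-step
        log_r = np.empty((n, k))
        for j in range(k):
            p = np.clip(theta[j][None, :] * conv, error_rate, 1 - eps)
            log_r[:, j] = _component_loglik(alt, depth, p, overdispersion)
        log_r += np.log(np.clip(pi, eps, None))[None, :]
        shift = log_r.max(axis=1, keepdims=True)
        r = np.exp(log_r - shift)
        norm = r.sum(axis=1, keepdims=True)
        resp = r / norm
        ll = float(np.sum(np.log(norm) + shift))
        # M-step
        weight = resp.sum(axis=0)
        pi = weight / n
        for j in range(k):
            num = resp[:, j] @ alt
            den = resp[:, j] @ (depth * conv)
            theta[j] = np.clip(num / np.maximum(den, eps), 0.0, CCF_CEILING)
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            break
        prev_ll = ll
    return pi, theta, resp, ll


def cluster_mutations(
    table: MutationTable,
    max_clusters: int = 8,
    seed: int = 0,
    overdispersion: float = 500.0,
    error_rate: float = 1e-3,
    min_cluster_size: int = 5,
) -> ClusterSolution:
    """Cluster mutations into evolutionary groups across all samples.

    Fits beta-binomial mixtures with 1..``max_clusters`` components
    (k-means++ initialisation on the CCF matrix, then EM) and keeps the
    BIC-optimal model. Components attracting fewer than
    ``min_cluster_size`` mutations are dissolved (outlier sinks, not
    clones) and their members reassigned to the best remaining
    component. Deterministic under ``seed``. Labels are ``C1, C2, ...``
    ordered by decreasing total CCF, so the truncal cluster (CCF ~1
    everywhere) sorts first.
    """
    if len(table) < 2:
        raise DataError("clustering needs at least 2 mutations")
    alt = table.alt.astype(float)
    depth = table.depth.astype(float)
    conv = _vaf_conversion(table)
    ccf = table.ccf_matrix()
    ccf_filled = np.nan_to_num(np.clip(ccf, 0, CCF_CEILING), nan=0.0)

    n = len(table)
    best = None
    max_k = int(min(max_clusters, n))
    for k in range(1, max_k + 1):
        if k == 1:
            init = ccf_filled.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=k, n_init=4, random_state=seed)
            km.fit(ccf_filled)
            init = km.cluster_centers_
        pi, theta, resp, ll = _binomial_em(
            alt, depth, conv, k, init,
            overdispersion=overdispersion, error_rate=error_rate,
        )
        n_params = k * len(table.samples) + (k - 1)
        bic = -2.0 * ll + n_params * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, pi, theta, resp, ll, k)
    bic, pi, theta, resp, ll, k = best

    # per-component log likelihood for (re)assignment
    log_l = np.empty((n, k))
    for j in range(k):
        p = np.clip(theta[j][None, :] * conv, error_rate, 1 - 1e-9)
        log_l[:, j] = _component_loglik(alt, depth, p, overdispersion) + np.log(
            max(pi[j], 1e-12)
        )
    hard = log_l.argmax(axis=1)
    active = list(range(k))
    while len(active) > 1:
        counts = {j: int(np.sum(hard == j)) for j in active}
        smallest = min(active, key=lambda j: (counts[j], j))
        if counts[smallest] >= min_cluster_size:
            break
        active.remove(smallest)
        hard = np.array(active)[log_l[:, active].argmax(axis=1)]

    # order components by total CCF so the truncal cluster is C1
    order = np.argsort(-theta.sum(axis=1), kind="stable")
    kept = [j for j in order if j in active and np.sum(hard == j) > 0]
    relabel = {j: f"C{i + 1}" for i, j in enumerate(kept)}
    labels = np.array([relabel.get(j, "C?") for j in hard])

    rows = []
    for j in kept:
        mask = hard == j
        med = np.nanmedian(ccf[mask], axis=0)
        rows.append(
            {"cluster": relabel[j], "n_mutations": int(mask.sum())}
            | {f"ccf_{s}": float(np.nan_to_num(med[i])) for i, s in enumerate(table.samples)}
        )
    clusters = pd.DataFrame(rows)
    return ClusterSolution(
        assignments=labels,
        clusters=clusters,
        samples=list(table.samples),
        log_likelihood=ll,
        bic=bic,
    )


def trinucleotide_spectrum(variants: pd.DataFrame) -> np.ndarray:
    """Proportion of mutations in each of the 96 substitution channels.

    ``variants`` needs ``ref``, ``alt`` and ``context`` columns; the
    result is non-negative and sums to one.
    """
    if len(variants) == 0:
        raise DataError("cannot compute a spectrum from zero mutations")
    counts = np.zeros(96)
    for ref, alt, context in zip(variants["ref"], variants["alt"], variants["context"]):
        counts[channel_index(ref, alt, context)] += 1
    return counts / counts.sum()


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two non-negative spectra, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("cosine similarity of a zero vector is undefined")
    return float(np.dot(a, b) / (na * nb))


def flag_artifact_clusters(
    solution: ClusterSolution,
    table: MutationTable,
    artifact_spectra: dict[str, np.ndarray] | list[np.ndarray],
    ccf_ceiling: float = 0.2,
    cos_threshold: float = 0.9,
) -> ClusterSolution:
    """Flag clusters that look like sequencing artifacts.

    A cluster is flagged iff *both* hold: its per-sample median CCFs
    are all below ``ccf_ceiling`` (too low and inconsistent for a real
    clone) and its spectrum has cosine >= ``cos_threshold`` to at least
    one artifact profile. Flags are recorded on the returned solution;
    mutations keep their labels.
    """
    spectra = (
        list(artifact_spectra.values())
        if isinstance(artifact_spectra, dict)
        else list(artifact_spectra)
    )
    flags = dict(solution.artifact_flags)
    for label in solution.clusters["cluster"]:
        ccfs = solution.ccf_vector(label)
        if not np.all(ccfs < ccf_ceiling):
            flags[label] = False
            continue
        members = table.variants[solution.assignments == label]
        if len(members) == 0:
            flags[label] = False
            continue
        spec = trinucleotide_spectrum(members)
        flags[label] = any(cosine_similarity(spec, ref) >= cos_threshold for ref in spectra)
    return ClusterSolution(
        assignments=solution.assignments,
        clusters=solution.clusters,
        samples=solution.samples,
        artifact_flags=flags,
        log_likelihood=solution.log_likelihood,
        bic=solution.bic,
    )


def count_sbs1(variants: pd.DataFrame) -> int:
    """Number of clock-like CpG>TpG mutations (strand-symmetric).

    Counts C>T substitutions whose 3' neighbour is G, folding purine
    representations (G>A with 5' C) onto the pyrimidine strand.
    """
    count = 0
    for ref, alt, context in zip(variants["ref"], variants["alt"], variants["context"]):
        if CHANNELS_96[channel_index(ref, alt, context)].endswith("[C>T]G"):
            count += 1
    return count
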