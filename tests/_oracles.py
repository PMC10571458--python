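"""Independent brute-force oracles used by the test suite.

These re-derive expected results from first principles (exhaustive
enumeration, direct definitions) without sharing code with the
implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def cluster_frame(tree) -> pd.DataFrame:
    """Flatten a CloneTree into the cluster-table input of build_tree."""
    rows = []
    for cid, c in tree.clones.items():
        rows.append(
            {"cluster": cid, "n_mutations": c.n_snv, "n_sbs1": c.n_sbs1, "n_td": c.n_td}
            | {f"ccf_{s}": c.ccf_in(s) for s in tree.samples}
        )
    return pd.DataFrame(rows)


def enumerate_canonical_tree(clusters: pd.DataFrame, tolerance=0.1, truncal_min=0.95):
    """Exhaustively enumerate sum-rule-feasible trees, pick the canonical one.

    Tries every parent function over the non-root clusters, keeps those
    that are acyclic, dominance-consistent and sum-rule-feasible, and
    returns the parent map minimising the declared preference score
    (placement order by decreasing CCF sum; parents ranked by
    increasing CCF sum, then SNV count, then id).
    """
    samples = [c[4:] for c in clusters.columns if c.startswith("ccf_")]
    ids = clusters["cluster"].tolist()
    ccf = clusters[[f"ccf_{s}" for s in samples]].to_numpy(float)
    n_snv = clusters["n_mutations"].to_numpy(int)
    n = len(ids)
    truncal = [i for i in range(n) if np.all(ccf[i] >= truncal_min)]
    if not truncal:
        return None
    root = min(truncal, key=lambda i: (-n_snv[i], ids[i]))
    order = sorted(
        (i for i in range(n) if i != root),
        key=lambda i: (-ccf[i].sum(), -n_snv[i], ids[i]),
    )
    pref = {
        c: sorted(
            (p for p in range(n) if p != c),
            key=lambda p: (ccf[p].sum(), -n_snv[p], ids[p]),
        )
        for c in order
    }
    best = None
    for combo in itertools.product(*[pref[c] for c in order]):
        parent = dict(zip(order, combo))
        ok = True
        for c in order:  # acyclicity, rooted at root
            seen = {c}
            node = parent[c]
            while node != root:
                if node in seen or node not in parent:
                    ok = False
                    break
                seen.add(node)
                node = parent[node]
            if not ok:
                break
        if not ok:
            continue
        if any(not np.all(ccf[parent[c]] >= ccf[c] - tolerance) for c in order):
            continue
        load = np.zeros((n, len(samples)))
        for c in order:
            load[parent[c]] += ccf[c]
        if np.any(load > ccf + tolerance):
            continue
        score = tuple(pref[c].index(parent[c]) for c in order)
        if best is None or score < best[0]:
            best = (score, {ids[c]: ids[p] for c, p in parent.items()})
    return best[1] if best else None


def seeding_set_by_construction(tree, anatomy: pd.DataFrame, threshold: float, sites) -> set:
    """Direct set construction of resident met populations (oracle)."""
    ana = anatomy.set_index("sample")
    mets = [s for s in tree.samples if ana.loc[s, "site_class"] in sites]
    out = set()
    for cid in tree.clones:
        if cid == tree.root:
            continue
        for s in mets:
            kids = sum(tree.ccf(k, s) for k in tree.children(cid))
            if tree.ccf(cid, s) - kids >= threshold:
                out.add(cid)
    return out


def acceptance_region_by_scan(tree, clock, grid: np.ndarray) -> np.ndarray:
    """Accepted change points by applying the definition through ages.

    For each candidate change point, maps every sample-private
    cluster's pre-branch cumulative SBS1 count to a calendar age with
    the piecewise clock evaluated longhand, and accepts the draw iff
    all those ages reach the change point.
    """
    from clonetrace.chronology import anchor_path

    _, cumulative = anchor_path(tree)
    N = float(cumulative[-1])
    T, k = clock.age_rp, clock.accel_factor
    private_m = []
    for cid, clone in tree.clones.items():
        if clone.parent is None:
            continue
        present = [s for s in tree.samples if clone.ccf_in(s) >= clock.presence_threshold]
        if len(present) == 1:
            private_m.append(tree.cumulative(cid, "n_sbs1") - clone.n_sbs1)
    accepted = []
    for t_a in grid:
        r = N / (t_a + k * (T - t_a))
        ok = True
        for m in private_m:
            age = m / r if m <= r * t_a else t_a + (m - r * t_a) / (k * r)
            if age < t_a - 1e-9:
                ok = False
                break
        accepted.append(ok)
    return np.asarray(accepted)
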