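"""Clone trees: the central container for subclonal reconstructions.

A :class:`CloneTree` is a rooted tree of mutation clusters. Each cluster
carries a per-sample cancer cell fraction (CCF) vector plus mutation
counts (total SNVs, clock-like CpG>TpG "SBS1" SNVs, tandem duplications).
CCFs are *cumulative*: the CCF of a cluster in a sample is the fraction
of tumor cells carrying that cluster's mutations, which includes every
descendant cell. Consequently the root (truncal/MRCA) cluster sits at
CCF ~1 in every tumor sample and, within each sample, a parent's CCF
must be at least the sum of its children's CCFs (the pigeonhole / sum
rule).

The *surface* (or resident population fraction) of a cluster in a sample
is its CCF minus the summed CCFs of its children: the fraction of cells
whose most-derived cluster is that node. Surfaces are what jawbreaker
plots display and what seeding-event counting uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import DataError

__all__ = ["Clone", "CloneTree"]


@dataclass
class Clone:
    """One evolutionary cluster (node) of a clone tree.

    Parameters
    ----------
    id:
        Cluster label, e.g. ``"T"``, ``"Ba"``.
    parent:
        Parent cluster id, or ``None`` for the root.
    ccf:
        Mapping sample id -> cumulative CCF of this cluster in that
        sample. Missing samples are treated as CCF 0.
    n_snv, n_sbs1, n_td:
        Mutations on the *branch* leading to this cluster: total SNVs,
        clock-like CpG>TpG SNVs, and tandem duplications.
    """

    id: str
    parent: str | None
    ccf: dict[str, float] = field(default_factory=dict)
    n_snv: int = 0
    n_sbs1: int = 0
    n_td: int = 0

    def ccf_in(self, sample: str) -> float:
        return float(self.ccf.get(sample, 0.0))


class CloneTree:
    """Rooted tree of :class:`Clone` nodes keyed by cluster id."""

    def __init__(self, clones: Iterable[Clone], samples: Iterable[str] | None = None):
        self.clones: dict[str, Clone] = {}
        for clone in clones:
            if clone.id in self.clones:
                raise DataError(f"duplicate cluster id {clone.id!r}")
            self.clones[clone.id] = clone
        roots = [c.id for c in self.clones.values() if c.parent is None]
        if len(roots) != 1:
            raise DataError(f"tree must have exactly one root, found {roots!r}")
        self.root: str = roots[0]
        self._children: dict[str, list[str]] = {cid: [] for cid in self.clones}
        for clone in self.clones.values():
            if clone.parent is not None:
                if clone.parent not in self.clones:
                    raise DataError(
                        f"cluster {clone.id!r} references unknown parent {clone.parent!r}"
                    )
                self._children[clone.parent].append(clone.id)
        for kids in self._children.values():
            kids.sort()
        if samples is None:
            seen: dict[str, None] = {}
            for clone in self.clones.values():
                for s in clone.ccf:
                    seen.setdefault(s)
            samples = list(seen)
        self.samples: list[str] = list(samples)
        # reject cycles / unreachable nodes
        if len(list(self.preorder())) != len(self.clones):
            raise DataError("tree contains a cycle or unreachable cluster")

    # -- traversal -----------------------------------------------------
    def children(self, cid: str) -> list[str]:
        return list(self._children[cid])

    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            cid = stack.pop()
            yield cid
            stack.extend(reversed(self._children[cid]))

    def leaves(self) -> list[str]:
        return [cid for cid in self.clones if not self._children[cid]]

    def path_to_root(self, cid: str) -> list[str]:
        """Node ids from the root down to (and including) ``cid``."""
        path = [cid]
        while self.clones[path[-1]].parent is not None:
            path.append(self.clones[path[-1]].parent)  # type: ignore[arg-type]
        return path[::-1]

    def depth(self, cid: str) -> int:
        return len(self.path_to_root(cid)) - 1

    def descendants(self, cid: str) -> list[str]:
        out: list[str] = []
        stack = list(self._children[cid])
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self._children[node])
        return out

    # -- derived quantities --------------------------------------------
    def ccf(self, cid: str, sample: str) -> float:
        return self.clones[cid].ccf_in(sample)

    def surface(self, cid: str, sample: str) -> float:
        """Resident population fraction of ``cid`` in ``sample``."""
        child_sum = sum(self.ccf(k, sample) for k in self._children[cid])
        return max(0.0, self.ccf(cid, sample) - child_sum)

    def cumulative(self, cid: str, attr: str = "n_sbs1") -> int:
        """Sum of a branch count along the root path of ``cid``."""
        return sum(getattr(self.clones[c], attr) for c in self.path_to_root(cid))

    def present_in(self, cid: str, sample: str, threshold: float = 0.01) -> bool:
        return self.ccf(cid, sample) >= threshold

    def samples_with(self, cid: str, threshold: float = 0.01) -> list[str]:
        return [s for s in self.samples if self.present_in(cid, s, threshold)]

    # -- validation ----------------------------------------------------
    def validate(self, tolerance: float = 0.1, truncal_min: float = 0.95) -> None:
        """Assert the structural invariants (root clonality, sum rule).

        Raises :class:`DataError` naming the violated constraint.
        """
        for s in self.samples:
            root_ccf = self.ccf(self.root, s)
            if root_ccf < truncal_min:
                raise DataError(
                    f"root cluster {self.root!r} has CCF {root_ccf:.3f} < "
                    f"{truncal_min} in sample {s!r}"
                )
            for cid in self.clones:
                child_sum = sum(self.ccf(k, s) for k in self._children[cid])
                if child_sum > self.ccf(cid, s) + tolerance:
                    raise DataError(
                        f"sum rule violated at cluster {cid!r} in sample {s!r}: "
                        f"children sum {child_sum:.3f} > parent {self.ccf(cid, s):.3f} "
                        f"+ tolerance {tolerance}"
                    )

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "samples": self.samples,
            "clusters": [
                {
                    "id": c.id,
                    "parent": c.parent,
                    "ccf": {s: c.ccf_in(s) for s in self.samples},
                    "n_snv": c.n_snv,
                    "n_sbs1": c.n_sbs1,
                    "n_td": c.n_td,
                }
                for c in self.clones.values()
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CloneTree":
        clones = [
            Clone(
                id=rec["id"],
                parent=rec.get("parent"),
                ccf=dict(rec.get("ccf", {})),
                n_snv=int(rec.get("n_snv", 0)),
                n_sbs1=int(rec.get("n_sbs1", 0)),
                n_td=int(rec.get("n_td", 0)),
            )
            for rec in payload["clusters"]
        ]
        return cls(clones, samples=payload.get("samples"))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CloneTree":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def __len__(self) -> int:
        return len(self.clones)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CloneTree(n_clusters={len(self)}, root={self.root!r}, samples={len(self.samples)})"
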