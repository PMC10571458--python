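"""Multi-sample mutation observations and the CCF transform.

A :class:`MutationTable` bundles, for every somatic SNV, its genomic
identity (chrom, pos, ref, alt, trinucleotide context) together with
per-sample read support (alt/total depth), the locus copy-number
context, and per-sample tumor purity. It is the input container for
clustering and the output container of the read simulator and the VCF
reader.

The cancer cell fraction (CCF) of a mutation in a sample is obtained
from its variant allele fraction (VAF) by correcting for purity and
local copy number::

    CCF = VAF * [purity * CN_tumor + (1 - purity) * CN_normal]
          / (purity * multiplicity)

clipped to [0, 2]; values above ~1.2 usually indicate a mis-specified
copy-number context rather than real super-clonality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["MutationTable", "compute_ccf", "estimate_multiplicity"]

#: Upper clip for CCF estimates; overshoot beyond ~1.2 flags CN problems.
CCF_CLIP = 2.0


def compute_ccf(
    alt_depth,
    total_depth,
    purity,
    tumor_cn,
    normal_cn=2,
    multiplicity=1,
):
    """Cancer cell fraction from read counts and copy-number context.

    All arguments broadcast as numpy arrays. Zero total depth yields
    ``nan`` (missing), not zero: absence of evidence is not CCF 0.
    Scalar ``purity`` must lie in (0, 1]; ``multiplicity`` >= 1.
    """
    alt = np.asarray(alt_depth, dtype=float)
    tot = np.asarray(total_depth, dtype=float)
    purity = np.asarray(purity, dtype=float)
    mult = np.asarray(multiplicity, dtype=float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise DataError("purity must lie in (0, 1]")
    if np.any(mult < 1):
        raise DataError("multiplicity must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(tot > 0, alt / np.where(tot > 0, tot, 1), np.nan)
        ccf = vaf * (purity * np.asarray(tumor_cn, float) + (1 - purity) * np.asarray(normal_cn, float)) / (
            purity * mult
        )
    return np.clip(ccf, 0.0, CCF_CLIP)


def estimate_multiplicity(vaf, purity, tumor_cn, normal_cn=2):
    """Integer number of mutated copies, estimated from the VAF.

    ``round(VAF * (purity*CN_t + (1-purity)*CN_n) / purity)`` floored
    at 1 and capped at the tumor copy number.
    """
    vaf = np.asarray(vaf, dtype=float)
    tumor_cn = np.asarray(tumor_cn, dtype=float)
    raw = vaf * (purity * tumor_cn + (1 - purity) * np.asarray(normal_cn, float)) / purity
    return np.clip(np.round(raw), 1, np.maximum(tumor_cn, 1)).astype(int)


@dataclass
class MutationTable:
    """Somatic SNVs observed across the samples of one tumor.

    Attributes
    ----------
    variants:
        DataFrame with columns ``chrom, pos, ref, alt, context`` (and
        optionally ``cluster`` when truth or an assignment is known),
        one row per mutation; positions are 1-based.
    alt, depth:
        Integer arrays of shape (n_mutations, n_samples).
    tumor_cn, multiplicity:
        Integer arrays of the same shape (locus total copy number and
        mutation multiplicity per sample).
    samples:
        Sample ids, column order of the matrices.
    purity:
        Sample id -> tumor purity in (0, 1].
    """

    variants: pd.DataFrame
    alt: np.ndarray
    depth: np.ndarray
    tumor_cn: np.ndarray
    multiplicity: np.ndarray
    samples: list[str]
    purity: dict[str, float]
    normal_cn: int = 2

    def __post_init__(self) -> None:
        n, m = self.alt.shape
        if len(self.variants) != n or self.depth.shape != (n, m):
            raise DataError("variant table and depth matrices are inconsistent")
        if len(self.samples) != m:
            raise DataError("sample list does not match matrix width")
        if np.any(self.alt > self.depth):
            raise DataError("alt depth exceeds total depth")

    def __len__(self) -> int:
        return len(self.variants)

    def ccf_matrix(self) -> np.ndarray:
        """Per-mutation, per-sample CCF estimates (nan where depth 0)."""
        pur = np.array([self.purity[s] for s in self.samples])
        return compute_ccf(
            self.alt,
            self.depth,
            pur[None, :],
            self.tumor_cn,
            self.normal_cn,
            self.multiplicity,
        )

    def subset(self, mask) -> "MutationTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return MutationTable(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            alt=self.alt[idx],
            depth=self.depth[idx],
            tumor_cn=self.tumor_cn[idx],
            multiplicity=self.multiplicity[idx],
            samples=list(self.samples),
            purity=dict(self.purity),
            normal_cn=self.normal_cn,
        )

    def concat(self, other: "MutationTable") -> "MutationTable":
        if other.samples != self.samples:
            raise DataError("cannot concatenate tables with different samples")
        return MutationTable(
            variants=pd.concat([self.variants, other.variants], ignore_index=True),
            alt=np.vstack([self.alt, other.alt]),
            depth=np.vstack([self.depth, other.depth]),
            tumor_cn=np.vstack([self.tumor_cn, other.tumor_cn]),
            multiplicity=np.vstack([self.multiplicity, other.multiplicity]),
            samples=list(self.samples),
            purity=dict(self.purity),
            normal_cn=self.normal_cn,
        )
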