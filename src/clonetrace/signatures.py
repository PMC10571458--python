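"""Trinucleotide substitution channels and reference spectra.

The 96 single-base-substitution channels follow the conventional
pyrimidine-centric ordering: six substitution types (C>A, C>G, C>T,
T>A, T>C, T>G) by sixteen flanking-base contexts, alphabetical in the
5' then 3' base. Purine-reference mutations are folded onto their
reverse complement.

Two built-in spectra are provided:

* :func:`clock_like_spectrum` — the pure CpG>TpG deamination profile
  (uniform over the four N[C>T]G channels), the idealised clock-like
  signature used to sanity-check simulated clock mutations.
* :func:`artifact_like_spectrum` — a synthetic, deterministically
  generated broad C>A-dominated profile standing in for a sequencing
  artifact signature. It is *not* a catalog signature; it exists so the
  artifact-cluster filter can be exercised without external data.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CHANNELS_96",
    "channel_index",
    "normalize_substitution",
    "clock_like_spectrum",
    "artifact_like_spectrum",
]

_BASES = "ACGT"
_SUBS = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _build_channels() -> list[str]:
    channels = []
    for ref, alt in _SUBS:
        for five in _BASES:
            for three in _BASES:
                channels.append(f"{five}[{ref}>{alt}]{three}")
    return channels


#: Canonical ordering of the 96 substitution classes.
CHANNELS_96: list[str] = _build_channels()
_CHANNEL_TO_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def normalize_substitution(ref: str, alt: str, context: str) -> str:
    """Fold a substitution into its pyrimidine-centric channel label.

    ``context`` is the reference trinucleotide centred on the mutated
    base, e.g. ``"ACG"`` for an A-C-G run with the middle C mutated.
    Purine references (A/G) are reverse-complemented.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if ref in "AG":
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if label not in _CHANNEL_TO_INDEX:
        raise ValueError(f"invalid substitution {ref}>{alt} in context {context}")
    return label


def channel_index(ref: str, alt: str, context: str) -> int:
    """Index of a substitution's channel in :data:`CHANNELS_96`."""
    return _CHANNEL_TO_INDEX[normalize_substitution(ref, alt, context)]


def clock_like_spectrum() -> np.ndarray:
    """Pure CpG>TpG profile: uniform mass on the four N[C>T]G channels."""
    spectrum = np.zeros(96)
    for five in _BASES:
        spectrum[_CHANNEL_TO_INDEX[f"{five}[C>T]G"]] = 0.25
    return spectrum


def artifact_like_spectrum() -> np.ndarray:
    """Synthetic broad artifact-like profile (C>A heavy, flat tail).

    Deterministic by construction: geometric weights over the sixteen
    C>A channels carrying 80% of the mass, the remaining 20% spread
    uniformly over all other channels. Orthogonal enough to the
    clock-like profile (cosine ~0.03) for filtering to be meaningful.
    """
    spectrum = np.full(96, 0.2 / 80.0)
    weights = 0.75 ** np.arange(16)
    weights /= weights.sum()
    spectrum[0:16] = 0.8 * weights
    return spectrum / spectrum.sum()
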