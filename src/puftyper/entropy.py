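"""Sequence-diversity metrics for indel profiles.

Shannon entropy (plug-in estimator, base 2) of the indel frequency
distribution, a depth-matched resampling estimate, and the expected
contribution to diversity of each indel size class (frequency times the
number of distinct sequences that size class can realise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Tuple, Union

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .errors import EmptyProfileError
from .indel import DELETION, INSERTION, IndelCall
from .profile import IndelProfile


@dataclass(frozen=True)
class EntropyEstimate:
    """Mean and spread of Shannon entropy over resampled read subsets."""

    mean_bits: float
    sd_bits: float
    n_subsample: int
    n_reps: int


def shannon_entropy(profile: Union[IndelProfile, Dict[str, int]]) -> float:
    """Plug-in Shannon entropy, in bits, of a profile's indel frequencies."""
    counts = profile.counts if isinstance(profile, IndelProfile) else profile
    if not counts:
        raise EmptyProfileError("cannot compute entropy of an empty profile")
    return float(_scipy_entropy(np.fromiter(counts.values(), dtype=float), base=2))


def resampled_entropy(
    profile: IndelProfile,
    n_subsample: int = 100_000,
    n_reps: int = 100,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> EntropyEstimate:
    """Mean Shannon entropy over ``n_reps`` without-replacement subsamples.

    Each repetition draws ``n_subsample`` reads without replacement from the
    profile's read multiset (a multivariate-hypergeometric draw over the key
    counts) and evaluates the plug-in entropy of the subsample. When
    ``n_subsample`` exceeds the profile depth it is clamped to the full
    profile with a warning (the estimate then degenerates to the plug-in
    entropy with sd 0).
    """
    profile.require_nonempty()
    rng = np.random.default_rng(seed)
    counts = np.fromiter(profile.counts.values(), dtype=np.int64)
    n_reads = int(counts.sum())
    if n_subsample > n_reads:
        warnings.warn(
            f"n_subsample {n_subsample} exceeds profile depth {n_reads}; "
            "clamping to the full profile",
            stacklevel=2,
        )
        n_subsample = n_reads
    values = np.empty(n_reps)
    for r in range(n_reps):
        draw = rng.multivariate_hypergeometric(counts, n_subsample)
        draw = draw[draw > 0]
        values[r] = _scipy_entropy(draw.astype(float), base=2)
    return EntropyEstimate(
        mean_bits=float(values.mean()),
        sd_bits=float(values.std()),
        n_subsample=n_subsample,
        n_reps=n_reps,
    )


SizeHistogram = Dict[Tuple[str, int], float]


def size_histogram(profile: IndelProfile) -> SizeHistogram:
    """Frequency of indel reads by (kind, length)."""
    profile.require_nonempty()
    n = profile.n_reads
    hist: SizeHistogram = {}
    for key, count in profile.counts.items():
        call = IndelCall.from_key(key)
        k = (call.kind, call.length)
        hist[k] = hist.get(k, 0.0) + count / n
    return hist


def n_replacements(kind: str, length: int) -> float:
    """Default count of distinct outcomes a size class can realise.

    Insertions of length s can be any of 4**s sequences; deletions of
    length s can occupy s distinct windows overlapping the cut junction.
    """
    if kind == INSERTION:
        return float(4**length)
    if kind == DELETION:
        return float(length)
    raise ValueError(f"unknown kind {kind!r}")


def diversity_contribution(
    hist: SizeHistogram,
    replacements: Callable[[str, int], float] = n_replacements,
) -> Dict[Tuple[str, int], float]:
    """Expected contribution to diversity per size class.

    Each (kind, length) class contributes its read frequency multiplied by
    the number of distinct sequences that class can realise; the weighting
    is pluggable via ``replacements``.
    """
    return {k: freq * replacements(*k) for k, freq in hist.items()}
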