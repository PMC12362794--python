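"""Bray-Curtis dissimilarity analysis of PUF libraries.

Pairwise Bray-Curtis dissimilarity (BCD) on frequency-normalized profiles,
top-fraction feature selection, intra/inter-PUF separation statistics and
fraction sweeps, singleton removal, common-indel exclusion, and the
passage-stability identification threshold.

BCD between samples i and j over the union key support is

    BCD_ij = sum_k |n_ik - n_jk| / sum_k (n_ik + n_jk)

with n the key frequencies; 0 for identical compositions, 1 for disjoint
supports. Profiles are renormalized to frequencies after every filtering
step so BCD stays in [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis

from .errors import EmptyProfileError
from .indel import key_sort_key
from .profile import IndelProfile, PUFLibrary

DEFAULT_FRACTION = 0.25


def bray_curtis(p: IndelProfile, q: IndelProfile) -> float:
    """Bray-Curtis dissimilarity between two profiles over their union keys."""
    if not p.counts and not q.counts:
        raise EmptyProfileError("cannot compare two empty profiles")
    p.require_nonempty()
    q.require_nonempty()
    keys = sorted(set(p.counts) | set(q.counts), key=key_sort_key)
    fp, fq = p.frequencies(), q.frequencies()
    u = np.array([fp.get(k, 0.0) for k in keys])
    v = np.array([fq.get(k, 0.0) for k in keys])
    return float(_braycurtis(u, v))


def top_fraction(profile: IndelProfile, fraction: float) -> IndelProfile:
    """Retain the ceil(fraction * m) most frequent unique indels.

    Ties at the cutoff rank are broken by the deterministic key order, so
    the retained set is the same across runs and implementations.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    profile.require_nonempty()
    m = profile.n_unique
    k = math.ceil(fraction * m)
    ranked = sorted(profile.counts, key=lambda key: (-profile.counts[key], key_sort_key(key)))
    kept = ranked[:k]
    return IndelProfile(
        sample_id=profile.sample_id, counts={key: profile.counts[key] for key in kept}
    )


@dataclass
class DissimilarityMatrix:
    """Symmetric zero-diagonal BCD matrix over a library's samples."""

    sample_ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample_ids")

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def pairwise_matrix(library: PUFLibrary, fraction: float = DEFAULT_FRACTION) -> DissimilarityMatrix:
    """BCD between every pair of profiles after per-profile top-fraction cropping."""
    if len(library.profiles) < 2:
        raise ValueError("need at least two profiles for a pairwise matrix")
    cropped = [top_fraction(p, fraction) for p in library.profiles]
    n = len(cropped)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = bray_curtis(cropped[i], cropped[j])
    return DissimilarityMatrix(sample_ids=[p.sample_id for p in cropped], values=values)


@dataclass(frozen=True)
class SeparationReport:
    """Intra- vs inter-PUF mean BCD from one reference sample."""

    reference_id: str
    intra_mean: float
    inter_mean: float
    fold_change: float


def separation(
    library: PUFLibrary, matrix: DissimilarityMatrix, reference_id: str
) -> SeparationReport:
    """Fold change between inter- and intra-PUF mean BCD for one reference."""
    replicates = library.replicates_of(reference_id)
    if not replicates:
        raise ValueError(f"reference {reference_id!r} has no replicate")
    ref_group = library.group_of(reference_id)
    inter = [
        matrix.get(reference_id, s)
        for s in library.sample_ids
        if library.groups[s] != ref_group
    ]
    intra = [matrix.get(reference_id, s) for s in replicates]
    intra_mean = float(np.mean(intra))
    inter_mean = float(np.mean(inter)) if inter else float("nan")
    if intra_mean == 0.0:
        warnings.warn(
            f"reference {reference_id!r}: intra-PUF BCD is 0; fold change is infinite",
            stacklevel=2,
        )
        fold = float("inf")
    else:
        fold = inter_mean / intra_mean
    return SeparationReport(
        reference_id=reference_id,
        intra_mean=intra_mean,
        inter_mean=inter_mean,
        fold_change=fold,
    )


def average_fold_change(
    library: PUFLibrary, fraction: float = DEFAULT_FRACTION
) -> float:
    """Mean intra/inter fold change using every replicated sample as reference."""
    matrix = pairwise_matrix(library, fraction)
    folds = [
        separation(library, matrix, s).fold_change
        for s in library.sample_ids
        if library.replicates_of(s)
    ]
    finite = [f for f in folds if math.isfinite(f)]
    if not finite:
        raise ValueError("no finite fold change in library")
    return float(np.mean(finite))


def sweep_fraction(
    library: PUFLibrary,
    reference_id: str,
    fractions: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Separation statistics across a grid of top-fraction values.

    Default grid: 5% to 100% in 5% steps.
    """
    if fractions is None:
        fractions = [round(0.05 * i, 2) for i in range(1, 21)]
    rows = []
    for f in fractions:
        rep = separation(library, pairwise_matrix(library, f), reference_id)
        rows.append(
            {
                "fraction": f,
                "intra_mean": rep.intra_mean,
                "inter_mean": rep.inter_mean,
                "fold_change": rep.fold_change,
            }
        )
    return pd.DataFrame(rows)


def remove_singletons(profile: IndelProfile) -> IndelProfile:
    """Drop keys observed exactly once in the sample."""
    return IndelProfile(
        sample_id=profile.sample_id,
        counts={k: c for k, c in profile.counts.items() if c > 1},
    )


def common_indels(library: PUFLibrary, reference_id: str) -> Set[str]:
    """Keys present in the reference profile and in every other profile."""
    ref = library.get(reference_id)
    common = set(ref.counts)
    for p in library.profiles:
        if p.sample_id == reference_id:
            continue
        common &= set(p.counts)
    if len(library.profiles) < 2:
        return set()
    return common


def exclude_common(library: PUFLibrary, reference_id: str) -> PUFLibrary:
    """Remove the reference-anchored common indel set from every profile."""
    shared = common_indels(library, reference_id)
    return library.map_profiles(
        lambda p: IndelProfile(
            sample_id=p.sample_id,
            counts={k: c for k, c in p.counts.items() if k not in shared},
        )
    )


def common_exclusion_pipeline(
    library: PUFLibrary, reference_id: str, fraction: float = DEFAULT_FRACTION
) -> DissimilarityMatrix:
    """Full heuristic pipeline: drop singletons, exclude common indels
    across all samples, then pairwise BCD on the top-fraction indels."""
    cleaned = library.map_profiles(remove_singletons)
    for p in cleaned.profiles:
        p.require_nonempty()
    excluded = exclude_common(cleaned, reference_id)
    return pairwise_matrix(excluded, fraction)


def stability_threshold(matrix: DissimilarityMatrix, library: PUFLibrary) -> float:
    """Minimum inter-group BCD: the minimum identification threshold.

    A time-course or query profile authenticates against a registered PUF
    iff its BCD to that profile stays below this threshold.
    """
    values = [
        matrix.values[i, j]
        for i, a in enumerate(matrix.sample_ids)
        for j, b in enumerate(matrix.sample_ids)
        if i < j and library.groups[a] != library.groups[b]
    ]
    if not values:
        raise ValueError("library has no inter-group pair")
    return float(min(values))
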