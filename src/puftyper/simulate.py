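"""Simulated-PUF scalability study.

Pools observed (or synthetic) profiles into a master indel distribution,
samples simulated PUFs from it with replacement, constructs replicates at a
controlled compositional overlap, and measures replicate-classification
accuracy of the logistic-regression authenticator as the library grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .classify import accuracy, predict, train
from .indel import INSERTION, IndelCall, key_sort_key
from .profile import IndelProfile, PUFLibrary

DEFAULT_LIBRARY_SIZES: Tuple[int, ...] = tuple(range(25, 301, 25))
DEFAULT_REPLICATE_OVERLAP = 0.77


@dataclass
class MasterDistribution:
    """Probability distribution over indel keys pooled across PUFs."""

    keys: List[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.keys) != len(self.probs):
            raise ValueError("keys and probs length mismatch")
        if len(self.keys) == 0:
            raise ValueError("master distribution is empty")
        if np.any(self.probs <= 0):
            raise ValueError("master probabilities must be positive")
        self.probs = self.probs / self.probs.sum()

    @property
    def support_size(self) -> int:
        return len(self.keys)

    @classmethod
    def from_dict(cls, weights: Dict[str, float]) -> "MasterDistribution":
        keys = sorted(weights, key=key_sort_key)
        return cls(keys=keys, probs=np.array([weights[k] for k in keys]))

    def to_dict(self) -> Dict[str, float]:
        return dict(zip(self.keys, self.probs))

    def restrict_insertion_sizes(self, lo: int, hi: int) -> "MasterDistribution":
        """Keep deletions and only those insertions with length in [lo, hi]."""
        kept = [
            i
            for i, k in enumerate(self.keys)
            if (call := IndelCall.from_key(k)).kind != INSERTION
            or lo <= call.length <= hi
        ]
        if not kept:
            raise ValueError("insertion-size restriction removes every key")
        return MasterDistribution(
            keys=[self.keys[i] for i in kept], probs=self.probs[kept]
        )


def build_master(library: PUFLibrary) -> MasterDistribution:
    """Pool every profile's counts into one normalized distribution."""
    pooled: Dict[str, float] = {}
    for p in library.profiles:
        for k, c in p.counts.items():
            pooled[k] = pooled.get(k, 0.0) + c
    return MasterDistribution.from_dict(pooled)


def _rng(seed: Optional[Union[int, np.random.Generator]]) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_puf(
    master: MasterDistribution,
    n_reads: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
    sample_id: str = "sim",
    n_unique_target: Optional[int] = None,
) -> IndelProfile:
    """Draw a simulated PUF: ``n_reads`` reads with replacement from the master.

    The resulting support size is stochastic. If ``n_unique_target`` is
    given, the master is first restricted to that many probability-weighted
    keys (without replacement) before drawing.
    """
    rng = _rng(seed)
    keys, probs = master.keys, master.probs
    if n_unique_target is not None and n_unique_target < len(keys):
        idx = rng.choice(len(keys), size=n_unique_target, replace=False, p=probs)
        keys = [keys[i] for i in idx]
        probs = probs[idx] / probs[idx].sum()
    draws = rng.multinomial(n_reads, probs)
    counts = {k: int(c) for k, c in zip(keys, draws) if c > 0}
    return IndelProfile(sample_id=sample_id, counts=counts)


def measure_overlap(p: IndelProfile, q: IndelProfile) -> float:
    """Compositional mass overlap: sum over keys of min frequency.

    Equals 1 - Bray-Curtis dissimilarity for frequency profiles.
    """
    fp, fq = p.frequencies(), q.frequencies()
    return float(sum(min(fp[k], fq.get(k, 0.0)) for k in fp))


def make_replicate(
    profile: IndelProfile,
    master: MasterDistribution,
    overlap: float = DEFAULT_REPLICATE_OVERLAP,
    seed: Optional[Union[int, np.random.Generator]] = None,
    sample_id: Optional[str] = None,
) -> IndelProfile:
    """Replicate a simulated PUF at a target compositional overlap.

    A fraction ``overlap`` of the replicate's reads is a without-replacement
    subsample of the original's reads; the remainder is drawn from the
    master restricted to keys outside the original's support, so the
    measured mass overlap equals the retained fraction.
    """
    if not 0 < overlap <= 1:
        raise ValueError(f"overlap must be in (0, 1], got {overlap}")
    rng = _rng(seed)
    sample_id = sample_id or f"{profile.sample_id}_rep"
    n = profile.n_reads
    n_keep = int(round(overlap * n))
    keys = sorted(profile.counts, key=key_sort_key)
    counts_arr = np.array([profile.counts[k] for k in keys], dtype=np.int64)
    kept = rng.multivariate_hypergeometric(counts_arr, n_keep)
    counts = {k: int(c) for k, c in zip(keys, kept) if c > 0}
    n_fresh = n - n_keep
    if n_fresh > 0:
        outside = [i for i, k in enumerate(master.keys) if k not in profile.counts]
        if outside:
            probs = master.probs[outside] / master.probs[outside].sum()
            draws = rng.multinomial(n_fresh, probs)
            for i, c in zip(outside, draws):
                if c > 0:
                    counts[master.keys[i]] = counts.get(master.keys[i], 0) + int(c)
        else:  # original exhausts the master support; fall back to full master
            draws = rng.multinomial(n_fresh, master.probs)
            for k, c in zip(master.keys, draws):
                if c > 0:
                    counts[k] = counts.get(k, 0) + int(c)
    return IndelProfile(sample_id=sample_id, counts=counts)


@dataclass
class SimulationConfig:
    """Conditions of the scalability study."""

    library_sizes: Tuple[int, ...] = DEFAULT_LIBRARY_SIZES
    reads_per_puf: int = 1000
    replicate_overlap: float = DEFAULT_REPLICATE_OVERLAP
    penalty: str = "l2"
    C: float = 1.0
    insertion_size_range: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.library_sizes):
            raise ValueError("library sizes must be >= 2")
        if not 0 < self.replicate_overlap <= 1:
            raise ValueError("replicate_overlap must be in (0, 1]")


def scaling_experiment(
    master: MasterDistribution,
    config: SimulationConfig = SimulationConfig(),
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> pd.DataFrame:
    """Average replicate-classification accuracy versus library size.

    For each library size: sample that many PUFs from the master, build one
    overlap-controlled replicate per PUF, train the logistic-regression
    authenticator on the originals, classify the replicates, and record the
    average accuracy. Returns a table with columns ``library_size`` and
    ``accuracy``.
    """
    rng = _rng(seed)
    if config.insertion_size_range is not None:
        lo, hi = config.insertion_size_range
        master = master.restrict_insertion_sizes(lo, hi)
    rows = []
    for size in config.library_sizes:
        originals, replicates, groups, rep_groups = [], [], {}, {}
        for i in range(size):
            gid = f"puf{i:04d}"
            orig = sample_puf(master, config.reads_per_puf, rng, sample_id=gid)
            rep = make_replicate(
                orig, master, config.replicate_overlap, rng, sample_id=f"{gid}_r"
            )
            originals.append(orig)
            replicates.append(rep)
            groups[gid] = gid
            rep_groups[rep.sample_id] = gid
        train_lib = PUFLibrary(profiles=originals, groups=groups)
        query_lib = PUFLibrary(profiles=replicates, groups=rep_groups)
        model = train(train_lib, penalty=config.penalty, C=config.C, seed=0)
        preds = predict(model, query_lib)
        rows.append(
            {"library_size": size, "accuracy": accuracy(preds, rep_groups)}
        )
    return pd.DataFrame(rows)


def restricted_size_experiment(
    master: MasterDistribution,
    config: SimulationConfig = SimulationConfig(insertion_size_range=(3, 7)),
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> pd.DataFrame:
    """Scaling experiment with master insertions restricted to a size range
    (default 3-7 bp) before sampling."""
    if config.insertion_size_range is None:
        config = SimulationConfig(
            library_sizes=config.library_sizes,
            reads_per_puf=config.reads_per_puf,
            replicate_overlap=config.replicate_overlap,
            penalty=config.penalty,
            C=config.C,
            insertion_size_range=(3, 7),
        )
    return scaling_experiment(master, config, seed)


def summarize_scaling(table: pd.DataFrame, threshold: float = 0.95) -> Dict[str, float]:
    """Headline numbers of a scaling run: min/mean accuracy and capacity.

    Capacity is the largest library size whose average accuracy exceeds
    ``threshold`` (0 if none does).
    """
    above = table[table["accuracy"] > threshold]["library_size"]
    return {
        "min_accuracy": float(table["accuracy"].min()),
        "mean_accuracy": float(table["accuracy"].mean()),
        "max_size_above_threshold": int(above.max()) if len(above) else 0,
    }
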