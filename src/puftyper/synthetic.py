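"""Synthetic loci, repair-outcome distributions and amplicon FASTQ fixtures.

Emulates the two repair regimes at an edited locus so the whole pipeline is
testable without external sequencing data:

* ``cas9_only`` — deletion-dominant non-homologous end joining (~84% of
  events are deletions, enriched at 1-2 bp);
* ``cas9_tdt`` — TdT-augmented repair, insertion-dominant (~80% insertions,
  mostly 1-4 bp, capped at 10 bp), with inserted-base composition biased
  toward the two nucleotides flanking the cut.

Outcome frequencies follow a Zipf rank-frequency law (default exponent
1.2); ranks within each kind are ordered by the generative probability of
the event (shorter, flank-biased insertions first), so the most frequent
indels are the short flank-matching insertions seen in real TdT spectra,
and the top-20 outcomes capture well over 30% of the reads.
"""

from __future__ import annotations

import csv
import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .errors import ConfigurationError
from .indel import DELETION, INSERTION, IndelCall, apply_call, infer_single_indel
from .locus import ReferenceLocus
from .profile import IndelProfile, PUFLibrary
from .read_processing import build_read_pattern
from .simulate import MasterDistribution

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Deletion lengths 1..20, enriched at 1-2 bp as seen for Cas9-only repair.
_DELETION_LENGTH_DIST = np.array(
    [0.40, 0.22, 0.10, 0.07, 0.05, 0.04, 0.03, 0.02] + [0.07 / 12] * 12
)

# TdT insertions 1..10 bp with most of the mass on 1-4 bp.
_TDT_INSERTION_LENGTH_DIST = np.array(
    [0.30, 0.27, 0.18, 0.12, 0.05, 0.03, 0.02, 0.015, 0.01, 0.005]
)

# Rare Cas9-only insertions are almost always +1.
_CAS9_INSERTION_LENGTH_DIST = np.array(
    [0.70, 0.20, 0.10, 0, 0, 0, 0, 0, 0, 0], dtype=float
)


@dataclass
class RepairModel:
    """Stochastic model of repair outcomes and read contamination."""

    mode: str
    insertion_fraction: float
    insertion_length_dist: np.ndarray  # over lengths 1..10
    deletion_length_dist: np.ndarray  # over lengths 1..20
    flank_weight: float = 6.0  # sampling weight of flank bases in insertions
    wt_fraction: float = 0.30
    substitution_fraction: float = 0.02
    corrupted_fraction: float = 0.03
    error_rate: float = 0.001
    zipf_exponent: float = 1.2

    def __post_init__(self) -> None:
        self.insertion_length_dist = np.asarray(self.insertion_length_dist, float)
        self.deletion_length_dist = np.asarray(self.deletion_length_dist, float)
        for name, dist in (
            ("insertion_length_dist", self.insertion_length_dist),
            ("deletion_length_dist", self.deletion_length_dist),
        ):
            if abs(dist.sum() - 1.0) > 1e-9 or np.any(dist < 0):
                raise ConfigurationError(f"{name} must be a probability vector")
        fracs = (
            self.insertion_fraction,
            self.wt_fraction,
            self.substitution_fraction,
            self.corrupted_fraction,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if self.wt_fraction + self.substitution_fraction + self.corrupted_fraction >= 1:
            raise ConfigurationError("contamination fractions leave no indel reads")

    @classmethod
    def cas9_tdt(cls, **overrides) -> "RepairModel":
        """TdT-augmented repair: 80% insertions, mostly 1-4 bp."""
        kwargs = dict(
            mode="cas9_tdt",
            insertion_fraction=0.80,
            insertion_length_dist=_TDT_INSERTION_LENGTH_DIST,
            deletion_length_dist=_DELETION_LENGTH_DIST,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def cas9_only(cls, **overrides) -> "RepairModel":
        """Plain Cas9 NHEJ: 84% deletions, enriched at 1-2 bp."""
        kwargs = dict(
            mode="cas9_only",
            insertion_fraction=0.16,
            insertion_length_dist=_CAS9_INSERTION_LENGTH_DIST,
            deletion_length_dist=_DELETION_LENGTH_DIST,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def base_probs(self, flank_dinucleotide: str) -> np.ndarray:
        """Inserted-base composition conditioned on the cut-flank bases."""
        flank = set(flank_dinucleotide.upper())
        w = np.array([self.flank_weight if b in flank else 1.0 for b in BASES])
        return w / w.sum()


def generate_locus(
    length: int = 160,
    cut_flank: str = "CG",
    seed: Optional[Union[int, np.random.Generator]] = None,
    name: Optional[str] = None,
) -> ReferenceLocus:
    """Random amplicon reference with the requested dinucleotide across the cut."""
    if length < 41:
        raise ConfigurationError(
            f"amplicon length {length} cannot hold the +/-20 bp indel window"
        )
    cut_flank = cut_flank.upper()
    if len(cut_flank) != 2 or set(cut_flank) - set(BASES):
        raise ConfigurationError("cut_flank must be a dinucleotide over ACGT")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = list(rng.choice(list(BASES), size=length))
    cut_pos = length // 2
    seq[cut_pos - 1], seq[cut_pos] = cut_flank[0], cut_flank[1]
    return ReferenceLocus(
        name=name or f"synthetic_{cut_flank}", sequence="".join(seq), cut_pos=cut_pos
    )


def _greedy_rank_assignment(
    ins_keys: List[str],
    del_keys: List[str],
    insertion_fraction: float,
    zipf_exponent: float,
) -> Dict[str, float]:
    """Assign Zipf rank weights so cumulative insertion mass tracks the
    target insertion fraction as closely as the discrete ranks allow."""
    total = len(ins_keys) + len(del_keys)
    weights = np.arange(1, total + 1, dtype=float) ** (-zipf_exponent)
    out: Dict[str, float] = {}
    i = d = 0
    cum_ins = cum_tot = 0.0
    for w in weights:
        # pick the kind that keeps the cumulative insertion-mass share
        # closest to the target
        err_ins = abs((cum_ins + w) / (cum_tot + w) - insertion_fraction)
        err_del = abs(cum_ins / (cum_tot + w) - insertion_fraction)
        take_ins = i < len(ins_keys) and (d >= len(del_keys) or err_ins <= err_del)
        if take_ins:
            out[ins_keys[i]] = w
            cum_ins += w
            i += 1
        else:
            out[del_keys[d]] = w
            d += 1
        cum_tot += w
    return out


def sample_outcome_distribution(
    locus: ReferenceLocus,
    model: RepairModel,
    n_unique: int = 2000,
    seed: Optional[Union[int, np.random.Generator]] = None,
    del_window: int = 20,
    max_insertion: int = 10,
    max_draws: int = 500_000,
    stall: int = 8000,
) -> MasterDistribution:
    """Draw a heavy-tailed outcome distribution over distinct indel keys.

    Candidate events are sampled from the repair model (kind, length,
    flank-biased content, cut-overlapping deletion window), canonicalized by
    left-alignment and de-duplicated until ``n_unique`` distinct keys are
    collected or the model's outcome space is exhausted (``stall``
    consecutive draws without a new key). Within each kind, keys are ranked
    by their generative probability; Zipf weights over the global ranks set
    the final frequencies, with the insertion/deletion split tracking
    ``model.insertion_fraction``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pattern = build_read_pattern(locus, max_insertion=max_insertion, del_window=del_window)
    ref_central, cut = pattern.ref_central, pattern.cut_index
    base_probs = model.base_probs(locus.flank_dinucleotide)
    log_base = np.log(base_probs)
    with np.errstate(divide="ignore"):
        log_ins_len = np.log(model.insertion_length_dist)
        log_del_len = np.log(model.deletion_length_dist)

    ins_scores: Dict[str, float] = {}
    del_scores: Dict[str, float] = {}
    draws = 0
    since_new = 0
    batch = 4096
    while draws < max_draws and since_new < stall:
        n_found = len(ins_scores) + len(del_scores)
        if n_found >= n_unique:
            break
        kinds = rng.random(batch) < model.insertion_fraction
        n_ins = int(kinds.sum())
        ins_lens = rng.choice(
            np.arange(1, 11), size=n_ins, p=model.insertion_length_dist
        )
        flat = rng.choice(len(BASES), size=int(ins_lens.sum()), p=base_probs)
        n_del = batch - n_ins
        del_lens = rng.choice(
            np.arange(1, 21), size=n_del, p=model.deletion_length_dist
        )
        del_starts = cut - del_lens + rng.integers(0, del_lens)
        ii = di = pos = 0
        for is_ins in kinds:
            draws += 1
            if is_ins:
                s = int(ins_lens[ii])
                bases = "".join(BASES[b] for b in flat[pos : pos + s])
                pos += s
                ii += 1
                raw = IndelCall(INSERTION, 0, bases)
                score = float(log_ins_len[s - 1] + log_base[[_BASE_INDEX[b] for b in bases]].sum())
                store = ins_scores
            else:
                s = int(del_lens[di])
                p0 = int(del_starts[di])
                di += 1
                raw = IndelCall(DELETION, p0 - cut, ref_central[p0 : p0 + s])
                score = float(log_del_len[s - 1] - np.log(s))
                store = del_scores
            key = infer_single_indel(
                ref_central, apply_call(ref_central, raw, cut), cut
            ).key
            if key in store:
                since_new += 1
            else:
                store[key] = score
                since_new = 0
            if len(ins_scores) + len(del_scores) >= n_unique:
                break

    n_found = len(ins_scores) + len(del_scores)
    if n_found < n_unique:
        warnings.warn(
            f"{model.mode}: outcome space yields {n_found} unique indels "
            f"(< requested {n_unique})",
            stacklevel=2,
        )
    ins_ranked = sorted(ins_scores, key=lambda k: (-ins_scores[k], k))
    del_ranked = sorted(del_scores, key=lambda k: (-del_scores[k], k))
    weights = _greedy_rank_assignment(
        ins_ranked, del_ranked, model.insertion_fraction, model.zipf_exponent
    )
    return MasterDistribution.from_dict(weights)


def default_synthetic_master(
    seed: Optional[Union[int, np.random.Generator]] = None,
    flanks: Tuple[str, ...] = ("CG", "AT", "CT"),
    n_unique_per_locus: int = 2000,
    model: Optional[RepairModel] = None,
) -> MasterDistribution:
    """Master distribution for the simulated-PUF study.

    Mirrors how an empirical master is assembled — outcome distributions of
    independently edited loci (here one per cleavage-site dinucleotide
    context) concatenated with equal weight into one comprehensive
    distribution. Short flank-matching insertion keys recur across loci and
    pool their mass; locus-specific tails stay distinct, so the pooled
    support comfortably exceeds any single locus's.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = model or RepairModel.cas9_tdt()
    pooled: Dict[str, float] = {}
    for flank in flanks:
        locus = generate_locus(cut_flank=flank, seed=rng)
        dist = sample_outcome_distribution(locus, model, n_unique=n_unique_per_locus, seed=rng)
        for k, p in zip(dist.keys, dist.probs):
            pooled[k] = pooled.get(k, 0.0) + p / len(flanks)
    return MasterDistribution.from_dict(pooled)


def emit_fastq(
    locus: ReferenceLocus,
    distribution: MasterDistribution,
    model: RepairModel,
    n_reads: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
    path: Union[str, Path] = "reads.fastq",
    truth_path: Optional[Union[str, Path]] = None,
    del_window: int = 20,
    max_insertion: int = 10,
) -> Path:
    """Write a synthetic single-end FASTQ for one sample.

    Reads are wild-type, single-substitution, flank-broken (corrupted) or
    indel-carrying per the model's contamination fractions; indel reads
    apply a key drawn from ``distribution`` to the reference central region.
    Every base is then perturbed at ``model.error_rate``. Qualities are
    constant (the filter ignores them). With ``truth_path``, a TSV records
    each read's generating category and indel key — note the category is
    the *generating* one; sequencing errors can corrupt it downstream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pattern = build_read_pattern(locus, max_insertion=max_insertion, del_window=del_window)
    ref_central, cut = pattern.ref_central, pattern.cut_index
    left, right = pattern.left_flank, pattern.right_flank

    n_wt = int(round(model.wt_fraction * n_reads))
    n_sub = int(round(model.substitution_fraction * n_reads))
    n_corr = int(round(model.corrupted_fraction * n_reads))
    n_indel = n_reads - n_wt - n_sub - n_corr

    records: List[Tuple[str, str, str]] = []  # (sequence, category, key)
    reference = left + ref_central + right
    for _ in range(n_wt):
        records.append((reference, "wildtype", ""))
    for _ in range(n_sub):
        p = len(left) + int(rng.integers(0, len(ref_central)))
        old = reference[p]
        new = BASES[(_BASE_INDEX[old] + int(rng.integers(1, 4))) % 4]
        records.append((reference[:p] + new + reference[p + 1 :], "substitution", ""))
    for _ in range(n_corr):
        if left:
            p = int(rng.integers(0, len(left)))
        elif right:
            p = len(reference) - 1 - int(rng.integers(0, len(right)))
        else:
            p = 0
        records.append((reference[:p] + "N" + reference[p + 1 :], "corrupted", ""))
    if n_indel > 0:
        picks = rng.choice(distribution.support_size, size=n_indel, p=distribution.probs)
        for i in picks:
            key = distribution.keys[int(i)]
            call = IndelCall.from_key(key)
            central = apply_call(ref_central, call, cut)
            records.append((left + central + right, "indel", key))

    if model.error_rate > 0:
        for idx, (seq, cat, key) in enumerate(records):
            n_err = rng.binomial(len(seq), model.error_rate)
            if n_err:
                seq_list = list(seq)
                for p in rng.choice(len(seq_list), size=n_err, replace=False):
                    old = seq_list[p]
                    shift = int(rng.integers(1, 4))
                    seq_list[p] = BASES[(_BASE_INDEX.get(old, 0) + shift) % 4]
                records[idx] = ("".join(seq_list), cat, key)

    order = rng.permutation(len(records))
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rank, idx in enumerate(order):
            seq, _, _ = records[idx]
            fh.write(f"@read{rank:07d}\n{seq}\n+\n{'I' * len(seq)}\n")
    if truth_path is not None:
        with open(truth_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["read_id", "category", "indel_key"])
            for rank, idx in enumerate(order):
                _, cat, key = records[idx]
                writer.writerow([f"read{rank:07d}", cat, key])
    return path


def perturb_profile(
    profile: IndelProfile,
    drift: float,
    master: MasterDistribution,
    seed: Optional[Union[int, np.random.Generator]] = None,
    sample_id: Optional[str] = None,
) -> IndelProfile:
    """Replace a ``drift`` fraction of read mass with fresh master draws.

    Models per-passage composition drift of a cultured PUF; drift 0 returns
    the profile unchanged, drift 1 an independent master sample.
    """
    if not 0 <= drift <= 1:
        raise ValueError(f"drift must be in [0, 1], got {drift}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = profile.n_reads
    n_keep = int(round((1 - drift) * n))
    keys = sorted(profile.counts)
    kept = rng.multivariate_hypergeometric(
        np.array([profile.counts[k] for k in keys], dtype=np.int64), n_keep
    )
    counts = {k: int(c) for k, c in zip(keys, kept) if c > 0}
    n_fresh = n - n_keep
    if n_fresh > 0:
        draws = rng.multinomial(n_fresh, master.probs)
        for k, c in zip(master.keys, draws):
            if c > 0:
                counts[k] = counts.get(k, 0) + int(c)
    return IndelProfile(sample_id=sample_id or f"{profile.sample_id}_drift", counts=counts)


def simulate_background_library(
    master: MasterDistribution,
    n_groups: int = 4,
    n_replicates: int = 1,
    background_mass: float = 0.5,
    n_background: int = 30,
    n_private: int = 150,
    n_reads: int = 5000,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> PUFLibrary:
    """Library of PUF groups sharing a high-frequency indel background.

    The top ``n_background`` master keys form a shared background carrying
    ``background_mass`` of every sample's reads (the common repair outcomes
    all transfections produce); each group additionally owns a disjoint
    private key set carrying the rest. Replicates are fresh multinomial
    samples of their group's composition.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    needed = n_background + n_groups * n_private
    if needed > master.support_size:
        raise ValueError(
            f"master support {master.support_size} < required {needed} keys"
        )
    order = np.argsort(-master.probs, kind="stable")
    bg_idx = order[:n_background]
    bg_keys = [master.keys[i] for i in bg_idx]
    bg_probs = master.probs[bg_idx] / master.probs[bg_idx].sum()
    pool = list(order[n_background:])
    profiles, groups = [], {}
    for g in range(n_groups):
        pool_probs = master.probs[pool] / master.probs[pool].sum()
        chosen = rng.choice(len(pool), size=n_private, replace=False, p=pool_probs)
        priv_idx = [pool[i] for i in chosen]
        pool = [p for i, p in enumerate(pool) if i not in set(chosen)]
        priv_keys = [master.keys[i] for i in priv_idx]
        priv_probs = master.probs[priv_idx] / master.probs[priv_idx].sum()
        keys = bg_keys + priv_keys
        probs = np.concatenate(
            [background_mass * bg_probs, (1 - background_mass) * priv_probs]
        )
        gid = f"g{g}"
        for r in range(n_replicates + 1):
            sid = gid if r == 0 else f"{gid}_r{r}"
            draws = rng.multinomial(n_reads, probs)
            counts = {k: int(c) for k, c in zip(keys, draws) if c > 0}
            profiles.append(IndelProfile(sample_id=sid, counts=counts))
            groups[sid] = gid
    return PUFLibrary(profiles=profiles, groups=groups)
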