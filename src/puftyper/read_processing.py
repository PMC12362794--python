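"""Amplicon read filtering, classification and indel calling.

The filter mirrors a fixed-flank pattern match: a read is accepted only if
its 5' and 3' ends match the reference outside a flexible central region
spanning ``del_window`` bp on either side of the cut, and the central region
length may shrink by at most the window span (deletions confined to
cut +/- del_window) or grow by at most ``max_insertion`` bp. Quality scores
are ignored; the filter is purely sequence-based.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Tuple, Union

from .errors import ComplexIndelError, ConfigurationError, EmptyProfileError
from .indel import IndelCall, infer_single_indel
from .locus import ReferenceLocus
from .profile import FilterReport, IndelProfile

logger = logging.getLogger(__name__)

_DNA = set("ACGT")

# read classes
CORRUPTED = "corrupted"
WILDTYPE = "wildtype"
SUBSTITUTION_ONLY = "substitution_only"
INDEL = "indel"


@dataclass(frozen=True)
class ReadPattern:
    """Locus-specific matcher: fixed flanks around a flexible indel region."""

    left_flank: str
    ref_central: str
    right_flank: str
    max_insertion: int
    del_window: int

    @property
    def cut_index(self) -> int:
        """Position of the cut within the central region."""
        return self.del_window

    def extract_central(self, read: str) -> Optional[str]:
        """Return the read's central region, or None if the pattern fails."""
        if not read:
            return None
        n_left, n_right = len(self.left_flank), len(self.right_flank)
        if len(read) < n_left + n_right:
            return None
        if read[:n_left] != self.left_flank:
            return None
        if n_right and read[-n_right:] != self.right_flank:
            return None
        central = read[n_left : len(read) - n_right]
        delta = len(central) - len(self.ref_central)
        if delta > self.max_insertion or delta < -len(self.ref_central):
            return None
        return central


def build_read_pattern(
    locus: ReferenceLocus, max_insertion: int = 10, del_window: int = 20
) -> ReadPattern:
    """Build the fixed-flank/flexible-centre matcher for ``locus``."""
    if max_insertion < 0:
        raise ConfigurationError("max_insertion must be >= 0")
    if del_window < 1:
        raise ConfigurationError("del_window must be >= 1")
    lo, hi = locus.cut_pos - del_window, locus.cut_pos + del_window
    if lo < 0 or hi > len(locus.sequence):
        raise ConfigurationError(
            f"indel window +/-{del_window} around cut {locus.cut_pos} falls "
            f"outside the {len(locus.sequence)} bp amplicon"
        )
    return ReadPattern(
        left_flank=locus.sequence[:lo],
        ref_central=locus.sequence[lo:hi],
        right_flank=locus.sequence[hi:],
        max_insertion=max_insertion,
        del_window=del_window,
    )


def classify_read(read: str, pattern: ReadPattern) -> str:
    """Classify one read as corrupted / wildtype / substitution_only / indel."""
    if not read:
        return CORRUPTED
    read = read.upper()
    if set(read) - _DNA:
        return CORRUPTED
    central = pattern.extract_central(read)
    if central is None:
        return CORRUPTED
    if central == pattern.ref_central:
        return WILDTYPE
    if len(central) == len(pattern.ref_central):
        return SUBSTITUTION_ONLY
    return INDEL


def call_indel(read: str, pattern: ReadPattern) -> IndelCall:
    """Call the left-aligned single indel carried by an indel-class read.

    Raises :class:`ComplexIndelError` for reads whose central region cannot
    be explained by one contiguous indel (indel plus separated mismatch).
    """
    central = pattern.extract_central(read.upper())
    if central is None:
        raise ValueError("read does not match the locus pattern")
    return infer_single_indel(pattern.ref_central, central, pattern.cut_index)


def iter_fastq(path: Union[str, Path]) -> Iterator[Optional[str]]:
    """Yield read sequences from a (possibly gzipped) FASTQ file.

    A structurally broken or truncated trailing record yields ``None`` once
    (counted corrupted by the caller) and parsing stops with a warning.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            if not header.startswith("@"):
                logger.warning("%s: malformed FASTQ header; stopping", path)
                yield None
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not qual or not plus.startswith("+"):
                logger.warning("%s: truncated FASTQ record; stopping", path)
                yield None
                return
            yield seq


def profile_sample(
    reads: Union[str, Path, Iterable[Optional[str]]],
    locus: ReferenceLocus,
    *,
    sample_id: str = "sample",
    max_insertion: int = 10,
    del_window: int = 20,
) -> Tuple[IndelProfile, FilterReport]:
    """Filter and call every read of a sample, assembling its indel profile.

    ``reads`` may be a FASTQ path (plain or .gz) or any iterable of read
    strings. Counting is order-invariant. Raises
    :class:`~puftyper.errors.EmptyProfileError` when no indel read survives.
    """
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    pattern = build_read_pattern(locus, max_insertion=max_insertion, del_window=del_window)
    report = FilterReport()
    counts: dict[str, int] = {}
    for read in reads:
        report.n_total += 1
        cls = CORRUPTED if read is None else classify_read(read, pattern)
        if cls == INDEL:
            try:
                call = call_indel(read, pattern)
            except ComplexIndelError:
                report.n_corrupted += 1
                report.n_complex += 1
                continue
            counts[call.key] = counts.get(call.key, 0) + 1
            report.n_indel += 1
        elif cls == WILDTYPE:
            report.n_wildtype += 1
        elif cls == SUBSTITUTION_ONLY:
            report.n_substitution_only += 1
        else:
            report.n_corrupted += 1
    report.validate()
    if not counts:
        raise EmptyProfileError(
            f"sample {sample_id!r}: no indel reads survive filtering "
            f"({report.n_total} reads total)"
        )
    return IndelProfile(sample_id=sample_id, counts=counts), report
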