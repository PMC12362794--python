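"""Canonical indel calls and their string keys.

An :class:`IndelCall` records one repair outcome relative to the cut site:
an insertion of ``bases`` at ``offset`` (0 = at the cut), or a deletion of
the reference ``bases`` starting at ``offset``. Calls are canonicalized by
left-alignment so that identical biological events collapse to one key
across samples; keys are plain strings like ``"I+0:GG"`` or ``"D-1:CG"``
with a deterministic total order for tie-breaking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Tuple

from .errors import ComplexIndelError

INSERTION = "I"
DELETION = "D"

_KEY_RE = re.compile(r"^([ID])([+-]\d+):([ACGT]+)$")


@dataclass(frozen=True, order=True)
class IndelCall:
    """One canonical (left-aligned) repair outcome relative to the cut."""

    kind: str  # INSERTION or DELETION
    offset: int  # leftmost-aligned start, relative to cut_pos
    bases: str  # inserted bases, or the deleted reference bases

    def __post_init__(self) -> None:
        if self.kind not in (INSERTION, DELETION):
            raise ValueError(f"kind must be 'I' or 'D', got {self.kind!r}")
        if not self.bases or set(self.bases) - set("ACGT"):
            raise ValueError(f"bases must be non-empty over ACGT, got {self.bases!r}")

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def key(self) -> str:
        return f"{self.kind}{self.offset:+d}:{self.bases}"

    @classmethod
    def from_key(cls, key: str) -> "IndelCall":
        m = _KEY_RE.match(key)
        if m is None:
            raise ValueError(f"malformed indel key {key!r}")
        return cls(kind=m.group(1), offset=int(m.group(2)), bases=m.group(3))


def key_sort_key(key: str) -> Tuple[str, int, str]:
    """Deterministic total order over indel keys: (kind, offset, bases)."""
    call = IndelCall.from_key(key)
    return (call.kind, call.offset, call.bases)


def apply_call(ref_central: str, call: IndelCall, cut_index: int) -> str:
    """Apply ``call`` to the central reference region; inverse of calling.

    ``cut_index`` is the position of the cut within ``ref_central`` (i.e. the
    deletion half-window size when the central region is cut +/- window).
    """
    p = cut_index + call.offset
    if call.kind == INSERTION:
        if not (0 <= p <= len(ref_central)):
            raise ValueError("insertion point outside central region")
        return ref_central[:p] + call.bases + ref_central[p:]
    if not (0 <= p and p + call.length <= len(ref_central)):
        raise ValueError("deletion window outside central region")
    if ref_central[p : p + call.length] != call.bases:
        raise ValueError("deletion bases do not match the reference")
    return ref_central[:p] + ref_central[p + call.length :]


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[len(a) - 1 - i] == b[len(b) - 1 - i]:
        i += 1
    return i


def infer_single_indel(ref_central: str, obs_central: str, cut_index: int) -> IndelCall:
    """Infer the single left-aligned indel turning ``ref_central`` into
    ``obs_central``.

    Raises :class:`ComplexIndelError` when the two regions cannot be related
    by one contiguous insertion or deletion (e.g. an indel plus a separated
    substitution), and :class:`ValueError` when the lengths are equal.
    """
    d = len(obs_central) - len(ref_central)
    if d == 0:
        raise ValueError("regions have equal length; not an indel")
    lcp = _lcp(ref_central, obs_central)
    lcs = _lcs(ref_central, obs_central)
    if d > 0:
        # insertion of d bases: leftmost placement p in
        # [max(0, len(ref) - lcs), lcp]
        p = max(0, len(ref_central) - lcs)
        if p > lcp:
            raise ComplexIndelError("no single-insertion alignment")
        return IndelCall(INSERTION, p - cut_index, obs_central[p : p + d])
    # deletion of -d reference bases: leftmost p in [max(0, len(obs) - lcs), lcp]
    p = max(0, len(obs_central) - lcs)
    if p > lcp:
        raise ComplexIndelError("no single-deletion alignment")
    return IndelCall(DELETION, p - cut_index, ref_central[p : p - d])


def canonicalize(ref_central: str, call: IndelCall, cut_index: int) -> IndelCall:
    """Return the left-aligned canonical form of ``call``."""
    return infer_single_indel(ref_central, apply_call(ref_central, call, cut_index), cut_index)
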