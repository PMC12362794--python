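"""Reference locus: the amplicon sequence and its annotated Cas9 cut site.

Coordinates are 0-based and half-open throughout. The blunt SpCas9 cut falls
between ``cut_pos - 1`` and ``cut_pos``; the two bases flanking the cut
(``sequence[cut_pos-1]`` and ``sequence[cut_pos]``) are the cleavage-site
dinucleotide that biases TdT insertion composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

from .errors import ConfigurationError

_DNA = set("ACGT")

#: SpCas9 cuts 3 bp 5' of the PAM; used to derive cut_pos from a protospacer.
CAS9_CUT_OFFSET_FROM_PAM = 3


@dataclass(frozen=True)
class ReferenceLocus:
    """An amplicon reference with an annotated cut site.

    Parameters
    ----------
    name : str
        Label for the locus (e.g. ``"AAVS1"``).
    sequence : str
        Expected amplicon sequence over {A, C, G, T}.
    cut_pos : int
        0-based index of the first base 3' of the blunt cut.
    protospacer_span : tuple of (int, int), optional
        Half-open interval of the protospacer on ``sequence``.
    pam_side : {"3prime", "5prime"}, optional
        Side of the protospacer carrying the PAM (SpCas9: 3').
    """

    name: str
    sequence: str
    cut_pos: int
    protospacer_span: Optional[Tuple[int, int]] = None
    pam_side: str = "3prime"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq or set(seq) - _DNA:
            raise ConfigurationError(
                f"locus {self.name!r}: sequence must be non-empty over ACGT"
            )
        if not (20 <= self.cut_pos <= len(seq) - 20):
            raise ConfigurationError(
                f"locus {self.name!r}: cut_pos {self.cut_pos} leaves no room for "
                f"the +/-20 bp indel window in a {len(seq)} bp amplicon"
            )
        if self.protospacer_span is not None:
            a, b = self.protospacer_span
            if not (0 <= a < b <= len(seq)):
                raise ConfigurationError(
                    f"locus {self.name!r}: protospacer_span {self.protospacer_span} "
                    "outside sequence"
                )

    @property
    def flank_dinucleotide(self) -> str:
        """The two bases immediately flanking the blunt cut."""
        return self.sequence[self.cut_pos - 1 : self.cut_pos + 1]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


def cut_pos_from_protospacer(
    sequence: str, protospacer: str, pam_side: str = "3prime"
) -> int:
    """Locate ``protospacer`` on the forward strand and derive the blunt cut.

    SpCas9 cleaves 3 bp 5' of the PAM, i.e. between positions 17 and 18 of a
    20-nt protospacer with a 3' PAM.
    """
    sequence = sequence.upper()
    protospacer = protospacer.upper()
    start = sequence.find(protospacer)
    if start < 0:
        raise ConfigurationError("protospacer not found on the forward strand")
    if sequence.find(protospacer, start + 1) >= 0:
        raise ConfigurationError("protospacer occurs more than once in the amplicon")
    if pam_side == "3prime":
        return start + len(protospacer) - CAS9_CUT_OFFSET_FROM_PAM
    if pam_side == "5prime":
        return start + CAS9_CUT_OFFSET_FROM_PAM
    raise ConfigurationError(f"unknown pam_side {pam_side!r}")
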