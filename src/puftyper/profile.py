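"""Per-sample indel frequency profiles — the PUF signatures — and libraries
of profiles with replicate-group structure."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

import pandas as pd

from .errors import EmptyProfileError, PufTyperError
from .indel import IndelCall, key_sort_key


@dataclass
class IndelProfile:
    """Frequency table over canonical indel keys for one sample."""

    sample_id: str
    counts: Dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("all indel counts must be >= 1")

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def frequency(self, key: str) -> float:
        return self.counts.get(key, 0) / self.n_reads

    def frequencies(self) -> Dict[str, float]:
        n = self.n_reads
        return {k: c / n for k, c in self.counts.items()}

    def require_nonempty(self) -> "IndelProfile":
        if not self.counts:
            raise EmptyProfileError(f"profile {self.sample_id!r} has no indel reads")
        return self

    def to_frame(self) -> pd.DataFrame:
        n = self.n_reads
        rows = []
        for key in sorted(self.counts, key=key_sort_key):
            call = IndelCall.from_key(key)
            rows.append(
                {
                    "indel_key": key,
                    "kind": call.kind,
                    "offset": call.offset,
                    "bases": call.bases,
                    "length": call.length,
                    "count": self.counts[key],
                    "frequency": self.counts[key] / n,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "indel_key",
                "kind",
                "offset",
                "bases",
                "length",
                "count",
                "frequency",
            ],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, sample_id: str | None = None) -> "IndelProfile":
        df = pd.read_csv(path, sep="\t")
        counts = dict(zip(df["indel_key"], df["count"].astype(int)))
        return cls(sample_id=sample_id or Path(path).stem, counts=counts)


@dataclass
class FilterReport:
    """Partition of a sample's reads by filtering outcome.

    ``n_complex`` counts reads rejected because they carried more than one
    separated difference; they are a subset of ``n_corrupted``, so the four
    main categories always sum to ``n_total``.
    """

    n_total: int = 0
    n_corrupted: int = 0
    n_wildtype: int = 0
    n_substitution_only: int = 0
    n_indel: int = 0
    n_complex: int = 0

    def validate(self) -> None:
        if (
            self.n_corrupted + self.n_wildtype + self.n_substitution_only + self.n_indel
            != self.n_total
        ):
            raise PufTyperError("filter report categories do not sum to n_total")

    def to_dict(self) -> Dict[str, int]:
        return {
            "n_total": self.n_total,
            "n_corrupted": self.n_corrupted,
            "n_wildtype": self.n_wildtype,
            "n_substitution_only": self.n_substitution_only,
            "n_indel": self.n_indel,
            "n_complex": self.n_complex,
        }


@dataclass
class PUFLibrary:
    """A set of profiles with replicate-group labels.

    Samples sharing a group label are intra-PUF replicates (technical
    repeats, freeze-thaw counterparts, passages); samples from different
    groups are inter-PUF.
    """

    profiles: List[IndelProfile]
    groups: Dict[str, str]

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        missing = [i for i in ids if i not in self.groups]
        if missing:
            raise ValueError(f"profiles without a group label: {missing}")

    @property
    def sample_ids(self) -> List[str]:
        return [p.sample_id for p in self.profiles]

    def get(self, sample_id: str) -> IndelProfile:
        for p in self.profiles:
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)

    def group_of(self, sample_id: str) -> str:
        return self.groups[sample_id]

    def replicates_of(self, sample_id: str) -> List[str]:
        g = self.groups[sample_id]
        return [
            s for s in self.sample_ids if s != sample_id and self.groups[s] == g
        ]

    def map_profiles(self, fn) -> "PUFLibrary":
        """Apply ``fn`` to every profile, keeping sample ids and groups."""
        return PUFLibrary(
            profiles=[fn(p) for p in self.profiles],
            groups=dict(self.groups),
        )


def library_from_profiles(
    profiles: Iterable[IndelProfile], groups: Mapping[str, str]
) -> PUFLibrary:
    return PUFLibrary(profiles=list(profiles), groups=dict(groups))
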