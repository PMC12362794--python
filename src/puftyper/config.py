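"""Locus configuration (YAML) and sample manifest (TSV) loading."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd
import yaml

from .errors import ConfigurationError
from .locus import ReferenceLocus, cut_pos_from_protospacer


def _read_fasta_sequence(path: Path) -> str:
    lines = path.read_text().splitlines()
    seq = [ln.strip() for ln in lines if ln and not ln.startswith(">")]
    if not seq:
        raise ConfigurationError(f"no sequence in FASTA {path}")
    return "".join(seq).upper()


def load_locus(path: str | Path) -> Tuple[ReferenceLocus, Dict]:
    """Load a locus YAML.

    Keys: ``name``; ``sequence`` (inline) or ``fasta`` (file path, relative
    to the YAML); ``cut_pos`` or ``protospacer``; optional ``max_insertion``
    (default 10) and ``del_window`` (default 20).
    Returns the locus and the filtering options.
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: locus config must be a mapping")
    if "sequence" in cfg:
        sequence = str(cfg["sequence"]).upper()
    elif "fasta" in cfg:
        sequence = _read_fasta_sequence(path.parent / cfg["fasta"])
    else:
        raise ConfigurationError(f"{path}: need 'sequence' or 'fasta'")
    if "cut_pos" in cfg:
        cut_pos = int(cfg["cut_pos"])
    elif "protospacer" in cfg:
        cut_pos = cut_pos_from_protospacer(
            sequence, str(cfg["protospacer"]), cfg.get("pam_side", "3prime")
        )
    else:
        raise ConfigurationError(f"{path}: need 'cut_pos' or 'protospacer'")
    locus = ReferenceLocus(
        name=str(cfg.get("name", path.stem)), sequence=sequence, cut_pos=cut_pos
    )
    options = {
        "max_insertion": int(cfg.get("max_insertion", 10)),
        "del_window": int(cfg.get("del_window", 20)),
    }
    return locus, options


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load a sample manifest TSV with columns sample_id, fastq_path, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "fastq_path", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"manifest {path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ConfigurationError(f"manifest {path}: duplicate sample_ids")
    return df
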