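"""FASTA input, TSV output with reproducibility metadata, and config files.

Output tables are plain TSV preceded by a ``#``-prefixed metadata header
(seed, config digest, parameter-table version, tool version). The header
contains nothing volatile, so a rerun with the same seed and config is
byte-identical. Infinite free energies are serialized as the literal
``inf``; probabilities are printed at 10 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .sequence import RnaSequence, SequenceError


class FastaError(ValueError):
    pass


def read_fasta(path, convert_t: bool = True) -> list:
    """Read a FASTA file into RnaSequence records, preserving order.

    DNA input (T) is transliterated to U with a warning by default; pass
    convert_t=False to reject it. An empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    records = []
    try:
        with open(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                try:
                    records.append(
                        RnaSequence.from_string(rec.id, str(rec.seq), convert_t=convert_t)
                    )
                except SequenceError as exc:
                    raise FastaError(f"{path}: record {rec.id!r}: {exc}") from exc
    except ValueError as exc:
        if isinstance(exc, FastaError):
            raise
        raise FastaError(f"{path}: malformed FASTA: {exc}") from exc
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(path, sequences) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n{s.bases}\n")


def config_digest(config: dict) -> str:
    """Stable short digest of a configuration mapping (key order ignored)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class RunMetadata:
    """Provenance block written at the top of every output table."""

    seed: int
    config_digest: str
    params_version: str
    tool_version: str = __version__

    def header_lines(self) -> list:
        return [
            f"# seed: {self.seed}",
            f"# config_digest: {self.config_digest}",
            f"# params_version: {self.params_version}",
            f"# tool_version: {self.tool_version}",
        ]


def write_table(path, df: pd.DataFrame, meta: RunMetadata | None = None) -> None:
    """Write a tidy TSV with a metadata header; floats at 10 significant
    digits, +inf as the literal ``inf`` (lossless round trip)."""
    with open(path, "w") as fh:
        if meta is not None:
            fh.write("\n".join(meta.header_lines()) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (metadata lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def load_config(path) -> dict:
    """Read a JSON config file mirroring ExperimentConfig keys."""
    with open(path) as fh:
        return json.load(fh)
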