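"""Shared readers/writers and pipeline configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
]


@dataclass
class PipelineConfig:
    """Stage parameters with defaults matching the standard analysis values."""

    window: int = 30
    step: int = 15
    background: int = 3000
    oligo_len: int = 40
    lfc: float = 1.0
    p_value: float = 0.01
    threshold: float = 2.0
    min_consecutive: int = 2
    loss_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.type in ("int",) and not isinstance(value, int):
                raise ValueError(f"config key {f.name!r} must be an integer, got {value!r}")
            if f.type in ("float",):
                if isinstance(value, bool) or not isinstance(value, (int, float)):
                    raise ValueError(f"config key {f.name!r} must be a number, got {value!r}")
                setattr(self, f.name, float(value))
        if self.window > self.background:
            raise ValueError("window must not exceed background")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def provenance(self) -> dict:
        from . import __version__

        return {"config": self.to_dict(), "seed": self.seed, "version": __version__}


def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON config; unknown keys are rejected by name."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def read_fasta(path) -> dict[str, str]:
    """Named sequences from FASTA, uppercased; duplicate names are an error."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(records, path) -> None:
    """Write a DataFrame or list of dicts/dataclasses as TSV."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
        frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
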