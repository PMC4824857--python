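"""File formats: FASTA, TSV tables, transition lists, config and manifests.

Canonical table dialect is TSV (tab-separated, UTF-8, '.' decimal); every
table carries a header row with a stable field order, and read(write(x)) = x
for all table types.  Peptide coordinates are 1-based inclusive.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .design import AMINO_ACIDS

__all__ = [
    "AbundanceTable", "read_fasta",
    "read_peak_table", "write_peak_table",
    "read_table", "write_table",
    "read_abundance_table", "write_abundance_table",
    "load_config", "save_config", "write_manifest", "log",
]

PEAK_TABLE_COLUMNS = [
    "peptide_id", "protein_group_id", "replicate", "spike_label",
    "spike_amount_mol", "light_area", "heavy_area", "sn", "q_value",
]


@dataclass
class AbundanceTable:
    """One quantitative proteome: per-protein abundances in a declared unit."""

    dataset_id: str
    abundances: pd.Series        # indexed by protein/group id
    unit: str = "cpc"            # 'cpc' | 'ppm' | 'arbitrary'
    metadata: dict | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("cpc", "ppm", "arbitrary"):
            raise ValueError(f"unknown unit {self.unit!r}")
        s = pd.Series(self.abundances).astype(float)
        if s.index.duplicated().any():
            raise ValueError("duplicate protein ids in dataset")
        if (s.dropna() < 0).any():
            raise ValueError("abundances must be >= 0")
        self.abundances = s


def read_fasta(path) -> list[tuple[str, str]]:
    """Read protein sequences: (first header token, uppercased sequence).

    Whitespace and gap characters are stripped; empty files, records without
    sequence and non-amino-acid characters raise ``ValueError``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).replace("-", "").replace(".", "").upper()
        seq = "".join(seq.split())
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has no sequence")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} has non-amino-acid characters {sorted(bad)}"
            )
        out.append((rec.id, seq))
    return out


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_peak_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in PEAK_TABLE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> pd.DataFrame:
    """Read a replicate-level peak table, validating schema and ranges.

    Mandatory columns are listed in :data:`PEAK_TABLE_COLUMNS`.  A missing
    light area is allowed (Type-B candidate); negative areas and q-values
    outside [0, 1] are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")
    for col in ("light_area", "heavy_area"):
        if (df[col].dropna() < 0).any():
            raise ValueError(f"{path}: negative values in {col}")
    q = df["q_value"].dropna()
    if ((q < 0) | (q > 1)).any():
        raise ValueError(f"{path}: q-values must lie in [0, 1]")
    if "ratio" not in df.columns:
        df["ratio"] = df["light_area"] / df["heavy_area"]
    return df


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = pd.DataFrame({
        "protein_id": table.abundances.index,
        "abundance": table.abundances.to_numpy(),
    })
    df.insert(0, "dataset_id", table.dataset_id)
    df["unit"] = table.unit
    df.to_csv(path, sep="\t", index=False)


def read_abundance_table(path) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t")
    need = {"dataset_id", "protein_id", "abundance", "unit"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return AbundanceTable(
        dataset_id=str(df["dataset_id"].iloc[0]),
        abundances=pd.Series(df["abundance"].to_numpy(), index=df["protein_id"]),
        unit=str(df["unit"].iloc[0]),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_manifest(out_dir, *, command: str, config: dict, seed: int | None) -> Path:
    """Run manifest for reproducibility: command, config hash, seed, outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "command": command,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def log(msg: str) -> None:
    print(msg, file=sys.stderr)
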