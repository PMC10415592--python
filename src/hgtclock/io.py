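"""Tabular writers, truth sidecars, and run configuration.

All tables are tab-separated with a single header row, ``.`` for
missing values, and floating point printed at 6 significant digits.
Ground-truth sidecars are flat ``key\\tvalue`` text files.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

__all__ = [
    "write_table",
    "write_truth",
    "read_truth",
    "write_tree_list",
    "load_config",
    "effective_config",
    "setup_logging",
]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")


def write_truth(values: Mapping[str, Any], path: str | Path) -> None:
    """Flat key/value ground-truth sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in values.items():
            if isinstance(val, float):
                fh.write(f"{key}\t{val:.6g}\n")
            else:
                fh.write(f"{key}\t{val}\n")


def read_truth(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, _, val = line.partition("\t")
            out[key] = val
    return out


def write_tree_list(newicks: list[str], path: str | Path) -> None:
    """One Newick tree per line, no translate tables."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for nwk in newicks:
            fh.write(nwk.rstrip() + "\n")


def load_config(path: str | Path | None, section: str) -> dict[str, Any]:
    """One flat section of a YAML run-configuration file."""
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must be a mapping of sections")
    sect = data.get(section, {})
    if not isinstance(sect, dict):
        raise ValueError(f"config section {section!r} must be a mapping")
    return sect


def effective_config(
    params: Mapping[str, Any], outdir: str | Path, subcommand: str
) -> Path:
    """Dump the effective parameters of a run for provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{subcommand}.config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump({subcommand: dict(params)}, fh, sort_keys=True)
    return path


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(message)s",
        force=True,
    )
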