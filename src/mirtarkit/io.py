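"""FASTA/TSV/config plumbing shared by all pipeline stages.

Every TSV written by the package starts with comment lines recording the
tool version, a hash of the effective configuration, and the seed, so any
output file is traceable to the run that produced it.  TSVs use a header
row, tab delimiters, UTF-8, and '.' for missing values.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .duplex import ScoringParams

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "params_from_dict",
    "load_config",
    "config_hash",
    "write_manifest",
]


class ParseError(ValueError):
    """Malformed input file; the message carries file and record context."""


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a FASTA file into (id, sequence) pairs.

    Line wrapping and CRLF endings are accepted and normalised; a
    header-only record (no sequence) is a parse error.
    """
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).strip()
            if not seq:
                raise ParseError(
                    f"{path}: record {rec.id!r} has a header but no sequence"
                )
            records.append((rec.id, seq))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: list[tuple[str, str]], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _header_lines(meta: dict | None) -> str:
    lines = [f"# mirtarkit {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a table as commented-header TSV ('.' for missing)."""
    path = Path(path)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep=".")
    path.write_text(_header_lines(meta) + buf.getvalue())


def read_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a commented-header TSV back into a DataFrame."""
    try:
        return pd.read_csv(
            Path(path), sep="\t", comment="#", na_values=".", **kwargs
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def params_from_dict(cfg: dict) -> ScoringParams:
    """Build scoring parameters from a config mapping.

    Recognised keys: mode ("standard" | "literal_paper"), max_total,
    total_inclusive, critical_region ([lo, hi]), critical_max,
    critical_strict, half_penalty_pairs (list of 2-base strings, e.g.
    ["GU"]).  Unknown keys are a config error.
    """
    cfg = dict(cfg)
    mode = cfg.pop("mode", "standard")
    known = {
        "max_total", "total_inclusive", "critical_region",
        "critical_max", "critical_strict", "half_penalty_pairs",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown scoring-config keys: {sorted(unknown)}")
    if "critical_region" in cfg:
        cfg["critical_region"] = tuple(cfg["critical_region"])
    if "half_penalty_pairs" in cfg:
        cfg["half_penalty_pairs"] = frozenset(
            tuple(sorted(p.upper().replace("T", "U"))) for p in cfg["half_penalty_pairs"]
        )
    if mode == "standard":
        return ScoringParams.standard(**cfg)
    if mode == "literal_paper":
        return ScoringParams.literal_paper(**cfg)
    raise ValueError(f"unknown scoring mode {mode!r}")


def load_config(path) -> dict:
    """Load a JSON or YAML config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def config_hash(obj) -> str:
    """Short stable hash of an effective configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(out_dir, artifacts: list[Path], meta: dict | None = None) -> Path:
    """Write manifest.json listing every artifact with a sha256 checksum."""
    out_dir = Path(out_dir)
    entries = []
    for p in artifacts:
        p = Path(p)
        entries.append(
            {
                "path": str(p.relative_to(out_dir)) if p.is_relative_to(out_dir) else str(p),
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                "bytes": p.stat().st_size,
            }
        )
    manifest = {"version": __version__, **(meta or {}), "artifacts": entries}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
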