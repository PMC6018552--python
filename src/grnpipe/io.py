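"""Text-format readers/writers shared by the CLI stages.

Every table written by the pipeline starts with ``#``-prefixed header lines
recording the tool version, the seed and a digest of the configuration, so
reruns can be audited byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def config_digest(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def header_lines(meta: dict | None = None) -> list[str]:
    lines = [f"# grnpipe {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    return lines


def write_table(frame: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines(meta):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", comment="#", **kwargs)


def write_plate(plate: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(plate, path, meta)


def read_plate(path) -> pd.DataFrame:
    plate = read_table(path)
    plate["is_reference"] = plate["is_reference"].astype(bool)
    return plate


def write_fasta(records, path) -> None:
    from Bio import SeqIO

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_coexpression(db, path, meta: dict | None = None) -> None:
    write_table(db.to_frame(), path, meta)


def read_coexpression(path):
    from .stepwise import CoexpressionDB

    return CoexpressionDB.from_frame(read_table(path))
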