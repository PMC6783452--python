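"""Interchange formats: headered TSV tables, FASTA sequences, JSON configs.

Every table written by the pipeline is seed-stamped through the resolved
config snapshot emitted next to it, so a run is fully determined by the
snapshot.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, List, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .libdesign import OligoVariant, SpliceContext


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_library_fasta(variants: Iterable[OligoVariant], path) -> None:
    records = [
        SeqRecord(Seq(v.full_sequence), id=v.variant_id, description="")
        for v in variants
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def write_design_manifest(variants: Iterable[OligoVariant], path) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "barcode": v.barcode,
            "library": v.library,
            "subset": v.subset,
            "context_id": v.context_id,
            "variable_region": v.variable_region,
            "recipe": json.dumps(v.recipe, default=str),
        }
        for v in variants
    ]
    write_tsv(pd.DataFrame(rows), path)


def read_contexts(fasta_path, manifest_path) -> List[SpliceContext]:
    """Read contexts from a FASTA plus a manifest TSV with columns
    context_id, splicing_type, anchors (comma-separated), frame."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    manifest = read_tsv(manifest_path)
    out = []
    for _, row in manifest.iterrows():
        out.append(
            SpliceContext(
                context_id=row["context_id"],
                splicing_type=row["splicing_type"],
                sequence=seqs[row["context_id"]],
                splice_site_positions=[int(x) for x in str(row["anchors"]).split(",")],
                reading_frame_offset=int(row.get("frame", 0)),
            )
        )
    return out


def write_config_snapshot(config, path) -> None:
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, default=str, sort_keys=True)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_output_manifest(paths: Mapping[str, str], path) -> None:
    rows = [
        {"output": name, "path": str(p), "sha256": file_checksum(p)}
        for name, p in paths.items()
    ]
    write_tsv(pd.DataFrame(rows), path)
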