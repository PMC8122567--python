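"""Readers and writers for the pipeline's on-disk artifacts.

Tabular artifacts are plain TSV/CSV with a leading schema-version comment
line so downstream stages can detect format drift; sequences go through
FASTA via Biopython with record IDs ``event_id|region``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import REGIONS, SpliceEvent

SCHEMA_VERSION = 1
SCHEMA_HEADER = f"# splicescreen schema={SCHEMA_VERSION}"

__all__ = [
    "SCHEMA_HEADER",
    "write_table",
    "read_table",
    "write_events",
    "read_events",
    "write_sequences",
    "read_sequences",
    "write_config_file",
    "read_config_file",
]


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a DataFrame with the schema-version header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def write_events(events: list[SpliceEvent], path: str | Path) -> None:
    """BED-like TSV, one row per region (chrom, start, end, name, score,
    strand, event_id, category, region)."""
    rows = []
    for ev in events:
        for region in REGIONS:
            s, e = ev.region(region)
            rows.append(
                {
                    "chrom": ev.chrom,
                    "start": s,
                    "end": e,
                    "name": f"{ev.event_id}|{region}",
                    "score": 0,
                    "strand": ev.strand,
                    "event_id": ev.event_id,
                    "gene": ev.gene,
                    "category": ev.category,
                    "region": region,
                }
            )
    write_table(pd.DataFrame(rows), path)


def read_events(path: str | Path) -> list[SpliceEvent]:
    df = read_table(path)
    events = []
    for event_id, grp in df.groupby("event_id", sort=True):
        by_region = grp.set_index("region")
        iv = {r: (int(by_region.loc[r, "start"]), int(by_region.loc[r, "end"])) for r in REGIONS}
        first = grp.iloc[0]
        events.append(
            SpliceEvent(
                event_id=str(event_id),
                category=str(first["category"]),
                gene=str(first["gene"]),
                chrom=str(first["chrom"]),
                strand=str(first["strand"]),
                upstream_flank=iv["upstream_flank"],
                cassette_region=iv["cassette"],
                downstream_flank=iv["downstream_flank"],
            )
        )
    return events


def write_sequences(sequences: dict[str, dict[str, str]], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{event_id}|{region}", description="")
        for event_id, regions in sequences.items()
        for region, seq in regions.items()
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def read_sequences(path: str | Path) -> dict[str, dict[str, str]]:
    sequences: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        event_id, _, region = rec.id.partition("|")
        sequences.setdefault(event_id, {})[region] = str(rec.seq).upper()
    return sequences


def write_config_file(config: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# splicescreen config schema={SCHEMA_VERSION}\n")
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config_file(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
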