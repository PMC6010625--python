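"""Tabular and sequence I/O.

All intermediates are TSV (diffable in tests); reads can also be exchanged
as FASTQ with ids carrying ``sample|locus`` provenance, and per-allele
consensus sequences as FASTA.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class InputError(ValueError):
    pass


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path, required=(), name="table") -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "allele": str,
                                                "ce_name": str, "length_name": str})
    except Exception as exc:
        raise InputError(f"cannot read {name} {path}: {exc}") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise InputError(f"{name} {path} lacks columns {sorted(missing)}")
    return df


def read_read_table(path) -> pd.DataFrame:
    """Read table TSV: sample, locus, sequence, count."""
    df = read_tsv(path, required=("sample", "locus", "sequence", "count"),
                  name="read table")
    df["count"] = df["count"].astype(int)
    return df


def read_ce_profile(path) -> pd.DataFrame:
    return read_tsv(path, required=("sample", "locus", "allele"), name="CE profile")


def read_profile(path) -> pd.DataFrame:
    return read_tsv(path, required=("sample", "locus", "mps_name", "length_name"),
                    name="profile")


# --------------------------------------------------------------------------- #
# FASTA / FASTQ
# --------------------------------------------------------------------------- #
def _parse_read_id(rid: str):
    parts = rid.split("|")
    if len(parts) < 2:
        raise InputError(
            f"read id {rid!r} lacks 'sample|locus' provenance fields")
    return parts[0], parts[1]


def read_fastq_reads(path) -> pd.DataFrame:
    """FASTQ with ids 'sample|locus|n' -> read table (counts aggregated)."""
    rows = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        sample, locus = _parse_read_id(rec.id)
        key = (sample, locus, str(rec.seq).upper())
        rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [{"sample": s, "locus": l, "sequence": q, "count": c}
         for (s, l, q), c in sorted(rows.items())])


def write_fastq_reads(read_table: pd.DataFrame, path) -> None:
    """Expand a read table (sample, locus, sequence, count) to FASTQ."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = []
    i = 0
    for _, row in read_table.iterrows():
        for _ in range(int(row["count"])):
            i += 1
            rec = SeqRecord(
                Seq(row["sequence"]),
                id=f"{row['sample']}|{row['locus']}|{i}",
                description="",
            )
            rec.letter_annotations["phred_quality"] = [40] * len(rec)
            records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fasta_sequences(path):
    """FASTA of per-allele consensus sequences, ids 'sample|locus[|n]'.
    Yields (sample, locus, sequence)."""
    for rec in SeqIO.parse(str(path), "fasta"):
        sample, locus = _parse_read_id(rec.id)
        yield sample, locus, str(rec.seq).upper()
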