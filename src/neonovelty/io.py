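"""TSV / FASTA readers and writers shared by the CLI.

Interchange conventions: tab-separated UTF-8 with a header row and "." for
missing values; standard multi-record FASTA for sequence databases, with
the record id taken as the protein id and an optional "gene=<id>" token in
the description line taken as the gene id (defaults to the protein id).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = "."

_GENE_TOKEN = re.compile(r"\bgene=(\S+)")


def read_fasta_records(path) -> list[tuple[str, str, str]]:
    """FASTA -> list of (protein_id, gene_id, sequence)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _GENE_TOKEN.search(rec.description)
        gene = m.group(1) if m else rec.id
        records.append((rec.id, gene, str(rec.seq).upper()))
    return records


def write_fasta_records(records: list[tuple[str, str, str]], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=pid, description=f"gene={gid}")
        for pid, gid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True)


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=MISSING)


class VariantInputError(ValueError):
    pass


def read_variants(path, proteome_path=None) -> pd.DataFrame:
    """Missense variant TSV -> frame with gene, protein_position, ref_aa,
    alt_aa, protein_seq.

    Each row supplies protein_seq directly or a protein_id resolved
    against the proteome FASTA.
    """
    frame = read_tsv(path)
    required = {"gene", "protein_position", "ref_aa", "alt_aa"}
    missing = required - set(frame.columns)
    if missing:
        raise VariantInputError(f"variant TSV lacks column(s) {sorted(missing)}")
    if "protein_seq" in frame.columns and frame["protein_seq"].notna().all():
        return frame
    if "protein_id" not in frame.columns:
        raise VariantInputError(
            "variant TSV needs either a full protein_seq column or a protein_id column"
        )
    if proteome_path is None:
        raise VariantInputError("protein_id rows require a proteome FASTA")
    by_id = {pid: seq for pid, _, seq in read_fasta_records(proteome_path)}
    seqs = []
    for row in frame.itertuples(index=False):
        seq = getattr(row, "protein_seq", None)
        if isinstance(seq, str) and seq:
            seqs.append(seq)
            continue
        pid = getattr(row, "protein_id", None)
        if pid not in by_id:
            raise VariantInputError(f"protein_id {pid!r} not found in proteome FASTA")
        seqs.append(by_id[pid])
    frame = frame.copy()
    frame["protein_seq"] = seqs
    return frame
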