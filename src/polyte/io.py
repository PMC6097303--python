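"""Readers and writers for GFF3, FASTA and the pipeline's TSV tables.

All readers convert GFF3 1-based inclusive coordinates to the internal
0-based half-open convention and return records sorted by
(chrom, start, end, id).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .core import GeneModel, GenomicInterval, PolyteError, TECopy, subgenome_of


class Gff3ParseError(PolyteError):
    """Raised on malformed GFF3 input, naming the offending line."""


def _sort_key(rec):
    iv = rec.interval
    rid = rec.copy_id if isinstance(rec, TECopy) else rec.gene_id
    return (iv.chrom, iv.start, iv.end, rid)


def read_gff3(
    path: Union[str, Path],
    feature_filter: Optional[Set[str]] = None,
) -> List[Union[TECopy, GeneModel]]:
    """Parse a GFF3 file into gene models and TE copies.

    ``feature_filter`` restricts parsing to the given feature types
    (by default ``gene`` and ``repeat_region``). Genes become
    :class:`GeneModel`; ``repeat_region`` features with ``Family=`` (and
    optionally ``Subfamily=``, ``Superfamily=``) attributes become
    :class:`TECopy`.
    """
    if feature_filter is None:
        feature_filter = {"gene", "repeat_region"}
    records: List[Union[TECopy, GeneModel]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise Gff3ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise Gff3ParseError(f"{path}: line {lineno}: {exc}") from exc
            if feat.featuretype not in feature_filter:
                continue
            if feat.end < feat.start:
                raise Gff3ParseError(
                    f"{path}: line {lineno}: end < start ({feat.end} < {feat.start})"
                )
            strand = feat.strand if feat.strand in ("+", "-") else "."
            try:
                interval = GenomicInterval(
                    feat.seqid, feat.start - 1, feat.end, strand
                )
            except ValueError as exc:
                raise Gff3ParseError(f"{path}: line {lineno}: {exc}") from exc
            attrs = {k: v[0] for k, v in feat.attributes.items() if v}
            try:
                if feat.featuretype == "gene":
                    gid = attrs.get("ID")
                    if gid is None:
                        raise Gff3ParseError(
                            f"{path}: line {lineno}: gene without ID attribute"
                        )
                    records.append(
                        GeneModel(interval, gid, subgenome_of(feat.seqid))
                    )
                else:
                    cid = attrs.get("ID")
                    family = attrs.get("Family")
                    if cid is None or family is None:
                        raise Gff3ParseError(
                            f"{path}: line {lineno}: repeat_region needs ID and Family"
                        )
                    superfam = attrs.get("Superfamily", family[:3])
                    records.append(
                        TECopy(interval, cid, family, superfam, attrs.get("Subfamily"))
                    )
            except ValueError as exc:
                raise Gff3ParseError(f"{path}: line {lineno}: {exc}") from exc
    records.sort(key=_sort_key)
    return records


def write_gff3(records: Iterable[Union[TECopy, GeneModel]], path: Union[str, Path]) -> None:
    """Write gene models / TE copies back to GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for rec in sorted(records, key=_sort_key):
        iv = rec.interval
        if isinstance(rec, GeneModel):
            ftype, source = "gene", "polyte"
            attrs = f"ID={rec.gene_id}"
        else:
            ftype, source = "repeat_region", "polyte"
            attrs = f"ID={rec.copy_id};Family={rec.family};Superfamily={rec.superfamily_code}"
            if rec.subfamily:
                attrs += f";Subfamily={rec.subfamily}"
        strand = iv.strand if iv.strand in ("+", "-") else "."
        lines.append(
            "\t".join(
                [iv.chrom, source, ftype, str(iv.start + 1), str(iv.end), ".", strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.interval.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "strand": [g.interval.strand for g in genes],
            "subgenome": [g.subgenome for g in genes],
            "tss": [g.tss for g in genes],
            "tts": [g.tts for g in genes],
        }
    )


def tes_to_frame(tes: Sequence[TECopy]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "copy_id": [t.copy_id for t in tes],
            "chrom": [t.interval.chrom for t in tes],
            "start": [t.interval.start for t in tes],
            "end": [t.interval.end for t in tes],
            "strand": [t.interval.strand for t in tes],
            "family": [t.family for t in tes],
            "subfamily": [t.subfamily for t in tes],
            "superfamily": [t.superfamily_code for t in tes],
        }
    )


def write_tsv_table(records: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a DataFrame as a TSV with header; round-trips with read_tsv_table."""
    records.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path: Union[str, Path]) -> dict:
    """Read a FASTA file into a chrom -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path: Union[str, Path]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(sequences.items())
    ]
    SeqIO.write(recs, str(path), "fasta")


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return json.load(fh)


def dump_json(obj, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
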