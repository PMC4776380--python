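"""Readers and writers for every external format the pipeline touches.

All downstream modules consume the domain types defined here (and
:class:`~effectorkit.expression.CountMatrix`); nothing else in the
package re-parses files.  Formats are deliberately plain: FASTA for
sequences, 12/13-column tabular BLAST (outfmt 6 dialect) for pairwise
similarity, TSV with header rows for counts, designs and annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .expression import CountMatrix

__all__ = [
    "SequenceRecord",
    "SimilarityEdge",
    "AnnotationRecord",
    "read_fasta",
    "write_fasta",
    "load_dataset",
    "read_blast_tab",
    "write_blast_tab",
    "read_counts_table",
    "write_counts_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_id_list",
    "write_abc",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class SequenceRecord:
    """A protein (optionally with its CDS) tagged with its dataset of origin."""

    id: str
    dataset: str
    protein: str
    cds: str | None = None

    def __post_init__(self) -> None:
        if "*" in self.protein.rstrip("*"):
            raise ValueError(f"{self.id}: internal stop symbol in protein")
        self.protein = self.protein.rstrip("*")
        if self.cds is not None:
            cds = self.cds.upper()
            if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
                cds_body = cds[:-3]
            else:
                cds_body = cds
            if len(cds_body) != 3 * len(self.protein):
                raise ValueError(
                    f"{self.id}: CDS length {len(self.cds)} does not match "
                    f"3 x protein length {len(self.protein)} (+/- stop codon)"
                )
            self.cds = cds

    @property
    def cds_no_stop(self) -> str:
        """CDS with any trailing stop codon removed."""
        if self.cds is None:
            raise ValueError(f"{self.id}: no CDS available")
        if len(self.cds) >= 3 and self.cds[-3:] in STOP_CODONS:
            return self.cds[:-3]
        return self.cds


@dataclass
class SimilarityEdge:
    """One pairwise similarity hit (BLAST outfmt-6 style)."""

    query: str
    subject: str
    evalue: float
    identity: float
    aln_length: int
    bitscore: float
    query_length: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.query}->{self.subject}: negative e-value")
        if not 0 <= self.identity <= 100:
            raise ValueError(f"{self.query}->{self.subject}: identity outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError(f"{self.query}->{self.subject}: alignment length < 1")
        if self.query_length < 1:
            raise ValueError(f"{self.query}->{self.subject}: query length < 1")

    @property
    def query_coverage(self) -> float:
        """Percent of the query covered by the alignment."""
        return 100.0 * self.aln_length / self.query_length


@dataclass
class AnnotationRecord:
    """Per-sequence secretion/localisation/database annotations.

    These carry the outputs of upstream predictors (signal peptide,
    transmembrane domain, nuclear localisation signal, best database hit,
    Pfam-A presence); the pipeline consumes, never computes, them.
    """

    id: str
    has_signal_peptide: bool
    has_tm_domain: bool
    has_nls: bool
    best_db_hit_evalue: float | None  # None == no hit
    has_pfamA: bool


def read_fasta(path: str | Path, dataset_label: str, *, seq_type: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Ids are the first whitespace token of each header (matching BLAST's
    behaviour, so edge ids join to sequence ids without post-processing).
    ``seq_type`` selects whether sequences populate the ``protein`` or
    ``cds`` field.
    """
    if seq_type not in ("protein", "cds"):
        raise ValueError("seq_type must be 'protein' or 'cds'")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        sid = entry.id  # Biopython already takes the first whitespace token
        seq = str(entry.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for id {sid!r}")
        if sid in seen:
            raise ValueError(f"{path}: duplicate id {sid!r}")
        seen.add(sid)
        if seq_type == "protein":
            records.append(SequenceRecord(id=sid, dataset=dataset_label, protein=seq))
        else:
            prot = str(Seq(seq[: len(seq) - len(seq) % 3]).translate()).rstrip("*")
            records.append(SequenceRecord(id=sid, dataset=dataset_label, protein=prot, cds=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, seq_type: str = "protein") -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.protein if seq_type == "protein" else rec.cds
            if seq is None:
                raise ValueError(f"{rec.id}: no {seq_type} sequence to write")
            fh.write(f">{rec.id}\n{seq}\n")


def load_dataset(
    protein_path: str | Path, cds_path: str | Path, dataset_label: str
) -> list[SequenceRecord]:
    """Read paired protein and CDS FASTA files for one dataset.

    Every protein id must have a CDS partner with the same id; the
    SequenceRecord invariant (CDS = 3 x protein, modulo trailing stop)
    is enforced on construction.
    """
    prots = read_fasta(protein_path, dataset_label, seq_type="protein")
    cds_map = {r.id: r.cds for r in read_fasta(cds_path, dataset_label, seq_type="cds")}
    out = []
    for rec in prots:
        if rec.id not in cds_map:
            raise ValueError(f"{dataset_label}: no CDS for protein {rec.id!r}")
        out.append(
            SequenceRecord(id=rec.id, dataset=dataset_label, protein=rec.protein, cds=cds_map[rec.id])
        )
    return out


def read_blast_tab(
    path: str | Path, query_lengths: Mapping[str, int] | None = None
) -> list[SimilarityEdge]:
    """Parse a 12- or 13-column tabular BLAST file into SimilarityEdges.

    Columns follow outfmt 6 (qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore), optionally followed by qlen.
    When qlen is absent the query length is looked up in ``query_lengths``.
    """
    edges: list[SimilarityEdge] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 13 tab-separated columns, got {len(parts)}"
                )
            try:
                evalue = float(parts[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric e-value {parts[10]!r}") from exc
            try:
                pident = float(parts[2])
                length = int(parts[3])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if bitscore < 0:
                warnings.warn(f"{path}:{lineno}: negative bitscore {bitscore}")
            if len(parts) == 13:
                qlen = int(parts[12])
            else:
                if query_lengths is None or parts[0] not in query_lengths:
                    raise ValueError(
                        f"{path}:{lineno}: no qlen column and no query length known for {parts[0]!r}"
                    )
                qlen = int(query_lengths[parts[0]])
            edges.append(
                SimilarityEdge(
                    query=parts[0],
                    subject=parts[1],
                    evalue=evalue,
                    identity=pident,
                    aln_length=length,
                    bitscore=bitscore,
                    query_length=qlen,
                )
            )
    return edges


def write_blast_tab(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    """Write edges as 13-column tabular BLAST (outfmt 6 + qlen).

    Fields the pipeline does not track (mismatch, gapopen, coordinates)
    are written as zeros / full-length spans.
    """
    with open(path, "w") as fh:
        for e in edges:
            fh.write(
                "\t".join(
                    [
                        e.query, e.subject, f"{e.identity:g}", str(e.aln_length),
                        "0", "0", "1", str(e.aln_length), "1", str(e.aln_length),
                        f"{e.evalue:g}", f"{e.bitscore:g}", str(e.query_length),
                    ]
                )
                + "\n"
            )


def read_counts_table(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a transcripts x libraries TSV plus a library design TSV.

    The design file has header ``library tissue replicate`` with tissue
    in {head, body}.  Libraries present in the design must exist in the
    counts table; extra count columns are dropped.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0, dtype={"replicate": str})
    if "tissue" not in design.columns:
        raise ValueError(f"{design_path}: design needs a 'tissue' column")
    lengths = None
    if "length" in counts.columns:  # optional transcript-length column
        lengths = counts.pop("length").astype(int)
    frac = counts.to_numpy(dtype=float)
    if not (frac == frac.astype(int)).all():
        raise ValueError(f"{path}: counts must be integers")
    return CountMatrix(counts=counts.astype(int), design=design, lengths=lengths)


def write_counts_table(cm: CountMatrix, path: str | Path, design_path: str | Path) -> None:
    out = cm.counts.copy()
    if cm.lengths is not None:
        out["length"] = cm.lengths
    out.to_csv(path, sep="\t", index_label="transcript")
    cm.design.to_csv(design_path, sep="\t", index_label="library")


_FLAG = {"yes": True, "no": False}

ANNOTATION_COLUMNS = ["id", "signal_peptide", "tm_domain", "nls", "best_db_hit_evalue", "pfamA"]


def read_annotation_table(path: str | Path) -> dict[str, AnnotationRecord]:
    """Read the per-sequence annotation TSV into a mapping id -> record.

    Flag columns accept yes/no; an empty best_db_hit_evalue field means
    "no database hit".
    """
    out: dict[str, AnnotationRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ANNOTATION_COLUMNS:
            raise ValueError(f"{path}: expected header {ANNOTATION_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            sid = parts[0]
            if sid in out:
                raise ValueError(f"{path}:{lineno}: duplicate id {sid!r}")
            flags = []
            for col, tok in zip(("signal_peptide", "tm_domain", "nls", "pfamA"), (parts[1], parts[2], parts[3], parts[5])):
                if tok not in _FLAG:
                    raise ValueError(f"{path}:{lineno}: unknown {col} token {tok!r} (expected yes/no)")
                flags.append(_FLAG[tok])
            ev = None if parts[4].strip() == "" else float(parts[4])
            out[sid] = AnnotationRecord(
                id=sid,
                has_signal_peptide=flags[0],
                has_tm_domain=flags[1],
                has_nls=flags[2],
                best_db_hit_evalue=ev,
                has_pfamA=flags[3],
            )
    return out


def write_annotation_table(annotations: Mapping[str, AnnotationRecord], path: str | Path) -> None:
    yn = {True: "yes", False: "no"}
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for sid, a in annotations.items():
            ev = "" if a.best_db_hit_evalue is None else f"{a.best_db_hit_evalue:g}"
            fh.write(
                "\t".join(
                    [sid, yn[a.has_signal_peptide], yn[a.has_tm_domain], yn[a.has_nls], ev, yn[a.has_pfamA]]
                )
                + "\n"
            )


def read_id_list(path: str | Path) -> set[str]:
    """One id per line (e.g. saliva protein ids, published candidate lists)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_abc(rows: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    """Write a graph edge file in abc dialect: query<TAB>hit<TAB>e-value."""
    with open(path, "w") as fh:
        for q, h, ev in rows:
            fh.write(f"{q}\t{h}\t{ev:g}\n")
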