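"""Probe re-annotation against coding and lncRNA transcript sets.

Array probes are intersected with two exon annotations: a coding
("Ensembl-like") set and a lncRNA ("LNCipedia-like") set.  A probe is
kept only when it is univocally referable to one lncRNA gene: it must
overlap at least one lncRNA exon, overlap no coding transcript, and all
lncRNA transcripts it touches must belong to a single gene.  Probe-level
expression of the surviving probes is summarized per lncRNA gene by the
per-sample median.

Coordinates are 0-based half-open internally (BED convention); GFF3
input is converted on load and reported coordinates are 1-based
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeRecord",
    "TranscriptAnnotation",
    "read_probes_bed",
    "read_annotation_gff3",
    "write_annotation_gff3",
    "assign_probes",
    "summarize_lncrna",
    "load_expression_tsv",
]

DROP_REASONS = ("coding_overlap", "no_hit", "ambiguous_gene")


@dataclass(frozen=True)
class ProbeRecord:
    """A probe's genomic target interval (0-based half-open)."""

    probe_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"probe {self.probe_id}: start must be < end "
                f"({self.start} >= {self.end})")


@dataclass
class TranscriptAnnotation:
    """One transcript with its exon intervals (0-based half-open).

    ``source`` is "coding" or "lncrna"; lncRNA transcript ids follow
    the '<gene>:<ordinal>' convention.
    """

    transcript_id: str
    gene_id: str
    source: str
    chrom: str
    strand: str = "."
    exons: list = field(default_factory=list)
    cytoband: str = ""

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons[:-1], self.exons[1:]):
            if e1 > s2:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_probes_bed(path) -> list[ProbeRecord]:
    """Read probes from a BED file (chrom, start, end, name[, score, strand])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    records = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 else "."
        records.append(ProbeRecord(
            probe_id=str(row[3]), chrom=str(row[0]),
            start=int(row[1]), end=int(row[2]), strand=str(strand)))
    return records


def read_annotation_gff3(path, source: str) -> list[TranscriptAnnotation]:
    """Load transcripts + exons from GFF3 via gffutils (in-memory db).

    Transcript features may carry a ``cytoband`` attribute; gene
    membership comes from the transcript's ``Parent`` or ``gene_id``.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique",
                            keep_order=True)
    out = []
    for tr in db.features_of_type("transcript"):
        gene_id = tr.attributes.get("gene_id",
                                    tr.attributes.get("Parent", [tr.id]))[0]
        cytoband = tr.attributes.get("cytoband", [""])[0]
        exons = [(e.start - 1, e.end)
                 for e in db.children(tr, featuretype="exon")]
        out.append(TranscriptAnnotation(
            transcript_id=tr.id, gene_id=gene_id, source=source,
            chrom=tr.seqid, strand=tr.strand, exons=exons,
            cytoband=cytoband))
    return out


def write_annotation_gff3(transcripts: Iterable[TranscriptAnnotation],
                          path) -> None:
    """Write transcripts and their exons as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tr in transcripts:
            if not tr.exons:
                continue
            start = tr.exons[0][0] + 1
            end = tr.exons[-1][1]
            attrs = (f"ID={tr.transcript_id};gene_id={tr.gene_id}")
            if tr.cytoband:
                attrs += f";cytoband={tr.cytoband}"
            fh.write(f"{tr.chrom}\t{tr.source}\ttranscript\t{start}\t{end}\t."
                     f"\t{tr.strand}\t.\t{attrs}\n")
            for i, (s, e) in enumerate(tr.exons, 1):
                fh.write(f"{tr.chrom}\t{tr.source}\texon\t{s + 1}\t{e}\t."
                         f"\t{tr.strand}\t.\tID={tr.transcript_id}.exon{i};"
                         f"Parent={tr.transcript_id}\n")


def load_expression_tsv(path) -> pd.DataFrame:
    """Feature-by-sample expression TSV (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"expression matrix {path} contains missing values")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {path}")
    return df


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def _exon_trees(transcripts: Iterable[TranscriptAnnotation],
                stranded: bool) -> dict:
    trees: dict = {}
    for tr in transcripts:
        for s, e in tr.exons:
            key = (tr.chrom, tr.strand) if stranded else tr.chrom
            trees.setdefault(key, IntervalTree()).addi(s, e, tr)
    return trees


def _query(trees: dict, probe: ProbeRecord, stranded: bool):
    if stranded:
        keys = ([(probe.chrom, probe.strand)] if probe.strand in "+-"
                else [(probe.chrom, "+"), (probe.chrom, "-")])
    else:
        keys = [probe.chrom]
    hits = []
    for key in keys:
        if key in trees:
            hits.extend(iv.data for iv in trees[key].overlap(
                probe.start, probe.end))
    return hits


def assign_probes(probes: Iterable[ProbeRecord],
                  coding: Iterable[TranscriptAnnotation],
                  lncrna: Iterable[TranscriptAnnotation],
                  stranded: bool = False,
                  gene_body: bool = False) -> pd.DataFrame:
    """Assign probes to lncRNA genes under the univocality rule.

    A probe is assigned iff it overlaps >= 1 lncRNA exon, overlaps no
    coding transcript, and all overlapped lncRNA transcripts belong to
    one gene; otherwise it is dropped with reason ``coding_overlap``,
    ``no_hit`` or ``ambiguous_gene``.  Overlap needs >= 1 bp, is
    exon-level by default (``gene_body=True`` uses whole transcript
    spans) and strand-ignored by default.

    Returns a frame indexed by probe_id with columns gene_id, status.
    """
    coding = list(coding)
    lncrna = list(lncrna)
    if gene_body:
        def spanned(trs):
            out = []
            for tr in trs:
                if tr.exons:
                    body = TranscriptAnnotation(
                        tr.transcript_id, tr.gene_id, tr.source, tr.chrom,
                        tr.strand, [(tr.exons[0][0], tr.exons[-1][1])],
                        tr.cytoband)
                    out.append(body)
            return out
        coding, lncrna = spanned(coding), spanned(lncrna)
    known_chroms = {tr.chrom for tr in coding} | {tr.chrom for tr in lncrna}
    coding_trees = _exon_trees(coding, stranded)
    lnc_trees = _exon_trees(lncrna, stranded)
    rows = []
    for probe in probes:
        if probe.chrom not in known_chroms:
            raise ValueError(
                f"probe {probe.probe_id} is on chromosome {probe.chrom!r}, "
                "absent from both annotation sets")
        if _query(coding_trees, probe, stranded):
            status, gene = "coding_overlap", ""
        else:
            lnc_hits = _query(lnc_trees, probe, stranded)
            genes = {tr.gene_id for tr in lnc_hits}
            if not genes:
                status, gene = "no_hit", ""
            elif len(genes) > 1:
                status, gene = "ambiguous_gene", ""
            else:
                status, gene = "assigned", genes.pop()
        rows.append({"probe_id": probe.probe_id, "gene_id": gene,
                     "status": status})
    return pd.DataFrame(rows).set_index("probe_id")


def summarize_lncrna(expr: pd.DataFrame,
                     assignment: Mapping[str, str] | pd.DataFrame,
                     ) -> pd.DataFrame:
    """Median-summarize assigned probe rows into lncRNA gene rows.

    ``assignment`` maps probe_id -> gene_id (or is the frame returned by
    :func:`assign_probes`, whose non-assigned rows are ignored).  Probes
    absent from the expression matrix are skipped with a warning; an
    even probe count takes the mean of the two central values (pandas
    median).  Genes with no surviving probe are absent from the output.
    """
    if isinstance(assignment, pd.DataFrame):
        assigned = assignment[assignment["status"] == "assigned"]
        mapping = dict(zip(assigned.index, assigned["gene_id"]))
    else:
        mapping = dict(assignment)
    if not mapping:
        logger.warning("empty probe assignment: summarized matrix is empty")
        return expr.iloc[0:0]
    present = {p: g for p, g in mapping.items() if p in expr.index}
    missing = set(mapping) - set(present)
    if missing:
        logger.warning("%d assigned probes absent from expression matrix",
                       len(missing))
    if not present:
        return expr.iloc[0:0]
    sub = expr.loc[list(present)]
    genes = pd.Series({p: present[p] for p in sub.index}, name="gene_id")
    out = sub.groupby(genes).median()
    out.index.name = expr.index.name
    return out
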