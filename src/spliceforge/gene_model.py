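"""Gene models as ordered exon/intron intervals over a transcription-oriented sequence.

A :class:`GeneModel` stores a DNA sequence plus the exon intervals of a single
gene on that sequence, in 0-based half-open coordinates.  Introns are never
stored: they are the gaps between consecutive exons.  Minus-strand genes are
reverse-complemented at load time so that every downstream module (splicing,
ORF finding, splice-site motifs) can assume transcription orientation.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

_DNA = set("ACGTN")


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval [start, end) in 0-based coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class GeneModel:
    """A gene as ordered exons over a transcription-oriented DNA sequence.

    Parameters
    ----------
    gene_id:
        Identifier used in GFF3 I/O.
    seq:
        Uppercase DNA (A/C/G/T/N), already transcription-oriented.
    exons:
        Strictly increasing, non-overlapping, non-adjacent intervals on
        ``seq`` (consecutive exons must leave a nonempty intron between them).
    strand_of_origin:
        '+' or '-'; recorded for provenance only, the sequence itself is
        always in transcription orientation.
    """

    gene_id: str
    seq: str
    exons: list[Interval] = field(default_factory=list)
    strand_of_origin: str = "+"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - _DNA
        if bad:
            raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
        if self.strand_of_origin not in {"+", "-"}:
            raise ValueError("strand_of_origin must be '+' or '-'")
        self.exons = [e if isinstance(e, Interval) else Interval(*e) for e in self.exons]
        if not self.exons:
            raise ValueError("a gene model needs at least one exon")
        for e in self.exons:
            if e.end > len(self.seq):
                raise ValueError(f"exon {e} outside sequence bounds (len {len(self.seq)})")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"exons {a} and {b} overlap or are adjacent")

    @property
    def span(self) -> Interval:
        """Genomic span of the gene (first exon start to last exon end)."""
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def introns(self) -> list[Interval]:
        return derive_introns(self)

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "seq": self.seq,
            "exons": [[e.start, e.end] for e in self.exons],
            "strand_of_origin": self.strand_of_origin,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(
            gene_id=d["gene_id"],
            seq=d["seq"],
            exons=[Interval(a, b) for a, b in d["exons"]],
            strand_of_origin=d.get("strand_of_origin", "+"),
        )

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "GeneModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def derive_introns(model: GeneModel) -> list[Interval]:
    """Gaps between consecutive exons, in order; ``n_exons - 1`` of them."""
    return [Interval(a.end, b.start) for a, b in zip(model.exons, model.exons[1:])]


def extract(model: GeneModel, intervals: Sequence[Interval | tuple[int, int]]) -> str:
    """Concatenate subsequences of the model sequence in interval order."""
    ivs = [iv if isinstance(iv, Interval) else Interval(*iv) for iv in intervals]
    prev_end = None
    for iv in ivs:
        if iv.end > len(model.seq):
            raise ValueError(f"interval {iv} outside sequence bounds")
        if prev_end is not None and iv.start < prev_end:
            raise ValueError("intervals must be ordered and non-overlapping")
        prev_end = iv.end
    return "".join(model.seq[iv.start : iv.end] for iv in ivs)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def load_gene_model(gff3_path: str, fasta_path: str, gene_id: str) -> GeneModel:
    """Load one gene from GFF3 + FASTA, normalized to transcription orientation.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    For minus-strand genes the parent sequence is reverse-complemented and
    exon coordinates are flipped, so the returned model reads 5'->3' along
    the transcript.
    """
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbpath = tmp.name
    try:
        db = gffutils.create_db(
            gff3_path, dbpath, force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        exon_rows = []
        strand = "+"
        seqid = None
        for feat in db.all_features(featuretype="exon"):
            parents = {feat.id, *feat.attributes.get("Parent", [])}
            # walk up to the gene: exon -> mRNA -> gene
            owner_ids = set(parents)
            for p in list(parents):
                try:
                    owner_ids.update(a.id for a in db.parents(p))
                except gffutils.exceptions.FeatureNotFoundError:
                    pass
            if gene_id in owner_ids or feat.attributes.get("gene_id", [None])[0] == gene_id:
                exon_rows.append((feat.start, feat.end))
                strand = feat.strand if feat.strand in "+-" else "+"
                seqid = feat.seqid
    finally:
        os.unlink(dbpath)
    if not exon_rows:
        raise KeyError(f"no exon features found for gene {gene_id!r} in {gff3_path}")

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    if seqid not in seqs:
        raise KeyError(f"sequence {seqid!r} not found in {fasta_path}")
    seq = seqs[seqid]

    # GFF3 1-based inclusive -> 0-based half-open
    exons = sorted(Interval(s - 1, e) for s, e in exon_rows)
    for e in exons:
        if e.end > len(seq):
            raise ValueError(f"exon {e} extends beyond sequence {seqid} (len {len(seq)})")
    if strand == "-":
        n = len(seq)
        seq = reverse_complement(seq)
        exons = sorted(Interval(n - e.end, n - e.start) for e in exons)
    return GeneModel(gene_id=gene_id, seq=seq, exons=exons, strand_of_origin=strand)


def write_gene_model(model: GeneModel, gff3_path: str, fasta_path: str) -> None:
    """Write the model as GFF3 (gene/mRNA/exon) plus FASTA, plus strand."""
    seqid = model.gene_id + "_region"
    with open(fasta_path, "w") as fh:
        fh.write(f">{seqid}\n")
        for i in range(0, len(model.seq), 70):
            fh.write(model.seq[i : i + 70] + "\n")
    span = model.span
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")

        def row(ftype: str, iv: Interval, attrs: str) -> str:
            return (
                f"{seqid}\tspliceforge\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t{attrs}\n"
            )

        fh.write(row("gene", span, f"ID={model.gene_id}"))
        fh.write(row("mRNA", span, f"ID={model.gene_id}.1;Parent={model.gene_id}"))
        for i, e in enumerate(model.exons, start=1):
            fh.write(row("exon", e, f"ID={model.gene_id}.1.exon{i};Parent={model.gene_id}.1"))
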