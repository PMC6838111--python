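"""ORF prediction, translation, premature-stop localization, shared termini.

Transcripts are already 5'->3', so only the forward strand is scanned.  The
default policy picks the longest ATG-initiated open reading frame over the
three forward frames, ending at the first in-frame stop (or at the
transcript end, flagged ``has_stop=False``).  Codons containing N translate
to X.  Protein lengths exclude the stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .gene_model import GeneModel
from .splice import TranscriptVariant

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class ORFRecord:
    """One predicted reading frame on a transcript.

    ``end_nt`` includes the stop codon when present, so
    ``end_nt - start_nt == 3 * (length_aa + 1)`` for stopped ORFs.
    ``stop_exon`` is filled by :func:`locate_stop_exon` (1-based exon number,
    or ``"intron"`` for stops inside retained intronic sequence).
    """

    start_nt: int
    end_nt: int
    protein: str
    has_stop: bool
    stop_exon: int | str | None = None
    premature: bool | None = None

    @property
    def length_aa(self) -> int:
        return len(self.protein)

    @property
    def is_empty(self) -> bool:
        return self.length_aa == 0 and not self.has_stop


def translate(seq: str, offset: int = 0) -> str:
    """Translate consecutive codons from ``offset`` until end or first stop.

    The stop is not appended; codons containing N become X; a trailing
    partial codon is ignored.
    """
    if offset not in (0, 1, 2):
        raise ValueError("offset must be 0, 1, or 2")
    seq = seq.upper()
    sub = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
    return str(Seq(sub).translate(to_stop=True))


def find_orf(seq: str, policy: str = "longest_atg", start_nt: int | None = None) -> ORFRecord:
    """Find the reading frame of a transcript.

    ``longest_atg`` scans all ATG positions in all three frames and returns
    the longest ORF in amino acids, ties broken by smallest start.
    ``anchored`` translates from a fixed ``start_nt``.
    """
    seq = seq.upper()
    if policy == "anchored":
        if start_nt is None or not (0 <= start_nt <= len(seq) - 3):
            raise ValueError("anchored policy needs a valid start_nt")
        return _orf_from(seq, start_nt)
    if policy != "longest_atg":
        raise ValueError(f"unknown ORF policy {policy!r}")
    best: ORFRecord | None = None
    pos = seq.find("ATG")
    while pos != -1:
        rec = _orf_from(seq, pos)
        if best is None or rec.length_aa > best.length_aa:
            best = rec
        pos = seq.find("ATG", pos + 1)
    if best is None:
        return ORFRecord(start_nt=0, end_nt=0, protein="", has_stop=False)
    return best


def _orf_from(seq: str, start: int) -> ORFRecord:
    protein = translate(seq[start:], 0)
    stop_at = start + 3 * len(protein)
    has_stop = stop_at + 3 <= len(seq) and seq[stop_at : stop_at + 3] in STOP_CODONS
    end = stop_at + 3 if has_stop else start + 3 * ((len(seq) - start) // 3)
    return ORFRecord(start_nt=start, end_nt=end, protein=protein, has_stop=has_stop)


def transcript_to_genomic(variant: TranscriptVariant, pos: int) -> int:
    """Map a transcript coordinate to the genomic coordinate it came from."""
    offset = pos
    for seg in variant.segments:
        if offset < len(seg):
            return seg.start + offset
        offset -= len(seg)
    raise IndexError(f"transcript position {pos} outside variant {variant.name}")


def locate_stop_exon(
    variant: TranscriptVariant, orf: ORFRecord, model: GeneModel
) -> ORFRecord:
    """Annotate the ORF with the exon containing the stop codon's first base.

    Exons are numbered 1-based in the report; a stop falling in retained
    intronic sequence is reported as ``"intron"``.  ``premature`` is True
    when the stop's genomic position differs from the canonical stop of the
    reference (fully spliced) reading frame.
    """
    if not orf.has_stop:
        orf.stop_exon = "none"
        orf.premature = False
        return orf
    gpos = transcript_to_genomic(variant, orf.end_nt - 3)
    orf.stop_exon = "intron"
    for i, exon in enumerate(model.exons, start=1):
        if exon.start <= gpos < exon.end:
            orf.stop_exon = i
            break
    # canonical stop of the reference form, from the same ORF policy
    from .splice import apply_events

    ref = apply_events(model, [], name="_canonical")
    ref_orf = find_orf(ref.seq)
    ref_stop = (
        transcript_to_genomic(ref, ref_orf.end_nt - 3) if ref_orf.has_stop else None
    )
    orf.premature = ref_stop is not None and gpos != ref_stop
    return orf


def shared_termini(proteins: dict[str, str]) -> "SharedRegionReport":
    """Longest common N-terminal prefix and C-terminal suffix of a protein set."""
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    seqs = list(proteins.values())
    if any(not s for s in seqs):
        raise ValueError("empty protein in input")
    n = _common_prefix_len(seqs)
    c = _common_prefix_len([s[::-1] for s in seqs])
    return SharedRegionReport(
        n_term_shared_aa=n, c_term_shared_aa=c, member_names=list(proteins)
    )


def _common_prefix_len(seqs: list[str]) -> int:
    shortest = min(seqs, key=len)
    for i, ch in enumerate(shortest):
        if any(s[i] != ch for s in seqs):
            return i
    return len(shortest)


@dataclass
class SharedRegionReport:
    n_term_shared_aa: int
    c_term_shared_aa: int
    member_names: list[str]
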