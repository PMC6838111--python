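"""Validation of introns against the five U2-type (major spliceosome) rules.

The five rules, stated on DNA (T for U):

1. donor: the intron starts with the obligatory GT; the full consensus
   AG|GTAAGT (2 exonic + 6 intronic positions) is scored but not required;
2. acceptor: the intron ends with the obligatory AG; full consensus
   TGYAG|GT (5 intronic + 2 exonic positions, Y = C/T) scored;
3. the intron is U/A-rich (fraction of A+T >= threshold, default 0.60);
4. a branchpoint YTRAY motif occurs with its first base 30-70 nt upstream
   of the intron's 3' junction (distance measured to the intron's last
   base, inclusive window);
5. a poly-U tract (>= 5 T with at most one single-base interruption) lies
   strictly between the branchpoint motif and the terminal AG.

Only GT/AG are obligatory for rules 1-2; N bases fail any motif position
they occupy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gene_model import GeneModel, Interval

DONOR_CONSENSUS = ("AG", "GTAAGT")      # exon end | intron start
ACCEPTOR_CONSENSUS = ("TGCAG", "GT")    # intron end | exon start; pos 3 is Y

_IUPAC = {"Y": "CT", "R": "AG", "A": "A", "C": "C", "G": "G", "T": "T"}
BRANCHPOINT_MOTIF = "YTRAY"
BRANCHPOINT_WINDOW = (30, 70)
UA_THRESHOLD = 0.60
POLYU_MIN_T = 5
POLYU_MAX_INTERRUPTIONS = 1


def _matches(base: str, pattern: str) -> bool:
    return base in _IUPAC[pattern]


@dataclass
class U2Report:
    """Per-intron evidence for the five U2-type rules."""

    intron_index: int
    donor_ok: bool
    donor_matches: int          # of 8 scored positions (AG|GTAAGT)
    acceptor_ok: bool
    acceptor_matches: int       # of 7 scored positions (TGYAG|GT)
    ua_fraction: float
    ua_ok: bool
    branchpoints: list[int]     # distances of motif first base to intron 3' end
    bp_ok: bool
    polyu_ok: bool
    polyu_tract: Interval | None
    warnings: list[str] = field(default_factory=list)

    @property
    def u2_type(self) -> bool:
        return self.donor_ok and self.acceptor_ok and self.ua_ok and self.bp_ok and self.polyu_ok


def _intron_context(model: GeneModel, intron_index: int) -> tuple[str, str, str]:
    introns = model.introns
    if not (0 <= intron_index < len(introns)):
        raise IndexError(f"intron index {intron_index} out of range")
    iv = introns[intron_index]
    upstream = model.seq[max(0, iv.start - 2) : iv.start]
    downstream = model.seq[iv.end : iv.end + 2]
    return upstream, model.seq[iv.start : iv.end], downstream


def check_donor(model: GeneModel, intron_index: int) -> tuple[bool, int]:
    """Rule 1: obligatory GT at the intron 5' end; AG|GTAAGT scored (of 8)."""
    upstream, intron, _ = _intron_context(model, intron_index)
    exon_part, intron_part = DONOR_CONSENSUS
    matches = sum(
        a == b for a, b in zip(upstream.rjust(2, "N")[-2:], exon_part)
    ) + sum(a == b for a, b in zip(intron[:6], intron_part))
    ok = len(intron) >= 2 and intron.startswith("GT")
    return ok, matches


def check_acceptor(model: GeneModel, intron_index: int) -> tuple[bool, int]:
    """Rule 2: obligatory AG at the intron 3' end; TGYAG|GT scored (of 7)."""
    _, intron, downstream = _intron_context(model, intron_index)
    intron_part, exon_part = ACCEPTOR_CONSENSUS
    tail = intron[-5:].rjust(5, "N")
    matches = sum(
        _matches(a, b) for a, b in zip(tail, "TGYAG")
    ) + sum(a == b for a, b in zip(downstream.ljust(2, "N")[:2], exon_part))
    ok = len(intron) >= 2 and intron.endswith("AG")
    return ok, matches


def check_ua_richness(
    model: GeneModel, intron_index: int, threshold: float = UA_THRESHOLD
) -> tuple[bool, float]:
    """Rule 3: fraction of A/T over the whole intron >= threshold."""
    _, intron, _ = _intron_context(model, intron_index)
    frac = (intron.count("A") + intron.count("T")) / len(intron)
    return frac >= threshold, frac


def find_branchpoint(
    model: GeneModel,
    intron_index: int,
    window: tuple[int, int] = BRANCHPOINT_WINDOW,
    anchor: str = "first",
) -> list[int]:
    """Rule 4: all YTRAY matches whose anchor base is 30-70 nt upstream.

    Distances are measured from the motif's ``anchor`` base ("first" by
    default, "last" switchable) to the intron's final base, inclusive.
    Returned sorted ascending (most 3' branchpoint first).  Introns shorter
    than 35 nt yield an empty list.
    """
    _, intron, _ = _intron_context(model, intron_index)
    lo, hi = window
    if len(intron) < 35:
        return []
    hits = []
    for s in range(len(intron) - 4):
        if all(_matches(intron[s + k], BRANCHPOINT_MOTIF[k]) for k in range(5)):
            a = s if anchor == "first" else s + 4
            dist = len(intron) - a
            if lo <= dist <= hi:
                hits.append(dist)
    return sorted(hits)


def check_polyu(
    model: GeneModel,
    intron_index: int,
    branchpoint_pos: int,
    min_t: int = POLYU_MIN_T,
    max_interruptions: int = POLYU_MAX_INTERRUPTIONS,
) -> tuple[bool, Interval | None]:
    """Rule 5: a poly-U tract between the branchpoint motif and the 3' AG.

    ``branchpoint_pos`` is a distance as returned by :func:`find_branchpoint`
    (anchored on the motif's first base).  The searched region lies strictly
    between the motif's last base and the terminal AG dinucleotide.  A tract
    needs >= ``min_t`` T bases with at most ``max_interruptions`` single
    non-T bases inside it; the longest tract is returned in intron-local
    coordinates.
    """
    _, intron, _ = _intron_context(model, intron_index)
    iv = model.introns[intron_index]
    motif_start = len(intron) - branchpoint_pos
    lo = motif_start + 5
    hi = len(intron) - 2
    region = intron[lo:hi]
    if len(region) < min_t:
        return False, None
    best: tuple[int, int, int] | None = None  # (n_t, -start, end)
    for start in range(len(region)):
        if region[start] != "T":
            continue
        interruptions = 0
        n_t = 0
        end = start
        j = start
        while j < len(region):
            if region[j] == "T":
                n_t += 1
                end = j + 1
            else:
                interruptions += 1
                if interruptions > max_interruptions or j + 1 >= len(region) or region[j + 1] != "T":
                    break
            j += 1
        if n_t >= min_t:
            cand = (n_t, -start, end)
            if best is None or cand > best:
                best = cand
    if best is None:
        return False, None
    n_t, neg_start, end = best
    return True, Interval(lo + (-neg_start), lo + end)


def validate_intron(
    model: GeneModel,
    intron_index: int,
    ua_threshold: float = UA_THRESHOLD,
    bp_window: tuple[int, int] = BRANCHPOINT_WINDOW,
    bp_anchor: str = "first",
) -> U2Report:
    """Aggregate the five rule checks for one intron.

    ``u2_type`` is the conjunction of the five flags; rule 5 is evaluated at
    the most 3' branchpoint (smallest distance) when any exists.
    """
    warnings: list[str] = []
    intron = model.introns[intron_index]
    donor_ok, donor_m = check_donor(model, intron_index)
    if len(intron) < 6:
        warnings.append(f"intron {intron_index} shorter than 6 nt")
        donor_ok = False
    acceptor_ok, acceptor_m = check_acceptor(model, intron_index)
    if len(intron) < 5:
        acceptor_ok = False
    ua_ok, ua_frac = check_ua_richness(model, intron_index, ua_threshold)
    bps = find_branchpoint(model, intron_index, bp_window, bp_anchor)
    if len(intron) < 35:
        warnings.append(f"intron {intron_index} shorter than 35 nt; no branchpoint scan")
    if bps:
        polyu_ok, tract = check_polyu(model, intron_index, bps[0])
    else:
        polyu_ok, tract = False, None
    return U2Report(
        intron_index=intron_index,
        donor_ok=donor_ok,
        donor_matches=donor_m,
        acceptor_ok=acceptor_ok,
        acceptor_matches=acceptor_m,
        ua_fraction=ua_frac,
        ua_ok=ua_ok,
        branchpoints=bps,
        bp_ok=bool(bps),
        polyu_ok=polyu_ok,
        polyu_tract=tract,
        warnings=warnings,
    )


def validate_all(model: GeneModel, **kwargs) -> list[U2Report]:
    return [validate_intron(model, i, **kwargs) for i in range(len(model.introns))]
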