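"""Alternative-splicing events and transcript-variant construction.

Events are defined relative to the canonical fully spliced form: starting
from "all introns removed", intron retention re-inserts an intron,
alternative 3' acceptor / 5' donor shift one boundary of an intron's removed
region, and exon skipping removes an internal exon while fusing the two
flanking removals.  Because events are applied declaratively to the set of
removed regions, the result is independent of event order.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .gene_model import GeneModel, Interval, extract

log = logging.getLogger(__name__)


class EventKind(enum.Enum):
    INTRON_RETENTION = "intron_retention"
    ALT_3_ACCEPTOR = "alt_3_acceptor"
    ALT_5_DONOR = "alt_5_donor"
    EXON_SKIP = "exon_skip"


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event.

    ``index`` is the 0-based intron index (retention / alt sites) or exon
    index (skip).  ``alt_site`` is a genomic position on the model sequence,
    required for the two alt-boundary kinds and forbidden otherwise.
    """

    kind: EventKind
    index: int
    alt_site: int | None = None

    def __post_init__(self) -> None:
        needs_site = self.kind in (EventKind.ALT_3_ACCEPTOR, EventKind.ALT_5_DONOR)
        if needs_site and self.alt_site is None:
            raise ValueError(f"{self.kind.value} requires alt_site")
        if not needs_site and self.alt_site is not None:
            raise ValueError(f"{self.kind.value} does not take alt_site")


def intron_retention(intron_index: int) -> SpliceEvent:
    return SpliceEvent(EventKind.INTRON_RETENTION, intron_index)


def alt_3_acceptor(intron_index: int, alt_site: int) -> SpliceEvent:
    return SpliceEvent(EventKind.ALT_3_ACCEPTOR, intron_index, alt_site)


def alt_5_donor(intron_index: int, alt_site: int) -> SpliceEvent:
    return SpliceEvent(EventKind.ALT_5_DONOR, intron_index, alt_site)


def exon_skip(exon_index: int) -> SpliceEvent:
    return SpliceEvent(EventKind.EXON_SKIP, exon_index)


@dataclass
class TranscriptVariant:
    """An isoform: the retained genomic segments and the spliced sequence."""

    name: str
    segments: list[Interval]
    seq: str
    events: frozenset[SpliceEvent] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.seq)

    def retained_introns(self, model: GeneModel) -> list[int]:
        """Indices of canonical introns wholly contained in the segments."""
        out = []
        for i, intron in enumerate(model.introns):
            if any(seg.contains(intron) for seg in self.segments):
                out.append(i)
        return out


class IncompatibleEvents(ValueError):
    """Raised when an event set cannot be realized on one transcript."""


def _validate_events(model: GeneModel, events: Iterable[SpliceEvent]) -> list[SpliceEvent]:
    events = list(events)
    introns = model.introns
    n_exons = len(model.exons)
    seen: set[tuple[EventKind, int]] = set()
    for ev in events:
        key = (ev.kind, ev.index)
        if key in seen:
            raise IncompatibleEvents(f"duplicate event {ev}")
        seen.add(key)
        if ev.kind is EventKind.EXON_SKIP:
            if not (0 < ev.index < n_exons - 1):
                raise IncompatibleEvents(
                    f"cannot skip terminal exon {ev.index} (gene has {n_exons} exons)"
                )
        else:
            if not (0 <= ev.index < len(introns)):
                raise IncompatibleEvents(f"intron index {ev.index} out of range")
        if ev.kind is EventKind.ALT_3_ACCEPTOR:
            intron = introns[ev.index]
            nxt = introns[ev.index + 1].start if ev.index + 1 < len(introns) else model.span.end
            if not (intron.start < ev.alt_site < nxt):
                raise IncompatibleEvents(
                    f"alt 3' site {ev.alt_site} not inside intron {ev.index} "
                    f"or its downstream exon"
                )
        if ev.kind is EventKind.ALT_5_DONOR:
            intron = introns[ev.index]
            prv = introns[ev.index - 1].end if ev.index > 0 else model.span.start
            if not (prv < ev.alt_site < intron.end):
                raise IncompatibleEvents(
                    f"alt 5' site {ev.alt_site} not inside intron {ev.index} "
                    f"or its upstream exon"
                )
    # pairwise incompatibilities on intron boundaries
    kinds = {(ev.kind, ev.index) for ev in events}
    for kind, i in kinds:
        if kind is EventKind.INTRON_RETENTION:
            for other in (EventKind.ALT_3_ACCEPTOR, EventKind.ALT_5_DONOR):
                if (other, i) in kinds:
                    raise IncompatibleEvents(
                        f"retention and {other.value} both touch intron {i}"
                    )
        if kind is EventKind.EXON_SKIP:
            # skipping exon e removes intron e-1's acceptor and intron e's donor
            for other, j in (
                (EventKind.INTRON_RETENTION, i - 1),
                (EventKind.INTRON_RETENTION, i),
                (EventKind.ALT_3_ACCEPTOR, i - 1),
                (EventKind.ALT_5_DONOR, i),
            ):
                if (other, j) in kinds:
                    raise IncompatibleEvents(
                        f"exon skip of exon {i} conflicts with {other.value} on intron {j}"
                    )
    return events


def apply_events(
    model: GeneModel, events: Iterable[SpliceEvent], name: str = "variant"
) -> TranscriptVariant:
    """Apply a compatible event set to the canonical form of the gene.

    Returns the transcript with its retained genomic segments merged where
    adjacent.  The empty event set yields the canonical fully spliced form.
    """
    events = _validate_events(model, events)
    introns = model.introns
    # removed regions, keyed by intron index; None = intron re-inserted
    removals: dict[int, list[int] | None] = {
        i: [iv.start, iv.end] for i, iv in enumerate(introns)
    }
    for ev in events:
        if ev.kind is EventKind.INTRON_RETENTION:
            removals[ev.index] = None
        elif ev.kind is EventKind.ALT_3_ACCEPTOR:
            removals[ev.index][1] = ev.alt_site
        elif ev.kind is EventKind.ALT_5_DONOR:
            removals[ev.index][0] = ev.alt_site
    for ev in events:
        if ev.kind is EventKind.EXON_SKIP:
            left, right = removals[ev.index - 1], removals[ev.index]
            assert left is not None and right is not None  # enforced above
            removals[ev.index - 1] = None
            removals[ev.index] = [left[0], right[1]]

    removed = sorted(r for r in removals.values() if r is not None)
    span = model.span
    segments: list[Interval] = []
    pos = span.start
    for s, e in removed + [[span.end, span.end]]:
        if s > pos:
            segments.append(Interval(pos, s))
        pos = max(pos, e)
    # merge adjacent segments (cannot normally occur, but harmless)
    merged: list[Interval] = []
    for seg in segments:
        if merged and merged[-1].end == seg.start:
            merged[-1] = Interval(merged[-1].start, seg.end)
        else:
            merged.append(seg)
    seq = extract(model, merged)
    return TranscriptVariant(name=name, segments=merged, seq=seq, events=frozenset(events))


def enumerate_variants(
    model: GeneModel, catalog: Sequence[tuple[str, Iterable[SpliceEvent]]]
) -> list[TranscriptVariant]:
    """Apply each named event set and deduplicate by exact sequence identity."""
    out: list[TranscriptVariant] = []
    by_seq: dict[str, str] = {}
    for name, events in catalog:
        try:
            var = apply_events(model, events, name=name)
        except IncompatibleEvents as err:
            raise IncompatibleEvents(f"event set {name!r}: {err}") from err
        if var.seq in by_seq:
            log.warning(
                "variant %s has the same sequence as %s; merged", name, by_seq[var.seq]
            )
            continue
        by_seq[var.seq] = name
        out.append(var)
    return out


def resplice(
    variant: TranscriptVariant,
    model: GeneModel,
    catalog: Sequence[tuple[str, Iterable[SpliceEvent]]] = (),
) -> list[TranscriptVariant]:
    """Products obtainable by splicing one retained intron out of ``variant``.

    Each retained canonical intron can be removed either canonically or via
    any alternative boundary site present in the catalog for that intron.
    A variant retaining no intron returns an empty list.  Product names are
    taken from the catalog when the product sequence matches an enumerated
    variant.
    """
    retained = variant.retained_introns(model)
    if not retained:
        return []
    # collect alt sites per intron from the catalog
    alt_removals: dict[int, set[tuple[int, int]]] = {}
    named: dict[str, str] = {}
    if catalog:
        for v in enumerate_variants(model, catalog):
            named[v.seq] = v.name
    introns = model.introns
    for _, events in catalog:
        for ev in events:
            if ev.kind is EventKind.ALT_3_ACCEPTOR:
                alt_removals.setdefault(ev.index, set()).add(
                    (introns[ev.index].start, ev.alt_site)
                )
            elif ev.kind is EventKind.ALT_5_DONOR:
                alt_removals.setdefault(ev.index, set()).add(
                    (ev.alt_site, introns[ev.index].end)
                )
    products: list[TranscriptVariant] = []
    seen: set[str] = set()
    for i in retained:
        options = [(introns[i].start, introns[i].end)]
        options += sorted(alt_removals.get(i, ()))
        for s, e in options:
            segs: list[Interval] = []
            ok = True
            for seg in variant.segments:
                if seg.contains(Interval(s, e)):
                    if seg.start < s:
                        segs.append(Interval(seg.start, s))
                    if e < seg.end:
                        segs.append(Interval(e, seg.end))
                elif seg.start >= e or seg.end <= s:
                    segs.append(seg)
                else:
                    ok = False  # removal straddles a junction of this variant
                    break
            if not ok:
                continue
            seq = extract(model, segs)
            if seq in seen:
                continue
            seen.add(seq)
            name = named.get(seq, f"{variant.name}_resplice_i{i}")
            products.append(
                TranscriptVariant(name=name, segments=segs, seq=seq, events=frozenset())
            )
    return products


# --- catalog I/O -----------------------------------------------------------

_KIND_ALIASES = {k.value: k for k in EventKind}


def catalog_from_dict(data: dict) -> list[tuple[str, list[SpliceEvent]]]:
    """Parse a catalog mapping variant name -> list of event dicts."""
    catalog = []
    for name, entries in data.items():
        events = []
        for entry in entries or []:
            kind = _KIND_ALIASES[entry["kind"]]
            events.append(SpliceEvent(kind, entry["index"], entry.get("alt_site")))
        catalog.append((name, events))
    return catalog


def catalog_to_dict(catalog: Sequence[tuple[str, Iterable[SpliceEvent]]]) -> dict:
    out: dict = {}
    for name, events in catalog:
        out[name] = [
            {
                "kind": ev.kind.value,
                "index": ev.index,
                **({"alt_site": ev.alt_site} if ev.alt_site is not None else {}),
            }
            for ev in events
        ]
    return out


def load_catalog(path: str) -> list[tuple[str, list[SpliceEvent]]]:
    with open(path) as fh:
        return catalog_from_dict(yaml.safe_load(fh))


def save_catalog(catalog: Sequence[tuple[str, Iterable[SpliceEvent]]], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(catalog_to_dict(catalog), fh, sort_keys=False)
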