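"""Merging per-fragment copy-state calls into exon-range CNV events.

Within each gene, maximal runs of consecutive fragments (by ``order_index``)
sharing the same non-normal call are reported as one event. ``no_call``
fragments break runs — a QC gap is surfaced, never imputed — and genes are
hard boundaries. Labels follow clinical reporting style: ``"exon 5-10
deletion"``, or ``"part of exon 11 deletion"`` when a run covers a strict
subset of the fragments subdividing one large exon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .panel import Fragment, FragmentPanel, parse_exon_label
from .tr import CALL_DELETION, CALL_DUPLICATION, CALL_NO_CALL, TRResult

STATUS_POSITIVE = "cnv_positive"
STATUS_NEGATIVE = "cnv_negative"


@dataclass(frozen=True)
class CNVEvent:
    """One merged exon-range deletion or duplication in one sample."""

    sample_id: str
    gene: str
    first_fragment: str
    last_fragment: str
    exon_range_label: str
    event_type: str
    n_fragments: int
    mean_tr: float


def _exon_range_label(member_fragments: Sequence[Fragment], panel: FragmentPanel, event_type: str) -> str:
    gene = member_fragments[0].gene
    member_ids = {f.fragment_id for f in member_fragments}
    exons = sorted({f.exon_number() for f in member_fragments})
    lo, hi = exons[0], exons[-1]

    def fully_covered(exon: int) -> bool:
        frags = [f for f in panel.targets(gene) if f.exon_number() == exon]
        return all(f.fragment_id in member_ids for f in frags)

    if lo == hi:
        if fully_covered(lo):
            return f"exon {lo} {event_type}"
        return f"part of exon {lo} {event_type}"
    if all(fully_covered(e) for e in range(lo, hi + 1) if any(
        f.exon_number() == e for f in panel.targets(gene)
    )):
        return f"exon {lo}-{hi} {event_type}"
    return f"exon {lo}-{hi} {event_type} (partial)"


def merge_events(
    results: Iterable[TRResult],
    panel: FragmentPanel,
    *,
    min_fragments: int = 1,
) -> list[CNVEvent]:
    """Merge one sample's per-fragment calls into CNV events.

    Adjacent deletion and duplication runs stay separate events, and a
    ``no_call`` fragment splits an otherwise uniform run in two. Runs
    shorter than ``min_fragments`` are suppressed.
    """
    results = list(results)
    if not results:
        return []
    samples = {r.sample_id for r in results}
    if len(samples) != 1:
        raise ValueError(f"merge_events expects one sample, got {sorted(samples)}")
    (sample_id,) = samples

    by_fragment = {r.fragment_id: r for r in results}
    events: list[CNVEvent] = []
    for gene in panel.genes():
        ordered = [f for f in panel.targets(gene) if f.fragment_id in by_fragment]
        run: list[tuple[Fragment, TRResult]] = []
        run_call: str | None = None

        def flush():
            nonlocal run, run_call
            if run_call in (CALL_DELETION, CALL_DUPLICATION) and len(run) >= min_fragments:
                frags = [f for f, _ in run]
                trs = [r.tr for _, r in run if r.tr is not None]
                events.append(
                    CNVEvent(
                        sample_id=sample_id,
                        gene=gene,
                        first_fragment=frags[0].fragment_id,
                        last_fragment=frags[-1].fragment_id,
                        exon_range_label=_exon_range_label(frags, panel, run_call),
                        event_type=run_call,
                        n_fragments=len(frags),
                        mean_tr=sum(trs) / len(trs) if trs else float("nan"),
                    )
                )
            run, run_call = [], None

        prev_idx: int | None = None
        for frag in ordered:
            res = by_fragment[frag.fragment_id]
            contiguous = prev_idx is None or frag.order_index == prev_idx + 1
            if res.call != run_call or not contiguous:
                flush()
                run_call = res.call
            if res.call in (CALL_DELETION, CALL_DUPLICATION):
                run.append((frag, res))
            prev_idx = frag.order_index
        flush()
    return events


def qc_gaps(results: Iterable[TRResult]) -> list[TRResult]:
    """The ``no_call`` fragments of a sample, surfaced as QC gaps."""
    return [r for r in results if r.call == CALL_NO_CALL]


def sample_status(events: Iterable[CNVEvent]) -> str:
    """A sample is CNV-positive iff it carries at least one event."""
    return STATUS_POSITIVE if any(True for _ in events) else STATUS_NEGATIVE
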