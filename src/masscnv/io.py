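"""Reading and writing the assay's on-disk tables.

Intensity input is a long-format TSV with one row per sample x fragment and
four required columns: ``sample_id``, ``fragment_id``, ``intensity_template``,
``intensity_competitor``. This deliberately abstracts away any particular
spectrometer export; adapting a vendor export means producing this table.

Call output is a pair of TSVs: a per-fragment table (one row per target
fragment with its TR, call and QC flags) and a per-event table (one row per
merged exon-range CNV event).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import IntensityParseError
from .panel import FragmentPanel

INTENSITY_COLUMNS = ["sample_id", "fragment_id", "intensity_template", "intensity_competitor"]

CALL_COLUMNS = [
    "sample_id",
    "fragment_id",
    "gene",
    "exon_label",
    "ratio_raw",
    "normalizer",
    "tr",
    "call",
    "qc_flags",
]

EVENT_COLUMNS = [
    "sample_id",
    "gene",
    "event_type",
    "exon_range_label",
    "first_fragment",
    "last_fragment",
    "n_fragments",
    "mean_tr",
]


@dataclass(frozen=True)
class IntensityRecord:
    """One sample x fragment measurement: template and competitor peak
    intensities in arbitrary (but shared) spectrometer units."""

    sample_id: str
    fragment_id: str
    intensity_template: float
    intensity_competitor: float


def read_intensities(path: str | Path, panel: FragmentPanel) -> list[IntensityRecord]:
    """Parse an intensity TSV, validating every row against the panel.

    Rows referencing fragments absent from the panel, negative intensities,
    or duplicate (sample, fragment) pairs raise :class:`IntensityParseError`
    carrying the offending 1-based line number. Records are returned in file
    order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "fragment_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise IntensityParseError(f"{path}: {exc}") from exc
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise IntensityParseError(f"{path}: missing column(s) {missing}")

    known = {f.fragment_id for f in panel.fragments}
    records: list[IntensityRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        frag = row.fragment_id
        if frag not in known:
            raise IntensityParseError(f"unknown fragment_id {frag!r}", line=line)
        t = float(row.intensity_template)
        c = float(row.intensity_competitor)
        if not (math.isfinite(t) and math.isfinite(c)):
            raise IntensityParseError(f"non-finite intensity for {frag!r}", line=line)
        if t < 0 or c < 0:
            raise IntensityParseError(f"negative intensity for {frag!r}", line=line)
        key = (row.sample_id, frag)
        if key in seen:
            raise IntensityParseError(f"duplicate (sample, fragment) pair {key}", line=line)
        seen.add(key)
        records.append(IntensityRecord(row.sample_id, frag, t, c))
    return records


def intensities_to_frame(records: Iterable[IntensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.fragment_id, r.intensity_template, r.intensity_competitor) for r in records],
        columns=INTENSITY_COLUMNS,
    )


def write_intensities(records: Iterable[IntensityRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write an intensity table; numeric values keep 12 significant digits."""
    df = records if isinstance(records, pd.DataFrame) else intensities_to_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", lineterminator="\n")


def write_calls(results: Sequence, events: Sequence, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write per-fragment calls and per-event tables.

    ``results`` are :class:`~masscnv.tr.TRResult` and ``events`` are
    :class:`~masscnv.events.CNVEvent`. Produces ``<prefix>.calls.tsv`` and
    ``<prefix>.events.tsv``; TR values are written with 4 decimal places.
    """
    if not results:
        raise ValueError("write_calls requires a non-empty result collection")
    out_prefix = Path(out_prefix)
    calls_path = out_prefix.with_name(out_prefix.name + ".calls.tsv")
    events_path = out_prefix.with_name(out_prefix.name + ".events.tsv")

    call_rows = []
    for r in results:
        call_rows.append(
            {
                "sample_id": r.sample_id,
                "fragment_id": r.fragment_id,
                "gene": r.gene,
                "exon_label": r.exon_label,
                "ratio_raw": _fmt4(r.ratio_raw),
                "normalizer": _fmt4(r.normalizer),
                "tr": _fmt4(r.tr),
                "call": r.call,
                "qc_flags": ";".join(sorted(r.qc_flags)) if r.qc_flags else ".",
            }
        )
    pd.DataFrame(call_rows, columns=CALL_COLUMNS).to_csv(
        calls_path, sep="\t", index=False, lineterminator="\n"
    )

    event_rows = []
    for e in events:
        event_rows.append(
            {
                "sample_id": e.sample_id,
                "gene": e.gene,
                "event_type": e.event_type,
                "exon_range_label": e.exon_range_label,
                "first_fragment": e.first_fragment,
                "last_fragment": e.last_fragment,
                "n_fragments": e.n_fragments,
                "mean_tr": _fmt4(e.mean_tr),
            }
        )
    pd.DataFrame(event_rows, columns=EVENT_COLUMNS).to_csv(
        events_path, sep="\t", index=False, lineterminator="\n"
    )
    return calls_path, events_path


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "fragment_id": str})


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def _fmt4(x: float | None) -> str:
    return "NA" if x is None else f"{x:.4f}"
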