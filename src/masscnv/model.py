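"""High-level modelling interface: :class:`TargetRatioModel` holds the data
(intensity records + panel) and the calling configuration; ``fit()`` runs
the double-calibration TR computation, cutoff calling and event merging and
returns a :class:`TargetRatioResults` carrying per-fragment TR estimates,
QC diagnostics, merged events, per-sample statuses and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import io as _io
from .events import CNVEvent, STATUS_NEGATIVE, STATUS_POSITIVE, merge_events, qc_gaps, sample_status
from .io import IntensityRecord
from .panel import FragmentPanel, read_panel
from .tr import (
    DEFAULT_CUTOFFS,
    DEFAULT_QC,
    CALL_NO_CALL,
    Cutoffs,
    QCThresholds,
    TRResult,
    compute_tr,
)


class TargetRatioModel:
    """Competitor + reference-gene calibrated dosage model for one batch.

    Parameters
    ----------
    records
        Intensity records (or a long-format DataFrame with the four
        standard columns) for one or many samples.
    panel
        Validated assay panel.
    cutoffs, qc, norm, min_fragments
        Calling configuration: TR thresholds, peak QC, reference
        aggregation mode ("mean", "median" or "geomean") and the minimum
        run length for an event.
    """

    def __init__(
        self,
        records: Iterable[IntensityRecord] | pd.DataFrame,
        panel: FragmentPanel,
        *,
        cutoffs: Cutoffs = DEFAULT_CUTOFFS,
        qc: QCThresholds = DEFAULT_QC,
        norm: str = "mean",
        min_fragments: int = 1,
    ):
        if isinstance(records, pd.DataFrame):
            records = [
                IntensityRecord(
                    str(r.sample_id), str(r.fragment_id),
                    float(r.intensity_template), float(r.intensity_competitor),
                )
                for r in records.itertuples(index=False)
            ]
        self.records = list(records)
        self.panel = panel
        self.cutoffs = cutoffs
        self.qc = qc
        self.norm = norm
        self.min_fragments = min_fragments

    @classmethod
    def from_files(
        cls, panel_path: str | Path, intensities_path: str | Path, **kwargs
    ) -> "TargetRatioModel":
        panel = read_panel(panel_path)
        records = _io.read_intensities(intensities_path, panel)
        return cls(records, panel, **kwargs)

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.sample_id, None)
        return list(seen)

    def fit(self) -> "TargetRatioResults":
        """Run TR computation, copy-state calling and event merging."""
        results: list[TRResult] = []
        events: list[CNVEvent] = []
        statuses: dict[str, str] = {}
        per_sample: dict[str, list[IntensityRecord]] = {}
        for r in self.records:
            per_sample.setdefault(r.sample_id, []).append(r)
        for sample_id, recs in per_sample.items():
            sample_results = compute_tr(
                recs, self.panel, qc=self.qc, norm=self.norm, cutoffs=self.cutoffs
            )
            sample_events = merge_events(
                sample_results, self.panel, min_fragments=self.min_fragments
            )
            results.extend(sample_results)
            events.extend(sample_events)
            statuses[sample_id] = sample_status(sample_events)
        return TargetRatioResults(self, results, events, statuses)


@dataclass
class TargetRatioResults:
    """Fitted calls for a batch: per-fragment TR values, merged events,
    per-sample statuses and QC diagnostics."""

    model: TargetRatioModel
    results: list[TRResult]
    events: list[CNVEvent]
    statuses: dict[str, str]

    # -- tabular views ---------------------------------------------------
    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "fragment_id": r.fragment_id,
                    "gene": r.gene,
                    "exon_label": r.exon_label,
                    "ratio_raw": r.ratio_raw,
                    "normalizer": r.normalizer,
                    "tr": r.tr,
                    "call": r.call,
                    "qc_flags": ";".join(sorted(r.qc_flags)) if r.qc_flags else "",
                }
                for r in self.results
            ]
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": e.sample_id,
                    "gene": e.gene,
                    "event_type": e.event_type,
                    "exon_range_label": e.exon_range_label,
                    "first_fragment": e.first_fragment,
                    "last_fragment": e.last_fragment,
                    "n_fragments": e.n_fragments,
                    "mean_tr": e.mean_tr,
                }
                for e in self.events
            ],
            columns=_io.EVENT_COLUMNS,
        )

    def status_map(self) -> dict[str, str]:
        return dict(self.statuses)

    def positive_samples(self) -> list[str]:
        return [s for s, st in self.statuses.items() if st == STATUS_POSITIVE]

    def no_call_results(self) -> list[TRResult]:
        return qc_gaps(self.results)

    # -- persistence -----------------------------------------------------
    def to_files(self, out_prefix: str | Path) -> tuple[Path, Path]:
        return _io.write_calls(self.results, self.events, out_prefix)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        n_samples = len(self.statuses)
        n_pos = len(self.positive_samples())
        n_nocall = len(self.no_call_results())
        lines = [
            "Target Ratio copy-number calling",
            "=" * 48,
            f"Panel:              {self.model.panel.name}"
            f" ({len(self.model.panel.targets())} targets, "
            f"{len(self.model.panel.references())} references)",
            f"Samples:            {n_samples}",
            f"Cutoffs:            deletion TR <= {self.model.cutoffs.deletion_max:g}, "
            f"duplication TR >= {self.model.cutoffs.duplication_min:g}",
            f"Normalization:      {self.model.norm} (within-well"
            f"{', pooled' if self.model.panel.pooled_normalization else ''})",
            f"CNV-positive:       {n_pos}",
            f"CNV-negative:       {n_samples - n_pos}",
            f"No-call fragments:  {n_nocall}",
        ]
        if self.events:
            lines.append("-" * 48)
            lines.append("Events:")
            for e in self.events:
                lines.append(
                    f"  {e.sample_id}  {e.gene}  {e.exon_range_label}"
                    f"  (n={e.n_fragments}, mean TR={e.mean_tr:.2f})"
                )
        return "\n".join(lines)

    # -- plotting --------------------------------------------------------
    def plot_tr(self, sample_id: str, ax=None):
        """Scatter of TR by fragment order for one sample, with cutoff
        lines; the assay's standard per-sample diagnostic view."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots(figsize=(10, 3.5))
        sample = [r for r in self.results if r.sample_id == sample_id and r.tr is not None]
        if not sample:
            raise ValueError(f"no callable fragments for sample {sample_id!r}")
        xs = range(len(sample))
        colors = {"deletion": "tab:red", "duplication": "tab:blue", "normal": "0.4"}
        ax.scatter(xs, [r.tr for r in sample], c=[colors.get(r.call, "0.4") for r in sample], s=18)
        ax.axhline(self.model.cutoffs.deletion_max, ls="--", lw=0.8, color="tab:red")
        ax.axhline(self.model.cutoffs.duplication_min, ls="--", lw=0.8, color="tab:blue")
        ax.axhline(1.0, ls=":", lw=0.8, color="0.6")
        ax.set_xticks(list(xs))
        ax.set_xticklabels([f"{r.gene}:{r.exon_label}" for r in sample], rotation=90, fontsize=5)
        ax.set_ylabel("TR")
        ax.set_title(f"{sample_id} — {self.statuses.get(sample_id, '?')}")
        return ax
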