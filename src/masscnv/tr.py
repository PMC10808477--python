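"""Target Ratio (TR) computation and copy-state calling.

The dosage statistic of the assay is a doubly calibrated intensity ratio.
For each fragment the template gDNA is co-amplified with a *competitor*
oligonucleotide (identical sequence apart from one base, same primers,
known input copies), so the raw ratio

    r(f) = intensity_template(f) / intensity_competitor(f)

cancels the fragment's amplification and extension efficiency. A second
calibration divides by the aggregate raw ratio of the internal diploid
reference fragments (RNaseP, EIF2C1, ALB) co-amplified in the same
multiplex well:

    TR(f) = r(f) / aggregate_i r(R_i)

With competitor input matched to two genomic copies, TR estimates
copy_number / 2: heterozygous deletions sit near 0.5, diploid fragments
near 1.0, duplications near 1.5. Fragments with TR <= 0.65 are called
deletions and TR >= 1.30 duplications (boundaries inclusive).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import CalibrationError, UncallableSampleError
from .io import IntensityRecord
from .panel import FragmentPanel

CALL_DELETION = "deletion"
CALL_NORMAL = "normal"
CALL_DUPLICATION = "duplication"
CALL_NO_CALL = "no_call"

FLAG_LOW_INTENSITY = "low_intensity"
FLAG_MISSING_PEAK = "missing_peak"
FLAG_NO_REFERENCE = "no_reference"

NORM_MODES = ("mean", "median", "geomean")


@dataclass(frozen=True)
class Cutoffs:
    """TR thresholds for copy-state calling (both boundaries inclusive)."""

    deletion_max: float = 0.65
    duplication_min: float = 1.30

    def __post_init__(self):
        if not (0 < self.deletion_max < 1 < self.duplication_min):
            raise CalibrationError(
                f"cutoffs must satisfy 0 < deletion_max < 1 < duplication_min, "
                f"got ({self.deletion_max}, {self.duplication_min})"
            )


DEFAULT_CUTOFFS = Cutoffs()


@dataclass(frozen=True)
class QCThresholds:
    """Peak-level QC. ``min_intensity`` defaults to 0: any positive peak is
    accepted, and the ``low_intensity`` flag fires only below a user-raised
    threshold. A zero competitor peak always fails (``missing_peak``)."""

    min_intensity: float = 0.0


DEFAULT_QC = QCThresholds()


@dataclass(frozen=True)
class TRResult:
    """TR value and copy-state call for one target fragment of one sample.

    ``tr = ratio_raw / normalizer`` whenever the fragment is callable;
    QC-failed fragments carry ``call == "no_call"``, a non-empty
    ``qc_flags`` set and ``tr is None``.
    """

    sample_id: str
    fragment_id: str
    gene: str
    exon_label: str
    ratio_raw: float | None
    normalizer: float | None
    tr: float | None
    call: str
    qc_flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if (self.call == CALL_NO_CALL) != bool(self.qc_flags):
            raise ValueError("no_call iff qc_flags non-empty")


def call_fragment(tr: float, cutoffs: Cutoffs = DEFAULT_CUTOFFS) -> str:
    """Classify a positive TR value as deletion / normal / duplication."""
    if not (tr > 0):
        raise ValueError(f"TR must be positive, got {tr}")
    return _classify(tr, cutoffs)


def _classify(tr: float, cutoffs: Cutoffs) -> str:
    # tr == 0 (homozygous deletion: no template peak) is classified here too
    if tr <= cutoffs.deletion_max:
        return CALL_DELETION
    if tr >= cutoffs.duplication_min:
        return CALL_DUPLICATION
    return CALL_NORMAL


def _aggregate(values: Sequence[float], mode: str) -> float:
    if mode == "mean":
        return float(np.mean(values))
    if mode == "median":
        return float(np.median(values))
    if mode == "geomean":
        return float(np.exp(np.mean(np.log(values))))
    raise ValueError(f"unknown normalization mode {mode!r}; expected one of {NORM_MODES}")


def _qc_flags(template: float, competitor: float, qc: QCThresholds) -> frozenset[str]:
    flags = set()
    if competitor <= 0:
        flags.add(FLAG_MISSING_PEAK)
    if template < qc.min_intensity or competitor < qc.min_intensity:
        flags.add(FLAG_LOW_INTENSITY)
    return frozenset(flags)


def compute_tr(
    records: Iterable[IntensityRecord],
    panel: FragmentPanel,
    *,
    qc: QCThresholds = DEFAULT_QC,
    norm: str = "mean",
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
) -> list[TRResult]:
    """Compute TR and copy-state calls for every target fragment of one sample.

    Normalization is within-well unless the panel enables
    ``pooled_normalization``, in which case all QC-passing references of the
    sample form a single normalizer. Reference fragments with a missing
    template or competitor peak (or below ``qc.min_intensity``) are excluded
    from the normalizer; if a well retains no usable reference, its targets
    are flagged ``no_reference``. A sample with no usable reference anywhere
    raises :class:`UncallableSampleError`.
    """
    records = list(records)
    samples = {r.sample_id for r in records}
    if len(samples) != 1:
        raise ValueError(f"compute_tr expects records from exactly one sample, got {sorted(samples)}")
    (sample_id,) = samples
    by_fragment = {r.fragment_id: r for r in records}

    # reference raw ratios per well
    ref_ratios: dict[str, list[float]] = {}
    for ref in panel.references():
        rec = by_fragment.get(ref.fragment_id)
        if rec is None:
            continue
        # a reference with no template peak cannot report diploid dosage
        if rec.intensity_competitor <= 0 or rec.intensity_template <= 0:
            continue
        if rec.intensity_template < qc.min_intensity or rec.intensity_competitor < qc.min_intensity:
            continue
        ref_ratios.setdefault(ref.well, []).append(rec.intensity_template / rec.intensity_competitor)

    all_ref = [v for vs in ref_ratios.values() for v in vs]
    if not all_ref:
        raise UncallableSampleError(
            f"uncallable sample {sample_id!r}: no QC-passing reference fragment in any well"
        )
    pooled_norm = _aggregate(all_ref, norm)

    results: list[TRResult] = []
    for frag in panel.targets():
        rec = by_fragment.get(frag.fragment_id)
        if rec is None:
            results.append(
                TRResult(
                    sample_id, frag.fragment_id, frag.gene, frag.exon_label,
                    None, None, None, CALL_NO_CALL, frozenset({FLAG_MISSING_PEAK}),
                )
            )
            continue
        flags = _qc_flags(rec.intensity_template, rec.intensity_competitor, qc)
        if panel.pooled_normalization:
            normalizer = pooled_norm
        elif frag.well in ref_ratios:
            normalizer = _aggregate(ref_ratios[frag.well], norm)
        else:
            flags = flags | {FLAG_NO_REFERENCE}
            normalizer = None
        if flags:
            results.append(
                TRResult(
                    sample_id, frag.fragment_id, frag.gene, frag.exon_label,
                    None, None, None, CALL_NO_CALL, frozenset(flags),
                )
            )
            continue
        ratio_raw = rec.intensity_template / rec.intensity_competitor
        tr = ratio_raw / normalizer
        results.append(
            TRResult(
                sample_id, frag.fragment_id, frag.gene, frag.exon_label,
                ratio_raw, normalizer, tr, _classify(tr, cutoffs),
            )
        )
    return results


def compute_tr_table(
    records: Iterable[IntensityRecord],
    panel: FragmentPanel,
    *,
    qc: QCThresholds = DEFAULT_QC,
    norm: str = "mean",
    cutoffs: Cutoffs = DEFAULT_CUTOFFS,
) -> list[TRResult]:
    """Batch variant of :func:`compute_tr` over a multi-sample record table.

    Samples are processed independently, in first-appearance order.
    """
    per_sample: dict[str, list[IntensityRecord]] = {}
    for r in records:
        per_sample.setdefault(r.sample_id, []).append(r)
    out: list[TRResult] = []
    for sample_records in per_sample.values():
        out.extend(compute_tr(sample_records, panel, qc=qc, norm=norm, cutoffs=cutoffs))
    return out


def calibrate_cutoffs(
    negative_controls: Sequence[float],
    deletion_standards: Sequence[float] = (),
    duplication_standards: Sequence[float] = (),
    k: float = 5.0,
) -> Cutoffs:
    """Derive TR cutoffs from diploid negative controls and optional
    CNV-positive standards.

    The primary rule places cutoffs at ``mean(neg) -/+ k * sd(neg)``
    (default k = 5). When positive standards are supplied and the k-rule
    fails to separate them from the controls, the cutoff falls back to the
    midpoint between the controls' extreme quantile (0.1% / 99.9%) and the
    nearest standard, provided that midpoint does separate the two label
    sets. The returned cutoffs classify every supplied standard correctly,
    otherwise a :class:`CalibrationError` lists the irreconcilable values.
    """
    neg = np.asarray(list(negative_controls), dtype=float)
    if neg.size < 20:
        raise CalibrationError(f"need >= 20 negative-control TR values, got {neg.size}")
    dels = sorted(float(x) for x in deletion_standards)
    dups = sorted(float(x) for x in duplication_standards)

    m = float(np.mean(neg))
    s = float(np.std(neg, ddof=1))
    deletion_max = m - k * s
    duplication_min = m + k * s

    neg_min, neg_max = float(np.min(neg)), float(np.max(neg))
    if dels:
        del_hi = max(dels)
        if not (del_hi <= deletion_max < neg_min):
            mid = (float(np.quantile(neg, 0.001)) + del_hi) / 2.0
            if del_hi <= mid < neg_min:
                deletion_max = mid
            else:
                overlap = [x for x in dels if x >= neg_min]
                raise CalibrationError(
                    "deletion standards overlap the diploid control distribution: "
                    f"standards {overlap or dels} vs control minimum {neg_min:.4f}"
                )
    if dups:
        dup_lo = min(dups)
        if not (neg_max < duplication_min <= dup_lo):
            mid = (float(np.quantile(neg, 0.999)) + dup_lo) / 2.0
            if neg_max < mid <= dup_lo:
                duplication_min = mid
            else:
                overlap = [x for x in dups if x <= neg_max]
                raise CalibrationError(
                    "duplication standards overlap the diploid control distribution: "
                    f"standards {overlap or dups} vs control maximum {neg_max:.4f}"
                )

    try:
        cutoffs = Cutoffs(deletion_max, duplication_min)
    except CalibrationError as exc:
        raise CalibrationError(
            f"calibrated cutoffs ({deletion_max:.4f}, {duplication_min:.4f}) are degenerate "
            f"(control sd = {s:.4g}); {exc}"
        ) from exc

    misclassified = [x for x in dels if call_fragment(x, cutoffs) != CALL_DELETION]
    misclassified += [x for x in dups if call_fragment(x, cutoffs) != CALL_DUPLICATION]
    if misclassified:
        raise CalibrationError(f"cutoffs fail to classify standards: {misclassified}")
    return cutoffs
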