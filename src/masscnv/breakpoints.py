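"""Breakpoint characterization for large genomic rearrangements.

Given a deletion/duplication expressed in HGVS-like genomic coordinates
(``g.61,101_98,034del`` on a RefSeqGene record), this module computes the
event size, the junction (micro)homology length against a reference
sequence, and a rearrangement-mechanism class:

* **NAHR** — non-allelic homologous recombination, signalled by extended
  junction identity (default >= 30 bp) or by both breakpoints falling in
  repeat elements of the same family (e.g. two Alu subfamilies);
* **NHEJ** — non-homologous end-joining, <= a few bp of homology
  (default <= 3);
* **MMEJ** — microhomology-mediated end-joining, in between;
* **ambiguous** — repeat evidence and homology contradict each other.

Coordinate conventions are explicit and centralized: HGVS g. positions are
1-based inclusive, BED intervals 0-based half-open; :func:`g_to_bed_pos`
is the single conversion point.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import BreakpointError

KIND_DEL = "del"
KIND_DUP = "dup"

MECH_NAHR = "NAHR"
MECH_NHEJ = "NHEJ"
MECH_MMEJ = "MMEJ"
MECH_AMBIGUOUS = "ambiguous"

_HGVS_G_RE = re.compile(
    r"^(?:(?P<ref>[A-Za-z0-9_.]+):)?g\.(?P<start>\d[\d,]*)_(?P<end>\d[\d,]*)(?P<kind>del|dup)$"
)


@dataclass(frozen=True)
class GenomicVariant:
    """A deletion or duplication in 1-based inclusive genomic coordinates."""

    sequence_name: str
    start: int
    end: int
    kind: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise BreakpointError(
                f"require 1 <= start <= end, got start={self.start}, end={self.end}"
            )
        if self.kind not in (KIND_DEL, KIND_DUP):
            raise BreakpointError(f"kind must be 'del' or 'dup', got {self.kind!r}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MechanismThresholds:
    """Homology thresholds in bp; both are exposed because published
    mechanism assignments rarely state numeric criteria."""

    nahr_min: int = 30
    nhej_max: int = 3

    def __post_init__(self):
        if not (0 <= self.nhej_max < self.nahr_min):
            raise BreakpointError("require 0 <= nhej_max < nahr_min")


DEFAULT_THRESHOLDS = MechanismThresholds()


@dataclass(frozen=True)
class BreakpointReport:
    variant: GenomicVariant
    size_bp: int
    homology_len: int
    mechanism: str
    repeat_left: str | None = None
    repeat_right: str | None = None


def parse_hgvs_g(text: str) -> GenomicVariant:
    """Parse ``[refseq:]g.<start>_<end>(del|dup)``; thousands separators in
    the coordinates are tolerated and stripped."""
    m = _HGVS_G_RE.match(text.strip())
    if m is None:
        raise BreakpointError(f"unparseable coordinate string {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    return GenomicVariant(
        sequence_name=m.group("ref") or "",
        start=start,
        end=end,
        kind=m.group("kind"),
    )


def event_size(v: GenomicVariant) -> int:
    """Event size in bp (1-based inclusive span)."""
    return v.size


def junction_homology(v: GenomicVariant, reference: str) -> tuple[int, tuple[int, int]]:
    """Junction homology length and the range of shift-equivalent starts.

    For a deletion of [start, end], the placement may slide right by one
    whenever the first retained base past the junction equals the first
    deleted base, and left symmetrically; every slid placement produces the
    identical mutant molecule. The homology length is the total number of
    such alternative placements minus one, i.e. right-extension +
    left-extension. The same sliding argument applies verbatim to a tandem
    duplication junction, so both kinds share this computation.

    Returns ``(homology_len, (min_start, max_start))`` over equivalent
    placements of the proximal breakpoint.
    """
    ref = str(reference).upper()
    if v.end > len(ref):
        raise BreakpointError(
            f"reference of length {len(ref)} does not cover required span 1..{v.end}"
        )
    s0, e0 = v.start - 1, v.end - 1  # 0-based inclusive

    right = 0
    while e0 + 1 + right < len(ref) and ref[s0 + right] == ref[e0 + 1 + right]:
        right += 1
    left = 0
    while s0 - 1 - left >= 0 and ref[s0 - 1 - left] == ref[e0 - left]:
        left += 1
    return left + right, (v.start - left, v.start + right)


def _repeat_family(name: str | None) -> str | None:
    if name is None:
        return None
    return "Alu" if name.lower().startswith("alu") else name


def classify_mechanism(
    homology_len: int,
    repeat_left: str | None = None,
    repeat_right: str | None = None,
    thresholds: MechanismThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Assign a rearrangement mechanism from junction homology and optional
    repeat annotations at the two breakpoints."""
    if homology_len < 0:
        raise BreakpointError("homology_len must be non-negative")
    same_family = (
        repeat_left is not None
        and repeat_right is not None
        and _repeat_family(repeat_left) == _repeat_family(repeat_right)
    )
    if homology_len >= thresholds.nahr_min:
        return MECH_NAHR
    if same_family:
        # repeats say NAHR but the junction shows no meaningful identity
        if homology_len <= thresholds.nhej_max:
            return MECH_AMBIGUOUS
        return MECH_NAHR
    if homology_len <= thresholds.nhej_max:
        return MECH_NHEJ
    return MECH_MMEJ


# ---------------------------------------------------------------------------
# Repeat annotation (BED consumption)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedInterval:
    """0-based half-open interval with a name, as in BED column 1-4."""

    chrom: str
    start: int
    end: int
    name: str
    line: int = 0  # 1-based source line, for tie-breaking and messages


def g_to_bed_pos(position_1based: int) -> int:
    """Convert a 1-based genomic position to its 0-based BED point."""
    return position_1based - 1


def read_bed(path: str | Path) -> list[BedInterval]:
    """Parse a minimal 4+-column BED file (chrom, start, end, name)."""
    intervals: list[BedInterval] = []
    for i, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
        line_no = i + 1
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise BreakpointError(f"{path}: line {line_no}: expected >= 4 BED columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise BreakpointError(f"{path}: line {line_no}: non-integer coordinates") from exc
        if not (0 <= start < end):
            raise BreakpointError(f"{path}: line {line_no}: require 0 <= start < end")
        intervals.append(BedInterval(parts[0], start, end, parts[3], line=line_no))
    return intervals


def _pick_repeat(
    point0: int, span: tuple[int, int], intervals: Sequence[BedInterval], chrom: str
) -> str | None:
    """Repeat containing a breakpoint point; ties broken by largest overlap
    with the variant span, then earliest in file."""
    candidates = [
        iv
        for iv in intervals
        if (not chrom or not iv.chrom or iv.chrom == chrom) and iv.start <= point0 < iv.end
    ]
    if not candidates:
        return None
    lo, hi = span  # 0-based half-open variant span

    def overlap(iv: BedInterval) -> int:
        return max(0, min(iv.end, hi) - max(iv.start, lo))

    best = max(candidates, key=lambda iv: (overlap(iv), -iv.line))
    return best.name


def annotate_repeats(
    v: GenomicVariant, repeats: Sequence[BedInterval]
) -> tuple[str | None, str | None]:
    """Repeat elements (if any) overlapping the proximal and distal
    breakpoint positions."""
    span = (g_to_bed_pos(v.start), v.end)  # 0-based half-open
    left = _pick_repeat(g_to_bed_pos(v.start), span, repeats, v.sequence_name)
    right = _pick_repeat(g_to_bed_pos(v.end), span, repeats, v.sequence_name)
    return left, right


def characterize(
    v: GenomicVariant,
    reference: str | None = None,
    repeats: Sequence[BedInterval] = (),
    thresholds: MechanismThresholds = DEFAULT_THRESHOLDS,
) -> BreakpointReport:
    """Full breakpoint report: size, junction homology (when a reference is
    supplied), repeat annotation and mechanism class."""
    homology = 0
    if reference is not None:
        homology, _ = junction_homology(v, reference)
    left, right = annotate_repeats(v, repeats) if repeats else (None, None)
    return BreakpointReport(
        variant=v,
        size_bp=v.size,
        homology_len=homology,
        mechanism=classify_mechanism(homology, left, right, thresholds),
        repeat_left=left,
        repeat_right=right,
    )


# ---------------------------------------------------------------------------
# Primer SNP screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerFlag:
    primer_name: str
    chrom: str
    positions: tuple[int, ...]  # 1-based positions of offending variants
    mafs: tuple[float, ...]


@dataclass(frozen=True)
class PrimerScreenResult:
    flagged: tuple[PrimerFlag, ...]
    n_primers: int
    n_variants: int
    n_skipped_no_frequency: int

    def flagged_names(self) -> list[str]:
        return [f.primer_name for f in self.flagged]


def read_variant_frequencies(path: str | Path) -> pd.DataFrame:
    """Load a variant table with allele frequencies.

    Accepts a VCF (allele frequency from the INFO ``AF`` field; records
    without it are skipped and counted) or a TSV with columns
    ``chrom``, ``pos`` (1-based) and ``af``. Returns a DataFrame with
    columns chrom/pos/af and an ``n_skipped`` attribute in ``df.attrs``.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf") or path.name.endswith(".vcf.gz"):
        from cyvcf2 import VCF

        rows = []
        skipped = 0
        for record in VCF(str(path)):
            af = record.INFO.get("AF")
            if af is None:
                skipped += 1
                continue
            if isinstance(af, (tuple, list)):
                af = af[0]
            rows.append({"chrom": record.CHROM, "pos": record.POS, "af": float(af)})
        df = pd.DataFrame(rows, columns=["chrom", "pos", "af"])
        df.attrs["n_skipped"] = skipped
        return df
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("chrom", "pos", "af") if c not in df.columns]
    if missing:
        raise BreakpointError(f"{path}: variant TSV missing column(s) {missing}")
    skipped = int(df["af"].isna().sum())
    df = df.dropna(subset=["af"]).reset_index(drop=True)
    df.attrs["n_skipped"] = skipped
    return df


def screen_primers(
    primers: Sequence[BedInterval],
    variants: pd.DataFrame,
    maf_max: float = 0.005,
) -> PrimerScreenResult:
    """Flag primers whose binding interval contains a common variant.

    A primer is flagged iff at least one overlapping variant has minor
    allele frequency MAF = min(AF, 1 - AF) above ``maf_max`` (default 0.5%).
    An SNV under a primer suppresses amplification of one genomic allele
    while leaving the competitor untouched, so such primers create
    deletion-mimicking artifacts and must be redesigned.
    """
    n_skipped = int(variants.attrs.get("n_skipped", 0))
    if n_skipped:
        warnings.warn(f"{n_skipped} variant(s) without allele frequency were skipped")
    flagged = []
    for primer in primers:
        hits_pos: list[int] = []
        hits_maf: list[float] = []
        for row in variants.itertuples(index=False):
            if primer.chrom and str(row.chrom) != primer.chrom:
                continue
            pos0 = g_to_bed_pos(int(row.pos))
            if not (primer.start <= pos0 < primer.end):
                continue
            af = float(row.af)
            maf = min(af, 1.0 - af)
            if maf > maf_max:
                hits_pos.append(int(row.pos))
                hits_maf.append(maf)
        if hits_pos:
            flagged.append(
                PrimerFlag(primer.name, primer.chrom, tuple(hits_pos), tuple(hits_maf))
            )
    return PrimerScreenResult(
        flagged=tuple(flagged),
        n_primers=len(primers),
        n_variants=len(variants),
        n_skipped_no_frequency=n_skipped,
    )
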