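"""Synthetic intensity-table generator with known copy-number truth.

The generative model mirrors the physics of a competitor-calibrated iPLEX
dosage assay. For sample s and fragment f:

* a shared amplification efficiency ``a ~ LogNormal(0, sigma_efficiency^2)``
  multiplies both template and competitor peaks (same primers, same well
  chemistry) — the competitor exists precisely so this factor cancels;
* the competitor is always spiked at two-copy equivalent dosage, while the
  template dosage equals the fragment's true copy number, optionally
  reduced by an allele-dropout artifact: an SNV under a primer binding
  site suppresses amplification of one genomic allele by a fraction
  ``delta`` while leaving the competitor untouched, which is the assay's
  false-positive mechanism;
* independent multiplicative lognormal measurement noise
  ``exp(eps), eps ~ Normal(0, sigma_noise^2)`` perturbs each peak;
* with probability ``missing_peak_prob`` a fragment's competitor peak is
  zeroed, producing a QC failure downstream.

Identical seeds give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .events import CNVEvent, STATUS_NEGATIVE, STATUS_POSITIVE, merge_events
from .io import INTENSITY_COLUMNS
from .panel import Fragment, FragmentPanel
from .tr import CALL_DELETION, CALL_DUPLICATION, CALL_NORMAL, TRResult


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    ``truth`` lists departures from the diploid default as
    ``(sample_id, fragment_ids, copy_number)`` with copy number in 0..4;
    ``artifacts`` lists allele-dropout artifacts as
    ``(sample_id, fragment_id, delta)`` with dropout fraction delta in [0, 1].
    Reference fragments are assumed diploid and may appear in neither list.
    """

    panel: FragmentPanel
    n_samples: int
    truth: tuple = ()
    artifacts: tuple = ()
    sigma_noise: float = 0.05
    sigma_efficiency: float = 0.3
    base_intensity: float = 10000.0
    missing_peak_prob: float = 0.0
    seed: int = 0
    sample_ids: tuple[str, ...] | None = None

    def resolved_sample_ids(self) -> tuple[str, ...]:
        if self.sample_ids is not None:
            return self.sample_ids
        return tuple(f"S{i + 1:03d}" for i in range(self.n_samples))

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be positive")
        for name, value in (("sigma_noise", self.sigma_noise), ("sigma_efficiency", self.sigma_efficiency)):
            if value < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.base_intensity <= 0:
            raise ConfigError("base_intensity must be positive")
        if not (0 <= self.missing_peak_prob <= 1):
            raise ConfigError("missing_peak_prob must lie in [0, 1]")
        samples = set(self.resolved_sample_ids())
        if self.sample_ids is not None and len(samples) != len(self.sample_ids):
            raise ConfigError("sample_ids must be unique")
        target_ids = {f.fragment_id for f in self.panel.targets()}
        all_ids = {f.fragment_id for f in self.panel.fragments}
        for sample_id, fragment_ids, cn in self.truth:
            if sample_id not in samples:
                raise ConfigError(f"truth references unknown sample {sample_id!r}")
            for fid in fragment_ids:
                if fid not in all_ids:
                    raise ConfigError(f"truth references unknown fragment {fid!r}")
                if fid not in target_ids:
                    raise ConfigError(f"truth may not alter reference fragment {fid!r}")
            if cn not in (0, 1, 2, 3, 4):
                raise ConfigError(f"copy number must be in 0..4, got {cn}")
        for sample_id, fid, delta in self.artifacts:
            if sample_id not in samples:
                raise ConfigError(f"artifact references unknown sample {sample_id!r}")
            if fid not in all_ids:
                raise ConfigError(f"artifact references unknown fragment {fid!r}")
            if fid not in target_ids:
                raise ConfigError(f"artifact may not target reference fragment {fid!r}")
            if not (0 <= delta <= 1):
                raise ConfigError(f"dropout fraction must lie in [0, 1], got {delta}")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a simulated cohort: per-fragment copy numbers and the
    per-sample CNV status / event list they imply. Artifact samples carry
    copy number 2 in truth — the assay's call on them is a false positive."""

    panel: FragmentPanel
    sample_ids: tuple[str, ...]
    copy_numbers: Mapping[tuple[str, str], int]  # only non-diploid entries stored
    artifacts: tuple = ()

    def copy_number(self, sample_id: str, fragment_id: str) -> int:
        return self.copy_numbers.get((sample_id, fragment_id), 2)

    def status(self, sample_id: str) -> str:
        if any(s == sample_id for (s, _f) in self.copy_numbers):
            return STATUS_POSITIVE
        return STATUS_NEGATIVE

    def status_map(self) -> dict[str, str]:
        return {s: self.status(s) for s in self.sample_ids}

    def true_events(self, sample_id: str) -> list[CNVEvent]:
        """Events implied by the true copy numbers, merged with the same
        contiguity rules the caller uses."""
        results = []
        for frag in self.panel.targets():
            cn = self.copy_number(sample_id, frag.fragment_id)
            call = CALL_DELETION if cn < 2 else CALL_DUPLICATION if cn > 2 else CALL_NORMAL
            results.append(
                TRResult(sample_id, frag.fragment_id, frag.gene, frag.exon_label,
                         cn / 2.0, 1.0, cn / 2.0, call)
            )
        return merge_events(results, self.panel)

    def fragment_table(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "fragment_id": f, "copy_number": self.copy_number(s, f)}
            for s in self.sample_ids
            for f in (fr.fragment_id for fr in self.panel.targets())
        ]
        return pd.DataFrame(rows, columns=["sample_id", "fragment_id", "copy_number"])

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for s in self.sample_ids:
            events = self.true_events(s)
            rows.append(
                {
                    "sample_id": s,
                    "status": self.status(s),
                    "events": "; ".join(f"{e.gene} {e.exon_range_label}" for e in events) or ".",
                }
            )
        return pd.DataFrame(rows, columns=["sample_id", "status", "events"])


def simulate(config: SimulationConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Draw one synthetic intensity table plus its truth table."""
    config.validate()
    panel = config.panel
    sample_ids = config.resolved_sample_ids()
    fragments = list(panel.fragments)
    n_s, n_f = len(sample_ids), len(fragments)

    cn_map: dict[tuple[str, str], int] = {}
    for sample_id, fragment_ids, cn in config.truth:
        for fid in fragment_ids:
            cn_map[(sample_id, fid)] = int(cn)
    delta_map = {(s, f): float(d) for s, f, d in config.artifacts}

    frag_index = {f.fragment_id: j for j, f in enumerate(fragments)}
    is_target = np.array([f.is_target for f in fragments])

    dosage_t = np.full((n_s, n_f), 2.0)
    for (s, f), cn in cn_map.items():
        dosage_t[sample_ids.index(s), frag_index[f]] = float(cn)
    for (s, f), d in delta_map.items():
        dosage_t[sample_ids.index(s), frag_index[f]] -= d  # one allele suppressed by delta
    dosage_c = np.full((n_s, n_f), 2.0)  # competitor spiked at 2-copy equivalent

    rng = np.random.default_rng(config.seed)
    eff = rng.lognormal(mean=0.0, sigma=config.sigma_efficiency, size=(n_s, n_f)) \
        if config.sigma_efficiency > 0 else np.ones((n_s, n_f))
    eps_t = rng.normal(0.0, config.sigma_noise, size=(n_s, n_f)) if config.sigma_noise > 0 else 0.0
    eps_c = rng.normal(0.0, config.sigma_noise, size=(n_s, n_f)) if config.sigma_noise > 0 else 0.0
    base = config.base_intensity
    intensity_t = base * eff * (dosage_t / 2.0) * np.exp(eps_t)
    intensity_c = base * eff * (dosage_c / 2.0) * np.exp(eps_c)
    if config.missing_peak_prob > 0:
        drop = rng.random(size=(n_s, n_f)) < config.missing_peak_prob
        intensity_c = np.where(drop, 0.0, intensity_c)

    df = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_f),
            "fragment_id": np.tile([f.fragment_id for f in fragments], n_s),
            "intensity_template": intensity_t.ravel(),
            "intensity_competitor": intensity_c.ravel(),
        },
        columns=INTENSITY_COLUMNS,
    )
    truth = TruthTable(
        panel=panel,
        sample_ids=sample_ids,
        copy_numbers={k: v for k, v in cn_map.items() if v != 2},
        artifacts=tuple(config.artifacts),
    )
    return df, truth


# ---------------------------------------------------------------------------
# Study fixture: a 293-sample cohort shaped like the validation cohort
# ---------------------------------------------------------------------------

def brca_fixture_panel() -> FragmentPanel:
    """A BRCA1/BRCA2 exon panel laid out over four multiplex wells.

    BRCA1 contributes 23 exon fragments, BRCA2 31 (its large exon 11 is
    subdivided into five fragments so partial-exon deletions are
    resolvable). Each well carries one fragment of each internal reference
    gene (ALB, EIF2C1, RNaseP).
    """
    fragments: list[Fragment] = []

    def add_targets(gene: str, labels: list[str], well_of: dict[int, str]):
        for i, label in enumerate(labels, start=1):
            fragments.append(
                Fragment(
                    fragment_id=f"{gene}_{label}",
                    gene=gene,
                    exon_label=label,
                    role="target",
                    well=well_of[i],
                    order_index=i,
                )
            )

    brca1_labels = [f"ex{i}" for i in range(1, 24)]
    brca1_wells = {i: ("W1" if i <= 12 else "W2") for i in range(1, 24)}
    add_targets("BRCA1", brca1_labels, brca1_wells)

    brca2_labels = (
        [f"ex{i}" for i in range(1, 11)]
        + [f"ex11_part{p}" for p in range(1, 6)]
        + [f"ex{i}" for i in range(12, 28)]
    )
    brca2_wells = {i: ("W3" if i <= 15 else "W4") for i in range(1, 32)}
    add_targets("BRCA2", brca2_labels, brca2_wells)

    for well in ("W1", "W2", "W3", "W4"):
        for gene in ("ALB", "EIF2C1", "RNaseP"):
            fragments.append(
                Fragment(
                    fragment_id=f"{gene}_{well}",
                    gene=gene,
                    exon_label="ex1",
                    role="reference",
                    well=well,
                )
            )
    return FragmentPanel(name="brca-fixture", fragments=tuple(fragments))


def study_truth_config(
    panel: FragmentPanel | None = None,
    *,
    seed: int = 0,
    sigma_noise: float = 0.05,
    sigma_efficiency: float = 0.3,
    missing_peak_prob: float = 0.0,
) -> SimulationConfig:
    """Configuration of the 293-sample study-shaped cohort.

    Eight true CNV carriers (S001-S006, S011, S012), four allele-dropout
    artifact samples (S007-S010, diploid in truth, delta = 1 on one
    fragment), and 281 plain diploid samples.
    """
    panel = panel or brca_fixture_panel()

    def frags(gene: str, labels: Iterable[str]) -> frozenset[str]:
        return frozenset(f"{gene}_{lab}" for lab in labels)

    truth = (
        ("S001", frags("BRCA1", ["ex1", "ex2"]), 1),                      # exon 1-2 deletion
        ("S002", frags("BRCA1", ["ex1"]), 1),                             # exon 1 deletion
        ("S003", frags("BRCA1", ["ex1", "ex2"]), 1),                      # exon 1-2 deletion
        ("S004", frags("BRCA2", ["ex17", "ex18"]), 1),                    # exon 17-18 deletion
        ("S005", frags("BRCA1", ["ex1", "ex2"]), 3),                      # exon 1-2 duplication
        ("S006", frags("BRCA1", ["ex5", "ex6", "ex7", "ex8", "ex9", "ex10"]), 1),  # exon 5-10 deletion
        ("S011", frags("BRCA2", ["ex11_part2", "ex11_part3"]), 1),        # part of exon 11 deletion
        ("S012", frags("BRCA2", ["ex11_part3", "ex11_part4"]), 1),        # part of exon 11 deletion
    )
    artifacts = (
        ("S007", "BRCA1_ex3", 1.0),
        ("S008", "BRCA1_ex14", 1.0),
        ("S009", "BRCA2_ex2", 1.0),
        ("S010", "BRCA2_ex20", 1.0),
    )
    return SimulationConfig(
        panel=panel,
        n_samples=293,
        truth=truth,
        artifacts=artifacts,
        sigma_noise=sigma_noise,
        sigma_efficiency=sigma_efficiency,
        missing_peak_prob=missing_peak_prob,
        seed=seed,
    )


def make_study_fixture(
    seed: int = 0,
    *,
    sigma_noise: float = 0.05,
    sigma_efficiency: float = 0.3,
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate the 293-sample study-shaped cohort (see
    :func:`study_truth_config`)."""
    config = study_truth_config(seed=seed, sigma_noise=sigma_noise, sigma_efficiency=sigma_efficiency)
    return simulate(config)
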