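"""Assay panel data model.

A *panel* describes the physical layout of a multiplex iPLEX dosage assay:
which genomic fragments are interrogated, which gene and exon each fragment
covers, whether it is a dosage *target* or an internal diploid *reference*
(RNaseP, EIF2C1, ALB by default), and in which multiplex PCR well it is
co-amplified. Targets carry an explicit 5'->3' ``order_index`` within their
gene so that exon-range events can be merged deterministically even when a
large exon is subdivided into several fragments.

Panels are stored as JSON (YAML is accepted transparently); see the README
for the schema.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import PanelError

DEFAULT_REFERENCE_GENES = frozenset({"ALB", "EIF2C1", "RNaseP"})

ROLE_TARGET = "target"
ROLE_REFERENCE = "reference"

_EXON_LABEL_RE = re.compile(r"^ex(?P<exon>\d+)(?:_part(?P<part>\d+))?$")


def parse_exon_label(label: str) -> tuple[int, int | None]:
    """Split an exon label such as ``"ex11_part3"`` into (exon, part).

    ``part`` is None for unsubdivided exons (``"ex5"`` -> ``(5, None)``).
    """
    m = _EXON_LABEL_RE.match(label)
    if m is None:
        raise PanelError(f"unparseable exon label {label!r} (expected 'ex<N>' or 'ex<N>_part<M>')")
    part = m.group("part")
    return int(m.group("exon")), (int(part) if part is not None else None)


@dataclass(frozen=True)
class Fragment:
    """One interrogated fragment (amplicon + extension probe) of the assay."""

    fragment_id: str
    gene: str
    exon_label: str
    role: str
    well: str
    order_index: int | None = None

    def __post_init__(self):
        if self.role not in (ROLE_TARGET, ROLE_REFERENCE):
            raise PanelError(
                f"fragment {self.fragment_id!r}: role must be 'target' or 'reference', got {self.role!r}"
            )
        if self.role == ROLE_TARGET and self.order_index is None:
            raise PanelError(f"target fragment {self.fragment_id!r} is missing order_index")

    @property
    def is_target(self) -> bool:
        return self.role == ROLE_TARGET

    def exon_number(self) -> int:
        return parse_exon_label(self.exon_label)[0]


@dataclass(frozen=True)
class FragmentPanel:
    """A validated collection of fragments defining one assay.

    Invariants enforced at construction:

    * fragment ids are unique;
    * at least one target and one reference fragment exist;
    * reference fragments belong to a configured reference gene;
    * every well that contains a target also contains a reference, unless
      ``pooled_normalization`` is enabled (references then calibrate all
      wells jointly);
    * target ``order_index`` is unique and strictly increasing per gene.
    """

    name: str
    fragments: tuple[Fragment, ...]
    reference_genes: frozenset[str] = DEFAULT_REFERENCE_GENES
    pooled_normalization: bool = False

    def __post_init__(self):
        object.__setattr__(self, "fragments", tuple(self.fragments))
        object.__setattr__(self, "reference_genes", frozenset(self.reference_genes))
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for f in self.fragments:
            if f.fragment_id in seen:
                raise PanelError(f"duplicate fragment_id {f.fragment_id!r}")
            seen.add(f.fragment_id)
        targets = [f for f in self.fragments if f.is_target]
        references = [f for f in self.fragments if not f.is_target]
        if not targets:
            raise PanelError("panel has no target fragments")
        if not references:
            raise PanelError("panel has no reference fragments")
        for f in references:
            if f.gene not in self.reference_genes:
                raise PanelError(
                    f"reference fragment {f.fragment_id!r} has gene {f.gene!r} "
                    f"outside the reference set {sorted(self.reference_genes)}"
                )
        if not self.pooled_normalization:
            wells_with_ref = {f.well for f in references}
            for f in targets:
                if f.well not in wells_with_ref:
                    raise PanelError(
                        f"well {f.well!r} contains target fragments but no reference fragment"
                    )
        per_gene: dict[str, list[Fragment]] = {}
        for f in targets:
            per_gene.setdefault(f.gene, []).append(f)
        for gene, frs in per_gene.items():
            idx = [f.order_index for f in frs]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise PanelError(
                    f"gene {gene!r}: target order_index must be strictly increasing and unique"
                )
        for f in targets:
            parse_exon_label(f.exon_label)  # must parse

    # -- accessors -------------------------------------------------------
    def targets(self, gene: str | None = None) -> list[Fragment]:
        out = [f for f in self.fragments if f.is_target]
        if gene is not None:
            out = [f for f in out if f.gene == gene]
        return sorted(out, key=lambda f: (f.gene, f.order_index))

    def references(self, well: str | None = None) -> list[Fragment]:
        out = [f for f in self.fragments if not f.is_target]
        if well is not None:
            out = [f for f in out if f.well == well]
        return out

    def wells(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.fragments:
            seen.setdefault(f.well, None)
        return list(seen)

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.fragments:
            if f.is_target:
                seen.setdefault(f.gene, None)
        return list(seen)

    def __contains__(self, fragment_id: str) -> bool:
        return any(f.fragment_id == fragment_id for f in self.fragments)

    def fragment(self, fragment_id: str) -> Fragment:
        for f in self.fragments:
            if f.fragment_id == fragment_id:
                return f
        raise KeyError(fragment_id)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "reference_genes": sorted(self.reference_genes),
            "pooled_normalization": self.pooled_normalization,
            "fragments": [
                {
                    "fragment_id": f.fragment_id,
                    "gene": f.gene,
                    "exon_label": f.exon_label,
                    "role": f.role,
                    "well": f.well,
                    **({"order_index": f.order_index} if f.order_index is not None else {}),
                }
                for f in self.fragments
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "FragmentPanel":
        try:
            name = data["name"]
            raw_fragments = data["fragments"]
        except (KeyError, TypeError) as exc:
            raise PanelError(f"panel is missing required field: {exc}") from exc
        fragments = []
        for i, entry in enumerate(raw_fragments):
            try:
                fragments.append(
                    Fragment(
                        fragment_id=entry["fragment_id"],
                        gene=entry["gene"],
                        exon_label=entry["exon_label"],
                        role=entry["role"],
                        well=entry["well"],
                        order_index=entry.get("order_index"),
                    )
                )
            except KeyError as exc:
                raise PanelError(f"fragment entry #{i + 1} is missing field {exc}") from exc
        return cls(
            name=name,
            fragments=tuple(fragments),
            reference_genes=frozenset(data.get("reference_genes", DEFAULT_REFERENCE_GENES)),
            pooled_normalization=bool(data.get("pooled_normalization", False)),
        )


def read_panel(path: str | Path) -> FragmentPanel:
    """Load and validate a panel from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)  # JSON is a subset of YAML
    except yaml.YAMLError as exc:
        raise PanelError(f"{path}: cannot parse panel file: {exc}") from exc
    if not isinstance(data, Mapping):
        raise PanelError(f"{path}: panel file does not contain a mapping")
    return FragmentPanel.from_dict(data)


def write_panel(panel: FragmentPanel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(panel.to_dict(), indent=2) + "\n", encoding="utf-8")
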