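"""Rule-based single-cell phenotyping.

Each phenotype is a *gating rule*: a set of markers that must be positive and
a set that must be negative; every other marker is "don't care", matching
everyday gating practice.  Rules are evaluated in priority order (lower rank
first) and the first match wins, so a cell receives exactly one label; cells
matching no rule fall through to ``"Unassigned"``.

Priority resolves the overlaps a marker table leaves implicit — e.g. a
CD68+CD163+HLA-DR+ cell is M2 rather than M1 because M1 carries an explicit
CD163− constraint, and a CD3+CD4+CD45RO+ cell is a memory helper T cell
rather than a plain helper T cell because the more constrained rule ranks
first.  Two rules may share a label (epithelial-like cells are gated by
Pan-CK or by E-cadherin); priorities must still be unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError

FALLBACK_LABEL = "Unassigned"


@dataclass(frozen=True)
class GatingRule:
    """One phenotype definition.

    Parameters
    ----------
    label
        Phenotype name assigned on match.
    positive, negative
        Marker names that must be 1 / must be 0.
    priority
        Evaluation rank; lower ranks are tested first.
    """

    label: str
    positive: frozenset[str]
    negative: frozenset[str] = frozenset()
    priority: int = 0

    def __post_init__(self):
        object.__setattr__(self, "positive", frozenset(self.positive))
        object.__setattr__(self, "negative", frozenset(self.negative))
        if self.positive & self.negative:
            both = ", ".join(sorted(self.positive & self.negative))
            raise ConfigError(f"rule {self.label!r}: markers both positive and negative: {both}")
        if not self.positive:
            raise ConfigError(f"rule {self.label!r}: needs at least one positive marker")

    def matches(self, cell: Mapping[str, int]) -> bool:
        return all(cell[m] == 1 for m in self.positive) and all(
            cell[m] == 0 for m in self.negative
        )


@dataclass
class RuleSet:
    """An ordered collection of gating rules with an Unassigned fallback."""

    rules: tuple[GatingRule, ...] = ()
    fallback: str = FALLBACK_LABEL

    def __post_init__(self):
        rules = tuple(sorted(self.rules, key=lambda r: r.priority))
        prios = [r.priority for r in rules]
        if len(set(prios)) != len(prios):
            raise ConfigError("rule priorities must be unique")
        self.rules = rules

    def __iter__(self) -> Iterator[GatingRule]:
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def labels(self) -> list[str]:
        """Unique labels in priority order (duplicates collapsed)."""
        seen: dict[str, None] = {}
        for r in self.rules:
            seen.setdefault(r.label, None)
        return list(seen)

    def markers(self) -> set[str]:
        out: set[str] = set()
        for r in self.rules:
            out |= r.positive | r.negative
        return out

    def rule(self, label: str) -> GatingRule:
        """Highest-priority rule carrying ``label``."""
        for r in self.rules:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_config(self) -> dict:
        return {
            r.label if self._label_count(r.label) == 1 else f"{r.label}#{r.priority}": {
                "label": r.label,
                "positive": sorted(r.positive),
                "negative": sorted(r.negative),
                "priority": r.priority,
            }
            for r in self.rules
        }

    def _label_count(self, label: str) -> int:
        return sum(1 for r in self.rules if r.label == label)

    @classmethod
    def from_config(cls, cfg: Mapping[str, Mapping]) -> "RuleSet":
        """Build from a ``label: {positive: [...], negative: [...], priority: n}`` mapping."""
        rules = []
        for key, spec in cfg.items():
            rules.append(
                GatingRule(
                    label=str(spec.get("label", key)),
                    positive=frozenset(spec.get("positive", ())),
                    negative=frozenset(spec.get("negative", ())),
                    priority=int(spec["priority"]),
                )
            )
        return cls(tuple(rules))


# The published marker combinations, ordered most-specific-first.  Memory T
# subsets precede their parent hT/cT, Treg precedes hT, macrophage subtypes
# precede generic myeloid gates, and mMDSC precedes cMono (whose gate its
# truth profile would otherwise satisfy).
_DEFAULT_RULES: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("mhT", ("CD3", "CD4", "CD45RO"), ()),
    ("mcT", ("CD3", "CD8", "CD45RO"), ()),
    ("Treg", ("CD3", "FoxP3"), ()),
    ("hT", ("CD3", "CD4"), ()),
    ("cT", ("CD3", "CD8"), ()),
    ("tNK", ("CD56", "CD3"), ()),
    ("aNK", ("CD56", "GZMB"), ()),
    ("cNK", ("CD56", "CD16"), ()),
    ("M1", ("CD68", "HLA-DR"), ("CD163",)),
    ("M2", ("CD68", "CD163"), ()),
    ("M0", ("CD68",), ("HLA-DR", "CD163")),
    ("mMDSC", ("CD11b", "CD14"), ("CD15",)),
    ("pMDSC", ("CD11b", "CD15"), ("CD14",)),
    ("ncMono", ("CD14", "CD16"), ("CD68",)),
    ("cMono", ("CD14",), ("CD16", "CD68")),
    ("Neutrophil", ("CD15", "CD16"), ()),
    ("DC", ("CD11c",), ("CD3", "CD14", "CD56")),
    ("Endothelial", ("CD31",), ()),
    ("Fibroblast", ("aSMA",), ()),
    ("Epithelial-like", ("PanCK",), ()),
    ("Epithelial-like", ("Ecad",), ()),
    ("StemC", ("CD44",), ()),
    ("Proliferating", ("Ki-67",), ()),
)


def default_ruleset() -> RuleSet:
    """The default gating rules for the osteosarcoma TME marker panel.

    M1 carries an explicit CD163− constraint (beyond the published
    CD68+HLA-DR+ combination) so that M1 and M2 stay disjoint; swap in a
    custom :class:`RuleSet` via configuration to change this.
    """
    rules = tuple(
        GatingRule(label, frozenset(pos), frozenset(neg), priority=(i + 1) * 10)
        for i, (label, pos, neg) in enumerate(_DEFAULT_RULES)
    )
    return RuleSet(rules)


def assign_phenotypes(cells: pd.DataFrame, rules: RuleSet | None = None) -> pd.DataFrame:
    """Assign exactly one phenotype label per cell.

    Rules are tested in priority order; the first rule whose positive markers
    are all 1 and negative markers all 0 wins.  Cells matching no rule get
    the fallback label.  Returns a copy with a ``phenotype`` column.
    """
    if rules is None:
        rules = default_ruleset()
    present = set(cells.columns)
    for r in rules:
        for m in sorted((r.positive | r.negative) - present):
            raise ConfigError(f"rule {r.label!r} references missing marker {m!r}")
    labels = np.full(len(cells), rules.fallback, dtype=object)
    unassigned = np.ones(len(cells), dtype=bool)
    for r in rules:
        mask = unassigned.copy()
        for m in r.positive:
            mask &= cells[m].to_numpy() == 1
        for m in r.negative:
            mask &= cells[m].to_numpy() == 0
        labels[mask] = r.label
        unassigned &= ~mask
    out = cells.copy()
    out["phenotype"] = labels
    return out


def naive_assign(cells: pd.DataFrame, rules: RuleSet | None = None) -> list[str]:
    """Plain per-cell scan over all rules in priority order.

    Reference implementation kept for cross-checking the vectorized engine.
    """
    if rules is None:
        rules = default_ruleset()
    out = []
    records = cells.to_dict("records")
    for cell in records:
        label = rules.fallback
        for r in rules:
            if r.matches(cell):
                label = r.label
                break
        out.append(label)
    return out


def truth_tables(rules: RuleSet, markers: Iterable[str]) -> dict[str, dict[str, int]]:
    """Per-label marker truth tables: positive markers 1, everything else 0.

    For labels with several rules, the highest-priority rule defines the
    table.  Used by the synthetic-data generator so gating inverts exactly
    at zero marker noise.
    """
    markers = list(markers)
    tables: dict[str, dict[str, int]] = {}
    for label in rules.labels():
        r = rules.rule(label)
        tables[label] = {m: (1 if m in r.positive else 0) for m in markers}
    return tables
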