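"""Marker fingerprints and ordered rule-based subtype classification.

Astrocytes are defined operationally by expression of the pan-astrocytic
marker Slc1a3 (GLAST).  Each of the five subtypes AST1-AST5 carries a
+/- fingerprint over a small ISH marker panel; classification applies an
ordered rule table (specific progenitor rules before broad mature rules)
to per-gene +/- calls derived from transcript counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

SUBTYPES = ("AST1", "AST2", "AST3", "AST4", "AST5")

#: Genes probed in the ISH experiments (plus the pan-astrocyte marker).
MARKER_GENES = ("Slc1a3", "Gfap", "Agt", "Unc13c", "Frzb", "Ascl1", "Ogt", "Fam107a")

PAN_ASTROCYTE_MARKER = "Slc1a3"

UNCLASSIFIED = "unclassified"

#: Expression-level class per (subtype, marker): "+" highly expressed,
#: "-" absent/low.  AST1: Gfap/Agt high; AST2: Unc13c high, Agt low;
#: AST3: Agt high, Gfap and Unc13c low; AST4 (progenitor-like): Frzb/Ascl1
#: high; AST5 (intermediate): Fam107a high, Ogt low.
FINGERPRINTS: dict[str, dict[str, str]] = {
    "AST1": {"Slc1a3": "+", "Gfap": "+", "Agt": "+", "Unc13c": "-",
             "Frzb": "-", "Ascl1": "-", "Ogt": "+", "Fam107a": "-"},
    "AST2": {"Slc1a3": "+", "Gfap": "-", "Agt": "-", "Unc13c": "+",
             "Frzb": "-", "Ascl1": "-", "Ogt": "+", "Fam107a": "-"},
    "AST3": {"Slc1a3": "+", "Gfap": "-", "Agt": "+", "Unc13c": "-",
             "Frzb": "-", "Ascl1": "-", "Ogt": "+", "Fam107a": "-"},
    "AST4": {"Slc1a3": "+", "Gfap": "-", "Agt": "-", "Unc13c": "-",
             "Frzb": "+", "Ascl1": "+", "Ogt": "+", "Fam107a": "-"},
    "AST5": {"Slc1a3": "+", "Gfap": "-", "Agt": "-", "Unc13c": "-",
             "Frzb": "-", "Ascl1": "-", "Ogt": "-", "Fam107a": "+"},
}

#: Genes available in each three-channel staining panel.  AST3 was mapped
#: with a split-panel approach (two complementary three-probe stainings);
#: the "full" panel is available for synthetic data.
PANELS: dict[str, frozenset[str]] = {
    "A": frozenset({"Gfap", "Agt", "Slc1a3"}),
    "B": frozenset({"Unc13c", "Agt", "Slc1a3"}),
    "full": frozenset(MARKER_GENES),
}


@dataclass(frozen=True)
class SubtypeRule:
    """One classification rule: all ``requirements`` must hold; if
    ``split_clause`` is non-empty, at least one of its alternatives whose
    gene is present in the staining panel must additionally hold."""

    subtype: str
    requirements: tuple[tuple[str, str], ...]
    split_clause: tuple[tuple[str, str], ...] = ()

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.requirements) | frozenset(
            g for g, _ in self.split_clause
        )


#: Ordered rule table.  Specific progenitor rules (AST4, AST5) are
#: evaluated before the broad mature-astrocyte rules; first match wins.
DEFAULT_RULES: tuple[SubtypeRule, ...] = (
    SubtypeRule("AST4", (("Frzb", "+"), ("Ascl1", "+"), ("Slc1a3", "+"))),
    SubtypeRule("AST5", (("Ogt", "-"), ("Fam107a", "+"), ("Slc1a3", "+"))),
    SubtypeRule("AST1", (("Gfap", "+"), ("Agt", "+"), ("Slc1a3", "+"))),
    SubtypeRule("AST2", (("Agt", "-"), ("Unc13c", "+"), ("Slc1a3", "+"))),
    SubtypeRule(
        "AST3",
        (("Agt", "+"), ("Slc1a3", "+")),
        split_clause=(("Gfap", "-"), ("Unc13c", "-")),
    ),
)


def validate_rules(rules: tuple[SubtypeRule, ...],
                   channels: Mapping[str, object] | frozenset[str]) -> None:
    """Check that every gene referenced by a rule has a probe channel."""
    available = set(channels)
    for rule in rules:
        missing = rule.genes - available
        if missing:
            raise ValueError(
                f"rule for {rule.subtype} references genes without a probe "
                f"channel: {sorted(missing)}"
            )


def call_markers(
    counts: Mapping[str, float],
    theta_hi: Mapping[str, float] | float = 5,
    theta_lo: Mapping[str, float] | float = 2,
) -> dict[str, str]:
    """Convert per-gene transcript (puncta) counts to +/- calls.

    A gene is called "+" when its count is at or above ``theta_hi``
    (boundary inclusive), "-" when at or below ``theta_lo``, and
    "indeterminate" strictly in between.  ``theta_lo < theta_hi`` is
    required per gene.
    """
    calls: dict[str, str] = {}
    for gene, n in counts.items():
        hi = theta_hi[gene] if isinstance(theta_hi, Mapping) else theta_hi
        lo = theta_lo[gene] if isinstance(theta_lo, Mapping) else theta_lo
        if not lo < hi:
            raise ValueError(
                f"theta_lo must be strictly below theta_hi for {gene!r} "
                f"(got lo={lo}, hi={hi})"
            )
        if n >= hi:
            calls[gene] = "+"
        elif n <= lo:
            calls[gene] = "-"
        else:
            calls[gene] = "indeterminate"
    return calls


def classify_subtype(
    calls: Mapping[str, str],
    rules: tuple[SubtypeRule, ...] = DEFAULT_RULES,
    panel: str = "full",
) -> str:
    """Assign a subtype from per-gene +/- calls via the ordered rule table.

    The cell must be an astrocyte (Slc1a3 call "+"); an "indeterminate"
    call fails any requirement on that gene.  Requirements on genes absent
    from the staining panel fail their rule, except inside AST3's split
    clause where unmeasured alternatives are simply skipped.  If no rule
    fires the cell is left ``unclassified``.
    """
    if panel not in PANELS:
        raise ValueError(f"unknown panel {panel!r}; choose from {sorted(PANELS)}")
    panel_genes = PANELS[panel]
    if calls.get(PAN_ASTROCYTE_MARKER) != "+":
        raise ValueError(
            "classify_subtype expects an astrocyte "
            f"({PAN_ASTROCYTE_MARKER} call must be '+')"
        )
    for rule in rules:
        ok = all(
            gene in panel_genes and calls.get(gene) == wanted
            for gene, wanted in rule.requirements
        )
        if ok and rule.split_clause:
            measurable = [
                (g, w) for g, w in rule.split_clause if g in panel_genes
            ]
            ok = any(calls.get(g) == w for g, w in measurable)
        if ok:
            return rule.subtype
    return UNCLASSIFIED


def classify_count_table(
    counts: pd.DataFrame,
    rules: tuple[SubtypeRule, ...] = DEFAULT_RULES,
    panel: str = "full",
    theta_hi: float | Mapping[str, float] = 5,
    theta_lo: float | Mapping[str, float] = 2,
) -> pd.Series:
    """Classify every row of a cell x marker-gene count table.

    Non-astrocytes (Slc1a3 not "+") are labelled ``"non-astrocyte"``;
    astrocytes matching no rule are ``"unclassified"``.
    """
    missing = [g for g in MARKER_GENES if g not in counts.columns]
    if missing:
        raise ValueError(f"count table lacks marker genes: {missing}")
    out = np.empty(len(counts), dtype=object)
    records = counts[list(MARKER_GENES)].to_numpy()
    for i, row in enumerate(records):
        calls = call_markers(dict(zip(MARKER_GENES, row)), theta_hi, theta_lo)
        if calls[PAN_ASTROCYTE_MARKER] != "+":
            out[i] = "non-astrocyte"
        else:
            out[i] = classify_subtype(calls, rules, panel)
    return pd.Series(out, index=counts.index, name="subtype")
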