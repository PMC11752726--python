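"""Transgressive / intermediate / conserved trait classification.

Each hybrid microbiota trait is compared with the same trait in both
progenitor populations:

* **T** (transgressive): significantly different from both progenitors AND
  more extreme than both (outside the progenitor range), direction '^'
  (higher) or 'v' (lower);
* **I** (intermediate): significantly different from both but strictly
  between the progenitor values, direction '-';
* **C** (conserved): not significantly different from one or both
  progenitors; annotated with which progenitor(s) it resembles.

A hybrid value exactly equal to a progenitor value with both tests
significant is classified conserved with that progenitor (equality is not
"more extreme"), keeping transgressive counts conservative.  Against the
syntopic (co-occurring) progenitor alone, a trait is **D** (differentiated)
or **C** (conserved).  Direction glyphs: '^' above, 'v' below, '-' between,
'0' equal to a progenitor value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CODES = ("T", "I", "C")
DIRECTIONS = ("^", "v", "-", "0")
FAMILIES = ("diversity", "composition", "abundance")


@dataclass(frozen=True)
class TraitComparison:
    """One trait x hybrid-population comparison.

    Central values are medians for diversity/abundance traits and means for
    composition traits; `statistic` records which.  `sig_p1`/`sig_p2` are
    the significance calls of hybrid vs each progenitor from whichever test
    the trait family uses (rank tests, CI overlap, or null-model
    comparisons).
    """

    trait: str
    family: str
    body_site: str
    hybrid_population: str
    hybrid_value: float
    p1_value: float
    p2_value: float
    sig_p1: bool
    sig_p2: bool
    p1_name: str = "P1"
    p2_name: str = "P2"
    syntopic: str | None = None        # "P1" or "P2"
    sig_syntopic: bool | None = None
    statistic: str = "median"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown trait family {self.family!r}")
        if self.syntopic not in (None, "P1", "P2"):
            raise ValueError("syntopic must be 'P1', 'P2' or None")

    @property
    def syntopic_value(self) -> float:
        if self.syntopic is None:
            raise ValueError("no syntopic progenitor recorded")
        return self.p1_value if self.syntopic == "P1" else self.p2_value


@dataclass
class TraitOutcome:
    trait: str
    family: str
    body_site: str
    hybrid_population: str
    code: str                          # T / I / C
    conserved_with: str | None         # "P1", "P2", "both" or None
    direction: str                     # ^ / v / - / 0
    syntopic_code: str | None = None   # D / C
    syntopic_direction: str | None = None

    def __post_init__(self):
        if self.code not in CODES:
            raise ValueError(f"invalid code {self.code!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.code == "I" and self.direction != "-":
            raise ValueError("intermediate outcomes are directionless ('-')")
        if self.code == "T" and self.direction not in ("^", "v"):
            raise ValueError("transgressive outcomes must be '^' or 'v'")

    def code_string(self, p1_symbol: str = "P1", p2_symbol: str = "P2") -> str:
        sup = ""
        if self.code == "C" and self.conserved_with:
            sym = {"P1": p1_symbol, "P2": p2_symbol,
                   "both": f"{p1_symbol}+{p2_symbol}"}[self.conserved_with]
            sup = f"[{sym}]"
        return f"{self.code}{sup}{self.direction}"


def _direction(hybrid: float, lo: float, hi: float) -> str:
    if hybrid > hi:
        return "^"
    if hybrid < lo:
        return "v"
    if hybrid == lo or hybrid == hi:
        return "0"
    return "-"


def classify_vs_both(c: TraitComparison) -> TraitOutcome:
    """Classify one trait against both progenitors (T / I / C)."""
    lo, hi = min(c.p1_value, c.p2_value), max(c.p1_value, c.p2_value)
    h = c.hybrid_value
    base = dict(trait=c.trait, family=c.family, body_site=c.body_site,
                hybrid_population=c.hybrid_population)
    if c.sig_p1 and c.sig_p2:
        if h > hi:
            return TraitOutcome(**base, code="T", conserved_with=None, direction="^")
        if h < lo:
            return TraitOutcome(**base, code="T", conserved_with=None, direction="v")
        if h == lo or h == hi:
            # tie rule: equality is not "more extreme"
            if h == c.p1_value and h == c.p2_value:
                with_whom = "both"
            elif h == c.p1_value:
                with_whom = "P1"
            else:
                with_whom = "P2"
            return TraitOutcome(**base, code="C", conserved_with=with_whom,
                                direction="0")
        return TraitOutcome(**base, code="I", conserved_with=None, direction="-")
    if not c.sig_p1 and not c.sig_p2:
        with_whom = "both"
    elif not c.sig_p1:
        with_whom = "P1"
    else:
        with_whom = "P2"
    return TraitOutcome(**base, code="C", conserved_with=with_whom,
                        direction=_direction(h, lo, hi))


def classify_vs_syntopic(c: TraitComparison) -> tuple:
    """(code, direction) against the syntopic progenitor: D iff significant;
    direction '^'/'v'/'0' relative to the syntopic central value."""
    if c.syntopic is None or c.sig_syntopic is None:
        raise ValueError("comparison lacks syntopic information")
    code = "D" if c.sig_syntopic else "C"
    s = c.syntopic_value
    if c.hybrid_value > s:
        direction = "^"
    elif c.hybrid_value < s:
        direction = "v"
    else:
        direction = "0"
    return code, direction


def classify_trait(c: TraitComparison) -> TraitOutcome:
    """Full outcome: vs-both code plus the syntopic annotation when the
    comparison carries syntopic information."""
    outcome = classify_vs_both(c)
    if c.syntopic is not None and c.sig_syntopic is not None:
        code, direction = classify_vs_syntopic(c)
        outcome.syntopic_code = code
        outcome.syntopic_direction = direction
    return outcome


def consistency_flags(outcome_site1, outcome_site2, which: str = "both") -> tuple:
    """(codes consistent?, trends consistent?) across the two hybrid
    populations.  `which` selects the vs-both codes or the syntopic codes;
    trend consistency compares direction glyphs regardless of significance.
    """
    if which == "both":
        codes = (outcome_site1.code, outcome_site2.code)
        dirs = (outcome_site1.direction, outcome_site2.direction)
    elif which == "syntopic":
        codes = (outcome_site1.syntopic_code, outcome_site2.syntopic_code)
        dirs = (outcome_site1.syntopic_direction, outcome_site2.syntopic_direction)
    else:
        raise ValueError("which must be 'both' or 'syntopic'")
    return codes[0] == codes[1], dirs[0] == dirs[1]


CODE_NAMES = {"T": "transgressive", "C": "conserved", "I": "intermediate"}


def tally_outcomes(outcomes, expected_cells=None) -> pd.DataFrame:
    """Tally T/C/I counts and percentages per body site and trait family.

    Parameters
    ----------
    outcomes : iterable of TraitOutcome or DataFrame
        A DataFrame must carry columns body_site, family, code (and
        trait / hybrid_population when `expected_cells` is used).
    expected_cells : iterable of (body_site, family, trait, hybrid_population)
        When given, the tally refuses to run unless every expected cell has
        exactly one outcome, and lists the missing ones.

    Returns a table indexed by (body_site, family) -- families in the fixed
    order diversity, composition, abundance, plus a 'total' row per body
    site -- with count and percentage (2 decimals) columns per outcome.
    """
    if isinstance(outcomes, pd.DataFrame):
        df = outcomes.copy()
    else:
        df = pd.DataFrame([
            {"body_site": o.body_site, "family": o.family, "code": o.code,
             "trait": o.trait, "hybrid_population": o.hybrid_population}
            for o in outcomes
        ])
    if expected_cells is not None:
        have = set(zip(df["body_site"], df["family"], df["trait"],
                       df["hybrid_population"]))
        missing = sorted(set(map(tuple, expected_cells)) - have)
        if missing:
            raise ValueError(f"missing outcome cells: {missing}")

    rows = []
    order = ["transgressive", "conserved", "intermediate"]
    for body_site in sorted(df["body_site"].unique()):
        site = df[df["body_site"] == body_site]
        fams = [f for f in FAMILIES if f in set(site["family"])]
        for family in fams + ["total"]:
            sub = site if family == "total" else site[site["family"] == family]
            total = len(sub)
            row = {"body_site": body_site, "family": family, "n": total}
            for code, name in CODE_NAMES.items():
                k = int((sub["code"] == code).sum())
                row[name] = k
                row[f"{name}_pct"] = round(100.0 * k / total, 2) if total else 0.0
            rows.append(row)
    out = pd.DataFrame(rows).set_index(["body_site", "family"])
    return out[["n"] + order + [f"{n}_pct" for n in order]]
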