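"""Loop-profile rules mapping GQ motifs to conformation and folding propensity.

The empirical picture: in single-stranded DNA a single-nucleotide loop is
dominant and drives parallel folding regardless of the other loops; motifs
whose loops are all short (≤3 nt) without a 1-nt loop favour the antiparallel
topology; longer-looped motifs stay unfolded.  Inside duplex DNA the
antiparallel fold is not supported at all — only short-looped motifs fold, as
parallel GQs, and the folded fraction decays with loop length.  Rule tables
encode that mapping as an ordered first-match-wins list per strandedness
context, plus a calibration map from loop triplets to measured dsDNA folded
percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml

from .motifs import GQMotif

__all__ = [
    "ConformationCall",
    "RuleRow",
    "RuleTable",
    "default_rule_table",
    "classify_conformation",
    "predict_ds_folded_fraction",
]

CONFORMATIONS = ("parallel", "antiparallel", "unfolded")
PROPENSITIES = ("high", "intermediate", "none")

#: Measured high-FRET (folded) percentages for dsDNA constructs, keyed by
#: sorted loop triplet.  CMYC (12 G + 4 loop nt) carries the (1,2,1) profile,
#: keyed sorted as (1,1,2).
DS_FOLDED_CALIBRATION: dict[tuple[int, int, int], float] = {
    (1, 1, 2): 92.0,  # CMYC
    (1, 3, 3): 86.0,
    (1, 4, 4): 66.0,
    (1, 5, 5): 58.0,
    (3, 3, 3): 0.0,  # (TTA)3
}


@dataclass(frozen=True)
class ConformationCall:
    context: str
    conformation: str
    propensity_class: str
    predicted_folded_percent: Optional[float]
    rule_id: str

    def __post_init__(self) -> None:
        if self.context == "ds" and self.conformation == "antiparallel":
            raise ValueError("antiparallel conformation is ss-only")
        if self.propensity_class == "none" and self.conformation != "unfolded":
            raise ValueError("propensity 'none' implies unfolded")


@dataclass(frozen=True)
class RuleRow:
    """One predicate row.  Supported predicate keys (AND-combined):

    - ``always``: matches any triplet (the mandatory final default row)
    - ``any_loop_eq``: some loop equals the value
    - ``max_loop_le``: every loop ≤ the value
    - ``one_loop_eq``: mapping ``{value: v, others_max: m}`` — exactly one
      loop equals ``v`` and the remaining two are ≤ ``m``
    """

    rule_id: str
    context: str
    predicate: Mapping[str, object]
    conformation: str
    propensity_class: str

    def matches(self, loops: Sequence[int]) -> bool:
        ok = True
        for key, val in self.predicate.items():
            if key == "always":
                ok &= bool(val)
            elif key == "any_loop_eq":
                ok &= any(l == val for l in loops)
            elif key == "max_loop_le":
                ok &= max(loops) <= val  # type: ignore[operator]
            elif key == "one_loop_eq":
                v = val["value"]  # type: ignore[index]
                m = val["others_max"]  # type: ignore[index]
                hits = [i for i, l in enumerate(loops) if l == v]
                ok &= len(hits) == 1 and all(
                    l <= m for i, l in enumerate(loops) if i != hits[0]
                )
            else:
                raise ValueError(f"unknown predicate key {key!r}")
        return ok


@dataclass
class RuleTable:
    rows: list[RuleRow]
    ds_calibration: dict[tuple[int, int, int], float] = field(
        default_factory=lambda: dict(DS_FOLDED_CALIBRATION)
    )

    def __post_init__(self) -> None:
        for context in ("ss", "ds"):
            ctx_rows = self.rows_for(context)
            if not ctx_rows:
                raise ValueError(f"rule table has no rows for context {context!r}")
            if "always" not in ctx_rows[-1].predicate:
                raise ValueError(
                    f"rule table for context {context!r} lacks a final default row;"
                    " rows must exhaustively cover all loop triplets"
                )
        for row in self.rows_for("ds"):
            if row.conformation == "antiparallel":
                raise ValueError("ds rules may not call antiparallel")
        self.ds_calibration = {
            tuple(sorted(k)): float(v) for k, v in self.ds_calibration.items()
        }

    def rows_for(self, context: str) -> list[RuleRow]:
        return [r for r in self.rows if r.context == context]

    def first_match(self, context: str, loops: Sequence[int]) -> RuleRow:
        for row in self.rows_for(context):
            if row.matches(loops):
                return row
        raise ValueError("non-exhaustive rule table")  # unreachable by invariant

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rows": [
                {
                    "rule_id": r.rule_id,
                    "context": r.context,
                    "predicate": dict(r.predicate),
                    "conformation": r.conformation,
                    "propensity_class": r.propensity_class,
                }
                for r in self.rows
            ],
            "ds_calibration": {
                "-".join(map(str, k)): v for k, v in self.ds_calibration.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RuleTable":
        rows = [RuleRow(**row) for row in data["rows"]]
        cal = {
            tuple(int(x) for x in key.split("-")): float(v)
            for key, v in data.get("ds_calibration", {}).items()
        }
        return cls(rows=rows, ds_calibration=cal or dict(DS_FOLDED_CALIBRATION))

    @classmethod
    def from_yaml(cls, path) -> "RuleTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_rule_table() -> RuleTable:
    """The packaged default mapping (boundaries are config-editable)."""
    rows = [
        RuleRow("ss_single_nt_loop", "ss", {"any_loop_eq": 1}, "parallel", "high"),
        RuleRow("ss_all_short", "ss", {"max_loop_le": 3}, "antiparallel", "intermediate"),
        RuleRow("ss_default_unfolded", "ss", {"always": True}, "unfolded", "none"),
        RuleRow("ds_very_short", "ds", {"max_loop_le": 2}, "parallel", "high"),
        RuleRow(
            "ds_single_nt_loop",
            "ds",
            {"one_loop_eq": {"value": 1, "others_max": 5}},
            "parallel",
            "intermediate",
        ),
        RuleRow("ds_default_unfolded", "ds", {"always": True}, "unfolded", "none"),
    ]
    return RuleTable(rows=rows)


def _loops_of(motif: GQMotif | Sequence[int]) -> tuple[int, int, int]:
    loops = tuple(motif.loop_lengths) if isinstance(motif, GQMotif) else tuple(motif)
    if len(loops) != 3:
        raise ValueError("motif must have exactly three loops")
    return loops  # type: ignore[return-value]


def predict_ds_folded_fraction(
    motif: GQMotif | Sequence[int], rules: RuleTable | None = None
) -> float:
    """Predicted folded percentage of a motif in duplex DNA.

    Exact calibration lookup on the sorted loop triplet; triplets matching the
    ds "unfolded" rule return 0; any other triplet takes the value of the
    nearest calibrated key by L1 distance on sorted triplets, ties broken
    toward the smaller total loop length (then lexicographically).
    """
    rules = rules or default_rule_table()
    if not rules.ds_calibration:
        raise ValueError("empty ds calibration table")
    key = tuple(sorted(_loops_of(motif)))
    if key in rules.ds_calibration:
        return rules.ds_calibration[key]
    row = rules.first_match("ds", key)
    if row.propensity_class == "none":
        return 0.0
    best = min(
        rules.ds_calibration,
        key=lambda k: (sum(abs(a - b) for a, b in zip(k, key)), sum(k), k),
    )
    return rules.ds_calibration[best]


def classify_conformation(
    motif: GQMotif | Sequence[int],
    context: str,
    rules: RuleTable | None = None,
) -> ConformationCall:
    """Call conformation and folding propensity for a motif in a given context.

    ``context`` is ``"ss"`` (single-stranded) or ``"ds"`` (the motif embedded
    in duplex DNA).  First matching rule row wins.  In the ds context the call
    carries the calibrated folded percentage.
    """
    if context not in ("ss", "ds"):
        raise ValueError("context must be 'ss' or 'ds'")
    rules = rules or default_rule_table()
    loops = _loops_of(motif)
    row = rules.first_match(context, loops)
    percent = predict_ds_folded_fraction(loops, rules) if context == "ds" else None
    return ConformationCall(
        context=context,
        conformation=row.conformation,
        propensity_class=row.propensity_class,
        predicted_folded_percent=percent,
        rule_id=row.rule_id,
    )
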