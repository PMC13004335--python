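"""Shrink/Expand scoring and gain/loss classification of communication sets.

The comparison operates on per-communication-type sets of ligand-receptor
(LR) pairs inferred in two biological states, a reference (state 1) and a
comparator (state 2).  For a communication type t(A->B) with LR sets L1 and
L2 and intersection I = L1 & L2, the intersection ratios

    r1 = |I| / |L1|        (fraction of reference interactions retained)
    r2 = |I| / |L2|        (fraction of comparator interactions pre-existing)

combine into the bounded directional Shrink/Expand score.  Two sign
conventions are provided.  Under the default ``semantic`` convention

    SE = |I| * (1/|L1| - 1/|L2|) = r1 - r2

a comparator that strictly gains pairs scores positive (expansion) and one
that strictly loses pairs scores negative (shrinkage), matching the
interpretation used throughout the downstream analysis.  The ``literal``
convention keeps the raw difference r2 - r1 (the same magnitude with the
opposite sign) for audit.

Each (communication type, LR pair) combination — a communication inference
unit — is classified into Consensus (present in both states), Gain (only the
comparator) or Potential Loss (only the reference), with the turnover
fractions GR = |G|/|L2| and PLR = |PL|/|L1|.  "Potential" loss because LR
inference confirms presence statistically but never absence: a pair missing
from the comparator may reflect power or sampling, not true disappearance.

Organ-level aggregation counts expanding (SE > 0) and shrinking (SE < 0)
communication types, ignoring stable ones, and reports their normalised
difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import AbstractSet, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import io as lr_io

Convention = Literal["semantic", "literal"]
Direction = Literal["expanding", "shrinking", "stable", "emergent", "vanished"]


@dataclass(frozen=True, order=True)
class CommType:
    """A directed communication inference type: source cell type A
    signalling to target cell type B.  A may equal B (autocrine /
    intra-type communication)."""

    source: str
    target: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.source}->{self.target}"


@dataclass(frozen=True, order=True)
class LRPair:
    """A ligand-receptor pair; equality is exact string equality on both
    members (complexes are not decomposed at this level)."""

    ligand: str
    receptor: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.ligand}^{self.receptor}"


@dataclass
class StateSet:
    """The per-communication-type LR sets of one biological state."""

    state_label: str
    state_index: int  # 1 = reference, 2 = comparator
    sets: dict[CommType, frozenset[LRPair]] = field(default_factory=dict)

    def comm_types(self) -> set[CommType]:
        return set(self.sets)

    def n_units(self) -> int:
        return sum(len(s) for s in self.sets.values())


@dataclass
class SEResult:
    comm_type: CommType | None
    n_ref: int
    n_cmp: int
    n_intersection: int
    r_ref: float  # NaN when the reference set is empty
    r_cmp: float  # NaN when the comparator set is empty
    se: float
    direction: Direction


@dataclass
class ClassificationResult:
    comm_type: CommType | None
    consensus: frozenset[LRPair]
    gain: frozenset[LRPair]
    potential_loss: frozenset[LRPair]
    gain_ratio: float  # NaN when the comparator set is empty
    potential_loss_ratio: float  # NaN when the reference set is empty


@dataclass
class OrganSummary:
    n_expand: int
    n_shrink: int
    n_stable: int
    n_total: int  # n_expand + n_shrink; stable types excluded
    se_organ: float | None  # None when no type shows net directional change


def build_state_set(records: pd.DataFrame, state_index: int) -> StateSet:
    """Materialise per-communication-type LR sets from a filtered table.

    All rows must share one state label; each row contributes its LR pair
    to exactly one communication type's set.
    """
    if state_index not in (1, 2):
        raise ValueError("state_index must be 1 (reference) or 2 (comparator)")
    labels = records["state"].unique() if len(records) else []
    if len(labels) > 1:
        raise ValueError(f"mixed state labels in one table: {sorted(labels)}")
    state_label = str(labels[0]) if len(labels) else ""
    sets: dict[CommType, set[LRPair]] = {}
    for row in records.itertuples(index=False):
        ct = CommType(row.source, row.target)
        sets.setdefault(ct, set()).add(LRPair(row.ligand, row.receptor))
    return StateSet(
        state_label=state_label,
        state_index=state_index,
        sets={ct: frozenset(s) for ct, s in sets.items()},
    )


def symmetrize_state_set(state: StateSet) -> StateSet:
    """Merge directed communication types (A, B) and (B, A) into the
    orientation with lexicographically smaller source."""
    merged: dict[CommType, set[LRPair]] = {}
    for ct, pairs in state.sets.items():
        key = ct if (ct.source, ct.target) <= (ct.target, ct.source) else (
            CommType(ct.target, ct.source)
        )
        merged.setdefault(key, set()).update(pairs)
    return StateSet(
        state_label=state.state_label,
        state_index=state.state_index,
        sets={ct: frozenset(s) for ct, s in merged.items()},
    )


def intersection_ratios(
    l_ref: AbstractSet, l_cmp: AbstractSet
) -> tuple[float, float, int]:
    """Return (r_ref, r_cmp, |I|) for two non-empty LR sets."""
    if not l_ref or not l_cmp:
        raise ValueError(
            "intersection ratios are undefined for an empty set; "
            "route single-state types to emergent/vanished handling"
        )
    n_int = len(set(l_ref) & set(l_cmp))
    return n_int / len(l_ref), n_int / len(l_cmp), n_int


def se_score(
    l_ref: AbstractSet,
    l_cmp: AbstractSet,
    convention: Convention = "semantic",
    comm_type: CommType | None = None,
) -> SEResult:
    """Compute the Shrink/Expand score between two LR sets.

    At least one set must be non-empty.  When exactly one is empty the
    score takes its limiting value and the direction is flagged
    ``emergent`` (reference empty) or ``vanished`` (comparator empty) so
    such types can be excluded downstream if desired.
    """
    if convention not in ("semantic", "literal"):
        raise ValueError(f"unknown sign convention {convention!r}")
    sign = 1.0 if convention == "semantic" else -1.0
    n_ref, n_cmp = len(l_ref), len(l_cmp)
    if n_ref == 0 and n_cmp == 0:
        raise ValueError("SE score undefined: both LR sets are empty")
    if n_ref == 0:
        return SEResult(comm_type, 0, n_cmp, 0, float("nan"), 0.0,
                        sign * 1.0, "emergent")
    if n_cmp == 0:
        return SEResult(comm_type, n_ref, 0, 0, 0.0, float("nan"),
                        sign * -1.0, "vanished")
    r_ref, r_cmp, n_int = intersection_ratios(l_ref, l_cmp)
    # r_ref - r_cmp == |I| * (1/|L1| - 1/|L2|); exactly 0.0 when the two
    # sets have equal size or the intersection is empty.
    se = sign * (n_int * (1.0 / n_ref - 1.0 / n_cmp))
    if se > 0:
        direction: Direction = "expanding"
    elif se < 0:
        direction = "shrinking"
    else:
        se = 0.0  # normalise -0.0
        direction = "stable"
    return SEResult(comm_type, n_ref, n_cmp, n_int, r_ref, r_cmp, se,
                    direction)


def classify_units(
    l_ref: AbstractSet,
    l_cmp: AbstractSet,
    comm_type: CommType | None = None,
) -> ClassificationResult:
    """Partition the units of one communication type into C / G / PL.

    Consensus C = L1 & L2, Gain G = L2 - L1, Potential Loss PL = L1 - L2;
    GR = |G| / |L2| and PLR = |PL| / |L1|, each reported as NaN when its
    denominator set is empty.
    """
    l_ref, l_cmp = frozenset(l_ref), frozenset(l_cmp)
    if not l_ref and not l_cmp:
        raise ValueError("classification undefined: both LR sets are empty")
    consensus = l_ref & l_cmp
    gain = l_cmp - l_ref
    loss = l_ref - l_cmp
    gr = len(gain) / len(l_cmp) if l_cmp else float("nan")
    plr = len(loss) / len(l_ref) if l_ref else float("nan")
    return ClassificationResult(comm_type, consensus, gain, loss, gr, plr)


def compare_states(
    ref: StateSet,
    cmp: StateSet,
    convention: Convention = "semantic",
) -> list[tuple[SEResult, ClassificationResult]]:
    """Score and classify every communication type present in either state.

    Types absent from both states never appear; a type present in only one
    state is scored with the emergent/vanished limit values.
    """
    if ref.state_index != 1 or cmp.state_index != 2:
        raise ValueError("compare_states expects (reference, comparator)")
    results = []
    for ct in sorted(ref.comm_types() | cmp.comm_types()):
        l1 = ref.sets.get(ct, frozenset())
        l2 = cmp.sets.get(ct, frozenset())
        results.append(
            (
                se_score(l1, l2, convention=convention, comm_type=ct),
                classify_units(l1, l2, comm_type=ct),
            )
        )
    return results


def aggregate_organ(
    se_results: Iterable[SEResult],
    include_single_state: bool = True,
) -> OrganSummary:
    """Aggregate per-type SE scores into an organ-level summary.

    Only types with a net directional change (SE != 0) enter the total:
    SE_organ = (N_expand - N_shrink) / (N_expand + N_shrink).  Stable types
    are counted separately and excluded.  Emergent/vanished types count by
    the sign of their limit score unless ``include_single_state`` is False.
    When no type changes direction, SE_organ is undefined (None, with a
    warning) rather than 0.
    """
    n_expand = n_shrink = n_stable = 0
    for res in se_results:
        if not include_single_state and res.direction in (
            "emergent", "vanished"
        ):
            continue
        if res.se > 0:
            n_expand += 1
        elif res.se < 0:
            n_shrink += 1
        else:
            n_stable += 1
    n_total = n_expand + n_shrink
    if n_total == 0:
        warnings.warn(
            "no communication type shows net directional change; "
            "organ-level SE is undefined",
            stacklevel=2,
        )
        se_organ = None
    else:
        se_organ = (n_expand - n_shrink) / n_total
    return OrganSummary(n_expand, n_shrink, n_stable, n_total, se_organ)


# ---------------------------------------------------------------------------
# Tabular views


def se_table(results: Sequence[SEResult]) -> pd.DataFrame:
    """Long-format per-type SE table (one row per communication type)."""
    rows = [
        {
            "source": r.comm_type.source if r.comm_type else "",
            "target": r.comm_type.target if r.comm_type else "",
            "n_ref": r.n_ref,
            "n_cmp": r.n_cmp,
            "n_intersection": r.n_intersection,
            "r_ref": r.r_ref,
            "r_cmp": r.r_cmp,
            "se": r.se,
            "direction": r.direction,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "source", "target", "n_ref", "n_cmp", "n_intersection",
            "r_ref", "r_cmp", "se", "direction",
        ],
    )


def classification_table(
    results: Sequence[ClassificationResult],
) -> pd.DataFrame:
    """Long-format unit classification (one row per communication inference
    unit, category in {consensus, gain, potential_loss})."""
    rows = []
    for res in results:
        ct = res.comm_type
        for category, pairs in (
            ("consensus", res.consensus),
            ("gain", res.gain),
            ("potential_loss", res.potential_loss),
        ):
            for pair in sorted(pairs):
                rows.append(
                    {
                        "source": ct.source if ct else "",
                        "target": ct.target if ct else "",
                        "ligand": pair.ligand,
                        "receptor": pair.receptor,
                        "category": category,
                    }
                )
    return pd.DataFrame(
        rows, columns=["source", "target", "ligand", "receptor", "category"]
    )


def ratio_table(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Per-type gain and potential-loss ratios."""
    rows = [
        {
            "source": r.comm_type.source if r.comm_type else "",
            "target": r.comm_type.target if r.comm_type else "",
            "n_consensus": len(r.consensus),
            "n_gain": len(r.gain),
            "n_potential_loss": len(r.potential_loss),
            "gain_ratio": r.gain_ratio,
            "potential_loss_ratio": r.potential_loss_ratio,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "source", "target", "n_consensus", "n_gain", "n_potential_loss",
            "gain_ratio", "potential_loss_ratio",
        ],
    )


def organ_summary_dict(summary: OrganSummary) -> dict:
    return {
        "n_expand": summary.n_expand,
        "n_shrink": summary.n_shrink,
        "n_stable": summary.n_stable,
        "n_total": summary.n_total,
        "se_organ": summary.se_organ,
    }


def compare_tables(
    ref_table: pd.DataFrame,
    cmp_table: pd.DataFrame,
    p_threshold: float = 0.05,
    convention: Convention = "semantic",
    symmetrize: bool = False,
) -> tuple[list[tuple[SEResult, ClassificationResult]], OrganSummary]:
    """Full two-state comparison from canonical state tables.

    Applies the double p-value filter to each state independently, builds
    the per-type LR sets, scores and classifies every type, and aggregates
    the organ summary.
    """
    ref = build_state_set(
        lr_io.double_pvalue_filter(ref_table, p_threshold), state_index=1
    )
    cmp = build_state_set(
        lr_io.double_pvalue_filter(cmp_table, p_threshold), state_index=2
    )
    if symmetrize:
        ref = symmetrize_state_set(ref)
        cmp = symmetrize_state_set(cmp)
    results = compare_states(ref, cmp, convention=convention)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = aggregate_organ([se for se, _ in results])
    return results, summary
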