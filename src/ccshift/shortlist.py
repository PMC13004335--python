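"""Prioritising communication inference units and molecules.

Gain and potential-loss units are shortlisted by expression magnitude: the
``lr_mean`` values of one category (per communication type by default) are
split into two groups by exact one-dimensional two-means clustering, and
the higher-mean group is selected.  Consensus units are shortlisted by
rank dynamics instead: pairs are ranked by ``lr_mean`` within each state
(rank 1 = largest, ties averaged) and the absolute rank change is clustered
the same way.

Organ-level frequency analysis counts, per stage interval and category, in
how many distinct communication types each LR pair shows the same
directional change; the top-k most frequent pairs feed a single-molecule
decomposition (ligands and receptors, optionally split into complex
subunits) for molecule-centric ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

CATEGORY_ORDER = ("consensus", "gain", "potential_loss")


@dataclass
class TwoClusterResult:
    high_group: list[int]  # indices into the input, higher-mean cluster
    low_group: list[int]
    degenerate: bool  # single value or all values identical


def two_cluster_partition(values: Sequence[float]) -> TwoClusterResult:
    """Optimal two-group split of 1-D values (exact k-means, k = 2).

    Minimises the within-group sum of squared deviations by scanning every
    split point of the sorted values (the optimal 1-D two-means partition
    is always a contiguous split of the sorted order).  The group with the
    larger mean is returned as ``high_group``.  With fewer than two
    distinct values no split exists: all indices are returned as the high
    group with ``degenerate=True``.  Ties in the objective resolve to the
    split with the smaller high group.
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n == 0:
        raise ValueError("two_cluster_partition requires at least one value")
    if n == 1 or np.all(vals == vals[0]):
        return TwoClusterResult(list(range(n)), [], True)
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    prefix = np.cumsum(sorted_vals)
    prefix_sq = np.cumsum(sorted_vals**2)
    total, total_sq = prefix[-1], prefix_sq[-1]
    best_ss, best_split = np.inf, None
    # split s: low = sorted[:s], high = sorted[s:], s in 1..n-1; scanning s
    # descending makes ties resolve to the smallest high group.
    for s in range(n - 1, 0, -1):
        low_sum, low_sq = prefix[s - 1], prefix_sq[s - 1]
        high_sum, high_sq = total - low_sum, total_sq - low_sq
        ss = (low_sq - low_sum**2 / s) + (high_sq - high_sum**2 / (n - s))
        if ss < best_ss - 1e-12:
            best_ss, best_split = ss, s
    high = sorted(int(i) for i in order[best_split:])
    low = sorted(int(i) for i in order[:best_split])
    return TwoClusterResult(high, low, False)


def _select_by_partition(df: pd.DataFrame, score_col: str) -> pd.Series:
    part = two_cluster_partition(df[score_col].to_numpy())
    selected = np.zeros(len(df), dtype=bool)
    selected[part.high_group] = True
    return pd.Series(selected, index=df.index)


def shortlist_gain_pl(
    classified: pd.DataFrame,
    category: str,
    pooled: bool = False,
) -> pd.DataFrame:
    """Shortlist gain or potential-loss units by ``lr_mean`` magnitude.

    Parameters
    ----------
    classified:
        Long table with columns ``source, target, ligand, receptor,
        category, lr_mean`` where ``lr_mean`` comes from the state in which
        the unit is present (comparator for gains, reference for losses).
    category:
        ``"gain"`` or ``"potential_loss"``.
    pooled:
        Cluster across all communication types at once instead of per type.

    Returns
    -------
    pandas.DataFrame
        ``source, target, ligand, receptor, category, score, selected``;
        selected units form the higher-mean cluster.
    """
    if category not in ("gain", "potential_loss"):
        raise ValueError(f"category must be gain or potential_loss, "
                         f"got {category!r}")
    sub = classified.loc[classified["category"] == category].copy()
    sub = sub.rename(columns={"lr_mean": "score"})
    cols = ["source", "target", "ligand", "receptor", "category", "score",
            "selected"]
    if len(sub) == 0:
        return pd.DataFrame(columns=cols)
    if pooled:
        sub["selected"] = _select_by_partition(
            sub.reset_index(drop=True), "score"
        ).to_numpy()
    else:
        sub["selected"] = False
        for _, idx in sub.groupby(["source", "target"], sort=False).groups.items():
            block = sub.loc[idx].reset_index(drop=True)
            sub.loc[idx, "selected"] = _select_by_partition(
                block, "score"
            ).to_numpy()
    out = sub[cols].sort_values(
        ["source", "target", "ligand", "receptor"], kind="stable"
    ).reset_index(drop=True)
    return out


def consensus_rank_changes(
    consensus_pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Absolute ``lr_mean`` rank change of consensus pairs between states.

    ``consensus_pairs`` needs columns ``source, target, ligand, receptor,
    lr_mean_ref, lr_mean_cmp``.  Within each communication type the pairs
    are ranked by ``lr_mean`` separately in each state (rank 1 = largest,
    ties get average ranks); the score is |rank_ref - rank_cmp|.
    """
    out = consensus_pairs.copy()
    out["score"] = 0.0
    for _, idx in out.groupby(["source", "target"], sort=False).groups.items():
        block = out.loc[idx]
        rank_ref = rankdata(-block["lr_mean_ref"].to_numpy(), method="average")
        rank_cmp = rankdata(-block["lr_mean_cmp"].to_numpy(), method="average")
        out.loc[idx, "score"] = np.abs(rank_ref - rank_cmp)
    return out


def shortlist_consensus(
    consensus_pairs: pd.DataFrame,
    pooled: bool = False,
) -> pd.DataFrame:
    """Shortlist consensus units by absolute rank change between states.

    Input as for :func:`consensus_rank_changes`.  Selection is the
    higher-score cluster of the two-means split (per communication type by
    default).
    """
    cols = ["source", "target", "ligand", "receptor", "category", "score",
            "selected"]
    if len(consensus_pairs) == 0:
        return pd.DataFrame(columns=cols)
    scored = consensus_rank_changes(consensus_pairs)
    scored["category"] = "consensus"
    if pooled:
        scored["selected"] = _select_by_partition(
            scored.reset_index(drop=True), "score"
        ).to_numpy()
    else:
        scored["selected"] = False
        for _, idx in scored.groupby(
            ["source", "target"], sort=False
        ).groups.items():
            block = scored.loc[idx].reset_index(drop=True)
            scored.loc[idx, "selected"] = _select_by_partition(
                block, "score"
            ).to_numpy()
    return scored[cols].sort_values(
        ["source", "target", "ligand", "receptor"], kind="stable"
    ).reset_index(drop=True)


def build_shortlist(
    classification: pd.DataFrame,
    ref_table: pd.DataFrame,
    cmp_table: pd.DataFrame,
    pooled: bool = False,
) -> pd.DataFrame:
    """Full shortlist across the three categories.

    ``classification`` is the long classification table
    (``source, target, ligand, receptor, category``); the state tables
    supply ``lr_mean`` values — the comparator's for gains, the
    reference's for potential losses, and both for consensus rank changes.
    """
    key = ["source", "target", "ligand", "receptor"]
    ref_means = ref_table[key + ["lr_mean"]]
    cmp_means = cmp_table[key + ["lr_mean"]]

    gains = classification[classification["category"] == "gain"].merge(
        cmp_means, on=key, how="left"
    )
    losses = classification[
        classification["category"] == "potential_loss"
    ].merge(ref_means, on=key, how="left")
    consensus = (
        classification[classification["category"] == "consensus"]
        .merge(ref_means.rename(columns={"lr_mean": "lr_mean_ref"}), on=key,
               how="left")
        .merge(cmp_means.rename(columns={"lr_mean": "lr_mean_cmp"}), on=key,
               how="left")
    )
    parts = [
        shortlist_gain_pl(gains, "gain", pooled=pooled),
        shortlist_gain_pl(losses, "potential_loss", pooled=pooled),
        shortlist_consensus(
            consensus.drop(columns=["category"]), pooled=pooled
        ),
    ]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(
            columns=["source", "target", "ligand", "receptor", "category",
                     "score", "selected"]
        )
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(
        ["category", "source", "target", "ligand", "receptor"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Frequency analysis


def pair_frequencies(
    classification: pd.DataFrame, stage_interval: str = ""
) -> pd.DataFrame:
    """Count, per (LR pair, category), the distinct communication types
    showing that change within one stage interval.

    E.g. a pair gained in both fibroblast->fibroblast and
    cardiomyocyte->fibroblast communication has gain-category frequency 2.
    """
    cols = ["ligand", "receptor", "stage_interval", "category", "frequency"]
    if len(classification) == 0:
        return pd.DataFrame(columns=cols)
    freq = (
        classification.assign(
            _ct=classification["source"] + "\x1f" + classification["target"]
        )
        .groupby(["ligand", "receptor", "category"], sort=True)["_ct"]
        .nunique()
        .reset_index(name="frequency")
    )
    freq["stage_interval"] = stage_interval
    return freq[cols].sort_values(
        ["category", "ligand", "receptor"], kind="stable"
    ).reset_index(drop=True)


def top_k_pairs(freqs: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Deterministic top-k frequency records.

    Sorted by (frequency desc, category asc, ligand asc, receptor asc);
    with fewer than k records all are returned.  Idempotent and invariant
    to input row order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = freqs.sort_values(
        ["frequency", "category", "ligand", "receptor"],
        ascending=[False, True, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return ordered.head(k).reset_index(drop=True)


def top_pairs_across_categories(
    freqs: pd.DataFrame, k: int = 20
) -> pd.DataFrame:
    """Top-k *pairs* by total frequency across categories, returned as all
    of those pairs' per-category frequency records (the input to the
    permutation overlap test, which needs each pair's category labels)."""
    if len(freqs) == 0:
        return freqs.copy()
    totals = (
        freqs.groupby(["ligand", "receptor"], sort=True)["frequency"]
        .sum()
        .reset_index(name="total")
        .sort_values(
            ["total", "ligand", "receptor"],
            ascending=[False, True, True],
            kind="stable",
        )
        .head(k)
    )
    keep = freqs.merge(
        totals[["ligand", "receptor"]], on=["ligand", "receptor"], how="inner"
    )
    return keep.sort_values(
        ["ligand", "receptor", "category"], kind="stable"
    ).reset_index(drop=True)


def decompose_molecules(
    top_pairs: pd.DataFrame,
    split_complexes: bool = True,
    separator: str = "_",
) -> pd.DataFrame:
    """Single-molecule decomposition of top LR pairs.

    Each pair contributes its ligand and receptor symbols once per record;
    multi-subunit complex names are split on ``separator`` when
    ``split_complexes`` is set.  Occurrence counts accumulate per
    (molecule, stage_interval, category), with a ligand/receptor role
    breakdown.
    """
    cols = ["molecule", "stage_interval", "category", "occurrence_count",
            "n_as_ligand", "n_as_receptor"]
    if len(top_pairs) == 0:
        return pd.DataFrame(columns=cols)
    counts: dict[tuple[str, str, str], list[int]] = {}
    for row in top_pairs.itertuples(index=False):
        interval = getattr(row, "stage_interval", "")
        category = getattr(row, "category", "")
        for role, name in (("ligand", row.ligand), ("receptor", row.receptor)):
            symbols = (
                name.split(separator) if split_complexes else [name]
            )
            for symbol in symbols:
                entry = counts.setdefault((symbol, interval, category), [0, 0])
                entry[0 if role == "ligand" else 1] += 1
    rows = [
        {
            "molecule": mol,
            "stage_interval": interval,
            "category": cat,
            "occurrence_count": n_lig + n_rec,
            "n_as_ligand": n_lig,
            "n_as_receptor": n_rec,
        }
        for (mol, interval, cat), (n_lig, n_rec) in counts.items()
    ]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(
        ["occurrence_count", "molecule", "category"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
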