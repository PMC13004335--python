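"""Hypothesis tests on communication changes.

Two tests accompany the set-level comparison:

* **Consensus-shift test** — for the LR pairs a communication type keeps in
  both states (the consensus set), do their ``lr_mean`` magnitudes shift
  between states?  Paired, non-parametric: the two-sided Wilcoxon
  signed-rank test on the per-pair differences (comparator - reference),
  with zero differences dropped before ranking.  The exact null
  distribution is used for n <= 25 without tied magnitudes, otherwise a
  normal approximation with continuity correction.

* **Permutation overlap test** — among the top-k highest-frequency LR pairs
  of one stage interval, how many carry more than one category label
  (gain in some communication types, loss or consensus in others)?  A low
  count means categorical change is ordered rather than random.  The null
  resamples k distinct pairs from the stage's pair universe and assigns
  each occurrence a uniformly random category; the empirical lower-tail
  p-value uses the add-one estimator, so it is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ClassificationResult, CommType

CATEGORIES = ("consensus", "gain", "potential_loss")


@dataclass
class ConsensusShiftResult:
    comm_type: CommType | None
    n_pairs: int  # non-zero differences actually ranked
    statistic: float
    p_value: float
    significant: bool
    testable: bool


@dataclass
class PermutationResult:
    stage_label: str
    observed_overlap: int
    null_distribution: np.ndarray
    cutoff_05: float  # 5th percentile of the null
    p_value: float
    rng_seed: int
    n_permutations: int
    k: int
    statistic: str
    tail: str


def consensus_shift_test(
    paired_lr_means: Sequence[tuple[float, float]],
    threshold: float = 0.05,
    comm_type: CommType | None = None,
) -> ConsensusShiftResult:
    """Wilcoxon signed-rank test on paired consensus ``lr_mean`` values.

    Parameters
    ----------
    paired_lr_means:
        ``(reference_value, comparator_value)`` per consensus LR pair of
        one communication type, matched by pair identity.
    threshold:
        Two-sided significance level.

    Notes
    -----
    Differences of exactly zero are discarded before ranking (classic
    Wilcoxon zero handling).  With no non-zero difference the type is
    flagged untestable and no p-value is produced.
    """
    diffs = np.asarray(
        [cmp - ref for ref, cmp in paired_lr_means], dtype=float
    )
    diffs = diffs[diffs != 0.0]
    n = len(diffs)
    if n == 0:
        return ConsensusShiftResult(
            comm_type, 0, float("nan"), float("nan"), False, False
        )
    has_ties = len(np.unique(np.abs(diffs))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(
        diffs, alternative="two-sided", correction=(method == "approx"),
        method=method,
    )
    p = float(res.pvalue)
    return ConsensusShiftResult(
        comm_type, n, float(res.statistic), p, p < threshold, True
    )


def consensus_shift_tests(
    ref_table: pd.DataFrame,
    cmp_table: pd.DataFrame,
    classifications: Sequence[ClassificationResult],
    threshold: float = 0.05,
    bh_correction: bool = False,
) -> list[ConsensusShiftResult]:
    """Run the consensus-shift test for every classified communication type.

    ``ref_table`` / ``cmp_table`` are canonical state tables supplying the
    per-state ``lr_mean`` of each consensus pair.  With ``bh_correction``
    the significance calls (not the p-values) are re-made with
    Benjamini-Hochberg across testable types.
    """
    ref_lookup = {
        (r.source, r.target, r.ligand, r.receptor): r.lr_mean
        for r in ref_table.itertuples(index=False)
    }
    cmp_lookup = {
        (r.source, r.target, r.ligand, r.receptor): r.lr_mean
        for r in cmp_table.itertuples(index=False)
    }
    results = []
    for cls in classifications:
        ct = cls.comm_type
        pairs = []
        for pair in sorted(cls.consensus):
            key = (ct.source, ct.target, pair.ligand, pair.receptor)
            if key in ref_lookup and key in cmp_lookup:
                pairs.append((ref_lookup[key], cmp_lookup[key]))
        results.append(
            consensus_shift_test(pairs, threshold=threshold, comm_type=ct)
        )
    if bh_correction:
        testable = [r for r in results if r.testable]
        if testable:
            pvals = np.array([r.p_value for r in testable])
            rejected = _benjamini_hochberg(pvals, threshold)
            for r, rej in zip(testable, rejected):
                r.significant = bool(rej)
    return results


def _benjamini_hochberg(pvals: np.ndarray, alpha: float) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    below = ranked <= (np.arange(1, m + 1) / m) * alpha
    rejected = np.zeros(m, dtype=bool)
    if below.any():
        rejected[order[: np.flatnonzero(below)[-1] + 1]] = True
    return rejected


def consensus_shift_table(
    results: Sequence[ConsensusShiftResult],
) -> pd.DataFrame:
    rows = [
        {
            "source": r.comm_type.source if r.comm_type else "",
            "target": r.comm_type.target if r.comm_type else "",
            "n_pairs": r.n_pairs,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "significant": int(r.significant),
            "testable": int(r.testable),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["source", "target", "n_pairs", "statistic", "p_value",
                 "significant", "testable"],
    )


def significance_matrix(
    interval_results: dict[str, Sequence[ConsensusShiftResult]],
) -> pd.DataFrame:
    """Binary communication-type x interval matrix of consensus-shift calls
    (1 = significant shift, 0 = not; untestable types are 0)."""
    intervals = list(interval_results)
    types: list[str] = []
    for results in interval_results.values():
        for r in results:
            name = str(r.comm_type) if r.comm_type else ""
            if name not in types:
                types.append(name)
    mat = pd.DataFrame(0, index=sorted(types), columns=intervals, dtype=int)
    for interval, results in interval_results.items():
        for r in results:
            name = str(r.comm_type) if r.comm_type else ""
            mat.loc[name, interval] = int(r.significant)
    return mat


# ---------------------------------------------------------------------------
# Permutation null for non-stochastic categorical change


def overlap_statistic(
    pair_labels: pd.DataFrame, statistic: str = "multi_label_pairs"
) -> int:
    """Label-overlap statistic over (ligand, receptor, category) rows.

    ``multi_label_pairs`` counts distinct pairs carrying >= 2 distinct
    category labels; ``multi_label_occurrences`` counts every distinct
    label beyond the first, summed over pairs.
    """
    if len(pair_labels) == 0:
        return 0
    n_labels = pair_labels.groupby(["ligand", "receptor"], sort=False)[
        "category"
    ].nunique()
    if statistic == "multi_label_pairs":
        return int((n_labels >= 2).sum())
    if statistic == "multi_label_occurrences":
        return int((n_labels - 1).sum())
    raise ValueError(f"unknown overlap statistic {statistic!r}")


def permutation_overlap_test(
    observed_top: pd.DataFrame,
    universe: pd.DataFrame,
    k: int = 20,
    n_permutations: int = 200,
    seed: int = 0,
    statistic: str = "multi_label_pairs",
    tail: str = "lower",
    stage_label: str = "",
) -> PermutationResult:
    """Test whether categorical change among top pairs is non-stochastic.

    Parameters
    ----------
    observed_top:
        ``(ligand, receptor, category)`` rows for the stage's top-k
        highest-frequency pairs (a pair may appear once per category it
        holds).
    universe:
        All ``(ligand, receptor, category)`` assignments of the stage; the
        null draws pairs from the distinct pairs of this table and
        preserves each drawn pair's number of label occurrences.
    k:
        Number of distinct pairs resampled per permutation.
    tail:
        ``"lower"`` (default): small observed overlap is evidence of
        ordered, single-category change; ``"upper"`` tests the opposite.

    Notes
    -----
    The null distribution is reproducible given ``seed`` and invariant to
    the row order of ``universe``.  The p-value uses the add-one
    estimator (1 + hits) / (n_permutations + 1).
    """
    if tail not in ("lower", "upper"):
        raise ValueError(f"unknown tail {tail!r}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = overlap_statistic(observed_top, statistic)
    # A pair's occurrence count is the number of communication-type
    # occurrences it has in the stage (the summed frequency); without a
    # frequency column each (pair, category) row counts once.
    if "frequency" in universe.columns:
        occurrences = (
            universe.groupby(["ligand", "receptor"], sort=True)["frequency"]
            .sum()
            .sort_index()
        )
    else:
        occurrences = (
            universe.groupby(["ligand", "receptor"], sort=True)["category"]
            .size()
            .sort_index()
        )
    n_pairs = len(occurrences)
    if k > n_pairs:
        raise ValueError(
            f"k = {k} exceeds the universe of {n_pairs} distinct pairs"
        )
    counts = occurrences.to_numpy()
    rng = np.random.default_rng(seed)
    n_cat = len(CATEGORIES)
    null = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        chosen = rng.choice(n_pairs, size=k, replace=False)
        stat = 0
        for m in counts[chosen]:
            labels = rng.integers(0, n_cat, size=int(m))
            n_distinct = len(np.unique(labels))
            if statistic == "multi_label_pairs":
                stat += int(n_distinct >= 2)
            else:
                stat += n_distinct - 1
        null[i] = stat
    if tail == "lower":
        hits = int((null <= observed).sum())
        cutoff = float(np.percentile(null, 5))
    else:
        hits = int((null >= observed).sum())
        cutoff = float(np.percentile(null, 95))
    p_value = (1 + hits) / (n_permutations + 1)
    return PermutationResult(
        stage_label=stage_label,
        observed_overlap=observed,
        null_distribution=null,
        cutoff_05=cutoff,
        p_value=p_value,
        rng_seed=seed,
        n_permutations=n_permutations,
        k=k,
        statistic=statistic,
        tail=tail,
    )


def permutation_report(result: PermutationResult) -> dict:
    """JSON-serialisable report including the full null distribution."""
    return {
        "stage_label": result.stage_label,
        "observed_overlap": result.observed_overlap,
        "null_distribution": [int(v) for v in result.null_distribution],
        "cutoff_05": result.cutoff_05,
        "p_value": result.p_value,
        "rng_seed": result.rng_seed,
        "n_permutations": result.n_permutations,
        "k": result.k,
        "statistic": result.statistic,
        "tail": result.tail,
    }
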