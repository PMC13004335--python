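"""Synthetic ligand-receptor inference tables with known ground truth.

The generator emulates the *downstream* contract of a LIANA-style
consensus run on one organ: per biological state, a table of
(source cell type, target cell type, ligand, receptor) rows with a
log-normal ``lr_mean`` magnitude and two per-method p-values.  Structure is
planted explicitly — per communication type the consensus, gain and
potential-loss sets between consecutive states are chosen first and the
rows are derived from them — so every pipeline stage can be checked
against exact expectations without any download.

Default dimensions mirror a Tabula-Muris-Senis-like organ with seven
annotated cell types (49 directed communication types including autocrine)
and a few to a few dozen significant LR pairs per type.  "Significant"
rows draw both p-values uniformly from (0, threshold/2]; decoy rows fail
the double-threshold on at least one method, with p-values at or above the
threshold, so the strict-inequality boundary is never exercised by chance
(it is tested explicitly instead).

Nothing upstream of the table contract — counts, cells, the inference
methods' internal scoring — is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CommType, LRPair
from .io import CANONICAL_COLUMNS

DEFAULT_STATE_LABELS = ("1m", "3m", "18m", "21m", "30m")

#: Per-transition (pairs gained, pairs lost) applied to every communication
#: type by default in the lifespan series: expansion during postnatal
#: development, then progressive shrinkage — the organ-level trajectory the
#: framework is designed to resolve.
DEFAULT_DRIFT = ((6, 1), (4, 2), (2, 4), (1, 5))


@dataclass
class TransitionTruth:
    """Planted per-type category sets for one state transition."""

    ref_label: str
    cmp_label: str
    consensus: dict[CommType, frozenset[LRPair]]
    gain: dict[CommType, frozenset[LRPair]]
    potential_loss: dict[CommType, frozenset[LRPair]]

    def comm_types(self) -> list[CommType]:
        return sorted(self.consensus)

    def l_ref(self, ct: CommType) -> frozenset[LRPair]:
        return self.consensus[ct] | self.potential_loss[ct]

    def l_cmp(self, ct: CommType) -> frozenset[LRPair]:
        return self.consensus[ct] | self.gain[ct]

    def expected_se(self, ct: CommType, convention: str = "semantic") -> float:
        """SE recomputed from the planted sets by direct arithmetic."""
        n1, n2 = len(self.l_ref(ct)), len(self.l_cmp(ct))
        n_int = len(self.consensus[ct])
        if n1 == 0 and n2 == 0:
            raise ValueError("type planted empty in both states")
        if n1 == 0:
            value = 1.0
        elif n2 == 0:
            value = -1.0
        else:
            value = n_int * (1.0 / n1 - 1.0 / n2)
        return value if convention == "semantic" else -value

    def expected_ratios(self, ct: CommType) -> tuple[float, float]:
        """(gain ratio, potential-loss ratio) from the planted sets."""
        n1, n2 = len(self.l_ref(ct)), len(self.l_cmp(ct))
        gr = len(self.gain[ct]) / n2 if n2 else float("nan")
        plr = len(self.potential_loss[ct]) / n1 if n1 else float("nan")
        return gr, plr

    def expected_organ_counts(self) -> tuple[int, int, int]:
        """(n_expand, n_shrink, n_stable) under the semantic convention."""
        n_exp = n_shr = n_sta = 0
        for ct in self.comm_types():
            se = self.expected_se(ct)
            if se > 0:
                n_exp += 1
            elif se < 0:
                n_shr += 1
            else:
                n_sta += 1
        return n_exp, n_shr, n_sta


@dataclass
class SyntheticTruth:
    """Full ground truth of one generated scenario."""

    seed: int
    p_threshold: float
    state_labels: list[str]
    lr_mean_params: tuple[float, float]
    transitions: list[TransitionTruth] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "p_threshold": self.p_threshold,
            "state_labels": self.state_labels,
            "lr_mean_params": list(self.lr_mean_params),
            "transitions": [
                {
                    "ref_label": t.ref_label,
                    "cmp_label": t.cmp_label,
                    "types": {
                        f"{ct.source}|{ct.target}": {
                            "consensus": sorted(
                                f"{p.ligand}|{p.receptor}"
                                for p in t.consensus[ct]
                            ),
                            "gain": sorted(
                                f"{p.ligand}|{p.receptor}" for p in t.gain[ct]
                            ),
                            "potential_loss": sorted(
                                f"{p.ligand}|{p.receptor}"
                                for p in t.potential_loss[ct]
                            ),
                        }
                        for ct in t.comm_types()
                    },
                }
                for t in self.transitions
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1), encoding="utf-8"
        )


def _pair_universe(rng: np.random.Generator, n_pairs: int) -> list[LRPair]:
    ligands = [f"LIG{i:03d}" for i in range(1, n_pairs + 1)]
    receptors = [f"REC{i:03d}" for i in range(1, n_pairs + 1)]
    rng.shuffle(receptors)
    return [LRPair(l, r) for l, r in zip(ligands, receptors)]


def _comm_types(n_cell_types: int) -> list[CommType]:
    names = [f"CT{i:02d}" for i in range(1, n_cell_types + 1)]
    return [CommType(a, b) for a in names for b in names]


def _state_rows(
    sets_by_type: Mapping[CommType, frozenset[LRPair]],
    state_label: str,
    rng: np.random.Generator,
    lr_mean_params: tuple[float, float],
    p_threshold: float,
    universe: Sequence[LRPair],
    n_decoys_per_type: int,
) -> pd.DataFrame:
    loc, scale = lr_mean_params
    rows = []
    for ct in sorted(sets_by_type):
        true_pairs = sorted(sets_by_type[ct])
        for pair in true_pairs:
            rows.append(
                (
                    ct.source, ct.target, pair.ligand, pair.receptor,
                    float(rng.lognormal(loc, scale)),
                    float(rng.uniform(0.0, p_threshold / 2)),
                    float(rng.uniform(0.0, p_threshold / 2)),
                    state_label,
                )
            )
        # Decoys: fail the double filter on at least one method so they
        # never enter any recovered set.
        candidates = [p for p in universe if p not in sets_by_type[ct]]
        n_decoys = min(n_decoys_per_type, len(candidates))
        idx = rng.choice(len(candidates), size=n_decoys, replace=False)
        for i in idx:
            pair = candidates[int(i)]
            regime = int(rng.integers(0, 3))  # 0: a sig, 1: b sig, 2: neither
            p_sig = float(rng.uniform(0.0, p_threshold / 2))
            p_a = p_sig if regime == 0 else float(
                rng.uniform(p_threshold, 1.0)
            )
            p_b = p_sig if regime == 1 else float(
                rng.uniform(p_threshold, 1.0)
            )
            rows.append(
                (
                    ct.source, ct.target, pair.ligand, pair.receptor,
                    float(rng.lognormal(loc, scale)), p_a, p_b, state_label,
                )
            )
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


def _normalise_planted(
    planted_sets: Mapping[CommType, Mapping[str, Sequence[LRPair]]],
) -> tuple[dict, dict, dict]:
    consensus, gain, loss = {}, {}, {}
    for ct, sets in planted_sets.items():
        consensus[ct] = frozenset(sets.get("consensus", ()))
        gain[ct] = frozenset(sets.get("gain", ()))
        loss[ct] = frozenset(sets.get("potential_loss", ()))
        overlap = (
            (consensus[ct] & gain[ct])
            | (consensus[ct] & loss[ct])
            | (gain[ct] & loss[ct])
        )
        if overlap:
            raise ValueError(
                f"planted categories overlap for {ct}: {sorted(overlap)}"
            )
        if not consensus[ct] and not gain[ct] and not loss[ct]:
            raise ValueError(f"type {ct} planted empty in both states")
    return consensus, gain, loss


def generate_two_state(
    n_comm_types: int = 49,
    sizes: Sequence[tuple[int, int, int]] | None = None,
    lr_mean_params: tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
    state_labels: tuple[str, str] = ("1m", "3m"),
    p_threshold: float = 0.05,
    n_decoys_per_type: int = 5,
    n_universe: int = 300,
    planted_sets: Mapping[CommType, Mapping[str, Sequence[LRPair]]]
    | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one reference/comparator table pair with planted structure.

    Parameters
    ----------
    n_comm_types:
        Number of directed communication types (default 49: all ordered
        pairs of 7 cell types, the scale of a kidney- or lung-like organ).
    sizes:
        Per-type planted (|consensus|, |gain|, |potential loss|).  ``None``
        draws |C| in [5, 20] and |G|, |PL| in [0, 8] per type.
    lr_mean_params:
        (location, scale) of the log-normal ``lr_mean`` distribution.
    planted_sets:
        Explicit per-type category sets (overrides ``n_comm_types`` and
        ``sizes``) for scenarios with hand-chosen pairs, e.g. the same
        pair gained in several communication types.

    Returns
    -------
    (ref_table, cmp_table, truth)
        Canonical state tables (decoy rows interleaved) plus the exact
        planted truth.  Byte-identical for identical arguments and seed.
    """
    rng = np.random.default_rng(seed)
    universe = _pair_universe(rng, n_universe)

    if planted_sets is not None:
        consensus, gain, loss = _normalise_planted(planted_sets)
        extra = sorted(
            {p for sets in (consensus, gain, loss) for s in sets.values()
             for p in s} - set(universe)
        )
        universe = universe + extra
    else:
        comm_types = _comm_types(int(np.ceil(np.sqrt(n_comm_types))))
        if len(comm_types) < n_comm_types:
            raise ValueError("internal: not enough communication types")
        chosen = [
            comm_types[int(i)]
            for i in rng.choice(
                len(comm_types), size=n_comm_types, replace=False
            )
        ]
        if sizes is None:
            sizes = [
                (
                    int(rng.integers(5, 21)),
                    int(rng.integers(0, 9)),
                    int(rng.integers(0, 9)),
                )
                for _ in chosen
            ]
        if len(sizes) != len(chosen):
            raise ValueError(
                f"sizes has {len(sizes)} entries for {len(chosen)} types"
            )
        consensus, gain, loss = {}, {}, {}
        for ct, (n_c, n_g, n_pl) in zip(chosen, sizes):
            if min(n_c, n_g, n_pl) < 0:
                raise ValueError(f"negative planted size for {ct}")
            if n_c + n_pl < 1 or n_c + n_g < 1:
                raise ValueError(
                    f"type {ct} would be empty in one state; plant at least "
                    "one consensus pair or request it explicitly"
                )
            total = n_c + n_g + n_pl
            if total > len(universe):
                raise ValueError("planted sizes exceed the pair universe")
            idx = rng.choice(len(universe), size=total, replace=False)
            pairs = [universe[int(i)] for i in idx]
            consensus[ct] = frozenset(pairs[:n_c])
            gain[ct] = frozenset(pairs[n_c:n_c + n_g])
            loss[ct] = frozenset(pairs[n_c + n_g:])

    transition = TransitionTruth(
        ref_label=state_labels[0],
        cmp_label=state_labels[1],
        consensus=consensus,
        gain=gain,
        potential_loss=loss,
    )
    truth = SyntheticTruth(
        seed=seed,
        p_threshold=p_threshold,
        state_labels=list(state_labels),
        lr_mean_params=lr_mean_params,
        transitions=[transition],
    )
    ref_sets = {
        ct: transition.l_ref(ct)
        for ct in transition.comm_types()
        if transition.l_ref(ct)
    }
    cmp_sets = {
        ct: transition.l_cmp(ct)
        for ct in transition.comm_types()
        if transition.l_cmp(ct)
    }
    ref_table = _state_rows(
        ref_sets, state_labels[0], rng, lr_mean_params, p_threshold,
        universe, n_decoys_per_type,
    )
    cmp_table = _state_rows(
        cmp_sets, state_labels[1], rng, lr_mean_params, p_threshold,
        universe, n_decoys_per_type,
    )
    return ref_table, cmp_table, truth


def generate_lifespan_series(
    n_states: int = 5,
    drift_spec: Sequence[tuple[int, int]] | None = None,
    seed: int = 0,
    n_comm_types: int = 49,
    initial_size: int = 15,
    lr_mean_params: tuple[float, float] = (0.0, 1.0),
    p_threshold: float = 0.05,
    n_decoys_per_type: int = 5,
    n_universe: int = 300,
    state_labels: Sequence[str] | None = None,
) -> tuple[list[pd.DataFrame], SyntheticTruth]:
    """Generate a consecutive-state series with planted drift per interval.

    ``drift_spec`` gives, per transition, the number of LR pairs every
    communication type gains and loses; the default profile expands early
    and shrinks late, emulating a postnatal-development-then-ageing
    trajectory over the five default ages (1, 3, 18, 21, 30 months).
    Transition truths are mutually consistent: each state's comparator
    sets are the next transition's reference sets.
    """
    if n_states < 2:
        raise ValueError("a series needs at least 2 states")
    if state_labels is None:
        state_labels = (
            list(DEFAULT_STATE_LABELS[:n_states])
            if n_states <= len(DEFAULT_STATE_LABELS)
            else [f"s{i}" for i in range(1, n_states + 1)]
        )
    if len(state_labels) != n_states:
        raise ValueError("state_labels length must equal n_states")
    if drift_spec is None:
        drift_spec = [
            DEFAULT_DRIFT[i % len(DEFAULT_DRIFT)] for i in range(n_states - 1)
        ]
    if len(drift_spec) != n_states - 1:
        raise ValueError("drift_spec needs one (gain, loss) per transition")

    rng = np.random.default_rng(seed)
    universe = _pair_universe(rng, n_universe)
    comm_types_all = _comm_types(int(np.ceil(np.sqrt(n_comm_types))))
    chosen = sorted(
        comm_types_all[int(i)]
        for i in rng.choice(
            len(comm_types_all), size=n_comm_types, replace=False
        )
    )
    current: dict[CommType, frozenset[LRPair]] = {}
    for ct in chosen:
        idx = rng.choice(len(universe), size=initial_size, replace=False)
        current[ct] = frozenset(universe[int(i)] for i in idx)

    truth = SyntheticTruth(
        seed=seed,
        p_threshold=p_threshold,
        state_labels=list(state_labels),
        lr_mean_params=lr_mean_params,
    )
    state_sets = [current]
    for n_gain, n_loss in drift_spec:
        nxt: dict[CommType, frozenset[LRPair]] = {}
        consensus, gain, loss = {}, {}, {}
        for ct in chosen:
            cur = sorted(state_sets[-1][ct])
            n_loss_ct = min(n_loss, max(len(cur) - 1, 0))
            lost_idx = set(
                int(i)
                for i in rng.choice(len(cur), size=n_loss_ct, replace=False)
            ) if n_loss_ct else set()
            kept = frozenset(
                p for i, p in enumerate(cur) if i not in lost_idx
            )
            candidates = [p for p in universe if p not in state_sets[-1][ct]]
            n_gain_ct = min(n_gain, len(candidates))
            gained = frozenset(
                candidates[int(i)]
                for i in rng.choice(
                    len(candidates), size=n_gain_ct, replace=False
                )
            ) if n_gain_ct else frozenset()
            nxt[ct] = kept | gained
            consensus[ct] = kept
            gain[ct] = gained
            loss[ct] = frozenset(cur[i] for i in lost_idx)
        truth.transitions.append(
            TransitionTruth(
                ref_label=state_labels[len(state_sets) - 1],
                cmp_label=state_labels[len(state_sets)],
                consensus=consensus,
                gain=gain,
                potential_loss=loss,
            )
        )
        state_sets.append(nxt)

    tables = [
        _state_rows(
            {ct: s for ct, s in sets.items() if s},
            label, rng, lr_mean_params, p_threshold, universe,
            n_decoys_per_type,
        )
        for sets, label in zip(state_sets, state_labels)
    ]
    return tables, truth


def write_state_table(
    table: pd.DataFrame,
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write a canonical state table in the on-disk (LIANA-named) schema
    that :func:`ccshift.io.read_interaction_table` reads back."""
    from .config import DEFAULT_COLUMN_MAP

    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    out = table.drop(columns=["state"]).rename(
        columns={role: col for role, col in column_map.items()}
    )
    out.to_csv(path, index=False)
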