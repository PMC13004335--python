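"""Run configuration for the two-phase communication comparison workflow.

A single :class:`AnalysisConfig` object carries every tunable the pipeline
uses: the dual p-value significance threshold, the two-cluster shortlisting
setting, the top-k cut for frequency ranking, the permutation count for the
categorical-change null, the SE sign convention, and the mapping from schema
roles to the column names of the input table (LIANA consensus output names by
default).  Configs round-trip through YAML so a run is fully described by one
file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: Schema-role -> column-name mapping matching LIANA v0.1.x ``rank_aggregate``
#: consensus output.  Every role is remappable; the roles themselves are fixed.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "source": "source",
    "target": "target",
    "ligand": "ligand_complex",
    "receptor": "receptor_complex",
    "lr_mean": "lr_means",
    "pval_cellphone": "cellphone_pvals",
    "pval_cellchat": "cellchat_pvals",
}

SIGN_CONVENTIONS = ("semantic", "literal")
OVERLAP_STATISTICS = ("multi_label_pairs", "multi_label_occurrences")
PERMUTATION_TAILS = ("lower", "upper")


@dataclass
class AnalysisConfig:
    """All pipeline tunables with their defaults.

    Parameters
    ----------
    p_threshold:
        Strict significance cutoff applied to *both* method p-values
        (CellPhoneDB-style and CellChat-style); an interaction is retained
        only when both are strictly below this value.
    n_clusters:
        Number of clusters for shortlisting; the method is defined for 2.
    top_k:
        Number of highest-frequency ligand-receptor pairs retained per stage.
    n_permutations:
        Replicates for the categorical-change permutation null.
    rng_seed:
        Seed for every stochastic step of a run.
    se_sign_convention:
        ``"semantic"`` (positive = expansion, the default) or ``"literal"``
        (the printed r(2) - r(1) algebra, opposite sign), see
        :func:`ccshift.core.se_score`.
    symmetrize_comm_types:
        Merge directed communication types (A, B) and (B, A) before scoring.
    complex_separator:
        Subunit separator inside multi-subunit complex names.
    overlap_statistic:
        Null-test statistic: ``"multi_label_pairs"`` counts pairs carrying
        at least two distinct category labels; ``"multi_label_occurrences"``
        counts every extra label beyond the first.
    permutation_tail:
        Tail for the permutation p-value; ``"lower"`` tests whether the
        observed overlap is unusually small (ordered, non-stochastic change).
    bh_correction:
        Apply Benjamini-Hochberg across communication types in the
        consensus-shift tests (off by default).
    pooled_shortlist:
        Cluster shortlisting scores pooled across communication types
        instead of per type.
    column_map:
        Schema-role -> input-column mapping; defaults to LIANA names.
    separator:
        Field separator of the input tables.
    """

    p_threshold: float = 0.05
    n_clusters: int = 2
    top_k: int = 20
    n_permutations: int = 200
    rng_seed: int = 0
    se_sign_convention: str = "semantic"
    symmetrize_comm_types: bool = False
    complex_separator: str = "_"
    overlap_statistic: str = "multi_label_pairs"
    permutation_tail: str = "lower"
    bh_correction: bool = False
    pooled_shortlist: bool = False
    column_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COLUMN_MAP)
    )
    separator: str = ","

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError(
                f"p_threshold must lie in (0, 1), got {self.p_threshold}"
            )
        if self.n_clusters != 2:
            raise ValueError("shortlisting is defined for n_clusters = 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.se_sign_convention not in SIGN_CONVENTIONS:
            raise ValueError(
                f"se_sign_convention must be one of {SIGN_CONVENTIONS}"
            )
        if self.overlap_statistic not in OVERLAP_STATISTICS:
            raise ValueError(
                f"overlap_statistic must be one of {OVERLAP_STATISTICS}"
            )
        if self.permutation_tail not in PERMUTATION_TAILS:
            raise ValueError(
                f"permutation_tail must be one of {PERMUTATION_TAILS}"
            )
        missing = set(DEFAULT_COLUMN_MAP) - set(self.column_map)
        if missing:
            raise ValueError(f"column_map missing roles: {sorted(missing)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def replace(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)
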