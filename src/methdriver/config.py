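"""Analysis configuration shared by all pipeline stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and switches of the driver-calling pipeline.

    All q thresholds are Benjamini-Hochberg FDR levels. ``discretize_q``
    controls the per-sample ternary call (0.05 default; 0.01 is the
    stricter robustness setting). ``min_frequency`` is the minimum
    fraction of tumors carrying an alteration for a locus to become a
    candidate. ``n_permutations`` is the replicate count B of the
    downstream-count null (100,000 for a full analysis; reduce for
    exploratory runs). ``permutation_estimator`` selects the empirical
    p-value rule: ``"literal"`` is the plain fraction r/B of replicates
    with at least the observed count; ``"add_one"`` is (r+1)/(B+1), which
    never returns 0.
    """

    discretize_q: float = 0.05
    discretize_scope: str = "per_sample"  # or "global"
    min_frequency: float = 0.10
    cis_q: float = 0.05
    de_q: float = 0.05
    n_permutations: int = 100_000
    permutation_q: float = 1.00e-4
    pathway_q: float = 1.00e-4
    subtype_q: float = 0.05
    n_clusters: int = 3
    seed: int = 0
    min_group_size: int = 3
    equal_var: bool = False  # Welch by default; True = Student pooled
    permutation_estimator: str = "literal"  # or "add_one"
    share_permutation_null: bool = True
    permutation_fdr_scope: str = "across_candidates"
    pathway_fdr_scope: str = "within_candidate"  # or "across_candidates"
    jaccard_binarize: bool = False
    detection_p_cut: float = 0.05
    detection_max_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "discretize_q",
            "min_frequency",
            "cis_q",
            "de_q",
            "permutation_q",
            "pathway_q",
            "subtype_q",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be at least 2")
        if self.permutation_estimator not in ("literal", "add_one"):
            raise ValueError("permutation_estimator must be 'literal' or 'add_one'")
        if self.discretize_scope not in ("per_sample", "global"):
            raise ValueError("discretize_scope must be 'per_sample' or 'global'")
        if self.pathway_fdr_scope not in ("within_candidate", "across_candidates"):
            raise ValueError("bad pathway_fdr_scope")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
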