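"""Analysis configuration shared across pipeline stages.

All thresholds that drive the statistical chain live here so that a run is
fully described by one structured-text (YAML) document plus the input paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

#: Grids must share shape exactly and affines must agree within this many mm.
AFFINE_ATOL_MM = 1e-4


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class AnalysisConfig:
    """Settings for the seed-map -> efficacy -> overlap -> graph chain.

    Parameters
    ----------
    t_threshold:
        Absolute t cutoff applied to group t-maps. The default 5.1 is the
        published whole-brain Bonferroni cutoff for a 1000-subject normative
        sample; when ``None`` the cutoff is derived from ``alpha`` and
        ``brain_voxel_count`` at run time.
    alpha:
        Family-wise error level for the Bonferroni derivation.
    brain_voxel_count:
        Number of voxelwise tests used by the Bonferroni derivation. 67_000
        approximates an in-brain 3 mm grid.
    group_stat:
        ``"per_subject_t"`` (Fisher-z each subject's r-map, one-sample t
        across subjects) or ``"average_r"`` (Fisher-z average across subjects
        back-transformed, then the single-correlation t with df = n - 2).
    edge_display_cutoff:
        Correlation magnitude below which graph edges are flagged as
        below-cutoff for rendering. Never affects centrality computation.
    n_clusters:
        Number of clusters cut from the hierarchical tree.
    negative_edge_policy:
        Fixed to ``"drop"``: anticorrelations never enter the graph.
    efficacy_mode:
        ``"mean"`` or ``"sum"`` combination of outcome-weighted binary maps.
    component_connectivity:
        3-D neighbourhood for connected components: 6 (faces) or 26 (faces,
        edges, corners).
    min_component_voxels:
        Components smaller than this are discarded as speckle.
    """

    t_threshold: Optional[float] = 5.1
    alpha: float = 0.05
    brain_voxel_count: int = 67_000
    group_stat: str = "per_subject_t"
    edge_display_cutoff: float = 0.3
    n_clusters: int = 5
    negative_edge_policy: str = "drop"
    efficacy_mode: str = "mean"
    pooling_weighting: str = "simple"
    component_connectivity: int = 26
    min_component_voxels: int = 5
    linkage_method: str = "complete"
    edge_length_convention: str = "inverse"   # 1/weight; alt: "one_minus"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.t_threshold is not None and not self.t_threshold > 0:
            raise ConfigError("t_threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.brain_voxel_count < 1:
            raise ConfigError("brain_voxel_count must be >= 1")
        if self.group_stat not in ("per_subject_t", "average_r"):
            raise ConfigError(f"unknown group_stat {self.group_stat!r}")
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.negative_edge_policy != "drop":
            raise ConfigError("negative_edge_policy is fixed to 'drop'")
        if self.efficacy_mode not in ("mean", "sum"):
            raise ConfigError(f"unknown efficacy_mode {self.efficacy_mode!r}")
        if self.pooling_weighting not in ("simple", "by_n"):
            raise ConfigError(f"unknown pooling_weighting {self.pooling_weighting!r}")
        if self.component_connectivity not in (6, 26):
            raise ConfigError("component_connectivity must be 6 or 26")
        if self.min_component_voxels < 0:
            raise ConfigError("min_component_voxels must be >= 0")
        if self.edge_length_convention not in ("inverse", "one_minus"):
            raise ConfigError(
                f"unknown edge_length_convention {self.edge_length_convention!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
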