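"""Run configuration shared across pipeline stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """All tunable knobs of the pipeline, with documented valid ranges.

    Every randomized stage reads its seed from here, so two runs with equal
    config and inputs produce identical outputs.
    """

    # ssGSEA
    ssgsea_alpha: float = 0.25          # rank-weight exponent, >= 0
    ssgsea_normalize: bool = True       # global min-max rescaling of the score matrix

    # consensus NMF clustering
    k_min: int = 2
    k_max: int = 6
    n_restarts: int = 50
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    stability_floor: float = 0.95       # cophenetic floor for rank eligibility

    # co-expression network
    n_top_genes: int = 1000             # MAD filter; 0 keeps all genes
    beta_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
    scale_free_target: float = 0.85
    min_module_size: int = 30
    cut_height: float = 0.90            # fixed dissimilarity for the tree cut
    merge_threshold: float = 0.75       # eigengene correlation for optional merging
    merge_modules: bool = False

    # module / hub selection
    module_r_floor: float = 0.5
    module_p_ceiling: float = 0.05
    mm_threshold: float = 0.8
    gs_threshold: float = 0.5

    # immune score
    cutpoint_q_low: float = 0.1
    cutpoint_q_high: float = 0.9
    pooled_pc1: bool = False            # pooled PCA across each sign instead of per-module

    # survival
    roc_horizon_months: float = 60.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be >= 0")
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n_restarts < 2:
            raise ValueError("n_restarts must be >= 2")
        if not (0 < self.stability_floor <= 1):
            raise ValueError("stability_floor must be in (0, 1]")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")
        if not (0 < self.cut_height < 1):
            raise ValueError("cut_height must be in (0, 1)")
        if not (0 <= self.cutpoint_q_low < self.cutpoint_q_high <= 1):
            raise ValueError("need 0 <= q_low < q_high <= 1")
        for name in ("module_r_floor", "mm_threshold", "gs_threshold"):
            if not (0 < getattr(self, name) <= 1.1):
                raise ValueError(f"{name} outside valid range")
        if self.roc_horizon_months <= 0:
            raise ValueError("roc_horizon_months must be > 0")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_grid"] = list(d["beta_grid"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"config_hash={self.config_hash()}", f"seed={self.seed}"]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        if "beta_grid" in data:
            data["beta_grid"] = tuple(data["beta_grid"])
        return cls(**data)
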