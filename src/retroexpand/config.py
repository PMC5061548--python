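"""Simulation configuration and deterministic seed derivation.

All randomness in the package flows from one master seed; per-stage generators
are derived by hashing a stage label into a numpy ``SeedSequence`` spawn key,
so adding or reordering stages never perturbs the streams of other stages.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

RatePiece = tuple[float, float, float]  # (start MY, end MY, rate/lineage/MY), start > end


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Independent generator for a labeled stage of the pipeline."""
    key = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic gene-family scenario.

    Defaults describe the study scenario: a single retrotransposition on the
    Paenungulata stem lineage at 65 MY, a quiescent interval, then segmental
    duplication at 0.0736 events/lineage/MY restricted to the proboscidean
    clade on (40, 0] MY — the pure-birth rate giving an expected ~19 extant
    copies (ln 19 / 40). Times are MY before present; coordinates downstream
    are 0-based half-open.
    """

    # gene-family history
    t_retro: float = 65.0
    retro_host: str = "Paenungulata"  # event occurs on the stem branch above this node
    duplication_rate: tuple[RatePiece, ...] = ((40.0, 0.0, 0.0736),)
    duplication_clade: Optional[str] = "Proboscidea"
    loss_rate: float = 0.0

    # sequence evolution
    substitution_rate: float = 0.002   # substitutions/site/MY
    kappa: float = 2.0                 # transition/transversion ratio
    gene_length: int = 1000
    deletion_length: int = 21          # diagnostic deletion shared by all retrogenes
    deletion_offset: int = 240         # 0-based start of the deletion in the root sequence
    orf_disruption_prob: float = 5 / 19  # fraction of copies receiving a premature stop

    # locus structure
    flank_length: int = 500
    flank_drift: float = 0.05          # subs/site applied to the new copy's flanks per duplication
    te_fingerprint: tuple[str, ...] = ("RTE1_LA", "AFROSINE1", "L1MB5")
    mechanism: str = "segmental"       # or "independent_retrotransposition"
    n_control_regions: int = 5

    # read simulation
    coverage: float = 5.0
    read_length: int = 100
    paired: bool = False
    insert_size: int = 300
    error_rate: float = 0.002
    ancient_read_length: tuple[int, int] = (40, 100)
    ancient_coverage: float = 0.5

    # expression table
    expressed_high: int = 1
    expressed_low: int = 2
    fpkm_high: float = 50.0
    fpkm_low: float = 4.0
    parent_fpkm: float = 150.0

    seed: int = 0

    def __post_init__(self) -> None:
        pieces = tuple(tuple(float(x) for x in p) for p in self.duplication_rate)
        self.duplication_rate = pieces  # normalize list-of-lists from YAML
        for start, end, rate in pieces:
            if rate < 0:
                raise ValueError(f"duplication rate must be >= 0, got {rate}")
            if start <= end:
                raise ValueError(f"rate piece ({start}, {end}] must run older -> younger")
        if self.loss_rate < 0:
            raise ValueError("loss rate must be >= 0")
        if not 15 <= self.deletion_length <= 30:
            raise ValueError("diagnostic deletion length must lie in [15, 30] nt")
        if self.substitution_rate < 0 or self.flank_drift < 0 or self.error_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.coverage < 0 or self.ancient_coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.gene_length <= self.deletion_length + 100:
            raise ValueError("gene_length must exceed deletion_length + 100")
        if self.mechanism not in ("segmental", "independent_retrotransposition"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        lo, hi = self.ancient_read_length
        if not 0 < lo <= hi:
            raise ValueError("ancient read-length range must satisfy 0 < lo <= hi")
        self.ancient_read_length = (int(lo), int(hi))
        self.te_fingerprint = tuple(self.te_fingerprint)

    def dup_rate_at(self, t: float) -> float:
        """Duplication rate at time ``t`` MY before present."""
        for start, end, rate in self.duplication_rate:
            if end < t <= start:
                return rate
        return 0.0

    def rng(self, label: str) -> np.random.Generator:
        return derive_rng(self.seed, label)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        data = self.to_dict()
        data["duplication_rate"] = [list(p) for p in data["duplication_rate"]]
        data["te_fingerprint"] = list(data["te_fingerprint"])
        data["ancient_read_length"] = list(data["ancient_read_length"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "duplication_rate" in data:
            data = dict(data)
            data["duplication_rate"] = tuple(tuple(p) for p in data["duplication_rate"])
        if "ancient_read_length" in data:
            data = dict(data)
            data["ancient_read_length"] = tuple(data["ancient_read_length"])
        return cls(**data)
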