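"""Analysis thresholds shared across the pipeline.

Every numeric cutoff used anywhere in the package lives in
:class:`AnalysisConfig`, so a run is fully described by one object (or the
YAML file that mirrors it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: mm9/mm10 autosomes; methylation analysis is restricted to these by default.
MOUSE_AUTOSOMES: frozenset[str] = frozenset(f"chr{i}" for i in range(1, 20))


@dataclass
class AnalysisConfig:
    """Thresholds for filtering, differential testing and aggregation.

    Parameters
    ----------
    min_depth:
        Minimum read depth a CpG must have in *every* sample to be analyzed.
    min_diff:
        Minimum absolute methylation difference (fraction) between a sample
        pair for a CpG to enter the Fisher test, and for significance.
    alpha:
        BH-adjusted p-value (q) threshold for a significant CpG.
    lm_cut, hm_cut:
        Class boundaries: lowly methylated below ``lm_cut``, highly
        methylated above ``hm_cut``, partially methylated in between
        (boundaries inclusive on the partial class).
    merge_gap:
        CpGs closer than this many bp are chained into one region for
        region-level clustering (strictly-less-than rule).
    min_fpkm:
        A gene is kept if its FPKM reaches this value in at least one sample.
    promoter_up, promoter_down:
        Promoter extent: ``promoter_up`` bp upstream of the TSS through
        ``promoter_down`` bp into the gene (the TSS base counts as the first
        downstream base, so the promoter spans up + down bp in total).
    shore_bp, shelf_bp:
        Width of the CpG-island shore band and of the shelf band beyond it.
    min_dmcs_per_dmp:
        Minimum number of same-direction significant CpGs a promoter must
        contain to be called a differentially methylated promoter.
    autosomes:
        Chromosome names considered autosomal. ``None`` means mouse chr1-19;
        synthetic genomes pass their own set.
    """

    min_depth: int = 10
    min_diff: float = 0.10
    alpha: float = 0.05
    lm_cut: float = 0.30
    hm_cut: float = 0.70
    merge_gap: int = 500
    min_fpkm: float = 1.0
    promoter_up: int = 1000
    promoter_down: int = 500
    shore_bp: int = 2000
    shelf_bp: int = 2000
    min_dmcs_per_dmp: int = 2
    autosomes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.lm_cut < self.hm_cut < 1.0):
            raise ValueError(
                f"class cuts must satisfy 0 < lm_cut < hm_cut < 1, "
                f"got lm_cut={self.lm_cut}, hm_cut={self.hm_cut}"
            )
        for name in ("min_depth", "merge_gap", "promoter_up", "promoter_down",
                     "shore_bp", "shelf_bp", "min_dmcs_per_dmp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.min_diff <= 1:
            raise ValueError("min_diff must be a fraction in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.autosomes is not None:
            self.autosomes = frozenset(self.autosomes)

    def autosome_set(self) -> frozenset[str]:
        return self.autosomes if self.autosomes is not None else MOUSE_AUTOSOMES

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["autosomes"] is not None:
            d["autosomes"] = sorted(d["autosomes"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
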