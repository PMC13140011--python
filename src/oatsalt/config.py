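"""Configuration objects for the simulation and the full pipeline.

The defaults encode the study design this package targets: an allohexaploid
oat (A/C/D subgenomes) salt-stress experiment with three tissues (Seed, Leaf,
Root) sampled at 0, 6, 12, 24 and 48 h in three biological replicates
(45 transcriptome samples), plus a germination-rate association panel of
225 accessions genotyped at biallelic SNP/InDel markers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

SUBGENOMES = ("A", "C", "D")
TF_FAMILIES = ("MYB", "WRKY", "bHLH", "AP2", "ERF", "NAC", "MADS", "Dof", "bZIP", "HSF")

#: dominance labels in fixed order; "balanced" closes the vocabulary
DOMINANCE_LABELS = ("A-dominant", "C-dominant", "D-dominant", "balanced")

#: focal 3-bp promoter InDel: the insertion-carrying allele (Hap1) is the
#: reference, the deletion allele (Hap2) the alternate
CAUSAL_MARKER_ID = "InDel_459300121"
CAUSAL_CHROM = "4D"
CAUSAL_POS = 459_300_121
CAUSAL_REF = "TCACTC"
CAUSAL_ALT = "TCC"


@dataclass
class SimulationConfig:
    """Ground-truth generator settings.

    Counts follow a negative binomial with a single shared dispersion
    (``var = mu + dispersion * mu**2``); ``nb_dispersion = 0`` is the
    noise-free degenerate mode where counts equal rounded means.
    """

    # homeolog structure
    n_triads: int = 400
    n_dyads_per_pattern: int = 30          # patterns AC, AD, CD
    n_singletons_per_subgenome: int = 40
    tf_fraction: float = 0.10              # fraction of homeolog groups with a TF family

    # expression design
    tissues: Sequence[str] = ("Seed", "Leaf", "Root")
    timepoints_h: Sequence[int] = (0, 6, 12, 24, 48)
    replicates: int = 3

    # count model
    nb_dispersion: float = 0.1
    baseline_log_mean: float = 6.0         # log2 mean counts per kb of exon
    de_fraction: float = 0.4
    de_log2fc_magnitude: float = 2.0

    # subgenome dominance (A-dom, C-dom, D-dom, balanced)
    dominance_mix: Sequence[float] = (0.3, 0.4, 0.2, 0.1)

    # planted co-expression modules
    n_modules: int = 5
    module_size_range: Sequence[int] = (40, 60)
    module_snr: float = 2.0                # sd (log2 scale) of the shared module profile

    # association panel
    n_accessions: int = 225
    n_markers: int = 500
    causal_effect: float = 10.0            # germination-rate points per Hap1 allele
    causal_maf: float = 0.30
    phenotype_mean: float = 40.0
    phenotype_sd: float = 8.0
    maf_range: Sequence[float] = (0.05, 0.5)
    missing_rate: float = 0.02

    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_triads": self.n_triads,
            "n_dyads_per_pattern": self.n_dyads_per_pattern,
            "n_singletons_per_subgenome": self.n_singletons_per_subgenome,
            "replicates": self.replicates,
            "n_modules": self.n_modules,
            "n_accessions": self.n_accessions,
            "n_markers": self.n_markers,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for name in ("de_fraction", "tf_fraction", "missing_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if abs(sum(self.dominance_mix) - 1.0) > 1e-9 or min(self.dominance_mix) < 0:
            raise ValueError("dominance_mix must be non-negative and sum to 1")
        if 0 not in tuple(self.timepoints_h):
            raise ValueError("timepoints_h must include the 0-h control")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        lo, hi = self.module_size_range
        if lo < 1 or hi < lo:
            raise ValueError("module_size_range must satisfy 1 <= min <= max")

    def n_genes(self) -> int:
        return (3 * self.n_triads
                + 2 * 3 * self.n_dyads_per_pattern
                + 3 * self.n_singletons_per_subgenome)

    def n_samples(self) -> int:
        return len(self.tissues) * len(self.timepoints_h) * self.replicates


@dataclass
class PipelineConfig:
    """Thresholds and knobs for every analysis stage.

    Defaults follow the study's stated parameters: |log2FC| >= 1 with an
    FPKM > 0.5 floor for differential expression, FPKM > 0.2 for network
    input, soft-threshold scan over beta = 1..30 targeting scale-free
    R^2 = 0.85, signed TOM, minimum module size 30, eigengene merge cut
    0.25, balanced-region radius 0.2, marker QC at MAF >= 0.05 and
    missing rate <= 0.1, and 3 genotype-PC covariates.
    """

    # differential expression
    fc_min: float = 1.0
    deg_fpkm_min: float = 0.5
    epsilon: float = 0.01
    deg_mode: str = "threshold"            # "threshold" | "test"
    alpha: float = 0.05

    # network
    network_fpkm_min: float = 0.2
    beta_range: Sequence[int] = tuple(range(1, 31))
    r2_target: float = 0.85
    min_module_size: int = 30
    merge_cut: float = 0.25
    cut_height_quantile: float = 0.99
    subnetwork_weight_min: float = 0.5

    # homeolog bias
    balanced_radius: float = 0.2
    expression_floor: float = 0.5
    bias_context: str = "salt"             # "salt" | "all"

    # association
    maf_min: float = 0.05
    miss_max: float = 0.1
    n_pcs: int = 3
    genome_wide_threshold: float = 1e-4    # alternative printed value: 2.76e-7
    candidate_window_bp: int = 50_000

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        self.simulation.validate()
        if self.deg_mode not in ("threshold", "test"):
            raise ValueError("deg_mode must be 'threshold' or 'test'")
        if self.bias_context not in ("salt", "all"):
            raise ValueError("bias_context must be 'salt' or 'all'")
        if not 0 < self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in (0, 0.5]")
        if not 0 <= self.miss_max <= 1:
            raise ValueError("miss_max must lie in [0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        cfg = cls(**data, simulation=SimulationConfig(**sim))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        """Stable hash of the full configuration, recorded for provenance."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _plain(obj):
    """Recursively convert tuples to lists so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
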