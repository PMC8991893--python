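"""Pipeline configuration: every analysis threshold, with its published default.

A single YAML file can override any field; unknown keys are rejected so typos
fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml


@dataclass
class FilterConfig:
    # plasma calling: alt-supporting reads, with one on each strand
    min_alt_reads: int = 3
    require_both_strands: bool = True
    # tumour rescue: >=1 plasma read if the matched tumour shows >=3
    rescue_min_plasma_reads: int = 1
    rescue_min_tumour_reads: int = 3
    min_mean_alt_bq: float = 25.0
    germline_min_depth: int = 20
    germline_undercovered: str = "drop"  # keep|drop
    drop_exonic_functions: tuple = ("synonymous", "unknown")
    # strand-bias (FPfilter-style): Fisher p AND minor-strand fraction
    strand_bias_p: float = 0.01
    strand_bias_min_fraction: float = 0.10
    drop_population_af: bool = False  # flagged by default, not dropped


@dataclass
class KataegisConfig:
    max_log10_imd: float = 4.0     # grouping bound: IMD <= 10^4 bp
    min_cluster_size: int = 6
    max_mean_imd: float = 1000.0   # bp
    min_score: float = 5.0         # hypermutation score threshold
    score_p: float = 0.05
    combine_plasma: bool = True


@dataclass
class SignatureConfig:
    discard_threshold: float = 0.06
    stop_rel_improvement: float = 1e-3
    dsbr_signatures: tuple = ("Signature.3",)
    mmr_signatures: tuple = ("Signature.6", "Signature.15", "Signature.20",
                             "Signature.21", "Signature.26")
    poln_signatures: tuple = ("Signature.9",)


@dataclass
class CopyNumberConfig:
    bin_size: int = 1_000_000
    min_mappability: float = 0.9
    # normal contamination grid; tumour fraction candidates are 1 - these
    normal_contamination_grid: tuple = (0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 0.99)
    self_transition: float = 0.99
    max_copy_state: int = 5
    # per-bin state prior (HOMD..HLAMP); mildly favours diploid so that a
    # single-copy loss at tumour fraction t is not aliased to a homozygous
    # loss at t/2
    state_prior: tuple = (0.001, 0.05, 0.85, 0.05, 0.02, 0.01)
    min_usable_bins: int = 10
    logr_floor: float = -8.0


@dataclass
class ClonalConfig:
    k_range: tuple = (1, 2, 3, 4, 5, 6, 7)
    n_restarts: int = 20
    max_em_iter: int = 300
    em_tol: float = 1e-8
    max_exhaustive_clones: int = 10
    detection_floor: float = 0.005
    decline_fraction: float = 0.5


@dataclass
class TrackingConfig:
    undetected_maf_policy: str = "zero"  # zero|drop
    ca199_max_day_gap: int = 14
    trackable_min_timepoints: int = 2


@dataclass
class PipelineConfig:
    filtering: FilterConfig = field(default_factory=FilterConfig)
    kataegis: KataegisConfig = field(default_factory=KataegisConfig)
    signatures: SignatureConfig = field(default_factory=SignatureConfig)
    copynumber: CopyNumberConfig = field(default_factory=CopyNumberConfig)
    clonal: ClonalConfig = field(default_factory=ClonalConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)

    def to_dict(self) -> dict:
        return asdict(self)


def default_config() -> PipelineConfig:
    return PipelineConfig()


def _build(cls, data: dict):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    kw = {name: tuple(value) if isinstance(value, list) else value
          for name, value in data.items()}
    return cls(**kw)


def load_config(path) -> PipelineConfig:
    """Load a YAML config; sections and keys not present keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sections = {f.name: f.default_factory for f in fields(PipelineConfig)}
    unknown = set(data) - set(sections)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    kw = {}
    for name, factory in sections.items():
        if name in data:
            kw[name] = _build(type(factory()), data[name] or {})
    return PipelineConfig(**kw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
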