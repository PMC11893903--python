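"""Configuration objects for the synthetic-data generators and the pipeline.

``SimConfig`` collects every knob of the simulated study: the flow-cytometry
recombination screen (fractions of fluorescent cells per well), the
replica-pinning screen (binary colony calls), the spike-in-calibrated
strand-specific DRIP experiment, the OK-seq replication-direction profile,
and the focus-counting image stacks.  A given ``SimConfig`` (including its
seed) always produces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Mapping

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field fails validation."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid config field {name!r}: {msg}")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Fractions live in [0, 1]; counts are >= 1; fold-changes and rates are
    positive.  ``hyper_effects`` / ``pinning_effects`` plant true effects for
    named mutant strains; every generator also emits a truth table so that
    downstream recovery can be scored against what was planted.
    """

    seed: int = 0

    # -- flow-cytometry screen (screen I) --
    n_plates: int = 4
    wells_per_plate: int = 96
    n_wt_wells: int = 96
    wt_baseline: float = 0.01
    plate_effect_sd: float = 0.15
    well_noise_sd: float = 0.25
    hyper_effects: Mapping[str, float] = field(default_factory=dict)
    n_replicates: int = 4

    # -- replica-pinning screen (screen II) --
    n_strains_pinning: int = 96
    pinning_p_wt: float = 0.02
    pinning_effects: Mapping[str, float] = field(default_factory=dict)
    poor_growth_strains: tuple = ()
    array_replicates: int = 16
    selective_plates: int = 3

    # -- DRIP experiment --
    n_genes: int = 200
    genome_length: int = 200_000
    bin_size: int = 20
    txn_level_mean: float = 10.0
    txn_level_sd: float = 1.0  # log-scale SD of per-gene transcription
    hybrid_per_txn: float = 0.5
    background_density: float = 0.5
    spike_fraction_input: float = 0.05
    ip_efficiency: float = 0.1
    condition_fold: float = 2.0
    rnh_residual: float = 0.1
    ip_depth: int = 1_000_000
    input_depth: int = 1_000_000

    # -- OK-seq profile --
    okseq_n_intervals: int = 20
    okseq_interval_bp: int = 10_000
    okseq_step_bp: int = 100
    okseq_slope_per_kb: float = 0.2
    okseq_noise_sd: float = 0.0

    # -- imaging --
    image_shape: tuple = (256, 256)
    n_z: int = 5
    n_nuclei: int = 12
    nucleus_radius: int = 14
    foci_per_nucleus: int = 3
    foci_snr: float = 20.0
    image_background: float = 20.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check(isinstance(self.seed, int) and self.seed >= 0, "seed", "must be a non-negative integer")
        for name in ("n_plates", "wells_per_plate", "n_wt_wells", "n_replicates",
                     "n_strains_pinning", "array_replicates", "selective_plates",
                     "n_genes", "genome_length", "bin_size", "okseq_n_intervals",
                     "okseq_interval_bp", "okseq_step_bp", "n_z", "n_nuclei",
                     "nucleus_radius", "ip_depth", "input_depth"):
            _check(int(getattr(self, name)) >= 1, name, "count must be >= 1")
        for name in ("wt_baseline", "pinning_p_wt", "spike_fraction_input", "rnh_residual"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, "fraction must lie in [0, 1]")
        for name in ("plate_effect_sd", "well_noise_sd", "txn_level_mean", "txn_level_sd",
                     "hybrid_per_txn", "background_density", "ip_efficiency",
                     "condition_fold", "okseq_slope_per_kb", "foci_snr", "image_background"):
            _check(getattr(self, name) > 0, name, "must be positive")
        _check(self.okseq_noise_sd >= 0, "okseq_noise_sd", "must be non-negative")
        _check(self.foci_per_nucleus >= 0, "foci_per_nucleus", "must be non-negative")
        for strain, f in dict(self.hyper_effects).items():
            _check(f > 0, "hyper_effects", f"fold-change for {strain!r} must be > 0")
        for strain, p in dict(self.pinning_effects).items():
            _check(0.0 <= p <= 1.0, "pinning_effects", f"probability for {strain!r} must be in [0, 1]")
        _check(self.n_genes * 2 * self.bin_size < self.genome_length, "genome_length",
               "genome too short for the requested gene count")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hyper_effects"] = dict(self.hyper_effects)
        d["pinning_effects"] = dict(self.pinning_effects)
        d["poor_growth_strains"] = list(self.poor_growth_strains)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        if "poor_growth_strains" in d:
            d["poor_growth_strains"] = tuple(d["poor_growth_strains"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
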