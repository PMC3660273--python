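"""Simulation configuration for the synthetic FF/FFPET cohort generator.

A :class:`SimulationConfig` describes one in-silico study: a random reference
transcriptome, an Affymetrix-style probe design with planted flaws, and a
matched fresh-frozen (FF) / formalin-fixed paraffin-embedded (FFPET) tumor
cohort processed with one or more amplification-kit degradation profiles.

All randomness is driven by ``seed`` through named, order-independent
``numpy.random.SeedSequence`` streams (PCG64), so a fixed seed yields
byte-identical outputs across runs and platforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ConfigurationError

__all__ = ["DegradationProfile", "SimulationConfig", "default_kit_profiles"]


@dataclass
class DegradationProfile:
    """Kit-specific FFPET degradation model, additive in log2 space.

    Parameters
    ----------
    kit_label : str
        Name of the amplification kit this profile emulates.
    three_prime_decay : float
        log2 signal attenuation per nucleotide of distance from the
        transcript 3' end (>= 0). Produces the 3' bias of degraded RNA.
    extra_noise_sd : float
        Additional log2 measurement noise on top of the FF noise (>= 0).
    dropout_prob : float
        Per probe x sample probability that the probe signal is lost and
        replaced by background only.
    global_attenuation : float
        Uniform log2 signal loss applied to every probe (>= 0).

    An all-zero profile leaves the FFPET cohort byte-identical to FF.
    """

    kit_label: str
    three_prime_decay: float = 0.0
    extra_noise_sd: float = 0.0
    dropout_prob: float = 0.0
    global_attenuation: float = 0.0

    def is_null(self) -> bool:
        return (
            self.three_prime_decay == 0.0
            and self.extra_noise_sd == 0.0
            and self.dropout_prob == 0.0
            and self.global_attenuation == 0.0
        )

    def validate(self) -> None:
        for name in ("three_prime_decay", "extra_noise_sd", "global_attenuation"):
            if getattr(self, name) < 0:
                raise ConfigurationError(
                    f"DegradationProfile[{self.kit_label}].{name} must be >= 0"
                )
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigurationError(
                f"DegradationProfile[{self.kit_label}].dropout_prob must be in [0, 1]"
            )


def default_kit_profiles() -> dict[str, DegradationProfile]:
    """Three presets ordered nugen < affy2c < wta in noise and attenuation.

    The ordering mirrors the observed quality ranking of the three
    commercial kits (NuGEN closest to FF, whole-transcriptome amplification
    farthest); the parameter values themselves are free simulator knobs.
    """
    return {
        "nugen": DegradationProfile(
            "nugen", three_prime_decay=0.0035, extra_noise_sd=0.3,
            dropout_prob=0.02, global_attenuation=1.0,
        ),
        "affy2c": DegradationProfile(
            "affy2c", three_prime_decay=0.006, extra_noise_sd=0.6,
            dropout_prob=0.05, global_attenuation=2.0,
        ),
        "wta": DegradationProfile(
            "wta", three_prime_decay=0.008, extra_noise_sd=1.0,
            dropout_prob=0.10, global_attenuation=3.0,
        ),
    }


@dataclass
class SimulationConfig:
    """Full description of one synthetic matched FF/FFPET study.

    Defaults encode the study conditions emulated throughout: 8 ER+ and
    8 ER- breast-tumor pairs, 11 probes of 25 nt per probe set, a minority
    of genes differentially expressed by more than 2-fold between ER
    groups, and a small planted fraction of misdesigned probes.
    """

    seed: int = 0
    n_genes: int = 200
    transcript_length_range: tuple[int, int] = (600, 1200)
    #: distribution of the number of probe sets interrogating one gene
    probe_sets_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.25, 3: 0.05}
    )
    probes_per_set: int = 11
    probe_length: int = 25
    frac_nonmatching_probes: float = 0.06
    frac_crosshyb_probes: float = 0.03
    n_complete_mismatch_sets: int = 25
    n_pairs_per_group: int = 8
    frac_de_genes: float = 0.2
    #: |delta| drawn uniformly from this log2 range, sign +/- with equal odds
    effect_log2_range: tuple[float, float] = (1.2, 3.0)
    kit_profiles: dict[str, DegradationProfile] = field(
        default_factory=default_kit_profiles
    )
    background_mean: float = 50.0       # linear intensity
    background_sd: float = 10.0         # linear intensity
    #: per-array multiplicative background variation (log2 SD); real chips
    #: differ in overall nonspecific background level
    background_scale_sd: float = 0.3
    probe_affinity_sd: float = 0.5      # log2
    measurement_sd_ff: float = 0.25     # log2
    tissue_sd: float = 0.5              # log2, per-tumor biological noise
    baseline_log2_range: tuple[float, float] = (6.0, 10.0)
    #: fraction of genes silenced to background in every sample
    frac_silenced_genes: float = 0.0
    #: append a densely tiled control transcript for the 3'/5' ratio assay
    include_degradation_control: bool = True
    control_transcript_length: int = 600
    control_tiling_step: int = 1
    #: optional per-gene overrides of the baseline log2 expression
    baseline_overrides: dict[str, float] = field(default_factory=dict)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first bad field."""
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("transcript_length_range must satisfy 0 < lo <= hi")
        if self.probe_length < 1:
            raise ConfigurationError("probe_length must be >= 1")
        if self.probe_length > min(lo, self.control_transcript_length):
            raise ConfigurationError(
                "probe_length must not exceed the minimum transcript length"
            )
        if self.probes_per_set < 1:
            raise ConfigurationError("probes_per_set must be >= 1")
        if abs(sum(self.probe_sets_per_gene.values()) - 1.0) > 1e-9:
            raise ConfigurationError("probe_sets_per_gene probabilities must sum to 1")
        if any(k < 1 for k in self.probe_sets_per_gene):
            raise ConfigurationError("probe_sets_per_gene counts must be >= 1")
        for name in (
            "frac_nonmatching_probes",
            "frac_crosshyb_probes",
            "frac_de_genes",
            "frac_silenced_genes",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.n_complete_mismatch_sets < 0:
            raise ConfigurationError("n_complete_mismatch_sets must be >= 0")
        if self.n_pairs_per_group < 2:
            raise ConfigurationError("n_pairs_per_group must be >= 2")
        e_lo, e_hi = self.effect_log2_range
        if not (0 < e_lo <= e_hi):
            raise ConfigurationError("effect_log2_range must satisfy 0 < lo <= hi")
        for name in (
            "background_mean",
            "background_sd",
            "background_scale_sd",
            "probe_affinity_sd",
            "measurement_sd_ff",
            "tissue_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.control_tiling_step < 1:
            raise ConfigurationError("control_tiling_step must be >= 1")
        for label, profile in self.kit_profiles.items():
            if not isinstance(profile, DegradationProfile):
                raise ConfigurationError(f"kit_profiles[{label}] is not a DegradationProfile")
            profile.validate()

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transcript_length_range"] = list(self.transcript_length_range)
        d["effect_log2_range"] = list(self.effect_log2_range)
        d["baseline_log2_range"] = list(self.baseline_log2_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        kits = d.pop("kit_profiles", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        for name in ("transcript_length_range", "effect_log2_range", "baseline_log2_range"):
            if name in d:
                d[name] = tuple(d[name])
        if "probe_sets_per_gene" in d:
            d["probe_sets_per_gene"] = {int(k): float(v) for k, v in d["probe_sets_per_gene"].items()}
        cfg = cls(**d)
        if kits is not None:
            profiles: dict[str, DegradationProfile] = {}
            for label, p in kits.items():
                if isinstance(p, DegradationProfile):
                    profiles[label] = p
                else:
                    p = dict(p)
                    p.setdefault("kit_label", label)
                    profiles[label] = DegradationProfile(**p)
            cfg.kit_profiles = profiles
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def with_seed(self, seed: Optional[int]) -> "SimulationConfig":
        if seed is None:
            return self
        return dataclasses.replace(self, seed=int(seed))
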