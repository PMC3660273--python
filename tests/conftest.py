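"""Shared fixtures: one small simulated cohort reused across test modules."""

from __future__ import annotations

import pytest

from ffpetconcord.annotate import revise_design
from ffpetconcord.config import DegradationProfile, SimulationConfig
from ffpetconcord.preprocess import expression_index
from ffpetconcord.synthetic import (
    generate_array_design,
    generate_reference,
    simulate_cohort,
)


def small_config(**overrides) -> SimulationConfig:
    """A fast cohort: 40 genes, two kits (one degradation-free)."""
    base = dict(
        seed=11,
        n_genes=40,
        n_complete_mismatch_sets=25,
        kit_profiles={
            "perfect": DegradationProfile("perfect"),
            "nugen": DegradationProfile(
                "nugen", three_prime_decay=0.0035, extra_noise_sd=0.3,
                dropout_prob=0.02, global_attenuation=1.0,
            ),
        },
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    """Simulated cohort with revised design and per-cohort expression."""
    cfg = small_config()
    reference = generate_reference(cfg)
    design, truth, reference = generate_array_design(reference, cfg)
    ff, ffpet, sheet = simulate_cohort(reference, design, truth, cfg)
    revised = revise_design(design, reference)
    expr = {}
    for label, m in {"ff": ff, **ffpet}.items():
        e, affin, _ = expression_index(m, revised, design_ref=label)
        expr[label] = e
    return dict(
        cfg=cfg,
        reference=reference,
        design=design,
        truth=truth,
        ff=ff,
        ffpet=ffpet,
        sheet=sheet,
        revised=revised,
        expr=expr,
    )
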