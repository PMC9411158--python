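"""End-to-end orchestration helpers shared by the CLI and the test-suite."""

from __future__ import annotations

from .comorbidity import all_pairs
from .core_io import PipelineConfig, WorldInputs
from .moa import MOAProfile, infer_moa_profiles


def run_pipeline(inputs: WorldInputs, config: PipelineConfig | None = None):
    """MOA inference followed by all-pairs comorbidity scoring.

    Returns ``(profiles, edges)`` where profiles maps disease id to
    :class:`MOAProfile` and edges is the full pair table.
    """
    config = config or inputs.config
    profiles = infer_moa_profiles(inputs, config)
    edges = all_pairs(profiles, inputs.universe.n_t, config)
    return profiles, edges


def eff_sets(profiles: dict[str, MOAProfile]) -> dict[str, frozenset]:
    """Efficacious drug set per disease (for easy-pair exclusion)."""
    return {d: p.eff_drugs for d, p in profiles.items()}
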