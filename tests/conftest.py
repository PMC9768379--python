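"""Shared fixtures: templates, pause models, and processed synthetic libraries.

The heavyweight fixture (`scenario_profiles`) simulates and fully processes
the six-library WT-vs-mutant scenario once per session at depth 5e5; the
end-to-end acceptance-style tests share it.
"""

from __future__ import annotations

import numpy as np
import pytest

import poliseq as pq

SCENARIO_DEPTH = 500_000
SCENARIO_CONTAMINATION = 0.1


@pytest.fixture(scope="session")
def default_template() -> pq.RDNATemplate:
    return pq.make_default_template()


@pytest.fixture(scope="session")
def small_template() -> pq.RDNATemplate:
    """100-nt template: 40 nt spacer + 60 nt mature."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    return pq.RDNATemplate(
        name="mini",
        sequence=seq,
        regions=(
            pq.Region("ETS1", 0, 40, "spacer"),
            pq.Region("18S", 40, 100, "mature"),
        ),
    )


@pytest.fixture(scope="session")
def strain_models(default_template):
    wt_params, mut_params = pq.make_strain_pair_scenario(default_template)
    return (
        pq.build_pause_model(default_template, wt_params),
        pq.build_pause_model(default_template, mut_params),
    )


def simulate_and_process(
    model: pq.PauseModel,
    template: pq.RDNATemplate,
    seed: int,
    depth: int = SCENARIO_DEPTH,
    contamination: float = SCENARIO_CONTAMINATION,
) -> pq.OccupancyProfile:
    """Simulate one library and run it through the full read pipeline."""
    lib = pq.simulate_netseq_library(
        model,
        depth=depth,
        contamination_frac=contamination,
        seed=seed,
        library_id=f"{model.strain_label}-s{seed}",
    )
    return pq.process_library(
        lib.full_sequences(),
        template,
        adaptor=lib.adaptor,
        umi_len=lib.umi_len,
        library_id=lib.library_id,
        strain=model.strain_label,
    )


@pytest.fixture(scope="session")
def scenario_profiles(default_template, strain_models):
    """3 WT + 3 mutant processed libraries at depth 5e5, contamination 0.1."""
    wt_model, mut_model = strain_models
    wt = [simulate_and_process(wt_model, default_template, seed) for seed in (11, 12, 13)]
    mut = [simulate_and_process(mut_model, default_template, seed) for seed in (14, 15, 16)]
    return {"WT": wt, "mutant": mut}
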