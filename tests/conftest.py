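"""Session fixtures; data builders and oracles live in _oracles."""

from __future__ import annotations

import pytest

from pairedsurv.simulate import SimulationConfig, simulate_paired_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small paired cohort with survival signal planted in the normal view."""
    cfg = SimulationConfig(
        n_patients=50, n_genes=300, n_blocks=10, n_signal_genes=20, seed=11
    )
    return simulate_paired_cohort(cfg)
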