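"""Shared configuration for the numbered analysis drivers."""

from pathlib import Path

from alascan.synth import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def default_config(seed: int = 1) -> SimulationConfig:
    """The study-scale synthetic configuration used by every driver."""
    return SimulationConfig(seed=seed)
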