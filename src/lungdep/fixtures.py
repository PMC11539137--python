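"""Ready-made study networks at several scales.

``symmetric_small`` is a complete symmetric tree small enough for exact
closed-form checks. ``asymmetric_medium`` is the desk-scale stand-in for
a full adult lung: ~5000 conducting airways, five lobes, terminal
generations spanning roughly 8-20. ``asymmetric_small`` is a few hundred
airways for quick unit tests.
"""

from __future__ import annotations

from .generate import GeneratorParams, generate_tree
from .network import AirwayNetwork

FIXTURE_KINDS = ("symmetric_small", "asymmetric_medium", "asymmetric_small")


def make_fixture(kind: str, seed: int = 0) -> AirwayNetwork:
    """Build a fixture network (deterministic per seed)."""
    if kind == "symmetric_small":
        params = GeneratorParams(symmetric=True, n_generations=4,
                                 trachea_radius=0.006, trachea_length=0.06)
    elif kind == "asymmetric_medium":
        params = GeneratorParams(n_terminal_target=2600)
    elif kind == "asymmetric_small":
        params = GeneratorParams(n_terminal_target=120)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    return generate_tree(params, seed=seed)
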