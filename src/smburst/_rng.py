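"""Named, independent random substreams derived from one master seed.

Each pipeline stage (diffusion, emission, background, channel splitting, …)
draws from its own Generator so that toggling one stage never perturbs the
random numbers seen by another.
"""

from __future__ import annotations

import numpy as np

_STAGES = {
    "diffusion": 1,
    "emission": 2,
    "background": 3,
    "channels": 4,
    "grid": 5,
    "test": 6,
}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Generator for ``stage`` under master ``seed``."""
    try:
        stage_key = _STAGES[stage]
    except KeyError:
        raise ValueError(f"unknown RNG stage {stage!r}") from None
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage_key]))
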