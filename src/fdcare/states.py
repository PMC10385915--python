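"""Shared vocabulary for the six functional-capacity (FC) states.

States 1-5 are living states identified by latent class analysis of 29
categorical functional indicators; state 6 is absorbing death:

    1  viability disorder        (most severe functional decline)
    2  acute disease
    3  somatic functional disorder
    4  health
    5  sub-disorder status

Severity runs, from mild to severe: 4 < 5 < 2 < 3 < 1.  The multi-state
chain permits instantaneous moves only between severity-adjacent living
states plus every living state -> death.
"""

from __future__ import annotations

N_STATES = 6
DEATH = 6
LIVING_STATES = (1, 2, 3, 4, 5)

STATE_NAMES = {
    1: "viability disorder",
    2: "acute disease",
    3: "somatic functional disorder",
    4: "health",
    5: "sub-disorder status",
    6: "death",
}

#: living states ordered from mild to severe
SEVERITY_ORDER = (4, 5, 2, 3, 1)

#: states that carry a community home-based care cost (state 4 is healthy,
#: state 6 dead; neither consumes care)
CARE_STATES = (1, 2, 3, 5)

SEXES = ("male", "female")
AGE_BANDS = ("60-69", "70+")
STRATA = tuple((s, b) for s in SEXES for b in AGE_BANDS)
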