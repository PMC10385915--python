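"""Default study conditions for the synthetic cohort.

These defaults define the conditions every simulation-based check runs
under; they are chosen once to emulate a Chinese ageing panel and are not
tuning knobs.

* Demographics: 50% female; 59.4% aged 60-69 at entry (the 2011 baseline
  composition of the study population).
* Initial FC state distribution (states 1-5), by sex, from the reported
  2011 composition: male 8.4 / 10.6 / 5.8 / 41.9 / 33.0 %, female
  14.3 / 10.0 / 9.6 / 25.9 / 40.0 %.
* Transition intensities: a severity-adjacent chain with baseline rates
  producing one-year transition probabilities on the scale of the fitted
  tables, plus the reported covariate effects on the state 2 <-> 5
  transitions -- female HR 0.72 on 2->5 and 1.56 on 5->2; age >=70 HR 0.42
  on 2->5 and 1.51 on 5->2 -- and a doubling of all death intensities for
  the >=70 band (a moderate ageing effect of our own choosing).
* Measurement model: 29 binary indicators in five blocks; each latent
  state elevates its own block on top of a state-specific base impairment
  probability ordered along the severity ladder 4 < 5 < 2 < 3 < 1.
"""

from __future__ import annotations

import numpy as np

from .lca import LCAParams
from .multistate import IntensityModel, build_Q, chain_structure
from .states import AGE_BANDS, DEATH, LIVING_STATES, SEXES, SEVERITY_ORDER
from .synthetic import SimConfig

#: baseline per-year intensities of the severity-adjacent chain
BASELINE_RATES = {
    (4, 5): 0.45, (5, 4): 0.18,
    (5, 2): 0.20, (2, 5): 0.30,
    (2, 3): 0.35, (3, 2): 0.30,
    (3, 1): 0.15, (1, 3): 0.25,
    (1, 6): 0.10, (2, 6): 0.06, (3, 6): 0.08, (4, 6): 0.02, (5, 6): 0.04,
}

#: reported covariate log hazard ratios on the 2 <-> 5 transitions
COVARIATE_EFFECTS = {
    ("female", (2, 5)): np.log(0.72),
    ("female", (5, 2)): np.log(1.56),
    ("age70", (2, 5)): np.log(0.42),
    ("age70", (5, 2)): np.log(1.51),
}

#: age >=70 effect on every death intensity (our choice: doubling)
AGE_DEATH_LOG_HR = np.log(2.0)

# as reported; the female shares print to 99.8% and are renormalized on use
INITIAL_STATE_DISTRIBUTION = {
    "male": np.array([0.084, 0.106, 0.058, 0.419, 0.333]),
    "female": np.array([0.143, 0.100, 0.096, 0.259, 0.400]),
}

SEX_PROPORTION_FEMALE = 0.5
AGE_BAND_PROPORTIONS = {"60-69": 0.594, "70+": 0.406}


def default_intensity_model() -> IntensityModel:
    """The ground-truth intensity model with sex and age covariates."""
    st = chain_structure()
    theta = np.array([np.log(BASELINE_RATES[t]) for t in st.transitions])
    beta = dict(COVARIATE_EFFECTS)
    for s in LIVING_STATES:
        beta[("age70", (s, DEATH))] = AGE_DEATH_LOG_HR
    return IntensityModel(st, theta, beta, ("female", "age70"))


def default_true_intensities() -> dict:
    """Per (sex, age_band) generator matrices implied by the default model."""
    model = default_intensity_model()
    out = {}
    for sex in SEXES:
        for band in AGE_BANDS:
            z = {"female": 1.0 if sex == "female" else 0.0,
                 "age70": 1.0 if band == "70+" else 0.0}
            out[(sex, band)] = build_Q(model, z)
    return out


def default_indicator_model(n_indicators: int = 29) -> LCAParams:
    """Five-class measurement model over binary functional indicators."""
    base = {1: 0.75, 2: 0.40, 3: 0.60, 4: 0.05, 5: 0.25}
    K = 5
    rho = []
    for j in range(n_indicators):
        block_state = SEVERITY_ORDER[j % K]  # indicator's "own" state block
        p = np.array([base[s] + (0.20 if s == block_state else 0.0)
                      for s in range(1, K + 1)])
        rho.append(np.stack([1.0 - p, p], axis=1))
    pi = (INITIAL_STATE_DISTRIBUTION["male"] + INITIAL_STATE_DISTRIBUTION["female"]) / 2.0
    return LCAParams(K, pi / pi.sum(), rho)


def default_sim_config(n_individuals: int = 2000, seed: int = 0,
                       wave_times=(0.0, 2.0, 4.0),
                       with_indicators: bool = True) -> SimConfig:
    """The study-condition simulation configuration."""
    init = {(sex, band): INITIAL_STATE_DISTRIBUTION[sex] /
            INITIAL_STATE_DISTRIBUTION[sex].sum()
            for sex in SEXES for band in AGE_BANDS}
    return SimConfig(
        n_individuals=n_individuals,
        wave_times=list(wave_times),
        sex_proportion_female=SEX_PROPORTION_FEMALE,
        age_band_proportions=dict(AGE_BAND_PROPORTIONS),
        true_intensities=default_true_intensities(),
        initial_state_distribution=init,
        indicator_model=default_indicator_model() if with_indicators else None,
        seed=seed,
    )


#: synthetic default entrants schedule (millions entering 60-69 per decade);
#: a stand-in for external population-prospects inputs, scaled to the
#: magnitude of the 60-69 band in the packaged population table
DEFAULT_ENTRANTS = {
    (2020, "male"): 40.0, (2020, "female"): 38.0,
    (2030, "male"): 45.0, (2030, "female"): 43.0,
}
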