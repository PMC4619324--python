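"""Show a signature's survival association beats random signatures.

Draws size-matched random probe sets, rebuilds delta-weight signatures from
the discovery cohort, scores the validation cohort with each, and compares
the observed Cox |z| of the real signature's score against that empirical
null distribution.
"""

import numpy as np

from dnamesig import (
    SimulationConfig,
    random_signature_null,
    select_signature_cv,
    simulate_cohort,
)

POPULATION = 7

discovery, _ = simulate_cohort(
    SimulationConfig(n_pos=35, n_neg=28, seed=1, population_seed=POPULATION), "discovery")
validation, _ = simulate_cohort(
    SimulationConfig(
        n_pos=120, n_neg=120, seed=2, population_seed=POPULATION,
        treatment_probs={"carboplatin": 1.0, "cisplatin": 0.0, "none": 0.0},
        hr_marker_by_treatment={"carboplatin": 3.5, "cisplatin": 1.0, "none": 1.0},
    ), "validation")

signature = select_signature_cv(discovery, [25, 50], folds=10, seed=3)
null = random_signature_null(validation, signature, discovery, n_draws=200, seed=4)

print(f"observed Cox |z| of the signature score: {null.observed:.2f}")
print(f"random-signature draws: mean |z| {np.mean(null.draws):.2f}, "
      f"max {np.max(null.draws):.2f}")
print(f"empirical p = {null.empirical_p:.4f} over {null.n_draws} draws")
# empirical p is (1 + #draws >= observed) / (n_draws + 1); a value near the
# minimum 1/(n_draws+1) means essentially no random signature predicts
# survival as strongly as the discovered one
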