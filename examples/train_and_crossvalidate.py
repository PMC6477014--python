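"""A reference-scale synthetic study: simulate, train the trio, cross-validate.

Run:  python examples/train_and_crossvalidate.py   (about 5 s)
"""
import pandas as pd

from prevoid import (
    CVScheme,
    SimulationConfig,
    TriggerPoint,
    cross_validate,
    default_volunteers,
    sensitivity_specificity,
    simulate_protocol_dataset,
)
from prevoid.states import BladderState

config = SimulationConfig(noise_sd=0.05)
v1, v2 = default_volunteers()
parts = [simulate_protocol_dataset(config, v, n_days=5, seed=s).features
         for v, s in ((v1, 11), (v2, 12))]
features = pd.concat(parts, ignore_index=True)
counts = {k: int(v) for k, v in features["state"].value_counts().items()}
print(f"simulated {len(features)} labelled samples ({counts})")

matrices = cross_validate(features, features["state"], CVScheme(kind="k_fold", k=10, seed=5))
trigger = TriggerPoint(BladderState.THREE_QUARTERS)
for name, cm in matrices.items():
    se, sp = sensitivity_specificity(cm, trigger)
    print(f"{name:>6}: accuracy {cm.accuracy:.3f}   Se {se:.2f} Sp {sp:.2f}  (trigger 3/4)")
# Each line is one classifier's out-of-fold confusion summarised at the
# imminent-voiding trigger; the voting row combines the three opinions.
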