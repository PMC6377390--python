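"""Score model-selected sampling locations against field-confirmed ones.

Builds a small synthetic pairing of predicted and actual coordinates plus
a binary field-suitability form, then prints the positional RMSE, the
coordinate agreement, and the suitability percentages.
"""

import numpy as np
import pandas as pd

from gwclhs import correlation_locations, rmse_locations, suitability_scores

rng = np.random.default_rng(0)
actual = rng.uniform(0, 5000, size=(10, 2))
predicted = actual + rng.normal(scale=20.0, size=(10, 2))  # ~20 m placement error

pairs = pd.DataFrame({
    "id": np.arange(10),
    "pred_x": predicted[:, 0], "pred_y": predicted[:, 1],
    "act_x": actual[:, 0], "act_y": actual[:, 1],
})
print(f"positional RMSE: {rmse_locations(pairs):.2f} m (map units)")
print(f"stacked-coordinate r^2: {correlation_locations(pairs):.4f}")

criteria = pd.DataFrame(
    rng.integers(0, 2, size=(10, 6)),
    columns=["soil_type", "geology", "landform", "access_tube", "drainage",
             "effective_depth_gt_100cm"],
)
criteria.insert(0, "location", [f"AT{i + 1:02d}" for i in range(10)])
scored, levels = suitability_scores(criteria)
print("\nper-location suitability (6 binary field criteria):")
print(scored[["location", "mean_score", "percentage"]].to_string(index=False))
print("\nfraction of locations at each percentage level:")
print(levels.to_string())
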