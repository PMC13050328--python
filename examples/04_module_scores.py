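"""Score zone-restricted pathway modules and check their spatial pattern.

Module scores compare a gene set's expression to expression-matched
control genes per pixel. The blueprint activates a BMP-like module in the
cortical zones and an RA-like module in the inner cortex, so the scores
should separate active from inactive zones.
"""

import numpy as np

from spatgonad import (
    default_blueprint,
    normalize,
    qc_filter,
    ranksum,
    score_named_modules,
    simulate_section,
)

blueprint = default_blueprint(seed=3)
sample, truth = simulate_section(blueprint, "E35", seed=3)
norm = normalize(qc_filter(sample, 100))

module_sets = {name: spec[0] for name, spec in blueprint.module_spec.items()}
scores = score_named_modules(norm, module_sets, seed=3)
zone = truth.pixels.set_index("pixel_id")["zone"]

for ms in scores:
    active_zones = blueprint.module_spec[ms.module_name][1]
    mask = np.isin(zone.loc[ms.pixel_ids].to_numpy(), active_zones)
    gap = ms.scores[mask].mean() - ms.scores[~mask].mean()
    p = ranksum(ms.scores[mask], ms.scores[~mask],
                alternative="greater").p_value
    print(f"{ms.module_name}: active-zone mean {ms.scores[mask].mean():.3f}, "
          f"inactive {ms.scores[~mask].mean():.3f}, gap {gap:.3f}, "
          f"one-sided p = {p:.2e}")
# A positive gap with a tiny p-value means the module lights up exactly
# where the blueprint made it active.
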