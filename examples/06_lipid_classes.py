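"""Parse shorthand lipid names and profile rhythmicity by lipid class.

Shorthand names encode class, total carbons:double bonds, optionally the
individual chains ('_' = positions undefined, '/' = defined) and ';'
modifiers.  The class distribution table mirrors a per-class rhythmicity
census of an untargeted lipidomics run.
"""

import numpy as np

from diurnalomics import (
    SimulationConfig,
    class_distribution,
    detect_all,
    generate_lipidome,
    parse_lipid_name,
)
from diurnalomics.datamodel import TimedSampleMatrix

for name in ("TG 58:9", "DG 18:1_22:6", "Cer 18:1;2O/23:0", "ST 28:1;O;S"):
    lipid = parse_lipid_name(name)
    chains = (
        "chains unknown" if not lipid.chains
        else " + ".join(c.format() for c in lipid.chains)
    )
    print(f"{name}: class {lipid.lipid_class}, "
          f"{lipid.total_carbons} C / {lipid.total_double_bonds} DB ({chains})")

config = SimulationConfig(
    n_features=285, fraction_rhythmic=0.36, noise_kind="lognormal",
    sigma=0.25, amplitude=("uniform", 0.3, 1.0), seed=6,
)
matrix, truth = generate_lipidome(config)
logged = matrix.values.copy()
logged.loc[:, :] = np.log(matrix.values.to_numpy())
calls = detect_all(
    TimedSampleMatrix(logged, matrix.samples, "continuous"), alpha=0.01
)
rhythmic = calls.rhythmic_features("WT")
table = class_distribution(
    matrix.feature_ids, [f in rhythmic for f in matrix.feature_ids]
)
print(f"\n{len(rhythmic)} of {matrix.n_features} lipid species rhythmic; "
      "per class:")
print(table.to_string())
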