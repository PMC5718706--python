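"""Select cell-type marker genes from sorted-cell sample groups.

Plants five perfect markers per cell type among shared-baseline noise
genes, adds a background tissue, and runs the selection: a marker must be
significantly overexpressed against every other cell type AND every
background tissue, so genes leaking into the background are rejected.
"""

import numpy as np
import pandas as pd

import bulkdecon as bd

rng = np.random.default_rng(8)
n_types, markers_per_type, n_noise, n_samples = 3, 5, 200, 8
genes = [f"marker_t{t}_{i}" for t in range(n_types) for i in range(markers_per_type)]
genes += [f"noise_{i}" for i in range(n_noise)]

groups = {}
for t in range(n_types):
    cols = {}
    for s in range(n_samples):
        v = np.zeros(len(genes))
        lo = t * markers_per_type
        v[lo:lo + markers_per_type] = rng.lognormal(np.log(100), 0.2, markers_per_type)
        v[n_types * markers_per_type:] = rng.lognormal(np.log(20), 0.5, n_noise)
        cols[f"type{t}_s{s}"] = v
    groups[f"type{t}"] = pd.DataFrame(cols, index=genes)

# a background tissue that expresses one of type0's would-be markers
background = pd.DataFrame(np.zeros((len(genes), 6)), index=genes)
background.loc["marker_t0_0"] = rng.lognormal(np.log(80), 0.1, 6)

signature = bd.select_signature_genes(groups, {"connective": background})
for cell_type, markers in signature.markers.items():
    print(f"{cell_type}: {sorted(markers)}")
print(
    f"\n{signature.n_genes} signature genes selected; note marker_t0_0 was\n"
    "rejected because the background tissue expresses it - exactly the\n"
    "genes a cancer/stromal component could confound."
)
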