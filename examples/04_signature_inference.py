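"""De-novo signature extraction and exposure refitting on planted truth.

Simulates 40 mutation catalogs from a known 3-signature mixture with
Poisson noise, extracts signatures by NMF with randomization-based rank
selection, matches them back to the planted basis by cosine similarity and
refits one sample's exposures with the 15% assignment threshold.
"""

import numpy as np
import pandas as pd

from tumorcomplexity import extract_signatures, match_to_reference, refit_exposures
from tumorcomplexity.synthetic_cohort import simulate_catalog, synthetic_sbs_signatures

W = synthetic_sbs_signatures(3)
rng = np.random.default_rng(1)
E = rng.dirichlet([5.0, 5.0, 5.0], size=40)
catalog = simulate_catalog("SBS96", W, E, 2000, seed=2)

model = extract_signatures(catalog, ranks=range(2, 6), n_runs=15,
                           n_randomized_runs=15, seed=3)
print(f"chosen rank: {model.chosen_rank}")
print(model.rank_diagnostics.round(3), "\n")

ref = pd.DataFrame(W, index=model.W.index, columns=["planted1", "planted2", "planted3"])
print(match_to_reference(model, ref).round(3), "\n")

ev = refit_exposures(catalog.counts.iloc[:, 0].to_numpy(), model.W)
print(f"sample {catalog.samples[0]} exposures: "
      + ", ".join(f"{k}={v:.2f}" for k, v in ev.exposures.items())
      + f", unassigned={ev.unassigned:.2f}")
print(f"planted exposures:          {np.round(E[0], 2)}")
print(
    "\nThe rank table shows consensus stability (cophenetic, silhouette)"
    "\nagainst the row-permuted baseline; the chosen rank is the largest"
    "\nstable one.  Refit proportions below 15% are reported as unassigned."
)
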