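"""Library screening: admissibility filtering and probability binning.

Filters a tiny mixed library (organometallic, overlapping and heavy
structures are excluded), then bins mock predicted probabilities into ten
0.1-wide risk intervals.
"""

import numpy as np

import carcstack as cs
from carcstack.screening import inchikey

library = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("ferrocene-ish", "[Fe+2].c1cc[cH-]c1.c1cc[cH-]c1"),
    ("already-modeled", "CCO"),
    ("waxy-giant", "C" * 80),
    ("aniline", "Nc1ccccc1"),
]
modeled_keys = [inchikey("CCO")]

kept, log = cs.filter_library(library, training_inchikeys=modeled_keys)
print("admissible:", [cid for cid, _ in kept])
for e in log:
    print(f"  excluded {e.compound_id}: {e.reason}")

probs = np.array([0.12, 0.93])  # mock model output for the two survivors
report = cs.bin_probabilities(probs, exclusions=log)
print("bin counts:", report.bin_counts)
print(f"risk (>=0.5): {report.n_risk}, high concern (>=0.9): {report.n_high_concern}")
# Each screened compound lands in exactly one 0.1-wide probability interval;
# the two tallies are the screening headline numbers.
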