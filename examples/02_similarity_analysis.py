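"""Within-class Tanimoto similarity — how well a representation clusters
each class.

Uses the fixture structures: per class, every unordered compound pair is
scored with the bit-count Tanimoto and summarized as mean +/- sd.
"""

import carcstack as cs

rows = cs.make_fixture_smiles()
ids, smiles, labels = zip(*rows)
maccs = cs.compute_maccs(smiles, ids)

for cls, name in ((1, "class 1"), (0, "class 0")):
    s = cs.within_class_similarity(maccs, labels, cls)
    print(f"{name}: {s.n_pairs} pairs, Tanimoto {s.mean:.3f} +/- {s.sd:.3f}")
# Higher within-class means indicate the representation pulls same-class
# compounds together — a prerequisite for a fingerprint-based classifier.
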