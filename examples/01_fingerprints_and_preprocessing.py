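"""MACCS fingerprints and the two-step descriptor preprocessing.

Computes 166-key fingerprints for a built-in fixture set, then removes
zero-variance keys and keys correlated above 0.9 with an earlier key.
"""

import carcstack as cs

rows = cs.make_fixture_smiles()
ids, smiles, _ = zip(*rows)

maccs = cs.compute_maccs(smiles, ids)
print(f"MACCS matrix: {maccs.n_compounds} compounds x {maccs.n_features} keys")

pre = cs.preprocess(maccs)
n_zero = len(pre.metadata["dropped_zero_variance"])
n_corr = len(pre.metadata["dropped_correlated"])
print(f"retained {pre.n_features} keys "
      f"({n_zero} zero-variance, {n_corr} correlated dropped)")
# Keys never set (or always set) across the library carry no information;
# near-duplicate keys would double-count the same substructure signal.
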