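"""Score alignment accuracy against a known reference alignment.

A simulated homologous pair comes with its true alignment (known from the
simulation's edit history).  The developer score f_D is the fraction of the
reference's aligned residue pairs that the test alignment reproduces; the
modeler score f_M is the fraction of the test's pairs present in the
reference; Q is their mean, in percent.
"""

import numpy as np

import propalign as pa

config = pa.SimulationConfig(ancestor_length=80, substitution_rate=0.4, seed=42)
pair = pa.generate_pair(config, np.random.default_rng(config.seed))
print(f"simulated pair at {pair.reference.percent_identity():.1f}% identity "
      f"(bin {pair.identity_bin})")

props = pa.load_example_properties()
test = pa.align_property(pair.x, pair.y, props, pa.GapParams(0.7, 0.1))

n_i = pa.identically_aligned_pairs(test, pair.reference)
q = pa.q_score(test, pair.reference)
print(f"reference aligned pairs: {pair.reference.n_aligned_pairs}")
print(f"test aligned pairs:      {test.n_aligned_pairs}")
print(f"identically aligned:     {n_i}")
print(f"accuracy Q = {q:.2f}%  (100 = the test reproduces the reference exactly)")
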