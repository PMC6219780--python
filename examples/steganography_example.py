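"""Hide the four secret interception offsets inside a DNA carrier.

The offsets select which 16-mers of the reference strand become the
pyramid's secret segments.  They are binary-encoded, mapped to bases
under the secret code table, and framed between the primer q and its
reverse complement among random redundancy — then published in a pool
of decoys.
"""

import numpy as np

from dnapad import extract_offsets, get_code_table, hide_offsets
from dnapad.assembly import OffsetSet
from dnapad.sequence import random_dna

offsets = OffsetSet(p_id="ref_0003", L=1000, r=(412, 87, 903, 256))
table = get_code_table(5)
carrier = hide_offsets(offsets, table, q="GCATG", seed=3)
print("carrier:", carrier.full)

rng = np.random.default_rng(0)
pool = [random_dna(58, rng) for _ in range(4)] + [carrier.full]
recovered = extract_offsets(pool, table, q="GCATG", L=1000)
print("pool size:", len(pool), "-> recovered offsets:", recovered.r)
print("-> only the primer + code table locate and decode the four offsets")
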