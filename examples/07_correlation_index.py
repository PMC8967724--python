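"""Quantify how tightly two cell characteristics are linked.

The correlation index (1 - C) / ((v1 + 1)(v2 + 1)) scores a bipartite map
of observed connections: 1 for a one-to-one pattern (minimum connections,
even degrees), 0 for all-to-all (every variable connected to every other).
"""

import itertools

from vagalseq import ConnectionMap, correlation_index

one_to_one = ConnectionMap(
    ("ME", "pIMA", "IGLE"), ("mucosa", "muscle_p", "muscle_i"),
    {("ME", "mucosa"), ("pIMA", "muscle_p"), ("IGLE", "muscle_i")},
)
print(f"ending type vs tissue layer (one-to-one): {correlation_index(one_to_one):.2f}")

organs = ("lung", "stomach", "duodenum")
types = ("ME", "pIMA", "cIMA", "IGLE")
all_to_all = ConnectionMap(organs, types, set(itertools.product(organs, types)))
print(f"organ vs ending type (all-to-all):        {correlation_index(all_to_all):.2f}")

partial = ConnectionMap(
    ("sustained", "transient"), ("C", "A"),
    {("sustained", "C"), ("sustained", "A"), ("transient", "A")},
)
print(f"response vs subpopulation (partial):      {correlation_index(partial):.2f}")
# 1 means the two characteristics code the same information; 0 means they
# form independent coding dimensions.
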