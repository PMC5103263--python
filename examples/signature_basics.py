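"""Per-vertex directed-graphlet signatures on three tiny networks.

Each vertex gets a 16-dimensional count vector: out-/in-/reciprocal degree,
6 wedge classes (counted at the wedge's centre) and 7 triangle classes
(counted at every incident vertex).
"""

from digraphlets import DirectedNetwork, signature_matrix

examples = {
    "path a->b->c": [("a", "b"), ("b", "c")],
    "directed 3-cycle": [("a", "b"), ("b", "c"), ("c", "a")],
    "reciprocal triangle": [
        ("a", "b"), ("b", "a"), ("b", "c"), ("c", "b"), ("a", "c"), ("c", "a")
    ],
}

for name, pairs in examples.items():
    g = DirectedNetwork.from_arcs_labelled(pairs)
    s = signature_matrix(g)
    print(f"\n{name}:")
    print(s.loc[:, (s != 0).any()])  # only the nonzero columns

print(
    "\nReading: on the path, b is the centre of one mixed-direction wedge "
    "(W_path); the 3-cycle puts one T_cycle triangle on every vertex; the "
    "reciprocal triangle gives every vertex two reciprocal neighbours and "
    "one all-reciprocal triangle (T_rec)."
)
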