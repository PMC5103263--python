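"""Direction-randomisation null: what survives when directions are destroyed.

Reassigning every connected pair to out/in/reciprocal with probability 1/3
each keeps the undirected skeleton but erases direction information; the
blockwise-normalised signatures then converge to fixed analytic targets
((1,1,1)/3, (1,1,2,2,2,1)/9, (6,2,3,3,6,6,1)/27) derived by enumerating the
equiprobable orientation assignments.
"""

from digraphlets import GeneratorConfig, convergence_check, random_digraph

g = random_digraph(GeneratorConfig(seed=7, n=60, p_arc=0.15, p_rec=0.5))
table = convergence_check(g, reps=500, seed=1)
print(table.round(4))
print(
    "\nReading: 'expected' is the analytic target, 'mean' the Monte-Carlo "
    "ensemble average over 500 flips, and z their distance in standard "
    "errors - all coordinates should sit within a few SE of the target, "
    "showing the original direction structure is fully destroyed."
)
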