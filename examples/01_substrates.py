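"""Inspect the standard assay substrates and their N-coordinate maps.

Prints, for each primer/template combination, the primer length n0, the
number of extendable positions K and the lesion or nick position. The
N-coordinate map of the 14-mer/thymine-glycol substrate shows which
template base is copied at each insertion step and which dNTP that step
requires: the lesion sits at N3 (template base 17 from the 3' end).
"""

import tlsquant as tq

substrates = tq.standard_substrates()
print(f"{'name':<12} {'n0':>3} {'K':>3} {'lesion_N':>9} {'nick_N':>7}")
for name, sub in substrates.items():
    print(f"{name:<12} {sub.n0:>3} {sub.k:>3} "
          f"{str(sub.lesion_n or '-'):>9} {str(sub.nick_n or '-'):>7}")

print("\nN-coordinate map of 14/Tg (product length = 14 + N):")
for entry in tq.position_map(substrates["14/Tg"]):
    mark = "  <- lesion" if entry.lesion is not tq.LesionKind.NONE else ""
    print(f"  N{entry.n:<3} template {entry.display_base:<2} needs {entry.dntp}{mark}")
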