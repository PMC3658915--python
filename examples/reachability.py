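"""Locate the active vertices reachable from a set of seed metabolites.

Seeding with {A} activates everything: R2 fires (A present), producing E;
R3 fires, producing B; with A and B present R1 fires forward, producing C;
and with C present the reverse of R1 fires too.  Seeding with {B} activates
nothing — no reaction direction has all its substrates available.
"""

from metnet import generate_fixture_model, locate_active_vertices

model = generate_fixture_model("diamond")

for seeds in ({"A"}, {"B"}):
    result = locate_active_vertices(model, seeds)
    print(f"seeds {sorted(seeds)}:")
    print("  active metabolites:", sorted(result.active_metabolites))
    print("  active reaction directions:", sorted(result.active_reactions))
    for iteration, added in result.trace:
        print(f"  iteration {iteration}: added {added}")
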