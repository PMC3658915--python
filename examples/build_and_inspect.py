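"""Build the three network representations of a small model and inspect them.

The model is the built-in "diamond" fixture: R1: A + B <=> C (reversible),
R2: A -> E, R3: E -> B.
"""

from metnet import build_network, degree_report, ego_subgraph, generate_fixture_model

model = generate_fixture_model("diamond")
print(f"model: {model.id}, {len(model.reactions)} reactions, "
      f"{len(model.metabolites)} metabolites")

for representation in ("RC", "CC", "RR"):
    net = build_network(model, representation)
    print(f"{representation}: {net.n_vertices} vertices, {net.n_edges} edges")

# The RC (reaction-compound) graph is bipartite; the reversible R1
# contributes two labeled edge sets, so it alone accounts for 6 of the
# 10 edges and is the highest-degree vertex.
rc = build_network(model, "RC")
report = degree_report(rc)
print(report.rows.to_string(index=False))
print("degree distribution:", report.distribution)

# A radius-1 ego subgraph around metabolite E: just its producing and
# consuming reactions.
sub = ego_subgraph(rc, "E", radius=1)
print("ego(E, r=1) vertices:", sub.vertices())
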