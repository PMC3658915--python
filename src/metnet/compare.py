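"""Network comparison and variation networks.

Comparing a mutant's flux-carrying snapshot with the wild-type's answers the
question *where did the flux go*: a single knockout typically reshuffles
dozens of reactions, and the differences are far easier to read as a small
"variation network" than as a genome-scale flux table.  Two selection
criteria are supported, separately or combined:

exclusivity
    reactions present in exactly one of the two snapshots;
flux variation
    reactions present in both whose flux difference exceeds a threshold
    (an absolute value, or a percentage of the reference flux).

Each selected reaction is lifted out of the *base* network together with its
metabolite neighbors and connecting edges, and every vertex is tagged with
the reason it was included plus the per-condition fluxes, so downstream
viewers (e.g. Cytoscape via XGMML) can color vertices by what changed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import UsageError, ValidationError
from .network import METABOLITE, REACTION, MetabolicNetwork
from .simulation import FluxDistribution

__all__ = [
    "ComparisonReport",
    "compare_networks",
    "build_variation_network",
    "EXCLUSIVE_A", "EXCLUSIVE_B", "FLUX_CHANGE", "PARTICIPANT",
]

EXCLUSIVE_A = "exclusive_a"
EXCLUSIVE_B = "exclusive_b"
FLUX_CHANGE = "flux_change"
PARTICIPANT = "participant"


@dataclass
class ComparisonReport:
    """Metric-by-metric comparison of two networks.

    Only metrics computed on *both* networks are compared (recomputing on
    demand would be wasteful on genome-scale inputs, so callers pass the
    values they already have).  ``vertex_table`` columns: metric, id,
    vtype, value_a, value_b, delta, presence (both/only_a/only_b);
    ``global_table`` columns: metric, value_a, value_b.  Vertices are
    matched on (id, vtype) — two networks derived from the same model share
    that id space, networks from different models may not (a provenance
    mismatch is flagged in ``provenance_warning``).
    """

    metrics_compared: list[str]
    vertex_table: pd.DataFrame
    global_table: pd.DataFrame
    provenance_warning: str | None = None


def _presence_rows(a: MetabolicNetwork, b: MetabolicNetwork):
    keys_a = {(v, a.vertex_type(v)) for v in a.vertices()}
    keys_b = {(v, b.vertex_type(v)) for v in b.vertices()}
    presence = {}
    for key in keys_a | keys_b:
        presence[key] = (
            "both" if key in keys_a and key in keys_b
            else ("only_a" if key in keys_a else "only_b")
        )
    return presence


def compare_networks(
    a: MetabolicNetwork,
    b: MetabolicNetwork,
    metrics_a: dict[str, dict[str, float] | float] | None = None,
    metrics_b: dict[str, dict[str, float] | float] | None = None,
) -> ComparisonReport:
    """Compare two networks on the metrics available for both.

    `metrics_a` / `metrics_b` map a metric name either to per-vertex scores
    (dict id -> value) or to a single global value (e.g. a diameter).  The
    intersection of the two name sets is compared; per-vertex metrics get
    one row per vertex present in either network, global metrics one row
    each.  An empty intersection is not an error — the report simply has no
    metric rows (vertex presence is still reported).
    """
    metrics_a = metrics_a or {}
    metrics_b = metrics_b or {}
    warning = None
    if a.provenance != b.provenance:
        warning = (
            f"provenance differs ({a.provenance!r} vs {b.provenance!r}); "
            "vertex identity assumes networks derive from the same model"
        )
    shared = sorted(set(metrics_a) & set(metrics_b))
    presence = _presence_rows(a, b)

    vertex_rows = []
    global_rows = []
    per_vertex_metrics = []
    for name in shared:
        va, vb = metrics_a[name], metrics_b[name]
        if isinstance(va, dict) != isinstance(vb, dict):
            raise UsageError(
                f"metric {name!r} is per-vertex on one network and global on the other"
            )
        if not isinstance(va, dict):
            global_rows.append({"metric": name, "value_a": va, "value_b": vb})
            continue
        per_vertex_metrics.append(name)
        for (vid, vtype), where in sorted(presence.items()):
            x = va.get(vid) if where != "only_b" else None
            y = vb.get(vid) if where != "only_a" else None
            vertex_rows.append(
                {
                    "metric": name,
                    "id": vid,
                    "vtype": vtype,
                    "value_a": x,
                    "value_b": y,
                    "delta": (y - x) if x is not None and y is not None else None,
                    "presence": where,
                }
            )
    if not shared:
        # still expose the structural diff
        for (vid, vtype), where in sorted(presence.items()):
            vertex_rows.append(
                {
                    "metric": None, "id": vid, "vtype": vtype,
                    "value_a": None, "value_b": None, "delta": None,
                    "presence": where,
                }
            )
    return ComparisonReport(
        metrics_compared=shared,
        vertex_table=pd.DataFrame(
            vertex_rows,
            columns=["metric", "id", "vtype", "value_a", "value_b", "delta",
                     "presence"],
        ),
        global_table=pd.DataFrame(
            global_rows, columns=["metric", "value_a", "value_b"]
        ),
        provenance_warning=warning,
    )


def _exceeds(
    delta: float, flux_a: float, flux_b: float,
    threshold: float, percentage: bool, pct_base: str,
) -> bool:
    if not percentage:
        return abs(delta) > threshold
    if pct_base == "max":
        base = max(abs(flux_a), abs(flux_b))
    else:
        base = abs(flux_a)
    if base == 0:
        # a percentage of zero flux is meaningless; any change exceeds it
        return abs(delta) > 0
    return abs(delta) > threshold * base / 100.0


def build_variation_network(
    base: MetabolicNetwork,
    net_a: MetabolicNetwork,
    net_b: MetabolicNetwork,
    fluxes_a: FluxDistribution,
    fluxes_b: FluxDistribution,
    *,
    use_exclusivity: bool = True,
    flux_threshold: float | None = None,
    percentage: bool = False,
    pct_base: str = "reference",
) -> MetabolicNetwork:
    """Build the variation network between two snapshot networks.

    Parameters
    ----------
    base : MetabolicNetwork (RC)
        The unfiltered network both snapshots derive from; supplies the
        metabolite neighborhoods and edges of selected reactions.
    net_a, net_b : MetabolicNetwork (RC)
        Snapshot networks (see
        :func:`metnet.simulation.filter_network_by_simulation`) for the two
        conditions, e.g. wild-type and mutant.
    fluxes_a, fluxes_b : FluxDistribution
        The flux distributions behind the snapshots (missing ids count 0).
    use_exclusivity : bool
        Select reactions present in exactly one snapshot.
    flux_threshold : float, optional
        Enables the flux-variation criterion on reactions present in BOTH
        snapshots: selected when |flux_b - flux_a| strictly exceeds the
        threshold.  With `percentage` the threshold is a percent of the
        reference condition's |flux_a| (or of max(|flux_a|, |flux_b|) when
        ``pct_base="max"``); a zero base falls back to "any change".
    """
    if base.representation != "RC":
        raise UsageError("variation networks are built over RC networks")
    if not use_exclusivity and flux_threshold is None:
        raise UsageError("enable exclusivity and/or give a flux threshold")
    if pct_base not in ("reference", "max"):
        raise UsageError(f"unknown pct_base {pct_base!r}")

    rxns_a = set(net_a.vertices(REACTION))
    rxns_b = set(net_b.vertices(REACTION))
    unknown = sorted((rxns_a | rxns_b) - set(base.vertices(REACTION)))
    if unknown:
        raise ValidationError(
            "snapshot reactions absent from base network: " + ", ".join(unknown)
        )

    selected: dict[str, str] = {}
    if use_exclusivity:
        for rid in rxns_a - rxns_b:
            selected[rid] = EXCLUSIVE_A
        for rid in rxns_b - rxns_a:
            selected[rid] = EXCLUSIVE_B
    if flux_threshold is not None:
        for rid in rxns_a & rxns_b:
            fa, fb = fluxes_a.get(rid), fluxes_b.get(rid)
            if _exceeds(fb - fa, fa, fb, flux_threshold, percentage, pct_base):
                selected.setdefault(rid, FLUX_CHANGE)

    out = MetabolicNetwork(
        "RC",
        provenance=(
            f"variation:{fluxes_a.label}|{fluxes_b.label};"
            f"exclusivity={use_exclusivity},threshold={flux_threshold!r}"
            + (",percentage" if percentage else "")
        ),
    )
    for rid in sorted(selected):
        fa, fb = fluxes_a.get(rid), fluxes_b.get(rid)
        meta = dict(base.vertex_metadata(rid))
        meta.update(
            tna_reason=selected[rid],
            tna_flux_a=fa, tna_flux_b=fb, tna_delta=fb - fa,
        )
        out.add_vertex(rid, REACTION, meta)
    for rid in sorted(selected):
        partners = set(base.graph.predecessors(rid)) | set(base.graph.successors(rid))
        for mid in sorted(partners):
            if not out.has_vertex(mid):
                meta = dict(base.vertex_metadata(mid))
                meta["tna_reason"] = PARTICIPANT
                out.add_vertex(mid, METABOLITE, meta)
        for u, v, d in base.graph.in_edges(rid, data=True):
            out.add_edge(u, v, d.get("set_label"), d.get("metadata"))
        for u, v, d in base.graph.out_edges(rid, data=True):
            out.add_edge(u, v, d.get("set_label"), d.get("metadata"))
    return out
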