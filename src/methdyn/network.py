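"""Methylation-driven regulatory network construction.

Per developmental transition, TF -> target-gene edges are inferred by
combining four independent lines of evidence: (i) motif enrichment in the
hyper- and hypo-DMR sets (raw p < 0.01 by default), (ii) an actual scan hit
of the enriched motif inside the supporting DMR, (iii) an interaction-map
assignment of the DMR to the gene, and (iv) expression anti-correlation —
a methylation gain (hyper-DMR) must pair with a down-regulated gene and a
loss (hypo-DMR) with an up-regulated one, with the TF itself expressed
(RPKM > 1) at the transition's time points.

Expression tables are plain DataFrames with a ``gene`` column, per-time-
point ``rpkm_<tp>`` columns, and per-transition ``log2fc_<transition>`` /
``padj_<transition>`` columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .dmr import DMRCall
from .motifs import EnrichmentResult
from .targets import TargetAssignment

__all__ = [
    "RegulatoryEdge",
    "anticorrelated_dmr_genes",
    "build_network",
    "ego_network",
    "edges_to_frame",
    "write_graphml",
    "write_sif",
]


@dataclass(frozen=True)
class RegulatoryEdge:
    tf: str
    gene: str
    transition: str  # "DevTrans" | "MatTrans"
    dmr_id: str
    dmr_direction: str  # "hyper" | "hypo"
    evidence: str  # "known" | "predicted"


def _dmr_id(dmr: DMRCall) -> str:
    return f"{dmr.interval.chrom}:{dmr.interval.start}-{dmr.interval.end}"


def anticorrelated_dmr_genes(
    dmrs: Sequence[DMRCall],
    locations: pd.DataFrame,
    assignments: Mapping[int, Sequence[TargetAssignment]],
    expression: pd.DataFrame,
    transition: str,
) -> pd.DataFrame:
    """DMR-gene pairs whose expression change opposes the methylation change.

    Only DMRs at promoters or distal to any TSS (> 5 kb; ``locations`` is
    the ``classify_location`` output aligned with ``dmrs``) are considered.
    A pair is kept when sign(log2fc) == -sign(delta).  Genes without an
    expression record are dropped with a warning.  The result feeds a
    delta-vs-log2fc scatter in which only the anti-correlated quadrants are
    populated.
    """
    fc_col = f"log2fc_{transition}"
    if fc_col not in expression.columns:
        raise ValueError(f"expression table lacks column {fc_col!r}")
    fc = dict(zip(expression["gene"], expression[fc_col]))
    rows = []
    for i, dmr in enumerate(dmrs):
        band = locations["band"].iat[i]
        if band not in ("promoter", "distal"):
            continue
        for a in assignments.get(i, []):
            if a.gene not in fc:
                warnings.warn(f"no expression record for gene {a.gene!r}; pair dropped")
                continue
            lfc = float(fc[a.gene])
            if lfc == 0 or (lfc > 0) == (dmr.delta > 0):
                continue
            rows.append(
                {
                    "dmr_id": _dmr_id(dmr),
                    "gene": a.gene,
                    "delta": dmr.delta,
                    "log2fc": lfc,
                    "direction": dmr.direction,
                    "band": band,
                }
            )
    return pd.DataFrame(
        rows, columns=["dmr_id", "gene", "delta", "log2fc", "direction", "band"]
    )


def build_network(
    dmrs: Sequence[DMRCall],
    enrichment_by_direction: Mapping[str, Sequence[EnrichmentResult]],
    dmr_motif_hits: Mapping[int, set[str]],
    assignments: Mapping[int, Sequence[TargetAssignment]],
    expression: pd.DataFrame | None,
    transition: str,
    transition_timepoints: Sequence[str],
    tf_of_motif: Mapping[str, str] | None = None,
    enrich_alpha: float = 0.01,
    deg_alpha: float = 0.05,
    rpkm_min: float = 1.0,
    require_hit: bool = True,
) -> list[RegulatoryEdge]:
    """Emit TF -> gene edges supported by all four evidence gates.

    ``enrichment_by_direction`` maps "hyper"/"hypo" to the enrichment
    results computed on that DMR set; ``dmr_motif_hits`` maps DMR index to
    the motif names with a scan hit inside the region (required unless
    ``require_hit`` is False, which falls back to set-level enrichment
    only); ``assignments`` maps DMR index to its target assignments.  With
    no expression table no edge can pass the gates and an empty list is
    returned.  Edges are deduplicated on (tf, gene, transition), keeping
    the strongest interaction evidence.
    """
    if expression is None or len(expression) == 0:
        return []
    tf_of = tf_of_motif or {}
    fc_col = f"log2fc_{transition}"
    padj_col = f"padj_{transition}"
    fc = dict(zip(expression["gene"], expression[fc_col]))
    padj = (
        dict(zip(expression["gene"], expression[padj_col]))
        if padj_col in expression.columns
        else {}
    )
    rpkm_cols = [
        f"rpkm_{tp}" for tp in transition_timepoints if f"rpkm_{tp}" in expression.columns
    ]
    rpkm = {
        row.gene: min(getattr(row, c) for c in rpkm_cols) if rpkm_cols else 0.0
        for row in expression.itertuples(index=False)
    }

    enriched: dict[str, set[str]] = {
        direction: {r.motif for r in results if r.p_value < enrich_alpha}
        for direction, results in enrichment_by_direction.items()
    }

    best: dict[tuple[str, str], RegulatoryEdge] = {}
    order = {"known": 0, "predicted": 1}
    for i, dmr in enumerate(dmrs):
        motifs_here = enriched.get(dmr.direction, set())
        if require_hit:
            motifs_here = motifs_here & dmr_motif_hits.get(i, set())
        for motif_name in sorted(motifs_here):
            tf = tf_of.get(motif_name, motif_name)
            if rpkm.get(tf, 0.0) <= rpkm_min:
                continue
            for a in assignments.get(i, []):
                lfc = fc.get(a.gene)
                if lfc is None or lfc == 0:
                    continue
                if (lfc > 0) == (dmr.delta > 0):
                    continue  # correlated quadrant: gate fails
                q = padj.get(a.gene)
                if q is not None and not pd.isna(q) and q >= deg_alpha:
                    continue
                edge = RegulatoryEdge(
                    tf, a.gene, transition, _dmr_id(dmr), dmr.direction, a.evidence
                )
                key = (tf, a.gene)
                prev = best.get(key)
                if prev is None or order[a.evidence] < order[prev.evidence]:
                    best[key] = edge
    return [best[k] for k in sorted(best)]


def to_graph(edges: Sequence[RegulatoryEdge]) -> nx.DiGraph:
    g = nx.DiGraph()
    for e in edges:
        g.add_edge(
            e.tf,
            e.gene,
            transition=e.transition,
            dmr_id=e.dmr_id,
            direction=e.dmr_direction,
            evidence=e.evidence,
            interaction_type=e.transition,
        )
    return g


def ego_network(
    edges: Sequence[RegulatoryEdge], center_tf: str, radius: int = 1
) -> nx.DiGraph:
    """Subnetwork within ``radius`` undirected steps of a centre factor.

    Edges touching the centre are flagged ``direct=True`` (the bold edges of
    a centred network rendering).  Requesting an absent centre raises with
    the list of available node names.
    """
    g = to_graph(edges)
    if center_tf not in g:
        available = ", ".join(sorted(g.nodes)) or "(none)"
        raise ValueError(f"{center_tf!r} not in network; available: {available}")
    nodes = nx.ego_graph(g.to_undirected(as_view=True), center_tf, radius=radius).nodes
    sub = g.subgraph(nodes).copy()
    for u, v in sub.edges:
        sub.edges[u, v]["direct"] = center_tf in (u, v)
    return sub


def edges_to_frame(edges: Sequence[RegulatoryEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [e.__dict__ for e in edges],
        columns=["tf", "gene", "transition", "dmr_id", "dmr_direction", "evidence"],
    )


def write_graphml(edges: Sequence[RegulatoryEdge], path: str | Path) -> None:
    nx.write_graphml(to_graph(edges), str(path))


def write_sif(edges: Sequence[RegulatoryEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.tf}\tregulates_{e.transition}\t{e.gene}\n")
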