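"""Per-residue feature-table assembly.

Combines the contact-graph centrality percentiles, the Cα-to-GCM
distance, relative solvent accessibility and the conservation profile
into one table with a fixed column layout (`FEATURE_TABLE_HEADER`).
"""

from __future__ import annotations

import io
import logging

import numpy as np
import pandas as pd

from . import conservation as cons
from . import geometry, graph
from .net import FEATURE_TABLE_HEADER
from .structure import ProteinChain

logger = logging.getLogger(__name__)


def compute_feature_table(
    chain: ProteinChain,
    conservation_scores: np.ndarray | None,
    structure_id: str = "",
    contact_cutoff: float = graph.DEFAULT_CONTACT_CUTOFF,
    probe_radius: float = geometry.DEFAULT_PROBE_RADIUS,
    sphere_points: int = geometry.DEFAULT_SPHERE_POINTS,
    pagerank_damping: float = 0.85,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per residue that has both a Cα and a conservation score.

    *conservation_scores* maps 1:1 onto chain residues (NaN where unknown);
    pass None to leave the column NaN (structure-only analyses).  Residues
    lacking a Cα are excluded from the table with a warning — the distance
    feature is undefined for them — but they still contribute to the GCM,
    the contact graph and the SASA occlusion environment.
    """
    n = len(chain)
    g = graph.build_contact_graph(chain, contact_cutoff)
    if n >= 2:
        closeness = graph.rank_percentile(graph.closeness_centrality(g))
        between = graph.rank_percentile(graph.betweenness_centrality(g))
        pagerank = graph.rank_percentile(graph.pagerank_centrality(g, pagerank_damping))
    else:
        closeness = between = pagerank = np.ones(n)
    gcm = geometry.general_center_of_mass(chain)
    distance = geometry.distance_to_gcm(chain, gcm)
    areas = geometry.solvent_accessible_area(chain, probe_radius, sphere_points)
    rsa = np.array(
        [r.relative for r in geometry.relative_accessibility(areas, chain.sequence)]
    )
    if conservation_scores is None:
        conservation_scores = np.full(n, np.nan)
    conservation_scores = np.asarray(conservation_scores, dtype=float)
    if conservation_scores.shape != (n,):
        raise ValueError("conservation scores must align 1:1 with chain residues")
    if labels is not None:
        labels = np.asarray(labels, dtype=float)
        if labels.shape != (n,):
            raise ValueError("labels must align 1:1 with chain residues")

    rows = []
    for i, res in enumerate(chain.residues):
        if not res.has_ca:
            logger.warning(
                "residue %s excluded from the feature table (no Cα)", res.label
            )
            continue
        rows.append(
            {
                "structure_id": structure_id or chain.source_id,
                "resnum": res.number,
                "icode": res.icode or "",
                "aa": res.aa,
                "conserv": conservation_scores[i],
                "distance": distance[i],
                "closeness": closeness[i],
                "between": between[i],
                "pagerank": pagerank[i],
                "rsa": rsa[i],
                "function": labels[i] if labels is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_TABLE_HEADER)


def map_conservation_to_chain(
    chain_sequence: str, aln: cons.Alignment, background="uniform",
    min_identity: float = 0.95,
) -> np.ndarray:
    """Per-chain-residue conservation scores via the MSA query.

    The MSA's ungapped query must match the ATOM-derived chain sequence at
    ≥ *min_identity* over aligned positions; positions are mapped through a
    global pairwise alignment, so chains with unresolved residues still
    line up.  Unmapped residues get NaN.
    """
    profile = cons.conservation_profile(aln, background)
    query = aln.query_sequence
    n = len(chain_sequence)
    if query == chain_sequence:
        return profile.scores.copy()
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-1,
        open_gap_score=-5,
        extend_gap_score=-0.5,
    )
    alignment = aligner.align(chain_sequence, query)[0]
    pairs = [
        (i, j)
        for (cs, ce), (qs, qe) in zip(*alignment.aligned)
        for i, j in zip(range(cs, ce), range(qs, qe))
    ]
    matches = sum(1 for i, j in pairs if chain_sequence[i] == query[j])
    identity = matches / len(pairs) if pairs else 0.0
    if identity < min_identity:
        mism = [i + 1 for i, j in pairs if chain_sequence[i] != query[j]]
        raise ValueError(
            f"MSA query does not match the chain sequence "
            f"(identity {identity:.2f} < {min_identity}); "
            f"mismatched chain positions: {mism[:20]}"
        )
    out = np.full(n, np.nan)
    for i, j in pairs:
        out[i] = profile.scores[j]
    return out


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Tab-separated serialization with the fixed header."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_feature_table(path_or_text) -> pd.DataFrame:
    if isinstance(path_or_text, str) and "\t" in path_or_text:
        handle = io.StringIO(path_or_text)
    else:
        handle = path_or_text
    table = pd.read_csv(handle, sep="\t", na_values=["NA"], keep_default_na=True)
    missing = [c for c in FEATURE_TABLE_HEADER if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    table["icode"] = table["icode"].fillna("").astype(str)
    return table
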