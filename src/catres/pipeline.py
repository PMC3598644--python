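"""End-to-end prediction: PDB chain + MSA + trained model -> ranked report.

The protocol: extract the chain, score per-column conservation from the
alignment, compute the structural features, discard residues whose
relative entropy is below the conservation threshold (3.8 in the final
protocol), run the network on the survivors and report the positive
calls ranked by network score.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import geometry, graph
from .conservation import Alignment
from .features import compute_feature_table, map_conservation_to_chain
from .geometry import RSA_REFERENCE_NAME
from .net import NetworkModel, predict_scores
from .structure import parse_pdb_chain


@dataclass
class PipelineConfig:
    """Every knob of the prediction protocol; serialized with each report."""

    contact_cutoff: float = graph.DEFAULT_CONTACT_CUTOFF
    conservation_threshold: float = 3.8
    background: str = "uniform"
    probe_radius: float = geometry.DEFAULT_PROBE_RADIUS
    sphere_points: int = geometry.DEFAULT_SPHERE_POINTS
    decision_threshold: float = 0.5
    min_query_identity: float = 0.95
    seed: int = 0
    rsa_reference: str = field(default=RSA_REFERENCE_NAME)

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0 or self.probe_radius <= 0:
            raise ValueError("distance parameters must be positive")
        if self.conservation_threshold < 0:
            raise ValueError("conservation threshold must be non-negative")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision threshold must lie in (0, 1)")

    def to_text(self) -> str:
        return "".join(f"{k} {v}\n" for k, v in asdict(self).items())

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, value = line.split(None, 1)
            if key not in fields:
                raise ValueError(f"unknown config key: {key}")
            typ = {"float": float, "int": int, "str": str}[fields[key]]
            kwargs[key] = typ(value)
        return cls(**kwargs)


@dataclass
class PredictionReport:
    """Ranked positive calls plus the accounting summary and config."""

    table: pd.DataFrame  # one row per reported residue, sorted by score desc
    summary: dict
    config: PipelineConfig

    def to_tsv(self) -> str:
        buf = io.StringIO()
        for k, v in self.summary.items():
            buf.write(f"# {k}\t{v}\n")
        for line in self.config.to_text().splitlines():
            buf.write(f"# config.{line.replace(' ', chr(9), 1)}\n")
        self.table.to_csv(buf, sep="\t", index=False, float_format="%.6g")
        return buf.getvalue()


def predict_catalytic_residues(
    pdb_text: str,
    chain_id: str,
    msa_text: str,
    model: NetworkModel,
    cfg: PipelineConfig | None = None,
    include_filtered: bool = False,
) -> PredictionReport:
    """Run the full protocol on one chain.

    The MSA query must match the ATOM-derived chain sequence at
    ``cfg.min_query_identity`` or better; residue numbering in the report
    uses author numbers plus insertion codes.  With *include_filtered*
    the report also lists the residues removed by the prefilter or called
    negative, flagged in the ``status`` column.
    """
    cfg = cfg or PipelineConfig()
    chain = parse_pdb_chain(pdb_text, chain_id)
    aln = Alignment.from_fasta(msa_text)
    conserv = map_conservation_to_chain(
        chain.sequence, aln, cfg.background, cfg.min_query_identity
    )
    table = compute_feature_table(
        chain,
        conserv,
        structure_id=chain.source_id,
        contact_cutoff=cfg.contact_cutoff,
        probe_radius=cfg.probe_radius,
        sphere_points=cfg.sphere_points,
    )
    table = table.drop(columns=["function"])
    known = table["conserv"].notna().to_numpy()
    survivor_mask = known & (table["conserv"].to_numpy() >= cfg.conservation_threshold)
    scores = np.full(len(table), np.nan)
    if survivor_mask.any():
        scores[survivor_mask] = predict_scores(model, table[survivor_mask])
    table = table.assign(score=scores)
    predicted_mask = survivor_mask & (scores >= cfg.decision_threshold)
    status = np.where(
        predicted_mask, "predicted", np.where(survivor_mask, "rejected", "prefiltered")
    )
    table = table.assign(status=status)

    n_input = len(chain)
    n_survivors = int(survivor_mask.sum())
    summary = {
        "structure": chain.source_id,
        "chain": chain_id,
        "input_residues": n_input,
        "prefilter_survivors": n_survivors,
        "prefiltered_out": n_input - n_survivors,
        "predicted_catalytic": int(predicted_mask.sum()),
    }
    keep = table if include_filtered else table[predicted_mask]
    keep = keep.sort_values(
        ["score", "resnum"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    residue_label = keep["resnum"].astype(str) + keep["icode"].fillna("").astype(str)
    keep = keep.assign(residue=residue_label)
    cols = [
        "residue", "aa", "conserv", "distance", "closeness", "between",
        "pagerank", "rsa", "score",
    ] + (["status"] if include_filtered else [])
    return PredictionReport(keep[cols], summary, cfg)


def read_label_list(text: str) -> set[str]:
    """Plain-text catalytic-residue list: one author residue label per line."""
    labels = set()
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if line:
            labels.add(line.split()[-1])
    return labels


def evaluate_report(report_text: str, label_text: str):
    """Confusion counts of a written report against an annotation list.

    Uses the report's own accounting line for the input-residue total, so
    prefiltered residues count as negative calls.
    """
    from .evaluation import ConfusionCounts, classification_metrics

    n_input = None
    header = []
    body = []
    for line in report_text.splitlines():
        if line.startswith("# input_residues\t"):
            n_input = int(line.split("\t")[1])
        if line.startswith("#"):
            continue
        body.append(line)
    if n_input is None:
        raise ValueError("report lacks the input_residues accounting line")
    tbl = pd.read_csv(io.StringIO("\n".join(body)), sep="\t")
    if "status" in tbl.columns:
        tbl = tbl[tbl["status"] == "predicted"]
    predicted = set(tbl["residue"].astype(str))
    truth = read_label_list(label_text)
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = n_input - tp - fp - fn
    counts = ConfusionCounts(tp, tn, fp, fn)
    return counts, classification_metrics(counts)
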