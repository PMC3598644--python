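"""Alignment filtering and relative-entropy sequence conservation.

Per-column conservation is the Kullback–Leibler divergence (log base 2)
of the column's amino-acid distribution from a background distribution.
With the default uniform background a fully conserved column scores
log2 20 ≈ 4.32, which is why the operating thresholds of the prediction
protocol (training prefilter 3.5, final prefilter 3.8) live on that scale.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

GAP_CHARS = frozenset("-.")

DEFAULT_MIN_COVERAGE = 0.75
DEFAULT_MAX_IDENTITY = 0.95

#: Uniform background: every residue type equally likely.
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)

#: Robinson & Robinson (1991) amino-acid frequencies, normalized to 1.
_RR = {
    "A": 78.05, "R": 51.29, "N": 44.87, "D": 53.64, "C": 19.25,
    "Q": 42.64, "E": 62.95, "G": 73.77, "H": 21.99, "I": 51.42,
    "L": 90.19, "K": 57.44, "M": 22.43, "F": 38.56, "P": 52.03,
    "S": 71.20, "T": 58.41, "W": 13.30, "Y": 32.16, "V": 64.41,
}
ROBINSON_BACKGROUND = np.array([_RR[a] for a in AA_ORDER])
ROBINSON_BACKGROUND = ROBINSON_BACKGROUND / ROBINSON_BACKGROUND.sum()

BACKGROUNDS: dict[str, np.ndarray] = {
    "uniform": UNIFORM_BACKGROUND,
    "robinson": ROBINSON_BACKGROUND,
}


@dataclass
class Alignment:
    """An aligned set of sequences; the query is the first row."""

    ids: list[str]
    rows: list[str]  # equal-length aligned strings, query first

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least the query row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("aligned rows must have equal length")

    @property
    def query(self) -> str:
        return self.rows[0]

    @property
    def query_sequence(self) -> str:
        """Ungapped query sequence."""
        return "".join(c for c in self.query if c not in GAP_CHARS)

    @property
    def n_hits(self) -> int:
        return len(self.rows) - 1

    @classmethod
    def from_fasta(cls, text: str) -> "Alignment":
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not records:
            raise ValueError("no sequences in FASTA input")
        return cls([r.id for r in records], [str(r.seq).upper() for r in records])

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{s}\n" for i, s in zip(self.ids, self.rows))


@dataclass
class ConservationProfile:
    """Per-query-position relative entropy and effective column depth."""

    scores: np.ndarray  # length = ungapped query length
    effective_counts: np.ndarray
    background_name: str = "uniform"

    def __len__(self) -> int:
        return len(self.scores)


def _ungapped_length(row: str) -> int:
    return sum(c not in GAP_CHARS for c in row)


def pairwise_identity(a: str, b: str) -> float:
    """Identity of two aligned rows: matches over the shorter ungapped length,
    counted on mutually aligned (both non-gap) columns."""
    matches = sum(
        1 for x, y in zip(a, b) if x not in GAP_CHARS and y not in GAP_CHARS and x == y
    )
    shorter = min(_ungapped_length(a), _ungapped_length(b))
    if shorter == 0:
        return 0.0
    return matches / shorter


def filter_alignment(
    aln: Alignment,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_identity: float = DEFAULT_MAX_IDENTITY,
) -> Alignment:
    """Coverage and redundancy filtering of alignment hits.

    Hits covering fewer than *min_coverage* of the query's non-gap positions
    are removed; the survivors are scanned greedily in input order and a hit
    is dropped if its identity to any already-retained hit exceeds
    *max_identity*.  The query row is always retained.
    """
    if not 0 < min_coverage <= 1 or not 0 < max_identity <= 1:
        raise ValueError("coverage and identity bounds must lie in (0, 1]")
    query = aln.query
    query_positions = [i for i, c in enumerate(query) if c not in GAP_CHARS]
    retained_ids = [aln.ids[0]]
    retained_rows = [query]
    kept_hits: list[str] = []
    for hid, row in zip(aln.ids[1:], aln.rows[1:]):
        covered = sum(1 for i in query_positions if row[i] not in GAP_CHARS)
        if covered < min_coverage * len(query_positions):
            continue
        if any(pairwise_identity(row, kept) > max_identity for kept in kept_hits):
            continue
        kept_hits.append(row)
        retained_ids.append(hid)
        retained_rows.append(row)
    if len(retained_rows) == 1:
        logger.warning(
            "all hits removed by filtering; conservation profile will use the query alone"
        )
    return Alignment(retained_ids, retained_rows)


def column_counts(column: str) -> np.ndarray:
    """Counts over the 20 standard letters; gaps, X and other symbols excluded."""
    counts = np.zeros(20)
    for c in column:
        idx = _AA_INDEX.get(c)
        if idx is not None:
            counts[idx] += 1
    return counts


def column_relative_entropy(counts: np.ndarray, background: np.ndarray) -> float:
    """RE = Σ_a p_a · log2(p_a / q_a), with 0·log 0 = 0; always ≥ 0."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total < 1:
        raise ValueError("column has no countable residues")
    q = np.asarray(background, dtype=float)
    # guard only against a pathological background with (near-)zero entries
    q = np.maximum(q, 1e-12)
    p = counts / total
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / q[nz])))


def conservation_profile(
    aln: Alignment,
    background: np.ndarray | str = "uniform",
) -> ConservationProfile:
    """Relative-entropy score for every ungapped query position.

    Each query position's score comes from the corresponding alignment
    column with gap and non-standard characters excluded from the counts.
    """
    if isinstance(background, str):
        bg_name, bg = background, BACKGROUNDS[background]
    else:
        bg_name, bg = "custom", np.asarray(background, dtype=float)
    cols = [i for i, c in enumerate(aln.query) if c not in GAP_CHARS]
    scores = np.empty(len(cols))
    eff = np.empty(len(cols), dtype=int)
    for k, i in enumerate(cols):
        column = "".join(row[i] for row in aln.rows)
        counts = column_counts(column)
        total = counts.sum()
        eff[k] = int(total)
        if total == 0:
            scores[k] = np.nan
            logger.warning("column %d has no countable residues", i)
        else:
            scores[k] = column_relative_entropy(counts, bg)
    return ConservationProfile(scores, eff, bg_name)


def conservation_prefilter(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of positions with score ≥ *threshold* (boundary retained)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    scores = np.asarray(scores, dtype=float)
    return np.flatnonzero(scores >= threshold)


def read_conservation_table(text: str) -> np.ndarray:
    """Adapter for a precomputed tab-separated ``position<TAB>score`` profile.

    Positions are 1-based and must form a contiguous run starting at 1.
    """
    pairs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"conservation table line {lineno}: expected position and score")
        pairs.append((int(parts[0]), float(parts[1])))
    pairs.sort()
    if [p for p, _ in pairs] != list(range(1, len(pairs) + 1)):
        raise ValueError("conservation table positions must be contiguous from 1")
    return np.array([s for _, s in pairs])
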