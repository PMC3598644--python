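"""Synthetic toy structures, alignments and catalytic annotations.

The generator emulates the statistical structure the predictor assumes:
a compact (globular) chain of Cα positions with 3.8 Å consecutive
spacing, catalytic residues planted in the inner distance quartile and
drawn from catalytic-propensity types, invariant alignment columns at
catalytic positions plus a fraction of buried "structural core" decoy
positions, and near-background variability elsewhere.  Real proteins add
secondary structure, rotamer chemistry and phylogenetic correlation that
these fixtures deliberately omit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .conservation import AA_ORDER, Alignment, conservation_profile
from .features import compute_feature_table
from .structure import Atom, ProteinChain, Residue, write_pdb_chain

CA_SPACING = 3.8  # Å between consecutive Cα atoms

#: Types over-represented among catalytic residues.
CATALYTIC_TYPES = "HDEKRCSTNY"
#: Hydrophobic types used for buried structural-core decoys.
CORE_TYPES = "AVLIFMW"

_SIDE_ELEMENTS = ("C", "C", "C", "N", "O", "S")
_ELEMENT_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


@dataclass
class FixtureSpec:
    """Parameters of one toy structure and its alignment."""

    n_residues: int = 50
    fraction_functional: float = 0.1
    seed: int = 0
    msa_depth: int = 30
    mutation_prob: float = 0.5  # per-row chance a variable column mutates
    decoy_conserved_fraction: float = 0.8  # conserved share of non-functional core
    structure_id: str = ""

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("need at least 10 residues")
        if not 0 < self.fraction_functional < 0.5:
            raise ValueError("fraction functional must lie in (0, 0.5)")
        if not self.structure_id:
            self.structure_id = f"SYN{self.seed % 100000:05d}"


@dataclass
class ToyStructure:
    chain: ProteinChain
    labels: np.ndarray  # 0/1 per residue
    conserved_positions: set[int]
    structure_id: str

    @property
    def sequence(self) -> str:
        return self.chain.sequence


def _compact_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """Cα trace: fixed 3.8 Å steps confined to a protein-density sphere."""
    radius = 3.2 * n ** (1.0 / 3.0)
    pos = np.zeros((n, 3))
    for i in range(1, n):
        prev = pos[i - 1]
        for attempt in range(20):
            d = rng.normal(size=3)
            if attempt >= 10 and np.linalg.norm(prev) > 1e-9:
                d -= 2.0 * prev / np.linalg.norm(prev)  # bias back inward
            d /= np.linalg.norm(d)
            cand = prev + CA_SPACING * d
            if np.linalg.norm(cand) <= radius:
                break
        pos[i] = cand
    return pos


def make_toy_structure(spec: FixtureSpec) -> ToyStructure:
    """Toy globular chain with planted catalytic labels.

    Catalytic residues sit in the inner quartile of Cα-to-GCM distances
    and carry catalytic-propensity types; the remaining core positions are
    hydrophobic and (mostly) conserved decoys.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    ca = _compact_walk(n, rng)

    residues: list[Residue] = []
    for i in range(n):
        atoms = [Atom("CA", "C", _ELEMENT_MASS["C"], ca[i], i)]
        # backbone-like companions
        for name, elem, dist in (("N", "N", 1.46), ("C", "C", 1.53), ("O", "O", 2.40)):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            atoms.append(Atom(name, elem, _ELEMENT_MASS[elem], ca[i] + dist * u, i))
        for k in range(rng.integers(0, 5)):
            elem = _SIDE_ELEMENTS[rng.integers(len(_SIDE_ELEMENTS))]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            atoms.append(
                Atom(
                    f"{elem}B{k + 1}", elem, _ELEMENT_MASS[elem],
                    ca[i] + rng.uniform(1.3, 2.4) * u, i,
                )
            )
        residues.append(Residue("A", i + 1, "", "A", atoms, ca[i]))
    chain = ProteinChain(residues, source_id=spec.structure_id)

    gcm = geometry.general_center_of_mass(chain)
    dist = geometry.distance_to_gcm(chain, gcm)
    core = np.argsort(dist)[: max(n // 4, 1)]
    n_func = min(int(round(spec.fraction_functional * n)), core.size)
    functional = rng.choice(core, size=n_func, replace=False)
    labels = np.zeros(n, dtype=int)
    labels[functional] = 1

    decoy_pool = [int(i) for i in core if labels[i] == 0]
    n_decoy = int(round(spec.decoy_conserved_fraction * len(decoy_pool)))
    decoys = rng.choice(decoy_pool, size=n_decoy, replace=False) if n_decoy else []

    types = np.array(list(AA_ORDER))[rng.integers(0, 20, size=n)]
    for i in functional:
        types[i] = CATALYTIC_TYPES[rng.integers(len(CATALYTIC_TYPES))]
    for i in core:
        if labels[i] == 0:
            types[i] = CORE_TYPES[rng.integers(len(CORE_TYPES))]
    for res, aa in zip(chain.residues, types):
        res.aa = aa

    conserved = set(int(i) for i in functional) | set(int(i) for i in decoys)
    return ToyStructure(chain, labels, conserved, spec.structure_id)


def make_synthetic_msa(
    sequence: str, conserved_positions: set[int], depth: int, seed: int
) -> Alignment:
    """Gapless alignment: conserved columns invariant, others mutated
    per row with probability 0.5 to uniform letters.  Query first."""
    rng = np.random.default_rng(seed)
    rows = [sequence]
    ids = ["query"]
    letters = list(AA_ORDER)
    for d in range(depth):
        row = list(sequence)
        for i in range(len(sequence)):
            if i in conserved_positions:
                continue
            if rng.random() < 0.5:
                row[i] = letters[rng.integers(20)]
        rows.append("".join(row))
        ids.append(f"hit_{d + 1}")
    return Alignment(ids, rows)


def make_labeled_dataset(specs: list[FixtureSpec], background="uniform") -> pd.DataFrame:
    """Full feature pipeline over several toy structures, concatenated."""
    if len(specs) < 2:
        raise ValueError("need at least 2 fixture specs")
    tables = []
    for spec in specs:
        toy = make_toy_structure(spec)
        msa = make_synthetic_msa(
            toy.sequence, toy.conserved_positions, spec.msa_depth, spec.seed + 1
        )
        profile = conservation_profile(msa, background)
        tables.append(
            compute_feature_table(
                toy.chain,
                profile.scores,
                structure_id=spec.structure_id,
                labels=toy.labels,
            )
        )
    return pd.concat(tables, ignore_index=True)


def write_fixture_files(toy: ToyStructure, msa: Alignment, directory) -> dict[str, Path]:
    """Write one fixture as PDB + aligned FASTA + plain-text label list."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = toy.structure_id
    paths = {
        "pdb": directory / f"{sid}.pdb",
        "msa": directory / f"{sid}.fasta",
        "labels": directory / f"{sid}.labels.txt",
    }
    paths["pdb"].write_text(write_pdb_chain(toy.chain))
    paths["msa"].write_text(msa.to_fasta())
    catalytic = [
        res.label for res, lab in zip(toy.chain.residues, toy.labels) if lab == 1
    ]
    paths["labels"].write_text("\n".join(catalytic) + "\n")
    return paths


# ---------------------------------------------------------------------------
# planted experiments used by the validation suite


def recovery_experiment(
    seed: int,
    n_structures: int = 10,
    n_residues: int = 50,
    fraction_functional: float = 0.1,
    n_train: int = 6,
    n_verification: int = 2,
    conservation_threshold: float = 3.8,
):
    """Train on planted fixtures and evaluate on held-out structures.

    Returns the held-out confusion counts together with sensitivity,
    precision and the precision enrichment over the held-out base rate.
    """
    from .evaluation import classification_metrics, confusion_counts
    from .net import TrainingConfig, predict_calls, train_network

    rng = np.random.default_rng(seed)
    struct_seeds = rng.integers(0, 2**31 - 1, size=n_structures)
    specs = [
        FixtureSpec(
            n_residues=n_residues,
            fraction_functional=fraction_functional,
            seed=int(s),
            structure_id=f"SYN{k:03d}",
        )
        for k, s in enumerate(struct_seeds)
    ]
    table = make_labeled_dataset(specs)
    ids = [s.structure_id for s in specs]
    train_ids = set(ids[:n_train])
    ver_ids = set(ids[n_train : n_train + n_verification])
    test_ids = set(ids[n_train + n_verification :])
    cfg = TrainingConfig(seed=int(rng.integers(0, 2**31 - 1)))
    model = train_network(
        table[table["structure_id"].isin(train_ids)],
        table[table["structure_id"].isin(ver_ids)],
        cfg,
    )
    test = table[table["structure_id"].isin(test_ids)]
    calls = predict_calls(model, test, conservation_threshold)
    truth = test["function"].to_numpy(dtype=int)
    counts = confusion_counts(calls, truth)
    metrics = classification_metrics(counts)
    base_rate = truth.mean()
    enrichment = (
        (metrics.precision / 100.0) / base_rate
        if metrics.precision is not None and base_rate > 0
        else 0.0
    )
    return {
        "counts": counts,
        "metrics": metrics,
        "base_rate": float(base_rate),
        "enrichment": float(enrichment),
        "model": model,
        "test_ids": sorted(test_ids),
    }


def _planted_rows(
    structure_id: str,
    n: int,
    aa_pool: str,
    dist_mu: float,
    dist_sd: float,
    conserv_lo: float,
    conserv_hi: float,
    label: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    aa = np.array(list(aa_pool))[rng.integers(0, len(aa_pool), size=n)]
    return pd.DataFrame(
        {
            "structure_id": structure_id,
            "resnum": np.arange(1, n + 1),
            "icode": "",
            "aa": aa,
            "conserv": rng.uniform(conserv_lo, conserv_hi, size=n),
            "distance": rng.normal(dist_mu, dist_sd, size=n).clip(min=0.1),
            "closeness": rng.uniform(0.01, 1.0, size=n),
            "between": rng.uniform(0.01, 1.0, size=n),
            "pagerank": rng.uniform(0.01, 1.0, size=n),
            "rsa": rng.uniform(0.0, 100.0, size=n),
            "function": label,
        }
    )


def planted_scan_tables(seed: int, optimum: float = 3.9):
    """Train/verification/scan tables with a planted optimal prefilter.

    Every functional residue is conserved at or above *optimum*; a band of
    "confusable" negatives — same types and central distances as the
    functional residues, so the network cannot reject them — is conserved
    strictly below it.  Scanning the prefilter therefore peaks at the
    planted threshold.
    """
    rng = np.random.default_rng(seed)
    max_re = np.log2(20.0)

    def block(sid: str) -> pd.DataFrame:
        pos = _planted_rows(sid, 40, "H", 4.0, 0.5, optimum, max_re, 1, rng)
        confusable = _planted_rows(sid, 120, "H", 4.0, 0.5, 0.5, optimum - 0.02, 0, rng)
        easy = _planted_rows(sid, 240, CORE_TYPES, 15.0, 2.0, 0.0, max_re, 0, rng)
        out = pd.concat([pos, confusable, easy], ignore_index=True)
        out["resnum"] = np.arange(1, len(out) + 1)
        return out

    return block("PLT_TRAIN"), block("PLT_VER"), block("PLT_SCAN")
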