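"""Multilocus sequence simulation with substitutions and indels on a tree.

Each locus starts from a root sequence drawn from the base frequencies and
evolves independently down the guide tree. Along a branch of length t
(expected substitutions per site):

* substitutions follow the chosen model (Jukes-Cantor by default, or HKY
  with transition/transversion ratio kappa), applied per site through the
  model's transition probabilities;
* insertions and deletions each occur as Poisson events with mean
  ``indel_rate * t`` per site; event lengths are geometric with the
  configured mean, and inserted residues draw from the base frequencies.

The true alignment is tracked through the event history: every residue
carries a sortable homology key; insertions mint fresh keys between their
neighbors', and the final alignment is the sorted union of the tips' keys
with "-" where a tip lacks a key. Ungapping any alignment row therefore
reproduces that tip's simulated sequence exactly.

With symmetric insertion/deletion rates the expected ungapped sequence
length stays near ``root_length``, while the alignment widens with the
number of insertion events — matching the behavior of gap-rich empirical
alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import dendropy
import numpy as np
from scipy.linalg import expm

from .seqio import DatasetBundle, LocusData

__all__ = [
    "SimConfig",
    "SimulatedLocus",
    "SimulatedDataset",
    "guide_tree_7",
    "guide_tree_14",
    "simulate_locus",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))

# Default guide-tree shapes for the simulation study: balanced binary trees
# on 7 and 14 tips, external branches 0.02 and internal branches 0.008
# substitutions/site. Expected alignment width for root length L0 is about
# L0 * (1 + mean_len * 2 * rate * T) with T the total tree length, so these
# lengths keep ~1 kb roots inside the 800-2000 bp band at both the moderate
# (0.02/site) and extreme (0.2/site) indel rates.
_TREE7 = (
    "((s1:0.02,s2:0.02):0.008,((s3:0.02,s4:0.02):0.008,s5:0.02):0.008,"
    "(s6:0.02,s7:0.02):0.008);"
)
_TREE14 = (
    "(((s1:0.02,s2:0.02):0.008,((s3:0.02,s4:0.02):0.008,s5:0.02):0.008):0.008,"
    "((s6:0.02,s7:0.02):0.008,(s8:0.02,s9:0.02):0.008):0.008,"
    "(((s10:0.02,s11:0.02):0.008,s12:0.02):0.008,(s13:0.02,s14:0.02):0.008):0.008);"
)


def guide_tree_7() -> dendropy.Tree:
    """Default 7-species guide tree for the simulation study."""
    return dendropy.Tree.get(data=_TREE7, schema="newick")


def guide_tree_14() -> dendropy.Tree:
    """Default 14-species guide tree for the simulation study."""
    return dendropy.Tree.get(data=_TREE14, schema="newick")


@dataclass
class SimConfig:
    """Simulation settings.

    indel_rate: events per site per unit branch length, separately for
        insertions and for deletions (0.02 = moderate, 0.2 = extreme).
    mean_indel_length: geometric mean event length (default 12).
    """

    guide_tree: dendropy.Tree | None = None
    root_length: int = 1000
    indel_rate: float = 0.02
    mean_indel_length: float = 12.0
    subst_model: Literal["JC", "HKY"] = "JC"
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.guide_tree is None:
            self.guide_tree = guide_tree_7()
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if self.mean_indel_length < 1:
            raise ValueError("mean_indel_length must be >= 1")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("base_freqs must be 4 probabilities summing to 1")


@dataclass
class SimulatedLocus:
    """True alignment (rows include '-' gaps) for one simulated locus."""

    locus_index: int
    alignment: dict[str, str]

    @property
    def width(self) -> int:
        return len(next(iter(self.alignment.values())))

    def ungapped(self) -> dict[str, str]:
        return {lab: seq.replace("-", "") for lab, seq in self.alignment.items()}


@dataclass
class SimulatedDataset:
    """All loci of one simulated replicate plus the generating tree."""

    loci: list[SimulatedLocus]
    true_tree: dendropy.Tree

    def aligned_bundle(self) -> DatasetBundle:
        """Gapped alignments: feeds both the *aligned* (gaps kept) and the
        *no gap-kmer* treatments, which differ only in tokenization."""
        loci = [
            LocusData(locus_id=f"locus{s.locus_index:04d}", documents=dict(s.alignment), aligned=True)
            for s in self.loci
        ]
        return DatasetBundle(loci=loci)

    def unaligned_bundle(self) -> DatasetBundle:
        """Gap-stripped sequences (the *not aligned* treatment)."""
        loci = [
            LocusData(locus_id=f"locus{s.locus_index:04d}", documents=s.ungapped(), aligned=False)
            for s in self.loci
        ]
        return DatasetBundle(loci=loci)


def _transition_matrix(config: SimConfig, t: float) -> np.ndarray:
    freqs = np.asarray(config.base_freqs, dtype=float)
    if config.subst_model == "JC":
        stay = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        change = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
        P = np.full((4, 4), change)
        np.fill_diagonal(P, stay)
        return P
    # HKY: rate matrix scaled to one expected substitution per unit t
    kappa = config.kappa
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(freqs @ np.diag(Q))
    return expm(Q * (t / scale))


def _substitute(residues: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(residues.size)
    return (u[:, None] > cum[residues]).sum(axis=1).astype(np.int8)


def _evolve_branch(keys, residues, t, config: SimConfig, rng):
    """One branch: substitutions, then indel events in random order."""
    if t > 0 and residues.size:
        residues = _substitute(residues, _transition_matrix(config, t), rng)
    if config.indel_rate <= 0 or t <= 0:
        return keys, residues
    L = residues.size
    n_ins = rng.poisson(config.indel_rate * t * (L + 1))
    n_del = rng.poisson(config.indel_rate * t * L)
    events = ["I"] * n_ins + ["D"] * n_del
    rng.shuffle(events)
    p_geom = 1.0 / config.mean_indel_length
    freqs = np.asarray(config.base_freqs, dtype=float)
    for ev in events:
        L = residues.size
        length = int(rng.geometric(p_geom))
        if ev == "I":
            pos = int(rng.integers(0, L + 1))
            lo = keys[pos - 1] if pos > 0 else (keys[0] - 1.0 if L else 0.0)
            hi = keys[pos] if pos < L else (keys[-1] + 1.0 if L else 1.0)
            new_keys = np.sort(rng.uniform(lo, hi, size=length))
            new_res = rng.choice(4, size=length, p=freqs).astype(np.int8)
            keys = np.concatenate([keys[:pos], new_keys, keys[pos:]])
            residues = np.concatenate([residues[:pos], new_res, residues[pos:]])
        else:
            if L == 0:
                continue
            pos = int(rng.integers(0, L))
            keys = np.delete(keys, slice(pos, pos + length))
            residues = np.delete(residues, slice(pos, pos + length))
    return keys, residues


def simulate_locus(config: SimConfig, rng: np.random.Generator, locus_index: int = 0) -> SimulatedLocus:
    """Simulate one locus along the guide tree and return its true alignment."""
    tree = config.guide_tree
    freqs = np.asarray(config.base_freqs, dtype=float)
    root_res = rng.choice(4, size=config.root_length, p=freqs).astype(np.int8)
    root_keys = np.arange(config.root_length, dtype=float)
    tip_states: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def walk(node, keys, residues):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            ck, cr = _evolve_branch(keys.copy(), residues.copy(), t, config, rng)
            if child.is_leaf():
                tip_states[child.taxon.label] = (ck, cr)
            else:
                walk(child, ck, cr)

    walk(tree.seed_node, root_keys, root_res)
    all_keys = np.unique(np.concatenate([k for k, _ in tip_states.values()]))
    alignment: dict[str, str] = {}
    for label, (keys, residues) in tip_states.items():
        row = np.full(all_keys.size, "-", dtype="<U1")
        idx = np.searchsorted(all_keys, keys)
        row[idx] = _BASES[residues]
        alignment[label] = "".join(row)
    return SimulatedLocus(locus_index=locus_index, alignment=alignment)


def simulate_dataset(
    config: SimConfig,
    n_loci: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Simulate *n_loci* independent loci on the same guide tree. The result
    exposes the aligned (gapped) and unaligned (gap-stripped) views the
    three tokenization treatments consume."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    loci = [simulate_locus(config, rng, locus_index=i) for i in range(n_loci)]
    return SimulatedDataset(loci=loci, true_tree=config.guide_tree)
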