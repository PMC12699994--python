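"""Bootstrap resampling and majority-rule consensus.

Aligned data are resampled at alignment columns (classic site bootstrap,
independently per locus); unaligned data are resampled at the k-mer level:
within each document, as many k-mers as the document holds are drawn with
replacement from its own multiset, so per-document token totals are
conserved and no k-mer migrates between taxa. Replicate trees are
summarized into a majority-rule consensus whose internal labels are
percentage supports.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import dendropy
import numpy as np

from .kmers import KmerCorpus
from .seqio import DatasetBundle, LocusData

__all__ = [
    "BootstrapPlan",
    "bootstrap_sites",
    "bootstrap_kmers",
    "run_bootstrap",
    "majority_consensus",
]


@dataclass
class BootstrapPlan:
    replicates: int = 100
    mode: Literal["sites", "kmers"] = "kmers"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mode not in ("sites", "kmers"):
            raise ValueError(f"unknown bootstrap mode {self.mode!r}")


def bootstrap_sites(locus: LocusData, rng: np.random.Generator) -> LocusData:
    """Resample alignment columns with replacement, identically across rows."""
    if not locus.aligned:
        raise ValueError(
            f"site bootstrap requires an aligned locus (locus {locus.locus_id!r})"
        )
    L = locus.alignment_length()
    cols = rng.integers(0, L, size=L)
    documents = {
        label: "".join(seq[c] for c in cols) for label, seq in locus.documents.items()
    }
    return LocusData(locus_id=locus.locus_id, documents=documents, aligned=True)


def bootstrap_kmers(corpus: KmerCorpus, rng: np.random.Generator) -> KmerCorpus:
    """Within each document, redraw its k-mers with replacement from its own
    multiset; document sizes are conserved exactly."""
    documents: dict[str, Counter] = {}
    for label, counts in corpus.documents.items():
        total = sum(counts.values())
        if total == 0:
            warnings.warn(f"document {label!r} is empty; left empty in replicate")
            documents[label] = Counter()
            continue
        words = list(counts)
        probs = np.array([counts[w] for w in words], dtype=float) / total
        draw = rng.multinomial(total, probs)
        documents[label] = Counter(
            {w: int(c) for w, c in zip(words, draw) if c > 0}
        )
    return KmerCorpus(locus_id=corpus.locus_id, documents=documents, k_used=corpus.k_used)


def run_bootstrap(
    bundle: DatasetBundle,
    plan: BootstrapPlan,
    kmer_config=None,
    lda_config=None,
    **pipeline_kwargs,
) -> list[dendropy.Tree]:
    """Full bootstrap: resample -> (tokenize) -> LDA per locus -> matrix ->
    tree, once per replicate, with replicate seeds derived deterministically
    from ``plan.seed``. Returns the replicate trees (summarize with
    :func:`majority_consensus`)."""
    from . import pipeline  # deferred: pipeline imports this module

    trees: list[dendropy.Tree] = []
    for r in range(plan.replicates):
        rep_seed = int(
            np.random.SeedSequence([plan.seed, r]).generate_state(1, np.uint32)[0]
        ) % (2**31)
        try:
            tree = pipeline.infer_replicate(
                bundle,
                mode=plan.mode,
                seed=rep_seed,
                kmer_config=kmer_config,
                lda_config=lda_config,
                **pipeline_kwargs,
            )
        except Exception as exc:
            raise RuntimeError(
                f"bootstrap replicate {r} (seed {rep_seed}) failed: {exc}"
            ) from exc
        trees.append(tree)
    return trees


def majority_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Majority-rule consensus: bipartitions in > 50% of the replicates,
    labeled with integer percentage support."""
    if not trees:
        raise ValueError("no trees to summarize")
    tns = trees[0].taxon_namespace
    tips0 = {leaf.taxon.label for leaf in trees[0].leaf_node_iter()}
    for t in trees[1:]:
        tips = {leaf.taxon.label for leaf in t.leaf_node_iter()}
        if tips != tips0:
            raise ValueError("bootstrap trees have differing tip sets")
    tree_list = dendropy.TreeList(trees, taxon_namespace=tns)
    consensus = tree_list.consensus(min_freq=0.5)
    for node in consensus.internal_nodes():
        freq = None
        ann = node.annotations.get_value("support", None)
        if ann is not None:
            freq = float(ann)
        elif node.label is not None:
            freq = float(node.label)
        if freq is not None and node.parent_node is not None:
            node.label = str(int(round(freq * 100)))
    return consensus
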