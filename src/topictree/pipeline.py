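"""End-to-end orchestration: tokenize -> LDA per locus -> frequency matrix
-> REML tree, plus bootstrap and the simulation-study driver.

Randomness is controlled by one master seed; per-locus and per-replicate
seeds are derived by hashing (master seed, indices) through numpy's
SeedSequence, so per-locus fits are independent and reproducible in any
execution order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import seqio, treestats
from .brownian_tree import FrequencyMatrix, assemble_matrix, search_tree
from .indelsim import SimConfig, guide_tree_7, guide_tree_14, simulate_dataset
from .kmers import KmerConfig, KmerCorpus, decompose, decompose_mixture, locus_k
from .resample import BootstrapPlan, bootstrap_kmers, bootstrap_sites, majority_consensus, run_bootstrap
from .seqio import DatasetBundle
from .topics import LdaConfig, TopicFit, fit_lda

__all__ = [
    "RunConfig",
    "derive_seed",
    "tokenize_bundle",
    "fit_loci",
    "infer_from_bundle",
    "infer_replicate",
    "run",
    "run_simulation_study",
    "TREATMENT_GAP_MODES",
]

# tokenization mode per study treatment (all consume the gapped alignment;
# strip_gaps reproduces the unaligned view exactly)
TREATMENT_GAP_MODES = {
    "aligned": "keep_all",
    "unaligned": "strip_gaps",
    "nogap": "drop_gap_kmers",
}


def derive_seed(master: int, *indices: int) -> int:
    """Deterministic sub-seed from (master seed, indices); < 2**31."""
    state = np.random.SeedSequence([int(master), *map(int, indices)])
    return int(state.generate_state(1, np.uint32)[0]) % (2**31)


@dataclass
class RunConfig:
    """Everything one inference run needs."""

    input_dir: str | Path | None = None
    aligned: bool = False
    merging: int | None = None
    kmer: KmerConfig = field(default_factory=KmerConfig)
    lda: LdaConfig = field(default_factory=LdaConfig)
    drop_last_topic: bool = True
    transform: Literal["none", "sqrt"] = "sqrt"
    global_rearrangements: bool = True
    bootstrap: BootstrapPlan | None = None
    output_dir: str | Path | None = None
    seed: int = 0


def tokenize_bundle(bundle: DatasetBundle, config: KmerConfig) -> list[KmerCorpus]:
    """Per-locus k estimation and non-overlapping decomposition."""
    corpora = []
    for locus in bundle.loci:
        if config.mode == "mixture":
            corpora.append(
                decompose_mixture(
                    locus,
                    config.mixture_ks,
                    gap_mode=config.gap_mode,
                    drop_ambiguous=config.drop_ambiguous,
                )
            )
            continue
        k = locus_k(locus, config)
        corpora.append(
            decompose(locus, k, gap_mode=config.gap_mode, drop_ambiguous=config.drop_ambiguous)
        )
    return corpora


def fit_loci(
    corpora: Sequence[KmerCorpus],
    config: LdaConfig,
    seed: int = 0,
) -> list[TopicFit]:
    """Independent LDA per locus with derived per-locus seeds."""
    fits = []
    for i, corpus in enumerate(corpora):
        cfg = LdaConfig(
            num_topics=config.num_topics,
            alpha=config.alpha,
            eta=config.eta,
            passes=config.passes,
            seed=derive_seed(seed, i),
            min_corpus_freq=config.min_corpus_freq,
            min_doc_freq=config.min_doc_freq,
        )
        fits.append(fit_lda(corpus, config=cfg))
    return fits


def infer_from_bundle(
    bundle: DatasetBundle,
    kmer_config: KmerConfig | None = None,
    lda_config: LdaConfig | None = None,
    seed: int = 0,
    drop_last_topic: bool = True,
    transform: Literal["none", "sqrt"] = "sqrt",
    global_rearrangements: bool = True,
    return_report: bool = False,
):
    """The two-phase pipeline on an in-memory dataset; returns the tree
    (optionally with a per-stage report)."""
    kmer_config = kmer_config or KmerConfig()
    lda_config = lda_config or LdaConfig()
    corpora = tokenize_bundle(bundle, kmer_config)
    fits = fit_loci(corpora, lda_config, seed=seed)
    matrix = assemble_matrix(
        fits, bundle.group_order, drop_last=drop_last_topic, transform=transform
    )
    tree = search_tree(matrix, seed=seed, global_rearrangements=global_rearrangements)
    if not return_report:
        return tree
    report = {
        "n_loci": bundle.n_loci,
        "n_tips": len(bundle.group_order),
        "k_per_locus": [c.k_used for c in corpora],
        "vocab_sizes": [f.vocabulary.size if f.vocabulary else None for f in fits],
        "lda_bounds": [f.bound for f in fits],
        "matrix_shape": list(matrix.X.shape),
        "logL": float(tree.logL),
        "seed": seed,
    }
    return tree, report


def infer_replicate(
    bundle: DatasetBundle,
    mode: Literal["sites", "kmers"],
    seed: int,
    kmer_config: KmerConfig | None = None,
    lda_config: LdaConfig | None = None,
    **kwargs,
) -> dendropy.Tree:
    """One bootstrap replicate: resample, then the standard pipeline.

    ``sites`` resamples alignment columns per locus before tokenization;
    ``kmers`` tokenizes the original data and resamples each document's
    k-mer multiset (k fixed at the original estimate across replicates).
    """
    kmer_config = kmer_config or KmerConfig()
    lda_config = lda_config or LdaConfig()
    rng = np.random.default_rng(seed)
    if mode == "sites":
        loci = [bootstrap_sites(locus, rng) for locus in bundle.loci]
        resampled = DatasetBundle(loci=loci, group_order=bundle.group_order)
        corpora = tokenize_bundle(resampled, kmer_config)
    else:
        corpora = [
            bootstrap_kmers(corpus, rng)
            for corpus in tokenize_bundle(bundle, kmer_config)
        ]
    fits = fit_loci(corpora, lda_config, seed=seed)
    matrix = assemble_matrix(
        fits,
        bundle.group_order,
        drop_last=kwargs.get("drop_last_topic", True),
        transform=kwargs.get("transform", "sqrt"),
    )
    return search_tree(
        matrix,
        seed=seed,
        global_rearrangements=kwargs.get("global_rearrangements", True),
    )


def run(config: RunConfig) -> dict:
    """Read inputs, infer the tree, optionally bootstrap, write outputs
    (tree.nwk, consensus.nwk, replicates.nwk, report.json)."""
    if config.input_dir is None:
        raise ValueError("RunConfig.input_dir is required")
    bundle = seqio.read_dataset(
        config.input_dir, aligned=config.aligned, merging=config.merging
    )
    tree, report = infer_from_bundle(
        bundle,
        kmer_config=config.kmer,
        lda_config=config.lda,
        seed=config.seed,
        drop_last_topic=config.drop_last_topic,
        transform=config.transform,
        global_rearrangements=config.global_rearrangements,
        return_report=True,
    )
    result = {"tree": tree, "consensus": None, "report": report}
    if config.bootstrap is not None:
        trees = run_bootstrap(
            bundle,
            config.bootstrap,
            kmer_config=config.kmer,
            lda_config=config.lda,
            drop_last_topic=config.drop_last_topic,
            transform=config.transform,
            global_rearrangements=config.global_rearrangements,
        )
        consensus = majority_consensus(trees)
        result["consensus"] = consensus
        result["replicates"] = trees
        report["bootstrap_replicates"] = config.bootstrap.replicates
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        seqio.write_newick(tree, outdir / "tree.nwk")
        if result["consensus"] is not None:
            seqio.write_newick(result["consensus"], outdir / "consensus.nwk")
            seqio.trees_to_newick(result["replicates"], outdir / "replicates.nwk")
        with open(outdir / "report.json", "wt") as fh:
            json.dump(report, fh, indent=2)
    return result


def _study_kmer_config(treatment: str) -> KmerConfig:
    if treatment not in TREATMENT_GAP_MODES:
        raise ValueError(
            f"unknown treatment {treatment!r}; expected one of {sorted(TREATMENT_GAP_MODES)}"
        )
    return KmerConfig(mode="estimate", gap_mode=TREATMENT_GAP_MODES[treatment])


def run_simulation_study(
    scenarios: Sequence[dict],
    replicates: int = 10,
    seed: int = 0,
    lda_config: LdaConfig | None = None,
    close_rf: int = treestats.CLOSE_RF_DEFAULT,
) -> pd.DataFrame:
    """Simulate -> treat -> infer -> score, per scenario and replicate.

    Each scenario is a dict with keys ``tree`` (7 or 14, or a dendropy
    tree), ``indel_rate``, ``loci``, ``treatment`` ('aligned' | 'unaligned'
    | 'nogap'). Returns one row per scenario with the fraction C of
    replicates close to the truth and the mean weighted RF distance.
    """
    lda_config = lda_config or LdaConfig()
    rows = []
    for s_idx, scenario in enumerate(scenarios):
        tree_spec = scenario.get("tree", 7)
        if isinstance(tree_spec, dendropy.Tree):
            guide = tree_spec
        elif int(tree_spec) == 7:
            guide = guide_tree_7()
        elif int(tree_spec) == 14:
            guide = guide_tree_14()
        else:
            raise ValueError(f"no default guide tree with {tree_spec} tips")
        sim_config = SimConfig(
            guide_tree=guide, indel_rate=float(scenario["indel_rate"])
        )
        n_loci = int(scenario["loci"])
        treatment = scenario["treatment"]
        kcfg = _study_kmer_config(treatment)
        estimates = []
        for r in range(replicates):
            rep_seed = derive_seed(seed, s_idx, r)
            dataset = simulate_dataset(sim_config, n_loci, seed=rep_seed)
            bundle = (
                dataset.unaligned_bundle()
                if treatment == "unaligned"
                else dataset.aligned_bundle()
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                estimates.append(
                    infer_from_bundle(
                        bundle,
                        kmer_config=kcfg,
                        lda_config=lda_config,
                        seed=rep_seed,
                    )
                )
        summary = treestats.score_simulation(estimates, guide, max_rf=close_rf)
        rows.append(
            {
                "tree": tree_spec if not isinstance(tree_spec, dendropy.Tree) else "custom",
                "indel_rate": float(scenario["indel_rate"]),
                "loci": n_loci,
                "treatment": treatment,
                "C": summary["C"],
                "wRF": summary["wRF"],
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)
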