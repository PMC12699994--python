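"""Non-overlapping k-mer decomposition of DNA documents.

The word length k is either fixed by the user or estimated from the document
size: for a random sequence X of length n over an alphabet of size sigma,
the chance that a given k-mer occurs is ``P = 1 - (1 - sigma**-k)**n``.
Requiring that this probability not exceed a small q gives

    k_hat = ceil(log_sigma(n * (1 - q) / q))

so that shared k-mers between documents reflect homology rather than chance.
The default q = 0.01 yields k = 9 for ~1 kb documents and k = 8 for the few
hundred bp typical of population-level loci; very long documents (e.g. Mb of
pooled reads) are better served by a user-fixed k around 20.

Gap and ambiguity handling is controlled by ``gap_mode``:

``keep_all``
    "-" is an ordinary symbol; windows are cut from the sequence as given
    (the *aligned* treatment: the alignment coordinate system keeps
    homologous windows in frame).
``drop_gap_kmers``
    cut first, then discard windows containing "-" (*no gap-kmer*).
``strip_gaps``
    delete every "-" before cutting (*unaligned* treatment).
``drop_gap_columns``
    remove alignment columns containing "-" in any row before cutting
    (requires an aligned locus).

Ambiguity codes other than "N"/"?" are kept verbatim; ``drop_ambiguous``
additionally discards windows containing "N" or "?".
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal

from .seqio import LocusData

__all__ = [
    "GapMode",
    "KmerConfig",
    "KmerCorpus",
    "random_kmer_probability",
    "estimate_k",
    "locus_k",
    "decompose",
]

GapMode = Literal["keep_all", "drop_gap_kmers", "strip_gaps", "drop_gap_columns"]

_GAP_MODES = ("keep_all", "drop_gap_kmers", "strip_gaps", "drop_gap_columns")
_AMBIG = ("N", "?")


@dataclass
class KmerConfig:
    """How to choose k and how to treat gaps/ambiguities.

    mode:      "estimate" (from document sizes), "fixed", or "mixture"
               (one corpus per length in ``mixture_ks``, counts pooled).
    q:         target probability of observing a random k-mer (estimate mode).
    aggregate: how per-document estimates combine into one per-locus k.
    """

    mode: Literal["estimate", "fixed", "mixture"] = "estimate"
    fixed_k: int = 9
    q: float = 0.01
    sigma: int = 4
    gap_mode: GapMode = "keep_all"
    drop_ambiguous: bool = False
    aggregate: Literal["max", "min", "median"] = "max"
    mixture_ks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must be in (0, 1)")
        if self.fixed_k < 1:
            raise ValueError("fixed_k must be >= 1")
        if self.sigma < 2:
            raise ValueError("alphabet size sigma must be >= 2")
        if self.gap_mode not in _GAP_MODES:
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")


@dataclass
class KmerCorpus:
    """Bag-of-kmers per document for one locus (the LDA input)."""

    locus_id: str
    documents: dict[str, Counter]
    k_used: int

    @property
    def labels(self) -> list[str]:
        return list(self.documents)

    def total_tokens(self, label: str) -> int:
        return sum(self.documents[label].values())


def random_kmer_probability(k: int, n: int, sigma: int = 4) -> float:
    """P(a given k-mer occurs in a random length-n sequence) =
    1 - (1 - sigma**-k)**n."""
    if k < 1 or n < 1:
        raise ValueError("k and n must be >= 1")
    return -math.expm1(n * math.log1p(-float(sigma) ** (-k)))


def estimate_k(n: int, q: float = 0.01, sigma: int = 4) -> int:
    """k_hat = ceil(log_sigma(n(1-q)/q)), floored at 1."""
    if n < 2:
        raise ValueError("document size n must be >= 2")
    k = math.ceil(math.log(n * (1.0 - q) / q) / math.log(sigma))
    return max(1, k)


def _effective_length(seq: str, gap_mode: GapMode) -> int:
    # the document size that the k estimate should see: strip modes remove
    # gaps before tokenization, so the tokenizable length excludes them
    if gap_mode == "strip_gaps":
        return len(seq) - seq.count("-")
    return len(seq)


def locus_k(locus: LocusData, config: KmerConfig) -> int:
    """One k per locus: per-document estimates aggregated per config.

    The maximum (default) is conservative against chance matches: it is the
    smallest k that satisfies the random-match bound for every document.
    """
    if config.mode == "fixed":
        return config.fixed_k
    if config.mode == "mixture":
        if not config.mixture_ks:
            raise ValueError("mixture mode requires mixture_ks")
        return max(config.mixture_ks)
    ks = sorted(
        estimate_k(max(2, _effective_length(seq, config.gap_mode)), config.q, config.sigma)
        for seq in locus.documents.values()
    )
    if config.aggregate == "max":
        return ks[-1]
    if config.aggregate == "min":
        return ks[0]
    return ks[len(ks) // 2]


def _drop_gap_columns(locus: LocusData) -> dict[str, str]:
    if not locus.aligned:
        raise ValueError(
            f"gap_mode='drop_gap_columns' requires an aligned locus "
            f"(locus {locus.locus_id!r})"
        )
    rows = list(locus.documents.values())
    keep = [i for i in range(len(rows[0])) if all(r[i] != "-" for r in rows)]
    return {
        label: "".join(seq[i] for i in keep) for label, seq in locus.documents.items()
    }


def decompose(
    locus: LocusData,
    k: int,
    gap_mode: GapMode = "keep_all",
    drop_ambiguous: bool = False,
) -> KmerCorpus:
    """Cut each document into consecutive non-overlapping length-k windows
    starting at position 0; a trailing remainder shorter than k is dropped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if gap_mode == "drop_gap_columns":
        docs = _drop_gap_columns(locus)
    else:
        docs = locus.documents
    corpus: dict[str, Counter] = {}
    for label, seq in docs.items():
        if gap_mode == "strip_gaps":
            seq = seq.replace("-", "")
        words = [seq[i : i + k] for i in range(0, len(seq) - k + 1, k)]
        if gap_mode == "drop_gap_kmers":
            words = [w for w in words if "-" not in w]
        if drop_ambiguous:
            words = [w for w in words if not any(a in w for a in _AMBIG)]
        corpus[label] = Counter(words)
    return KmerCorpus(locus_id=locus.locus_id, documents=corpus, k_used=k)


def decompose_mixture(
    locus: LocusData,
    ks: tuple[int, ...],
    gap_mode: GapMode = "keep_all",
    drop_ambiguous: bool = False,
) -> KmerCorpus:
    """Tokenize with several word lengths and pool the bags (mixture mode);
    words of different lengths are distinct vocabulary entries. ``k_used``
    reports the largest length."""
    if not ks:
        raise ValueError("need at least one k")
    pooled: dict[str, Counter] = {label: Counter() for label in locus.documents}
    for k in sorted(set(ks)):
        part = decompose(locus, k, gap_mode=gap_mode, drop_ambiguous=drop_ambiguous)
        for label, counts in part.documents.items():
            pooled[label].update(counts)
    return KmerCorpus(locus_id=locus.locus_id, documents=pooled, k_used=max(ks))
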