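"""Genome-background over-representation and pathway crosstalk.

The core statistic asks whether a phenotype dataset (n genes drawn from an
N-gene universe) contains more targets of a pathway (K genes in the
universe) than its genome frequency p = K/N predicts:

    z = (k - n*p) / sqrt(n * p * (1 - p) [* (N-n)/(N-1)])

``variance="binomial"`` (default) treats dataset membership as n
independent Bernoulli(p) trials — the usual genome-background
approximation when n << N.  ``variance="hypergeometric"`` applies the
finite-population correction, which matters when the dataset is a large
fraction of the universe (n/N up to 0.86 for the datasets modeled here).
A pathway is called over-represented one-sided at the configured
confidence (default 90%, i.e. z >= 1.2816); depletion is not tested.

The exact hypergeometric upper tail is provided as an independent oracle
for the normal approximation, and :func:`decision_agreement` quantifies
how often the two disagree on small count grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .genesets import GeneSet, GeneUniverse, restrict_to_universe

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "RepresentativityMatrix",
    "CrosstalkResult",
    "critical_z",
    "enrichment_z",
    "exact_tail_oracle",
    "screen",
    "crosstalk",
    "decision_agreement",
]


def critical_z(confidence: float) -> float:
    """One-sided critical value: z at the given confidence level."""
    if not 0.5 < confidence < 1.0:
        raise ValidationError(f"confidence must be in (0.5, 1), got {confidence}")
    return float(stats.norm.ppf(confidence))


def _validate_counts(k, n, K, N) -> None:
    k, n, K, N = (np.asarray(x) for x in (k, n, K, N))
    if np.any(n <= 0):
        raise ValidationError("dataset size n must be positive")
    if np.any((K < 0) | (K > N)):
        raise ValidationError("pathway size K must satisfy 0 <= K <= N")
    if np.any(n > N):
        raise ValidationError("dataset size n cannot exceed universe size N")
    if np.any((k < 0) | (k > np.minimum(n, K))):
        raise ValidationError("overlap k must satisfy 0 <= k <= min(n, K)")


def enrichment_z(k, n, K, N, variance: str = "binomial"):
    """Over-representation z of overlap k against genome frequency p = K/N.

    Accepts scalars or broadcastable arrays.  Raises on degenerate
    backgrounds (p in {0, 1}), where the statistic is undefined.
    """
    _validate_counts(k, n, K, N)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    K = np.asarray(K, dtype=float)
    N = np.asarray(N, dtype=float)
    p = K / N
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValidationError("degenerate background: pathway frequency p must be in (0, 1)")
    var = n * p * (1.0 - p)
    if variance == "hypergeometric":
        if np.any(n >= N):
            raise ValidationError(
                "hypergeometric variance is degenerate when the dataset is the "
                "whole universe (n == N)"
            )
        var = var * (N - n) / (N - 1.0)
    elif variance != "binomial":
        raise ValidationError(f"unknown variance model {variance!r}")
    z = (k - n * p) / np.sqrt(var)
    return float(z) if z.ndim == 0 else z


def exact_tail_oracle(k, n, K, N, model: str = "hypergeometric"):
    """Exact upper-tail P(X >= k) for the overlap count.

    ``hypergeometric``: X counts pathway genes among n drawn without
    replacement from an N-gene universe with K pathway genes.
    ``binomial``: the with-replacement analogue at p = K/N.
    """
    _validate_counts(k, n, K, N)
    k = np.asarray(k)
    if model == "hypergeometric":
        tail = stats.hypergeom.sf(k - 1, np.asarray(N), np.asarray(K), np.asarray(n))
    elif model == "binomial":
        tail = stats.binom.sf(k - 1, np.asarray(n), np.asarray(K) / np.asarray(N))
    else:
        raise ValidationError(f"unknown tail model {model!r}")
    tail = np.asarray(tail, dtype=float)
    return float(tail) if tail.ndim == 0 else tail


@dataclass(frozen=True)
class EnrichmentResult:
    """One dataset x pathway over-representation test."""

    dataset: str
    pathway: str
    k: int
    n: int
    K: int
    N: int
    z: float
    significant: bool

    @property
    def expected(self) -> float:
        return self.n * self.K / self.N


# ---------------------------------------------------------------------------
# Screening


def _screen_core(
    pathway_idx: Sequence[np.ndarray],
    dataset_idx: Sequence[np.ndarray],
    N: int,
    confidence: float,
    variance: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized screen on universe index arrays.

    Returns (k, n, K, z, flags); k and z have shape (pathways, datasets).
    Shared by the public :func:`screen` and the Monte-Carlo study helpers
    so that simulations exercise the same computation.
    """
    n = np.array([len(d) for d in dataset_idx])
    K = np.array([len(p) for p in pathway_idx])
    masks = np.zeros((len(dataset_idx), N), dtype=bool)
    for j, d in enumerate(dataset_idx):
        masks[j, d] = True
    k = np.empty((len(pathway_idx), len(dataset_idx)), dtype=np.int64)
    for i, p in enumerate(pathway_idx):
        k[i] = masks[:, p].sum(axis=1)
    z = enrichment_z(k, n[None, :], K[:, None], N, variance=variance)
    flags = z >= critical_z(confidence)
    return k, n, K, z, flags


class RepresentativityMatrix:
    """Pathway x dataset matrix of over-representation results.

    Significance marks (asterisks in formatted exports) flag cells whose z
    exceeds the one-sided critical value at the configured confidence.
    """

    def __init__(
        self,
        pathway_names: Sequence[str],
        dataset_names: Sequence[str],
        k: np.ndarray,
        n: np.ndarray,
        K: np.ndarray,
        N: int,
        z: np.ndarray,
        flags: np.ndarray,
        confidence: float,
        variance: str,
        excluded: Sequence[str] = (),
    ):
        self.pathway_names = list(pathway_names)
        self.dataset_names = list(dataset_names)
        self.k = pd.DataFrame(k, index=self.pathway_names, columns=self.dataset_names)
        self.n = pd.Series(n, index=self.dataset_names)
        self.K = pd.Series(K, index=self.pathway_names)
        self.N = N
        self.z = pd.DataFrame(z, index=self.pathway_names, columns=self.dataset_names)
        self.flags = pd.DataFrame(flags, index=self.pathway_names, columns=self.dataset_names)
        self.confidence = confidence
        self.variance = variance
        self.excluded = list(excluded)

    @property
    def n_tests(self) -> int:
        """Number of tests performed (no multiplicity correction is applied;
        users may correct externally)."""
        return self.z.size

    def result(self, pathway: str, dataset: str) -> EnrichmentResult:
        return EnrichmentResult(
            dataset=dataset,
            pathway=pathway,
            k=int(self.k.loc[pathway, dataset]),
            n=int(self.n[dataset]),
            K=int(self.K[pathway]),
            N=self.N,
            z=float(self.z.loc[pathway, dataset]),
            significant=bool(self.flags.loc[pathway, dataset]),
        )

    def significant_in_all(self, datasets: Sequence[str] | None = None) -> list[str]:
        """Pathways flagged in every listed dataset (default: all datasets).

        This is the screen filter used to call a pathway over-represented
        across an entire phenotype panel."""
        cols = list(datasets) if datasets is not None else self.dataset_names
        sub = self.flags[cols]
        return [p for p in self.pathway_names if bool(sub.loc[p].all())]

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for p in self.pathway_names:
            for d in self.dataset_names:
                r = self.result(p, d)
                rows.append(
                    {
                        "pathway": p,
                        "dataset": d,
                        "k": r.k,
                        "n": r.n,
                        "K": r.K,
                        "N": r.N,
                        "expected": r.expected,
                        "z": r.z,
                        "significant": r.significant,
                    }
                )
        return pd.DataFrame(rows)

    def to_marked(self) -> pd.DataFrame:
        """z values formatted with an asterisk on significant cells."""
        out = self.z.round(2).astype(str)
        return out.where(~self.flags, out + " *")


def screen(
    datasets: Sequence[GeneSet],
    pathways: Sequence[GeneSet],
    universe: GeneUniverse,
    confidence: float = 0.90,
    variance: str = "binomial",
) -> RepresentativityMatrix:
    """Test every pathway against every dataset over the universe.

    Pathways covering none or all of the universe are excluded with a
    warning (their background frequency is degenerate).
    """
    if not datasets or not pathways:
        raise ValidationError("screen needs at least one dataset and one pathway")
    names = [s.name for s in list(datasets) + list(pathways)]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate set names in screen input")
    datasets = [restrict_to_universe(d, universe) for d in datasets]
    kept, excluded = [], []
    for p in pathways:
        pr = restrict_to_universe(p, universe)
        if pr.size in (0, universe.size):
            excluded.append(pr.name)
        else:
            kept.append(pr)
    if excluded:
        log.warning("screen: excluded degenerate pathways: %s", ", ".join(excluded))
    if not kept:
        raise ValidationError("all pathways are degenerate over this universe")
    index = {g: i for i, g in enumerate(sorted(universe.genes))}
    d_idx = [np.fromiter((index[g] for g in d.genes), dtype=np.int64) for d in datasets]
    p_idx = [np.fromiter((index[g] for g in p.genes), dtype=np.int64) for p in kept]
    k, n, K, z, flags = _screen_core(p_idx, d_idx, universe.size, confidence, variance)
    return RepresentativityMatrix(
        [p.name for p in kept],
        [d.name for d in datasets],
        k, n, K, universe.size, z, flags, confidence, variance, excluded,
    )


# ---------------------------------------------------------------------------
# Crosstalk


@dataclass(frozen=True)
class CrosstalkResult:
    """Crosstalk of a focal pathway with another pathway inside a dataset.

    ``shared_genes`` are the dataset genes regulatable by both pathways;
    ``representativity_pct`` is their share of the dataset's genes for the
    other pathway (missing when the dataset and the other pathway are
    disjoint); significance tests the focal-regulatable part of the
    dataset for over-representation of the other pathway's targets.
    """

    focal: str
    other: str
    dataset: str
    shared_genes: frozenset[str]
    representativity_pct: float | None
    z: float | None
    significant: bool


def crosstalk(
    focal: GeneSet,
    others: Iterable[GeneSet],
    dataset: GeneSet,
    universe: GeneUniverse,
    confidence: float = 0.90,
    variance: str = "binomial",
) -> list[CrosstalkResult]:
    focal = restrict_to_universe(focal, universe)
    dataset = restrict_to_universe(dataset, universe)
    d_focal = dataset.genes & focal.genes
    results = []
    zcrit = critical_z(confidence)
    for other in others:
        other = restrict_to_universe(other, universe)
        shared = frozenset(d_focal & other.genes)
        d_other = dataset.genes & other.genes
        pct = 100.0 * len(shared) / len(d_other) if d_other else None
        if other.size in (0, universe.size) or not d_focal:
            z = None
            sig = False
        else:
            z = enrichment_z(len(shared), len(d_focal), other.size, universe.size,
                             variance=variance)
            sig = bool(z >= zcrit)
        results.append(
            CrosstalkResult(
                focal=focal.name,
                other=other.name,
                dataset=dataset.name,
                shared_genes=shared,
                representativity_pct=pct,
                z=z,
                significant=sig,
            )
        )
    return results


def crosstalk_to_tidy(results: Sequence[CrosstalkResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "focal": r.focal,
                "other": r.other,
                "dataset": r.dataset,
                "n_shared": len(r.shared_genes),
                "representativity_pct": r.representativity_pct,
                "z": r.z,
                "significant": r.significant,
                "shared_genes": ";".join(sorted(r.shared_genes)),
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Normal approximation vs exact tail


@dataclass
class AgreementReport:
    """Agreement between z decisions and exact-tail decisions on count grids."""

    n_tested: int
    n_agree: int
    disagreements: pd.DataFrame

    @property
    def fraction_agree(self) -> float:
        return self.n_agree / self.n_tested if self.n_tested else float("nan")


def decision_agreement(
    confidence: float = 0.90,
    variance: str = "hypergeometric",
    N_values: Sequence[int] = tuple(range(20, 201, 10)),
    n_values: Sequence[int] = tuple(range(5, 31, 5)),
    K_step: int = 5,
    min_np: float = 5.0,
) -> AgreementReport:
    """Compare significance decisions of the z approximation against the
    exact hypergeometric tail over a deterministic grid of small counts.

    Grids are restricted to n*p >= ``min_np`` where the normal
    approximation is conventionally considered usable.  Disagreements are
    returned with their exact tail probabilities.
    """
    alpha = 1.0 - confidence
    zcrit = critical_z(confidence)
    n_tested = 0
    n_agree = 0
    rows = []
    for N in N_values:
        for K in range(K_step, N, K_step):
            p = K / N
            for n in n_values:
                if n >= N or n * p < min_np:
                    continue
                k = np.arange(0, min(n, K) + 1)
                z = enrichment_z(k, n, K, N, variance=variance)
                tail = exact_tail_oracle(k, n, K, N)
                dz = z >= zcrit
                de = tail <= alpha
                agree = dz == de
                n_tested += k.size
                n_agree += int(agree.sum())
                for kk in k[~agree]:
                    rows.append(
                        {"k": int(kk), "n": n, "K": K, "N": N,
                         "z": float(enrichment_z(kk, n, K, N, variance=variance)),
                         "exact_tail": float(exact_tail_oracle(kk, n, K, N))}
                    )
    dis = pd.DataFrame(rows, columns=["k", "n", "K", "N", "z", "exact_tail"])
    if len(dis):
        log.info("decision_agreement: %d/%d disagreements", len(dis), n_tested)
    return AgreementReport(n_tested=n_tested, n_agree=n_agree, disagreements=dis)
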