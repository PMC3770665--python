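"""Signature-group selection from the differential axis and the group-size
sensitivity sweep.

Group A holds the genes with the largest positive differential scores y'
(up-regulated by rest insertion); Group B the most negative (down-regulated
by rest).  Selection takes a fixed fraction of the analyzed universe from
each tail; sign-restricted membership means a group is truncated (with a
warning) if its tail runs out of same-signed genes.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Sequence

import pandas as pd

from .enrichment import GeneSetCollection, ora_report

logger = logging.getLogger(__name__)

__all__ = ["SignatureGroups", "SweepResult", "select_groups", "sensitivity_sweep"]


@dataclasses.dataclass
class SignatureGroups:
    """Ranked up-/down-regulation signatures.

    ``group_a`` is ordered by decreasing y' (largest positive first),
    ``group_b`` by increasing y' (most negative first); the groups never
    overlap.
    """

    group_a: list[str]
    group_b: list[str]
    fraction: float
    universe_size: int


@dataclasses.dataclass
class SweepResult:
    """Per-size, per-set FDR for one ranked list.

    ``fdr`` is a size x set DataFrame of BH-FDR q-values;
    ``first_significant_size`` maps each set to the smallest size with
    FDR < alpha (NaN when never significant); ``min_fdr_size`` to the size
    attaining the minimum FDR (smallest such size on ties).
    """

    sizes: list[int]
    fdr: pd.DataFrame
    first_significant_size: dict[str, float]
    min_fdr_size: dict[str, int]
    alpha: float


def select_groups(y_prime: pd.Series, fraction: float = 0.01) -> SignatureGroups:
    """Select the top-fraction tails of the differential score.

    With universe size N, Group A takes the ceil(fraction*N) genes with the
    largest y' and Group B the floor(fraction*N) with the smallest (the
    ceiling/floor split is a documented convention).  Ties are broken
    deterministically by gene id.  Members must carry the sign of their
    tail; exhausted tails truncate the group with a warning.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError(f"fraction must lie in (0, 0.5], got {fraction!r}")
    if y_prime.size < 1.0 / fraction:
        raise ValueError(
            f"universe of {y_prime.size} genes is too small for fraction {fraction}"
        )
    if not pd.api.types.is_numeric_dtype(y_prime) or y_prime.isna().any():
        raise ValueError("y_prime must be finite and numeric")
    n = y_prime.size
    n_a = math.ceil(fraction * n)
    n_b = math.floor(fraction * n)
    frame = pd.DataFrame({"gene": y_prime.index.astype(str), "y_prime": y_prime.to_numpy()})
    positives = frame[frame["y_prime"] > 0].sort_values(
        ["y_prime", "gene"], ascending=[False, True], kind="stable"
    )
    negatives = frame[frame["y_prime"] < 0].sort_values(
        ["y_prime", "gene"], ascending=[True, True], kind="stable"
    )
    group_a = positives["gene"].head(n_a).tolist()
    group_b = negatives["gene"].head(n_b).tolist()
    if len(group_a) < n_a:
        logger.warning(
            "positive tail exhausted: Group A truncated to %d of %d", len(group_a), n_a
        )
    if len(group_b) < n_b:
        logger.warning(
            "negative tail exhausted: Group B truncated to %d of %d", len(group_b), n_b
        )
    return SignatureGroups(
        group_a=group_a, group_b=group_b, fraction=fraction, universe_size=n
    )


def sensitivity_sweep(
    ranked_genes: Sequence[str],
    collection: GeneSetCollection,
    sizes: Sequence[int] = tuple(range(5, 205, 5)),
    *,
    alpha: float = 0.05,
    mode: str = "membership",
) -> SweepResult:
    """Sweep signature size against gene-set enrichment.

    For each size k the top-k prefix of the ranked list is tested against
    every set in the collection; per-set BH-FDR q-values are collected into
    a size x set table, along with the first size reaching FDR < alpha and
    the size attaining the minimum FDR per set.
    """
    sizes = [int(k) for k in sizes]
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    if sizes and sizes[0] < 1:
        raise ValueError("sizes must be positive")
    if not sizes:
        raise ValueError("no sizes given")
    if max(sizes) > len(ranked_genes):
        raise ValueError(
            f"size {max(sizes)} exceeds ranked list length {len(ranked_genes)}"
        )
    rows = {}
    for k in sizes:
        report = ora_report(ranked_genes[:k], collection, alpha=alpha, mode=mode)
        rows[k] = report.set_index("set")["q"]
    fdr = pd.DataFrame(rows).T.sort_index()
    fdr.index.name = "size"
    first_significant: dict[str, float] = {}
    min_fdr_size: dict[str, int] = {}
    for set_name in fdr.columns:
        q = fdr[set_name]
        hits = q[q < alpha]
        first_significant[set_name] = float(hits.index[0]) if len(hits) else float("nan")
        min_fdr_size[set_name] = int(q.idxmin())  # idxmin takes the smallest size on ties
    return SweepResult(
        sizes=sizes,
        fdr=fdr,
        first_significant_size=first_significant,
        min_fdr_size=min_fdr_size,
        alpha=alpha,
    )
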