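"""Over-representation analysis of gene lists against GMT-style gene-set
collections: upper-tail hypergeometric tests with Benjamini-Hochberg FDR.

One engine serves two querying modes — pathway *membership* collections and
perturbation-response *signature_overlap* collections — which differ only in
the semantics of the sets, not in the statistics.  The universe is the list
of analyzed genes (what could have been selected), not the whole array.
"""
from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "hypergeometric_pvalue",
    "hypergeometric_enrich",
    "bh_fdr",
    "ora_report",
]


@dataclasses.dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets harmonized against an analysis universe.

    Symbols are matched case-insensitively (stored upper-case); set members
    absent from the universe are dropped with a logged count, and sets left
    empty after harmonization are discarded.  Duplicate set names and empty
    input sets are rejected.
    """

    sets: dict[str, tuple[str, ...]]
    universe: frozenset[str]

    @classmethod
    def from_sets(
        cls,
        named_sets: Sequence[tuple[str, Sequence[str]]],
        universe: Iterable[str],
        *,
        case_insensitive: bool = True,
    ) -> "GeneSetCollection":
        norm = (lambda s: str(s).upper()) if case_insensitive else str
        uni = frozenset(norm(g) for g in universe)
        if not uni:
            raise ValueError("universe is empty")
        seen: set[str] = set()
        harmonized: dict[str, tuple[str, ...]] = {}
        n_dropped = 0
        for name, members in named_sets:
            if name in seen:
                raise ValueError(f"duplicate gene set name {name!r}")
            seen.add(name)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            deduped = list(dict.fromkeys(norm(m) for m in members))
            kept = tuple(m for m in deduped if m in uni)
            n_dropped += len(deduped) - len(kept)
            if not kept:
                logger.warning("gene set %r has no members in the universe; dropped", name)
                continue
            harmonized[name] = kept
        if n_dropped:
            logger.info("dropped %d set members absent from the universe", n_dropped)
        return cls(sets=harmonized, universe=uni)


def hypergeometric_pvalue(k, m: int, n: int, N: int):
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap between a random size-``n`` draw from a universe of
    ``N`` genes and a fixed set of ``m`` genes.  Accepts scalar or array
    ``k``; adding one overlapping gene (k -> k+1) strictly decreases p
    whenever the event is not already certain/impossible.
    """
    k = np.asarray(k)
    p = hypergeom.sf(k - 1, N, m, n)
    return float(p) if p.ndim == 0 else p


def hypergeometric_enrich(
    query: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
    *,
    on_missing: str = "error",
) -> float:
    """Hypergeometric over-representation p-value for one gene set.

    ``on_missing`` controls query genes absent from the universe:
    ``"error"`` raises, ``"drop"`` removes them with a logged count.
    """
    uni = frozenset(universe)
    q = set(query)
    missing = q - uni
    if missing:
        if on_missing == "drop":
            logger.warning("dropping %d query genes absent from universe", len(missing))
            q -= missing
        else:
            raise ValueError(
                f"{len(missing)} query genes absent from universe, e.g. "
                f"{sorted(missing)[:3]!r}"
            )
    if not q:
        raise ValueError("query is empty (after universe harmonization)")
    s = set(gene_set) & uni
    k = len(q & s)
    return hypergeometric_pvalue(k, m=len(s), n=len(q), N=len(uni))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora_report(
    query: Iterable[str],
    collection: GeneSetCollection,
    *,
    mode: str = "membership",
    alpha: float = 0.05,
    on_missing: str = "drop",
) -> pd.DataFrame:
    """Test every set in the collection against the query.

    Returns one row per set with overlap count ``k``, set size ``m``, query
    size ``n``, universe size ``N``, hypergeometric ``p``, BH-FDR ``q``, a
    significance flag at ``alpha`` and the overlapping genes, sorted by
    (q, p, set name).
    """
    if mode not in ("membership", "signature_overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    if not collection.sets:
        raise ValueError("collection has no gene sets")
    uni = collection.universe
    q = set(str(g).upper() for g in query)
    missing = q - uni
    if missing:
        if on_missing == "drop":
            logger.warning("dropping %d query genes absent from universe", len(missing))
            q -= missing
        else:
            raise ValueError(f"{len(missing)} query genes absent from universe")
    if not q:
        raise ValueError("query is empty after universe harmonization")
    rows = []
    for name, members in collection.sets.items():
        s = set(members)
        overlap = sorted(q & s)
        rows.append(
            {
                "set": name,
                "k": len(overlap),
                "m": len(s),
                "n": len(q),
                "N": len(uni),
                "p": hypergeometric_pvalue(len(overlap), m=len(s), n=len(q), N=len(uni)),
                "overlap_genes": ",".join(overlap),
            }
        )
    report = pd.DataFrame(rows)
    report["q"] = bh_fdr(report["p"].to_numpy())
    report["significant"] = report["q"] < alpha
    report["mode"] = mode
    report = report.sort_values(["q", "p", "set"], kind="stable").reset_index(drop=True)
    return report[
        ["set", "k", "m", "n", "N", "p", "q", "significant", "overlap_genes", "mode"]
    ]
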