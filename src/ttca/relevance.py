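"""Literature relevance score from publication counts.

The relevance score tells known players apart from novel candidates: a
gene with ``p`` publications linking it to the studied condition scores
``log(p) / log(p_max)`` where ``p_max`` is the best-documented gene's
count, so the most-published gene scores 1 and unpublished genes score 0.

Counts come from an offline two-column table (gene, count).  A live
literature-query client can be plugged in behind the same
:class:`PublicationCounts` interface but is deliberately not shipped:
results must be reproducible without network access.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ttca")


@dataclass
class PublicationCounts:
    """Gene -> publication-count map with query provenance."""

    counts: dict[str, int]
    query: str = ""

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.counts.items() if c < 0}
        if bad:
            raise ValueError(f"negative publication counts: {bad}")

    @property
    def p_max(self) -> int:
        return max(self.counts.values(), default=0)

    def get(self, gene: str) -> int:
        return int(self.counts.get(gene, 0))


def load_counts(path: str | Path, query: str = "") -> PublicationCounts:
    """Parse a two-column (gene, count) table; '#' comment lines allowed."""
    table = pd.read_csv(
        path, sep=None, engine="python", comment="#", header=None,
        names=["gene", "count"], dtype={"gene": str},
    )
    if table["gene"].duplicated().any():
        dup = table["gene"][table["gene"].duplicated()].tolist()
        raise ValueError(f"duplicate gene rows in counts table: {dup}")
    counts: dict[str, int] = {}
    for i, row in enumerate(table.itertuples(index=False), start=1):
        c = row.count
        if isinstance(c, float) and not float(c).is_integer():
            raise ValueError(f"non-integer count at row {i}: {c!r}")
        c = int(c)
        if c < 0:
            raise ValueError(f"negative count at row {i}: {c}")
        counts[str(row.gene)] = c
    return PublicationCounts(counts=counts, query=query)


def relevance_score(counts: PublicationCounts, gene: str) -> float:
    """``R = log(p) / log(p_max)`` in [0, 1]; zero-count genes score 0."""
    return float(relevance_scores(counts, [gene])[0])


def relevance_scores(counts: PublicationCounts, genes) -> np.ndarray:
    """Vectorised relevance score for a sequence of genes."""
    p_max = counts.p_max
    p = np.array([counts.get(g) for g in genes], dtype=float)
    if p_max < 2:
        logger.warning("degenerate publication corpus (p_max=%d): all relevance 0", p_max)
        return np.zeros(len(p))
    with np.errstate(divide="ignore"):
        r = np.where(p >= 1, np.log(np.maximum(p, 1)) / np.log(p_max), 0.0)
    return np.clip(r, 0.0, 1.0)
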