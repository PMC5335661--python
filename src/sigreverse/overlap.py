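"""Gene-set overlap statistics against a protein-coding background.

The intersection size of two gene sets drawn from a fixed background is
modelled as hypergeometric.  Both the point probability of exactly the
observed overlap and the upper-tail probability of at least that overlap
are reported — a report of "p (hypergeometric)" in the literature can mean
either, so neither is silently preferred here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

from scipy.stats import hypergeom

from .io import GeneSet, ValidationError

__all__ = [
    "PROTEIN_CODING_GENES",
    "OverlapResult",
    "intersect",
    "expected_overlap",
    "hypergeom_point",
    "hypergeom_tail",
    "GeneSetOverlap",
]

#: Protein-coding genes in the human genome (NCBI CCDS release 21); the
#: documented default background size for headless runs without an explicit
#: background universe file.
PROTEIN_CODING_GENES = 20354


@dataclass
class OverlapResult:
    """Observed and expected overlap of two gene sets in a background of N
    genes, with exact hypergeometric probabilities."""

    k: int                      # observed intersection size
    expected: float             # K * n_draw / N
    p_point: float              # P(X = k)
    p_tail: float               # P(X >= k)
    N: int
    K: int                      # size of set 1 within the background
    n_draw: int                 # size of set 2 within the background
    overlap_genes: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "k": self.k, "expected": self.expected,
            "p_point": self.p_point, "p_tail": self.p_tail,
            "N": self.N, "K": self.K, "n_draw": self.n_draw,
            "overlap_genes": list(self.overlap_genes),
        }

    def summary(self) -> str:
        return "\n".join([
            "Gene-set overlap (hypergeometric)",
            "=" * 37,
            f"background N            {self.N}",
            f"set sizes (K, n)        {self.K}, {self.n_draw}",
            f"observed overlap k      {self.k}",
            f"expected overlap        {self.expected:.3f}",
            f"P(X = k)  [point]       {self.p_point:.4f}",
            f"P(X >= k) [upper tail]  {self.p_tail:.4f}",
            f"overlap genes           {', '.join(self.overlap_genes) or '(none)'}",
        ])


def _check_params(K: int, n_draw: int, N: int) -> None:
    if N < 1:
        raise ValueError("background size N must be >= 1")
    if not (0 <= K <= N and 0 <= n_draw <= N):
        raise ValueError(f"need 0 <= K, n_draw <= N; got K={K}, n_draw={n_draw}, N={N}")


def expected_overlap(K: int, n_draw: int, N: int) -> float:
    """Expected intersection size of random K- and n-subsets of N genes."""
    _check_params(K, n_draw, N)
    return K * n_draw / N


def hypergeom_point(k: int, K: int, n_draw: int, N: int) -> float:
    """P(X = k): probability of exactly k shared genes (log-space safe for
    backgrounds beyond 1e6 genes)."""
    _check_params(K, n_draw, N)
    lo, hi = max(0, K + n_draw - N), min(K, n_draw)
    if not lo <= k <= hi:
        raise ValueError(f"k={k} outside the feasible range [{lo}, {hi}]")
    return float(hypergeom.pmf(k, N, K, n_draw))


def hypergeom_tail(k: int, K: int, n_draw: int, N: int) -> float:
    """P(X >= k): probability of at least k shared genes.  Out-of-support k
    returns 1 (below the support) or 0 (above it)."""
    _check_params(K, n_draw, N)
    lo, hi = max(0, K + n_draw - N), min(K, n_draw)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    return float(hypergeom.sf(k - 1, N, K, n_draw))


def intersect(a: GeneSet, b: GeneSet, background: GeneSet) -> tuple[int, tuple[str, ...]]:
    """Case-insensitive intersection of two sets restricted to a background.

    Genes outside the background are dropped with a warning.  Symmetric in
    ``a`` and ``b``; the returned symbols keep the case used in ``a``.
    """
    if len(background) == 0:
        raise ValidationError("empty background")
    bg = background.casefolded()

    def restrict(s: GeneSet) -> dict[str, str]:
        kept = {g.casefold(): g for g in s.genes if g.casefold() in bg}
        dropped = len(s) - len(kept)
        if dropped:
            warnings.warn(f"{dropped} gene(s) of set {s.name!r} absent from background; dropped")
        return kept

    fa, fb = restrict(a), restrict(b)
    common = sorted(set(fa) & set(fb))
    return len(common), tuple(fa[c] for c in common)


class GeneSetOverlap:
    """Overlap model for two gene sets against a protein-coding background.

    The background may be an explicit :class:`GeneSet` universe (sets are
    restricted to it before counting) or a bare size for headless runs, in
    which case both sets are assumed to lie inside the background.
    """

    def __init__(self, set_a: GeneSet, set_b: GeneSet,
                 background: GeneSet | int = PROTEIN_CODING_GENES):
        self.set_a = set_a
        self.set_b = set_b
        self.background = background

    def fit(self) -> OverlapResult:
        if isinstance(self.background, GeneSet):
            N = len(self.background)
            k, genes = intersect(self.set_a, self.set_b, self.background)
            bg = self.background.casefolded()
            K = sum(1 for g in self.set_a.genes if g.casefold() in bg)
            n_draw = sum(1 for g in self.set_b.genes if g.casefold() in bg)
        else:
            N = int(self.background)
            fa = {g.casefold(): g for g in self.set_a.genes}
            common = sorted(set(fa) & self.set_b.casefolded())
            k, genes = len(common), tuple(fa[c] for c in common)
            K, n_draw = len(self.set_a), len(self.set_b)
        return OverlapResult(
            k=k,
            expected=expected_overlap(K, n_draw, N),
            p_point=hypergeom_point(k, K, n_draw, N),
            p_tail=hypergeom_tail(k, K, n_draw, N),
            N=N, K=K, n_draw=n_draw, overlap_genes=genes,
        )

    def fit_to_json(self, path: str | Path) -> OverlapResult:
        res = self.fit()
        Path(path).write_text(json.dumps(res.as_dict(), indent=2))
        return res
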