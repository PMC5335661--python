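"""Connectivity scoring of a directional signature against a perturbation
rank database.

Each database instance is a full ranking of the gene universe (rank 1 = most
up-regulated by the treatment).  A Kolmogorov-Smirnov-style tag enrichment
statistic measures whether a tag list concentrates at the top (+) or bottom
(-) of the ranking; up- and down-tag scores combine into a per-instance
connectivity in [-2, 2] (zero when both sides agree in sign), instances are
rescaled per side into [-1, 1], and a compound's enrichment is the same KS
statistic applied to the positions of its instances in the raw-score
ordering.  Compound p-values come from random same-size instance subsets.
Negative compound enrichment means the compound's transcriptional effect
opposes the query signature — the signature-reversal candidates this screen
exists to find.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneSet, RankDatabase, ValidationError
from .signature import GeneSignature

__all__ = [
    "TagList",
    "InstanceScore",
    "CompoundResult",
    "ks_tag_score",
    "instance_connectivity",
    "scale_scores",
    "score_instances",
    "compound_enrichment",
    "compound_p_value",
    "screen",
    "ConnectivityScreen",
    "ScreenResults",
]


@dataclass(frozen=True)
class TagList:
    """A directional tag list: signature genes used to interrogate rankings."""

    genes: GeneSet
    direction: str  # "up" or "down"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


@dataclass
class InstanceScore:
    instance: str
    es_up: float
    es_down: float
    raw: float
    scaled: float | None = None


@dataclass
class CompoundResult:
    compound: str
    n_instances: int
    enrichment: float
    p: float


def _ks_statistic(V: np.ndarray, n: int) -> np.ndarray:
    """KS tag enrichment from sorted tag ranks.

    ``V`` has shape (..., t) with ascending ranks along the last axis;
    ``a = max_j [j/t - V_j/n]``, ``b = max_j [V_j/n - (j-1)/t]``; the score
    is ``a`` when ``a >= b`` else ``-b``, always in [-1, 1].
    """
    V = np.asarray(V, dtype=float)
    t = V.shape[-1]
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - V / n, axis=-1)
    b = np.max(V / n - (j - 1) / t, axis=-1)
    return np.where(a >= b, a, -b)


def _tag_ranks(tags: TagList, ranking: Mapping[str, int] | pd.Series) -> np.ndarray:
    """Look up tag ranks case-insensitively; drop absent tags with a warning."""
    if isinstance(ranking, pd.Series):
        lookup = {str(g).casefold(): r for g, r in ranking.items()}
    else:
        lookup = {str(g).casefold(): r for g, r in ranking.items()}
    ranks = [lookup[g.casefold()] for g in tags.genes.genes if g.casefold() in lookup]
    n_absent = len(tags.genes) - len(ranks)
    if n_absent:
        warnings.warn(f"{n_absent} tag gene(s) absent from the ranked universe; dropped")
    if not ranks:
        raise ValidationError("no tag genes present in the ranked universe")
    return np.sort(np.asarray(ranks, dtype=float))


def ks_tag_score(tags: TagList, ranking: Mapping[str, int] | pd.Series) -> float:
    """Score one tag list against one ranking (a permutation of 1..n)."""
    n = len(ranking)
    V = _tag_ranks(tags, ranking)
    return float(_ks_statistic(V, n))


def instance_connectivity(up: TagList | None, down: TagList | None,
                          ranking: Mapping[str, int] | pd.Series,
                          instance: str = "") -> InstanceScore:
    """Combine up- and down-tag scores for one instance.

    ``raw = es_up - es_down`` when the two scores differ in sign (a zero
    score counts as opposite to either), else 0.  A missing direction
    contributes a score of 0 (single-list queries).
    """
    if up is not None and down is not None:
        shared = up.genes.casefolded() & down.genes.casefolded()
        if shared:
            raise ValidationError(f"up/down tag lists overlap: {sorted(shared)[:5]}")
    if up is None and down is None:
        raise ValidationError("need at least one tag direction")
    es_up = ks_tag_score(up, ranking) if up is not None else 0.0
    es_down = ks_tag_score(down, ranking) if down is not None else 0.0
    raw = 0.0 if es_up * es_down > 0 else es_up - es_down
    return InstanceScore(instance=instance, es_up=es_up, es_down=es_down, raw=raw)


def scale_scores(scores: Sequence[InstanceScore]) -> list[InstanceScore]:
    """Rescale raw connectivities per side: positives by the max positive,
    negatives by the magnitude of the min negative; zeros stay zero."""
    if not scores:
        raise ValidationError("need at least one instance score")
    raws = np.array([s.raw for s in scores])
    pos = raws[raws > 0].max() if (raws > 0).any() else 1.0
    neg = abs(raws[raws < 0].min()) if (raws < 0).any() else 1.0
    for s in scores:
        s.scaled = s.raw / pos if s.raw > 0 else (s.raw / neg if s.raw < 0 else 0.0)
    return list(scores)


def _signature_tag_rows(db: RankDatabase, signature: GeneSignature
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Row positions of up/down tag genes in the database universe."""
    lookup = db.gene_rank_lookup()

    def rows(gs: GeneSet | None, label: str) -> np.ndarray:
        if gs is None:
            return np.empty(0, dtype=int)
        idx = [lookup[g.casefold()] for g in gs.genes if g.casefold() in lookup]
        n_absent = len(gs) - len(idx)
        if n_absent:
            warnings.warn(
                f"{n_absent} {label}-tag gene(s) absent from database universe; "
                f"effective tag size {len(idx)}"
            )
        return np.asarray(idx, dtype=int)

    up_rows = rows(signature.up, "up")
    down_rows = rows(signature.down, "down")
    if up_rows.size == 0 and down_rows.size == 0:
        raise ValidationError("signature has no usable tags in the database universe")
    overlap = set(up_rows) & set(down_rows)
    if overlap:
        raise ValidationError("up/down tag lists overlap within the database universe")
    return up_rows, down_rows


def score_instances(db: RankDatabase, signature: GeneSignature) -> pd.DataFrame:
    """Connectivity of every database instance with the signature.

    Returns a DataFrame indexed by instance id with columns ``es_up``,
    ``es_down``, ``raw`` and ``scaled`` (per-side rescaled into [-1, 1]).
    """
    up_rows, down_rows = _signature_tag_rows(db, signature)
    arr = db.ranks.to_numpy()          # genes x instances
    n = db.n_genes

    def side(rows: np.ndarray) -> np.ndarray:
        if rows.size == 0:
            return np.zeros(arr.shape[1])
        V = np.sort(arr[rows, :].astype(float), axis=0).T  # instances x t
        return _ks_statistic(V, n)

    es_up, es_down = side(up_rows), side(down_rows)
    raw = np.where(es_up * es_down > 0, 0.0, es_up - es_down)
    pos = raw[raw > 0].max() if (raw > 0).any() else 1.0
    neg = abs(raw[raw < 0].min()) if (raw < 0).any() else 1.0
    scaled = np.where(raw > 0, raw / pos, np.where(raw < 0, raw / neg, 0.0))
    return pd.DataFrame(
        {"es_up": es_up, "es_down": es_down, "raw": raw, "scaled": scaled},
        index=db.instances,
    )


def _instance_order(scores: pd.DataFrame) -> pd.Index:
    """Instances by raw connectivity, descending; ties by id ascending for
    bit-reproducible compound enrichment."""
    df = scores.sort_index()  # secondary key first (stable sort)
    return df.sort_values("raw", ascending=False, kind="mergesort").index


def compound_enrichment(db: RankDatabase, scores: pd.DataFrame, compound: str) -> float:
    """KS enrichment of a compound's instances within the raw-score ordering
    of all instances (positive: the compound's instances cluster at the top,
    i.e. mimic the signature; negative: they cluster at the bottom, i.e.
    reverse it)."""
    order = _instance_order(scores)
    members = set(db.instances_of(compound))
    positions = np.sort([i + 1 for i, inst in enumerate(order) if inst in members])
    return float(_ks_statistic(positions.astype(float), len(order)))


def compound_p_value(db: RankDatabase, scores: pd.DataFrame, compound: str,
                     permutations: int = 10000, seed: int | None = None,
                     sided: str = "two") -> float:
    """Permutation p-value for a compound's enrichment.

    Random same-size instance subsets are drawn from the ordering;
    ``p = (1 + #{extreme}) / (1 + B)`` where "extreme" is ``|ES*| >= |ES|``
    (two-sided, default) or ``ES* <= ES`` (one-sided toward reversal).
    """
    if permutations < 100:
        raise ValueError("permutations must be >= 100")
    if sided not in ("two", "one"):
        raise ValueError("sided must be 'two' or 'one'")
    obs = compound_enrichment(db, scores, compound)
    N = len(db.instances)
    t = len(db.instances_of(compound))
    rng = np.random.default_rng(seed)
    # B random t-subsets of positions 1..N via partial argsort of uniforms
    u = rng.random((permutations, N))
    subset = np.argpartition(u, t - 1, axis=1)[:, :t] + 1
    V = np.sort(subset.astype(float), axis=1)
    null = _ks_statistic(V, N)
    if sided == "two":
        count = int(np.sum(np.abs(null) >= abs(obs)))
    else:
        count = int(np.sum(null <= obs))
    return (1 + count) / (1 + permutations)


def screen(db: RankDatabase, signature: GeneSignature, alpha: float = 0.05,
           permutations: int = 10000, seed: int | None = None,
           sided: str = "two") -> pd.DataFrame:
    """Score every compound and select signature reversers.

    Returns the full compound table (columns ``compound``, ``n_instances``,
    ``enrichment_score``, ``p_value``, ``selected``) sorted by enrichment
    ascending; ``selected`` marks compounds with enrichment < 0 and
    p <= alpha, the candidates whose perturbation opposes the signature.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    scores = score_instances(db, signature)
    order = _instance_order(scores)
    pos_of = {inst: i + 1 for i, inst in enumerate(order)}
    N = len(order)
    rng = np.random.default_rng(seed)

    rows = []
    for compound in db.compounds:
        members = db.instances_of(compound)
        t = len(members)
        V = np.sort([float(pos_of[m]) for m in members])
        es = float(_ks_statistic(np.asarray(V), N))
        u = rng.random((permutations, N))
        subset = np.argpartition(u, t - 1, axis=1)[:, :t] + 1
        null = _ks_statistic(np.sort(subset.astype(float), axis=1), N)
        if sided == "two":
            count = int(np.sum(np.abs(null) >= abs(es)))
        else:
            count = int(np.sum(null <= es))
        p = (1 + count) / (1 + permutations)
        rows.append((compound, t, es, p))

    table = pd.DataFrame(rows, columns=["compound", "n_instances", "enrichment_score", "p_value"])
    table["selected"] = (table["enrichment_score"] < 0) & (table["p_value"] <= alpha)
    table = table.sort_values(
        ["enrichment_score", "compound"], ascending=[True, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


class ConnectivityScreen:
    """Signature-reversal screen of a perturbation rank database.

    Parameters
    ----------
    db
        The rank corpus (instances x genes, with compound metadata).
    signature
        Directional query signature.  A one-sided signature is accepted
        (the missing side contributes 0 to each instance's connectivity).
    """

    def __init__(self, db: RankDatabase, signature: GeneSignature):
        self.db = db
        self.signature = signature

    @classmethod
    def from_files(cls, rank_path, meta_path, signature_path) -> "ConnectivityScreen":
        from .io import read_rank_database
        from .signature import read_signature

        return cls(read_rank_database(rank_path, meta_path), read_signature(signature_path))

    def fit(self, alpha: float = 0.05, permutations: int = 10000,
            seed: int | None = None, sided: str = "two") -> "ScreenResults":
        instance_scores = score_instances(self.db, self.signature)
        table = screen(self.db, self.signature, alpha=alpha,
                       permutations=permutations, seed=seed, sided=sided)
        return ScreenResults(model=self, instance_scores=instance_scores,
                             table=table, alpha=alpha,
                             permutations=permutations, seed=seed)


@dataclass
class ScreenResults:
    """Per-instance connectivities and the compound-level screen table."""

    model: ConnectivityScreen
    instance_scores: pd.DataFrame
    table: pd.DataFrame
    alpha: float
    permutations: int
    seed: int | None

    @property
    def selected(self) -> pd.DataFrame:
        """Signature-reversing compounds (enrichment < 0, p <= alpha),
        most negative first."""
        return self.table[self.table["selected"]].reset_index(drop=True)

    def compound_results(self) -> list[CompoundResult]:
        return [
            CompoundResult(r.compound, int(r.n_instances), float(r.enrichment_score),
                           float(r.p_value))
            for r in self.table.itertuples()
        ]

    def summary(self) -> str:
        sel = self.selected
        lines = [
            "Connectivity screen",
            "=" * 37,
            f"instances / compounds  {len(self.instance_scores)} / {len(self.table)}",
            f"tags (up/down)         {self.model.signature.n_up}/{self.model.signature.n_down}",
            f"permutations           {self.permutations} (seed={self.seed})",
            f"selected (ES<0, p<={self.alpha})  {len(sel)}",
            "",
            "compound  enrichment_score  p_value",
        ]
        for r in sel.itertuples():
            lines.append(f"{r.compound}  {r.enrichment_score:+.2f}  {r.p_value:.3g}")
        return "\n".join(lines)
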