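"""Differential-expression signature construction.

A two-group expression matrix is tested gene-by-gene with a Welch t
statistic whose null distribution is built by random permutation of the
sample group labels, giving exact finite-sample p-values without normality
assumptions.  P-values are FDR-adjusted (Benjamini-Hochberg) and genes
passing the threshold are split by the sign of t into directional up/down
tag lists, optionally translated to human symbols through a one-to-one
ortholog map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GeneSet, ExpressionMatrix, OrthologMap, ValidationError, write_gmt

__all__ = [
    "permutation_t_test",
    "adjust_fdr",
    "map_orthologs",
    "MappingReport",
    "GeneSignature",
    "build_signature",
    "write_signature",
    "read_signature",
    "SignatureModel",
    "SignatureResults",
]


def _welch_t(sum1, sumsq1, n1, sum2, sumsq2, n2):
    """Welch t from per-group sums and sums of squares (vectorised).

    Zero-variance pairs with equal means give t = 0; unequal means give
    +/- inf, which compares correctly in the permutation count.
    """
    m1, m2 = sum1 / n1, sum2 / n2
    # unbiased variances from raw moments; clip tiny negatives from rounding
    v1 = np.clip((sumsq1 - n1 * m1 ** 2) / (n1 - 1), 0.0, None)
    v2 = np.clip((sumsq2 - n2 * m2 ** 2) / (n2 - 1), 0.0, None)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        t = np.where(denom == 0.0, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), t)
    return t


def permutation_t_test(matrix: ExpressionMatrix, permutations: int = 1000,
                       seed: int | None = None) -> pd.DataFrame:
    """Per-gene Welch t (case minus control) with a permutation p-value.

    The null distribution is built by shuffling the case/control labels over
    samples ``permutations`` times (one shared shuffle set for all genes);
    ``p_perm = (1 + #{|t*| >= |t_obs|}) / (1 + B)`` never returns 0.

    Returns a DataFrame indexed by gene with columns ``t``, ``p_perm`` and
    ``zero_variance`` (True for genes constant across all samples, which are
    flagged with t = 0 and p_perm = 1, not dropped).
    """
    if permutations < 100:
        raise ValueError("permutations must be >= 100")
    case = matrix.group_columns("case")
    control = matrix.group_columns("control")
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"need >= 2 samples per group, got case={n1}, control={n2}")

    X = matrix.values[list(case) + list(control)].to_numpy(dtype=float)  # G x S
    G, S = X.shape
    Xsq = X ** 2
    tot, totsq = X.sum(axis=1), Xsq.sum(axis=1)

    def t_for(case_idx: np.ndarray) -> np.ndarray:
        s1 = X[:, case_idx].sum(axis=1)
        q1 = Xsq[:, case_idx].sum(axis=1)
        return _welch_t(s1, q1, n1, tot - s1, totsq - q1, n2)

    t_obs = t_for(np.arange(n1))
    zero_var = totsq - tot ** 2 / S <= 0.0

    rng = np.random.default_rng(seed)
    abs_obs = np.abs(t_obs)
    count = np.zeros(G, dtype=np.int64)
    for _ in range(permutations):
        perm = rng.permutation(S)[:n1]
        t_star = t_for(perm)
        count += np.abs(t_star) >= abs_obs
    p = (1.0 + count) / (1.0 + permutations)

    t_out = np.where(zero_var, 0.0, t_obs)
    p = np.where(zero_var, 1.0, p)
    return pd.DataFrame(
        {"t": t_out, "p_perm": p, "zero_variance": zero_var}, index=matrix.genes
    )


def adjust_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MappingReport:
    mapped: int = 0
    unmapped: int = 0
    ambiguous: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"mapped": self.mapped, "unmapped": self.unmapped, "ambiguous": self.ambiguous}


def map_orthologs(genes: Iterable[str], omap: OrthologMap) -> tuple[list[str], MappingReport]:
    """Translate gene ids to human symbols through a one-to-one map.

    Genes with exactly one human partner are translated; genes with zero or
    more than one partner are dropped (counted in the report, never fatal —
    expanding many-to-many orthologs would double-count tags downstream).
    Output symbols are unique, first occurrence order preserved.
    """
    partners = omap.partners()
    report = MappingReport()
    out: list[str] = []
    seen: set[str] = set()
    for g in genes:
        hits = partners.get(g.casefold(), [])
        if len(hits) == 1:
            report.mapped += 1
            h = hits[0]
            if h.casefold() not in seen:
                seen.add(h.casefold())
                out.append(h)
        elif len(hits) == 0:
            report.unmapped += 1
        else:
            report.ambiguous += 1
    return out, report


@dataclass
class GeneSignature:
    """Directional differential-expression signature: the query object for
    connectivity scoring.  One side may be empty (flagged), not both."""

    up: GeneSet | None
    down: GeneSet | None
    fdr_threshold: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.up is None and self.down is None:
            raise ValidationError("signature has no genes on either side")
        if self.up is not None and self.down is not None:
            shared = self.up.casefolded() & self.down.casefolded()
            if shared:
                raise ValidationError(f"up/down tag lists overlap: {sorted(shared)[:5]}")
        if self.up is None or self.down is None:
            warnings.warn("one-sided signature: only one tag direction present")

    @property
    def n_up(self) -> int:
        return 0 if self.up is None else len(self.up)

    @property
    def n_down(self) -> int:
        return 0 if self.down is None else len(self.down)


def build_signature(de: pd.DataFrame, fdr_threshold: float = 0.05,
                    omap: OrthologMap | None = None,
                    name: str = "signature",
                    provenance: str = "") -> GeneSignature:
    """Select genes at ``q < fdr_threshold``, split by sign of t into up and
    down tag lists, and (optionally) translate through an ortholog map."""
    if not 0.0 < fdr_threshold < 1.0:
        raise ValueError("fdr_threshold must be in (0, 1)")
    q = adjust_fdr(de["p_perm"])
    passing = de.index[(q < fdr_threshold)]
    if len(passing) == 0:
        raise ValidationError(
            f"no genes pass FDR < {fdr_threshold}; inspect the data or relax the threshold"
        )
    t = de.loc[passing, "t"]
    up_genes = [str(g) for g in passing[t > 0]]
    down_genes = [str(g) for g in passing[t < 0]]
    report = None
    if omap is not None:
        up_genes, rep_up = map_orthologs(up_genes, omap)
        down_genes, rep_down = map_orthologs(down_genes, omap)
        report = MappingReport(
            mapped=rep_up.mapped + rep_down.mapped,
            unmapped=rep_up.unmapped + rep_down.unmapped,
            ambiguous=rep_up.ambiguous + rep_down.ambiguous,
        )
    # symbols mapping to the same human gene from both directions would
    # contradict disjointness; keep the up copy and drop from down
    up_fold = {g.casefold() for g in up_genes}
    down_genes = [g for g in down_genes if g.casefold() not in up_fold]
    up = GeneSet(f"{name}_UP", "up-regulated tags", tuple(up_genes)) if up_genes else None
    down = GeneSet(f"{name}_DN", "down-regulated tags", tuple(down_genes)) if down_genes else None
    prov = provenance or f"q<{fdr_threshold} split by sign(t)"
    if report is not None:
        prov += f"; ortholog mapping {report.as_dict()}"
    return GeneSignature(up=up, down=down, fdr_threshold=fdr_threshold, provenance=prov)


def write_signature(sig: GeneSignature, gmt_path: str | Path,
                    sidecar: dict | None = None) -> None:
    """Write a signature as a two-set GMT (suffixes ``_UP`` / ``_DN``) plus a
    JSON sidecar with threshold and provenance."""
    gmt_path = Path(gmt_path)
    sets = [s for s in (sig.up, sig.down) if s is not None]
    write_gmt(sets, gmt_path)
    meta = {"fdr_threshold": sig.fdr_threshold, "provenance": sig.provenance,
            "n_up": sig.n_up, "n_down": sig.n_down}
    meta.update(sidecar or {})
    gmt_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_signature(gmt_path: str | Path, fdr_threshold: float = 0.05) -> GeneSignature:
    """Load a signature written by :func:`write_signature` (or any GMT whose
    set names end in ``_UP`` / ``_DN``).  Direction must be explicit."""
    from .io import read_gmt

    gmt_path = Path(gmt_path)
    sets = read_gmt(gmt_path)
    up = down = None
    for s in sets:
        if s.name.upper().endswith("_UP"):
            up = s
        elif s.name.upper().endswith(("_DN", "_DOWN")):
            down = s
        else:
            raise ValidationError(
                f"gene set {s.name!r} has no direction suffix (_UP or _DN); "
                "signatures must state tag direction explicitly"
            )
    sidecar = gmt_path.with_suffix(".json")
    prov = ""
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fdr_threshold = meta.get("fdr_threshold", fdr_threshold)
        prov = meta.get("provenance", "")
    return GeneSignature(up=up, down=down, fdr_threshold=fdr_threshold, provenance=prov)


class SignatureModel:
    """Differential-expression signature model for a two-group expression
    matrix.

    Parameters
    ----------
    matrix
        Normalized expression with case/control sample labels.
    ortholog_map
        Optional one-to-one translation to human symbols applied after
        selection (cross-species queries).

    ``fit`` runs the permutation t-test, BH adjustment and signature
    construction and returns :class:`SignatureResults`.
    """

    def __init__(self, matrix: ExpressionMatrix, ortholog_map: OrthologMap | None = None):
        self.matrix = matrix
        self.ortholog_map = ortholog_map

    @classmethod
    def from_files(cls, matrix_path, groups_path, ortholog_path=None) -> "SignatureModel":
        from .io import read_expression_matrix, read_ortholog_map

        omap = read_ortholog_map(ortholog_path) if ortholog_path else None
        return cls(read_expression_matrix(matrix_path, groups_path), omap)

    def fit(self, permutations: int = 1000, seed: int | None = None,
            fdr_threshold: float = 0.05, name: str = "signature") -> "SignatureResults":
        de = permutation_t_test(self.matrix, permutations=permutations, seed=seed)
        de = de.assign(q=adjust_fdr(de["p_perm"]))
        signature = build_signature(de, fdr_threshold=fdr_threshold,
                                    omap=self.ortholog_map, name=name)
        return SignatureResults(model=self, de=de, signature=signature,
                                permutations=permutations, seed=seed)


@dataclass
class SignatureResults:
    """Fitted differential-expression results and the derived signature."""

    model: SignatureModel
    de: pd.DataFrame              # columns t, p_perm, zero_variance, q
    signature: GeneSignature
    permutations: int
    seed: int | None

    def summary(self) -> str:
        d = self.de
        lines = [
            "Differential-expression signature",
            "=" * 37,
            f"genes tested        {len(d)}",
            f"samples (case/ctrl) {len(self.model.matrix.group_columns('case'))}/"
            f"{len(self.model.matrix.group_columns('control'))}",
            f"permutations        {self.permutations} (seed={self.seed})",
            f"FDR threshold       {self.signature.fdr_threshold}",
            f"signature size      {self.signature.n_up} up / {self.signature.n_down} down",
            f"zero-variance genes {int(d['zero_variance'].sum())}",
        ]
        return "\n".join(lines)
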