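"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the statistical structure the pipeline assumes:

* a two-group microarray-like expression matrix with planted differentially
  expressed genes (Gaussian noise, mean shifts in SD units);
* a perturbation rank corpus of uniform-random permutations with planted
  signature-reversing (antagonist) and signature-mimicking (agonist)
  compounds, built by displacing tag genes toward the rank extremes;
* a right-censored survival cohort whose hazard depends on whether the
  biomarker exceeds mean + 1 SD (high expression protective for hazard
  ratios above 1).

All generators are pure functions of (config, seed): each draws from its
own RNG stream derived from the master seed by a fixed offset, so adding a
generator never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, RankDatabase, SurvivalCohort, ValidationError
from .signature import GeneSignature

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_rank_database",
    "simulate_survival",
]

# fixed RNG stream offsets: one stream per generator
_STREAM_EXPRESSION = 0
_STREAM_RANKS = 1
_STREAM_SURVIVAL = 2


@dataclass
class SimulationConfig:
    """Knobs for all three generators.

    Defaults describe the emulated study conditions: a 2,000-gene two-group
    microarray with 10 samples per group and 50 planted effects of 2 SD; a
    200-instance, 40-compound rank corpus with one fully displaced
    antagonist; and a 216-patient cohort with a protective biomarker at
    hazard ratio 2.5 and 30% censoring.
    """

    seed: int = 0
    # expression
    genes: int = 2000
    samples_per_group: int = 10
    planted_de: int = 50
    de_fraction_up: float = 0.5
    effect_size: float = 2.0        # mean shift in units of noise SD
    noise_sd: float = 1.0
    # rank database
    instances: int = 200
    compounds: int = 40
    antagonists: int = 1
    agonists: int = 0
    strength: float = 1.0           # 0 = null, 1 = fully displaced tags
    # survival
    cohort_size: int = 216
    hazard_ratio: float = 2.5       # low-group hazard / high-group hazard
    baseline_hazard: float = 0.1    # event hazard of the high group, per time unit
    censoring_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.planted_de > self.genes:
            raise ValidationError("planted_de exceeds total genes")
        if not 0.0 <= self.strength <= 1.0:
            raise ValidationError("strength must be in [0, 1]")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValidationError("censoring_fraction must be in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValidationError("hazard_ratio must be positive")
        if not 0.0 <= self.de_fraction_up <= 1.0:
            raise ValidationError("de_fraction_up must be in [0, 1]")
        if self.antagonists + self.agonists > self.compounds:
            raise ValidationError("planted compounds exceed total compounds")
        for name in ("genes", "samples_per_group", "planted_de", "instances",
                     "compounds", "antagonists", "agonists", "cohort_size"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def as_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-group expression matrix with planted differential expression.

    Null genes are Normal(0, noise_sd) in both groups; planted genes get a
    +/- effect_size * noise_sd mean shift in the case group (the first
    ``round(planted_de * de_fraction_up)`` planted genes shift up, the rest
    down).  Returns the matrix and a truth table (gene, direction).
    """
    rng = _rng(config, _STREAM_EXPRESSION)
    g, s = config.genes, config.samples_per_group
    genes = _gene_ids(g)
    samples = [f"case_{i+1}" for i in range(s)] + [f"ctrl_{i+1}" for i in range(s)]
    X = rng.normal(0.0, config.noise_sd, size=(g, 2 * s))

    n_up = int(round(config.planted_de * config.de_fraction_up))
    directions = ["up"] * n_up + ["down"] * (config.planted_de - n_up)
    shift = config.effect_size * config.noise_sd
    for i, d in enumerate(directions):
        X[i, :s] += shift if d == "up" else -shift

    values = pd.DataFrame(X, index=genes, columns=samples)
    groups = pd.Series(["case"] * s + ["control"] * s, index=samples)
    truth = pd.DataFrame({"gene": genes[: config.planted_de], "direction": directions})
    return ExpressionMatrix(values=values, groups=groups), truth


def _displace(perm_ranks: np.ndarray, rows: np.ndarray, n: int,
              strength: float, toward_bottom: bool) -> np.ndarray:
    """Sort keys after geometrically interpolating tag ranks toward one
    extreme: key = r^(1-s) * target^s with target n+0.5 (bottom) or 0.5
    (top), so strength 1 pushes tags strictly past every non-tag gene."""
    keys = perm_ranks.astype(float).copy()
    target = n + 0.5 if toward_bottom else 0.5
    keys[rows] = keys[rows] ** (1.0 - strength) * target ** strength
    return keys


def simulate_rank_database(config: SimulationConfig, signature: GeneSignature
                           ) -> tuple[RankDatabase, pd.DataFrame]:
    """Rank corpus with planted signature-perturbing compounds.

    Null instances are independent uniform permutations of the universe.
    Antagonist instances displace the signature's up-tags toward the bottom
    and down-tags toward the top of the ranking (the treatment *reverses*
    the signature); agonists mirror that.  Displacement interpolates
    geometrically between the null rank and the extreme with the configured
    strength, then the column is re-ranked into a valid permutation.

    Instances are spread over compounds as evenly as possible; planted
    compounds are named ``antagonist_#`` / ``agonist_#``, nulls ``drug_#``.
    Returns the database and a truth table (compound, role).
    """
    rng = _rng(config, _STREAM_RANKS)
    n = config.genes
    universe = _gene_ids(n)
    fold = {g.casefold(): i for i, g in enumerate(universe)}

    def rows_of(side) -> np.ndarray:
        if side is None:
            return np.empty(0, dtype=int)
        missing = [g for g in side.genes if g.casefold() not in fold]
        if missing:
            raise ValidationError(f"signature gene(s) missing from universe: {missing[:5]}")
        return np.asarray([fold[g.casefold()] for g in side.genes], dtype=int)

    up_rows, down_rows = rows_of(signature.up), rows_of(signature.down)

    n_planted = config.antagonists + config.agonists
    roles = (["antagonist"] * config.antagonists + ["agonist"] * config.agonists
             + ["null"] * (config.compounds - n_planted))
    names = []
    counters = {"antagonist": 0, "agonist": 0, "null": 0}
    for r in roles:
        counters[r] += 1
        names.append(f"{r}_{counters[r]}" if r != "null" else f"drug_{counters[r]}")

    base, extra = divmod(config.instances, config.compounds)
    inst_compound: list[str] = []
    for i, name in enumerate(names):
        inst_compound += [name] * (base + (1 if i < extra else 0))

    cols, meta_rows = {}, []
    for j, compound in enumerate(inst_compound):
        inst_id = f"inst_{j+1:04d}"
        perm = rng.permutation(n) + 1          # a uniform permutation of 1..n
        role = roles[names.index(compound)]
        if role != "null" and config.strength > 0:
            s = config.strength
            to_bottom, to_top = (up_rows, down_rows) if role == "antagonist" \
                else (down_rows, up_rows)
            keys = perm.astype(float)
            keys = _displace(keys, to_bottom, n, s, toward_bottom=True)
            keys = _displace(keys, to_top, n, s, toward_bottom=False)
            # stable re-rank back to a permutation of 1..n
            order = np.argsort(keys, kind="mergesort")
            perm = np.empty(n, dtype=np.int64)
            perm[order] = np.arange(1, n + 1)
        cols[inst_id] = perm
        meta_rows.append((inst_id, compound, "10uM", "SYN1"))

    ranks = pd.DataFrame(cols, index=universe, dtype=np.int64)
    metadata = pd.DataFrame(meta_rows, columns=["instance_id", "compound", "dose", "cell_line"]
                            ).set_index("instance_id")
    truth = pd.DataFrame({"compound": names, "role": roles})
    return RankDatabase(ranks=ranks, metadata=metadata), truth


def simulate_survival(config: SimulationConfig) -> tuple[SurvivalCohort, pd.DataFrame]:
    """Right-censored cohort with a protective high-biomarker stratum.

    Biomarkers are Normal(0, 1); samples above mean + 1 sample SD ("high")
    get exponential event times at the baseline hazard, the rest at
    baseline * hazard_ratio (so high expression is protective for ratios
    above 1).  A random ``censoring_fraction`` of subjects is censored at a
    uniform fraction of its event time.  Returns the cohort and per-sample
    truth labels (id, group).
    """
    rng = _rng(config, _STREAM_SURVIVAL)
    m = config.cohort_size
    biomarker = rng.normal(0.0, 1.0, size=m)
    threshold = biomarker.mean() + biomarker.std(ddof=1)
    high = biomarker > threshold

    hazard = np.where(high, config.baseline_hazard,
                      config.baseline_hazard * config.hazard_ratio)
    event_time = rng.exponential(1.0 / hazard)

    event = np.ones(m, dtype=int)
    time = event_time.copy()
    n_cens = int(round(config.censoring_fraction * m))
    if n_cens > 0:
        idx = rng.choice(m, size=n_cens, replace=False)
        time[idx] = event_time[idx] * rng.random(n_cens)
        event[idx] = 0

    ids = [f"pt_{i+1:04d}" for i in range(m)]
    cohort = SurvivalCohort(table=pd.DataFrame({
        "id": ids, "biomarker": biomarker, "time": time, "event": event,
    }))
    truth = pd.DataFrame({"id": ids, "group": np.where(high, "high", "low")})
    return cohort, truth
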