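"""Balanced multi-environment trial (MET) simulator.

Generates replicate-level trait values for a genotype x condition x season x
replicate design with known (planted) components, so that every downstream
stage — tolerance indices, joint ANOVA, AMMI, WAASB, MGIDI, clustering —
can be checked against ground truth.

The generative model per trait is

    y = (mu + g_i + r_k(j) + sum_m lambda_m u_im v_jm + eps) * f(group_i, c)

where g_i ~ N(0, sd_g^2) are genotype main effects, r_k(j) ~ N(0, sd_block^2)
are replicate-within-environment (block) effects, the bilinear term plants a
low-rank genotype-by-environment interaction over the condition x season
cells (u, v columns orthonormal within the sum-to-zero subspace, so the
planted singular-value profile is exact), eps ~ N(0, sd_res^2), and
f(group, condition) is a multiplicative stress-response factor (1 under the
optimal condition).  The multiplicative stress response makes the tolerance
ratio stress/optimal group-separated by construction, which is what the
clustering and discriminant stages are tested against.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BalanceError, ConfigurationError, FormatError

logger = logging.getLogger(__name__)

MET_COLUMNS = ["genotype", "condition", "season", "rep", "trait", "value"]

OPTIMAL = "optimal"


@dataclass(frozen=True)
class TraitSpec:
    """Per-trait generative parameters.

    mean: grand mean under the optimal condition (trait units).
    sd_g / sd_res / sd_block: genotypic, residual and block SDs (>= 0).
    gei_sv: singular values of the planted interaction, one per axis;
        the interaction rank is ``len(gei_sv)``.
    sense: 'increase' if larger values are agronomically better.
    positive: truncate generated values at 1e-6 (ratio-bound traits).
    """

    name: str
    mean: float = 1.0
    sd_g: float = 0.0
    sd_res: float = 0.0
    sd_block: float = 0.0
    gei_sv: tuple[float, ...] = ()
    sense: str = "increase"
    positive: bool = True


@dataclass(frozen=True)
class SimConfig:
    """Design and generative parameters of a simulated balanced MET."""

    n_genotypes: int = 20
    seasons: tuple[str, ...] = ("S1", "S2", "S3")
    conditions: tuple[str, ...] = (OPTIMAL, "drought", "heat")
    n_reps: int = 3
    traits: tuple[TraitSpec, ...] = ()
    #: tolerance-group name -> multiplicative stress factor; either a single
    #: float applied to every stress condition or a condition -> float map.
    group_effects: Mapping[str, object] = field(
        default_factory=lambda: {"all": 1.0}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_genotypes < 2:
            raise ConfigurationError("n_genotypes", "must be >= 2")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps", "must be >= 2")
        if len(self.conditions) < 2 or OPTIMAL not in self.conditions:
            raise ConfigurationError(
                "conditions", "need at least 2 conditions including 'optimal'"
            )
        if not self.seasons:
            raise ConfigurationError("seasons", "need at least one season")
        if not self.traits:
            raise ConfigurationError("traits", "need at least one trait")
        if not self.group_effects:
            raise ConfigurationError("group_effects", "need at least one group")
        n_env = len(self.conditions) * len(self.seasons)
        max_rank = min(self.n_genotypes, n_env) - 1
        for t in self.traits:
            for attr in ("sd_g", "sd_res", "sd_block"):
                if getattr(t, attr) < 0:
                    raise ConfigurationError(
                        f"traits[{t.name}].{attr}", "SD must be >= 0"
                    )
            if len(t.gei_sv) > max_rank:
                raise ConfigurationError(
                    f"traits[{t.name}].gei_sv",
                    f"interaction rank {len(t.gei_sv)} exceeds "
                    f"min(g, e) - 1 = {max_rank}",
                )
            if t.sense not in ("increase", "decrease"):
                raise ConfigurationError(
                    f"traits[{t.name}].sense", "must be 'increase' or 'decrease'"
                )

    @property
    def genotypes(self) -> list[str]:
        width = max(2, len(str(self.n_genotypes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]

    @property
    def environments(self) -> list[tuple[str, str]]:
        """(condition, season) cells, condition-major in declared order."""
        return [(c, s) for c in self.conditions for s in self.seasons]

    def group_of(self) -> dict[str, str]:
        """Assign genotypes to tolerance groups in contiguous blocks."""
        names = list(self.group_effects)
        gens = self.genotypes
        per = int(np.ceil(len(gens) / len(names)))
        return {g: names[min(i // per, len(names) - 1)] for i, g in enumerate(gens)}

    def stress_factor(self, group: str, condition: str) -> float:
        if condition == OPTIMAL:
            return 1.0
        eff = self.group_effects[group]
        if isinstance(eff, Mapping):
            return float(eff.get(condition, 1.0))
        return float(eff)


@dataclass
class METDataset:
    """Long-format replicate-level trial data, fully balanced.

    ``planted`` holds the generative components per trait (genotype effects,
    interaction matrix, block effects, group map, stress factors) when the
    dataset came from :func:`generate_met`.
    """

    data: pd.DataFrame
    planted: dict | None = None

    def __post_init__(self):
        missing = [c for c in MET_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        self.data = self.data[MET_COLUMNS]

    def validate(self) -> None:
        """Check full balance and finite positive values."""
        levels = [sorted(self.data[c].unique()) for c in MET_COLUMNS[:5]]
        expected = pd.MultiIndex.from_product(levels, names=MET_COLUMNS[:5])
        observed = pd.MultiIndex.from_frame(self.data[MET_COLUMNS[:5]])
        if observed.has_duplicates:
            dups = self.data[observed.duplicated()][MET_COLUMNS[:5]]
            raise FormatError(f"duplicated cells: {dups.values[:5].tolist()}")
        missing = expected.difference(observed)
        if len(missing):
            raise BalanceError(missing.tolist())
        if not np.isfinite(self.data["value"]).all():
            raise FormatError("non-finite values present")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "METDataset":
        data = pd.read_csv(
            path,
            dtype={"genotype": str, "condition": str, "season": str,
                   "trait": str},
            float_precision="round_trip",
        )
        ds = cls(data)
        ds.validate()
        return ds

    def __eq__(self, other) -> bool:
        return isinstance(other, METDataset) and self.data.equals(other.data)


def _centered_orthonormal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """m orthonormal columns of length n inside the sum-to-zero subspace."""
    if m == 0:
        return np.zeros((n, 0))
    a = rng.standard_normal((n, m + 1))
    a -= a.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(a)
    return q[:, :m]


def generate_met(config: SimConfig) -> METDataset:
    """Generate a balanced MET dataset with recorded planted components.

    Deterministic under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gens = config.genotypes
    envs = config.environments
    g, e, r = len(gens), len(envs), config.n_reps
    group_of = config.group_of()

    frames = []
    planted: dict = {"group_of": group_of, "environments": envs, "traits": {}}
    n_truncated = 0
    for spec in config.traits:
        g_eff = rng.normal(0.0, spec.sd_g, size=g) if spec.sd_g else np.zeros(g)
        blocks = (
            rng.normal(0.0, spec.sd_block, size=(e, r))
            if spec.sd_block
            else np.zeros((e, r))
        )
        m = len(spec.gei_sv)
        u = _centered_orthonormal(rng, g, m)
        v = _centered_orthonormal(rng, e, m)
        gei = (u * np.asarray(spec.gei_sv)) @ v.T  # g x e bilinear form
        noise = (
            rng.normal(0.0, spec.sd_res, size=(g, e, r))
            if spec.sd_res
            else np.zeros((g, e, r))
        )
        base = (
            spec.mean
            + g_eff[:, None, None]
            + gei[:, :, None]
            + blocks[None, :, :]
            + noise
        )
        factors = np.array(
            [
                [config.stress_factor(group_of[gen], cond) for cond, _ in envs]
                for gen in gens
            ]
        )
        values = base * factors[:, :, None]
        if spec.positive:
            low = values < 1e-6
            if low.any():
                n_truncated += int(low.sum())
                values = np.where(low, 1e-6, values)
        idx = pd.MultiIndex.from_product(
            [gens, [f"{c}|{s}" for c, s in envs], range(1, r + 1)],
            names=["genotype", "env", "rep"],
        )
        df = pd.DataFrame({"value": values.ravel()}, index=idx).reset_index()
        df[["condition", "season"]] = df["env"].str.split("|", expand=True)
        df["trait"] = spec.name
        frames.append(df[MET_COLUMNS])
        planted["traits"][spec.name] = {
            "mean": spec.mean,
            "genotype_effects": pd.Series(g_eff, index=gens),
            "interaction": pd.DataFrame(
                gei, index=gens, columns=[f"{c}|{s}" for c, s in envs]
            ),
            "block_effects": blocks,
            "singular_values": np.asarray(spec.gei_sv, dtype=float),
            "stress_factors": pd.DataFrame(
                factors, index=gens, columns=[f"{c}|{s}" for c, s in envs]
            ),
            "sense": spec.sense,
        }
    if n_truncated:
        logger.info("truncated %d non-positive values at 1e-6", n_truncated)
    data = pd.concat(frames, ignore_index=True)
    ds = METDataset(data, planted=planted)
    ds.validate()
    return ds


def default_trait_specs(
    n_traits: int = 20, seed: int = 0
) -> tuple[TraitSpec, ...]:
    """Trait battery emulating the 20-trait wheat panel.

    Grand means near 1 on the ratio scale is not assumed here — raw trait
    values are on arbitrary positive scales; moderate genotypic and residual
    variation and a rank-2 interaction are planted per trait.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_traits):
        mean = float(rng.uniform(5.0, 50.0))
        specs.append(
            TraitSpec(
                name=f"T{i + 1:02d}" if i < n_traits - 1 else "GY",
                mean=mean,
                sd_g=0.08 * mean,
                sd_res=0.05 * mean,
                sd_block=0.02 * mean,
                gei_sv=(0.5 * mean, 0.25 * mean),
                sense="decrease" if i % 7 == 3 else "increase",
            )
        )
    return tuple(specs)


def default_config(seed: int = 0, n_traits: int = 20) -> SimConfig:
    """The study-design defaults: 20 genotypes, 3 seasons, optimal/drought/
    heat, 3 replicates, 20 traits, 5 tolerance groups."""
    return SimConfig(
        n_genotypes=20,
        seasons=("S1", "S2", "S3"),
        conditions=(OPTIMAL, "drought", "heat"),
        n_reps=3,
        traits=default_trait_specs(n_traits=n_traits, seed=seed + 1),
        group_effects={
            "HT": {"drought": 0.92, "heat": 0.87},
            "T": {"drought": 0.85, "heat": 0.81},
            "M": {"drought": 0.78, "heat": 0.74},
            "S": {"drought": 0.70, "heat": 0.64},
            "HS": {"drought": 0.60, "heat": 0.52},
        },
        seed=seed,
    )
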