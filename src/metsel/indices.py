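"""Drought/heat tolerance multi-indices.

For every trait, genotype, season and replicate the tolerance index is the
ratio of the value under a stress condition to the value under the optimal
condition of the same season and replicate block:

    DTI = x_drought / x_optimal        HTI = x_heat / x_optimal

Each (stress condition, season) pair becomes one derived *index environment*
E1, E2, ... labelled season-major with drought before heat, so a three-season
drought+heat trial yields exactly six index environments.  The index is
formed per replicate (stress block k against optimal block k), which keeps a
replicate-within-environment stratum in the joint ANOVA of the indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BalanceError, DomainError
from .simulate import METDataset, OPTIMAL

INDEX_COLUMNS = ["genotype", "env", "rep", "trait", "value"]

#: preferred order of stress conditions within a season
STRESS_ORDER = ("drought", "heat")


def tolerance_index(x_stress, x_optimal, context: str = ""):
    """Ratio of a trait value under stress to its optimal-condition value.

    Raises :class:`DomainError` when the optimal value is not positive.
    """
    x_stress = np.asarray(x_stress, dtype=float)
    x_optimal = np.asarray(x_optimal, dtype=float)
    if np.any(x_optimal <= 0):
        where = np.argwhere(np.atleast_1d(x_optimal <= 0)).ravel()[:5].tolist()
        raise DomainError(
            f"optimal value <= 0 at {context or 'positions'} {where}; "
            "tolerance index undefined"
        )
    out = x_stress / x_optimal
    return float(out) if out.ndim == 0 else out


@dataclass
class IndexTable:
    """Per-replicate tolerance indices over the derived index environments.

    ``env_map`` maps each environment code to its (stress condition, season).
    """

    data: pd.DataFrame
    env_map: dict[str, tuple[str, str]]

    @property
    def environments(self) -> list[str]:
        return list(self.env_map)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def n_reps(self) -> int:
        return self.data["rep"].nunique()

    def trait_frame(self, trait: str) -> pd.DataFrame:
        sel = self.data[self.data["trait"] == trait]
        if sel.empty:
            raise KeyError(f"unknown trait {trait!r}")
        return sel

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def env_map_json(self) -> str:
        return json.dumps(
            {e: {"stress": c, "season": s} for e, (c, s) in self.env_map.items()},
            indent=2,
        )


def build_index_environments(
    met: METDataset, optimal: str = OPTIMAL
) -> IndexTable:
    """Convert raw trial values into the tolerance-index environments.

    Environment codes are assigned season-major (seasons in sorted,
    i.e. chronological-label, order) with drought before heat within each
    season.  Every stress replicate is paired with the same-numbered optimal
    replicate of its season; a missing optimal counterpart raises
    :class:`BalanceError`.
    """
    data = met.data
    conditions = set(data["condition"].unique())
    if optimal not in conditions:
        raise BalanceError([], f"no {optimal!r} condition present")
    stresses = [c for c in STRESS_ORDER if c in conditions]
    stresses += sorted(c for c in conditions - {optimal} - set(STRESS_ORDER))
    seasons = sorted(data["season"].unique())

    key = ["genotype", "season", "rep", "trait"]
    wide = data.pivot_table(
        index=key, columns="condition", values="value", aggfunc="first"
    )
    if wide[optimal].isna().any():
        missing = wide.index[wide[optimal].isna()].tolist()
        raise BalanceError(missing, "missing optimal counterpart")

    env_map: dict[str, tuple[str, str]] = {}
    frames = []
    code = 1
    for season in seasons:
        for stress in stresses:
            env = f"E{code}"
            env_map[env] = (stress, season)
            code += 1
            sub = wide.xs(season, level="season")[[optimal, stress]]
            if sub[stress].isna().any():
                missing = sub.index[sub[stress].isna()].tolist()
                raise BalanceError(missing, f"missing {stress} cells")
            vals = tolerance_index(
                sub[stress].to_numpy(), sub[optimal].to_numpy(),
                context=f"{stress}/{season}",
            )
            out = sub.reset_index()[["genotype", "rep", "trait"]]
            out.insert(1, "env", env)
            out["value"] = vals
            frames.append(out[INDEX_COLUMNS])
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(INDEX_COLUMNS[:4], kind="stable").reset_index(
        drop=True
    )
    return IndexTable(table, env_map)
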