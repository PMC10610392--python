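import numpy as np
import pandas as pd
import pytest

from metsel.indices import IndexTable
from metsel.simulate import METDataset, SimConfig, TraitSpec, generate_met


def make_config(
    n_genotypes=6,
    seasons=("S1", "S2", "S3"),
    conditions=("optimal", "drought", "heat"),
    n_reps=3,
    traits=None,
    group_effects=None,
    seed=0,
):
    traits = traits or (TraitSpec(name="GY", mean=10.0, sd_g=0.8,
                                  sd_res=0.5, sd_block=0.2,
                                  gei_sv=(4.0, 2.0)),)
    return SimConfig(
        n_genotypes=n_genotypes,
        seasons=tuple(seasons),
        conditions=tuple(conditions),
        n_reps=n_reps,
        traits=tuple(traits),
        group_effects=group_effects or {"all": 1.0},
        seed=seed,
    )


def synthetic_index_table(
    g=20, e=6, r=3, trait="GY", sigma_g=0.0, sigma_ge=0.0, sigma_e=1.0,
    mu=1.0, seed=0,
) -> IndexTable:
    """Balanced index table generated directly from variance components:
    y_ijk = mu + G_i + GE_ij + eps_ijk (no environment main effect)."""
    rng = np.random.default_rng(seed)
    gens = [f"G{i + 1:02d}" for i in range(g)]
    envs = [f"E{j + 1}" for j in range(e)]
    gi = rng.normal(0, np.sqrt(sigma_g), g) if sigma_g else np.zeros(g)
    ge = (
        rng.normal(0, np.sqrt(sigma_ge), (g, e))
        if sigma_ge
        else np.zeros((g, e))
    )
    eps = (
        rng.normal(0, np.sqrt(sigma_e), (g, e, r))
        if sigma_e
        else np.zeros((g, e, r))
    )
    y = mu + gi[:, None, None] + ge[:, :, None] + eps
    idx = pd.MultiIndex.from_product(
        [gens, envs, range(1, r + 1)], names=["genotype", "env", "rep"]
    )
    df = pd.DataFrame({"value": y.ravel()}, index=idx).reset_index()
    df["trait"] = trait
    env_map = {env: ("drought" if j % 2 == 0 else "heat", f"S{j // 2 + 1}")
               for j, env in enumerate(envs)}
    return IndexTable(df[["genotype", "env", "rep", "trait", "value"]],
                      env_map)


@pytest.fixture
def noise_free_met() -> METDataset:
    cfg = make_config(
        traits=(TraitSpec(name="GY", mean=10.0, sd_g=1.0),),
        group_effects={"tol": 0.8, "sens": 0.6},
        seed=3,
    )
    return generate_met(cfg)


@pytest.fixture
def small_met() -> METDataset:
    cfg = make_config(
        n_genotypes=8,
        traits=(
            TraitSpec(name="GY", mean=10.0, sd_g=0.8, sd_res=0.4,
                      sd_block=0.2, gei_sv=(3.0, 1.5)),
            TraitSpec(name="CT", mean=30.0, sd_g=1.5, sd_res=0.8,
                      sense="decrease"),
        ),
        group_effects={"tol": 0.85, "sens": 0.65},
        seed=11,
    )
    return generate_met(cfg)
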