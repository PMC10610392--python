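"""Packaged worked-example data.

The fixtures transcribe the published summary tables of a 20-genotype wheat
multi-stress trial (three seasons, optimal/drought/heat conditions): the
WAASB score table with five interaction axes, the AMMI analysis-of-variance
table for the grain-yield tolerance index, the stepwise-regression table with
its four retained predictor indices and per-genotype diagnostics, the prior
and posterior tolerance-category labels, and the factor-analysis eigenvalues.
They let the worked-example tests and the acceptance script run offline from
printed inputs alone.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

IPCA_COLUMNS = ["IPC1", "IPC2", "IPC3", "IPC4", "IPC5"]


def _path(name: str):
    return resources.files("metsel.fixtures").joinpath(name)


def load_waasb_scores() -> pd.DataFrame:
    """Printed mean performance, IPCA scores, WAASB values and ranks.

    Returns a frame indexed by code (G01..G20, E1..E6) with a ``side`` column
    distinguishing genotype from environment rows.
    """
    with _path("wheat_waasb_scores.csv").open() as fh:
        return pd.read_csv(fh).set_index("code")


def load_ammi_anova() -> pd.DataFrame:
    """Printed AMMI ANOVA for the grain-yield tolerance index."""
    with _path("wheat_ammi_anova.csv").open() as fh:
        return pd.read_csv(fh).set_index("source")


def axis_proportions() -> pd.Series:
    """Percent of interaction sum of squares per IPCA axis, as printed."""
    tab = load_ammi_anova()
    return tab.loc[IPCA_COLUMNS, "proportion"].astype(float)


def load_smlr_table() -> pd.DataFrame:
    """Per-genotype predictor indices, observed/predicted grain-yield index,
    diagnostics and tolerance-category labels."""
    with _path("wheat_smlr.csv").open() as fh:
        return pd.read_csv(fh).set_index("genotype")


def load_smlr_model() -> dict:
    """The printed stepwise model: intercept, coefficients, partial R²."""
    with _path("wheat_smlr_model.json").open() as fh:
        return json.load(fh)


def load_fa_eigenvalues(trait_set: str = "gy_related") -> pd.Series:
    """Printed correlation-matrix eigenvalues ('all' or 'gy_related')."""
    with _path("wheat_fa_eigenvalues.csv").open() as fh:
        tab = pd.read_csv(fh)
    sel = tab[tab["trait_set"] == trait_set]
    if sel.empty:
        raise KeyError(f"unknown trait_set {trait_set!r}")
    return sel.set_index("component")["eigenvalue"]
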