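"""WAASB stability index, WAASBY joint index and quadrant classification.

WAASB_i is the weighted average of the absolute interaction-axis scores of
genotype (or environment) i, weighted by each axis's explained proportion of
the interaction sum of squares:

    WAASB_i = sum_k |score_ik| * EP_k / sum_k EP_k

Lower WAASB means more stable.  By default the decomposition input is the
BLUP-shrunken G x E interaction matrix; a fixed-effects variant decomposes
the raw centered means.  WAASBY combines 0-100 rescaled mean performance
(rY) and rescaled stability (rW, reversed so that stable = 100) with weights
theta_Y + theta_S.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .ammi import AMMI, AMMIResults
from .anova import BlupSet
from .errors import DomainError
from .indices import IndexTable


def _weighted_abs_scores(
    scores: pd.DataFrame, proportions: pd.Series, n_axes
) -> pd.Series:
    if n_axes == "all":
        n_axes = scores.shape[1]
    if not 1 <= n_axes <= scores.shape[1]:
        raise ValueError(f"n_axes must be in 1..{scores.shape[1]}")
    cols = scores.columns[:n_axes]
    w = proportions[cols].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise DomainError("all axis proportions are zero (no interaction)")
    vals = np.abs(scores[cols].to_numpy()) @ w / w.sum()
    return pd.Series(vals, index=scores.index)


def _rank_ascending(values: pd.Series) -> pd.Series:
    """Dense 1..n ranks, ties broken by label order (stable sort)."""
    order = values.sort_index().sort_values(kind="stable").index
    return pd.Series(np.arange(1, len(order) + 1), index=order).reindex(
        values.index
    )


@dataclass
class WAASBResult:
    """WAASB values and ranks for genotypes and environments."""

    genotypes: pd.DataFrame      # columns: Y, IPC..., waasb, rank
    environments: pd.DataFrame
    proportions: pd.Series
    source: str = "blup"         # 'blup' or 'fixed'

    def summary(self) -> str:
        return (
            f"WAASB ({self.source} interaction matrix, "
            f"{len(self.proportions)} axes)\n"
            + self.genotypes.to_string(float_format=lambda v: f"{v:.3f}")
            + "\n"
            + self.environments.to_string(float_format=lambda v: f"{v:.3f}")
        )


def waasb_scores(
    decomp: AMMIResults,
    n_axes="all",
    genotype_means: pd.Series | None = None,
    environment_means: pd.Series | None = None,
    source: str = "fixed",
) -> WAASBResult:
    """WAASB values for genotypes and environments from a decomposition.

    ``genotype_means``/``environment_means`` override the decomposition's
    additive means (used when the decomposition ran on a BLUP interaction
    matrix, whose own means are zero).
    """
    gmeans = (
        decomp.genotype_means if genotype_means is None else genotype_means
    )
    emeans = (
        decomp.environment_means
        if environment_means is None
        else environment_means
    )
    out = {}
    for side, scores, means in (
        ("genotypes", decomp.genotype_scores, gmeans),
        ("environments", decomp.environment_scores, emeans),
    ):
        w = _weighted_abs_scores(scores, decomp.proportions, n_axes)
        frame = scores.copy()
        frame.insert(0, "Y", means)
        frame["waasb"] = w
        frame["rank"] = _rank_ascending(w)
        out[side] = frame
    return WAASBResult(
        out["genotypes"], out["environments"], decomp.proportions.copy(),
        source=source,
    )


def waasb_from_scores(
    scores: pd.DataFrame, proportions: pd.Series, n_axes="all"
) -> pd.Series:
    """WAASB values directly from a table of axis scores and the per-axis
    explained proportions (e.g. from a published score table)."""
    return _weighted_abs_scores(scores, proportions, n_axes)


def waasb_from_index_table(
    table: IndexTable,
    trait: str,
    blup: BlupSet | None = None,
    n_axes="all",
) -> WAASBResult:
    """End-to-end WAASB for one trait.

    With ``blup`` given (the default pipeline path) the decomposition runs on
    the BLUP-shrunken interaction matrix; otherwise on the raw centered
    genotype x environment means (fixed-effects variant).
    """
    from .ammi import two_way_means

    means = two_way_means(table, trait)
    if blup is None:
        decomp = AMMI(means).fit()
        return waasb_scores(decomp, n_axes, source="fixed")
    decomp = AMMI.from_interaction(blup.ge_matrix).fit()
    return waasb_scores(
        decomp,
        n_axes,
        genotype_means=means.mean(axis=1),
        environment_means=means.mean(axis=0),
        source="blup",
    )


@dataclass
class WAASBYResult:
    table: pd.DataFrame          # rY, rW, waasby, rank per genotype
    theta_y: float
    theta_s: float
    flags: list

    def summary(self) -> str:
        return (
            f"WAASBY (theta_Y={self.theta_y:g}, theta_S={self.theta_s:g})\n"
            + self.table.to_string(float_format=lambda v: f"{v:.2f}")
        )


def _rescale_0_100(x: pd.Series, higher_better: bool) -> tuple[pd.Series, bool]:
    rng = x.max() - x.min()
    if rng == 0:
        return pd.Series(100.0, index=x.index), True
    if higher_better:
        return 100.0 * (x - x.min()) / rng, False
    return 100.0 * (x.max() - x) / rng, False


def waasby(
    result: WAASBResult,
    theta_y: float = 50.0,
    theta_s: float = 50.0,
    sense: str = "increase",
) -> WAASBYResult:
    """Joint performance/stability index on the 0-100 scale.

    theta_y weights rescaled mean performance, theta_s rescaled stability
    (lower WAASB -> higher rW); theta_y = 100 reduces the ranking to mean
    performance, theta_s = 100 to stability alone.
    """
    if theta_y < 0 or theta_s < 0 or theta_y + theta_s == 0:
        raise ValueError("weights must be >= 0 and not both 0")
    gt = result.genotypes
    flags = []
    ry, deg_y = _rescale_0_100(gt["Y"], higher_better=sense == "increase")
    rw, deg_w = _rescale_0_100(gt["waasb"], higher_better=False)
    if deg_y:
        flags.append("constant performance: rY set to 100 for all")
        warnings.warn(flags[-1])
    if deg_w:
        flags.append("constant stability: rW set to 100 for all")
        warnings.warn(flags[-1])
    score = (ry * theta_y + rw * theta_s) / (theta_y + theta_s)
    table = pd.DataFrame(
        {"Y": gt["Y"], "waasb": gt["waasb"], "rY": ry, "rW": rw,
         "waasby": score}
    )
    table["rank"] = _rank_ascending(-score)
    return WAASBYResult(table, theta_y, theta_s, flags)


def classify_quadrants(
    means: pd.Series,
    waasb: pd.Series,
    x_cut: float | None = None,
    y_cut: float | None = None,
) -> pd.DataFrame:
    """Four-quadrant reading of the performance x WAASB biplot.

    I: low performance, high WAASB; II: high/high; III: low/low;
    IV: high performance, low WAASB (the stable high performers).
    Items exactly on a cut go to the lower side and are flagged.
    """
    x_cut = float(means.mean()) if x_cut is None else float(x_cut)
    y_cut = float(waasb.mean()) if y_cut is None else float(y_cut)
    if not (np.isfinite(x_cut) and np.isfinite(y_cut)):
        raise ValueError("cut points must be finite")
    hi_y = means > x_cut
    hi_w = waasb > y_cut
    quad = np.where(
        hi_y, np.where(hi_w, "II", "IV"), np.where(hi_w, "I", "III")
    )
    on_cut = (means == x_cut) | (waasb == y_cut)
    return pd.DataFrame(
        {
            "Y": means,
            "waasb": waasb,
            "quadrant": quad,
            "on_cut": on_cut,
        },
        index=means.index,
    )
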