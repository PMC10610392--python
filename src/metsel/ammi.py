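"""AMMI: additive main effects and multiplicative interaction.

The genotype-by-environment means table y_ij is decomposed as

    y_ij = mu + a_i + b_j + sum_k lambda_k u_ik v_jk + rho_ij

where the multiplicative terms come from the SVD of the double-centered
interaction matrix GEI_ij = y_ij - ybar_i. - ybar_.j + mu.  Scores are
symmetric-scaled (both sides carry sqrt(lambda_k)), axes are ordered by
descending singular value, and the per-axis explained proportion is
lambda_k^2 / sum lambda^2.  The multiplicative-term ANOVA assigns Gollob
degrees of freedom g + e - 1 - 2k to axis k and tests r*lambda_k^2 against
the replicate-level residual mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BalanceError, ConsistencyError
from .indices import IndexTable


def two_way_means(table: IndexTable, trait: str) -> pd.DataFrame:
    """Genotype x environment table of replicate means for one trait."""
    df = table.trait_frame(trait)
    piv = df.pivot_table(index="genotype", columns="env", values="value",
                         aggfunc="mean")
    piv = piv.reindex(columns=table.environments)
    if piv.isna().any().any():
        missing = [
            (g, e)
            for g in piv.index
            for e in piv.columns
            if pd.isna(piv.loc[g, e])
        ]
        raise BalanceError(missing, "missing genotype x environment cells")
    piv.columns.name = None
    piv.index.name = "genotype"
    return piv


def gollob_df(g: int, e: int, k: int) -> int:
    """Degrees of freedom of the k-th multiplicative axis (1-based)."""
    return g + e - 1 - 2 * k


class AMMI:
    """AMMI model for a complete genotype x environment means table.

    Accepts the means table directly or builds it from an
    :class:`~metsel.indices.IndexTable` via :meth:`from_index_table`.
    ``fit()`` returns an :class:`AMMIResults`.
    """

    def __init__(self, table: pd.DataFrame):
        table = pd.DataFrame(table, dtype=float)
        if table.isna().any().any():
            raise BalanceError([], "means table has missing cells")
        self.table = table

    @classmethod
    def from_index_table(cls, table: IndexTable, trait: str) -> "AMMI":
        return cls(two_way_means(table, trait))

    @classmethod
    def from_interaction(cls, gei: pd.DataFrame) -> "AMMI":
        """Model an already-centered interaction matrix (e.g. a BLUP G x E
        matrix); main effects are zero by construction."""
        model = cls(pd.DataFrame(gei, dtype=float))
        model._interaction_only = True
        return model

    def fit(self) -> "AMMIResults":
        y = self.table.to_numpy()
        g, e = y.shape
        mu = y.mean()
        row = y.mean(axis=1)
        col = y.mean(axis=0)
        gei = y - row[:, None] - col[None, :] + mu
        u, lam, vt = np.linalg.svd(gei, full_matrices=False)
        rank = min(g - 1, e - 1)
        u, lam, v = u[:, :rank], lam[:rank], vt[:rank].T
        # sign convention: largest-|loading| environment coordinate positive
        for k in range(rank):
            j = np.argmax(np.abs(v[:, k]))
            if v[j, k] < 0:
                u[:, k] *= -1
                v[:, k] *= -1
        sq = np.sqrt(lam)
        gscores = u * sq
        escores = v * sq
        ss = lam**2
        total = ss.sum()
        prop = 100 * ss / total if total > 0 else np.zeros_like(ss)
        axes = [f"IPC{k + 1}" for k in range(rank)]
        return AMMIResults(
            model=self,
            grand_mean=float(mu),
            genotype_means=pd.Series(row, index=self.table.index),
            environment_means=pd.Series(col, index=self.table.columns),
            interaction=pd.DataFrame(
                gei, index=self.table.index, columns=self.table.columns
            ),
            singular_values=pd.Series(lam, index=axes),
            genotype_scores=pd.DataFrame(
                gscores, index=self.table.index, columns=axes
            ),
            environment_scores=pd.DataFrame(
                escores, index=self.table.columns, columns=axes
            ),
            proportions=pd.Series(prop, index=axes),
        )


@dataclass
class AMMIResults:
    """Symmetric-scaled SVD of the double-centered interaction matrix."""

    model: AMMI
    grand_mean: float
    genotype_means: pd.Series
    environment_means: pd.Series
    interaction: pd.DataFrame
    singular_values: pd.Series
    genotype_scores: pd.DataFrame
    environment_scores: pd.DataFrame
    proportions: pd.Series          # percent per axis, sums to 100

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    @property
    def accumulated(self) -> pd.Series:
        return self.proportions.cumsum()

    def predict(self, n_terms: int) -> pd.DataFrame:
        """AMMI(n) fitted means: additive part plus the first n
        multiplicative terms.  n equal to the full rank reproduces the
        observed means table."""
        if not 0 <= n_terms <= self.n_axes:
            raise ValueError(
                f"n_terms must be in [0, {self.n_axes}], got {n_terms}"
            )
        add = (
            self.genotype_means.to_numpy()[:, None]
            + self.environment_means.to_numpy()[None, :]
            - self.grand_mean
        )
        mult = (
            self.genotype_scores.iloc[:, :n_terms].to_numpy()
            @ self.environment_scores.iloc[:, :n_terms].to_numpy().T
        )
        return pd.DataFrame(
            add + mult,
            index=self.genotype_means.index,
            columns=self.environment_means.index,
        )

    def anova(self, anova_table: pd.DataFrame, r: int) -> pd.DataFrame:
        """Extend a replicate-level joint ANOVA with one row per axis.

        SS per axis is r * lambda_k^2 (replicate scale), df is Gollob's
        g + e - 1 - 2k, and F tests against the residual mean square.
        """
        g = len(self.genotype_means)
        e = len(self.environment_means)
        if anova_table.loc["GEN", "df"] != g - 1 or (
            anova_table.loc["GEN:ENV", "df"] != (g - 1) * (e - 1)
        ):
            raise ConsistencyError(
                "ANOVA table degrees of freedom do not match the means table"
            )
        exp_rep_df = e * (r - 1)
        if anova_table.loc["REP(ENV)", "df"] != exp_rep_df:
            raise ConsistencyError(
                f"replicate count r={r} inconsistent with REP(ENV) df "
                f"{anova_table.loc['REP(ENV)', 'df']} (expected {exp_rep_df})"
            )
        ms_res = anova_table.loc["Residuals", "ms"]
        df_res = anova_table.loc["Residuals", "df"]
        rows = []
        for k, axis in enumerate(self.singular_values.index, start=1):
            dfk = gollob_df(g, e, k)
            ssk = r * self.singular_values[axis] ** 2
            msk = ssk / dfk if dfk > 0 else np.nan
            fk = msk / ms_res if ms_res > 0 else np.nan
            pk = stats.f.sf(fk, dfk, df_res) if fk == fk else np.nan
            rows.append(
                {
                    "source": axis,
                    "df": dfk,
                    "ss": ssk,
                    "ms": msk,
                    "f": fk,
                    "p": pk,
                    "proportion": self.proportions[axis],
                    "accumulated": self.accumulated[axis],
                }
            )
        ipca = pd.DataFrame(rows).set_index("source")
        base = anova_table.copy()
        base["proportion"] = np.nan
        base["accumulated"] = np.nan
        out = pd.concat(
            [base.loc[["ENV", "REP(ENV)", "GEN", "GEN:ENV"]], ipca,
             base.loc[["Residuals"]]]
        )
        total = pd.DataFrame(
            {
                "df": [base["df"].sum()],
                "ss": [base["ss"].sum()],
            },
            index=["Total"],
        )
        total["ms"] = total["ss"] / total["df"]
        return pd.concat([out, total])

    def biplot_coordinates(self, axes: tuple[int, int] = (1, 2)) -> dict:
        """Genotype/environment scores on two axes plus pairwise environment
        vector angles (degrees; > 90 reads as negative association)."""
        for a in axes:
            if not 1 <= a <= self.n_axes:
                raise ValueError(f"axis {a} outside 1..{self.n_axes}")
        cols = [f"IPC{a}" for a in axes]
        env = self.environment_scores[cols]
        vecs = env.to_numpy()
        norms = np.linalg.norm(vecs, axis=1)
        names = env.index
        angle = pd.DataFrame(0.0, index=names, columns=names)
        for i in range(len(names)):
            for j in range(len(names)):
                if norms[i] == 0 or norms[j] == 0:
                    angle.iloc[i, j] = np.nan
                    continue
                c = np.clip(
                    vecs[i] @ vecs[j] / (norms[i] * norms[j]), -1.0, 1.0
                )
                angle.iloc[i, j] = np.degrees(np.arccos(c))
        return {
            "genotypes": self.genotype_scores[cols].copy(),
            "environments": env.copy(),
            "environment_angles": angle,
        }

    def summary(self) -> str:
        tab = pd.DataFrame(
            {
                "singular_value": self.singular_values,
                "proportion_%": self.proportions,
                "accumulated_%": self.accumulated,
            }
        )
        return (
            f"AMMI decomposition (g={len(self.genotype_means)}, "
            f"e={len(self.environment_means)})\n"
            f"grand mean {self.grand_mean:.4f}\n"
            + tab.to_string(float_format=lambda v: f"{v:.4f}")
        )
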