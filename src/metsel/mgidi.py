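"""MGIDI: multi-trait genotype-ideotype distance index.

Pipeline: (1) rescale each trait's genotype means to [0, 100] so that 100 is
always the desired direction ('decrease' traits use the reversed map);
(2) exploratory factor analysis on the trait correlation matrix — retain
factors with eigenvalue > 1 (Kaiser), loadings = eigenvectors scaled by
sqrt(eigenvalue), varimax rotation with Kaiser normalization, factor scores
by the regression method F = Z R^{-1} A; (3) project the all-100 ideotype
through the same score equation and take the Euclidean distance of every
genotype to it in factor space; (4) select the round(alpha * g) closest
genotypes and report per-trait selection differentials and genetic gains
SG% = 100 * (Xs - Xo) * h2mg / Xo.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def rescale(traits: pd.DataFrame, senses: dict[str, str]) -> pd.DataFrame:
    """Linear per-trait map onto [0, 100]; 100 is the desired direction.

    Constant columns cannot be oriented and are dropped with a warning.
    """
    out = {}
    for col in traits.columns:
        x = traits[col].astype(float)
        rng = x.max() - x.min()
        if rng == 0:
            warnings.warn(f"constant trait {col!r} dropped from rescaling")
            continue
        sense = senses.get(col, "increase")
        if sense not in ("increase", "decrease"):
            raise ValueError(f"unknown sense {sense!r} for trait {col!r}")
        if sense == "increase":
            out[col] = 100.0 * (x - x.min()) / rng
        else:
            out[col] = 100.0 * (x.max() - x) / rng
    return pd.DataFrame(out, index=traits.index)


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix)."""
    A = np.asarray(loadings, dtype=float).copy()
    p, f = A.shape
    if f < 2:
        return A, np.eye(f)
    comm = np.sqrt((A**2).sum(axis=1))
    if kaiser_normalize:
        safe = np.where(comm > 0, comm, 1.0)
        A = A / safe[:, None]
    R = np.eye(f)
    d = 0.0
    for _ in range(max_iter):
        L = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    L = A @ R
    if kaiser_normalize:
        L = L * np.where(comm > 0, comm, 1.0)[:, None]
    # orient each factor so its largest-|loading| trait loads positively
    for k in range(f):
        j = np.argmax(np.abs(L[:, k]))
        if L[j, k] < 0:
            L[:, k] *= -1
            R[:, k] *= -1
    return L, R


def kaiser_retained(eigenvalues) -> int:
    """Number of factors with eigenvalue strictly greater than 1."""
    return max(int(np.sum(np.asarray(eigenvalues, dtype=float) > 1.0)), 1)


@dataclass
class FactorModel:
    """Varimax-rotated factor model of the rescaled trait matrix."""

    eigenvalues: pd.Series
    loadings: pd.DataFrame        # traits x factors, rotated
    communality: pd.Series
    uniqueness: pd.Series
    scores: pd.DataFrame          # genotypes x factors (regression method)
    column_means: pd.Series
    column_sds: pd.Series
    _rinv: np.ndarray = field(repr=False, default=None)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def project(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Score new rows (same trait columns) through the fitted equation."""
        z = (rows[self.column_means.index] - self.column_means) / self.column_sds
        f = z.to_numpy() @ self._rinv @ self.loadings.to_numpy()
        return pd.DataFrame(f, index=rows.index, columns=self.loadings.columns)


def factor_analysis(
    rescaled: pd.DataFrame, n_factors: int | None = None
) -> FactorModel:
    """Eigendecomposition of the trait correlation matrix with varimax
    rotation and regression factor scores.

    ``n_factors=None`` applies the Kaiser rule (eigenvalue > 1).  A singular
    correlation matrix gets a 1e-8 ridge (logged).
    """
    X = rescaled.astype(float)
    g, t = X.shape
    means = X.mean()
    sds = X.std(ddof=1)
    if (sds == 0).any():
        raise ValueError(
            f"constant columns in rescaled matrix: {list(sds.index[sds == 0])}"
        )
    Z = (X - means) / sds
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    eig, vec = np.linalg.eigh(R)
    order = np.argsort(eig)[::-1]
    eig, vec = np.maximum(eig[order], 0.0), vec[:, order]
    if n_factors is None:
        n_factors = kaiser_retained(eig)
    if n_factors >= g:
        raise ValueError(
            f"{n_factors} factors with only {g} genotypes; need g > factors"
        )
    A = vec[:, :n_factors] * np.sqrt(eig[:n_factors])
    L, _ = varimax(A)
    if np.linalg.cond(R) > 1e12:
        logger.info("singular correlation matrix; 1e-8 ridge added")
        R = R + 1e-8 * np.eye(t)
    rinv = np.linalg.inv(R)
    scores = Z.to_numpy() @ rinv @ L
    axes = [f"FA{k + 1}" for k in range(n_factors)]
    comm = pd.Series((L**2).sum(axis=1), index=X.columns)
    return FactorModel(
        eigenvalues=pd.Series(eig, index=range(1, t + 1)),
        loadings=pd.DataFrame(L, index=X.columns, columns=axes),
        communality=comm,
        uniqueness=1.0 - comm,
        scores=pd.DataFrame(scores, index=X.index, columns=axes),
        column_means=means,
        column_sds=sds,
        _rinv=rinv,
    )


@dataclass
class MGIDIResults:
    """Distances to the ideotype, ranking, selection and diagnostics."""

    factor_model: FactorModel
    ideotype_scores: pd.Series
    distances: pd.Series
    ranks: pd.Series
    selected: list[str]
    intensity: float
    rescaled: pd.DataFrame
    senses: dict[str, str]

    def factor_contributions(self) -> pd.DataFrame:
        """Share of each factor in each genotype's squared distance."""
        gap2 = (
            self.factor_model.scores - self.ideotype_scores
        ) ** 2
        tot = gap2.sum(axis=1)
        shares = gap2.div(tot, axis=0)
        zero = tot == 0
        if zero.any():
            warnings.warn(
                f"zero ideotype distance for {list(tot.index[zero])}; "
                "uniform factor shares assigned"
            )
            shares.loc[zero] = 1.0 / self.factor_model.n_factors
        return shares

    def selection_gains(
        self,
        raw_means: pd.DataFrame,
        h2mg,
        senses: dict[str, str] | None = None,
    ) -> pd.DataFrame:
        """Per-trait selection differential and predicted genetic gain.

        ``h2mg`` is a scalar or per-trait Series (mean-basis heritability).
        Xo is the original-population mean of each trait, Xs the selected
        mean; SG% = 100 * (Xs - Xo) * h2mg / Xo.  A gain is 'desired' when
        its sign matches the trait's sense.
        """
        if not self.selected:
            raise ValueError("selected set is empty")
        senses = self.senses if senses is None else senses
        h2 = (
            pd.Series(h2mg, index=raw_means.columns)
            if np.isscalar(h2mg)
            else pd.Series(h2mg)
        )
        factor_of = self.factor_model.loadings.abs().idxmax(axis=1)
        rows = []
        for trait in raw_means.columns:
            xo = raw_means[trait].mean()
            xs = raw_means.loc[self.selected, trait].mean()
            sd = xs - xo
            if xo == 0:
                warnings.warn(f"zero population mean for {trait!r}; gain undefined")
                sg = np.nan
            else:
                sg = 100.0 * sd * h2.get(trait, np.nan) / xo
            sense = senses.get(trait, "increase")
            desired = (sg > 0 and sense == "increase") or (
                sg < 0 and sense == "decrease"
            )
            rows.append(
                {
                    "factor": factor_of.get(trait, ""),
                    "trait": trait,
                    "Xo": xo,
                    "Xs": xs,
                    "SD": sd,
                    "SG%": sg,
                    "sense": sense,
                    "desired": desired,
                }
            )
        out = pd.DataFrame(rows).set_index("trait")
        out.attrs["total_increase"] = float(
            out.loc[out["sense"] == "increase", "SG%"].sum()
        )
        out.attrs["total_decrease"] = float(
            out.loc[out["sense"] == "decrease", "SG%"].sum()
        )
        out.attrs["heritability_basis"] = "h2mg (genotype-mean basis)"
        return out

    def summary(self) -> str:
        lines = [
            f"MGIDI — {self.factor_model.n_factors} factors, "
            f"intensity {self.intensity:.0%}",
            f"selected: {', '.join(self.selected)}",
            pd.DataFrame(
                {"MGIDI": self.distances, "rank": self.ranks}
            ).to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


class MGIDI:
    """Model object: genotype x trait means plus per-trait senses.

    ``fit(intensity)`` rescales, fits the factor model and returns an
    :class:`MGIDIResults`.
    """

    def __init__(
        self,
        trait_means: pd.DataFrame,
        senses: dict[str, str] | None = None,
        n_factors: int | None = None,
    ):
        self.trait_means = trait_means
        self.senses = senses or {}
        self.n_factors = n_factors

    def fit(self, intensity: float = 0.20) -> MGIDIResults:
        if not 0 < intensity <= 1:
            raise ValueError("selection intensity must be in (0, 1]")
        scaled = rescale(self.trait_means, self.senses)
        model = factor_analysis(scaled, self.n_factors)
        ideal = pd.DataFrame(
            100.0, index=["ideotype"], columns=scaled.columns
        )
        ideo = model.project(ideal).iloc[0]
        gaps = model.scores - ideo
        dist = pd.Series(
            np.sqrt((gaps**2).sum(axis=1)), index=model.scores.index
        )
        order = dist.sort_index().sort_values(kind="stable").index
        ranks = pd.Series(
            np.arange(1, len(order) + 1), index=order
        ).reindex(dist.index)
        n_sel = max(int(round(intensity * len(dist))), 1)
        selected = list(order[:n_sel])
        return MGIDIResults(
            factor_model=model,
            ideotype_scores=ideo,
            distances=dist,
            ranks=ranks,
            selected=selected,
            intensity=intensity,
            rescaled=scaled,
            senses=dict(self.senses),
        )
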