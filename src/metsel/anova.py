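"""Joint ANOVA of tolerance indices, variance components, quantitative-genetic
parameters and BLUPs.

The observation model for one trait's index over genotypes (i), index
environments (j) and replicate blocks (k) is

    y_ijk = mu + G_i + E_j + R_k(j) + GE_ij + eps_ijk

For the F-tests genotypes are treated as fixed (GEN and GEN:ENV tested
against the pooled residual, ENV against blocks-within-environment); for
variance components, heritabilities and BLUPs genotypes are random.  On a
balanced design the ANOVA (method-of-moments) estimators coincide with REML
whenever the solution is interior; REML here maximizes the restricted
likelihood in its stratum form, sum_s [df_s log(theta_s) + SS_s/theta_s],
subject to non-negative components.

BLUPs use the balanced-design closed form: the genotype effect shrinks the
centered genotype mean by h2_mg = s2_g / (s2_g + s2_ge/e + s2_eps/(e r)),
and each interaction cell shrinks the double-centered cell mean by
s2_ge / (s2_ge + s2_eps/r).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import BalanceError
from .indices import IndexTable

logger = logging.getLogger(__name__)

SOURCES = ["ENV", "REP(ENV)", "GEN", "GEN:ENV", "Residuals"]


def _trait_cube(table: IndexTable, trait: str) -> tuple[np.ndarray, list, list]:
    """Return the g x e x r value cube and its labels; check balance."""
    df = table.trait_frame(trait)
    gens = sorted(df["genotype"].unique())
    envs = table.environments
    reps = sorted(df["rep"].unique())
    piv = df.set_index(["genotype", "env", "rep"])["value"]
    if piv.index.has_duplicates:
        raise BalanceError([], "duplicate cells in index table")
    full = pd.MultiIndex.from_product([gens, envs, reps])
    missing = full.difference(piv.index)
    if len(missing):
        raise BalanceError(missing.tolist())
    cube = piv.reindex(full).to_numpy().reshape(len(gens), len(envs), len(reps))
    return cube, gens, envs


def joint_anova(table: IndexTable, trait: str) -> pd.DataFrame:
    """Joint (pooled over seasons and stresses) ANOVA for one trait's index.

    Returns a frame indexed by source with df, ss, ms, f and p columns.
    GEN and GEN:ENV are tested against the residual mean square, ENV against
    the replicate-within-environment mean square.
    """
    y, gens, envs = _trait_cube(table, trait)
    g, e, r = y.shape
    grand = y.mean()
    env_means = y.mean(axis=(0, 2))
    gen_means = y.mean(axis=(1, 2))
    cell_means = y.mean(axis=2)          # g x e
    block_means = y.mean(axis=0)         # e x r

    ss_env = g * r * np.sum((env_means - grand) ** 2)
    ss_rep = g * np.sum((block_means - env_means[:, None]) ** 2)
    ss_gen = e * r * np.sum((gen_means - grand) ** 2)
    ss_ge = r * np.sum(
        (cell_means - gen_means[:, None] - env_means[None, :] + grand) ** 2
    )
    ss_tot = np.sum((y - grand) ** 2)
    ss_res = ss_tot - ss_env - ss_rep - ss_gen - ss_ge

    df = {
        "ENV": e - 1,
        "REP(ENV)": e * (r - 1),
        "GEN": g - 1,
        "GEN:ENV": (g - 1) * (e - 1),
        "Residuals": (g - 1) * e * (r - 1),
    }
    ss = {
        "ENV": ss_env,
        "REP(ENV)": ss_rep,
        "GEN": ss_gen,
        "GEN:ENV": ss_ge,
        "Residuals": max(ss_res, 0.0),
    }
    ms = {k: ss[k] / df[k] if df[k] else np.nan for k in ss}

    def ftest(num, den):
        if ms[den] <= 0:
            return np.nan, np.nan
        f = ms[num] / ms[den]
        return f, stats.f.sf(f, df[num], df[den])

    out = pd.DataFrame(index=SOURCES, columns=["df", "ss", "ms", "f", "p"],
                       dtype=float)
    for k in SOURCES:
        out.loc[k, ["df", "ss", "ms"]] = df[k], ss[k], ms[k]
    out.loc["ENV", ["f", "p"]] = ftest("ENV", "REP(ENV)")
    out.loc["GEN", ["f", "p"]] = ftest("GEN", "Residuals")
    out.loc["GEN:ENV", ["f", "p"]] = ftest("GEN:ENV", "Residuals")
    out["df"] = out["df"].astype(int)
    out.attrs["design"] = {"g": g, "e": e, "r": r, "grand_mean": float(grand)}
    return out


def pretests(table: IndexTable, trait: str) -> tuple[float, float]:
    """Shapiro–Wilk normality p on full-model residuals and Bartlett
    homogeneity p across environments.  Diagnostic only; returns (nan, nan)
    with a warning on constant data."""
    y, _, _ = _trait_cube(table, trait)
    g, e, r = y.shape
    cell = y.mean(axis=2, keepdims=True)
    block = y.mean(axis=0, keepdims=True) - y.mean(axis=(0, 2))[None, :, None]
    resid = (y - cell - block).ravel()
    if np.ptp(y) == 0 or np.allclose(resid, 0):
        warnings.warn("constant or noise-free data; pretests skipped")
        return float("nan"), float("nan")
    sw = stats.shapiro(resid if resid.size <= 5000 else resid[:5000])
    groups = [y[:, j, :].ravel() for j in range(e)]
    if np.ptp([gp.var(ddof=1) for gp in groups]) == 0:
        bart_p = 1.0
    else:
        bart_p = stats.bartlett(*groups).pvalue
    return float(sw.pvalue), float(bart_p)


@dataclass
class VarianceComponents:
    """Genotypic, interaction and residual variances (squared index units)."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    truncated: list[str] = field(default_factory=list)

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_ge + self.sigma2_e

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "GEN": self.sigma2_g,
                "GEN:ENV": self.sigma2_ge,
                "Residual": self.sigma2_e,
                "Phenotypic": self.sigma2_p,
            }
        )


def variance_components(
    anova: pd.DataFrame, g: int, e: int, r: int
) -> VarianceComponents:
    """Method-of-moments components from expected mean squares (genotypes
    random).  Negative solutions are truncated at zero and flagged."""
    ms_res = anova.loc["Residuals", "ms"]
    ms_ge = anova.loc["GEN:ENV", "ms"]
    ms_g = anova.loc["GEN", "ms"]
    raw = {
        "sigma2_e": ms_res,
        "sigma2_ge": (ms_ge - ms_res) / r,
        "sigma2_g": (ms_g - ms_ge) / (r * e),
    }
    truncated = [k for k, v in raw.items() if v < 0]
    if truncated:
        logger.info("variance components truncated at 0: %s", truncated)
    return VarianceComponents(
        sigma2_g=max(raw["sigma2_g"], 0.0),
        sigma2_ge=max(raw["sigma2_ge"], 0.0),
        sigma2_e=max(raw["sigma2_e"], 0.0),
        truncated=truncated,
    )


def reml_components(
    anova: pd.DataFrame, g: int, e: int, r: int
) -> VarianceComponents:
    """REML components via the balanced-design stratum likelihood.

    Minimizes sum_s df_s log(theta_s) + SS_s / theta_s over non-negative
    (s2_g, s2_ge, s2_eps) where theta_GEN = s2_eps + r s2_ge + r e s2_g,
    theta_GE = s2_eps + r s2_ge, theta_res = s2_eps.  Coincides with the
    method-of-moments solution whenever that solution is interior.
    """
    ss = anova["ss"]
    dfs = anova["df"]
    strata = [
        ("GEN", np.array([r * e, r, 1.0])),
        ("GEN:ENV", np.array([0.0, r, 1.0])),
        ("Residuals", np.array([0.0, 0.0, 1.0])),
    ]
    if ss[[s for s, _ in strata]].max() <= 0:
        return VarianceComponents(0.0, 0.0, 0.0, truncated=["degenerate"])

    def nll(x):
        tot = 0.0
        for name, coef in strata:
            theta = coef @ x
            if theta <= 0:
                return np.inf
            tot += dfs[name] * np.log(theta) + ss[name] / theta
        return tot

    mom = variance_components(anova, g, e, r)
    x0 = np.maximum(
        [mom.sigma2_g, mom.sigma2_ge, mom.sigma2_e], 1e-10
    )
    scale = max(x0.max(), 1e-8)
    res = optimize.minimize(
        lambda z: nll(z * scale),
        x0 / scale,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000},
    )
    x = np.maximum(res.x * scale, 0.0)
    truncated = [n for n, v in zip(["sigma2_g", "sigma2_ge", "sigma2_e"], x)
                 if v <= 1e-12]
    return VarianceComponents(x[0], x[1], x[2], truncated=truncated)


@dataclass
class GeneticParameters:
    """Broad-sense heritability and companions, all dimensionless except the
    CVs (percent of the grand mean)."""

    H2: float
    R2gei: float
    h2mg: float
    accuracy: float
    rge: float
    CVg: float
    CVr: float
    CV_ratio: float
    flags: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "Heritability": self.H2,
                "R2gei": self.R2gei,
                "h2mg": self.h2mg,
                "Accuracy": self.accuracy,
                "rge": self.rge,
                "CVg": self.CVg,
                "CVr": self.CVr,
                "CV ratio": self.CV_ratio,
            }
        )


def genetic_parameters(
    vc: VarianceComponents, e: int, r: int, grand_mean: float
) -> GeneticParameters:
    """Quantitative-genetic parameters from variance components.

    H2 is plot-basis heritability, h2mg the genotype-mean-basis
    heritability over e environments and r replicates, accuracy its square
    root, rge the genotype-environment correlation, and the CVs are
    genotypic/residual coefficients of variation in percent.
    """
    flags = []
    if vc.sigma2_p <= 0:
        flags.append("sigma2_p=0: ratios undefined")
        nan = float("nan")
        return GeneticParameters(nan, nan, nan, nan, nan, nan, nan, nan, flags)
    H2 = vc.sigma2_g / vc.sigma2_p
    R2gei = vc.sigma2_ge / vc.sigma2_p
    den = vc.sigma2_g + vc.sigma2_ge / e + vc.sigma2_e / (e * r)
    h2mg = vc.sigma2_g / den if den > 0 else float("nan")
    acc = float(np.sqrt(h2mg)) if h2mg == h2mg else float("nan")
    den_rge = vc.sigma2_ge + vc.sigma2_e
    rge = vc.sigma2_ge / den_rge if den_rge > 0 else float("nan")
    if grand_mean <= 0:
        flags.append("grand_mean<=0: CVs undefined")
        CVg = CVr = CVratio = float("nan")
    else:
        CVg = 100.0 * np.sqrt(vc.sigma2_g) / grand_mean
        CVr = 100.0 * np.sqrt(vc.sigma2_e) / grand_mean
        CVratio = CVg / CVr if CVr > 0 else float("inf")
    return GeneticParameters(H2, R2gei, h2mg, acc, rge, CVg, CVr, CVratio, flags)


@dataclass
class BlupSet:
    """Shrunken genotype effects and the g x e interaction BLUP matrix."""

    genotype_effects: pd.Series
    ge_matrix: pd.DataFrame
    components: VarianceComponents
    grand_mean: float
    method: str = "reml"

    def genotype_means(self) -> pd.Series:
        """Predicted genotype means: grand mean + BLUP effect."""
        return self.grand_mean + self.genotype_effects


def fit_blup(table: IndexTable, trait: str, method: str = "reml") -> BlupSet:
    """Random-genotype BLUPs for one trait's index table.

    ``method`` selects the variance-component estimator ('reml' or 'mom');
    the effect predictions use the balanced closed-form shrinkage either way.
    """
    y, gens, envs = _trait_cube(table, trait)
    g, e, r = y.shape
    anova = joint_anova(table, trait)
    est = reml_components if method == "reml" else variance_components
    vc = est(anova, g, e, r)
    grand = y.mean()
    gen_means = y.mean(axis=(1, 2))
    env_means = y.mean(axis=(0, 2))
    cell = y.mean(axis=2)
    raw_g = gen_means - grand
    raw_ge = cell - gen_means[:, None] - env_means[None, :] + grand

    den_g = vc.sigma2_g + vc.sigma2_ge / e + vc.sigma2_e / (e * r)
    shrink_g = vc.sigma2_g / den_g if den_g > 0 else 0.0
    den_ge = vc.sigma2_ge + vc.sigma2_e / r
    shrink_ge = vc.sigma2_ge / den_ge if den_ge > 0 else 0.0
    if den_g <= 0 or den_ge <= 0:
        logger.info("degenerate variance structure; BLUPs fully shrunk to 0")
    return BlupSet(
        genotype_effects=pd.Series(shrink_g * raw_g, index=gens),
        ge_matrix=pd.DataFrame(shrink_ge * raw_ge, index=gens, columns=envs),
        components=vc,
        grand_mean=float(grand),
        method=method,
    )


class JointANOVA:
    """Model object for the joint ANOVA of one trait's tolerance index.

    Parameters
    ----------
    table : IndexTable
    trait : str

    ``fit()`` returns a :class:`JointANOVAResults` with the ANOVA table,
    variance components (random-genotype parameterization), genetic
    parameters and BLUPs.
    """

    def __init__(self, table: IndexTable, trait: str):
        self.table = table
        self.trait = trait

    def fit(self, method: str = "reml") -> "JointANOVAResults":
        anova = joint_anova(self.table, self.trait)
        d = anova.attrs["design"]
        est = reml_components if method == "reml" else variance_components
        vc = est(anova, d["g"], d["e"], d["r"])
        params = genetic_parameters(vc, d["e"], d["r"], d["grand_mean"])
        return JointANOVAResults(self, anova, vc, params, method)


class JointANOVAResults:
    def __init__(self, model, anova, vc, params, method):
        self.model = model
        self.anova_table = anova
        self.variance_components = vc
        self.genetic_parameters = params
        self.method = method
        self.design = anova.attrs["design"]

    def blup(self) -> BlupSet:
        return fit_blup(self.model.table, self.model.trait, self.method)

    def pretests(self) -> tuple[float, float]:
        return pretests(self.model.table, self.model.trait)

    def summary(self) -> str:
        d = self.design
        lines = [
            f"Joint ANOVA — trait {self.model.trait!r} "
            f"(g={d['g']}, e={d['e']}, r={d['r']})",
            self.anova_table.to_string(float_format=lambda v: f"{v:.4g}"),
            "",
            "Variance components (genotypes random, "
            f"{self.method}):",
            self.variance_components.as_series().to_string(
                float_format=lambda v: f"{v:.4g}"
            ),
            "",
            "Genetic parameters:",
            self.genetic_parameters.as_series().to_string(
                float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)
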