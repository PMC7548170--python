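"""Latitude-gradient regressions and the mixed model for divergence.

Two questions are addressed.  First, how sampling effort relates to
latitude: species richness along a latitudinal grid is derived from
per-species range limits (a species is counted at every integer latitude
between its southern and northern European records), and linear or
quadratic trends are fitted to richness or barcode counts by ordinary
least squares, with the vertex of a concave quadratic giving the latitude
at which barcode availability peaks.

Second, whether divergence between populations depends on geography beyond
mere distance: a linear mixed model with a random species intercept,

    max_div ~ contrast + geo_km + n_max + (1 | species),

contrasts two classes of population pairs (e.g. Europe-Europe against
Europe-Iberia) while controlling for the geographic distance between the
populations and the larger of the two sample sizes.  The model is fitted
by maximum likelihood so that the sigma_u = 0 boundary nests ordinary
least squares exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .distances import ContrastRow, contrasts_to_frame

logger = logging.getLogger("barcodescope")

#: Public COI barcodes per country for the study taxa (oak-feeding moths),
#: as recorded in BOLD in January 2018.  Input data for the
#: latitudinal-bias bookkeeping; countries on the southern European
#: peninsulas are listed separately below.
BOLD_BARCODES_BY_COUNTRY: dict[str, int] = {
    "Austria": 16,
    "Croatia": 1,
    "Czech Republic": 24,
    "Finland": 20,
    "France": 20,
    "Germany": 60,
    "Greece": 1,
    "Italy": 41,
    "Macedonia": 2,
    "Netherlands": 22,
    "Romania": 10,
    "Slovenia": 1,
    "Spain": 30,
    "United Kingdom": 29,
}

#: Countries belonging to the southern European peninsulas (Iberia, Italy,
#: Balkans) in the per-country barcode survey.
SOUTHERN_PENINSULA_COUNTRIES: frozenset[str] = frozenset(
    {"Croatia", "Greece", "Italy", "Spain"}
)

#: Newly sequenced Iberian specimens pooled with the public barcodes.
N_NEW_IBERIAN_SEQUENCES = 375


def barcode_survey_totals(
    counts: dict[str, int] | None = None,
    southern: frozenset[str] = SOUTHERN_PENINSULA_COUNTRIES,
    n_new: int = N_NEW_IBERIAN_SEQUENCES,
) -> dict[str, int]:
    """Summarise the per-country barcode survey.

    Returns the total public barcode count, its split between southern
    peninsulas and the rest of the continent, and the pooled total after
    adding the newly sequenced specimens.
    """
    counts = BOLD_BARCODES_BY_COUNTRY if counts is None else counts
    total = sum(counts.values())
    south = sum(v for c, v in counts.items() if c in southern)
    return {
        "public_total": total,
        "southern_peninsulas": south,
        "rest_of_continent": total - south,
        "pooled_total": total + n_new,
    }


# ---------------------------------------------------------------------------
# Richness and trend fitting
# ---------------------------------------------------------------------------

def read_range_limits(path) -> pd.DataFrame:
    """Range-limit CSV with columns species, south_lat, north_lat."""
    df = pd.read_csv(path)
    required = {"species", "south_lat", "north_lat"}
    if required - set(df.columns):
        raise ValueError(f"range table needs columns {sorted(required)}")
    return df


def richness_by_latitude(ranges: pd.DataFrame, grid) -> pd.DataFrame:
    """Species counts per grid latitude from per-species range limits.

    A species is present at latitude L when south_lat <= L <= north_lat.
    """
    if (ranges["south_lat"] > ranges["north_lat"]).any():
        bad = ranges[ranges["south_lat"] > ranges["north_lat"]]["species"].tolist()
        raise ValueError(f"inverted range limits for: {bad}")
    grid = [float(g) for g in grid]
    counts = [
        int(((ranges["south_lat"] <= lat) & (lat <= ranges["north_lat"])).sum())
        for lat in grid
    ]
    return pd.DataFrame({"lat": grid, "n_species": counts})


def barcode_counts_by_latitude(lats, grid=None) -> pd.DataFrame:
    """Barcode record counts binned to rounded integer latitude."""
    binned = pd.Series([round(float(v)) for v in lats if v is not None and not (
        isinstance(v, float) and math.isnan(v))])
    if grid is None:
        grid = range(int(binned.min()), int(binned.max()) + 1)
    counts = binned.value_counts()
    return pd.DataFrame(
        {"lat": [float(g) for g in grid],
         "n_barcodes": [int(counts.get(g, 0)) for g in grid]}
    )


@dataclass
class TrendFit:
    """Polynomial latitude trend fitted by OLS."""

    degree: int
    coefficients: tuple[float, ...]   # (intercept, linear[, quadratic])
    r: float                          # multiple correlation
    f_statistic: float
    df_model: int
    df_resid: int
    p_value: float
    n: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(c * x ** k for k, c in enumerate(self.coefficients))

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coefficients": list(self.coefficients),
            "R": self.r,
            "F": self.f_statistic,
            "df": [self.df_model, self.df_resid],
            "p_value": self.p_value,
            "n": self.n,
        }


def fit_latitude_trend(x, y, degree: int = 1) -> TrendFit:
    """OLS polynomial fit of counts against latitude (degree 1 or 2)."""
    if degree not in (1, 2):
        raise ValueError(f"unsupported degree {degree}; use 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size <= degree + 1:
        raise ValueError("too few points for the requested degree")
    X = np.column_stack([x ** k for k in range(1, degree + 1)])
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    return TrendFit(
        degree=degree,
        coefficients=tuple(res.params),
        r=float(np.sqrt(max(res.rsquared, 0.0))),
        f_statistic=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        p_value=float(res.f_pvalue),
        n=int(x.size),
    )


def quadratic_peak(fit: TrendFit) -> float:
    """Latitude of the maximum of a concave quadratic trend: -b / (2c)."""
    if fit.degree != 2:
        raise ValueError("quadratic_peak requires a degree-2 fit")
    _, b, c = fit.coefficients
    if c >= 0:
        raise ValueError("quadratic coefficient is non-negative: no maximum")
    return -b / (2.0 * c)


# ---------------------------------------------------------------------------
# Mixed model for divergence
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """ML fit of max_div ~ contrast + geo_km + n_max + (1 | species)."""

    contrast_pair: tuple[str, str]
    fixed_effects: dict[str, float]
    std_errors: dict[str, float]
    f_tests: dict[str, tuple[float, float]]   # term -> (F, p)
    sigma_u2: float
    sigma_e2: float
    loglik: float
    n_rows: int
    n_species: int
    df_denom: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "contrast_pair": list(self.contrast_pair),
            "fixed_effects": self.fixed_effects,
            "std_errors": self.std_errors,
            "F_tests": {k: list(v) for k, v in self.f_tests.items()},
            "sigma_u2": self.sigma_u2,
            "sigma_e2": self.sigma_e2,
            "loglik": self.loglik,
            "n_rows": self.n_rows,
            "n_species": self.n_species,
            "df_denom": self.df_denom,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_divergence_lmm(
    rows: list[ContrastRow] | pd.DataFrame,
    contrast_pair: tuple[str, str] = ("EUEU", "EUIB"),
    max_geo_km: float | None = None,
    reml: bool = False,
) -> LMMFit:
    """Mixed model contrasting two classes of population comparisons.

    Rows are restricted to the two contrast levels (the first level is the
    reference); with ``max_geo_km`` only pairs closer than the cap enter
    (used for the Europe-Europe versus Iberia-Iberia comparison, where the
    spatial range is reduced to 1,000 km).  The species random intercept is
    fitted by ML unless ``reml``; per-term Wald F statistics use n - rank
    denominator degrees of freedom.
    """
    df = rows if isinstance(rows, pd.DataFrame) else contrasts_to_frame(rows)
    level_ref, level_alt = contrast_pair
    df = df[df["contrast"].isin(contrast_pair)].copy()
    if max_geo_km is not None:
        df = df[df["geo_km"] <= max_geo_km]
    df = df.dropna(subset=["max_div_pct", "geo_km", "n_max"])
    if df["species"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 species")
    df["is_alt"] = (df["contrast"] == level_alt).astype(float)

    import warnings

    # covariates without variation cannot enter the design matrix
    covariates = ["is_alt", "geo_km", "n_max"]
    for cov in ("geo_km", "n_max"):
        if df[cov].nunique() <= 1:
            logger.warning("fit_divergence_lmm: covariate %s is constant; dropped", cov)
            covariates.remove(cov)
    if df["is_alt"].nunique() <= 1:
        raise ValueError("both contrast levels must be present")

    formula = "max_div_pct ~ " + " + ".join(covariates)
    model = smf.mixedlm(formula, data=df, groups=df["species"])
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method=["lbfgs", "powell"])
        except np.linalg.LinAlgError:
            res = None
            logger.warning(
                "fit_divergence_lmm: mixed fit failed; using sigma_u2=0 boundary"
            )

    terms = ["Intercept"] + covariates
    names = {"Intercept": "intercept", "is_alt": "contrast",
             "geo_km": "geo_km", "n_max": "n_max"}
    k_fixed = len(terms)
    df_denom = len(df) - k_fixed

    # ML on the sigma_u^2 = 0 boundary is exactly OLS: if the boundary beats
    # the interior optimum the optimiser stopped at, the MLE is OLS.
    X = sm.add_constant(df[covariates].to_numpy())
    ols = sm.OLS(df["max_div_pct"].to_numpy(), X).fit()
    if res is None or (not reml and ols.llf >= res.llf - 1e-9):
        fe = dict(zip((names[t] for t in terms), map(float, ols.params)))
        se = dict(zip((names[t] for t in terms), map(float, ols.bse)))
        sigma_u2, loglik = 0.0, float(ols.llf)
        sigma_e2 = float(ols.ssr / len(df))
        converged = True
    else:
        fe = {names[k]: float(v) for k, v in res.fe_params.items()}
        se = {names[k]: float(res.bse[k]) for k in res.fe_params.index}
        sigma_u2 = float(res.cov_re.iloc[0, 0])
        sigma_e2 = float(res.scale)
        loglik = float(res.llf)
        converged = bool(res.converged)

    f_tests = {}
    for t in terms:
        if t == "Intercept":
            continue
        f_stat = float((fe[names[t]] / se[names[t]]) ** 2)
        f_tests[names[t]] = (f_stat, float(stats.f.sf(f_stat, 1, df_denom)))

    fit = LMMFit(
        contrast_pair=contrast_pair,
        fixed_effects=fe,
        std_errors=se,
        f_tests=f_tests,
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        loglik=loglik,
        n_rows=len(df),
        n_species=int(df["species"].nunique()),
        df_denom=df_denom,
        converged=converged,
    )
    logger.info(
        "fit_divergence_lmm %s vs %s: contrast beta=%.4f (F=%.2f, p=%.3g), "
        "n=%d rows / %d species",
        level_ref, level_alt, fe["contrast"], *f_tests["contrast"],
        fit.n_rows, fit.n_species,
    )
    return fit
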