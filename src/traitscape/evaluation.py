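"""Evaluation of map-based composition estimates against survey data.

Each metric estimated from the stacked range maps is compared with the
same metric computed from observed site abundances: ordinary least
squares of estimate on observation gives precision (R^2, correlation P)
and accuracy (slope, with a t-test for departure from the ideal y = x
slope of 1).  Robustness checks: a spatial-error simultaneous
autoregressive (SAR) refit, the Jaccard similarity of estimated vs
observed species composition, per-site screens for trait-abundance
relationships, and a quasi-Poisson model of how many sites record each
species (detectability).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.spatial import Delaunay

from . import metrics as tsm
from .abundance import site_species_abundance
from .metrics import Community, MetricConfig, TraitDistanceMatrix, TraitSpaceCoordinates

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    metric: str
    trait_scope: str
    method_tag: str
    r2: float
    p_corr: float
    slope: float
    t_unity: float
    p_unity: float
    n_sites: int
    sar_significant: str = "not_run"  # yes | no | not_run


# ---------------------------------------------------------------------------
# site handling
# ---------------------------------------------------------------------------

def split_sites(
    sites: pd.DataFrame,
    n_eval: int,
    stratify_by: str | None = None,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive training/evaluation split of site ids.

    The real scheme reserved roughly one evaluation site per political
    unit; here the analogue is stratified random sampling over the values
    of ``stratify_by`` (e.g. a grid-quadrant column), allocating each
    stratum's share proportionally (largest-remainder rounding).
    """
    if n_eval >= len(sites):
        raise ValueError("n_eval must be smaller than the number of sites")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        ids = sites["site_id"].to_numpy()
        eval_ids = rng.choice(ids, size=n_eval, replace=False)
    else:
        groups = sites.groupby(stratify_by)["site_id"].apply(list)
        quota = n_eval * groups.str.len() / len(sites)
        base = np.floor(quota).astype(int)
        rem = quota - base
        short = n_eval - int(base.sum())
        order = np.argsort(-rem.to_numpy(), kind="stable")[:short]
        base.iloc[order] += 1
        eval_ids = np.concatenate(
            [
                rng.choice(np.array(g), size=int(k), replace=False)
                for g, k in zip(groups, base)
                if k > 0
            ]
        )
    eval_set = set(eval_ids)
    training = [s for s in sites["site_id"] if s not in eval_set]
    evaluation = [s for s in sites["site_id"] if s in eval_set]
    return training, evaluation


def observed_site_communities(
    records: pd.DataFrame, evaluation_sites: list[str]
) -> dict[str, Community]:
    """Observed community (effort-corrected, year-averaged, rounded-up
    abundances) at each evaluation site; empty sites skipped with a log."""
    site_abund = site_species_abundance(records[records["site_id"].isin(set(evaluation_sites))])
    out: dict[str, Community] = {}
    for sid in evaluation_sites:
        grp = site_abund[site_abund["site_id"] == sid]
        if grp.empty:
            logger.info("site %s has no recorded species; skipped", sid)
            continue
        out[sid] = Community(list(grp["species_id"]), grp["abundance"].to_numpy(dtype=float))
    return out


def observed_site_metrics(
    community: Community,
    traits: pd.DataFrame,
    distances: dict[str, TraitDistanceMatrix],
    coords: TraitSpaceCoordinates | None = None,
    config: MetricConfig | None = None,
    include_hull: bool = True,
) -> list[tsm.MetricValue]:
    """Observed metrics at a site: the SAME code path as map-cell metrics."""
    return tsm.community_metrics(
        community, traits, distances, coords, config, method_tag="observed", include_hull=include_hull
    )


# ---------------------------------------------------------------------------
# regression and composition similarity
# ---------------------------------------------------------------------------

def regress_estimate_on_observed(
    observed: np.ndarray,
    estimated: np.ndarray,
    sided: str = "two",
) -> dict:
    """OLS of estimated (y) on observed (x) with a slope-vs-unity t-test.

    Returns r2, p_corr (correlation test), slope, t_unity = (slope-1)/SE
    and its p-value (two-sided by default; ``sided='one'`` halves it in
    the direction of departure).  Requires >= 3 finite pairs and
    variation in x.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(estimated, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0:
        logger.info("zero variance in observed values; fit refused")
        return {
            "r2": np.nan, "p_corr": np.nan, "slope": np.nan,
            "t_unity": np.nan, "p_unity": np.nan, "n": int(x.size),
        }
    if np.ptp(y) == 0:
        # a constant estimate carries no information: R^2 = 0, slope 0
        return {
            "r2": 0.0, "p_corr": np.nan, "slope": 0.0,
            "t_unity": -np.inf, "p_unity": 0.0, "n": int(x.size),
        }
    res = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(res.params[1])
    se = float(res.bse[1])
    if res.ssr <= 1e-12 * float(np.sum(y**2)):
        # numerically exact fit: the slope test is vacuous
        t_unity = 0.0 if np.isclose(slope, 1.0) else np.inf * np.sign(slope - 1.0)
    elif se > 0:
        t_unity = (slope - 1.0) / se
    else:
        t_unity = np.inf * np.sign(slope - 1.0)
    df = res.df_resid
    if sided == "two":
        p_unity = 2.0 * stats.t.sf(abs(t_unity), df)
    elif sided == "one":
        p_unity = stats.t.sf(abs(t_unity), df)
    else:
        raise ValueError("sided must be 'two' or 'one'")
    p_corr = float(stats.pearsonr(x, y).pvalue)
    return {
        "r2": float(res.rsquared),
        "p_corr": p_corr,
        "slope": slope,
        "t_unity": float(t_unity),
        "p_unity": float(p_unity),
        "n": int(x.size),
    }


def jaccard(set_a, set_b) -> float:
    """Jaccard similarity |A & B| / |A | B|; undefined (nan) if both empty."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        logger.info("Jaccard of two empty sets is undefined")
        return float("nan")
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# SAR spatial-error model
# ---------------------------------------------------------------------------

def delaunay_weights(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Row-standardised neighbour weights from a Delaunay triangulation.

    Duplicate/collinear site coordinates are jittered slightly (logged)
    so the triangulation exists.
    """
    pts = np.asarray(coords, dtype=float)
    n = pts.shape[0]
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] < n or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        logger.info("degenerate site coordinates; applying deterministic jitter")
        rng = np.random.default_rng(seed)
        scale = max(np.ptp(pts), 1.0) * 1e-6
        pts = pts + rng.normal(0.0, scale, pts.shape)
    tri = Delaunay(pts)
    W = np.zeros((n, n))
    for simplex in tri.simplices:
        for i in simplex:
            for j in simplex:
                if i != j:
                    W[i, j] = 1.0
    W /= W.sum(axis=1, keepdims=True)
    return W


def sar_error_model(
    observed: np.ndarray,
    estimated: np.ndarray,
    site_coords: np.ndarray,
    seed: int = 0,
) -> dict:
    """Spatial-error regression of estimated on observed.

    Model: y = a + b x + u, u = lambda W u + eps, with W row-standardised
    Delaunay neighbour weights.  lambda is estimated by concentrated
    maximum likelihood (log-determinant via the eigenvalues of W); the
    slope and its SE come from the GLS fit at the ML lambda.  Returns
    slope, slope_se, slope_p, lam, lr_lambda_p (LR test of lambda = 0).
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(estimated, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, pts = x[ok], y[ok], np.asarray(site_coords, dtype=float)[ok]
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 sites for the SAR model")
    W = delaunay_weights(pts, seed=seed)
    X = np.column_stack([np.ones(n), x])
    eigs = np.linalg.eigvals(W)
    lam_lo = 1.0 / eigs.real.min() + 1e-6 if eigs.real.min() < 0 else -0.999999
    lam_hi = 0.999999

    def neg_loglik(lam: float) -> float:
        A = np.eye(n) - lam * W
        ys, Xs = A @ y, A @ X
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid = ys - Xs @ beta
        sigma2 = max(float(resid @ resid) / n, 1e-300)  # exact fits degenerate
        logdet = np.sum(np.log(np.abs(1.0 - lam * eigs.real)))
        return 0.5 * n * np.log(2 * np.pi * sigma2) + 0.5 * n - logdet

    opt = optimize.minimize_scalar(neg_loglik, bounds=(lam_lo, lam_hi), method="bounded")
    lam = float(opt.x)
    A = np.eye(n) - lam * W
    ys, Xs = A @ y, A @ X
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    sigma2 = float(resid @ resid) / (n - X.shape[1])
    cov = sigma2 * np.linalg.inv(Xs.T @ Xs)
    slope, slope_se = float(beta[1]), float(np.sqrt(max(cov[1, 1], 0.0)))
    slope_p = 2.0 * stats.t.sf(abs(slope / slope_se), n - 2) if slope_se > 0 else 0.0
    lr = 2.0 * (neg_loglik(0.0) - neg_loglik(lam))
    lr_lambda_p = float(stats.chi2.sf(max(lr, 0.0), 1))
    return {
        "slope": slope,
        "slope_se": slope_se,
        "slope_p": float(slope_p),
        "lam": lam,
        "lr_lambda_p": lr_lambda_p,
        "n": n,
    }


# ---------------------------------------------------------------------------
# trait-abundance screens and detectability
# ---------------------------------------------------------------------------

def trait_abundance_screen(
    site_abundance: pd.DataFrame,
    traits: pd.DataFrame,
    min_species: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Per-site tests of whether local abundance tracks traits.

    For every site with enough species: Pearson correlation of
    log(abundance) with log mass and with log generation length, and a
    one-way ANOVA of log(abundance) across migratory and diet classes
    (needs >= 2 classes present).  The summary reports the mean
    correlation +/- SE across sites and the number of sites significant
    at P < 0.05 — near-zero means are the regime in which ignoring
    abundance differences is safe.
    """
    rows = []
    for sid, grp in site_abundance.groupby("site_id"):
        tr = traits.loc[grp["species_id"]]
        la = np.log(grp["abundance"].to_numpy(dtype=float))
        row: dict = {"site_id": sid, "n_species": len(grp)}
        if len(grp) >= min_species and np.ptp(la) > 0:
            for trait in ("log_mass", "log_genlength"):
                x = tr[trait].to_numpy(dtype=float)
                if np.ptp(x) > 0:
                    r, p = stats.pearsonr(x, la)
                    row[f"r_{trait}"], row[f"p_{trait}"] = float(r), float(p)
        for trait in ("migratory_class", "diet_class"):
            if len(grp) < min_species or np.ptp(la) == 0:
                continue
            groups = [la[tr[trait].to_numpy() == c] for c in tr[trait].unique()]
            groups = [g for g in groups if g.size > 0]
            # need >= 2 classes and at least one within-group residual df
            if len(groups) >= 2 and sum(g.size - 1 for g in groups) >= 1:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        f, p = stats.f_oneway(*groups)
                    except ValueError:
                        continue
                if np.isfinite(f):
                    row[f"F_{trait}"], row[f"p_{trait}"] = float(f), float(p)
        rows.append(row)
    per_site = pd.DataFrame(rows)
    summary: dict = {"n_sites": len(per_site)}
    for trait in ("log_mass", "log_genlength"):
        col = per_site.get(f"r_{trait}")
        if col is not None and col.notna().any():
            r = col.dropna()
            summary[f"mean_r_{trait}"] = float(r.mean())
            summary[f"se_r_{trait}"] = float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else np.nan
            p = per_site[f"p_{trait}"].dropna()
            summary[f"n_sig_{trait}"] = int((p < 0.05).sum())
    for trait in ("migratory_class", "diet_class"):
        col = per_site.get(f"F_{trait}")
        if col is not None and col.notna().any():
            f = col.dropna()
            summary[f"mean_F_{trait}"] = float(f.mean())
            p = per_site[f"p_{trait}"].dropna()
            summary[f"n_sig_{trait}"] = int((p < 0.05).sum())
            summary[f"n_tested_{trait}"] = int(len(f))
    return per_site, summary


def detectability_glm(species_stats: pd.DataFrame, min_species: int = 20) -> dict:
    """Quasi-Poisson model of the number of sites recording each species.

    ``species_stats`` columns: species_id, n_sites_recorded, range_size,
    log_mass, migratory_class.  Predictors: log range size, log mass and
    migratory class.  Reports coefficients with SEs and the percent of
    null deviance explained overall and sequentially per term (range
    size, then mass, then migratory class).
    """
    df = species_stats.copy()
    if len(df) < min_species:
        raise ValueError(f"need at least {min_species} species")
    df = df[df["range_size"] > 0]
    y = df["n_sites_recorded"].to_numpy(dtype=float)
    log_range = np.log(df["range_size"].to_numpy(dtype=float))
    log_mass = df["log_mass"].to_numpy(dtype=float)
    mig = pd.get_dummies(df["migratory_class"], drop_first=True, dtype=float)
    if mig.shape[1] == 0:
        logger.info("single migratory class present; term dropped")
    if np.ptp(y) == 0:
        # every species recorded at the same number of sites: nothing to explain
        names = ["intercept", "log_range_size", "log_mass"] + [
            f"migratory[{c}]" for c in mig.columns
        ]
        coefs = {n: 0.0 for n in names}
        coefs["intercept"] = float(np.log(max(y[0], 1e-12)))
        return {
            "coefficients": coefs,
            "standard_errors": {n: float("nan") for n in names},
            "scale": 0.0,
            "pct_deviance_overall": 0.0,
            "pct_deviance_range_size": 0.0,
            "pct_deviance_mass": 0.0,
            "pct_deviance_migratory": 0.0,
            "n_species": int(len(y)),
        }
    fam = sm.families.Poisson()

    def deviance(X: np.ndarray) -> float:
        return float(sm.GLM(y, X, family=fam).fit().deviance)

    ones = np.ones((len(y), 1))
    dev_null = deviance(ones)
    X1 = np.column_stack([ones, log_range])
    X2 = np.column_stack([X1, log_mass])
    X3 = np.column_stack([X2, mig.to_numpy()]) if mig.shape[1] else X2
    dev1, dev2, dev3 = deviance(X1), deviance(X2), deviance(X3)
    full = sm.GLM(y, X3, family=fam).fit(scale="X2")  # quasi-Poisson: Pearson scale
    names = ["intercept", "log_range_size", "log_mass"] + [f"migratory[{c}]" for c in mig.columns]
    coefs = dict(zip(names, map(float, full.params)))
    ses = dict(zip(names, map(float, full.bse)))
    return {
        "coefficients": coefs,
        "standard_errors": ses,
        "scale": float(full.scale),
        "pct_deviance_overall": 100.0 * (dev_null - dev3) / dev_null,
        "pct_deviance_range_size": 100.0 * (dev_null - dev1) / dev_null,
        "pct_deviance_mass": 100.0 * (dev1 - dev2) / dev_null,
        "pct_deviance_migratory": 100.0 * (dev2 - dev3) / dev_null,
        "n_species": int(len(y)),
    }


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def evaluation_report(results: list[EvaluationResult]) -> pd.DataFrame:
    """Long-format table, one row per (trait_scope, metric, method), with
    best-R^2 and closest-to-unity-slope flags within each metric group."""
    if not results:
        raise ValueError("no evaluation results")
    df = pd.DataFrame([vars(r) for r in results])
    df["best_r2"] = False
    df["best_slope"] = False
    for _, idx in df.groupby(["metric", "trait_scope"]).groups.items():
        sub = df.loc[idx]
        if sub["r2"].notna().any():
            df.loc[sub["r2"].idxmax(), "best_r2"] = True
        dist = (sub["slope"] - 1.0).abs()
        if dist.notna().any():
            df.loc[dist.idxmin(), "best_slope"] = True
    return df
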