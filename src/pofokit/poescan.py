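"""Parent-of-origin-aware association scans and POE statistics.

Four scans share one regression machinery: additive (diploid dosage),
paternal (DS_pat), maternal (DS_mat) and differential (the paternal
fraction DS_pat/DS_dip over near-certain heterozygotes, which directly
contrasts paternal versus maternal transmission of the effect allele).
Quantitative traits use OLS with covariates; binary traits logistic
maximum likelihood.  On top sit the differential Z test, the five-way POE
classification from the maternal/paternal Z-scores, effective-test
counting (simpleM), significance thresholds, LD pruning, conditional and
sex-stratified scans, the paternal/maternal odds-ratio contrast and the
heritability-difference Z.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "prep_phenotype",
    "assoc_scan",
    "conditional_scan",
    "differential_z",
    "classify_poe",
    "n_eff",
    "thresholds",
    "prune",
    "sex_diff_z",
    "or_ratio",
    "h2_diff_z",
    "load_known_poe_table",
]

SCAN_MODES = ("add", "pat", "mat", "diff")


# --------------------------------------------------------------------------- #
# phenotype preparation
# --------------------------------------------------------------------------- #
def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform Phi^-1((rank - 0.5)/n), mid-ranks
    at ties; NaN preserved."""
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    n = ok.sum()
    if n:
        ranks = stats.rankdata(v[ok])
        out[ok] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def prep_phenotype(records: pd.DataFrame, kind: str = "quantitative",
                   include_codes: set | None = None,
                   exclude_codes: set | None = None) -> pd.Series:
    """Per-individual phenotype vector from raw records.

    Quantitative: ``records`` has columns ``iid`` and ``value`` with one row
    per time point; values are averaged per individual and inverse-normal
    transformed.  Binary: ``records`` has ``iid`` and ``code``; individuals
    carrying an inclusion code become cases, those carrying an exclusion
    code are removed from cases and controls alike.
    """
    if kind == "quantitative":
        means = records.groupby("iid")["value"].mean()
        means = means.dropna()
        if len(means) == 0:
            raise ValueError("no phenotyped individuals")
        return pd.Series(inverse_normal_transform(means.to_numpy()),
                         index=means.index, name="phenotype")
    if kind == "binary":
        include_codes = include_codes or set()
        exclude_codes = exclude_codes or set()
        codes = records.groupby("iid")["code"].agg(set)
        excluded = codes[codes.apply(lambda s: bool(s & exclude_codes))].index
        status = codes.apply(lambda s: float(bool(s & include_codes)))
        return status.drop(excluded).rename("phenotype")
    raise ValueError(f"unknown phenotype kind {kind!r}")


# --------------------------------------------------------------------------- #
# association scans
# --------------------------------------------------------------------------- #
def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    return np.column_stack([np.ones(n), cov])


def _ols_scan(G: np.ndarray, y: np.ndarray, C: np.ndarray) -> pd.DataFrame:
    """Per-variant OLS slope/se/P with covariates.

    Complete-data variants use a residualised (Frisch-Waugh) vectorised
    path; variants with missing entries are fit on their complete cases.
    """
    n, m = G.shape
    k = C.shape[1]
    rows = np.empty((m, 4))
    has_nan = np.isnan(G).any(axis=0)
    if (~has_nan).any():
        idx = np.flatnonzero(~has_nan)
        Q, _ = np.linalg.qr(C)
        y_res = y - Q @ (Q.T @ y)
        Gc = G[:, idx]
        G_res = Gc - Q @ (Q.T @ Gc)
        ss = (G_res ** 2).sum(axis=0)
        # a residual sum of squares near zero means the regressor is
        # collinear with the covariates (e.g. conditioning on itself)
        ss = np.where(ss > 1e-8 * n, ss, np.nan)
        beta = (G_res * y_res[:, None]).sum(axis=0) / ss
        dof = n - k - 1
        resid_ss = (y_res ** 2).sum() - beta ** 2 * ss
        se = np.sqrt(np.maximum(resid_ss, 0) / dof / ss)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta / se
        p = 2 * stats.t.sf(np.abs(z), dof)
        rows[idx, 0], rows[idx, 1], rows[idx, 2] = beta, se, p
        rows[idx, 3] = n
    for j in np.flatnonzero(has_nan):
        g = G[:, j]
        ok = ~np.isnan(g)
        nn = int(ok.sum())
        if nn <= k + 1 or np.nanstd(g[ok]) == 0:
            rows[j] = (np.nan, np.nan, np.nan, nn)
            continue
        X = np.column_stack([C[ok], g[ok]])
        XtX = X.T @ X
        try:
            coef = np.linalg.solve(XtX, X.T @ y[ok])
        except np.linalg.LinAlgError:
            rows[j] = (np.nan, np.nan, np.nan, nn)
            continue
        resid = y[ok] - X @ coef
        dof = nn - X.shape[1]
        sigma2 = resid @ resid / dof
        se_j = np.sqrt(sigma2 * np.linalg.inv(XtX)[-1, -1])
        z = coef[-1] / se_j
        rows[j] = (coef[-1], se_j, 2 * stats.t.sf(abs(z), dof), nn)
    return pd.DataFrame(rows, columns=["beta", "se", "p", "n"])


def _logistic_scan(G: np.ndarray, y: np.ndarray, C: np.ndarray) -> pd.DataFrame:
    rows = []
    for j in range(G.shape[1]):
        g = G[:, j]
        ok = ~np.isnan(g)
        X = np.column_stack([C[ok], g[ok]])
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y[ok], X).fit(disp=0, maxiter=200)
            beta = fit.params[-1]
            se = fit.bse[-1]
            if not np.isfinite(se) or se > 50:   # separation
                rows.append((beta, np.nan, np.nan, ok.sum()))
            else:
                z = beta / se
                rows.append((beta, se, 2 * stats.norm.sf(abs(z)), ok.sum()))
        except Exception:
            rows.append((np.nan, np.nan, np.nan, ok.sum()))
    return pd.DataFrame(rows, columns=["beta", "se", "p", "n"])


def assoc_scan(
    encoding,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    mode: str,
    kind: str = "quantitative",
    variant_ids=None,
    diff_entry_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """One association scan across variants.

    ``encoding`` is a mapping/namespace with arrays ``ds_mat``, ``ds_pat``
    and ``ds_dip`` of shape (n_individuals, n_variants).  The regressor is
    the diploid dosage (``add``), one parental dosage (``pat``/``mat``), or
    the paternal fraction DS_pat/DS_dip over heterozygous entries
    (``diff``), optionally restricted by ``diff_entry_mask``.
    """
    if mode not in SCAN_MODES:
        raise ValueError(f"unknown scan mode {mode!r}")
    ds_mat = np.asarray(getattr(encoding, "ds_mat", None)
                        if not isinstance(encoding, dict) else encoding["ds_mat"],
                        dtype=float)
    ds_pat = np.asarray(getattr(encoding, "ds_pat", None)
                        if not isinstance(encoding, dict) else encoding["ds_pat"],
                        dtype=float)
    ds_dip = ds_mat + ds_pat
    if mode == "add":
        G = ds_dip
    elif mode == "pat":
        G = ds_pat
    elif mode == "mat":
        G = ds_mat
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            G = np.where(ds_dip > 0, ds_pat / ds_dip, np.nan)
        het = np.round(ds_mat + ds_pat) == 1
        G = np.where(het, G, np.nan)
        if diff_entry_mask is not None:
            G = np.where(diff_entry_mask, G, np.nan)
    y = np.asarray(phenotype, dtype=float)
    ok_ind = np.isfinite(y)
    G = G[ok_ind]
    y = y[ok_ind]
    C = _design(covariates, len(ok_ind))[ok_ind]
    res = (_ols_scan(G, y, C) if kind == "quantitative"
           else _logistic_scan(G, y, C))
    res.insert(0, "mode", mode)
    res.insert(0, "variant",
               variant_ids if variant_ids is not None else np.arange(G.shape[1]))
    return res


def conditional_scan(
    encoding, phenotype, covariates, mode, lead_dosage: np.ndarray,
    kind: str = "quantitative", **kwargs,
) -> pd.DataFrame:
    """Scan with the lead variant's dosage appended to the covariates,
    yielding conditional P values; variants collinear with the lead are
    flagged with NaN results."""
    lead = np.asarray(lead_dosage, dtype=float).reshape(-1, 1)
    if covariates is None:
        cov = lead
    else:
        cov = np.column_stack([np.atleast_2d(np.asarray(covariates, dtype=float)
                                             ).reshape(len(lead), -1), lead])
    return assoc_scan(encoding, phenotype, cov, mode, kind=kind, **kwargs)


# --------------------------------------------------------------------------- #
# POE statistics
# --------------------------------------------------------------------------- #
def differential_z(beta_p: float, se_p: float, beta_m: float, se_m: float
                   ) -> tuple[float, float]:
    """Z and two-sided P for paternal-versus-maternal effect difference:
    Z_D = (beta_P - beta_M) / sqrt(se_P^2 + se_M^2)."""
    if se_p <= 0 or se_m <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_p - beta_m) / np.hypot(se_p, se_m)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def classify_poe(z_pat: float, z_mat: float) -> str:
    """Five-way POE pattern from the parental Z-scores.

    Parent-dominant rules (one |Z| at least twice the other) are evaluated
    before the bipolar/asymmetric rules so the five classes partition the
    plane: ``maternal``, ``paternal``, ``bipolar`` (opposite signs, similar
    magnitudes), ``maternal_asymmetric`` / ``paternal_asymmetric`` (same
    sign, one effect dominant but the other still substantial).
    """
    if not (np.isfinite(z_pat) and np.isfinite(z_mat)) or z_pat == 0 or z_mat == 0:
        return "unclassified"
    ap, am = abs(z_pat), abs(z_mat)
    if ap < 0.5 * am:
        return "maternal"
    if am < 0.5 * ap:
        return "paternal"
    if np.sign(z_pat) != np.sign(z_mat):
        return "bipolar"
    if am > ap:
        return "maternal_asymmetric"
    return "paternal_asymmetric"


def n_eff(corr: np.ndarray, variance_explained: float = 0.995) -> int:
    """simpleM effective number of tests: the smallest k such that the top-k
    eigenvalues of the correlation matrix explain >= 99.5% of the total."""
    c = np.asarray(corr, dtype=float)
    c = 0.5 * (c + c.T)
    vals = np.linalg.eigvalsh(c)[::-1]
    if vals[-1] < -1e-8:
        raise ValueError("matrix not positive semi-definite")
    vals = np.clip(vals, 0, None)
    frac = np.cumsum(vals) / vals.sum()
    return int(np.searchsorted(frac, variance_explained) + 1)


def thresholds(
    n_eff_traits: int = 48,
    n_additive: int | None = None,
    n_imprinted_tests: int | None = None,
    suggestive: float | None = None,
    genomewide_alpha: float = 5e-8,
) -> dict:
    """Significance levels for the POE scans.

    Genome-wide POE: 5e-8 divided by the effective number of traits.
    Additive-region POE: 0.05 / N_a independent additive hits.  Imprinted
    regions: suggestive = 0.05 / N independent tests in those regions, and
    significant = suggestive / N_eff(traits).  ``suggestive`` may be given
    directly (e.g. a published rounded value) instead of ``n_imprinted_tests``.
    """
    out = {"genomewide": genomewide_alpha / n_eff_traits}
    if n_additive is not None:
        if n_additive <= 0:
            raise ValueError("n_additive must be positive")
        out["additive_region"] = 0.05 / n_additive
    if suggestive is None and n_imprinted_tests is not None:
        suggestive = 0.05 / n_imprinted_tests
    if suggestive is not None:
        out["imprinted_suggestive"] = suggestive
        out["imprinted_significant"] = suggestive / n_eff_traits
    return out


def prune(
    results: pd.DataFrame,
    genotypes: np.ndarray | None = None,
    distance_bp: int = 500_000,
    r2_max: float = 0.01,
) -> pd.DataFrame:
    """Greedy LD pruning: keep the smallest-P hit, drop neighbours within
    500 kb or with r^2 >= 0.01, repeat.

    ``results`` needs ``chrom``, ``pos``, ``p`` columns (and a positional
    column index into ``genotypes`` via row order when r^2 is used).
    """
    res = results.reset_index(drop=True)
    order = res["p"].to_numpy().argsort(kind="stable")
    alive = np.ones(len(res), dtype=bool)
    kept = []
    chrom = res["chrom"].to_numpy()
    pos = res["pos"].to_numpy()
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) < distance_bp)
        near[i] = False
        if genotypes is not None:
            cand = np.flatnonzero(alive)
            cand = cand[cand != i]
            if len(cand):
                gi = genotypes[:, i]
                gc = genotypes[:, cand]
                gi_c = gi - gi.mean()
                gc_c = gc - gc.mean(axis=0)
                denom = np.sqrt((gi_c ** 2).sum() * (gc_c ** 2).sum(axis=0))
                with np.errstate(invalid="ignore", divide="ignore"):
                    r2 = np.where(denom > 0, (gi_c @ gc_c) ** 2 / denom ** 2, 0.0)
                near[cand[r2 >= r2_max]] = True
        alive[near] = False
    return res.iloc[sorted(kept)].reset_index(drop=True)


def sex_diff_z(beta_d_males, se_d_males, beta_d_females, se_d_females
               ) -> tuple[float, float]:
    """Z and P for a male-versus-female difference in differential effects."""
    if se_d_males <= 0 or se_d_females <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_d_males - beta_d_females) / np.hypot(se_d_males, se_d_females)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def or_ratio(
    or_pat: float, ci_pat: tuple[float, float],
    or_mat: float, ci_mat: tuple[float, float],
    level_z: float = 1.96,
) -> tuple[float, tuple[float, float]]:
    """Ratio of paternal to maternal odds ratios with its 95% CI.

    Each log-OR standard error is recovered from the reported CI as
    (ln U - ln L) / (2 * 1.96); the ratio CI combines them in quadrature.
    """
    for v in (or_pat, or_mat, *ci_pat, *ci_mat):
        if v <= 0:
            raise ValueError("odds ratios and CI bounds must be positive")
    if ci_pat[0] >= ci_pat[1] or ci_mat[0] >= ci_mat[1]:
        raise ValueError("CI bounds inverted")
    se_p = (np.log(ci_pat[1]) - np.log(ci_pat[0])) / (2 * level_z)
    se_m = (np.log(ci_mat[1]) - np.log(ci_mat[0])) / (2 * level_z)
    diff = np.log(or_pat) - np.log(or_mat)
    half = level_z * np.hypot(se_p, se_m)
    return float(np.exp(diff)), (float(np.exp(diff - half)),
                                 float(np.exp(diff + half)))


def h2_diff_z(h2_a: float, se_a: float, h2_b: float, se_b: float,
              weight_a: float = 1.0, weight_b: float = 1.0
              ) -> tuple[float, float]:
    """Z and P for a difference of two heritability estimates; subset
    estimates may be pre-weighted by the proportion of variants included."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    z = (h2_a * weight_a - h2_b * weight_b) / np.hypot(se_a, se_b)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# --------------------------------------------------------------------------- #
def load_known_poe_table() -> pd.DataFrame:
    """Published POE summary statistics (imprinted-region and additive-region
    scans): per row the parental effect sizes, standard errors, P values,
    scan flags and reported POE class letter."""
    ref = importlib.resources.files("pofokit.data") / "known_poe_table.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str})
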