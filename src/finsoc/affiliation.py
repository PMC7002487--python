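"""Generalized affiliation indices and dyadic hypothesis tests.

The association index between two individuals confounds social preference
with structure: two dolphins sharing a bay, or two highly gregarious ones,
co-occur often regardless of any affinity.  The generalized affiliation
index (GAI) removes this by regressing the dyadic co-occurrence counts on
structural predictor matrices and taking the *deviance residual* of each
dyad as its affiliation:

    x_ij ~ Binomial(d_ij, mu_ij),  logit(mu_ij) = b0 + sum_k b_k * P_k,ij

    GAI_ij = sign(x - d*mu) * sqrt(2 * [x ln(x / (d mu))
                                        + (d - x) ln((d - x) / (d - d mu))])

where ``x`` is the number of sampling days the dyad was grouped together
and ``d`` the half-weight denominator.  Predictors are screened beforehand
with an MRQAP (node-permutation matrix regression); only those
significantly correlated with the HWI are retained.

The module follows a model/results pattern:
:class:`GeneralizedAffiliationModel` holds the dyadic counts and predictor
matrices, and its :meth:`~GeneralizedAffiliationModel.fit` returns a
:class:`GAIResults` carrying coefficients, the GAI matrix, the
preferred/casual/avoided classification and a summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .associations import DyadCounts, dyad_counts, gregariousness_predictor, hwi, validate_sightings
from .dyadmatrix import DyadMatrix

__all__ = [
    "MRQAPScreen",
    "mrqap_screen",
    "GeneralizedAffiliationModel",
    "GAIResults",
    "fit_gai",
    "AffiliationClasses",
    "classify",
    "binomial_deviance_residual",
    "PermutationTestResult",
    "checkerboard_swaps",
    "preferred_avoided_test",
    "reproductive_similarity",
    "mantel",
    "gai_by_condition",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MRQAP predictor screen
# ---------------------------------------------------------------------------

@dataclass
class MRQAPScreen:
    """Partial correlations, permutation p-values and the retained set."""

    names: list[str]
    partial_r: dict[str, float]
    p_values: dict[str, float]
    retained: list[str]
    n_perm: int
    alpha: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "partial_r": [self.partial_r[k] for k in self.names],
                "p": [self.p_values[k] for k in self.names],
                "retained": [k in self.retained for k in self.names],
            },
            index=self.names,
        )


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residual of y on X (with intercept included in X)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def mrqap_screen(
    response: DyadMatrix,
    predictors: dict[str, DyadMatrix],
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    max_condition: float = 1e8,
) -> MRQAPScreen:
    """Screen structural predictors against the association matrix.

    Uses Dekker's double-semi-partialing MRQAP: for each predictor, both
    the response and the predictor are residualized on the remaining
    predictors; the partial correlation of the two residual vectors is the
    statistic, and its null distribution comes from joint row/column (node)
    permutations of the predictor's residual *matrix*, which respects the
    dyadic dependence structure.  Predictors with p < ``alpha`` are
    retained.
    """
    names = list(predictors)
    ids = response.ids
    n = response.n
    if n < 4:
        raise ValueError("MRQAP needs at least 4 individuals")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)

    mats = {}
    for k, m in predictors.items():
        if m.ids != ids:
            m = m.reindex(ids)
        mats[k] = m.values
    vecs = {k: v[iu, ju] for k, v in mats.items()}
    yvec = response.values[iu, ju]

    # collinearity guard
    std = {k: (v - v.mean()) / v.std() for k, v in vecs.items() if v.std() > 0}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ka, kb = names[a], names[b]
            if ka in std and kb in std:
                r = float(np.mean(std[ka] * std[kb]))
                if abs(r) > 0.999:
                    raise ValueError(f"collinear predictors: {ka!r} and {kb!r}")
    design = np.column_stack([np.ones_like(yvec)] + [vecs[k] for k in names])
    if np.linalg.cond(design) > max_condition:
        raise ValueError(f"predictor design is ill-conditioned: {names}")

    partial_r: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for k in names:
        others = [vecs[o] for o in names if o != k]
        X = np.column_stack([np.ones_like(yvec)] + others)
        ey = _residualize(yvec, X)
        ek_vec = _residualize(vecs[k], X)
        ek_mat = DyadMatrix.from_dyad_values(ids, ek_vec).values
        denom = np.linalg.norm(ey) * np.linalg.norm(ek_vec)
        if denom == 0:
            raise ValueError(f"zero-variance residual for predictor {k!r}")
        r_obs = float(ey @ ek_vec / denom)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            pv = ek_mat[np.ix_(perm, perm)][iu, ju]
            r_p = ey @ pv / (np.linalg.norm(ey) * np.linalg.norm(pv))
            if abs(r_p) >= abs(r_obs) - 1e-12:
                count += 1
        partial_r[k] = r_obs
        p_values[k] = (1 + count) / (1 + n_perm)
    retained = [k for k in names if p_values[k] < alpha]
    return MRQAPScreen(
        names=names, partial_r=partial_r, p_values=p_values,
        retained=retained, n_perm=n_perm, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# GAI model / results
# ---------------------------------------------------------------------------

def binomial_deviance_residual(x: np.ndarray, d: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Signed binomial deviance residual with the 0*ln(0/.) = 0 convention."""
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    mu = np.asarray(mu, dtype=float)
    fitted = d * mu
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(x > 0, x * np.log(x / fitted), 0.0)
        t2 = np.where(d - x > 0, (d - x) * np.log((d - x) / (d - fitted)), 0.0)
    dev = np.clip(2.0 * (t1 + t2), 0.0, None)
    return np.sign(x - fitted) * np.sqrt(dev)


def _fit_binomial_mu(xvec, dvec, exog):
    """Fitted binomial mean per dyad; closed form for the intercept-only model."""
    if exog.shape[1] == 1:
        mu = np.full(len(xvec), xvec.sum() / dvec.sum())
        return mu, np.array([sm.families.links.Logit()(mu[0])]), None
    model = sm.GLM(xvec / dvec, exog, family=sm.families.Binomial(), var_weights=dvec)
    res = model.fit()
    if not res.converged:
        raise RuntimeError(f"GAI binomial regression did not converge: {res.fit_history}")
    return np.asarray(res.fittedvalues), np.asarray(res.params), res


class GeneralizedAffiliationModel:
    """Binomial regression of dyadic co-occurrence on structural predictors.

    Parameters
    ----------
    counts
        Per-dyad tallies (x successes out of d half-weight trials).
    predictors
        Retained structural predictor matrices, possibly empty (the model
        then reduces to a single shared co-occurrence rate and the GAIs
        are residuals around it).
    """

    def __init__(self, counts: DyadCounts, predictors: dict[str, DyadMatrix] | None = None):
        self.counts = counts
        self.predictors = dict(predictors or {})
        self.ids = list(counts.ids)
        for k, m in self.predictors.items():
            if m.ids != self.ids:
                self.predictors[k] = m.reindex(self.ids)

    @classmethod
    def from_sightings(
        cls, records: pd.DataFrame, ids: list, predictors: dict[str, DyadMatrix] | None = None
    ) -> "GeneralizedAffiliationModel":
        return cls(dyad_counts(records, ids), predictors)

    def _design(self):
        n = len(self.ids)
        iu, ju = np.triu_indices(n, k=1)
        x = self.counts.x[iu, ju].astype(float)
        d = self.counts.denominator[iu, ju]
        keep = d > 0
        if not keep.all():
            logger.warning("fit_gai: excluding %d dyads with d = 0", int((~keep).sum()))
        cols = [np.ones(int(keep.sum()))]
        for k in self.predictors:
            cols.append(self.predictors[k].values[iu, ju][keep])
        return x, d, keep, np.column_stack(cols), (iu, ju)

    def fit(self) -> "GAIResults":
        x, d, keep, exog, (iu, ju) = self._design()
        mu, params, res = _fit_binomial_mu(x[keep], d[keep], exog)
        gai_vec = np.full(len(x), np.nan)
        gai_vec[keep] = binomial_deviance_residual(x[keep], d[keep], mu)
        gai = DyadMatrix.from_dyad_values(self.ids, np.nan_to_num(gai_vec))
        names = ["intercept"] + list(self.predictors)
        bse = dict(zip(names, res.bse)) if res is not None else {"intercept": np.nan}
        return GAIResults(
            model=self,
            params=dict(zip(names, params)),
            bse=bse,
            gai=gai,
            mu=mu,
            dyad_mask=keep,
            _glm_results=res,
        )


@dataclass
class GAIResults:
    """Fitted GAI regression: coefficients, residual matrix, diagnostics."""

    model: GeneralizedAffiliationModel
    params: dict[str, float]
    bse: dict[str, float]
    gai: DyadMatrix
    mu: np.ndarray
    dyad_mask: np.ndarray
    _glm_results: object = field(repr=False, default=None)

    def classify(self, threshold: float = 2.5) -> "AffiliationClasses":
        return classify(self.gai, threshold)

    def predictor_correlations(self) -> dict[str, float]:
        """Pearson r between GAIs and each retained predictor (diagnostic:
        should be near zero — the residuals are controlled for them)."""
        vals = self.gai.dyad_values()[self.dyad_mask]
        out = {}
        for k, m in self.model.predictors.items():
            pv = m.dyad_values()[self.dyad_mask]
            out[k] = float(np.corrcoef(vals, pv)[0, 1]) if pv.std() > 0 else np.nan
        return out

    def summary(self) -> str:
        g = self.gai.dyad_values()[self.dyad_mask]
        lines = [
            "Generalized Affiliation Index (binomial, logit link)",
            "=" * 56,
            f"individuals: {len(self.gai.ids)}    dyads used: {int(self.dyad_mask.sum())}",
            f"GAI range: [{g.min():.2f}, {g.max():.2f}]   mean {g.mean():.2f}   SD {g.std(ddof=1):.2f}",
            "-" * 56,
            f"{'term':<24}{'coef':>10}{'std err':>12}",
        ]
        for k, v in self.params.items():
            se = self.bse.get(k, np.nan)
            lines.append(f"{k:<24}{v:>10.4f}{se:>12.4f}")
        lines.append("-" * 56)
        for k, r in self.predictor_correlations().items():
            lines.append(f"residual corr with {k}: {r:+.4f}")
        return "\n".join(lines)


def fit_gai(counts: DyadCounts, predictors: dict[str, DyadMatrix] | None = None) -> GAIResults:
    """Functional wrapper: ``GeneralizedAffiliationModel(counts, predictors).fit()``."""
    return GeneralizedAffiliationModel(counts, predictors).fit()


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class AffiliationClasses:
    """Preferred / casual / avoided partition of the dyads."""

    table: pd.DataFrame  # columns: id_i, id_j, gai, label
    threshold: float

    @property
    def counts(self) -> dict[str, int]:
        c = self.table["label"].value_counts()
        return {k: int(c.get(k, 0)) for k in ("preferred", "casual", "avoided")}

    def labels_for(self, matrix: DyadMatrix) -> pd.DataFrame:
        """Join dyad values of another matrix onto the class table."""
        out = self.table.copy()
        out["value"] = [matrix[(a, b)] for a, b in zip(out["id_i"], out["id_j"])]
        return out


def classify(gai: DyadMatrix, threshold: float = 2.5) -> AffiliationClasses:
    """Three-way partition: > threshold preferred, < -threshold avoided,
    the closed interval in between (including the boundaries) casual."""
    iu, ju = gai.triu_indices()
    vals = gai.values[iu, ju]
    labels = np.where(vals > threshold, "preferred", np.where(vals < -threshold, "avoided", "casual"))
    table = pd.DataFrame(
        {
            "id_i": [gai.ids[a] for a in iu],
            "id_j": [gai.ids[b] for b in ju],
            "gai": vals,
            "label": labels,
        }
    )
    return AffiliationClasses(table=table, threshold=threshold)


# ---------------------------------------------------------------------------
# Bejder-style data-stream permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    observed: float
    null_stats: np.ndarray
    p: float
    n_perm: int
    flips_per_perm: int
    seed: int | None
    statistic: str = "sd"

    @property
    def null_mean(self) -> float:
        return float(self.null_stats.mean())


def _incidence(records: pd.DataFrame, ids: list[str]):
    """Group x individual boolean incidence plus each group's day index."""
    pos = {i: k for k, i in enumerate(ids)}
    rec = records[records["individual_id"].isin(set(ids))]
    groups = []
    day_of = []
    days = []
    for dkey, day in rec.groupby("date"):
        gidx = []
        for _, g in day.groupby("group_id"):
            members = [pos[i] for i in g["individual_id"]]
            gidx.append(len(groups))
            groups.append(members)
            day_of.append(len(days))
        days.append(gidx)
        del dkey
    A = np.zeros((len(groups), len(ids)), dtype=bool)
    for gi, members in enumerate(groups):
        A[gi, members] = True
    return A, np.array(day_of), days


def checkerboard_swaps(A: np.ndarray, swap_days: list, n_swaps: int, rng) -> None:
    """Apply ``n_swaps`` restricted checkerboard swaps to the incidence in place.

    Each swap picks two groups from one day, an individual in the first
    only and one in the second only, and exchanges them — preserving
    every group size, every individual's sighting total, and the day
    structure.  Raises if no legal swap can be found.
    """
    failures = 0
    done = 0
    while done < n_swaps:
        gidx = swap_days[rng.integers(len(swap_days))]
        g1, g2 = rng.choice(gidx, size=2, replace=False)
        only1 = np.flatnonzero(A[g1] & ~A[g2])
        only2 = np.flatnonzero(A[g2] & ~A[g1])
        if len(only1) == 0 or len(only2) == 0:
            failures += 1
            if failures > 1000 * max(n_swaps, 1):
                raise ValueError("degenerate incidence structure: no legal swap found")
            continue
        i = only1[rng.integers(len(only1))]
        j = only2[rng.integers(len(only2))]
        A[g1, i] = False
        A[g2, i] = True
        A[g2, j] = False
        A[g1, j] = True
        done += 1


def preferred_avoided_test(
    records: pd.DataFrame,
    ids: list,
    predictors: dict[str, DyadMatrix] | None = None,
    index: str = "gai",
    n_perm: int = 10_000,
    flips_per_perm: int = 1_000,
    seed: int | None = None,
    recompute_gregariousness: bool = True,
) -> PermutationTestResult:
    """Test for preferred/avoided companionship by data-stream permutation.

    The group-by-individual incidence matrix is permuted by checkerboard
    swaps restricted to pairs of groups observed on the *same day*: pick
    groups g1, g2 from one day and individuals i in g1 only, j in g2 only,
    and exchange them.  Every swap preserves each group's size, each
    individual's sighting total, and the day structure.  After each batch
    of ``flips_per_perm`` swaps the affiliation indices are recomputed from
    the permuted stream and the test statistic (SD of the dyadic indices)
    saved; p is the fraction of permuted statistics >= the observed one.

    ``index`` selects the statistic's matrix: ``"gai"`` (deviance
    residuals, refitted each permutation; gregariousness, when among the
    predictors, is recomputed from the permuted association matrix while
    spatial and effort predictors are held at their observed values) or
    ``"hwi"``.
    """
    rec = validate_sightings(records)
    ids = [str(i) for i in ids]
    if rec["date"].nunique() < 2:
        raise ValueError("need at least 2 sampling days")
    A, day_of, days = _incidence(rec, ids)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 groups")
    swap_days = [d for d in days if len(d) >= 2]
    if not swap_days:
        raise ValueError("degenerate incidence structure: no day has two groups")
    rng = np.random.default_rng(seed)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)

    # invariants of the swap chain: sighting totals, days-both-seen, denominator
    n_days_total = len(days)
    S = np.zeros((n_days_total, n), dtype=bool)
    for di, gidx in enumerate(days):
        S[di] = A[gidx].any(axis=0)
    n_i = S.sum(axis=0).astype(float)
    d_mat = (n_i[:, None] + n_i[None, :]) / 2.0  # holds because yAB days count in both margins
    dvec = d_mat[iu, ju]
    keep = dvec > 0

    preds = dict(predictors or {})
    static_cols = [
        preds[k].values[iu, ju][keep] for k in preds if k != "gregariousness"
    ]
    use_greg = "gregariousness" in preds

    def statistic(Acur: np.ndarray) -> float:
        x = (Acur.astype(np.int64).T @ Acur.astype(np.int64))[iu, ju].astype(float)
        if index == "hwi":
            vals = np.where(keep, x / np.where(keep, dvec, 1.0), np.nan)
            return float(np.nanstd(vals, ddof=1))
        hwi_mat = DyadMatrix.from_dyad_values(
            ids, np.where(keep, x / np.where(keep, dvec, 1.0), 0.0)
        )
        cols = [np.ones(int(keep.sum()))]
        if use_greg and recompute_gregariousness:
            cols.append(gregariousness_predictor(hwi_mat).values[iu, ju][keep])
        elif use_greg:
            cols.append(preds["gregariousness"].values[iu, ju][keep])
        cols.extend(static_cols)
        mu, _, _ = _fit_binomial_mu(x[keep], dvec[keep], np.column_stack(cols))
        return float(np.std(binomial_deviance_residual(x[keep], dvec[keep], mu), ddof=1))

    observed = statistic(A)
    Ap = A.copy()
    null_stats = np.empty(n_perm)
    for p_i in range(n_perm):
        checkerboard_swaps(Ap, swap_days, flips_per_perm, rng)
        null_stats[p_i] = statistic(Ap)
    p = float((null_stats >= observed - 1e-12).sum() + 1) / (n_perm + 1)
    return PermutationTestResult(
        observed=observed, null_stats=null_stats, p=p,
        n_perm=n_perm, flips_per_perm=flips_per_perm, seed=seed, statistic=f"sd({index})",
    )


# ---------------------------------------------------------------------------
# reproductive condition
# ---------------------------------------------------------------------------

def reproductive_similarity(categories: dict | pd.Series) -> DyadMatrix:
    """Binary similarity: 1 if two females share the reproductive category
    (with a dependent calf for most of the study vs. without), else 0."""
    if isinstance(categories, pd.Series):
        categories = categories.to_dict()
    ids = [str(k) for k in categories]
    cats = []
    for k in categories:
        v = categories[k]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing reproductive category for individual {k!r}")
        cats.append(v)
    arr = np.asarray(cats)
    sim = (arr[:, None] == arr[None, :]).astype(float)
    return DyadMatrix(ids, sim)


def mantel(
    mat_a: DyadMatrix,
    mat_b: DyadMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel test between two dyadic matrices.

    Pearson correlation over the off-diagonal dyads; the null is built by
    jointly permuting rows and columns of the second matrix.
    ``alternative`` fixes the tail: ``"greater"`` (default; every
    directional hypothesis here predicts a positive correlation),
    ``"less"``, or ``"two-sided"``.  Fixing the tail a priori keeps the
    test calibrated; picking it from the observed sign would not.
    """
    if mat_a.ids != mat_b.ids:
        mat_a, mat_b = mat_a.align_with(mat_b)
    a = mat_a.dyad_values()
    n = mat_a.n
    iu, ju = np.triu_indices(n, k=1)
    bm = mat_b.values
    b = bm[iu, ju]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance matrix in Mantel test")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    az = (a - a.mean()) / a.std()
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = bm[np.ix_(perm, perm)][iu, ju]
        r_p = float(np.mean(az * (bp - bp.mean()) / bp.std()))
        if alternative == "greater":
            count += r_p >= r_obs - 1e-12
        elif alternative == "less":
            count += r_p <= r_obs + 1e-12
        else:
            count += abs(r_p) >= abs(r_obs) - 1e-12
    return r_obs, (1 + count) / (1 + n_perm)


def gai_by_condition(
    gai: DyadMatrix, similarity: DyadMatrix
) -> tuple[float, float, float, float]:
    """Compare affiliation strength between same- and different-condition dyads.

    Returns (median same, median different, Mann-Whitney U, p) using the
    normal approximation with tie correction.  Dyads are treated as
    independent observations, which overstates the effective sample size;
    interpret p as descriptive.
    """
    if gai.ids != similarity.ids:
        gai, similarity = gai.align_with(similarity)
    g = gai.dyad_values()
    s = similarity.dyad_values()
    same = g[s == 1]
    diff = g[s == 0]
    if len(same) == 0 or len(diff) == 0:
        raise ValueError("one of the condition groups has no dyads")
    stat = scipy.stats.mannwhitneyu(same, diff, alternative="two-sided", method="asymptotic")
    return float(np.median(same)), float(np.median(diff)), float(stat.statistic), float(stat.pvalue)
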