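"""Single-trial N400 amplitudes: nested mixed-model ladder with AIC selection.

The response is the single-trial mean voltage in the N400 window over the
centro-parietal cluster.  Eight models M0..M7 share one random-effect
structure — correlated Constraint-by-Participant intercepts and slopes plus
Item intercepts (participants and items crossed) — and add sum-coded fixed
effects in a fixed order: Accent, Constraint, Face, Accent*Constraint,
Constraint*Face, Accent*Face, Accent*Constraint*Face.

Fitting maximises the marginal likelihood (ML, not REML, so AICs are
comparable across fixed-effect structures) by profiling beta and the
residual variance out of the deviance and optimising the low-dimensional
relative-covariance parameters: with b ~ N(0, sigma^2 Lambda Lambda'), the
penalised least-squares system

    [Lambda' Z'Z Lambda + I] u = Lambda' Z'(y - X beta)

yields the profiled deviance

    d(theta) = log|Lambda' Z'Z Lambda + I| + n [1 + log(2 pi r^2(theta)/n)]

where r^2 is the minimised penalised residual sum of squares.  All
products with the data are precomputed (Z'Z, Z'X, Z'y, ...), so each
deviance evaluation is independent of the number of trials.

Model comparison reports AIC = d + 2k with k counting fixed effects,
variance/covariance parameters (4) and the residual (1); delta-AIC and
Akaike weights exp(-dAIC/2)/sum follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, sparse, stats

from .dataset import DatasetError

__all__ = [
    "ModelSpec",
    "build_ladder",
    "LadderData",
    "fit_lmm",
    "fit_ladder",
    "compare_aic",
    "summarize_best",
    "posthoc_face_by_constraint",
    "SUM_CODES",
]

#: sum coding, level shown in brackets coded +1
SUM_CODES = {
    "accent": {"L2": 1.0, "L1": -1.0},
    "constraint": {"HC": 1.0, "LC": -1.0},
    "face": {"Face": 1.0, "NoFace": -1.0},
}

_LABELS = {"accent": "Accent[L2]", "constraint": "Constraint[HC]", "face": "Face[Face]"}

_LADDER_ORDER = (
    "accent",
    "constraint",
    "face",
    "accent:constraint",
    "constraint:face",
    "accent:face",
    "accent:constraint:face",
)


def term_label(term: str) -> str:
    return "*".join(_LABELS[f] for f in term.split(":"))


@dataclass(frozen=True)
class ModelSpec:
    name: str
    terms: tuple[str, ...]  # fixed-effect terms beyond the intercept

    @property
    def formula(self) -> str:
        parts = [
            t.replace(":", "*")
            .replace("accent", "Accent")
            .replace("constraint", "Constraint")
            .replace("face", "Face")
            for t in self.terms
        ]
        rhs = " + ".join(parts + ["(Constraint|Participant)", "(1|Item)"]) if parts else (
            "(Constraint|Participant) + (1|Item)"
        )
        return f"Amplitude ~ {rhs}"


def build_ladder() -> list[ModelSpec]:
    """The eight nested specs M0..M7 over the shared random structure."""
    specs = [ModelSpec("M0", ())]
    for i, term in enumerate(_LADDER_ORDER, start=1):
        specs.append(ModelSpec(f"M{i}", specs[-1].terms + (term,)))
    return specs


def _design_matrix(df: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    coded = {
        f: df[f].map(SUM_CODES[f]).to_numpy(dtype=float) for f in SUM_CODES
    }
    for f, col in coded.items():
        if np.isnan(col).any():
            raise DatasetError(f"unknown level in column {f!r}")
    for term in terms:
        x = np.ones(len(df))
        for f in term.split(":"):
            x = x * coded[f]
        cols.append(x)
        names.append(term_label(term))
    return np.column_stack(cols), names


class LadderData:
    """Precomputed cross-products shared by every model in a ladder fit."""

    def __init__(self, trials: pd.DataFrame):
        required = {"participant", "item", "accent", "constraint", "face", "amplitude"}
        missing = required - set(trials.columns)
        if missing:
            raise DatasetError(f"trial table missing columns: {sorted(missing)}")
        trials = trials.reset_index(drop=True)
        if not np.isfinite(trials["amplitude"].to_numpy(dtype=float)).all():
            raise DatasetError("amplitudes must be finite")
        self.trials = trials
        y = trials["amplitude"].to_numpy(dtype=float)
        part = pd.Categorical(trials["participant"])
        item = pd.Categorical(trials["item"])
        self.n = len(y)
        self.n_part = len(part.categories)
        self.n_item = len(item.categories)
        if self.n_part < 2 or self.n_item < 2:
            raise DatasetError("need at least two participants and two items")
        c = trials["constraint"].map(SUM_CODES["constraint"]).to_numpy(dtype=float)
        rows = np.arange(self.n)
        pi = np.asarray(part.codes, dtype=int)
        ii = np.asarray(item.codes, dtype=int)
        q = 2 * self.n_part + self.n_item
        # column layout: participant intercepts [0:P), slopes [P:2P), items [2P:)
        data = np.concatenate([np.ones(self.n), c, np.ones(self.n)])
        r = np.concatenate([rows, rows, rows])
        col = np.concatenate([pi, self.n_part + pi, 2 * self.n_part + ii])
        Z = sparse.csr_matrix((data, (r, col)), shape=(self.n, q))
        self.q = q
        self.ZtZ = np.asarray((Z.T @ Z).todense())
        self.Zty = Z.T @ y
        self.yty = float(y @ y)
        self.y = y
        self._Z = Z

    def model_blocks(self, terms):
        X, names = _design_matrix(self.trials, terms)
        return dict(
            X=X,
            names=names,
            ZtX=np.asarray((self._Z.T @ X)),
            XtX=X.T @ X,
            Xty=X.T @ self.y,
        )

    def lambda_mat(self, theta) -> np.ndarray:
        """Relative covariance factor: participant 2x2 blocks + item diagonal."""
        t11, t21, t22, ti = theta
        q, P = self.q, self.n_part
        lam = np.zeros((q, q))
        d = np.empty(q)
        d[:P] = t11
        d[P : 2 * P] = t22
        d[2 * P :] = ti
        np.fill_diagonal(lam, d)
        lam[np.arange(P, 2 * P), np.arange(P)] = t21
        return lam


def _lam_product(data: LadderData, theta, M):
    """Lambda' M for the block-structured relative covariance factor."""
    t11, t21, t22, ti = theta
    P = data.n_part
    out = np.empty_like(M)
    out[:P] = t11 * M[:P] + t21 * M[P : 2 * P]
    out[P : 2 * P] = t22 * M[P : 2 * P]
    out[2 * P :] = ti * M[2 * P :]
    return out


def _profiled(data: LadderData, blocks, theta):
    """Profiled ML deviance and the PLS by-products at theta."""
    t11, t21, t22, ti = theta
    P = data.n_part
    ZtZ = data.ZtZ
    C = np.empty_like(ZtZ)  # ZtZ @ Lambda, column-block form
    C[:, :P] = t11 * ZtZ[:, :P] + t21 * ZtZ[:, P : 2 * P]
    C[:, P : 2 * P] = t22 * ZtZ[:, P : 2 * P]
    C[:, 2 * P :] = ti * ZtZ[:, 2 * P :]
    A = _lam_product(data, theta, C)
    A[np.diag_indices_from(A)] += 1.0
    L = sla.cholesky(A, lower=True, check_finite=False)
    LZX = sla.solve_triangular(
        L, _lam_product(data, theta, blocks["ZtX"]), lower=True, check_finite=False
    )
    cu = sla.solve_triangular(
        L, _lam_product(data, theta, data.Zty), lower=True, check_finite=False
    )
    XtVX = blocks["XtX"] - LZX.T @ LZX
    rhs = blocks["Xty"] - LZX.T @ cu
    try:
        cf = sla.cho_factor(XtVX, check_finite=False)
        beta = sla.cho_solve(cf, rhs)
    except np.linalg.LinAlgError:
        # cancellation can leave XtVX indefinite at extreme theta; a tiny
        # symmetric ridge keeps the profiled objective finite there
        jitter = 1e-10 * max(np.trace(XtVX) / XtVX.shape[0], 1.0)
        XtVX = XtVX + jitter * np.eye(XtVX.shape[0])
        beta = np.linalg.solve(XtVX, rhs)
    pwrss = data.yty - cu @ cu - beta @ rhs
    pwrss = max(float(pwrss), 1e-12)
    n = data.n
    logdet = 2.0 * np.log(np.diag(L)).sum()
    dev = logdet + n * (1.0 + np.log(2.0 * np.pi * pwrss / n))
    return dev, beta, pwrss, XtVX


@dataclass
class LMMFit:
    spec: ModelSpec
    theta: np.ndarray
    beta: pd.Series
    se: pd.Series
    cov_beta: np.ndarray
    sigma2: float
    loglik: float
    deviance: float
    aic: float
    k_params: int
    n_obs: int
    converged: bool
    singular: bool
    random_effects: dict = field(default_factory=dict)


_THETA0 = np.array([1.0, 0.0, 1.0, 1.0])
_BOUNDS = [(0.0, None), (None, None), (0.0, None), (0.0, None)]


def fit_lmm(
    trials,
    spec: ModelSpec,
    data: LadderData | None = None,
    theta0: np.ndarray | None = None,
) -> LMMFit:
    """ML fit of one ladder model; deterministic optimizer settings."""
    if data is None:
        data = LadderData(trials)
    blocks = data.model_blocks(spec.terms)

    def fun(th):
        return _profiled(data, blocks, th)[0]

    # absolute finite-difference step: the deviance is O(n), so the default
    # relative step underflows the curvature and stalls the line search
    res = optimize.minimize(
        fun,
        _THETA0 if theta0 is None else np.asarray(theta0, dtype=float),
        method="L-BFGS-B",
        bounds=_BOUNDS,
        options=dict(maxiter=500, ftol=1e-13, gtol=1e-7, eps=1e-6),
    )
    if not res.success:
        # derivative-free fallback for line-search stalls
        res2 = optimize.minimize(
            fun,
            res.x,
            method="Nelder-Mead",
            options=dict(maxiter=800, fatol=1e-7, xatol=1e-6),
        )
        if res2.fun <= res.fun:
            res = res2
        if not (res.success or res2.success):
            raise DatasetError(f"model {spec.name} did not converge: {res.message}")
    theta = res.x
    dev, beta, pwrss, XtVX = _profiled(data, blocks, theta)
    sigma2 = pwrss / data.n
    cov_beta = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    p = len(beta)
    k = p + 4 + 1
    singular = bool(min(theta[0], theta[2], theta[3]) < 1e-4)
    if singular:
        warnings.warn(
            f"model {spec.name}: singular random-effect covariance (theta={theta})",
            stacklevel=2,
        )
    t11, t21, t22, ti = theta
    sd = np.sqrt(sigma2)
    cov_p = sigma2 * np.array([[t11**2, t11 * t21], [t11 * t21, t21**2 + t22**2]])
    re = dict(
        participant_intercept_sd=float(np.sqrt(cov_p[0, 0])),
        participant_slope_sd=float(np.sqrt(cov_p[1, 1])),
        participant_corr=float(
            cov_p[0, 1] / np.sqrt(cov_p[0, 0] * cov_p[1, 1])
            if cov_p[0, 0] > 0 and cov_p[1, 1] > 0
            else np.nan
        ),
        item_sd=float(ti * sd),
        residual_sd=float(sd),
    )
    names = blocks["names"]
    return LMMFit(
        spec=spec,
        theta=theta,
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        loglik=-dev / 2.0,
        deviance=float(dev),
        aic=float(dev + 2 * k),
        k_params=k,
        n_obs=data.n,
        converged=bool(res.success),
        singular=singular,
    )


def fit_ladder(trials: pd.DataFrame, ladder: list[ModelSpec] | None = None) -> list[LMMFit]:
    """Fit every model of the ladder on shared precomputed cross-products."""
    if ladder is None:
        ladder = build_ladder()
    data = LadderData(trials)
    fits: list[LMMFit] = []
    theta0 = None
    for spec in ladder:
        fit = fit_lmm(None, spec, data=data, theta0=theta0)
        theta0 = fit.theta  # warm start: the random structure is shared
        fits.append(fit)
    return fits


def compare_aic(
    aics=None, daics=None, names=None, deviances=None, fits=None
) -> pd.DataFrame:
    """Delta-AIC and Akaike weights; the zero-dAIC model is flagged best.

    Accepts raw AICs, a dAIC column (as printed in comparison tables), or a
    list of fitted models.
    """
    if fits is not None:
        aics = [f.aic for f in fits]
        names = [f.spec.name for f in fits]
        deviances = [f.deviance for f in fits]
    if daics is None:
        if aics is None or len(aics) < 2:
            raise DatasetError("need at least two models")
        aics = np.asarray(aics, dtype=float)
        daics = aics - aics.min()
    else:
        daics = np.asarray(daics, dtype=float)
        if len(daics) < 2:
            raise DatasetError("need at least two models")
        daics = daics - daics.min()
    w = np.exp(-daics / 2.0)
    w = w / w.sum()
    out = pd.DataFrame(
        {
            "model": names if names is not None else [f"M{i}" for i in range(len(daics))],
            "dAIC": daics,
            "AICw": w,
            "best": daics == 0.0,
        }
    )
    if deviances is not None:
        out.insert(1, "deviance", np.asarray(deviances, dtype=float))
    if aics is not None:
        out.insert(1, "AIC", np.asarray(aics, dtype=float))
    return out


def summarize_best(fit: LMMFit) -> pd.DataFrame:
    """Fixed-effect table: estimate, 95% CI (+-1.96 SE), SE, t, normal-approx p."""
    est = fit.beta.to_numpy()
    se = fit.se.to_numpy()
    t = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(t))
    return pd.DataFrame(
        {
            "term": fit.beta.index,
            "estimate": est,
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
            "se": se,
            "t_value": t,
            "p": p,
        }
    )


def posthoc_face_by_constraint(fit: LMMFit, family_size: int = 2) -> pd.DataFrame:
    """Face effect within each Constraint level from the fitted fixed effects.

    With +-1 sum coding, the Face - NoFace cell-mean difference at
    Constraint level c is 2*beta_Face + 2c*beta_Constraint*Face (terms
    involving Accent average out).  z = b/SE from the fixed-effect
    covariance; Bonferroni over the two contrasts.
    """
    names = list(fit.beta.index)
    f_lab, cf_lab = term_label("face"), term_label("constraint:face")
    if cf_lab not in names:
        raise DatasetError("model does not include the Constraint*Face term")
    rows = []
    for level, c in (("HC", 1.0), ("LC", -1.0)):
        w = np.zeros(len(names))
        w[names.index(f_lab)] = 2.0
        w[names.index(cf_lab)] = 2.0 * c
        b = float(w @ fit.beta.to_numpy())
        se = float(np.sqrt(w @ fit.cov_beta @ w))
        z = b / se if se > 0 else np.inf * np.sign(b)
        p_raw = float(2 * stats.norm.sf(abs(z)))
        rows.append(
            dict(
                contrast=f"Face|{level}",
                estimate=b,
                se=se,
                z_ratio=z,
                p_raw=p_raw,
                p_adj=min(1.0, family_size * p_raw),
                family_size=family_size,
            )
        )
    return pd.DataFrame(rows)
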