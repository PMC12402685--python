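"""Temporal exploratory factor analysis of averaged ERP waveforms.

Time samples play the role of variables and waveforms (one per participant
x condition x electrode) the role of observations.  The decomposition runs
per accent: observation matrix -> Empirical Kaiser Criterion (number of
factors) -> common-factor extraction from the time-point covariance ->
oblique Geomin rotation (30 random starts, eps = 0.01) -> regression factor
scores -> variance-explained accounting -> retention of factors explaining
more than 3% of total variance -> signed peak amplitudes per electrode
cluster.

Loadings live in the covariance (microvolt) metric, so a factor's loading
curve is its voltage contribution over time; scores are standardized, so
score x peak loading is a microvolt amplitude per observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import AverageSet, ClusterSpec, DatasetError
from .rotation import RotationResult, geomin_rotate

__all__ = [
    "ObservationMatrix",
    "EkcResult",
    "FactorSolution",
    "build_observation_matrix",
    "compute_ekc",
    "extract_factors",
    "compute_scores",
    "variance_explained",
    "select_factors",
    "align_signs",
    "fit_temporal_efa",
    "peak_amplitude",
    "reconstruct_component",
    "suggest_cluster",
    "ExtractionError",
]


class ExtractionError(RuntimeError):
    """Factor extraction failed to converge; carries the last discrepancy."""

    def __init__(self, msg, discrepancy=None):
        super().__init__(msg)
        self.discrepancy = discrepancy


@dataclass
class ObservationMatrix:
    """Rows = participant x condition x electrode waveforms; columns = time samples."""

    X: np.ndarray
    meta: pd.DataFrame  # participant, constraint, face, electrode (one accent)
    times: np.ndarray
    accent: str

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != len(self.meta):
            raise DatasetError("metadata rows do not match X")
        if self.X.shape[1] != np.asarray(self.times).size:
            raise DatasetError("time axis does not match X columns")

    @property
    def shape(self):
        return self.X.shape


def build_observation_matrix(averages: AverageSet, accent: str) -> ObservationMatrix:
    """Stack one accent's averaged waveforms into the EFA input matrix.

    Row order is deterministic: participant-major, then condition cell,
    then electrode.  The full epoch, including the pre-stimulus baseline,
    enters the analysis.
    """
    cmask = averages.cell_index(accent=accent)
    if not cmask.any():
        raise DatasetError(f"accent {accent!r} not present in the average set")
    cell_idx = np.flatnonzero(cmask)
    rows, meta = [], []
    for i, pid in enumerate(averages.participants):
        for j in cell_idx:
            cell = averages.cells.iloc[j]
            for e, lab in enumerate(averages.montage.labels):
                rows.append(averages.voltages[i, j, e])
                meta.append(
                    dict(
                        participant=pid,
                        constraint=cell["constraint"],
                        face=cell["face"],
                        electrode=lab,
                    )
                )
    return ObservationMatrix(
        X=np.asarray(rows),
        meta=pd.DataFrame(meta),
        times=averages.times.copy(),
        accent=accent,
    )


# ---------------------------------------------------------------------------
# Empirical Kaiser Criterion


@dataclass
class EkcResult:
    sample_eigenvalues: np.ndarray
    reference_eigenvalues: np.ndarray
    n_retained: int
    n_obs: int
    n_vars: int


def compute_ekc(X) -> EkcResult:
    """Empirical Kaiser Criterion on the correlation matrix of the columns.

    Eigenvalues l_1 >= ... >= l_p of the p x p correlation matrix are
    compared with sample-size-adjusted references

        ref_j = max( (1 + sqrt(p/n))^2 * (p - sum_{i<j} l_i) / (p - j + 1), 1 )

    and factors are retained greedily from j = 1 while l_j > ref_j,
    stopping at the first failure.
    """
    if isinstance(X, ObservationMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        warnings.warn(
            f"EKC: n_obs ({n}) <= n_vars ({p}); references are unreliable",
            stacklevel=2,
        )
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DatasetError("constant column: correlation matrix undefined")
    R = np.corrcoef(X, rowvar=False)
    ev = np.linalg.eigvalsh(R)[::-1]
    if ev[-1] < -1e-8:
        warnings.warn("rank-deficient correlation matrix; eigenvalues clipped at 0", stacklevel=2)
    ev = np.clip(ev, 0.0, None)
    shrink = (1.0 + np.sqrt(p / n)) ** 2
    csum = np.concatenate([[0.0], np.cumsum(ev)[:-1]])
    j = np.arange(1, p + 1)
    refs = np.maximum(shrink * (p - csum) / (p - j + 1), 1.0)
    above = ev > refs
    n_retained = p if above.all() else int(np.argmin(above))
    return EkcResult(ev, refs, n_retained, n, p)


# ---------------------------------------------------------------------------
# extraction


def _sample_cov(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / (X.shape[0] - 1)


def _principal_loadings(S, m):
    ev, V = np.linalg.eigh(S)
    ev, V = ev[::-1], V[:, ::-1]
    lam = np.sqrt(np.clip(ev[:m], 0.0, None))
    return V[:, :m] * lam


def extract_factors(X, m: int, method: str = "uls"):
    """Unrotated loadings (time x m, covariance metric) and uniquenesses.

    method='pca'  : principal components of the covariance; column k is
                    sqrt(l_k) v_k, uniquenesses zero.
    method='uls'  : unweighted-least-squares common factors via the
                    iterated principal-factor fixed point (diag(S - LL' - Psi) = 0).
    method='ml'   : maximum-likelihood common factors via EM.
    """
    if isinstance(X, ObservationMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    S = _sample_cov(X) if X.shape[0] != X.shape[1] or not np.allclose(X, X.T) else X
    p = S.shape[0]
    max_m = p if method == "pca" else p - 1
    if not 1 <= m <= max_m:
        raise DatasetError(f"need 1 <= m <= {max_m} for {method}, got m={m} (p={p})")
    if method == "pca":
        return _principal_loadings(S, m), np.zeros(p)
    if method == "uls":
        return _uls_factors(S, m)
    if method == "ml":
        return _ml_factors(S, m)
    raise DatasetError(f"unknown extraction method {method!r}")


def _uls_factors(S, m, max_iter=500, tol=1e-7):
    d = np.diag(S)
    # squared-multiple-correlation start for the communalities
    sd = np.sqrt(d)
    R = S / np.outer(sd, sd)
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(S.shape[0], 0.5)
    h2 = np.clip(smc, 0.0, 0.999) * d
    floor = 1e-3 * d
    last = None
    for _ in range(max_iter):
        Sr = S - np.diag(d - h2)
        L = _principal_loadings(Sr, m)
        h2_new = np.clip((L * L).sum(axis=1), 0.0, d - floor)
        delta = np.max(np.abs(h2_new - h2) / np.maximum(d, 1e-12))
        h2 = h2_new
        resid = S - L @ L.T - np.diag(d - h2)
        last = float((resid**2).sum() - (np.diag(resid) ** 2).sum())
        if delta < tol:
            return L, d - h2
    raise ExtractionError(
        f"ULS extraction did not converge in {max_iter} iterations", discrepancy=last
    )


def _ml_factors(S, m, max_iter=2000, tol=1e-9):
    p = S.shape[0]
    L = _principal_loadings(S, m)
    psi = np.clip(np.diag(S) - (L * L).sum(axis=1), 1e-4 * np.diag(S), None)
    ll_old = -np.inf
    for _ in range(max_iter):
        Sigma = L @ L.T + np.diag(psi)
        Sinv = np.linalg.inv(Sigma)
        B = L.T @ Sinv  # m x p
        Ezz = np.eye(m) - B @ L + B @ S @ B.T
        SB = S @ B.T
        L = SB @ np.linalg.inv(Ezz)
        psi = np.clip(np.diag(S - L @ (B @ S)), 1e-6 * np.diag(S), None)
        sign, logdet = np.linalg.slogdet(Sigma)
        ll = -0.5 * (logdet + np.trace(Sinv @ S))
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            return L, psi
        ll_old = ll
    raise ExtractionError(
        f"ML (EM) extraction did not converge in {max_iter} iterations",
        discrepancy=float(ll_old),
    )


# ---------------------------------------------------------------------------
# scores, variance explained, selection


def compute_scores(
    X,
    loadings: np.ndarray,
    phi: np.ndarray,
    psi: np.ndarray | None = None,
    method: str = "regression",
    use_model_sigma: bool = True,
    standardize: bool = True,
):
    """Regression (Thurstone) factor scores.

    scores = X_centered @ Sigma^-1 @ Lambda @ Phi, with Sigma the
    model-implied covariance Lambda Phi Lambda' + diag(psi) (or the sample
    covariance when ``use_model_sigma`` is false).  Columns are divided by
    their standard deviation when ``standardize`` (all-zero columns are
    left untouched).  Returns (scores, raw_scores).
    """
    if method != "regression":
        raise DatasetError(f"unknown score method {method!r}")
    if isinstance(X, ObservationMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    L = np.asarray(loadings, dtype=float)
    Phi = np.asarray(phi, dtype=float)
    if use_model_sigma:
        Sigma = L @ Phi @ L.T
        if psi is not None:
            Sigma = Sigma + np.diag(psi)
    else:
        Sigma = _sample_cov(X)
    W = _solve_psd(Sigma, L @ Phi)
    raw = Xc @ W
    if standardize:
        sd = raw.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        scores = raw / sd
    else:
        scores = raw
    return scores, raw


def _solve_psd(A, B):
    """Solve A X = B for symmetric PSD A, ridge-regularizing if singular."""
    jitter = 0.0
    scale = np.trace(A) / A.shape[0]
    for _ in range(12):
        try:
            c = np.linalg.cholesky(A + jitter * np.eye(A.shape[0]))
            y = np.linalg.solve(c, B)
            return np.linalg.solve(c.T, y)
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * scale)
            warnings.warn(f"singular covariance; ridge jitter {jitter:g}", stacklevel=2)
    raise np.linalg.LinAlgError("covariance not positive definite even with ridge")


def variance_explained(loadings, phi, sample_cov):
    """Per-factor fraction of total variance, pattern x structure accounting.

    VE_k = sum_t lambda_tk s_tk / trace(S) with structure S = Lambda Phi;
    the factor-wise sum equals trace(Lambda Phi Lambda') / trace(S_sample),
    so a full-rank principal-component solution totals exactly 1.
    """
    L = np.asarray(loadings, dtype=float)
    struct = L @ np.asarray(phi, dtype=float)
    return (L * struct).sum(axis=0) / float(np.trace(sample_cov))


def select_factors(ve: np.ndarray, threshold: float = 0.03) -> np.ndarray:
    """Mask of factors explaining strictly more than ``threshold`` of variance."""
    mask = np.asarray(ve) > threshold
    if not mask.any():
        warnings.warn("no factor exceeds the variance-explained threshold", stacklevel=2)
    return mask


# ---------------------------------------------------------------------------
# the fitted solution


@dataclass
class FactorSolution:
    loadings_unrotated: np.ndarray
    loadings: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    scores: np.ndarray
    scores_raw: np.ndarray
    ve: np.ndarray
    criterion_value: float
    rotation_config: dict
    start_log: list
    sign_flips: np.ndarray
    retained_mask: np.ndarray
    sample_cov: np.ndarray
    meta: pd.DataFrame
    times: np.ndarray
    accent: str
    method: str
    ekc: EkcResult | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def peak_info(self):
        """(peak index, signed peak loading, peak latency ms) per factor."""
        idx = np.abs(self.loadings).argmax(axis=0)
        lam = self.loadings[idx, np.arange(self.n_factors)]
        lat = np.asarray(self.times)[idx]
        return idx, lam, lat


def align_signs(solution: FactorSolution) -> FactorSolution:
    """Orient each factor so its largest-|value| loading is positive.

    Scores flip in tandem and Phi is conjugated by the sign matrix, so the
    model-implied covariance is untouched.  Idempotent.
    """
    idx, lam, _ = solution.peak_info()
    s = np.where(lam < 0, -1.0, 1.0)
    solution.loadings = solution.loadings * s
    solution.scores = solution.scores * s
    solution.scores_raw = solution.scores_raw * s
    solution.phi = solution.phi * np.outer(s, s)
    solution.sign_flips = solution.sign_flips * s
    return solution


def fit_temporal_efa(
    obs: ObservationMatrix,
    m: int | None = None,
    method: str = "uls",
    eps: float = 0.01,
    n_starts: int = 30,
    seed: int | None = 0,
    ve_threshold: float = 0.03,
    oblique: bool = True,
) -> FactorSolution:
    """Run the full decomposition on one accent's observation matrix.

    When ``m`` is None the Empirical Kaiser Criterion picks the number of
    factors.  Returns a sign-aligned :class:`FactorSolution`.
    """
    ekc = None
    if m is None:
        ekc = compute_ekc(obs)
        m = ekc.n_retained
        if m < 1:
            raise DatasetError("EKC retained no factors; specify m explicitly")
    S = _sample_cov(obs.X)
    L0, psi = extract_factors(S, m, method=method)
    rot: RotationResult = geomin_rotate(
        L0, eps=eps, n_starts=n_starts, seed=seed, oblique=oblique
    )
    scores, raw = compute_scores(obs.X, rot.loadings, rot.phi, psi)
    ve = variance_explained(rot.loadings, rot.phi, S)
    sol = FactorSolution(
        loadings_unrotated=L0,
        loadings=rot.loadings,
        phi=rot.phi,
        psi=psi,
        scores=scores,
        scores_raw=raw,
        ve=ve,
        criterion_value=rot.criterion,
        rotation_config=rot.config,
        start_log=rot.start_log,
        sign_flips=np.ones(m),
        retained_mask=select_factors(ve, ve_threshold),
        sample_cov=S,
        meta=obs.meta,
        times=np.asarray(obs.times),
        accent=obs.accent,
        method=method,
        ekc=ekc,
    )
    return align_signs(sol)


# ---------------------------------------------------------------------------
# component summaries


def peak_amplitude(
    solution: FactorSolution,
    cluster: ClusterSpec,
    factors=None,
) -> pd.DataFrame:
    """Peak amplitudes (score x signed peak loading) per participant x cell.

    Per factor the peak loading is the signed loading of maximal absolute
    value; each observation's amplitude is its score times that loading;
    amplitudes are averaged over the cluster's electrode rows within
    participant x condition.  Negative-going factors therefore yield
    negative amplitudes.
    """
    meta = solution.meta
    missing = [e for e in cluster.electrodes if e not in set(meta["electrode"])]
    if missing:
        raise DatasetError(f"cluster electrodes absent from solution rows: {missing}")
    if factors is None:
        factors = np.flatnonzero(solution.retained_mask)
    _, lam, lat = solution.peak_info()
    sel = meta["electrode"].isin(cluster.electrodes).to_numpy()
    out = []
    for k in factors:
        amp = solution.scores[:, k] * lam[k]
        tab = meta.loc[sel, ["participant", "constraint", "face"]].copy()
        tab["amplitude"] = amp[sel]
        cellmeans = (
            tab.groupby(["participant", "constraint", "face"], sort=True, observed=True)[
                "amplitude"
            ]
            .mean()
            .reset_index()
        )
        cellmeans.insert(0, "factor", int(k))
        cellmeans["peak_latency_ms"] = lat[k]
        cellmeans["peak_loading"] = lam[k]
        cellmeans["cluster"] = cluster.name
        out.append(cellmeans)
    return pd.concat(out, ignore_index=True)


def reconstruct_component(solution: FactorSolution, k: int):
    """Per-condition, per-electrode waveform and peak-amplitude topography.

    The factor's contribution to row r is scores_raw[r, k] * loadings[:, k];
    waveforms average that over participants within (condition cell,
    electrode).  Summed over all factors of a full-rank principal-component
    solution (with the column means added back) this reproduces the
    grand-average waveforms exactly.

    Returns (waveforms, topography): waveforms is a dict mapping
    (constraint, face, electrode) -> time course; topography a DataFrame of
    electrode-wise mean peak amplitude per cell.
    """
    meta = solution.meta
    lamvec = solution.loadings[:, k]
    idx, lam, _ = solution.peak_info()
    contrib = np.outer(solution.scores_raw[:, k], lamvec)
    peak_amp = solution.scores[:, k] * lam[k]
    tab = meta.copy()
    tab["_row"] = np.arange(len(meta))
    waveforms = {}
    topo_rows = []
    for (con, fac, elec), grp in tab.groupby(
        ["constraint", "face", "electrode"], sort=True, observed=True
    ):
        rows = grp["_row"].to_numpy()
        waveforms[(con, fac, elec)] = contrib[rows].mean(axis=0)
        topo_rows.append(
            dict(
                constraint=con,
                face=fac,
                electrode=elec,
                peak_amplitude=peak_amp[rows].mean(),
            )
        )
    return waveforms, pd.DataFrame(topo_rows)


def suggest_cluster(solution: FactorSolution, k: int, montage) -> str:
    """Suggest anterior vs. posterior cluster from the topography centroid.

    The |peak-amplitude|-weighted centroid of electrode positions is
    compared with the montage midline (y = 0, nose up): anterior centroids
    suggest the fronto-central cluster, posterior ones the centro-parietal
    cluster.  This is only a suggestion for the run manifest; cluster
    assignment stays an explicit configuration choice.
    """
    _, topo = reconstruct_component(solution, k)
    per_elec = topo.groupby("electrode", observed=True)["peak_amplitude"].mean()
    pos = montage.positions[montage.index(per_elec.index)]
    w = np.abs(per_elec.to_numpy())
    if w.sum() == 0:
        return "centro_parietal"
    cy = float((pos[:, 1] * w).sum() / w.sum())
    return "fronto_central" if cy > 0 else "centro_parietal"
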