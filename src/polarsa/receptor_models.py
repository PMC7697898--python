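"""Desk-scale receptor models: effective-variance CMB and uncertainty-weighted PMF.

Both solve the mass balance X_ij = sum_k g_ik f_kj + e_ij for n samples of m
species and p sources: X_ij is the measured species concentration, g_ik the
source contribution (ug/m3) and f_kj the species mass fraction in the
source profile.

Chemical mass balance (CMB) takes the profiles F as measured and solves for
G per sample by effective-variance least squares: species are weighted by
1 / V_eff,j with V_eff,j = sigma_j^2 + sum_k g_k^2 sigma_fkj^2, iterated
because the weights depend on the current contribution estimates.

Positive matrix factorization (PMF) estimates F and G jointly under
non-negativity by minimizing the uncertainty-weighted objective

    Q = sum_ij [(X_ij - sum_k g_ik f_kj) / sigma_ij]^2

via alternating non-negative least squares with multiple seeded restarts.
Rotational tools (Fpeak, bootstrap, displacement) are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

#: sigma assigned to missing X entries in PMF so they carry ~zero weight
MISSING_SIGMA = 1.0e6


@dataclass
class SpeciatedSamples:
    """Speciated PM samples: concentrations X and uncertainties sigma
    (both samples x species, congruent; sigma strictly positive)."""

    X: pd.DataFrame
    sigma: pd.DataFrame
    periods: list | None = None

    def validate(self) -> None:
        if self.X.shape != self.sigma.shape:
            raise ValueError("X and sigma must be congruent")
        if (self.sigma.to_numpy() <= 0).any():
            raise ValueError("sigma must be strictly positive")


@dataclass
class ProfileMatrix:
    """Source profiles F (sources x species mass fractions), with optional
    per-entry uncertainties for the effective-variance weighting."""

    F: pd.DataFrame
    sigma_f: pd.DataFrame | None = None

    def validate(self, tol: float = 1e-6) -> None:
        arr = self.F.to_numpy(float)
        if (arr < 0).any():
            raise ValueError("profile entries must be >= 0")
        if (arr.sum(axis=1) > 1 + tol).any():
            bad = self.F.index[arr.sum(axis=1) > 1 + tol].tolist()
            raise ValueError(f"profile row sums exceed 1: {bad}")

    @property
    def sources(self) -> list[str]:
        return list(self.F.index)


@dataclass
class ContributionMatrix:
    """Fit result: contributions G (samples x sources) with standard errors,
    residuals e = X - G.F, and fit metrics."""

    G: pd.DataFrame
    se: pd.DataFrame | None
    residuals: pd.DataFrame
    q: float
    dof: int
    converged: bool = True
    n_negative: int = 0
    q_history: list[float] = field(default_factory=list)


def _check_rank(F: np.ndarray, sources: list[str]) -> None:
    rank = np.linalg.matrix_rank(F)
    if rank < F.shape[0]:
        raise ValueError(
            f"profiles are rank deficient (rank {rank} < {F.shape[0]} sources); "
            f"collinear sources among: {sources}"
        )


def cmb_fit(
    samples: SpeciatedSamples,
    profiles: ProfileMatrix,
    max_iter: int = 100,
    rtol: float = 1e-6,
) -> ContributionMatrix:
    """Effective-variance least-squares solution of the mass balance for G.

    Per sample, iterate weighted least squares with weights
    1 / (sigma_j^2 + sum_k g_k^2 sigma_fkj^2) until the contributions move
    by less than ``rtol`` (relative) or ``max_iter`` passes. With zero
    profile uncertainty this is a single weighted least-squares solve.
    Contributions are unconstrained in sign (classic CMB); negative values
    are counted and warned about, not clipped. Standard errors come from
    the weighted normal-equations covariance (F W F^T)^-1.
    """
    samples.validate()
    profiles.validate()
    if samples.X.isna().to_numpy().any():
        raise ValueError("CMB does not support missing X entries")
    F = profiles.F.to_numpy(float)  # p x m
    p, m = F.shape
    if m < p:
        raise ValueError(f"need at least as many species ({m}) as sources ({p})")
    _check_rank(F, profiles.sources)
    sf2 = (
        profiles.sigma_f.to_numpy(float) ** 2
        if profiles.sigma_f is not None
        else np.zeros_like(F)
    )
    has_profile_unc = sf2.any()

    X = samples.X.to_numpy(float)
    S2 = samples.sigma.to_numpy(float) ** 2
    n = X.shape[0]
    G = np.zeros((n, p))
    SE = np.zeros((n, p))
    converged = True

    for i in range(n):
        x, s2 = X[i], S2[i]
        g = np.zeros(p)
        v_eff = s2.copy()
        for _ in range(max_iter):
            w = 1.0 / v_eff
            A = (F * w) @ F.T  # p x p
            b = (F * w) @ x
            cov = np.linalg.inv(A)
            g_new = cov @ b
            if not has_profile_unc:
                g = g_new
                break
            denom = np.maximum(np.abs(g_new), 1e-12)
            if np.max(np.abs(g_new - g) / denom) < rtol:
                g = g_new
                break
            g = g_new
            v_eff = s2 + (g**2) @ sf2
        else:
            converged = False
        G[i] = g
        SE[i] = np.sqrt(np.diag(cov))

    resid = X - G @ F
    q = float(((resid**2) / S2).sum())
    dof = n * m - n * p
    n_neg = int((G < 0).sum())
    if n_neg:
        warnings.warn(
            f"CMB produced {n_neg} negative contribution estimates "
            "(weak or collinear signal)",
            stacklevel=2,
        )
    return ContributionMatrix(
        G=pd.DataFrame(G, index=samples.X.index, columns=profiles.sources),
        se=pd.DataFrame(SE, index=samples.X.index, columns=profiles.sources),
        residuals=pd.DataFrame(resid, index=samples.X.index, columns=samples.X.columns),
        q=q,
        dof=dof,
        converged=converged,
        n_negative=n_neg,
    )


def _nnls_rows(A: np.ndarray, B: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve, for each row i: min_{g>=0} || (g A - B_i) * W_i ||^2.

    A is p x m; B and W are n x m; returns n x p.
    """
    n, _ = B.shape
    p = A.shape[0]
    out = np.empty((n, p))
    for i in range(n):
        Aw = (A * W[i]).T  # m x p
        bw = B[i] * W[i]
        out[i], _ = nnls(Aw, bw)
    return out


def pmf_fit(
    samples: SpeciatedSamples,
    p: int,
    seed: int = 0,
    n_restarts: int = 5,
    max_outer: int = 500,
    rtol: float = 1e-8,
) -> tuple[ContributionMatrix, ProfileMatrix]:
    """Uncertainty-weighted non-negative factorization X ~ G.F minimizing Q.

    Alternates exact non-negative least squares over G (rows) and F
    (columns), which cannot increase Q; an increase beyond round-off
    tolerance indicates an update bug and raises. Restarts from seeded
    random non-negative initials; the best-Q run is kept. After
    convergence each profile row is normalized to sum 1 with the scale
    moved into G (the objective is scale-ambiguous). PMF standard errors
    are out of scope and reported as unavailable (``se=None``).
    """
    samples.validate()
    X = samples.X.to_numpy(float)
    sigma = samples.sigma.to_numpy(float)
    n, m = X.shape
    if not (1 <= p < min(n, m)):
        raise ValueError(f"need 1 <= p < min(n, m) = {min(n, m)}, got p={p}")
    missing = ~np.isfinite(X)
    if missing.any():
        X = np.where(missing, 0.0, X)
        sigma = np.where(missing, MISSING_SIGMA, sigma)
    W = 1.0 / sigma

    def q_of(G, F):
        return float((((X - G @ F) * W) ** 2).sum())

    rng = np.random.default_rng(seed)
    best = None
    scale = max(X.mean(), 1e-12)
    for _ in range(n_restarts):
        G = rng.random((n, p)) * scale
        F = rng.random((p, m))
        F /= F.sum(axis=1, keepdims=True)
        q_hist = [q_of(G, F)]
        for _ in range(max_outer):
            G = _nnls_rows(F, X, W)
            F = _nnls_rows(G.T, X.T, W.T).T
            q = q_of(G, F)
            if q > q_hist[-1] * (1 + 1e-9) + 1e-12:
                raise RuntimeError("Q increased between outer iterations (update bug)")
            q_hist.append(q)
            if q_hist[-2] - q <= rtol * max(q, 1.0):
                break
        if best is None or q_hist[-1] < best[0]:
            best = (q_hist[-1], G, F, q_hist)

    q, G, F, q_hist = best
    # scale convention: profile rows sum to 1, scale absorbed by G
    row_sums = F.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    F = F / row_sums[:, None]
    G = G * row_sums[None, :]

    order = np.argsort(-G.mean(axis=0))  # factors in decreasing mean contribution
    G, F = G[:, order], F[order]

    sources = [f"factor_{k + 1}" for k in range(p)]
    resid = X - G @ F
    dof = n * m - p * (n + m)
    contrib = ContributionMatrix(
        G=pd.DataFrame(G, index=samples.X.index, columns=sources),
        se=None,
        residuals=pd.DataFrame(resid, index=samples.X.index, columns=samples.X.columns),
        q=q,
        dof=dof,
        q_history=q_hist,
    )
    prof = ProfileMatrix(F=pd.DataFrame(F, index=sources, columns=samples.X.columns))
    return contrib, prof


def rm_period_summary(
    contributions: ContributionMatrix,
    grouping: dict[str, list] | None = None,
) -> pd.DataFrame:
    """Per-period source means with standard errors.

    ``grouping`` maps period label -> list of sample labels; by default each
    sample is its own period. The SE of a period mean combines per-sample
    SEs in quadrature divided by the sample count (for PMF fits, which have
    no SEs, the SE columns are NaN). Empty periods are omitted.
    """
    G = contributions.G
    if grouping is None:
        grouping = {str(idx): [idx] for idx in G.index}
    rows = {}
    for period, members in grouping.items():
        members = [s for s in members if s in G.index]
        if not members:
            continue
        sub = G.loc[members]
        row = {}
        for src in G.columns:
            row[(src, "mean")] = sub[src].mean()
            if contributions.se is not None:
                se = contributions.se.loc[members, src]
                row[(src, "se")] = float(np.sqrt((se**2).sum()) / len(members))
            else:
                row[(src, "se")] = np.nan
        rows[period] = row
    out = pd.DataFrame(rows).T
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["source", "stat"])
    return out
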