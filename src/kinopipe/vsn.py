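"""Variance-stabilizing normalization of raw spot intensities.

The transform is the canonical two-parameter affine-arsinh (generalized-log)
calibration, fitted jointly across arrays under a common-mean model:

    arsinh(a_k + b_k * x_pki) = mu_p + eps,   eps ~ Normal(0, sigma^2)

where ``k`` indexes arrays, ``p`` peptides and ``i`` technical replicates.
``mu_p`` and ``sigma^2`` have closed-form maximizers for a fixed transform
and are profiled out; the per-array parameters ``(a_k, log b_k)`` are then
estimated jointly by quasi-Newton ascent of the profile likelihood with its
analytic gradient.  The likelihood includes the Jacobian of the transform
(without it, it is unbounded as ``b_k -> 0``).  An optional
least-trimmed-squares outer loop masks the spots with the largest squared
residuals and refits until the mask stabilizes, so truly differential
peptides (which violate the common-mean assumption) cannot drag the
calibration.

arsinh compresses like ``log`` at high intensity but stays finite and smooth
through zero, which is what stabilizes the variance of additive-noise
dominated low-intensity spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

__all__ = ["VsnFit", "fit_vsn", "apply_vsn"]


@dataclass(frozen=True)
class VsnFit:
    """Fitted per-array calibration ``y = arsinh(a_k + b_k x)``."""

    offsets: dict[str, float]        # array_id -> a_k
    scales: dict[str, float]         # array_id -> b_k (> 0)
    residual_sd: float
    n_iterations: int
    converged: bool

    def frame(self) -> pd.DataFrame:
        ids = sorted(self.offsets)
        return pd.DataFrame(
            {"array_id": ids,
             "a": [self.offsets[i] for i in ids],
             "b": [self.scales[i] for i in ids]}
        )


def _profile_nll(params: np.ndarray, x: np.ndarray, arr_codes: np.ndarray,
                 pep_codes: np.ndarray, n_arr: int, n_pep: int,
                 mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Profiled negative log-likelihood and its gradient.

    ``params`` stacks (a_1..a_K, log b_1..log b_K).  For the given transform
    the optimal peptide means and residual variance are closed-form, so by
    the envelope theorem the gradient only needs the direct dependence of
    the residuals and the Jacobian term on the array parameters.
    """
    a = params[:n_arr][arr_codes]
    log_b = params[n_arr:][arr_codes]
    b = np.exp(log_b)
    u = a + b * x
    y = np.arcsinh(u)

    w = mask.astype(float)
    n_eff = w.sum()
    counts = np.bincount(pep_codes, weights=w, minlength=n_pep)
    sums = np.bincount(pep_codes, weights=y * w, minlength=n_pep)
    mu = np.divide(sums, counts, out=np.zeros(n_pep), where=counts > 0)
    resid = (y - mu[pep_codes]) * w
    sigma2 = float(resid @ resid) / n_eff
    if sigma2 <= 0 or not np.isfinite(sigma2):
        raise ValueError("degenerate residual variance during VSN fit")

    denom = 1.0 + u * u
    # log |dy/dx| = log b - 0.5 log(1 + u^2)
    log_jac = (log_b - 0.5 * np.log1p(u * u)) * w
    nll = 0.5 * n_eff * np.log(sigma2) - float(log_jac.sum())

    # d nll / d y_i = resid_i / sigma2 ; chain through y = arcsinh(u)
    dy = resid / sigma2
    inv_root = 1.0 / np.sqrt(denom)
    grad_a = dy * inv_root + w * u / denom
    grad_lb = dy * inv_root * b * x - w * (1.0 - u * b * x / denom)
    grad = np.concatenate([
        np.bincount(arr_codes, weights=grad_a, minlength=n_arr),
        np.bincount(arr_codes, weights=grad_lb, minlength=n_arr),
    ])
    return nll, grad


def fit_vsn(spots: pd.DataFrame, tolerance: float = 1e-8, max_iter: int = 200,
            trim_fraction: float = 0.1) -> VsnFit:
    """Fit the affine-arsinh calibration across all arrays of a spot table.

    Parameters
    ----------
    spots
        Long-form spot table (``array_id``, ``peptide_id``, ``raw_intensity``
        columns are used).  At least two arrays sharing a peptide catalogue.
    tolerance
        Convergence threshold on the maximum relative parameter change
        between trimming rounds (the quasi-Newton solve inside each round
        runs to much tighter internal tolerances).
    max_iter
        Maximum trimming rounds; non-convergence yields a fit flagged
        ``converged=False``, not an exception.
    trim_fraction
        Fraction of spots (largest squared residuals) excluded from each
        re-estimation step.  0 disables trimming.

    Returns
    -------
    VsnFit
    """
    array_ids = sorted(spots["array_id"].unique())
    if len(array_ids) < 2:
        raise ValueError("VSN requires at least 2 arrays")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")

    x_all = spots["raw_intensity"].to_numpy(float)
    arr_codes = pd.Categorical(spots["array_id"], categories=array_ids).codes
    pep_cat = pd.Categorical(spots["peptide_id"])
    pep_codes = pep_cat.codes
    n_pep = len(pep_cat.categories)

    # scale-free initialization: a = 0, b = 1 / mad(x_k)
    a = np.zeros(len(array_ids))
    b = np.empty(len(array_ids))
    for k in range(len(array_ids)):
        xk = x_all[arr_codes == k]
        if np.ptp(xk) == 0:
            raise ValueError(f"array {array_ids[k]!r} has constant intensity")
        mad = np.median(np.abs(xk - np.median(xk)))
        if mad == 0:
            mad = np.std(xk)
        b[k] = 1.0 / mad

    n_arr = len(array_ids)
    n_trim = int(np.floor(trim_fraction * len(x_all)))
    params = np.concatenate([a, np.log(b)])
    mask = np.ones(len(x_all), dtype=bool)

    converged = False
    total_inner = 0

    def solve(start: np.ndarray) -> tuple[np.ndarray, int]:
        """Quasi-Newton solve plus an explicit search along the common-scale
        ridge (all b_k scaled together), the direction the likelihood
        constrains only through low-intensity curvature and along which
        gradient descent barely moves."""
        nit = 0
        p = start
        for _cycle in range(3):
            res = minimize(
                _profile_nll, x0=p,
                args=(x_all, arr_codes, pep_codes, n_arr, n_pep, mask),
                jac=True, method="L-BFGS-B",
                options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
            )
            nit += res.nit
            p = res.x

            def ridge(s: float) -> float:
                # u -> e^s * u for every array: a scales, log b shifts
                q = p.copy()
                q[:n_arr] *= np.exp(s)
                q[n_arr:] += s
                return _profile_nll(q, x_all, arr_codes, pep_codes, n_arr,
                                    n_pep, mask)[0]

            line = minimize_scalar(ridge, bounds=(-1.0, 1.0), method="bounded",
                                   options={"xatol": 1e-10})
            if line.fun < res.fun - 1e-9:
                p = p.copy()
                p[:n_arr] *= np.exp(line.x)
                p[n_arr:] += line.x
            else:
                break
        return p, nit

    for _round in range(1, max_iter + 1):
        new_params, nit = solve(params)
        total_inner += nit

        # re-select the trimmed spots under the refitted transform
        new_mask = np.ones(len(x_all), dtype=bool)
        if n_trim > 0:
            a_s = new_params[:n_arr][arr_codes]
            b_s = np.exp(new_params[n_arr:][arr_codes])
            y = np.arcsinh(a_s + b_s * x_all)
            mu = np.bincount(pep_codes, weights=y, minlength=n_pep) / np.bincount(
                pep_codes, minlength=n_pep
            )
            resid2 = (y - mu[pep_codes]) ** 2
            order = np.argpartition(resid2, len(resid2) - n_trim)
            new_mask[order[len(resid2) - n_trim:]] = False

        # relative change, floored at unit magnitude so near-zero offsets
        # do not stall the criterion
        delta = float(np.max(np.abs(new_params - params)
                             / np.maximum(np.abs(params), 1.0)))
        mask_stable = bool(np.array_equal(new_mask, mask))
        params, mask = new_params, new_mask
        if mask_stable and delta < tolerance:
            converged = True
            break

    a = params[:n_arr]
    b = np.exp(params[n_arr:])
    # residual sd at the final fit
    y = np.arcsinh(a[arr_codes] + b[arr_codes] * x_all)
    mu = np.bincount(pep_codes, weights=y * mask, minlength=n_pep) / np.maximum(
        np.bincount(pep_codes, weights=mask.astype(float), minlength=n_pep), 1
    )
    resid2 = ((y - mu[pep_codes]) ** 2)[mask]
    return VsnFit(
        offsets={array_ids[k]: float(a[k]) for k in range(n_arr)},
        scales={array_ids[k]: float(b[k]) for k in range(n_arr)},
        residual_sd=float(np.sqrt(resid2.mean())),
        n_iterations=total_inner,
        converged=converged,
    )


def apply_vsn(spots: pd.DataFrame, fit: VsnFit) -> pd.DataFrame:
    """Apply a fitted calibration: adds a ``normalized_intensity`` column
    ``y = arsinh(a_k + b_k x)``, exact elementwise and monotone per array."""
    missing = sorted(set(spots["array_id"].unique()) - set(fit.offsets))
    if missing:
        raise ValueError(f"arrays missing from VSN fit: {missing}")
    a = spots["array_id"].map(fit.offsets).to_numpy(float)
    b = spots["array_id"].map(fit.scales).to_numpy(float)
    out = spots.copy()
    out["normalized_intensity"] = np.arcsinh(a + b * spots["raw_intensity"].to_numpy(float))
    return out
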