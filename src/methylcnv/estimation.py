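"""Per-probe log2 copy-number ratios against a diploid control panel.

Copy number acts multiplicatively on probe intensity, so each query sample's
combined (methylated + unmethylated) intensities are modelled as a linear
combination of the control samples' intensities, fitted by unconstrained
least squares without intercept on the linear intensity scale:

    beta = argmin_b sum_p (I_query,p - sum_c b_c * I_control,p,c)^2
    r_p  = log2(I_query,p / sum_c beta_c * I_control,p,c),  median(r) = 0

The fitted combination is a synthetic diploid reference tailored to the query
array; the residual ratio ``r_p`` is the probe's log2 copy-number estimate.
Fitting on the intensity scale makes the result exactly invariant to a
sample-wide rescaling (the scale is absorbed into beta), which is the property
a per-sample normalization must have; the final median-centring removes any
residual global offset.

Dim probes (low median combined intensity across controls) and probes missing
in any sample are masked out before fitting, identically for every sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
import scipy.linalg

from .io import SampleIntensitySet, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "LogRatioMatrix",
    "combined_intensity",
    "log_intensity",
    "filter_probes",
    "fit_reference",
    "probe_log2_ratios",
]

DEFAULT_MIN_COMBINED = 100.0


def combined_intensity(meth, unmeth):
    """Total probe signal: methylated + unmethylated channel intensity."""
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if np.nanmin(meth, initial=0.0) < 0 or np.nanmin(unmeth, initial=0.0) < 0:
        raise ValidationError("negative intensity")
    return meth + unmeth


def log_intensity(intensity):
    """log2(I + 1); the pseudocount keeps zero-intensity probes finite."""
    intensity = np.asarray(intensity, dtype=float)
    if np.nanmin(intensity, initial=0.0) < 0:
        raise ValidationError("negative intensity")
    return np.log2(intensity + 1.0)


@dataclass
class LogRatioMatrix:
    """Per-probe log2 copy-number ratios for each query sample.

    ``values``: probes x query-samples DataFrame over the *full* manifest probe
    index; masked-out probes are NaN for every sample identically.
    ``coefficients``: controls x query-samples fit coefficients.
    ``mask``: boolean Series over probes, True = retained.
    """

    values: pd.DataFrame
    coefficients: pd.DataFrame
    mask: pd.Series


def filter_probes(intensities: SampleIntensitySet,
                  min_combined: float = DEFAULT_MIN_COMBINED) -> pd.Series:
    """Probe retention mask (True = keep).

    Excludes probes whose median combined intensity over the control samples
    falls below ``min_combined`` and probes missing in any sample (missing
    values would otherwise masquerade as copy-number signal).
    """
    if min_combined < 0:
        raise ValidationError("min_combined must be >= 0")
    controls = intensities.control_samples
    if len(controls) < 2:
        raise ValidationError("need >= 2 control samples")
    combined = intensities.meth + intensities.unmeth
    present = combined.notna().all(axis=1)
    ctrl_median = combined[controls].median(axis=1)
    mask = present & (ctrl_median >= min_combined)
    n_excluded = int((~mask).sum())
    if n_excluded:
        log.info("filter_probes: excluded %d/%d probes (min_combined=%g)",
                 n_excluded, len(mask), min_combined)
    if not mask.any():
        raise ValidationError(
            f"probe filter excluded all {len(mask)} probes "
            f"(min_combined={min_combined})")
    return mask


def _independent_controls(controls: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent subset of control columns."""
    n, m = controls.shape
    _, R, piv = scipy.linalg.qr(controls, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = (diag[0] * max(n, m) * np.finfo(float).eps) if diag.size and diag[0] > 0 \
        else 0.0
    rank = int((diag > tol).sum())
    if rank < 2:
        raise ValidationError("fewer than 2 linearly independent control samples")
    if rank < m:
        dropped = sorted(piv[rank:])
        log.warning("dropping %d collinear control column(s): %s",
                    m - rank, dropped)
    return np.sort(piv[:rank])


def fit_reference(query: np.ndarray, controls: np.ndarray,
                  min_probes: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Fit one query sample against the control panel.

    ``query``: combined intensities over retained probes; ``controls``: the
    matching probes x controls intensity matrix.  Returns ``(beta, r)`` where
    ``beta`` has one coefficient per control column (zero for any collinear
    column that was dropped) and ``r`` is the median-centred log2 ratio vector.
    Probes where the query or the fitted reference is non-positive get NaN.
    """
    q = np.asarray(query, dtype=float)
    C = np.asarray(controls, dtype=float)
    if C.ndim != 2 or q.shape != (C.shape[0],):
        raise ValidationError("query/controls shapes incompatible")
    if C.shape[1] < 2:
        raise ValidationError("need >= 2 control samples")
    if C.shape[0] < min_probes:
        raise ValidationError(f"need >= {min_probes} retained probes")
    keep = _independent_controls(C)
    coef, *_ = np.linalg.lstsq(C[:, keep], q, rcond=None)
    beta = np.zeros(C.shape[1])
    beta[keep] = coef
    fitted = C @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(q / fitted)
    r[~np.isfinite(r)] = np.nan
    n_bad = int(np.isnan(r).sum())
    if n_bad:
        log.warning("fit_reference: %d probe(s) with non-positive signal or fit",
                    n_bad)
    r = r - np.nanmedian(r)
    return beta, r


def probe_log2_ratios(intensities: SampleIntensitySet,
                      mask: pd.Series | None = None,
                      min_combined: float = DEFAULT_MIN_COMBINED) -> LogRatioMatrix:
    """Estimate per-probe log2 ratios for every query sample.

    Applies the probe filter (unless ``mask`` is given), then fits each query
    sample's combined intensities against the control panel.  Deterministic;
    the result does not depend on control ordering beyond float round-off.
    """
    queries = intensities.query_samples
    controls = intensities.control_samples
    if len(controls) < 2:
        raise ValidationError("need >= 2 control samples")
    if not queries:
        raise ValidationError("no query samples")
    if mask is None:
        mask = filter_probes(intensities, min_combined)
    mask = mask.reindex(intensities.meth.index, fill_value=False).astype(bool)

    combined = combined_intensity(intensities.meth.to_numpy(),
                                  intensities.unmeth.to_numpy())
    combined = pd.DataFrame(combined, index=intensities.meth.index,
                            columns=intensities.sample_ids)
    kept = mask.to_numpy()
    C = combined.loc[kept, controls].to_numpy()
    keep_cols = _independent_controls(C)

    # one multi-RHS solve; identical per-column results to fit_reference
    Q = combined.loc[kept, queries].to_numpy()
    coef, *_ = np.linalg.lstsq(C[:, keep_cols], Q, rcond=None)
    betas = np.zeros((len(controls), len(queries)))
    betas[keep_cols, :] = coef
    fitted = C @ betas
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(Q / fitted)
    r[~np.isfinite(r)] = np.nan
    r = r - np.nanmedian(r, axis=0, keepdims=True)

    values = pd.DataFrame(np.nan, index=intensities.meth.index, columns=queries)
    values.iloc[kept, :] = r
    coefficients = pd.DataFrame(betas, index=pd.Index(controls, name="control"),
                                columns=queries)
    return LogRatioMatrix(values=values, coefficients=coefficients, mask=mask)
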