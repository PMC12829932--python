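"""Multi-criteria evaluation primitives.

The numeric heart of the suitability analysis:

* **AHP** — criterion weights as the normalized principal eigenvector of a
  reciprocal pairwise-comparison matrix, with Saaty's consistency ratio
  CR = CI/RI, CI = (lambda_max - n)/(n - 1).
* **WLC** — weighted linear combination of standardized scores, weights
  summing to 1; nodata in any input propagates to the output.
* **1–9 rescaling** — affine min-max standardization onto the suitability
  scale (1 least, 9 most suitable), with an ``invert`` flag for cost-like
  criteria such as distances.
* **Jenks natural breaks** — optimal 1-D classification minimizing the
  within-class sum of squared deviations (Fisher's dynamic program), with
  goodness of variance fit GVF = 1 - SDCM/SDAM.

Scores stay continuous on [1, 9] until preference binning; discretization
would only discard information the Jenks classifier can use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .raster import Raster

log = logging.getLogger(__name__)

#: Saaty's random consistency index by matrix order.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45}

#: Weight vectors must sum to 1 within this tolerance (printed weight tables
#: are rounded to two decimals, e.g. 0.33/0.34/0.33).
WEIGHT_SUM_TOL = 0.01

#: Consistency ratio above which an AHP matrix is conventionally rejected.
CR_THRESHOLD = 0.1


# ---------------------------------------------------------------------------
# AHP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseMatrix:
    """Square reciprocal matrix of pairwise importance judgments (1/9..9)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("pairwise matrix must be square")
        if not (a > 0).all():
            raise ValidationError("pairwise matrix entries must be positive")
        if not np.allclose(a * a.T, 1.0, atol=1e-9):
            raise ValidationError("pairwise matrix must be reciprocal (a_ij * a_ji = 1)")

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @classmethod
    def from_weights(cls, weights: np.ndarray) -> "PairwiseMatrix":
        """Perfectly consistent matrix a_ij = w_i / w_j."""
        w = np.asarray(weights, dtype=float)
        if not (w > 0).all():
            raise ValidationError("weights must be positive")
        return cls(np.outer(w, 1.0 / w))


@dataclass(frozen=True)
class AhpResult:
    weights: np.ndarray
    lambda_max: float
    consistency_index: float
    consistency_ratio: float

    @property
    def is_consistent(self) -> bool:
        return self.consistency_ratio <= CR_THRESHOLD


def ahp_weights(
    matrix: PairwiseMatrix, tol: float = 1e-10, max_iter: int = 10_000
) -> AhpResult:
    """Principal-eigenvector weights and consistency ratio of an AHP matrix.

    Power iteration on the positive matrix (Perron–Frobenius guarantees the
    dominant eigenpair is real and positive).  CR > 0.1 is flagged with a
    warning but the result is still returned.
    """
    a = matrix.entries
    n = matrix.n
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        aw = a @ w
        w_new = aw / aw.sum()
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    aw = a @ w
    lam = float((aw / w).mean())
    ci = 0.0 if n <= 2 else (lam - n) / (n - 1)
    ri = RANDOM_INDEX.get(n)
    if ri is None:
        raise ValidationError(f"no random-index value for matrix order {n}")
    cr = 0.0 if n <= 2 or ri == 0 else ci / ri
    result = AhpResult(weights=w, lambda_max=lam, consistency_index=ci, consistency_ratio=cr)
    if not result.is_consistent:
        warnings.warn(
            f"AHP matrix is inconsistent (CR={cr:.3f} > {CR_THRESHOLD}); "
            "judgments should be revised"
        )
    return result


# ---------------------------------------------------------------------------
# Weighted linear combination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightVector:
    """Criterion weights in (0, 1] summing to 1 (within printing tolerance)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or len(w) == 0:
            raise ValidationError("weights must be a non-empty 1-D vector")
        if not ((w > 0) & (w <= 1)).all():
            raise ValidationError("weights must lie in (0, 1]")
        if abs(w.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ValidationError(f"weights must sum to 1 (+-{WEIGHT_SUM_TOL}), got {w.sum():.4f}")

    def __len__(self) -> int:
        return len(self.weights)

    def normalized(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def wlc_aggregate(
    scores: np.ndarray, weights: WeightVector, nodata: float | None = None
) -> float:
    """Weighted sum of criterion scores; nodata in any score propagates."""
    s = np.asarray(scores, dtype=float)
    if s.shape != (len(weights),):
        raise ValidationError(
            f"scores length {s.shape} does not match {len(weights)} weights"
        )
    if nodata is not None and (s == nodata).any():
        return nodata
    return float(s @ weights.normalized())


def wlc_aggregate_columns(
    columns: np.ndarray, weights: WeightVector, nodata: float
) -> np.ndarray:
    """Vectorized WLC over stacked score columns (shape n_criteria x n_units)."""
    cols = np.asarray(columns, dtype=float)
    if cols.shape[0] != len(weights):
        raise ValidationError("column count does not match weight count")
    bad = (cols == nodata).any(axis=0)
    out = weights.normalized() @ cols
    out[bad] = nodata
    return out


# ---------------------------------------------------------------------------
# 1-9 rescaling
# ---------------------------------------------------------------------------

def rescale_linear_1_9(data: Raster | np.ndarray, invert: bool = False):
    """Affine min-max rescale onto the 1–9 suitability scale.

    ``invert=True`` maps the minimum to 9 and the maximum to 1 (cost-like
    criteria).  Nodata is preserved.  Constant input maps to the scale
    midpoint 5 with a logged warning rather than erroring, so degenerate
    layers do not abort a pipeline run.
    """
    if isinstance(data, Raster):
        out = rescale_linear_1_9_array(data.values, data.nodata, invert)
        return data.with_values(out)
    return rescale_linear_1_9_array(np.asarray(data, dtype=float), None, invert)


def rescale_linear_1_9_array(
    values: np.ndarray, nodata: float | None, invert: bool
) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    valid = np.ones(v.shape, dtype=bool) if nodata is None else (v != nodata)
    if not valid.any():
        raise ValidationError("cannot rescale an all-nodata input")
    lo, hi = float(v[valid].min()), float(v[valid].max())
    out = v.astype(float).copy()
    if hi == lo:
        log.warning("rescale_linear_1_9: constant input, mapping to midpoint 5")
        out[valid] = 5.0
        return out
    scaled = 1.0 + 8.0 * (v[valid] - lo) / (hi - lo)
    if invert:
        scaled = 10.0 - scaled
    out[valid] = scaled
    return out


# ---------------------------------------------------------------------------
# Jenks natural breaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JenksResult:
    """Optimal k-class 1-D classification.

    ``breaks`` holds the k-1 interior class maxima in ascending order;
    ``assignments`` the 1-based class of each input value (input order);
    ``gvf`` the goodness of variance fit, 1 - SDCM/SDAM.
    """

    breaks: np.ndarray
    assignments: np.ndarray
    gvf: float
    k: int

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Assign 1..k classes to new values using the fitted breaks."""
        v = np.asarray(values, dtype=float)
        return np.digitize(v, self.breaks, right=True) + 1


#: Break fitting subsamples inputs larger than this (seeded), then classifies
#: everything with the fitted breaks.  The O(k n^2) dynamic program is exact
#: below the cap and the sampled breaks are statistically indistinguishable
#: for the unit counts this pipeline produces.
JENKS_SAMPLE_CAP = 4_000


def _fisher_jenks(sorted_vals: np.ndarray, k: int) -> np.ndarray:
    """Fisher's optimal-partition DP on sorted data.

    Returns the k-1 indices i such that class boundaries fall after
    sorted_vals[i] (class maxima).  Ties break toward the lowest break
    values (smallest indices).
    """
    x = sorted_vals
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(a: np.ndarray, b: int) -> np.ndarray:
        # within-class SSE of x[a..b] inclusive, vectorized over a
        cnt = b - a + 1
        tot = s1[b + 1] - s1[a]
        return (s2[b + 1] - s2[a]) - tot * tot / cnt

    # cost[i] = optimal SSE of x[0..i] for the current class count (1 class here)
    cost = np.array([sse(np.array([0]), i)[0] for i in range(n)])
    back = np.zeros((k, n), dtype=int)
    for j in range(1, k):
        new_cost = np.full(n, np.inf)
        for i in range(j, n):
            m = np.arange(j - 1, i)  # last index of previous class
            cand = cost[m] + sse(m + 1, i)
            best = int(np.argmin(cand))  # first minimum -> lowest breaks
            new_cost[i] = cand[best]
            back[j, i] = m[best]
        cost = new_cost
    # recover break indices
    idx = []
    i = n - 1
    for j in range(k - 1, 0, -1):
        i = back[j, i]
        idx.append(i)
    return np.array(idx[::-1], dtype=int)


def jenks_breaks(
    values: np.ndarray, k: int, rng: np.random.Generator | None = None
) -> JenksResult:
    """Jenks natural-breaks classification into k classes.

    The assignment minimizes the within-class sum of squared deviations over
    all ordered partitions (global optimum of Fisher's dynamic program).
    Requires at least k distinct values; classes are never empty.
    """
    v = np.asarray(values, dtype=float).ravel()
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(np.unique(v)) < k:
        raise ValidationError(
            f"need at least {k} distinct values for {k} classes, got {len(np.unique(v))}"
        )

    fit_vals = v
    if len(v) > JENKS_SAMPLE_CAP:
        rng = rng or np.random.default_rng(0)
        sample = rng.choice(v, size=JENKS_SAMPLE_CAP, replace=False)
        if len(np.unique(sample)) < k:  # pathological sample; fall back
            sample = v
        fit_vals = sample

    x = np.sort(fit_vals)
    if k == 1:
        breaks = np.array([])
    else:
        idx = _fisher_jenks(x, k)
        breaks = x[idx]

    assignments = np.digitize(v, breaks, right=True) + 1
    mean = v.mean()
    sdam = float(((v - mean) ** 2).sum())
    sdcm = 0.0
    for cls in range(1, k + 1):
        members = v[assignments == cls]
        if len(members):
            sdcm += float(((members - members.mean()) ** 2).sum())
    gvf = 0.0 if sdam == 0 else 1.0 - sdcm / sdam
    return JenksResult(breaks=breaks, assignments=assignments, gvf=gvf, k=k)
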