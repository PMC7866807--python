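"""Binary STAPLE: Simultaneous Truth and Performance Level Estimation.

Several raters each delineate the same structure; none of them is the
truth.  STAPLE treats the hidden true segmentation T and each rater j's
sensitivity p_j = P(d_j = 1 | T = 1) and specificity
q_j = P(d_j = 0 | T = 0) as unknowns and estimates them jointly by
expectation-maximization:

E-step, per pixel i with rater decisions d_ij:

    a_i = gamma * prod_j p_j^d_ij (1 - p_j)^(1 - d_ij)
    b_i = (1 - gamma) * prod_j (1 - q_j)^d_ij q_j^(1 - d_ij)
    W_i = a_i / (a_i + b_i)

M-step, per rater:

    p_j = sum_i W_i d_ij / sum_i W_i
    q_j = sum_i (1 - W_i)(1 - d_ij) / sum_i (1 - W_i)

The posterior map W is the probabilistic ground truth; thresholding it
gives the consensus mask.  The same computation, fed with algorithm outputs
instead of human masks, rates automatic segmentation approaches.

Implementation notes: products are computed in log space; pixels are
grouped by their (identical) rater-decision pattern, so each EM sweep costs
O(2^R) pattern evaluations plus one O(N) scatter, and the observed-data
log-likelihood sum_i log(a_i + b_i) is tracked at every iteration (it is
provably non-decreasing, which the test suite asserts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .frames import BinaryMask

_EPS = 1e-6  # clamp for performance estimates


@dataclass
class RaterStack:
    """R binary masks of identical size, one per rater (or per algorithm)."""

    masks: list[BinaryMask]
    rater_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.masks) < 1:
            raise ParameterError("need at least one rater mask")
        shape = self.masks[0].shape
        if any(m.shape != shape for m in self.masks):
            raise ParameterError("all rater masks must share dimensions")
        if not self.rater_ids:
            self.rater_ids = [f"rater{i + 1}" for i in range(len(self.masks))]
        if len(self.rater_ids) != len(self.masks):
            raise ParameterError("rater_ids length must match masks")

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks[0].shape

    def decisions(self) -> np.ndarray:
        """(R, N) uint8 decision matrix, pixels flattened row-major."""
        return np.stack([m.data.ravel() for m in self.masks])


@dataclass
class StapleResult:
    """Posterior foreground-probability map plus per-rater performance."""

    posterior: np.ndarray              # (H, W) in [0, 1]
    sensitivity: np.ndarray            # (R,) p_j
    specificity: np.ndarray            # (R,) q_j
    rater_ids: list[str]
    prior: float                       # global foreground prior gamma
    iterations_run: int
    converged: bool
    log_likelihoods: np.ndarray        # per-iteration observed-data ll


def staple_fuse(
    stack: RaterStack,
    prior: float | None = None,
    init: tuple[float, float] = (0.99999, 0.99999),
    tol: float = 1e-7,
    max_iter: int = 200,
) -> StapleResult:
    """Run binary STAPLE EM on a stack of rater masks.

    ``prior`` is the global foreground prior gamma; by default it is set to
    the mean foreground fraction over the raters.  ``init`` gives the
    initial (p0, q0) for every rater.  Iteration stops when the largest
    absolute change over all (p_j, q_j) drops below ``tol`` or after
    ``max_iter`` sweeps.
    """
    if tol <= 0:
        raise ParameterError("tol must be positive")
    p0, q0 = init
    if not (0 < p0 < 1 and 0 < q0 < 1):
        raise ParameterError("initial (p0, q0) must lie strictly in (0, 1)")
    d = stack.decisions()               # (R, N)
    r, n = d.shape
    frac = d.mean()
    if frac == 0.0 or frac == 1.0:
        raise DegenerateInputError(
            "all rater masks are entirely background or entirely foreground; "
            "the foreground prior is empirically undefined")
    gamma = float(prior) if prior is not None else float(frac)
    if not (0 < gamma < 1):
        raise ParameterError("prior must lie strictly in (0, 1)")

    # Group pixels by identical rater-decision pattern.
    if r <= 62:
        keys = (d.T.astype(np.int64) @ (1 << np.arange(r, dtype=np.int64)))
    else:  # pragma: no cover - more raters than any realistic study
        keys = np.array([hash(col.tobytes()) for col in d.T])
    _, first, inverse, counts = np.unique(
        keys, return_index=True, return_inverse=True, return_counts=True)
    patterns = d[:, first].T.astype(np.float64)   # (U, R)
    counts = counts.astype(np.float64)

    p = np.full(r, p0, dtype=np.float64)
    q = np.full(r, q0, dtype=np.float64)
    lls: list[float] = []
    converged = False
    it = 0
    w_pat = np.full(len(patterns), gamma)
    for it in range(1, max_iter + 1):
        # E-step in log space on unique patterns
        log_a = np.log(gamma) + patterns @ np.log(p) + (1 - patterns) @ np.log1p(-p)
        log_b = np.log1p(-gamma) + patterns @ np.log1p(-q) + (1 - patterns) @ np.log(q)
        log_den = np.logaddexp(log_a, log_b)
        w_pat = np.exp(log_a - log_den)
        lls.append(float(counts @ log_den))

        # M-step
        wsum = counts @ w_pat
        cw = counts * w_pat
        cnotw = counts * (1.0 - w_pat)
        p_new = (patterns.T @ cw) / wsum
        q_new = ((1.0 - patterns).T @ cnotw) / (counts @ (1.0 - w_pat))
        p_new = np.clip(p_new, _EPS, 1.0 - _EPS)
        q_new = np.clip(q_new, _EPS, 1.0 - _EPS)
        delta = max(np.abs(p_new - p).max(), np.abs(q_new - q).max())
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    # final E-step so the posterior reflects the converged parameters
    log_a = np.log(gamma) + patterns @ np.log(p) + (1 - patterns) @ np.log1p(-p)
    log_b = np.log1p(-gamma) + patterns @ np.log1p(-q) + (1 - patterns) @ np.log(q)
    w_pat = np.exp(log_a - np.logaddexp(log_a, log_b))
    posterior = w_pat[inverse].reshape(stack.shape)

    return StapleResult(
        posterior=posterior, sensitivity=p, specificity=q,
        rater_ids=list(stack.rater_ids), prior=gamma,
        iterations_run=it, converged=converged,
        log_likelihoods=np.asarray(lls),
    )


def consensus_mask(result: StapleResult, threshold: float = 0.5) -> BinaryMask:
    """Threshold the posterior map into the consensus (ground-truth) mask."""
    if not (0 < threshold < 1):
        raise ParameterError("threshold must lie strictly in (0, 1)")
    return BinaryMask(data=(result.posterior >= threshold).astype(np.uint8))


def rate_segmentations(
    predictions: RaterStack,
    prior: float | None = None,
    init: tuple[float, float] = (0.99999, 0.99999),
    tol: float = 1e-7,
    max_iter: int = 200,
) -> StapleResult:
    """Rate automatic segmentation approaches against their STAPLE consensus.

    Identical computation to :func:`staple_fuse` — each approach plays the
    role of a rater and receives a sensitivity/specificity estimate.
    """
    return staple_fuse(predictions, prior=prior, init=init, tol=tol,
                       max_iter=max_iter)


def fuse_sides(left: RaterStack, right: RaterStack, **kwargs) -> tuple[
        BinaryMask, StapleResult, StapleResult]:
    """Fuse per-foot rater stacks independently (left and right feet are
    delineated separately) and OR-combine the consensus masks into a
    whole-frame ground truth."""
    res_l = staple_fuse(left, **kwargs)
    res_r = staple_fuse(right, **kwargs)
    combined = consensus_mask(res_l).data | consensus_mask(res_r).data
    return BinaryMask(data=combined), res_l, res_r
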